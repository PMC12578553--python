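"""Synthetic surgical-cohort generator.

Emulates the statistical structure the pattern-discovery analysis assumes:

* a mixture of latent psychological profiles over the 16 PHQ-9/GAD-7 items
  (a "normal functioning" majority plus five distress classes, calibrated to
  the reported mixture 32.6 / 13.2 / 3.2 / 14.0 / 8.1 / 26.6 %),
* a small outlier fraction (default 2.2 %) of idiosyncratic extreme
  responders that no pattern should absorb,
* covariates drawn from the published cohort marginals, and
* outcomes generated from logistic/linear models with planted pattern
  effects, so downstream association models have a known truth.

Items are generated by a thresholded latent-Gaussian (graded-response
style) model: each patient draws a 16-dimensional latent vector around the
class profile with a one-factor-per-block covariance (four symptom blocks,
descending item loadings), which is then rounded and clipped to {0..3}.
The latent class means are solved numerically (bisection) so the realised
ordinal item means match the target profile.

Heterogeneous ("ladder") loadings within each block are deliberate: the
highest-loading item acts as a hub that every other block item is most
correlated with, which keeps the item-level nearest-neighbour graph of the
discovery stage connected within blocks.  Outliers are placed at block-wise
{0,3} corner profiles far from every class profile, in micro-groups small
enough that a density-based clusterer cannot treat them as clusters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import itertools

import numpy as np
import pandas as pd
from scipy.stats import norm

from .scales import (
    ITEM_COLUMNS, PHQ_ITEMS, GAD_ITEMS, OUTCOMES, COVARIATE_COLUMNS,
    EDUCATION_LEVELS, SMOKING_LEVELS, SURGERY_SITES, ANESTHESIA_TYPES,
    SEX_LEVELS, ALCOHOL_LEVELS, validate_items, validate_covariates,
)

NORMAL_PATTERN = "normal psychological functioning"
OUTLIER_LABEL = "outlier"

# ---------------------------------------------------------------------------
# Symptom blocks and item profiles
# ---------------------------------------------------------------------------

#: Partition of the 16 items into four symptom blocks (varying size):
#: somatic/vegetative (sleep, fatigue, appetite), anxious (nervousness,
#: worry, fear), tension (restlessness, irritability), depressive core.
ITEM_BLOCKS = {
    "somatic": ("phq3", "phq4", "phq5"),
    "anxious": ("gad1", "gad2", "gad3", "gad7"),
    "tension": ("gad4", "gad5", "gad6"),
    "depressive": ("phq1", "phq2", "phq6", "phq7", "phq8", "phq9"),
}

#: Descending within-block loadings (hub first).  The hub item of every
#: block is each other member's most-correlated partner.
BLOCK_LOADINGS = {
    "somatic": (0.72, 0.56, 0.50),
    "anxious": (0.72, 0.58, 0.52, 0.46),
    "tension": (0.72, 0.56, 0.50),
    "depressive": (0.72, 0.60, 0.55, 0.50, 0.45, 0.40),
}

CROSS_BLOCK_ATTENUATION = 0.05  # factor-factor correlation between blocks

# Baseline 0.55 keeps the all-zero response vector rare enough (well below
# the patient-stage n_neighbors) that it cannot island in the k-NN graph,
# and gives the low-severity region enough response diversity to embed as
# one connected cloud.
_BASE, _HIGH = 0.55, 2.4

#: Shared per-item "difficulty" offsets (zero-sum within each block): some
#: items are endorsed more readily than others in every class.  Because the
#: offsets are identical across classes they cancel in every between-class
#: difference, but they give each pattern profile item-level shape, so
#: profile correlations replicate across cohorts instead of comparing flat
#: lines.
ITEM_DELTAS = {
    # ascending with the loading ladder: the hub (highest-loading) item gets
    # the negative offset, which keeps its discretised values off the most
    # bimodal regime in low-severity classes
    "somatic": (-0.15, 0.0, 0.15),
    "anxious": (-0.15, -0.05, 0.05, 0.15),
    "tension": (-0.15, 0.0, 0.15),
    "depressive": (-0.15, -0.09, -0.03, 0.03, 0.09, 0.15),
}


def _block_profile(somatic, anxious, tension, depressive):
    values = dict(somatic=somatic, anxious=anxious, tension=tension,
                  depressive=depressive)
    profile = np.empty(16)
    for block, items in ITEM_BLOCKS.items():
        for delta, item in zip(ITEM_DELTAS[block], items):
            profile[ITEM_COLUMNS.index(item)] = values[block] + delta
    return profile


@dataclass(frozen=True)
class PatternSpec:
    """One latent class: name, mixing proportion, 16 target item means.

    ``within_sd`` optionally overrides the generator-wide latent spread for
    this class (low-severity responders are more heterogeneous relative to
    their ordinal lattice than acutely distressed ones).
    """

    name: str
    mixing_proportion: float
    item_means: np.ndarray
    within_sd: float | None = None

    def __post_init__(self):
        means = np.asarray(self.item_means, dtype=float)
        if means.shape != (16,):
            raise ValueError("item_means must be a 16-vector")
        if (means < 0).any() or (means > 3).any():
            raise ValueError("item_means must lie in [0, 3]")
        object.__setattr__(self, "item_means", means)


def default_pattern_specs() -> list:
    """The six study patterns, proportions as published, schematic profiles."""
    return [
        # the low-severity majority is more heterogeneous relative to its
        # ordinal lattice than the distress classes (within_sd 0.7), which
        # keeps its response cloud connected rather than stratified on the
        # discretisation boundaries of individual items
        PatternSpec(NORMAL_PATTERN, 0.326,
                    _block_profile(_BASE, _BASE, _BASE, _BASE),
                    within_sd=0.7),
        PatternSpec("sleep and eating disturbance", 0.132,
                    _block_profile(_HIGH, _BASE, _BASE, _BASE)),
        PatternSpec("sleep disturbance and irritability", 0.032,
                    _block_profile(2.0, _BASE, _HIGH, _BASE)),
        PatternSpec("nervousness", 0.140,
                    _block_profile(_BASE, _HIGH, _BASE, _BASE)),
        PatternSpec("nervousness, sleep disturbance, and excessive worry", 0.081,
                    _block_profile(_HIGH, _HIGH, _BASE, _BASE)),
        # all blocks elevated, graded upward toward the depressive core so
        # the profile shape is distinct from the flat normal profile
        PatternSpec("highly combined symptoms", 0.266,
                    _block_profile(1.8, 1.85, 1.95, 2.0)),
    ]


@dataclass
class GeneratorConfig:
    n: int = 10_000
    seed: int = 0
    pattern_specs: list = field(default_factory=default_pattern_specs)
    outlier_frac: float = 0.022
    within_sd: float = 0.6
    item_blocks: dict = field(default_factory=lambda: dict(ITEM_BLOCKS))
    loadings: dict = field(default_factory=lambda: dict(BLOCK_LOADINGS))
    cross_attenuation: float = CROSS_BLOCK_ATTENUATION
    outlier_micro_size: int = 25
    outlier_sd: float = 0.35
    outlier_min_separation: float = 4.0
    confound_covariates: bool = False  # if True, age/sex shift with class
    baseline_cognitive_rate: float = 0.03
    baseline_memory_rate: float = 0.06
    effect_spec: dict = field(default_factory=lambda: default_effects())

    def __post_init__(self):
        if not 0 <= self.outlier_frac < 1:
            raise ValueError("outlier_frac must be in [0, 1)")
        total = sum(p.mixing_proportion for p in self.pattern_specs) + self.outlier_frac
        if not np.isclose(total, 1.0, atol=0.05):
            raise ValueError(
                f"mixing proportions + outlier_frac must sum to ~1 (got {total:.3f})")
        flat = [i for items in self.item_blocks.values() for i in items]
        if sorted(flat) != sorted(ITEM_COLUMNS):
            raise ValueError("item_blocks must partition the 16 items")

    def child_seeds(self):
        """Per-stage child seeds (items, covariates, outcomes) from the root."""
        ss = np.random.SeedSequence(self.seed)
        return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]


# ---------------------------------------------------------------------------
# Latent-Gaussian machinery
# ---------------------------------------------------------------------------

def _discretized_mean(latent_mean: float, sd: float) -> float:
    """E[clip(round(X), 0, 3)] for X ~ Normal(latent_mean, sd)."""
    if sd == 0:
        return float(np.clip(np.round(latent_mean), 0, 3))
    return sum(norm.sf((k - 0.5 - latent_mean) / sd) for k in (1, 2, 3))


def solve_latent_mean(target: float, sd: float, tol: float = 1e-10) -> float:
    """Bisection for the latent mean whose discretised expectation hits target."""
    if not 0 <= target <= 3:
        raise ValueError("target item mean must lie in [0, 3]")
    if sd == 0:
        return target
    lo, hi = -6.0, 9.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _discretized_mean(mid, sd) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def latent_correlation(config: GeneratorConfig) -> np.ndarray:
    """16x16 latent correlation: one factor per block, ladder loadings."""
    lv = np.empty(16)
    block_of = np.empty(16, dtype=int)
    for b, (block, items) in enumerate(config.item_blocks.items()):
        loadings = config.loadings[block]
        if len(loadings) != len(items):
            raise ValueError(f"loadings/items length mismatch for block {block!r}")
        for load, item in zip(loadings, items):
            idx = ITEM_COLUMNS.index(item)
            lv[idx] = load
            block_of[idx] = b
    corr = np.empty((16, 16))
    for i in range(16):
        for j in range(16):
            if i == j:
                corr[i, j] = 1.0
            elif block_of[i] == block_of[j]:
                corr[i, j] = lv[i] * lv[j]
            else:
                corr[i, j] = lv[i] * lv[j] * config.cross_attenuation
    return corr


def outlier_corner_profiles(config: GeneratorConfig) -> np.ndarray:
    """Block-wise {0,3} corner profiles kept far from every class profile."""
    class_profiles = np.array([p.item_means for p in config.pattern_specs])
    blocks = list(config.item_blocks.values())
    corners = []
    for bits in itertools.product((0.0, 3.0), repeat=len(blocks)):
        v = np.empty(16)
        for level, items in zip(bits, blocks):
            for item in items:
                v[ITEM_COLUMNS.index(item)] = level
        if np.linalg.norm(class_profiles - v, axis=1).min() >= config.outlier_min_separation:
            corners.append(v)
    if not corners:
        raise ValueError("no admissible outlier corner profiles; relax separation")
    return np.array(corners)


def generate_item_responses(config: GeneratorConfig):
    """Draw the item matrix and ground-truth labels.

    Returns ``(items, truth)``: an integer DataFrame over the 16-item schema
    indexed by patient id, and a Series of latent labels (pattern names, or
    "outlier").
    """
    seed_items = config.child_seeds()[0]
    rng = np.random.default_rng(seed_items)
    names = [p.name for p in config.pattern_specs]
    props = np.array([p.mixing_proportion for p in config.pattern_specs], dtype=float)
    props = props * (1.0 - config.outlier_frac) / props.sum()
    labels = rng.choice(len(names) + 1, size=config.n,
                        p=list(props) + [config.outlier_frac])

    chol = (np.linalg.cholesky(latent_correlation(config))
            if config.within_sd > 0 else None)
    latent = np.empty((config.n, 16))
    for k, spec in enumerate(config.pattern_specs):
        sel = labels == k
        sd = spec.within_sd if spec.within_sd is not None else config.within_sd
        mu = np.array([solve_latent_mean(t, sd) for t in spec.item_means])
        if sd > 0:
            noise = rng.standard_normal((int(sel.sum()), 16)) @ chol.T
            latent[sel] = mu + sd * noise
        else:
            latent[sel] = mu

    out_rows = np.where(labels == len(names))[0]
    if out_rows.size:
        corners = outlier_corner_profiles(config)
        n_micro = min(len(corners),
                      max(1, round(out_rows.size / config.outlier_micro_size)))
        chosen = rng.choice(len(corners), n_micro, replace=False)
        micro = rng.integers(0, n_micro, out_rows.size)
        latent[out_rows] = (corners[chosen[micro]]
                            + config.outlier_sd * rng.standard_normal((out_rows.size, 16)))

    items = np.clip(np.round(latent), 0, 3).astype(int)
    ids = [f"P{i:06d}" for i in range(config.n)]
    frame = pd.DataFrame(items, columns=ITEM_COLUMNS, index=pd.Index(ids, name="patient_id"))
    truth = pd.Series([names[k] if k < len(names) else OUTLIER_LABEL for k in labels],
                      index=frame.index, name="truth")
    return validate_items(frame), truth


# ---------------------------------------------------------------------------
# Covariates (published Table-1 marginals)
# ---------------------------------------------------------------------------

DEFAULT_COVARIATE_MARGINALS = {
    "age": {"mean": 52.27, "sd": 7.07, "min": 40, "max": 65},
    "sex": {"female": 0.583},
    "education": {"probs": (0.030, 0.252, 0.219, 0.499)},
    "bmi": {"mean": 23.6, "sd": 3.1, "min": 15, "max": 42},
    "cci": {"poisson_lam": 0.45},
    "smoking": {"probs": (0.735, 0.083, 0.182)},
    "alcohol": {"yes": 0.181},
    "surgery_site": {"probs": (0.461, 0.206, 0.151, 0.182)},
    "surgery_duration": {"meanlog": 4.50, "sdlog": 0.60, "min": 15, "max": 600},
    "anesthesia_type": {"probs": (0.944, 0.045, 0.011)},
}


def generate_covariates(config: GeneratorConfig, truth=None) -> pd.DataFrame:
    """Draw covariates from the configured marginals (independent of class
    unless ``confound_covariates`` is set, in which case distress classes
    are drawn slightly older and more often female)."""
    seed_cov = config.child_seeds()[1]
    rng = np.random.default_rng(seed_cov)
    m = DEFAULT_COVARIATE_MARGINALS
    n = config.n

    def trunc_normal(mean, sd, lo, hi, size):
        x = rng.normal(mean, sd, size)
        bad = (x < lo) | (x > hi)
        while bad.any():
            x[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = (x < lo) | (x > hi)
        return x

    age = trunc_normal(m["age"]["mean"], m["age"]["sd"], m["age"]["min"], m["age"]["max"], n)
    p_female = np.full(n, m["sex"]["female"])
    if config.confound_covariates and truth is not None:
        distress = (truth.to_numpy() != NORMAL_PATTERN) & (truth.to_numpy() != OUTLIER_LABEL)
        age = age + 1.5 * distress
        p_female = np.where(distress, p_female + 0.05, p_female)
        age = np.clip(age, m["age"]["min"], m["age"]["max"])
    sex = np.where(rng.random(n) < p_female, "female", "male")

    edu_probs = np.array(m["education"]["probs"]); edu_probs = edu_probs / edu_probs.sum()
    smoking_probs = np.array(m["smoking"]["probs"]); smoking_probs = smoking_probs / smoking_probs.sum()
    site_probs = np.array(m["surgery_site"]["probs"]); site_probs = site_probs / site_probs.sum()
    an_probs = np.array(m["anesthesia_type"]["probs"]); an_probs = an_probs / an_probs.sum()

    cov = pd.DataFrame({
        "age": np.round(age, 1),
        "sex": sex,
        "education": rng.choice(EDUCATION_LEVELS, n, p=edu_probs),
        "bmi": np.round(trunc_normal(m["bmi"]["mean"], m["bmi"]["sd"],
                                     m["bmi"]["min"], m["bmi"]["max"], n), 1),
        "cci": rng.poisson(m["cci"]["poisson_lam"], n),
        "smoking": rng.choice(SMOKING_LEVELS, n, p=smoking_probs),
        "alcohol": np.where(rng.random(n) < m["alcohol"]["yes"], "yes", "no"),
        "surgery_site": rng.choice(SURGERY_SITES, n, p=site_probs),
        "surgery_duration": np.round(np.clip(
            rng.lognormal(m["surgery_duration"]["meanlog"], m["surgery_duration"]["sdlog"], n),
            m["surgery_duration"]["min"], m["surgery_duration"]["max"]), 0),
        "anesthesia_type": rng.choice(ANESTHESIA_TYPES, n, p=an_probs),
    }, index=pd.Index([f"P{i:06d}" for i in range(n)], name="patient_id"))
    return validate_covariates(cov)


# ---------------------------------------------------------------------------
# Outcomes with planted effects
# ---------------------------------------------------------------------------

#: Marginal targets used to calibrate model intercepts: binary prevalences
#: follow the published cohort (any complication 10.9 %, pulmonary 8.9 %,
#: infection 5.8 %); remaining values are field-plausible defaults.
BINARY_PREVALENCE = {
    "complication_any": 0.109,
    "complication_pulmonary": 0.089,
    "complication_infection": 0.058,
    "cognitive_dysfunction": 0.05,
    "memory_deterioration": 0.08,
    "sleep_disturbance": 0.25,
}

CONTINUOUS_BASELINE = {  # (mean, residual sd) on the native scale
    "length_of_stay": (4.1, 3.0),
    "pain_rest": {"day1": (3.0, 2.0), "day3": (2.0, 1.8)},
    "pain_movement": {"day1": (4.0, 2.0), "day3": (2.8, 1.8)},
    "nausea_vomiting": {"day1": (1.5, 1.6), "day3": (0.8, 1.2)},
    "recovery": {"month1": (7.5, 1.8), "month6": (8.2, 1.5), "month12": (8.5, 1.4)},
    "life_satisfaction": {"month1": (3.0, 0.8), "month6": (3.1, 0.8), "month12": (3.1, 0.8)},
}

#: Small covariate contributions (log-odds for binary, native units for
#: continuous) shared across outcomes, adding realistic signal.
COVARIATE_EFFECTS_BINARY = {"age": 0.015, "cci": 0.15, "duration": 0.0015, "female": -0.05}
COVARIATE_EFFECTS_CONTINUOUS = {"age": 0.005, "cci": 0.1, "duration": 0.002, "female": 0.05}


def default_effects() -> dict:
    """Planted per-pattern effects: log-ORs for binary outcomes, native-scale
    shifts for continuous ones.  Magnitudes echo the reported ranges
    (complication ORs ~1.2-1.3, sleep-disturbance ORs ~2-3, pain shifts a
    few tenths of an NRS point)."""
    distress = [p.name for p in default_pattern_specs() if p.name != NORMAL_PATTERN]
    eff = {}
    for name in distress:
        heavy = name == "highly combined symptoms"
        eff[name] = {
            "complication_any": np.log(1.30 if heavy else 1.27),
            "complication_pulmonary": np.log(1.25 if heavy else 1.22),
            "complication_infection": np.log(1.25 if heavy else 1.20),
            "length_of_stay": 0.40 if heavy else 0.30,
            "pain_rest": 0.35 if heavy else 0.25,
            "pain_movement": 0.40 if heavy else 0.30,
            "nausea_vomiting": 0.25 if heavy else 0.15,
            "cognitive_dysfunction": np.log(2.0 if heavy else 1.6),
            "memory_deterioration": np.log(1.3 if heavy else 1.2),
            "sleep_disturbance": np.log(3.0 if heavy else 2.2),
            "recovery": -0.40 if heavy else -0.28,
            "life_satisfaction": -0.25 if heavy else -0.15,
        }
    return eff


def _outcome_grid():
    for name, defn in OUTCOMES.items():
        timepoints = defn.timepoints or (None,)
        for tp in timepoints:
            yield name, tp, defn


def outcome_column(name: str, timepoint) -> str:
    return name if timepoint is None else f"{name}_{timepoint}"


def generate_outcomes(truth: pd.Series, covariates: pd.DataFrame,
                      effect_spec: dict, seed: int,
                      baseline_cognitive_rate: float = 0.03,
                      baseline_memory_rate: float = 0.06) -> pd.DataFrame:
    """Generate the outcome table given truth labels and covariates.

    Binary outcomes: Bernoulli(logistic(alpha + pattern effect + covariate
    terms)), with alpha calibrated so the realised marginal prevalence
    matches the configured target.  Continuous outcomes: Normal(linear
    predictor, sigma) clipped to the native range.  Outliers receive the
    reference (zero) pattern effect.  Baseline cognitive/memory flags are
    drawn independently to support exclusion-rule testing.
    """
    for pattern, spec in effect_spec.items():
        for out_name in spec:
            if out_name not in OUTCOMES:
                raise KeyError(f"unknown outcome in effect_spec: {out_name!r}")
    rng = np.random.default_rng(seed)
    n = len(truth)
    labels = truth.to_numpy()

    age_c = covariates["age"].to_numpy() - 52.27
    cci = covariates["cci"].to_numpy().astype(float)
    dur_c = covariates["surgery_duration"].to_numpy() - 110.0
    female = (covariates["sex"] == "female").to_numpy().astype(float)

    def pattern_effect(out_name):
        eff = np.zeros(n)
        for k, pattern in enumerate(labels):
            spec = effect_spec.get(pattern)
            if spec:
                eff[k] = spec.get(out_name, 0.0)
        return eff

    data = {}
    for name, tp, defn in _outcome_grid():
        col = outcome_column(name, tp)
        eff = pattern_effect(name)
        if defn.kind == "binary":
            ce = COVARIATE_EFFECTS_BINARY
            lp = (eff + ce["age"] * age_c + ce["cci"] * cci
                  + ce["duration"] * dur_c + ce["female"] * female)
            target = BINARY_PREVALENCE[name]
            alpha = np.log(target / (1 - target)) - lp.mean()
            p = 1.0 / (1.0 + np.exp(-(alpha + lp)))
            data[col] = (rng.random(n) < p).astype(int)
        else:
            base = CONTINUOUS_BASELINE[name]
            mean, sdres = base[tp] if isinstance(base, dict) else base
            ce = COVARIATE_EFFECTS_CONTINUOUS
            sign = -1.0 if defn.adverse_low else 1.0
            lp = (mean + eff + sign * (ce["age"] * age_c + ce["cci"] * cci
                                       + ce["duration"] * dur_c + ce["female"] * female))
            raw = rng.normal(lp, sdres)
            lo, hi = defn.native_range
            data[col] = np.round(np.clip(raw, lo, hi), 1)

    data["baseline_cognitive_dysfunction"] = (rng.random(n) < baseline_cognitive_rate).astype(int)
    data["baseline_memory_deterioration"] = (rng.random(n) < baseline_memory_rate).astype(int)
    return pd.DataFrame(data, index=truth.index)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    items: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.Series
    config: GeneratorConfig

    def __post_init__(self):
        if not (self.items.index.equals(self.covariates.index)
                and self.items.index.equals(self.outcomes.index)
                and self.items.index.equals(self.truth.index)):
            raise ValueError("cohort tables are not row-aligned")

    def write(self, directory):
        from pathlib import Path
        d = Path(directory); d.mkdir(parents=True, exist_ok=True)
        self.items.to_csv(d / "items.csv", index_label="patient_id")
        self.covariates.to_csv(d / "covariates.csv", index_label="patient_id")
        self.outcomes.to_csv(d / "outcomes.csv", index_label="patient_id")
        self.truth.to_frame().to_csv(d / "truth.csv", index_label="patient_id")

    @classmethod
    def read(cls, directory, config=None):
        from pathlib import Path
        d = Path(directory)
        items = pd.read_csv(d / "items.csv", index_col="patient_id")
        cov = pd.read_csv(d / "covariates.csv", index_col="patient_id")
        out = pd.read_csv(d / "outcomes.csv", index_col="patient_id")
        truth = pd.read_csv(d / "truth.csv", index_col="patient_id")["truth"]
        return cls(validate_items(items), validate_covariates(cov), out, truth,
                   config or GeneratorConfig(n=len(items)))


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Full draw: items + truth, covariates, outcomes, all from one seed."""
    items, truth = generate_item_responses(config)
    covariates = generate_covariates(config, truth)
    outcomes = generate_outcomes(
        truth, covariates, config.effect_spec, config.child_seeds()[2],
        config.baseline_cognitive_rate, config.baseline_memory_rate)
    return SyntheticCohort(items, covariates, outcomes, truth, config)
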