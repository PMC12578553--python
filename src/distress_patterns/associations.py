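"""Covariate-adjusted association models: patterns / cut-off status versus
surgery-related outcomes.

Binary outcomes are fit with maximum-likelihood logistic regression and
reported as odds ratios with Wald 95% confidence intervals; continuous
outcomes are standardised to a 0-10 scale and fit with ordinary least
squares, reported as betas.  The reference group is the normal-functioning
pattern (or symptom-negative status for the cut-off exposure).  All models
adjust for age, sex, education, BMI, Charlson index, smoking, alcohol,
surgery site and surgery duration; anesthesia-related discomfort outcomes
additionally adjust for anesthesia type.  Patients already positive for
cognitive dysfunction or memory deterioration at baseline are excluded from
the corresponding models only.  Noise-labelled patients are excluded from
every association model.

No multiplicity correction is applied and significance is two-sided at
alpha = 0.05 — a faithful-reproduction choice, not a recommendation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .scales import (
    OUTCOMES, PHQ9, GAD7, score_scale, classify_cutoff, standardize_0_10,
)
from .cohort import NORMAL_PATTERN, outcome_column
from .discovery import NOISE, PatternAssignment

DEFAULT_ADJUSTMENT = (
    "age", "sex", "education", "bmi", "cci", "smoking", "alcohol",
    "surgery_site", "surgery_duration",
)

_CATEGORICAL = {"sex", "education", "smoking", "alcohol", "surgery_site",
                "anesthesia_type"}


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    timepoint: str | None = None
    exposure: str = "patterns"            # "patterns" | "cutoff"
    reference: str = NORMAL_PATTERN
    adjustment: tuple = DEFAULT_ADJUSTMENT
    extra_adjustment: tuple = ()
    subgroup: str | None = None           # surgery-site stratum

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise KeyError(f"unknown outcome {self.outcome!r}")
        if self.exposure not in ("patterns", "cutoff"):
            raise ValueError("exposure must be 'patterns' or 'cutoff'")


@dataclass
class AssociationEstimate:
    exposure_type: str
    exposure_level: str
    outcome: str
    timepoint: str | None
    effect_type: str          # "OR" | "beta"
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    n_excluded: int
    n_noise: int
    subgroup: str | None = None
    note: str = ""

    def __post_init__(self):
        if np.isfinite(self.estimate):
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError("CI does not bracket the point estimate")
            if self.effect_type == "OR" and self.estimate <= 0:
                raise ValueError("odds ratio must be positive")


def cutoff_status(items: pd.DataFrame) -> pd.Series:
    """Conventional screening status per patient (PHQ-9>=10 or GAD-7>=10)."""
    phq = score_scale(items, PHQ9)
    gad = score_scale(items, GAD7)
    return classify_cutoff(phq, gad).rename("cutoff_positive").set_axis(items.index)


def pattern_series(assignment: PatternAssignment, names: dict) -> pd.Series:
    """Per-patient pattern name; noise patients get NaN (excluded later)."""
    lab = assignment.labels
    mapped = lab.map(lambda v: names.get(int(v)) if v != NOISE else np.nan)
    return mapped.rename("pattern_name")


def apply_exclusions(cohort_outcomes: pd.DataFrame, spec: ModelSpec):
    """Drop baseline-positive patients for the two cognitive outcome
    families only; returns (keep mask, n_excluded)."""
    defn = OUTCOMES[spec.outcome]
    keep = pd.Series(True, index=cohort_outcomes.index)
    if defn.baseline_exclusion:
        flag = f"baseline_{spec.outcome}"
        if flag not in cohort_outcomes.columns:
            raise ValueError(f"missing baseline flag column {flag!r} "
                             f"required for {spec.outcome}")
        keep = cohort_outcomes[flag] == 0
    return keep, int((~keep).sum())


def _formula(spec: ModelSpec, exposure_term: str) -> str:
    terms = [exposure_term]
    for cov in tuple(spec.adjustment) + tuple(spec.extra_adjustment):
        terms.append(f"C({cov})" if cov in _CATEGORICAL else cov)
    return "__y ~ " + " + ".join(terms)


def _exposure_frame(spec, exposure: pd.Series):
    if spec.exposure == "patterns":
        term = f"C(pattern_name, Treatment({NORMAL_PATTERN!r}))"
        frame = exposure.rename("pattern_name").to_frame()
    else:
        term = "C(cutoff_positive, Treatment(False))"
        frame = exposure.rename("cutoff_positive").to_frame()
    return term, frame


def _levels_from_param(param_name: str) -> str:
    # patsy encodes e.g. C(pattern_name, Treatment('...'))[T.nervousness]
    return param_name.split("[T.", 1)[1].rstrip("]")


def _fit(spec: ModelSpec, data: pd.DataFrame, exposure_term: str,
         binary: bool):
    formula = _formula(spec, exposure_term)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore")
        if binary:
            model = smf.glm(formula, data=data, family=sm.families.Binomial())
            fit = model.fit(maxiter=200)
            converged = bool(fit.converged)
        else:
            fit = smf.ols(formula, data=data).fit()
            converged = True
    return fit, converged


def _estimates_from_fit(fit, converged, spec, n_used, n_excluded, n_noise,
                        binary) -> list:
    out = []
    ci = fit.conf_int()
    note = "" if converged else "non-convergence or separation; interpret with caution"
    huge_se = fit.bse > 50  # flag quasi-separated levels
    for name in fit.params.index:
        if "[T." not in name or not name.startswith("C(pattern_name") \
                and not name.startswith("C(cutoff_positive"):
            continue
        level = _levels_from_param(name)
        est, lo, hi = fit.params[name], ci.loc[name, 0], ci.loc[name, 1]
        level_note = note
        if huge_se[name]:
            level_note = (level_note + "; " if level_note else "") + "separation suspected"
        if binary:
            with np.errstate(over="ignore"):
                est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        out.append(AssociationEstimate(
            exposure_type=spec.exposure, exposure_level=level,
            outcome=spec.outcome, timepoint=spec.timepoint,
            effect_type="OR" if binary else "beta",
            estimate=float(est), ci_low=float(lo), ci_high=float(hi),
            p=float(fit.pvalues[name]), n_used=n_used,
            n_excluded=n_excluded, n_noise=n_noise,
            subgroup=spec.subgroup, note=level_note))
    return out


def _prepare(cohort_cov, cohort_out, exposure, spec):
    col = outcome_column(spec.outcome, spec.timepoint)
    if col not in cohort_out.columns:
        raise KeyError(f"outcome column {col!r} not present")
    keep, _ = apply_exclusions(cohort_out, spec)
    term, exp_frame = _exposure_frame(spec, exposure)
    data = pd.concat([cohort_cov, exp_frame, cohort_out[[col]]], axis=1)
    is_noise = exp_frame.iloc[:, 0].isna()
    n_noise = int(is_noise.sum())
    n_excluded = int((~keep & ~is_noise).sum())  # so n_used + n_excluded + n_noise = n
    data = data.loc[keep].dropna(subset=[exp_frame.columns[0]])
    if spec.subgroup is not None:
        data = data[data["surgery_site"] == spec.subgroup]
    defn = OUTCOMES[spec.outcome]
    if defn.kind == "binary":
        data["__y"] = data[col].astype(float)
    else:
        data["__y"] = standardize_0_10(data[col].to_numpy(), defn.native_range)
    return data, term, n_excluded, n_noise


def fit_binary(cohort_cov: pd.DataFrame, cohort_out: pd.DataFrame,
               exposure: pd.Series, spec: ModelSpec) -> list:
    """Logistic model for one binary outcome; one estimate per non-reference
    exposure level.  A constant outcome raises; separation and
    non-convergence yield flagged estimates, never silent NaN."""
    if OUTCOMES[spec.outcome].kind != "binary":
        raise ValueError(f"{spec.outcome} is not binary")
    data, term, n_excluded, n_noise = _prepare(cohort_cov, cohort_out, exposure, spec)
    y = data["__y"]
    if y.nunique() < 2:
        raise ValueError(f"outcome {spec.outcome!r} is constant; no model fit")
    if spec.exposure == "patterns" and data["pattern_name"].nunique() < 2:
        raise ValueError("exposure has a single level after filtering")
    fit, converged = _fit(spec, data, term, binary=True)
    return _estimates_from_fit(fit, converged, spec, len(data), n_excluded,
                               n_noise, binary=True)


def fit_linear(cohort_cov: pd.DataFrame, cohort_out: pd.DataFrame,
               exposure: pd.Series, spec: ModelSpec) -> list:
    """OLS for one continuous outcome (standardised to 0-10 beforehand)."""
    if OUTCOMES[spec.outcome].kind != "continuous":
        raise ValueError(f"{spec.outcome} is not continuous")
    data, term, n_excluded, n_noise = _prepare(cohort_cov, cohort_out, exposure, spec)
    fit, _ = _fit(spec, data, term, binary=False)
    # rank deficiency: statsmodels silently drops nothing; detect via NaN bse
    if fit.bse.isna().any():
        bad = fit.bse.index[fit.bse.isna()].tolist()
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    return _estimates_from_fit(fit, True, spec, len(data), n_excluded,
                               n_noise, binary=False)


def estimates_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates])


def default_model_specs() -> list:
    """The full outcome x timepoint grid for both exposures."""
    specs = []
    for name, defn in OUTCOMES.items():
        timepoints = defn.timepoints or (None,)
        for tp in timepoints:
            for exposure in ("patterns", "cutoff"):
                specs.append(ModelSpec(
                    outcome=name, timepoint=tp, exposure=exposure,
                    extra_adjustment=defn.extra_adjustment))
    return specs


def run_association_suite(cohort_cov, cohort_out, assignment: PatternAssignment,
                          pattern_names: dict, items: pd.DataFrame,
                          specs: list | None = None) -> pd.DataFrame:
    """Fit the whole grid of exposures x outcomes x timepoints.

    Per-model failures are recorded as rows with NaN estimates and a note;
    the suite always completes.
    """
    specs = specs if specs is not None else default_model_specs()
    patterns = pattern_series(assignment, pattern_names)
    cut = cutoff_status(items).astype(object)
    cut[patterns.isna()] = np.nan  # noise patients leave the analytic set entirely
    rows = []
    for spec in specs:
        exposure = patterns if spec.exposure == "patterns" else cut
        fn = fit_binary if OUTCOMES[spec.outcome].kind == "binary" else fit_linear
        try:
            rows.extend(fn(cohort_cov, cohort_out, exposure, spec))
        except Exception as exc:
            rows.append(AssociationEstimate(
                exposure_type=spec.exposure, exposure_level="(all)",
                outcome=spec.outcome, timepoint=spec.timepoint,
                effect_type="OR" if OUTCOMES[spec.outcome].kind == "binary" else "beta",
                estimate=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                n_used=0, n_excluded=0,
                n_noise=int((assignment.labels == NOISE).sum()),
                subgroup=spec.subgroup, note=f"failed: {exc}"))
    return estimates_frame(rows)


def subgroup_analyses(cohort_cov, cohort_out, assignment, pattern_names, items,
                      specs: list | None = None, min_stratum: int = 50) -> pd.DataFrame:
    """Re-fit the association suite within each surgery-site stratum.

    Strata smaller than ``min_stratum`` are skipped with a warning row-free
    log message.  Site is removed from the adjustment set within strata.
    """
    base = specs if specs is not None else default_model_specs()
    frames = []
    for site in sorted(cohort_cov["surgery_site"].unique()):
        n_site = int((cohort_cov["surgery_site"] == site).sum())
        if n_site < min_stratum:
            warnings.warn(f"stratum {site!r} too small (n={n_site}); skipped")
            continue
        adj = tuple(c for c in DEFAULT_ADJUSTMENT if c != "surgery_site")
        site_specs = [ModelSpec(outcome=s.outcome, timepoint=s.timepoint,
                                exposure=s.exposure, reference=s.reference,
                                adjustment=adj,
                                extra_adjustment=s.extra_adjustment,
                                subgroup=site) for s in base]
        frames.append(run_association_suite(
            cohort_cov, cohort_out, assignment, pattern_names, items, site_specs))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
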