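"""Psychometric scales, outcome definitions and deterministic scoring rules.

The two instruments are the 9-item Patient Health Questionnaire (PHQ-9,
depression) and the 7-item Generalized Anxiety Disorder scale (GAD-7,
anxiety).  Every item is an ordinal score in {0, 1, 2, 3} ("not at all" to
"nearly every day"); scale totals are plain item sums.  Conventional
symptom screening dichotomises patients at a total of 10 on either scale.

Surgery-related outcomes are either binary (threshold rules on screening
instruments, or adjudicated complication flags consumed as-is) or
continuous (numeric rating scales, length of stay); continuous outcomes are
standardised to a common 0-10 range before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Scale definitions
# ---------------------------------------------------------------------------

PHQ_ITEMS = [f"phq{i}" for i in range(1, 10)]
GAD_ITEMS = [f"gad{i}" for i in range(1, 8)]
ITEM_COLUMNS = PHQ_ITEMS + GAD_ITEMS  # fixed 16-column schema
ITEM_MIN, ITEM_MAX = 0, 3


@dataclass(frozen=True)
class ScaleDefinition:
    """One questionnaire: name, its items and the screening cut-off."""

    name: str
    items: tuple
    cutoff: int = 10

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        return ITEM_MAX * self.n_items


PHQ9 = ScaleDefinition("PHQ9", tuple(PHQ_ITEMS))
GAD7 = ScaleDefinition("GAD7", tuple(GAD_ITEMS))
SCALES = {"PHQ9": PHQ9, "GAD7": GAD7}


def validate_items(responses, items=ITEM_COLUMNS) -> pd.DataFrame:
    """Check a response table against the 16-item schema.

    Missing items or out-of-range values raise ``ValueError`` naming the
    offending column; incomplete assessments are rejected, not imputed.
    """
    if isinstance(responses, pd.Series):
        responses = responses.to_frame().T
    responses = pd.DataFrame(responses)
    missing = [c for c in items if c not in responses.columns]
    if missing:
        raise ValueError(f"missing item columns: {missing}")
    sub = responses[list(items)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing (NaN) item responses in: {bad}")
    arr = sub.to_numpy()
    if not np.array_equal(arr, np.round(arr)):
        bad = sub.columns[(sub != sub.round()).any()].tolist()
        raise ValueError(f"non-integer item responses in: {bad}")
    out = (arr < ITEM_MIN) | (arr > ITEM_MAX)
    if out.any():
        bad = sub.columns[out.any(axis=0)].tolist()
        raise ValueError(f"item responses outside 0-3 in: {bad}")
    return sub.astype(int)


def score_scale(responses, scale: ScaleDefinition):
    """Total score for one scale: the sum of its items.

    Accepts a single row (Series/dict) or a table; returns an int or an
    integer Series accordingly.
    """
    single = isinstance(responses, (pd.Series, dict))
    frame = pd.DataFrame([responses]) if single else pd.DataFrame(responses)
    sub = validate_items(frame, scale.items)
    totals = sub.sum(axis=1)
    return int(totals.iloc[0]) if single else totals


def classify_cutoff(phq_total, gad_total) -> bool:
    """Conventional screening: positive iff PHQ-9 >= 10 or GAD-7 >= 10."""
    phq = np.asarray(phq_total)
    gad = np.asarray(gad_total)
    if ((phq < 0) | (phq > PHQ9.max_total)).any():
        raise ValueError("PHQ-9 total outside [0, 27]")
    if ((gad < 0) | (gad > GAD7.max_total)).any():
        raise ValueError("GAD-7 total outside [0, 21]")
    result = (phq >= PHQ9.cutoff) | (gad >= GAD7.cutoff)
    return bool(result) if result.ndim == 0 else pd.Series(result)


# ---------------------------------------------------------------------------
# Outcome definitions
# ---------------------------------------------------------------------------

SHORT_TERM_DAYS = ("day1", "day3")
FOLLOWUP_MONTHS = ("month1", "month6", "month12")


@dataclass(frozen=True)
class OutcomeDefinition:
    """One adverse-outcome variable.

    ``kind`` is "binary" or "continuous".  Binary outcomes defined through a
    screening instrument carry the underlying score's range and a threshold
    rule; continuous outcomes carry their native range, used for 0-10
    standardisation before linear modelling.  ``adverse_low`` marks
    variables where *lower* values are the adverse direction (recovery,
    life satisfaction).
    """

    name: str
    kind: str
    native_range: tuple = (0, 10)
    timepoints: tuple = ()
    threshold: float | None = None
    threshold_side: str = "above"  # adverse side: "above" (strict >) or "below" (strict <)
    adverse_low: bool = False
    extra_adjustment: tuple = ()
    baseline_exclusion: bool = False


OUTCOMES = {
    # -- short term --------------------------------------------------------
    "length_of_stay": OutcomeDefinition(
        "length_of_stay", "continuous", native_range=(0, 60)),
    "complication_any": OutcomeDefinition(
        "complication_any", "binary"),
    "complication_pulmonary": OutcomeDefinition(
        "complication_pulmonary", "binary"),
    "complication_infection": OutcomeDefinition(
        "complication_infection", "binary"),
    "pain_rest": OutcomeDefinition(
        "pain_rest", "continuous", native_range=(0, 10),
        timepoints=SHORT_TERM_DAYS, extra_adjustment=("anesthesia_type",)),
    "pain_movement": OutcomeDefinition(
        "pain_movement", "continuous", native_range=(0, 10),
        timepoints=SHORT_TERM_DAYS, extra_adjustment=("anesthesia_type",)),
    "nausea_vomiting": OutcomeDefinition(
        "nausea_vomiting", "continuous", native_range=(0, 10),
        timepoints=SHORT_TERM_DAYS, extra_adjustment=("anesthesia_type",)),
    # -- intermediate / long term -----------------------------------------
    "cognitive_dysfunction": OutcomeDefinition(
        "cognitive_dysfunction", "binary", native_range=(0, 8),
        timepoints=FOLLOWUP_MONTHS, threshold=2, threshold_side="below",
        baseline_exclusion=True),
    "memory_deterioration": OutcomeDefinition(
        "memory_deterioration", "binary", native_range=(0, 3),
        timepoints=FOLLOWUP_MONTHS, threshold=3, threshold_side="below",
        baseline_exclusion=True),
    "sleep_disturbance": OutcomeDefinition(
        "sleep_disturbance", "binary", native_range=(0, 21),
        timepoints=FOLLOWUP_MONTHS, threshold=5, threshold_side="above"),
    "recovery": OutcomeDefinition(
        "recovery", "continuous", native_range=(0, 10),
        timepoints=FOLLOWUP_MONTHS, adverse_low=True),
    "life_satisfaction": OutcomeDefinition(
        "life_satisfaction", "continuous", native_range=(0, 4),
        timepoints=FOLLOWUP_MONTHS, adverse_low=True),
}

#: The AD8 rule is implemented exactly as the cohort protocol prints it
#: (total < 2 = dysfunction), which inverts the instrument's usual
#: direction (>= 2 impaired).  Flip this flag to use the conventional rule.
AD8_LOW_IS_IMPAIRED_DEFAULT = True


def classify_outcome(raw, name: str, *, ad8_low_is_impaired: bool = AD8_LOW_IS_IMPAIRED_DEFAULT):
    """Apply a binary outcome's threshold rule to raw instrument scores.

    Examples: PSQI 6 -> sleep disturbance True (rule is strict ">5");
    three-word recall 3 of 3 -> memory deterioration False.
    """
    if name not in OUTCOMES:
        raise KeyError(f"unknown outcome: {name!r}")
    defn = OUTCOMES[name]
    if defn.threshold is None:
        raise ValueError(f"outcome {name!r} carries no threshold rule")
    arr = np.asarray(raw, dtype=float)
    lo, hi = defn.native_range
    if ((arr < lo) | (arr > hi)).any():
        raise ValueError(f"{name}: raw score outside native range {defn.native_range}")
    side = defn.threshold_side
    if name == "cognitive_dysfunction" and not ad8_low_is_impaired:
        side = "above"
        arr_adverse = arr >= defn.threshold
    elif side == "below":
        arr_adverse = arr < defn.threshold
    else:
        arr_adverse = arr > defn.threshold
    return bool(arr_adverse) if arr_adverse.ndim == 0 else pd.Series(arr_adverse)


def standardize_0_10(values, native_range):
    """Affine map of a continuous score onto [0, 10]; order preserving."""
    lo, hi = native_range
    if not hi > lo:
        raise ValueError(f"degenerate native range {native_range}")
    arr = np.asarray(values, dtype=float)
    if ((arr < lo) | (arr > hi)).any():
        raise ValueError(f"values outside native range {native_range}")
    return 10.0 * (arr - lo) / (hi - lo)


def unstandardize_0_10(values, native_range):
    lo, hi = native_range
    if not hi > lo:
        raise ValueError(f"degenerate native range {native_range}")
    return lo + np.asarray(values, dtype=float) * (hi - lo) / 10.0


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

EDUCATION_LEVELS = ("elementary_or_lower", "junior_school", "senior_secondary", "college_or_above")
SMOKING_LEVELS = ("never", "previous", "current")
SURGERY_SITES = ("abdomen", "head_neck", "thorax", "others")
ANESTHESIA_TYPES = ("combined_iv_inhalation", "total_iv", "inhalation")
SEX_LEVELS = ("female", "male")
ALCOHOL_LEVELS = ("no", "yes")

COVARIATE_COLUMNS = (
    "age", "sex", "education", "bmi", "cci", "smoking", "alcohol",
    "surgery_site", "surgery_duration", "anesthesia_type",
)

_CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS,
    "education": EDUCATION_LEVELS,
    "smoking": SMOKING_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "surgery_site": SURGERY_SITES,
    "anesthesia_type": ANESTHESIA_TYPES,
}


def validate_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Schema check for the covariate table (closed categorical levels)."""
    table = pd.DataFrame(table)
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    for col, levels in _CATEGORICAL_LEVELS.items():
        bad = set(table[col].dropna().unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown levels in {col!r}: {sorted(bad)}")
    if (table["age"] < 18).any() or (table["age"] > 100).any():
        raise ValueError("implausible age values")
    if (table["cci"] < 0).any():
        raise ValueError("negative Charlson comorbidity index")
    return table


# ---------------------------------------------------------------------------
# CSV input/output (fixed, documented column schema)
# ---------------------------------------------------------------------------

def read_items_csv(path) -> pd.DataFrame:
    """Read an item-score table (patient_id + 16 item columns)."""
    df = pd.read_csv(path)
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    return validate_items(df)


def write_items_csv(items: pd.DataFrame, path) -> None:
    items.to_csv(path, index_label="patient_id")


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    return validate_covariates(df)


def write_covariates_csv(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, index_label="patient_id")
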