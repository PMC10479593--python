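"""Synthetic cohorts drawn from the network's own generative model.

The naive-Bayes graph read generatively is: draw the outcome Y from its
prior, then draw each covariate state from the CPT column selected by Y.
Cohorts produced this way carry exactly the dependence structure the scorer
assumes, so they give the model every other module needs for testing —
parameter-recovery, self-calibration, discrimination — without any external
data.  Registry-style incompleteness is layered on top as per-variable MCAR
blanking, with presets mimicking a heavily incomplete clinical registry
("euclid-like") versus an almost complete protocol study ("gckd-like").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .inference import EvidenceVector
from .knowledge import NetworkModel, VariableSpec, discretize

OUTCOME_COLUMN = "cv_hosp_1y"

# Qualitative missingness presets.  "euclid-like": biomarker panels ordered at
# physician discretion go largely unrecorded (lipids, inflammation, mineral
# metabolism 40-70%), research-only assays entirely so, while demographics and
# coded comorbidities are complete.  "gckd-like": per-protocol collection,
# <=5% missing except assays outside the protocol.
_HEAVY = {
    "hdl_cholesterol": 0.65, "ldl_cholesterol": 0.65, "triglyceride": 0.45,
    "crp": 0.45, "glucose": 0.20, "pth": 0.60, "albuminuria": 0.60,
    "hstnt": 1.0, "il6": 1.0, "smoking": 0.40, "alcohol": 0.35,
    "albumin": 0.15, "phosphate": 0.10, "uric_acid": 0.10, "bmi": 0.05,
}
_LIGHT = {
    "hstnt": 0.25, "il6": 1.0, "pth": 0.05, "glucose": 0.05,
    "hdl_cholesterol": 0.02, "ldl_cholesterol": 0.02, "triglyceride": 0.02,
    "crp": 0.02, "albuminuria": 0.02, "smoking": 0.05, "alcohol": 0.05,
    "albumin": 0.02, "phosphate": 0.02, "uric_acid": 0.02, "bmi": 0.02,
}
PRESETS = {"euclid-like": _HEAVY, "gckd-like": _LIGHT, "none": {}}


@dataclass(frozen=True)
class CohortConfig:
    n: int
    seed: int
    missingness: dict[str, float] = field(default_factory=dict)
    mechanism: str = "MCAR"
    preset: str = "none"

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("cohort size must be >= 1")
        if self.mechanism != "MCAR":
            raise ValidationError(f"only MCAR is supported, got {self.mechanism!r}")
        if self.preset not in PRESETS:
            raise ValidationError(f"unknown preset {self.preset!r}; options: {sorted(PRESETS)}")
        for var, rate in self.missingness.items():
            if not (0.0 <= rate <= 1.0):
                raise ValidationError(f"missingness rate for {var!r} outside [0,1]: {rate}")

    def rates_for(self, variables: list[str]) -> dict[str, float]:
        rates = {v: 0.0 for v in variables}
        for v, r in PRESETS[self.preset].items():
            if v in rates:
                rates[v] = r
        rates.update({v: r for v, r in self.missingness.items() if v in rates})
        return rates


@dataclass(frozen=True)
class PatientTable:
    """Simulated cohort: one row per patient, state-labelled covariates."""

    data: pd.DataFrame

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")

    def __len__(self) -> int:
        return len(self.data)


def simulate_cohort(model: NetworkModel, config: CohortConfig) -> PatientTable:
    """Draw a cohort of ``config.n`` patients from the generative model."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    y = (rng.random(n) < model.prior).astype(int)
    columns: dict[str, object] = {"row_id": [f"P{i:06d}" for i in range(n)]}
    for spec in model.variables:
        cpt = model.cpts[spec.name]
        states = np.array(cpt.states, dtype=object)
        p1 = np.array(cpt.p_given_event)
        p0 = np.array(cpt.p_given_noevent)
        u = rng.random(n)
        idx1 = np.searchsorted(np.cumsum(p1), u[y == 1], side="right").clip(max=len(states) - 1)
        idx0 = np.searchsorted(np.cumsum(p0), u[y == 0], side="right").clip(max=len(states) - 1)
        col = np.empty(n, dtype=object)
        col[y == 1] = states[idx1]
        col[y == 0] = states[idx0]
        columns[spec.name] = col
    columns[OUTCOME_COLUMN] = y
    return PatientTable(data=pd.DataFrame(columns))


def apply_missingness(table: PatientTable, config: CohortConfig) -> PatientTable:
    """Blank each covariate cell independently at its variable's MCAR rate.

    The outcome column and row ids are never blanked.  The blanking stream
    is seeded separately from the sampling stream so the same cohort can be
    re-used under several missingness patterns.
    """
    rng = np.random.default_rng([config.seed, 0x4D43])  # distinct MCAR stream
    df = table.data.copy()
    variables = [c for c in df.columns if c not in ("row_id", OUTCOME_COLUMN)]
    rates = config.rates_for(variables)
    for var in variables:
        rate = rates.get(var, 0.0)
        if rate <= 0.0:
            continue
        mask = rng.random(len(df)) < rate
        col = df[var].astype(object)
        col[mask] = ""
        df[var] = col
    return PatientTable(data=df)


# ---------------------------------------------------------------------------
# worked clinical case
# ---------------------------------------------------------------------------

def case_study_measurements() -> dict[str, object]:
    """Raw chart data for the worked case: a 45-year-old obese man with
    stage G4 CKD of diabetic origin, hypertension and COPD.

    Calcium has no corresponding node in the 31-variable model and is kept
    here for completeness only; hemoglobin 12.53 g/dl is coded through the
    anemia node (WHO threshold, <13 g/dl for men).
    """
    return {
        "age": 45.0,
        "sex": "male",
        "bmi": 41.0,
        "egfr": 25.0,
        "etiology": "diabetes",
        "smoking": "ex-smoker",
        "hypertension": True,
        "copd": True,
        "albumin_g_dl": 4.00,
        "calcium_mg_dl": 8.9,
        "hemoglobin_g_dl": 12.53,
        "phosphate_mg_dl": 4.19,
        "pth_ng_l": 289.0,
        "urine_protein_g_24h": 2.49,
    }


def case_study_fixture(variables: list[VariableSpec] | None = None) -> EvidenceVector:
    """The worked case as model evidence; everything not charted is missing.

    Continuous measurements are discretized with the default variable
    definitions, so the fixture stays consistent with whatever cut-points
    the shipped configuration uses.
    """
    if variables is None:
        from .defaults import load_default_variables

        variables = load_default_variables()
    by_name = {v.name: v for v in variables}
    raw = case_study_measurements()

    def disc(name: str, value: float, channel: str | None = None) -> str:
        state = discretize(value, by_name[name], channel=channel)
        assert state is not None
        return state

    assignments = {
        "age": disc("age", raw["age"]),
        "gender": "male",
        "bmi": disc("bmi", raw["bmi"]),
        "egfr": disc("egfr", raw["egfr"]),
        "diabetes": "yes",
        "smoking": "ex-smoker",
        "hypertension": "yes",
        "copd": "yes",
        "albumin": disc("albumin", raw["albumin_g_dl"]),
        "anemia": "yes" if raw["hemoglobin_g_dl"] < 13.0 else "no",
        "phosphate": disc("phosphate", raw["phosphate_mg_dl"]),
        "pth": disc("pth", raw["pth_ng_l"]),
        "albuminuria": disc("albuminuria", raw["urine_protein_g_24h"], channel="urine_protein_g_24h"),
    }
    return EvidenceVector(assignments=assignments, source_record_id="case-study")


# ---------------------------------------------------------------------------
# raw inputs for equation-based comparators
# ---------------------------------------------------------------------------

_RAW_HEAVY = {
    "total_cholesterol": 0.60, "hdl": 0.65, "sbp": 0.20, "smoker": 0.40,
    "bp_treated": 0.25, "creatinine": 0.05, "prior_mi": 0.0, "prior_stroke": 0.0,
}
_RAW_LIGHT = {k: 0.03 for k in _RAW_HEAVY}
RAW_PRESETS = {"euclid-like": _RAW_HEAVY, "gckd-like": _RAW_LIGHT, "none": {}}


def simulate_raw_inputs(n: int, seed: int, preset: str = "none") -> pd.DataFrame:
    """Plausible raw inputs for the equation-based comparator scores.

    Marginals approximate an elderly CKD clinic population (age ~70,
    SBP ~138 mmHg, 40% diabetes); values are independent draws — sufficient
    for computability and ranking exercises, not a joint-distribution
    emulation of any real cohort.
    """
    if preset not in RAW_PRESETS:
        raise ValidationError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(70, 11, n), 30, 95).round(1),
            "sex": np.where(rng.random(n) < 0.52, "male", "female"),
            "total_cholesterol": np.clip(rng.normal(190, 40, n), 90, 400).round(1),
            "hdl": np.clip(rng.normal(50, 15, n), 15, 120).round(1),
            "sbp": np.clip(rng.normal(138, 18, n), 85, 220).round(1),
            "smoker": (rng.random(n) < 0.12).astype(int),
            "diabetes": (rng.random(n) < 0.40).astype(int),
            "bp_treated": (rng.random(n) < 0.70).astype(int),
            "creatinine": np.clip(rng.normal(2.0, 0.7, n), 0.5, 8.0).round(2),
            "prior_mi": (rng.random(n) < 0.10).astype(int),
            "prior_stroke": (rng.random(n) < 0.08).astype(int),
        }
    )
    rates = RAW_PRESETS[preset]
    mrng = np.random.default_rng([seed, 0x4D43])
    for col, rate in rates.items():
        if rate <= 0.0 or col not in df.columns:
            continue
        mask = mrng.random(n) < rate
        if df[col].dtype.kind in "iu":
            df[col] = df[col].astype(float)
        df.loc[mask, col] = math.nan
    return df
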