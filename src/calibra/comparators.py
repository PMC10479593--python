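"""Equation-based comparator risk scores as data, not code.

Cox-form calculators (Framingham general-CVD, the pooled-cohort ASCVD
equations, an INDANA-style calculator) are represented as JSON
specifications: a list of terms, each a coefficient times a product of
transformed inputs, an optional centering constant, and a per-stratum
baseline survival.  Risk = 1 - S0 ^ exp(LP).  Unlike the naive-Bayes score,
these need every required input: a patient missing any of them is flagged
not-computable, reproducing the complete-case behaviour of equation scores
on registry data.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputOutputError, ValidationError

logger = logging.getLogger(__name__)

_TRANSFORMS = ("identity", "log")


@dataclass(frozen=True)
class ScoreTerm:
    """coefficient * (prod_j t_j(x_j) - center); optional gating condition."""

    inputs: tuple[str, ...]
    transforms: tuple[str, ...]
    coefficient: float
    center: float = 0.0
    condition: tuple[str, float] | None = None  # (input, required value)

    def __post_init__(self):
        if len(self.inputs) != len(self.transforms):
            raise ValidationError("term inputs/transforms length mismatch")
        bad = [t for t in self.transforms if t not in _TRANSFORMS]
        if bad:
            raise ValidationError(f"unknown transforms {bad}")


@dataclass(frozen=True)
class Stratum:
    baseline_survival: float
    terms: tuple[ScoreTerm, ...]
    center: float = 0.0  # stratum-level constant (e.g. published mean sum)

    def __post_init__(self):
        if not (0.0 < self.baseline_survival < 1.0):
            raise ValidationError("baseline survival must lie in (0,1)")


@dataclass(frozen=True)
class EquationScoreSpec:
    name: str
    required_inputs: tuple[str, ...]
    strata: dict[str, Stratum]
    horizon_years: float
    strata_by: str | None = None  # input selecting the stratum, e.g. "sex"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        req = set(self.required_inputs)
        if self.strata_by is not None and self.strata_by not in req:
            raise ValidationError(f"{self.name}: strata_by {self.strata_by!r} not in required_inputs")
        for sname, s in self.strata.items():
            for t in s.terms:
                missing = [i for i in t.inputs if i not in req]
                if missing:
                    raise ValidationError(f"{self.name}/{sname}: term inputs {missing} not in required_inputs")


@dataclass(frozen=True)
class ScoreResult:
    risk: float | None
    missing_inputs: tuple[str, ...]
    linear_predictor: float | None = None

    @property
    def computable(self) -> bool:
        return self.risk is not None


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def compute_equation_score(spec: EquationScoreSpec, record: dict | pd.Series) -> ScoreResult:
    """Evaluate one Cox-form score on one patient record."""
    rec = dict(record)
    missing = tuple(i for i in spec.required_inputs if _is_missing(rec.get(i)))
    if missing:
        return ScoreResult(risk=None, missing_inputs=missing)
    if spec.strata_by is not None:
        key = str(rec[spec.strata_by])
        if key not in spec.strata:
            raise ValidationError(f"{spec.name}: no stratum {key!r}")
        stratum = spec.strata[key]
    else:
        stratum = next(iter(spec.strata.values()))
    lp = -stratum.center
    for term in stratum.terms:
        if term.condition is not None:
            cond_input, cond_value = term.condition
            if float(rec[cond_input]) != cond_value:
                continue
        prod = 1.0
        for inp, tf in zip(term.inputs, term.transforms):
            x = float(rec[inp])
            if tf == "log":
                if x <= 0.0:
                    logger.warning("%s: log of non-positive input %s=%g; not computable", spec.name, inp, x)
                    return ScoreResult(risk=None, missing_inputs=(inp,))
                x = math.log(x)
            prod *= x
        lp += term.coefficient * (prod - term.center)
    if not math.isfinite(lp):
        logger.warning("%s: non-finite linear predictor; not computable", spec.name)
        return ScoreResult(risk=None, missing_inputs=())
    risk = 1.0 - stratum.baseline_survival ** math.exp(lp)
    return ScoreResult(risk=float(risk), missing_inputs=(), linear_predictor=lp)


@dataclass(frozen=True)
class ComputabilityReport:
    score_name: str
    n_rows: int
    n_computable: int
    fraction_computable: float
    missingness_by_input: dict[str, float]


def computability_report(spec: EquationScoreSpec, cohort: pd.DataFrame) -> ComputabilityReport:
    """Fraction of cohort rows on which the score can be evaluated at all."""
    n = len(cohort)
    miss_by_input = {}
    computable_mask = pd.Series(True, index=cohort.index)
    for inp in spec.required_inputs:
        if inp in cohort.columns:
            m = cohort[inp].map(_is_missing)
        else:
            m = pd.Series(True, index=cohort.index)
        miss_by_input[inp] = float(m.mean()) if n else 0.0
        computable_mask &= ~m
    n_comp = int(computable_mask.sum())
    return ComputabilityReport(
        score_name=spec.name,
        n_rows=n,
        n_computable=n_comp,
        fraction_computable=(n_comp / n if n else 0.0),
        missingness_by_input=miss_by_input,
    )


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

def _term_from_json(d: dict) -> ScoreTerm:
    cond = d.get("condition")
    return ScoreTerm(
        inputs=tuple(d["inputs"]),
        transforms=tuple(d["transforms"]),
        coefficient=float(d["coefficient"]),
        center=float(d.get("center", 0.0)),
        condition=(cond["input"], float(cond["equals"])) if cond else None,
    )


def load_score_spec(path: str | os.PathLike) -> EquationScoreSpec:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except OSError as e:
        raise InputOutputError(f"cannot read score spec {path}: {e}") from e
    except json.JSONDecodeError as e:
        raise ValidationError(f"score spec {path} is not valid JSON: {e}") from e
    try:
        strata = {
            name: Stratum(
                baseline_survival=float(s["baseline_survival"]),
                center=float(s.get("center", 0.0)),
                terms=tuple(_term_from_json(t) for t in s["terms"]),
            )
            for name, s in doc["strata"].items()
        }
        return EquationScoreSpec(
            name=doc["name"],
            required_inputs=tuple(doc["required_inputs"]),
            strata=strata,
            horizon_years=float(doc["horizon_years"]),
            strata_by=doc.get("strata_by"),
            metadata=dict(doc.get("metadata", {})),
        )
    except KeyError as e:
        raise ValidationError(f"score spec missing field {e.args[0]!r}", fields=[str(e.args[0])]) from None
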