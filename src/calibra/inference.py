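"""Posterior risk under arbitrary missingness.

Because every covariate is conditionally independent given the outcome,
unobserved variables marginalize out of the posterior exactly — their
likelihood terms sum to one — so a patient is scored with whatever subset of
the 31 variables happens to be recorded.  Computation is done on the
log-odds scale:

    logit P(Y=1|E) = logit P(Y=1) + sum_i log [P(e_i|Y=1) / P(e_i|Y=0)]

which is numerically stable for any number of extreme likelihood ratios.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import StateSpaceError, ValidationError
from .knowledge import NetworkModel, discretize

logger = logging.getLogger(__name__)

MAX_ENUMERATION_STATES = 1_000_000


@dataclass(frozen=True)
class EvidenceVector:
    """Observed variable states for one patient; absent keys are missing."""

    assignments: dict[str, str] = field(default_factory=dict)
    source_record_id: str | None = None

    def validate_against(self, model: NetworkModel) -> None:
        names = set(model.variable_names)
        for var, state in self.assignments.items():
            if var not in names:
                raise ValidationError(f"evidence names unknown variable {var!r}")
            if state not in model.variable(var).states:
                raise ValidationError(f"{state!r} is not a state of {var!r}")

    def without(self, variable: str) -> "EvidenceVector":
        return EvidenceVector(
            {k: v for k, v in self.assignments.items() if k != variable},
            self.source_record_id,
        )


@dataclass(frozen=True)
class RiskResult:
    posterior: float
    prior_used: float
    log_odds: float
    contributions: dict[str, float]
    n_observed: int
    n_missing: int


def log_likelihood_ratio(model: NetworkModel, variable: str, state: str) -> float:
    """log [P(state|Y=1) / P(state|Y=0)], finite thanks to CPT smoothing."""
    cpt = model.cpts.get(variable)
    if cpt is None:
        raise ValidationError(f"unknown variable {variable!r}")
    i = cpt.state_index(state)
    return math.log(cpt.p_given_event[i]) - math.log(cpt.p_given_noevent[i])


def predict_risk(model: NetworkModel, evidence: EvidenceVector) -> RiskResult:
    """Posterior P(Y=1 | observed evidence) with per-item contributions."""
    if not model.variables:
        raise ValidationError("model has no variables")
    evidence.validate_against(model)
    contributions = {
        var: log_likelihood_ratio(model, var, state)
        for var, state in evidence.assignments.items()
    }
    log_odds = float(logit(model.prior)) + sum(contributions.values())
    return RiskResult(
        posterior=float(expit(log_odds)),
        prior_used=model.prior,
        log_odds=log_odds,
        contributions=contributions,
        n_observed=len(contributions),
        n_missing=len(model.variables) - len(contributions),
    )


def enumerate_joint_posterior(model: NetworkModel, evidence: EvidenceVector) -> float:
    """Brute-force oracle: build the full joint over (Y, all variables),
    condition on the evidence by summing out every unobserved variable, and
    return exact P(Y=1 | E).  Only for small models."""
    evidence.validate_against(model)
    size = 1
    for v in model.variables:
        size *= len(v.states)
        if size > MAX_ENUMERATION_STATES:
            raise StateSpaceError(f"joint state space exceeds {MAX_ENUMERATION_STATES}")
    mass = {0: 0.0, 1: 0.0}
    state_lists = [v.states for v in model.variables]
    for y, p_y in ((1, model.prior), (0, 1.0 - model.prior)):
        for combo in itertools.product(*state_lists):
            ok = all(
                evidence.assignments.get(v.name, s) == s
                for v, s in zip(model.variables, combo)
            )
            if not ok:
                continue
            p = p_y
            for v, s in zip(model.variables, combo):
                cpt = model.cpts[v.name]
                i = cpt.states.index(s)
                p *= cpt.p_given_event[i] if y == 1 else cpt.p_given_noevent[i]
            mass[y] += p
    total = mass[0] + mass[1]
    if total == 0.0:
        raise ValidationError("evidence has zero probability under the model")
    return mass[1] / total


def row_to_evidence(
    model: NetworkModel,
    row: dict | pd.Series,
    row_id: str | None = None,
) -> EvidenceVector:
    """Map one cohort row to evidence.

    Cells may hold state labels directly or, for continuous-discretized
    variables, raw numeric measurements (discretized on the fly).  Blank /
    NaN cells are missing.
    """
    assignments: dict[str, str] = {}
    names = set(model.variable_names)
    for col, value in dict(row).items():
        if col not in names:
            continue
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        text = str(value).strip()
        if text == "" or text.lower() in ("na", "nan"):
            continue
        spec = model.variable(col)
        if text in spec.states:
            assignments[col] = text
            continue
        if spec.kind == "continuous-discretized":
            try:
                raw = float(text)
            except ValueError:
                raise ValidationError(f"row {row_id}: {col}={text!r} is neither a state nor numeric") from None
            state = discretize(raw, spec)
            if state is not None:
                assignments[col] = state
            continue
        raise ValidationError(f"row {row_id}: {text!r} is not a state of {col!r}")
    return EvidenceVector(assignments, source_record_id=row_id)


def batch_score(model: NetworkModel, cohort: pd.DataFrame) -> list[RiskResult]:
    """Score every row of a cohort table; order-preserving and deterministic.

    Columns that match no model variable are ignored with a logged warning;
    rows with nothing observed are scored at the prior.
    """
    known = set(model.variable_names)
    ignorable = {"row_id", "cv_hosp_1y"}
    unknown = [c for c in cohort.columns if c not in known and c not in ignorable]
    if unknown:
        logger.warning("ignoring %d unmappable column(s): %s", len(unknown), unknown)
    results = []
    for idx, row in cohort.iterrows():
        ev = row_to_evidence(model, row, row_id=str(row.get("row_id", idx)))
        results.append(predict_risk(model, ev))
    return results


def scores_array(results: list[RiskResult]) -> np.ndarray:
    return np.array([r.posterior for r in results])
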