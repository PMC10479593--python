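"""Prognostic explanation metrics: impact and value of information.

Impact of an observed item is its normalized likelihood
NL = P(e|Y=1) / P(e) = P(Y=1|e) / P(Y=1): values above one mark
risk-increasing evidence, below one protective evidence.

Value of information for an unmeasured variable X given evidence E is the
expected reduction in outcome entropy from observing X, i.e. the
conditional mutual information I(Y; X | E) under the model, in bits.
Because covariates are independent given Y, the predictive distribution of
X given E is a posterior-weighted mixture of its two CPT columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .errors import ValidationError
from .inference import EvidenceVector, log_likelihood_ratio, predict_risk
from .knowledge import NetworkModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImpactEntry:
    variable: str
    state: str
    nl: float
    direction: str  # "risk-increasing" | "protective" | "neutral"


@dataclass(frozen=True)
class ImpactReport:
    entries: tuple[ImpactEntry, ...]  # sorted descending by NL


@dataclass(frozen=True)
class VOIEntry:
    variable: str
    voi_bits: float
    indexed_voi: float
    rank: int


@dataclass(frozen=True)
class VOIReport:
    entries: tuple[VOIEntry, ...]  # ranked descending by voi_bits
    normalization_mode: str  # "max" | "residual-entropy"
    residual_entropy_bits: float


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def normalized_likelihood(model: NetworkModel, variable: str, state: str) -> float:
    """NL = P(state|Y=1) / P(state), with P(state) the prior-weighted marginal."""
    cpt = model.cpts.get(variable)
    if cpt is None:
        raise ValidationError(f"unknown variable {variable!r}")
    i = cpt.state_index(state)
    a = cpt.p_given_event[i]
    b = cpt.p_given_noevent[i]
    marginal = model.prior * a + (1.0 - model.prior) * b
    return a / marginal


def _direction(nl: float, tol: float = 1e-9) -> str:
    if abs(nl - 1.0) <= tol:
        return "neutral"
    return "risk-increasing" if nl > 1.0 else "protective"


def impact_report(model: NetworkModel, evidence: EvidenceVector) -> ImpactReport:
    """One NL per observed item, sorted descending, with direction labels."""
    if not evidence.assignments:
        raise ValidationError("impact report requires non-empty evidence")
    evidence.validate_against(model)
    entries = [
        ImpactEntry(var, state, nl, _direction(nl))
        for var, state in evidence.assignments.items()
        for nl in (normalized_likelihood(model, var, state),)
    ]
    entries.sort(key=lambda e: (-e.nl, e.variable))
    return ImpactReport(entries=tuple(entries))


def value_of_information(model: NetworkModel, evidence: EvidenceVector, candidate: str) -> float:
    """I(Y; candidate | evidence) in bits; 0 if the candidate is already observed."""
    if candidate in evidence.assignments:
        logger.info("VOI requested for already-observed variable %r: 0 by definition", candidate)
        return 0.0
    cpt = model.cpts.get(candidate)
    if cpt is None:
        raise ValidationError(f"unknown variable {candidate!r}")
    p1 = predict_risk(model, evidence).posterior
    h_prior = _binary_entropy(p1)
    prior_log_odds = math.log(p1 / (1.0 - p1)) if 0.0 < p1 < 1.0 else math.inf * (1 if p1 >= 1 else -1)
    expected_h = 0.0
    for i, state in enumerate(cpt.states):
        p_state = p1 * cpt.p_given_event[i] + (1.0 - p1) * cpt.p_given_noevent[i]
        if p_state <= 0.0:
            continue
        post = 1.0 / (1.0 + math.exp(-(prior_log_odds + log_likelihood_ratio(model, candidate, state))))
        expected_h += p_state * _binary_entropy(post)
    voi = h_prior - expected_h
    return max(voi, 0.0)  # clip -1e-16-scale rounding


def indexed_voi(
    model: NetworkModel,
    evidence: EvidenceVector,
    candidates: list[str],
    mode: str = "max",
) -> VOIReport:
    """Rank candidate measurements by VOI and index the values.

    ``mode="max"`` divides by the largest VOI (top entry reads 1.0);
    ``mode="residual-entropy"`` divides by H(Y|E), so the index is the
    fraction of remaining outcome uncertainty each test would remove.  The
    ordering is identical under both modes.
    """
    if mode not in ("max", "residual-entropy"):
        raise ValidationError(f"unknown normalization mode {mode!r}")
    unobserved = [c for c in candidates if c not in evidence.assignments]
    p1 = predict_risk(model, evidence).posterior
    residual = _binary_entropy(p1)
    if not unobserved:
        return VOIReport(entries=(), normalization_mode=mode, residual_entropy_bits=residual)
    vois = [(c, value_of_information(model, evidence, c)) for c in unobserved]
    vois.sort(key=lambda t: (-t[1], t[0]))
    denom = vois[0][1] if mode == "max" else residual
    entries = tuple(
        VOIEntry(
            variable=c,
            voi_bits=v,
            indexed_voi=(v / denom if denom > 0.0 else 0.0),
            rank=r,
        )
        for r, (c, v) in enumerate(vois, start=1)
    )
    return VOIReport(entries=entries, normalization_mode=mode, residual_entropy_bits=residual)
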