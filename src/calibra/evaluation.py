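"""Discrimination, comparison and calibration of risk scores.

Covers the evaluation pipeline used to validate a risk score against
equation-based comparators on a one-year hospitalization endpoint:

* AUC as the Mann-Whitney statistic (ties count one half) with a DeLong
  structural-components confidence interval;
* paired DeLong comparison of two correlated AUCs;
* a fixed-order non-inferiority (margin 0.05) then superiority
  (delta AUC >= 0.05 and DeLong p < 0.05) gatekeeping procedure, which
  spends no alpha on the second step when the first fails;
* calibration by score quantiles with adjacent risk ratios;
* exact (chi-square based) Poisson confidence limits for incidence density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValidationError(f"labels must be 0/1, got {sorted(uniq)}")
    if uniq != {0, 1}:
        raise ValidationError("both outcome classes must be present")
    return labels.astype(int)


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the per-subject structural components V10 (cases) and V01
    (controls), computed with midranks in O(n log n)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return auc, v10, v01


def _var(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1)) if len(x) > 1 else 0.0


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    variance: float


def roc_auc(scores, labels, ci_level: float = 0.95) -> ROCResult:
    """Mann-Whitney AUC with a DeLong-variance Wald CI truncated to [0,1]."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if len(scores) != len(labels):
        raise ValidationError("scores and labels must have equal length")
    auc, v10, v01 = _delong_components(scores, labels)
    var = _var(v10) / len(v10) + _var(v01) / len(v01)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return ROCResult(
        auc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
        variance=float(var),
    )


@dataclass(frozen=True)
class DeLongComparison:
    delta_auc: float  # AUC_a - AUC_b
    variance: float
    z: float
    p_value: float
    auc_a: float
    auc_b: float
    effective_n: int


def delong_paired(scores_a, scores_b, labels) -> DeLongComparison:
    """Paired DeLong comparison of two correlated AUCs on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValidationError("paired comparison requires equal-length inputs")
    auc_a, v10a, v01a = _delong_components(scores_a, labels)
    auc_b, v10b, v01b = _delong_components(scores_b, labels)
    var = _var(v10a - v10b) / len(v10a) + _var(v01a - v01b) / len(v01a)
    delta = float(auc_a - auc_b)
    if var <= 0.0:
        # identical scores (or a degenerate pairing): no sampling variability
        z = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
        p = 1.0 if delta == 0.0 else 0.0
    else:
        z = delta / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(
        delta_auc=delta,
        variance=float(var),
        z=float(z),
        p_value=float(p),
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        effective_n=len(labels),
    )


@dataclass(frozen=True)
class GatekeepingVerdict:
    noninferior: bool
    superior: bool
    margin: float
    superiority_threshold: float
    alpha: float
    delta_auc: float
    ci_lower_one_sided: float
    p_value: float
    notes: str


def gatekeeping_test(
    scores_new,
    scores_ref,
    labels,
    margin: float = 0.05,
    superiority_threshold: float = 0.05,
    alpha: float = 0.05,
    ci_on: str = "delta",
) -> GatekeepingVerdict:
    """Fixed-order non-inferiority then superiority test.

    Step 1: the one-sided (1-alpha) lower confidence bound — on the AUC
    difference by default, or on the new score's AUC alone with
    ``ci_on="auc_new"`` — must clear the non-inferiority margin.
    Step 2 is entered only if step 1 passes: superiority requires both a
    point delta of at least the threshold and a significant paired DeLong
    test.  Sequential testing keeps the type-I error at alpha.
    """
    if ci_on not in ("delta", "auc_new"):
        raise ValidationError(f"ci_on must be 'delta' or 'auc_new', got {ci_on!r}")
    cmp = delong_paired(scores_new, scores_ref, labels)
    z_crit = stats.norm.ppf(1.0 - alpha)
    if ci_on == "delta":
        lower = cmp.delta_auc - z_crit * math.sqrt(max(cmp.variance, 0.0))
        noninferior = lower > -margin
    else:
        single = roc_auc(scores_new, labels)
        lower = single.auc - z_crit * math.sqrt(max(single.variance, 0.0))
        noninferior = lower > cmp.auc_b - margin
        lower = lower - cmp.auc_b  # report on the delta scale either way
    superior = bool(
        noninferior
        and cmp.delta_auc >= superiority_threshold
        and cmp.p_value < alpha
    )
    notes = "superiority not assessed: non-inferiority failed" if not noninferior else ""
    return GatekeepingVerdict(
        noninferior=bool(noninferior),
        superior=superior,
        margin=margin,
        superiority_threshold=superiority_threshold,
        alpha=alpha,
        delta_auc=cmp.delta_auc,
        ci_lower_one_sided=float(lower),
        p_value=cmp.p_value,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# calibration and incidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTable:
    table: pd.DataFrame  # bin, n, score_min, score_max, mean_predicted, observed
    adjacent_risk_ratios: tuple[float, ...]  # observed_{i+1}/observed_i; nan if undefined
    k: int


def calibration_by_quantile(predicted, labels, k: int = 5) -> CalibrationTable:
    """Observed incidence by quantile of predicted risk.

    Bins are formed by stable rank so tied scores cannot empty a bin; sizes
    are equal up to one unit.  Adjacent risk ratios with a zero-incidence
    denominator are reported as NaN.
    """
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(predicted)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n < k:
        raise ValidationError(f"need at least k={k} rows, got {n}")
    order = np.argsort(predicted, kind="stable")
    bin_of_sorted = (np.arange(n) * k) // n
    bins = np.empty(n, dtype=int)
    bins[order] = bin_of_sorted
    rows = []
    observed = []
    for b in range(k):
        mask = bins == b
        p = predicted[mask]
        y = labels[mask]
        rows.append(
            {
                "bin": b + 1,
                "n": int(mask.sum()),
                "score_min": float(p.min()),
                "score_max": float(p.max()),
                "mean_predicted": float(p.mean()),
                "observed": float(y.mean()),
            }
        )
        observed.append(float(y.mean()))
    rrs = tuple(
        (observed[i + 1] / observed[i]) if observed[i] > 0 else float("nan")
        for i in range(k - 1)
    )
    return CalibrationTable(table=pd.DataFrame(rows), adjacent_risk_ratios=rrs, k=k)


@dataclass(frozen=True)
class IncidenceDensity:
    events: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float


def incidence_density(events: int, person_years: float, ci_level: float = 0.95) -> IncidenceDensity:
    """Events per person-year with exact Poisson (chi-square) confidence limits."""
    if events < 0 or person_years <= 0:
        raise ValidationError("events must be >= 0 and person_years > 0")
    alpha = 1.0 - ci_level
    lower = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2.0, 2 * events) / (2.0 * person_years)
    upper = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * events + 2) / (2.0 * person_years)
    return IncidenceDensity(
        events=int(events),
        person_years=float(person_years),
        rate=events / person_years,
        ci_low=float(lower),
        ci_high=float(upper),
    )
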