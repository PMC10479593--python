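"""Compile published effect sizes into a naive-Bayes risk network.

The model is a single binary outcome node Y (one or more cardiovascular
hospitalizations within one year) with every risk factor a child of Y.
Knowledge enters as per-study effect sizes (odds ratios, risk ratios or
hazard ratios) abstracted from observational cohorts; these are pooled by a
fixed-effect meta-analysis weighted by normalized study sample size, then
inverted — together with the outcome prior and each exposure state's
marginal prevalence — into conditional probability tables P(state | Y).

The inversion is exact: for an odds ratio ``w`` the pair
(a, b) = (P(E=1|Y=1), P(E=1|Y=0)) is the root of the quadratic obtained from
the margin constraint ``q = p*a + (1-p)*b`` and ``odds(a)/odds(b) = w``; for
a risk ratio the system is linear.  Hazard ratios over the one-year horizon
are treated as risk ratios.
"""

from __future__ import annotations

import bisect
import csv
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    IncompleteKnowledgeError,
    InfeasibleParameterError,
    InputOutputError,
    MeasureHeterogeneityError,
    ValidationError,
)

SMOOTHING_EPS = 1e-6
_MEASURES = ("OR", "RR", "HR")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Definition of one risk-factor node.

    ``kind`` is one of ``binary``, ``categorical`` or
    ``continuous-discretized``.  Continuous variables carry strictly
    ascending ``cutpoints`` in the variable's units; ``len(states) ==
    len(cutpoints) + 1``.  ``channels`` optionally maps alternative
    measurement channels (e.g. 24-h urine protein as an alternative to ACR
    for the albuminuria node) to their own cut-points over the same states.
    """

    name: str
    kind: str
    states: tuple[str, ...]
    reference_state: str
    cutpoints: tuple[float, ...] = ()
    units: str = ""
    channels: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "cutpoints", tuple(self.cutpoints))
        probs = []
        if self.kind not in ("binary", "categorical", "continuous-discretized"):
            probs.append(f"{self.name}: unknown kind {self.kind!r}")
        if len(self.states) < 2:
            probs.append(f"{self.name}: needs >=2 states")
        if len(set(self.states)) != len(self.states):
            probs.append(f"{self.name}: duplicate state labels")
        if self.reference_state not in self.states:
            probs.append(f"{self.name}: reference_state {self.reference_state!r} not a state")
        if self.kind == "continuous-discretized":
            for label, cp in [("cutpoints", self.cutpoints), *self.channels.items()]:
                if len(self.states) != len(cp) + 1:
                    probs.append(f"{self.name}/{label}: |states| != |cutpoints|+1")
                if any(cp[i] >= cp[i + 1] for i in range(len(cp) - 1)):
                    probs.append(f"{self.name}/{label}: cutpoints not strictly ascending")
        elif self.cutpoints:
            probs.append(f"{self.name}: cutpoints only allowed for continuous variables")
        if probs:
            raise ValidationError("invalid VariableSpec: " + "; ".join(probs), fields=probs)


@dataclass(frozen=True)
class PopulationFlags:
    pediatric: bool = False
    rrt: bool = False
    other_disease: bool = False

    def any(self) -> bool:
        return self.pediatric or self.rrt or self.other_disease


@dataclass(frozen=True)
class EffectSizeRecord:
    """One published finding: effect of an exposure state on the outcome."""

    study_id: str
    variable: str
    exposure_state: str
    measure: str
    point: float
    ci_low: float
    ci_high: float
    n: int
    followup_years: float
    flags: PopulationFlags = PopulationFlags()

    def __post_init__(self):
        if self.measure not in _MEASURES:
            raise ValidationError(f"{self.study_id}: measure must be one of {_MEASURES}")
        if not (0 < self.ci_low <= self.point <= self.ci_high):
            raise ValidationError(
                f"{self.study_id}: requires 0 < ci_low <= point <= ci_high"
            )
        if self.n < 1:
            raise ValidationError(f"{self.study_id}: n must be >= 1")
        if self.followup_years <= 0:
            raise ValidationError(f"{self.study_id}: followup_years must be positive")


@dataclass(frozen=True)
class PooledEffect:
    """Fixed-effect pooled (log-scale) effect for one variable state.

    ``weights`` are normalized study sample sizes, n_i / sum(n_j).
    ``measure`` records the shared effect measure of the pooled studies.
    """

    variable: str
    exposure_state: str
    pooled_log_effect: float
    weights: tuple[float, ...]
    n_studies: int
    measure: str

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValidationError(f"{self.variable}/{self.exposure_state}: weights must sum to 1")

    @property
    def pooled_effect(self) -> float:
        return math.exp(self.pooled_log_effect)


@dataclass(frozen=True)
class ConditionalTable:
    """P(state | Y=1) and P(state | Y=0) for one variable, smoothed."""

    variable: str
    states: tuple[str, ...]
    p_given_event: tuple[float, ...]
    p_given_noevent: tuple[float, ...]

    def __post_init__(self):
        for label, col in (("event", self.p_given_event), ("noevent", self.p_given_noevent)):
            if len(col) != len(self.states):
                raise ValidationError(f"{self.variable}: {label} column length mismatch")
            if abs(sum(col) - 1.0) > 1e-12:
                raise ValidationError(f"{self.variable}: {label} column does not sum to 1")
            if any(not (0.0 < p < 1.0) for p in col):
                raise ValidationError(f"{self.variable}: {label} column has entries outside (0,1)")

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValidationError(f"unknown state {state!r} for variable {self.variable!r}") from None


@dataclass(frozen=True)
class NetworkModel:
    """The compiled naive-Bayes network: outcome prior plus one CPT per node."""

    prior: float
    variables: tuple[VariableSpec, ...]
    cpts: dict[str, ConditionalTable]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.prior < 1.0):
            raise ValidationError("prior must lie in (0,1)", fields=["prior"])
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate variable names", fields=["variables"])
        missing = [n for n in names if n not in self.cpts]
        extra = [n for n in self.cpts if n not in names]
        if missing or extra:
            raise ValidationError(
                f"CPT/variable mismatch (missing={missing}, extra={extra})",
                fields=missing + extra,
            )
        for v in self.variables:
            if self.cpts[v.name].states != v.states:
                raise ValidationError(f"{v.name}: CPT states disagree with spec")

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise ValidationError(f"unknown variable {name!r}")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_studies(records: list[EffectSizeRecord]) -> list[EffectSizeRecord]:
    """Apply the study inclusion rules.

    Keeps adult, non-RRT, on-topic studies with at least one year of
    follow-up; order is preserved and an empty result is allowed.
    """
    return [r for r in records if r.followup_years >= 1.0 and not r.flags.any()]


def pool_effect_sizes(records: list[EffectSizeRecord]) -> PooledEffect:
    """Fixed-effect pooling on the log scale, weighted by normalized sample size."""
    if not records:
        raise ValidationError("cannot pool an empty record list")
    key = (records[0].variable, records[0].exposure_state)
    measures = {r.measure for r in records}
    if len(measures) > 1:
        raise MeasureHeterogeneityError(
            f"{key}: mixed effect measures {sorted(measures)} cannot be pooled"
        )
    if any((r.variable, r.exposure_state) != key for r in records):
        raise ValidationError(f"pooling requires a single variable/state, got records beyond {key}")
    ns = np.array([r.n for r in records], dtype=float)
    weights = ns / ns.sum()
    pooled = float(np.sum(weights * np.log([r.point for r in records])))
    return PooledEffect(
        variable=key[0],
        exposure_state=key[1],
        pooled_log_effect=pooled,
        weights=tuple(weights),
        n_studies=len(records),
        measure=records[0].measure,
    )


def or_to_conditionals(or_value: float, outcome_prev: float, exposure_prev: float) -> tuple[float, float]:
    """Invert an odds ratio into (P(E=1|Y=1), P(E=1|Y=0)).

    Solves the margin constraint q = p*a + (1-p)*b jointly with
    odds(a)/odds(b) = OR via the quadratic in b, selecting the root that
    yields both probabilities inside (0,1).
    """
    p, q, w = outcome_prev, exposure_prev, or_value
    _check_inversion_inputs(w, p, q, "odds ratio")
    if abs(w - 1.0) < 1e-14:
        return q, q
    # substitute a = w*b / (1 + (w-1)*b) into the margin constraint
    A = (1.0 - p) * (w - 1.0)
    B = (1.0 - p) + p * w - q * (w - 1.0)
    C = -q
    disc = B * B - 4.0 * A * C
    if disc < 0:
        raise InfeasibleParameterError(
            f"odds-ratio inversion has no real root (or={w}, prior={p}, prevalence={q})",
            constraint="margin+odds-ratio",
        )
    sq = math.sqrt(disc)
    for b in ((-B + sq) / (2.0 * A), (-B - sq) / (2.0 * A)):
        if 0.0 < b < 1.0:
            a = w * b / (1.0 + (w - 1.0) * b)
            if 0.0 < a < 1.0:
                return a, b
    raise InfeasibleParameterError(
        f"no admissible root in (0,1) for or={w}, prior={p}, prevalence={q}",
        constraint="root in (0,1)",
    )


def rr_to_conditionals(rr_value: float, outcome_prev: float, exposure_prev: float) -> tuple[float, float]:
    """Invert a risk ratio P(Y|E=1)/P(Y|E=0) into (P(E=1|Y=1), P(E=1|Y=0)).

    Bayes inversion makes the system linear: a = rr*q / (1 - q + rr*q),
    b from the margin constraint.  Infeasible when the implied
    P(Y=1|E=1) would exceed 1.
    """
    p, q, rr = outcome_prev, exposure_prev, rr_value
    _check_inversion_inputs(rr, p, q, "risk ratio")
    a = rr * q / (1.0 - q + rr * q)
    b = (q - p * a) / (1.0 - p)
    if not (0.0 < b < 1.0) or p * a / q >= 1.0:
        raise InfeasibleParameterError(
            f"risk ratio {rr} with prior {p} and prevalence {q} implies "
            f"P(Y=1|E=1)={p * a / q:.4g} >= 1 or P(E=1|Y=0)={b:.4g} outside (0,1)",
            constraint="P(Y=1|E=1) <= 1",
        )
    return a, b


def _check_inversion_inputs(effect: float, p: float, q: float, what: str) -> None:
    if effect <= 0 or not math.isfinite(effect):
        raise ValidationError(f"{what} must be a positive finite real, got {effect}")
    if not (0.0 < p < 1.0) or not (0.0 < q < 1.0):
        raise ValidationError(f"prevalences must lie in (0,1), got prior={p}, exposure={q}")


def discretize(value: float, spec: VariableSpec, channel: str | None = None) -> str | None:
    """Map a continuous measurement to its state label.

    Half-open binning [low, high): a value exactly at a cut-point belongs to
    the upper bin.  Non-finite values are treated as missing (``None``).
    """
    if spec.kind != "continuous-discretized":
        raise ValidationError(f"{spec.name} is not continuous-discretized")
    if channel is None:
        cutpoints = spec.cutpoints
    else:
        if channel not in spec.channels:
            raise ValidationError(f"{spec.name}: unknown measurement channel {channel!r}")
        cutpoints = spec.channels[channel]
    v = float(value)
    if not math.isfinite(v):
        return None
    return spec.states[bisect.bisect_right(cutpoints, v)]


def build_network(
    prior: float,
    specs: list[VariableSpec],
    pooled_effects: dict[tuple[str, str], PooledEffect],
    exposure_prevalences: dict[tuple[str, str], float],
    metadata: dict[str, str] | None = None,
    smoothing_eps: float = SMOOTHING_EPS,
) -> NetworkModel:
    """Assemble the full network from pooled effects and state prevalences.

    Every non-reference state of every variable needs a pooled effect and a
    marginal prevalence; the reference state's conditional mass is the
    remainder.  Boundary cells are additively smoothed (eps then
    renormalize) so log-likelihood ratios stay finite.
    """
    cpts: dict[str, ConditionalTable] = {}
    for spec in specs:
        a_col = np.zeros(len(spec.states))
        b_col = np.zeros(len(spec.states))
        ref_i = spec.states.index(spec.reference_state)
        for i, state in enumerate(spec.states):
            if i == ref_i:
                continue
            key = (spec.name, state)
            if key not in pooled_effects:
                raise IncompleteKnowledgeError(f"no pooled effect for {spec.name!r} state {state!r}")
            if key not in exposure_prevalences:
                raise IncompleteKnowledgeError(f"no exposure prevalence for {spec.name!r} state {state!r}")
            eff = pooled_effects[key]
            q = exposure_prevalences[key]
            value = eff.pooled_effect
            if eff.measure == "OR":
                a, b = or_to_conditionals(value, prior, q)
            else:  # RR, or HR read as a one-year risk ratio
                a, b = rr_to_conditionals(value, prior, q)
            a_col[i], b_col[i] = a, b
        a_ref = 1.0 - a_col.sum()
        b_ref = 1.0 - b_col.sum()
        if a_ref <= 0.0 or b_ref <= 0.0:
            raise InfeasibleParameterError(
                f"{spec.name}: non-reference state conditionals exceed 1 "
                f"(reference remainder {a_ref:.4g}/{b_ref:.4g})",
                constraint="reference-state mass > 0",
            )
        a_col[ref_i], b_col[ref_i] = a_ref, b_ref
        a_col = (a_col + smoothing_eps) / (1.0 + smoothing_eps * len(spec.states))
        b_col = (b_col + smoothing_eps) / (1.0 + smoothing_eps * len(spec.states))
        # renormalize exactly to absorb float round-off before validation
        a_col /= a_col.sum()
        b_col /= b_col.sum()
        cpts[spec.name] = ConditionalTable(
            variable=spec.name,
            states=spec.states,
            p_given_event=tuple(float(x) for x in a_col),
            p_given_noevent=tuple(float(x) for x in b_col),
        )
    return NetworkModel(
        prior=prior,
        variables=tuple(specs),
        cpts=cpts,
        metadata=dict(metadata or {}),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _spec_to_json(spec: VariableSpec) -> dict:
    d = {
        "name": spec.name,
        "kind": spec.kind,
        "states": list(spec.states),
        "reference_state": spec.reference_state,
        "units": spec.units,
    }
    if spec.kind == "continuous-discretized":
        d["cutpoints"] = list(spec.cutpoints)
        if spec.channels:
            d["channels"] = {k: list(v) for k, v in spec.channels.items()}
    return d


def spec_from_json(d: dict) -> VariableSpec:
    try:
        return VariableSpec(
            name=d["name"],
            kind=d["kind"],
            states=tuple(d["states"]),
            reference_state=d["reference_state"],
            cutpoints=tuple(d.get("cutpoints", ())),
            units=d.get("units", ""),
            channels={k: tuple(v) for k, v in d.get("channels", {}).items()},
        )
    except KeyError as e:
        raise ValidationError(f"variable spec missing field {e.args[0]!r}", fields=[e.args[0]]) from None


def save_model(model: NetworkModel, path: str | os.PathLike) -> None:
    """Serialize to JSON. Probabilities use shortest-round-trip decimals
    (>=17 significant digits where needed), so load(save(m)) is bit-exact."""
    doc = {
        "prior": model.prior,
        "variables": [_spec_to_json(v) for v in model.variables],
        "cpts": {
            name: {
                "states": list(t.states),
                "p_given_event": list(t.p_given_event),
                "p_given_noevent": list(t.p_given_noevent),
            }
            for name, t in model.cpts.items()
        },
        "metadata": model.metadata,
    }
    tmp = f"{path}.tmp"
    try:
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        os.replace(tmp, path)
    except OSError as e:
        raise InputOutputError(f"cannot write model to {path}: {e}") from e


def load_model(path: str | os.PathLike) -> NetworkModel:
    """Load and validate a serialized model; schema violations list fields."""
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except OSError as e:
        raise InputOutputError(f"cannot read model from {path}: {e}") from e
    except json.JSONDecodeError as e:
        raise ValidationError(f"model file {path} is not valid JSON: {e}") from e
    missing = [k for k in ("prior", "variables", "cpts") if k not in doc]
    if missing:
        raise ValidationError(f"model file missing keys {missing}", fields=missing)
    specs = [spec_from_json(d) for d in doc["variables"]]
    cpts = {}
    for name, t in doc["cpts"].items():
        bad = [k for k in ("states", "p_given_event", "p_given_noevent") if k not in t]
        if bad:
            raise ValidationError(f"CPT {name!r} missing {bad}", fields=[f"cpts.{name}.{k}" for k in bad])
        cpts[name] = ConditionalTable(
            variable=name,
            states=tuple(t["states"]),
            p_given_event=tuple(float(x) for x in t["p_given_event"]),
            p_given_noevent=tuple(float(x) for x in t["p_given_noevent"]),
        )
    return NetworkModel(
        prior=float(doc["prior"]),
        variables=tuple(specs),
        cpts=cpts,
        metadata=dict(doc.get("metadata", {})),
    )


def read_evidence_table(path: str | os.PathLike) -> list[EffectSizeRecord]:
    """Read a literature evidence table (CSV) into effect-size records."""
    records = []
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                records.append(
                    EffectSizeRecord(
                        study_id=row["study_id"],
                        variable=row["variable"],
                        exposure_state=row["exposure_state"],
                        measure=row["measure"],
                        point=float(row["point"]),
                        ci_low=float(row["ci_low"]),
                        ci_high=float(row["ci_high"]),
                        n=int(row["n"]),
                        followup_years=float(row["followup_years"]),
                        flags=PopulationFlags(
                            pediatric=_as_bool(row.get("pediatric", "0")),
                            rrt=_as_bool(row.get("rrt", "0")),
                            other_disease=_as_bool(row.get("other_disease", "0")),
                        ),
                    )
                )
    except OSError as e:
        raise InputOutputError(f"cannot read evidence table {path}: {e}") from e
    except (KeyError, ValueError) as e:
        raise ValidationError(f"malformed evidence table {path}: {e}") from e
    return records


def _as_bool(x: str) -> bool:
    return str(x).strip().lower() in ("1", "true", "yes")
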