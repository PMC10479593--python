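"""Packaged default configuration: variables, evidence, comparator specs.

The shipped literature table (``data/synthetic_evidence.csv``) is a
SYNTHETIC stand-in for a pooled-evidence supplement that is not publicly
deposited: effect sizes and prevalences are clinically plausible values for
an elderly non-dialysis CKD population, chosen so the compiled network is a
realistic, fully feasible model — not a reproduction of any published
parameter set.  Swap in a real evidence table to deploy actual pooled
estimates.
"""

from __future__ import annotations

import json
from importlib import resources

from .comparators import EquationScoreSpec, load_score_spec
from .knowledge import (
    EffectSizeRecord,
    NetworkModel,
    PooledEffect,
    VariableSpec,
    build_network,
    filter_studies,
    pool_effect_sizes,
    read_evidence_table,
    spec_from_json,
)

DEFAULT_PRIOR = 0.03  # one-year outcome prior; settable per deployment

_DATA = resources.files("calibra.data")


def load_default_variables() -> list[VariableSpec]:
    doc = json.loads(_DATA.joinpath("default_variables.json").read_text())
    return [spec_from_json(d) for d in doc["variables"]]


def load_default_prevalences() -> dict[tuple[str, str], float]:
    doc = json.loads(_DATA.joinpath("default_variables.json").read_text())
    prevs: dict[tuple[str, str], float] = {}
    for d in doc["variables"]:
        for state, q in d.get("prevalences", {}).items():
            prevs[(d["name"], state)] = float(q)
    return prevs


def load_default_evidence() -> list[EffectSizeRecord]:
    with resources.as_file(_DATA.joinpath("synthetic_evidence.csv")) as path:
        return read_evidence_table(path)


def pool_all(records: list[EffectSizeRecord]) -> dict[tuple[str, str], PooledEffect]:
    """Group filtered records by (variable, state) and pool each group."""
    groups: dict[tuple[str, str], list[EffectSizeRecord]] = {}
    for r in records:
        groups.setdefault((r.variable, r.exposure_state), []).append(r)
    return {key: pool_effect_sizes(rs) for key, rs in groups.items()}


def build_default_model(prior: float = DEFAULT_PRIOR) -> NetworkModel:
    """Compile the packaged synthetic evidence into the 31-variable network."""
    specs = load_default_variables()
    pooled = pool_all(filter_studies(load_default_evidence()))
    prevs = load_default_prevalences()
    return build_network(
        prior,
        specs,
        pooled,
        prevs,
        metadata={
            "source": "packaged synthetic literature table (synthetic_evidence.csv)",
            "prior": f"{prior}",
        },
    )


def load_comparator_spec(name: str) -> EquationScoreSpec:
    """Load one of the packaged comparator score specs: fhs, ascvd, indana."""
    files = {
        "fhs": "fhs_general_cvd_2008.json",
        "ascvd": "ascvd_pooled_cohort_2013.json",
        "indana": "synthetic_indana.json",
    }
    key = name.lower()
    if key not in files:
        from .errors import ValidationError

        raise ValidationError(f"unknown comparator {name!r}; options: {sorted(files)}")
    with resources.as_file(_DATA.joinpath(files[key])) as path:
        return load_score_spec(path)
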