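import numpy as np
import pytest

from calibra import build_default_model
from calibra.knowledge import ConditionalTable, NetworkModel, VariableSpec


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


def make_random_model(rng: np.random.Generator, max_vars: int = 8, max_states: int = 4) -> NetworkModel:
    """A small random naive-Bayes model with strictly interior CPT entries."""
    n_vars = int(rng.integers(1, max_vars + 1))
    prior = float(rng.uniform(0.05, 0.6))
    specs, cpts = [], {}
    for i in range(n_vars):
        k = int(rng.integers(2, max_states + 1))
        states = tuple(f"s{j}" for j in range(k))
        name = f"v{i}"
        p1 = rng.dirichlet(np.full(k, 1.5))
        p0 = rng.dirichlet(np.full(k, 1.5))
        # keep entries away from 0/1 so log-ratios stay tame
        p1 = (p1 + 0.02) / (p1 + 0.02).sum()
        p0 = (p0 + 0.02) / (p0 + 0.02).sum()
        p1 /= p1.sum()
        p0 /= p0.sum()
        specs.append(VariableSpec(name=name, kind="categorical", states=states, reference_state=states[0]))
        cpts[name] = ConditionalTable(
            variable=name,
            states=states,
            p_given_event=tuple(float(x) for x in p1),
            p_given_noevent=tuple(float(x) for x in p0),
        )
    return NetworkModel(prior=prior, variables=tuple(specs), cpts=cpts)


def make_random_evidence(rng: np.random.Generator, model: NetworkModel) -> dict:
    assignments = {}
    for v in model.variables:
        if rng.random() < 0.5:
            assignments[v.name] = v.states[int(rng.integers(len(v.states)))]
    return assignments


def make_binary_model(prior: float, p1: float, p0: float, name: str = "x") -> NetworkModel:
    """One binary variable with P(x=1|Y=1)=p1 and P(x=1|Y=0)=p0."""
    spec = VariableSpec(name=name, kind="binary", states=("0", "1"), reference_state="0")
    cpt = ConditionalTable(
        variable=name,
        states=("0", "1"),
        p_given_event=(1.0 - p1, p1),
        p_given_noevent=(1.0 - p0, p0),
    )
    return NetworkModel(prior=prior, variables=(spec,), cpts={name: cpt})
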