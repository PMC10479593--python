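"""Knowledge compilation: study filtering, pooling, effect inversion, CPTs."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calibra.errors import (
    IncompleteKnowledgeError,
    InfeasibleParameterError,
    MeasureHeterogeneityError,
    ValidationError,
)
from calibra.knowledge import (
    EffectSizeRecord,
    PopulationFlags,
    VariableSpec,
    build_network,
    discretize,
    filter_studies,
    load_model,
    or_to_conditionals,
    pool_effect_sizes,
    rr_to_conditionals,
    save_model,
)

from conftest import make_random_evidence, make_random_model


def _rec(study_id="S1", variable="diabetes", state="yes", measure="OR", point=2.0,
         n=100, followup=2.0, **flags):
    return EffectSizeRecord(
        study_id=study_id, variable=variable, exposure_state=state, measure=measure,
        point=point, ci_low=point / 1.3, ci_high=point * 1.3, n=n,
        followup_years=followup, flags=PopulationFlags(**flags),
    )


class TestFilterStudies:
    def test_short_followup_excluded(self):
        assert filter_studies([_rec(followup=0.5)]) == []

    @pytest.mark.parametrize("flag", ["pediatric", "rrt", "other_disease"])
    def test_special_populations_excluded(self, flag):
        assert filter_studies([_rec(**{flag: True})]) == []

    def test_eligible_adult_study_retained_in_order(self):
        keep1, keep2 = _rec(study_id="A"), _rec(study_id="B", followup=1.0)
        out = filter_studies([keep1, _rec(study_id="X", pediatric=True), keep2])
        assert out == [keep1, keep2]


class TestPooling:
    def test_single_study_identity(self):
        pooled = pool_effect_sizes([_rec(point=1.5, n=200)])
        assert pooled.pooled_effect == pytest.approx(1.5, abs=1e-12)
        assert pooled.weights == (1.0,)

    def test_equal_n_geometric_mean(self):
        pooled = pool_effect_sizes([_rec("A", point=1.0, n=500), _rec("B", point=4.0, n=500)])
        assert pooled.pooled_effect == pytest.approx(2.0, abs=1e-12)

    def test_sample_size_weighted_log_mean(self):
        # weights 100/400 and 300/400 on log(2) and log(1): pooled OR = 2**0.25
        pooled = pool_effect_sizes([_rec("A", point=2.0, n=100), _rec("B", point=1.0, n=300)])
        assert pooled.pooled_effect == pytest.approx(2.0 ** 0.25, abs=1e-12)
        assert pooled.weights == pytest.approx((0.25, 0.75))

    def test_mixed_measures_rejected(self):
        with pytest.raises(MeasureHeterogeneityError):
            pool_effect_sizes([_rec("A", measure="OR"), _rec("B", measure="RR")])

    @given(st.lists(st.tuples(st.floats(0.2, 5.0), st.integers(1, 10000)), min_size=1, max_size=8),
           st.randoms())
    @settings(max_examples=60, deadline=None)
    def test_order_invariant_and_bounded(self, studies, pyrandom):
        recs = [_rec(f"S{i}", point=p, n=n) for i, (p, n) in enumerate(studies)]
        pooled = pool_effect_sizes(recs)
        shuffled = list(recs)
        pyrandom.shuffle(shuffled)
        assert pool_effect_sizes(shuffled).pooled_log_effect == pytest.approx(
            pooled.pooled_log_effect, abs=1e-12)
        logs = [math.log(p) for p, _ in studies]
        assert min(logs) - 1e-12 <= pooled.pooled_log_effect <= max(logs) + 1e-12


class TestOddsRatioInversion:
    def test_null_association_returns_marginal(self):
        assert or_to_conditionals(1.0, 0.17, 0.3) == (0.3, 0.3)

    def test_symmetric_closed_form(self):
        a, b = or_to_conditionals(9.0, 0.5, 0.5)
        assert (a, b) == pytest.approx((0.75, 0.25), abs=1e-10)

    def test_quadratic_example(self):
        a, b = or_to_conditionals(2.0, 0.1, 0.2)
        assert (a, b) == pytest.approx((0.31532, 0.18717), abs=5e-5)
        # constraints hold to 1e-10
        assert 0.1 * a + 0.9 * b == pytest.approx(0.2, abs=1e-10)
        odds_ratio = (a / (1 - a)) / (b / (1 - b))
        assert odds_ratio == pytest.approx(2.0, abs=1e-9)

    def test_round_trip_over_random_feasible_triples(self):
        rng = np.random.default_rng(11)
        worst = 0.0
        for _ in range(1000):
            p = rng.uniform(0.01, 0.9)
            q = rng.uniform(0.01, 0.95)
            w = math.exp(rng.uniform(-2.5, 2.5))
            a, b = or_to_conditionals(w, p, q)
            w_back = (a / (1 - a)) / (b / (1 - b))
            worst = max(worst, abs(math.log(w_back) - math.log(w)))
            assert p * a + (1 - p) * b == pytest.approx(q, abs=1e-9)
        assert worst < 1e-9

    def test_agrees_with_grid_search_oracle(self):
        # exhaustive search over b resolves the same root as the quadratic
        rng = np.random.default_rng(7)
        grid = np.arange(1e-4, 1.0, 1e-4)
        for _ in range(50):
            p = rng.uniform(0.05, 0.8)
            q = rng.uniform(0.05, 0.9)
            w = math.exp(rng.uniform(-2.0, 2.0))
            a_grid = w * grid / (1.0 + (w - 1.0) * grid)
            margin = p * a_grid + (1.0 - p) * grid
            b_star = grid[np.argmin(np.abs(margin - q))]
            _, b = or_to_conditionals(w, p, q)
            assert abs(b - b_star) < 1e-3


class TestRiskRatioInversion:
    def test_null_association(self):
        assert rr_to_conditionals(1.0, 0.2, 0.4) == pytest.approx((0.4, 0.4), abs=1e-12)

    def test_symmetric_round_trip(self):
        a, b = rr_to_conditionals(3.0, 0.5, 0.5)
        assert (a, b) == pytest.approx((0.75, 0.25), abs=1e-10)
        # recompute the risk ratio from the 2x2 table
        rr = (0.5 * a / 0.5) / (0.5 * (1 - a) / 0.5)
        assert rr == pytest.approx(3.0, abs=1e-10)

    def test_infeasible_when_conditional_risk_exceeds_one(self):
        with pytest.raises(InfeasibleParameterError):
            rr_to_conditionals(5.0, 0.5, 0.1)

    def test_round_trip_random_triples(self):
        rng = np.random.default_rng(3)
        done = 0
        while done < 300:
            p = rng.uniform(0.01, 0.4)
            q = rng.uniform(0.05, 0.9)
            rr = math.exp(rng.uniform(-1.5, 1.5))
            try:
                a, b = rr_to_conditionals(rr, p, q)
            except InfeasibleParameterError:
                continue
            rr_back = (p * a / q) / (p * (1 - a) / (1 - q))
            assert abs(math.log(rr_back) - math.log(rr)) < 1e-9
            done += 1


class TestDiscretize:
    EGFR = VariableSpec(
        name="egfr", kind="continuous-discretized",
        states=("G5", "G4", "G3b", "G3a", "G2", "G1"),
        cutpoints=(15, 30, 45, 60, 90), reference_state="G3b",
    )

    def test_stage_g4(self):
        assert discretize(25, self.EGFR) == "G4"

    def test_below_first_cutpoint(self):
        assert discretize(7, self.EGFR) == "G5"

    def test_boundary_maps_to_upper_bin(self):
        assert discretize(30, self.EGFR) == "G3b"
        assert discretize(90, self.EGFR) == "G1"

    def test_non_finite_is_missing(self):
        assert discretize(float("nan"), self.EGFR) is None

    def test_alternative_channel(self):
        spec = VariableSpec(
            name="albuminuria", kind="continuous-discretized",
            states=("A1", "A2", "A3"), cutpoints=(3, 30), reference_state="A1",
            channels={"urine_protein_g_24h": (0.15, 0.5)},
        )
        assert discretize(2.49, spec, channel="urine_protein_g_24h") == "A3"
        assert discretize(2.49, spec) == "A1"  # same number read as ACR

    def test_spec_invariants(self):
        with pytest.raises(ValidationError):
            VariableSpec(name="x", kind="continuous-discretized",
                         states=("a", "b"), cutpoints=(2, 1), reference_state="a")
        with pytest.raises(ValidationError):
            VariableSpec(name="x", kind="binary", states=("a",), reference_state="a")


class TestBuildNetwork:
    BIN = VariableSpec(name="e", kind="binary", states=("no", "yes"), reference_state="no")

    def test_null_effect_gives_identical_columns(self):
        pooled = {("e", "yes"): pool_effect_sizes([_rec(variable="e", state="yes", point=1.0)])}
        m = build_network(0.1, [self.BIN], pooled, {("e", "yes"): 0.2})
        cpt = m.cpts["e"]
        assert cpt.p_given_event == pytest.approx(cpt.p_given_noevent, abs=1e-12)

    def test_binary_or2_columns(self):
        pooled = {("e", "yes"): pool_effect_sizes([_rec(variable="e", state="yes", point=2.0)])}
        m = build_network(0.1, [self.BIN], pooled, {("e", "yes"): 0.2}, smoothing_eps=0.0)
        assert m.cpts["e"].p_given_event == pytest.approx((0.68468, 0.31532), abs=5e-5)
        assert m.cpts["e"].p_given_noevent == pytest.approx((0.81283, 0.18717), abs=5e-5)

    def test_missing_knowledge_is_reported(self):
        with pytest.raises(IncompleteKnowledgeError, match="e"):
            build_network(0.1, [self.BIN], {}, {("e", "yes"): 0.2})

    def test_default_31_variable_model_valid(self, default_model):
        assert len(default_model.variables) == 31
        for name, cpt in default_model.cpts.items():
            assert sum(cpt.p_given_event) == pytest.approx(1.0, abs=1e-12)
            assert sum(cpt.p_given_noevent) == pytest.approx(1.0, abs=1e-12)
            assert all(0.0 < p < 1.0 for p in cpt.p_given_event + cpt.p_given_noevent)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, default_model):
        path = tmp_path / "model.json"
        save_model(default_model, path)
        loaded = load_model(path)
        assert loaded.prior == default_model.prior
        for name in default_model.cpts:
            assert loaded.cpts[name].p_given_event == default_model.cpts[name].p_given_event
            assert loaded.cpts[name].p_given_noevent == default_model.cpts[name].p_given_noevent

    def test_round_trip_posteriors_identical(self, tmp_path):
        from calibra.inference import EvidenceVector, predict_risk

        rng = np.random.default_rng(5)
        model = make_random_model(rng)
        path = tmp_path / "m.json"
        save_model(model, path)
        loaded = load_model(path)
        for _ in range(100):
            ev = EvidenceVector(make_random_evidence(rng, model))
            assert predict_risk(loaded, ev).posterior == predict_risk(model, ev).posterior

    def test_missing_cpt_rejected(self, tmp_path, default_model):
        path = tmp_path / "m.json"
        save_model(default_model, path)
        doc = json.loads(path.read_text())
        del doc["cpts"]["age"]
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError):
            load_model(path)

    def test_prior_out_of_range_rejected(self, tmp_path, default_model):
        path = tmp_path / "m.json"
        save_model(default_model, path)
        doc = json.loads(path.read_text())
        doc["prior"] = 1.5
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError):
            load_model(path)


def test_generative_reading_recovers_cpts():
    """Sampling from a built network and re-estimating conditionals recovers
    the CPT entries within 3 binomial standard errors."""
    from calibra.simulate import CohortConfig, simulate_cohort

    rng = np.random.default_rng(21)
    model = make_random_model(rng, max_vars=4, max_states=3)
    table = simulate_cohort(model, CohortConfig(n=10_000, seed=33)).data
    for v in model.variables:
        cpt = model.cpts[v.name]
        for y, col in ((1, cpt.p_given_event), (0, cpt.p_given_noevent)):
            sub = table[table["cv_hosp_1y"] == y][v.name]
            n = len(sub)
            for state, p in zip(v.states, col):
                phat = (sub == state).mean()
                se = math.sqrt(p * (1 - p) / n)
                assert abs(phat - p) <= 3 * se + 1e-9
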