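"""Markov engine: decision tree, transition algebra, accrual, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import afibcea as af
from afibcea.markov import (
    HealthState,
    N_STATES,
    residual_mortality,
    state_costs,
    state_utilities,
)
from afibcea.params import ParamError

from conftest import make_params, random_params

S = HealthState


@pytest.mark.parametrize(
    "value,rate,cycle,expected",
    [(100.0, 0.0, 7, 100.0), (100.0, 0.045, 1, 100 / 1.045), (100.0, 0.045, 0, 100.0)],
)
def test_discount(value, rate, cycle, expected):
    assert af.discount(value, rate, cycle) == pytest.approx(expected)


def test_discount_rejects_negative_cycle():
    with pytest.raises(ParamError):
        af.discount(1.0, 0.045, -1)


class TestPeriproceduralTree:
    def test_no_complications(self):
        p = make_params(proc=(0.0, 0.0, 0.0))
        dist, upfront = af.run_periprocedural_tree(p)
        assert upfront == pytest.approx(1879.4)
        assert dist[S.EVENT_FREE_AF] == pytest.approx(1.0)

    def test_table_values(self, table1):
        """Tree arithmetic from the raw counts: deaths 2/2,131 plus fatal
        periprocedural strokes (88/2,131)x(3/88); survivors of stroke
        (88/2,131)x(1 - 3/88) in the post-stroke state."""
        dist, upfront = af.run_periprocedural_tree(table1)
        assert dist[S.DEAD] == pytest.approx(5 / 2131)
        assert dist[S.POST_PROC_STROKE] == pytest.approx(85 / 2131)
        assert dist.sum() == pytest.approx(1.0)
        expected_upfront = (
            (2006 / 2131) * 1879.4 + (88 / 2131) * 6187.9 + (37 / 2131) * 5189.8
        )
        assert upfront == pytest.approx(expected_upfront)

    def test_certain_tamponade(self):
        p = make_params(proc=(0.0, 1.0, 0.0))
        dist, upfront = af.run_periprocedural_tree(p)
        assert upfront == pytest.approx(5189.8)
        assert dist[S.EVENT_FREE_AF] == pytest.approx(1.0)

    def test_overfull_tree_rejected(self):
        p = make_params(proc=(0.7, 0.2, 0.0))
        p.proc_death = af.FixedProb(0.5)  # branches now sum to 1.4
        with pytest.raises(ParamError):
            af.run_periprocedural_tree(p)


class TestStepCycle:
    def test_dead_is_absorbing(self, table1):
        dist = np.zeros(N_STATES)
        dist[S.DEAD] = 1.0
        new, cost, qaly = af.step_cycle(dist, "aads", table1)
        assert new[S.DEAD] == 1.0 and cost == 0.0 and qaly == 0.0

    def test_stationary_healthy_cohort(self):
        p = make_params()  # no events, no mortality
        dist = np.zeros(N_STATES)
        dist[S.EVENT_FREE_AF] = 1.0
        new, _, qaly = af.step_cycle(dist, "aads", p)
        assert np.allclose(new, dist)
        assert qaly == pytest.approx(0.95)

    def test_dead_inflow_matches_all_cause_mortality(self, table1):
        """With a positive residual, the one-cycle death probability from the
        event-free state equals the arm's all-cause mortality (the
        decomposition removes event deaths and adds them back via fatality)."""
        assert residual_mortality(table1, "aads") > 0
        T = af.transition_matrix(table1, "aads")
        assert T[S.EVENT_FREE_AF, S.DEAD] == pytest.approx(101 / 8048)

    def test_ablation_residual_floored(self, table1):
        """Ablation event-fatality mass exceeds its printed all-cause
        mortality, so the residual floors at zero and event deaths set the
        death flux."""
        assert residual_mortality(table1, "ablation") == 0.0
        T = af.transition_matrix(table1, "ablation")
        expected = sum(
            table1.event_probs["ablation"][ev].prob * table1.fatality[ev].prob
            for ev in af.EVENT_TYPES
        )
        assert T[S.EVENT_FREE_AF, S.DEAD] == pytest.approx(expected)

    def test_gi_bleed_transient_contract(self, table1):
        dist = np.zeros(N_STATES)
        dist[S.GI_BLEED_TRANSIENT] = 1.0
        new, _, _ = af.step_cycle(dist, "aads", table1)
        assert new[S.EVENT_FREE_AF] + new[S.DEAD] == pytest.approx(1.0)

    def test_rejects_invalid_distribution(self, table1):
        with pytest.raises(ParamError):
            af.step_cycle(np.ones(N_STATES), "aads", table1)


class TestRunMarkov:
    def test_trivial_horizon_one(self):
        p = make_params(utilities={k: 1.0 for k in
                                   ("EVENT_FREE", "HF_HOSP", "MI", "ISCHEMIC_STROKE", "ICH")},
                        discount=0.0, horizon=1)
        res = af.run_markov("aads", p)
        assert res.total_qaly == pytest.approx(1.0)

    def test_mass_conservation(self, table1):
        for arm in af.ARMS:
            trace = af.run_markov(arm, table1).trace
            occ = trace[[s.name for s in HealthState]].to_numpy()
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
            assert (occ >= -1e-12).all()

    def test_total_bounds(self, table1):
        res = af.run_both_arms(table1)
        max_u = max(u.value for u in table1.utilities.values())
        for arm, r in res.items():
            assert r.total_qaly <= table1.horizon * max_u
        _, upfront = af.run_periprocedural_tree(table1)
        assert res["ablation"].total_cost >= upfront

    def test_no_event_cohort_accrues_horizon_times_utility(self):
        p = make_params(discount=0.0, horizon=13)
        res = af.run_markov("aads", p)
        assert res.total_qaly == pytest.approx(13 * 0.95)

    def test_utility_monotonicity(self, table1):
        from afibcea.sensitivity import set_params

        base = af.run_markov("aads", table1).total_qaly
        bumped = af.run_markov(
            "aads", set_params(table1, {"utility:ISCHEMIC_STROKE": 0.75})
        ).total_qaly
        assert bumped >= base

    def test_discount_monotonicity(self, table1):
        lo = af.run_markov("aads", table1.replace(discount_rate=0.02))
        hi = af.run_markov("aads", table1.replace(discount_rate=0.08))
        assert hi.total_cost <= lo.total_cost
        assert hi.total_qaly <= lo.total_qaly

    def test_errors(self, table1):
        with pytest.raises(ParamError):
            af.run_markov("surgery", table1)
        with pytest.raises(ParamError):
            table1.replace(horizon=0)

    def test_post_event_cost_switch_lowers_costs(self, table1):
        """Reverting post-event years to the maintenance cost must cut the
        totals: chronic states dominate late occupancy."""
        alt = table1.replace(post_event_cost="event_free")
        for arm in af.ARMS:
            assert af.run_markov(arm, alt).total_cost < af.run_markov(arm, table1).total_cost


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_transition_matrix_is_stochastic_for_random_params(seed):
    """Any valid parameter set yields a row-stochastic, non-negative matrix
    with an absorbing dead state."""
    params = random_params(np.random.default_rng(seed))
    for arm in af.ARMS:
        T = af.transition_matrix(params, arm)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)
        assert (T >= -1e-12).all()
        assert T[S.DEAD, S.DEAD] == 1.0


@settings(max_examples=10, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_totals_bounded_for_random_params(seed):
    params = random_params(np.random.default_rng(seed))
    max_u = max(u.value for u in params.utilities.values())
    for arm in af.ARMS:
        res = af.run_markov(arm, params)
        assert 0.0 <= res.total_qaly <= params.horizon * max_u + 1e-9
        assert res.total_cost >= 0.0


def test_small_cohort_oracle_agreement(table1):
    """Cohort algebra matches a 200k-patient microsimulation of the same
    generative process (quick check; the full-scale one runs in the
    acceptance suite)."""
    import oracle_microsim as oracle

    n = 200_000
    occ = oracle.simulate_occupancy(table1, "aads", n, seed=3)
    exact = af.run_markov("aads", table1).trace[[s.name for s in HealthState]].to_numpy()
    se = np.sqrt(exact * (1 - exact) / n)
    mask = exact * n >= 5
    z = np.abs(occ - exact) / np.where(se > 0, se, 1.0)
    assert (z[mask] <= 5.0).all()
    assert (z[mask] <= 3.0).mean() >= 0.99
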