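"""One-way DSA (tornado), discount sweep, and PSA behaviour."""

import numpy as np
import pandas as pd
import pytest

import afibcea as af
from afibcea.params import ParamError
from afibcea.sensitivity import (
    DSARange,
    PSADistribution,
    _two_arm_icer,
    get_param,
    set_params,
)

from conftest import make_params


class TestParamAddressing:
    def test_get_set_roundtrip(self, table1):
        for pid, new in [
            ("utility:HF_HOSP", 0.8),
            ("cost:event:ablation:ICH", 12345.0),
            ("cost:event_free:aads", 999.0),
            ("cost:procedure:TAMPONADE", 4000.0),
            ("prob:event:aads:MI", 0.02),
            ("prob:mortality:ablation", 0.01),
            ("prob:fatality:ICH", 0.3),
            ("prob:proc:stroke", 0.05),
        ]:
            assert get_param(table1, pid) != new
            assert get_param(set_params(table1, {pid: new}), pid) == pytest.approx(new)

    def test_unknown_id_rejected(self, table1):
        with pytest.raises(ParamError):
            get_param(table1, "prob:event:aads:BROKEN_LEG")
        with pytest.raises(ParamError):
            set_params(table1, {"nonsense": 1.0})

    def test_out_of_support_clamped_with_warning(self, table1):
        with pytest.warns(UserWarning, match="clamped"):
            p = set_params(table1, {"utility:ICH": 1.4})
        assert p.utilities["ICH"].value == 1.0
        with pytest.warns(UserWarning):
            p = set_params(table1, {"cost:event:aads:MI": -10.0})
        assert p.event_costs["aads"]["MI"] == 0.0

    def test_base_params_untouched(self, table1):
        before = table1.to_dict()
        set_params(table1, {"utility:HF_HOSP": 0.5, "prob:event:aads:MI": 0.05})
        assert table1.to_dict() == before


class TestTornado:
    def test_inert_parameter_has_zero_spread(self):
        """A fatality whose event never occurs cannot move the ICER."""
        p = make_params(
            probs_ablation={"HF_HOSP": 0.3},
            probs_aads={"HF_HOSP": 0.16, "MI": 0.01},
            mort_ablation=0.005,
            mort_aads=0.012,
            fatality={"HF_HOSP": 0.02},
            proc=(0.0, 0.0, 0.0),  # no periprocedural strokes
        )
        base = _two_arm_icer(p)
        table = af.one_way_dsa(
            p, [DSARange("prob:fatality:PROC_STROKE_TIA", 0.0, 0.5, "pm10pct")]
        )
        assert table["spread"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert table["icer_low"].iloc[0] == pytest.approx(base)

    def test_sorted_by_spread_and_base_attr(self, table1):
        ranges = af.default_dsa_ranges(table1)
        assert {r.source for r in ranges} == {"CI95", "pm10pct"}
        table = af.one_way_dsa(table1, ranges[:6] + ranges[-6:])
        spreads = table["spread"].to_numpy()
        assert (np.diff(spreads) <= 1e-9).all()
        assert "base_icer" in table.attrs

    def test_range_must_be_ordered(self):
        with pytest.raises(ParamError):
            DSARange("utility:ICH", 0.8, 0.5, "CI95")


def test_discount_sweep_monotone_and_continuous(table1):
    """Over a fine grid on [0, 0.07] the ICER moves smoothly and in one
    direction with the discount rate."""
    grid = np.linspace(0.0, 0.07, 15)
    icers = np.array(list(af.discount_sweep(table1, tuple(grid)).values()))
    diffs = np.diff(icers)
    assert (diffs < 0).all() or (diffs > 0).all()
    assert np.abs(diffs).max() < 0.2 * np.abs(icers).mean()


class TestCEAC:
    def test_hand_worked_three_replicates(self):
        """NMB at WTP 32,000: 16,000-2,000 > 0; 16,000-20,000 < 0;
        -3,200-1,000 < 0 — one replicate of three is cost-effective."""
        reps = pd.DataFrame(
            {"delta_effect": [0.5, 0.5, -0.1], "delta_cost": [2000.0, 20000.0, 1000.0]}
        )
        curve = af.ceac_curve(reps, [32_000.0, 50_000.0])
        assert curve[32_000.0] == pytest.approx(1 / 3)
        assert curve[50_000.0] == pytest.approx(2 / 3)

    def test_dominant_replicates_always_accepted(self):
        reps = pd.DataFrame({"delta_effect": [0.2, 0.4], "delta_cost": [-10.0, -5.0]})
        curve = af.ceac_curve(reps, [0.0, 10_000.0, 1e9])
        assert all(v == 1.0 for v in curve.values())

    def test_wtp_zero_is_probability_of_saving(self):
        rng = np.random.default_rng(0)
        reps = pd.DataFrame(
            {"delta_effect": rng.normal(0, 1, 400), "delta_cost": rng.normal(0, 1, 400)}
        )
        curve = af.ceac_curve(reps, [0.0])
        assert curve[0.0] == pytest.approx((reps["delta_cost"] < 0).mean())

    def test_empty_grid_rejected(self):
        reps = pd.DataFrame({"delta_effect": [0.1], "delta_cost": [1.0]})
        with pytest.raises(ParamError):
            af.ceac_curve(reps, [])


class TestPSA:
    def test_seeded_reproducibility(self, table1):
        a = af.run_psa(table1, n_reps=40, seed=9)
        b = af.run_psa(table1, n_reps=40, seed=9)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        assert a.ceac == b.ceac and a.quadrants == b.quadrants

    def test_point_mass_distributions_reproduce_base_case(self, table1):
        """Zero-variance sampling collapses the PSA onto the base case."""
        dists = [
            PSADistribution(pid, "normal", {"mu": get_param(table1, pid), "sigma": 0.0})
            for pid in [
                "prob:event:aads:HF_HOSP",
                "prob:mortality:ablation",
                "utility:EVENT_FREE",
            ]
        ]
        out = af.run_psa(table1, n_reps=5, seed=1, distributions=dists)
        res = af.run_both_arms(table1)
        assert out.replicates["cost_i"].std() == 0.0
        assert out.replicates["cost_i"].iloc[0] == pytest.approx(res["ablation"].total_cost)
        assert out.replicates["qaly_c"].iloc[0] == pytest.approx(res["aads"].total_qaly)
        base_icer = _two_arm_icer(table1)
        assert out.summary["icer"]["mean"] == pytest.approx(base_icer)

    def test_means_converge_to_base_with_shrinking_variance(self, table1):
        """As every hyperparameter variance is scaled toward zero the PSA
        means approach the deterministic totals."""
        base = af.run_both_arms(table1)

        def shrunk(scale):
            out = []
            for d in af.default_psa_distributions(table1):
                h = dict(d.hyperparameters)
                if d.family == "normal":
                    h["sigma"] *= scale
                elif d.family == "beta":
                    h = {"alpha": h["alpha"] / scale**2, "beta": h["beta"] / scale**2}
                else:  # gamma: keep the mean, shrink the CV
                    mean = h["shape"] * h["scale"]
                    h = {"shape": h["shape"] / scale**2, "scale": scale**2 * h["scale"]}
                    assert h["shape"] * h["scale"] == pytest.approx(mean)
                out.append(PSADistribution(d.parameter_id, d.family, h))
            return out

        errs = []
        for scale in (1.0, 0.3, 0.03):
            psa = af.run_psa(table1, n_reps=60, seed=2, distributions=shrunk(scale))
            errs.append(
                abs(psa.summary["intervention_cost"]["mean"] - base["ablation"].total_cost)
                + abs(psa.summary["comparator_qaly"]["mean"] - base["aads"].total_qaly)
            )
        assert errs[2] < errs[0]
        assert errs[2] < 0.01 * base["ablation"].total_cost

    def test_quadrants_sum_to_one_and_shapes(self, table1):
        out = af.run_psa(table1, n_reps=30, seed=4)
        assert sum(out.quadrants.values()) == pytest.approx(1.0)
        assert len(out.replicates) == 30
        assert set(out.ceac) == set(float(w) for w in np.arange(0, 100_001, 1000))

    def test_invalid_hyperparameters_named(self, table1):
        bad = [PSADistribution("prob:fatality:ICH", "beta", {"alpha": -3, "beta": 2})]
        with pytest.raises(ParamError, match="prob:fatality:ICH"):
            af.run_psa(table1, n_reps=3, seed=0, distributions=bad)
        with pytest.raises(ParamError):
            af.run_psa(table1, n_reps=0, seed=0)
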