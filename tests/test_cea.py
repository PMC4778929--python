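import numpy as np
import pandas as pd
import pytest

from tkrcea import config as cfg
from tkrcea.cea import (PSAResult, acceptability_frontier, evaluate_subgroup,
                        icer_ladder, nmb, run_psa, run_scenario)

#: Printed per-brand lifetime means for 70-year-olds (men, women):
#: cost then QALYs, order PFC Sigma / AGC Biomet / Nexgen / Genesis 2 / Triathlon.
PRINTED_MEANS = {
    "M": ([5900.0, 5226.0, 5721.0, 5799.0, 5600.0],
          [7.57, 7.50, 7.72, 7.38, 7.50]),
    "F": ([5876.0, 5166.0, 5696.0, 5756.0, 5553.0],
          [8.27, 8.20, 8.44, 8.06, 8.19]),
}


def printed_table(sex: str) -> pd.DataFrame:
    costs, qalys = PRINTED_MEANS[sex]
    return pd.DataFrame({"brand": list(cfg.BRANDS), "cost": costs,
                         "qalys": qalys})


class TestNMB:
    def test_zero_wtp_is_negative_cost(self):
        assert nmb(7.5, 5000.0, 0.0) == -5000.0

    def test_arithmetic_from_printed_means(self):
        # 20 000 x 7.72 - 5 721 (paper prints 148 658 from unrounded values)
        assert nmb(7.72, 5721.0, 20_000.0) == pytest.approx(148_679.0)

    def test_difference_linear_in_wtp(self):
        lams = np.array([0.0, 10_000.0, 20_000.0, 30_000.0])
        diff = nmb(7.72, 5721.0, lams) - nmb(7.50, 5226.0, lams)
        slopes = np.diff(diff) / np.diff(lams)
        assert np.allclose(slopes, slopes[0])

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            nmb(7.5, 5000.0, -1.0)


class TestICERLadder:
    @pytest.mark.parametrize("sex,icer", [("M", 495.0 / 0.22),
                                          ("F", 530.0 / 0.24)])
    def test_printed_means_reproduce_dominance_pattern(self, sex, icer):
        """On the printed lifetime means: Genesis 2, Triathlon and PFC Sigma
        are dominated, AGC Biomet is the base, and the Nexgen ICER matches the
        ratio of the printed increments."""
        out = icer_ladder(printed_table(sex)).set_index("brand")
        assert out.loc["AGC Biomet", "status"] == "base"
        for b in ("Genesis 2", "Triathlon", "PFC Sigma"):
            assert out.loc[b, "status"] == "dominated"
        assert out.loc["Nexgen", "status"] == "nondominated"
        assert out.loc["Nexgen", "icer"] == pytest.approx(icer, rel=1e-6)

    def test_equal_qalys_costlier_option_dominated(self):
        df = pd.DataFrame({"brand": ["A", "B"], "cost": [100.0, 200.0],
                           "qalys": [5.0, 5.0]})
        out = icer_ladder(df).set_index("brand")
        assert out.loc["A", "status"] == "base"
        assert out.loc["B", "status"] == "dominated"

    def test_extended_dominance_excludes_middle_option(self):
        # B's ICER vs A (200/QALY) exceeds C's vs B (33/QALY): B excluded and
        # the ladder jumps A -> C with ICER 150/2 = 75.
        df = pd.DataFrame({"brand": ["A", "B", "C"],
                           "cost": [0.0, 100.0, 150.0],
                           "qalys": [0.0, 0.5, 2.0]})
        out = icer_ladder(df).set_index("brand")
        assert out.loc["B", "status"] == "extendedly dominated"
        assert out.loc["C", "icer"] == pytest.approx(75.0)

    def test_icer_equals_nmb_crossing_wtp(self):
        """The ICER between two frontier options is the willingness-to-pay at
        which their NMBs are equal (algebraic identity)."""
        out = icer_ladder(printed_table("M")).set_index("brand")
        lam = out.loc["Nexgen", "icer"]
        n_nex = nmb(7.72, 5721.0, lam)
        n_agc = nmb(7.50, 5226.0, lam)
        assert n_nex == pytest.approx(n_agc, abs=1e-6)

    def test_requires_two_brands(self):
        with pytest.raises(ValueError):
            icer_ladder(pd.DataFrame({"brand": ["A"], "cost": [1.0],
                                      "qalys": [1.0]}))


def _degenerate_psa(qalys_by_brand, costs_by_brand, n=50):
    q = pd.DataFrame({b: np.full(n, v) for b, v in qalys_by_brand.items()})
    c = pd.DataFrame({b: np.full(n, v) for b, v in costs_by_brand.items()})
    p = pd.DataFrame({b: np.zeros(n) for b in qalys_by_brand})
    return PSAResult("M", 70, q, c, p)


class TestFrontier:
    def test_zero_wtp_frontier_is_cheapest_brand(self):
        costs, qalys = PRINTED_MEANS["M"]
        psa = _degenerate_psa(dict(zip(cfg.BRANDS, qalys)),
                              dict(zip(cfg.BRANDS, costs)))
        f = acceptability_frontier(psa, wtp_grid=[0.0])
        assert f.loc[0, "brand"] == "AGC Biomet"

    def test_degenerate_psa_probabilities_are_zero_or_one(self):
        costs, qalys = PRINTED_MEANS["M"]
        psa = _degenerate_psa(dict(zip(cfg.BRANDS, qalys)),
                              dict(zip(cfg.BRANDS, costs)))
        f = acceptability_frontier(psa, wtp_grid=[0.0, 20_000.0, 50_000.0])
        assert set(f["probability"]) <= {0.0, 1.0}
        probs = psa.probability_highest_nmb(20_000.0)
        assert set(probs) <= {0.0, 1.0}

    def test_probabilities_sum_to_one(self, small_models, small_run):
        psa = run_psa(small_models, "M", 70, n_sims=150, seed=3, run=small_run)
        probs = psa.probability_highest_nmb(20_000.0)
        assert probs.sum() == pytest.approx(1.0)

    def test_frontier_qalys_nondecreasing_in_wtp(self, small_models, small_run):
        psa = run_psa(small_models, "F", 70, n_sims=150, seed=4, run=small_run)
        f = acceptability_frontier(psa, wtp_grid=np.arange(0, 50_001, 5_000.0))
        mean_q = psa.qalys.mean()
        seq = [mean_q[b] for b in f["brand"]]
        assert all(b >= a - 1e-12 for a, b in zip(seq[:-1], seq[1:]))

    def test_empty_grid_rejected(self, small_models):
        psa = _degenerate_psa({"A": 1.0, "B": 2.0}, {"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError):
            acceptability_frontier(psa, wtp_grid=[])


class TestPSA:
    def test_same_seed_identical_draws(self, small_models, small_run):
        a = run_psa(small_models, "M", 70, n_sims=100, seed=9, run=small_run)
        b = run_psa(small_models, "M", 70, n_sims=100, seed=9, run=small_run)
        pd.testing.assert_frame_equal(a.qalys, b.qalys)
        pd.testing.assert_frame_equal(a.costs, b.costs)

    def test_mean_over_draws_near_point_estimate(self, small_models, small_run):
        from tkrcea.markov import run_cohort
        from tkrcea.pipeline import build_point_inputs
        psa = run_psa(small_models, "M", 70, n_sims=800, seed=10, run=small_run)
        for b in ("Nexgen", "AGC Biomet"):
            _, point = run_cohort(build_point_inputs(
                small_models, b, "M", 70, run=small_run))
            mc_se = psa.qalys[b].std() / np.sqrt(len(psa.qalys))
            assert abs(psa.qalys[b].mean() - point.qalys) < 4 * mc_se + 0.01


class TestScenarios:
    def test_scenario5_shrinks_cost_spread(self, small_data, small_models,
                                           small_run):
        base = evaluate_subgroup(small_models, "M", 70, run=small_run, seed=21)
        sc5 = run_scenario(5, small_data, small_models, "M", 70,
                           run=small_run, seed=21)
        spread = lambda t: t["cost"].max() - t["cost"].min()
        assert spread(sc5.psa_table) < spread(base.psa_table)

    def test_scenario1_reduces_qaly_spread(self, small_data, small_models,
                                           small_run):
        base = evaluate_subgroup(small_models, "M", 70, run=small_run, seed=22)
        sc1 = run_scenario(1, small_data, small_models, "M", 70,
                           run=small_run, seed=22)
        spread = lambda t: t["qalys"].max() - t["qalys"].min()
        assert spread(sc1.point_table) < spread(base.point_table)

    @pytest.mark.parametrize("scenario_id", [4, 5])
    def test_scenarios_produce_complete_tables(self, scenario_id, small_data,
                                               small_models, small_run):
        res = run_scenario(scenario_id, small_data, small_models, "F", 70,
                           run=small_run, seed=23)
        assert set(res.psa_table["brand"]) == set(cfg.BRANDS)
        assert res.p_best.sum() == pytest.approx(1.0)
        assert (res.psa_table["status"] == "base").sum() == 1

    def test_unknown_scenario_rejected(self, small_data, small_models,
                                       small_run):
        with pytest.raises(ValueError):
            run_scenario(9, small_data, small_models, "M", 70, run=small_run)
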