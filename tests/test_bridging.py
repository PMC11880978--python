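"""Dilution fits, pairwise ratios and the chained affinity-cancelling bridge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import blotbridge as bb
from blotbridge.synth import simulate_bridge_study


class TestDilutionFit:
    def test_perfectly_linear_uses_all_points(self):
        fit = bb.fit_dilution_response([(0.1, 10), (0.5, 50), (1.0, 100)])
        assert fit.slope == pytest.approx(100.0)
        assert (fit.used_points, fit.excluded_points) == (3, 0)

    def test_saturated_undiluted_lane_excluded(self):
        # origin line through the 1:10 lane predicts 100 at full load;
        # 60 < 0.8 * 100, so the undiluted lane is saturation-flagged
        fit = bb.fit_dilution_response([(0.1, 10), (0.5, 50), (1.0, 60)], 0.20)
        assert fit.slope == pytest.approx(100.0)
        assert (fit.used_points, fit.excluded_points) == (2, 1)

    def test_single_point_through_origin(self):
        fit = bb.fit_dilution_response([(0.5, 40)])
        assert fit.slope == pytest.approx(80.0)
        assert fit.used_points == 1

    def test_flagging_stops_at_first_linear_point(self):
        # middle lane is fine, so only the top lane can be flagged
        fit = bb.fit_dilution_response([(0.1, 10), (0.5, 50), (1.0, 70)], 0.20)
        assert fit.excluded_points == 1
        fit2 = bb.fit_dilution_response([(0.1, 10), (0.5, 35), (1.0, 95)], 0.20)
        # top lane within tolerance -> nothing below it is checked
        assert fit2.excluded_points == 0

    def test_all_zero_intensities_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            bb.fit_dilution_response([(0.1, 0.0), (1.0, 0.0)])


def _comparison(slopes=(200.0, 100.0), antibody="anti-X", analytes=("A", "B")):
    def lanes(analyte, slope, first_lane):
        return tuple(
            bb.BandRecord(
                experiment_id="e1", blot_id="b1", lane=first_lane + i,
                condition="WT", analyte=analyte, antibody=antibody,
                dilution=d, intensity=slope * d,
            )
            for i, d in enumerate((0.1, 0.5, 1.0))
        )

    return bb.PairwiseComparison(
        antibody=antibody, analyte_a=analytes[0], analyte_b=analytes[1],
        lanes_a=lanes(analytes[0], slopes[0], 1), lanes_b=lanes(analytes[1], slopes[1], 4),
    )


class TestPairwiseRatio:
    @pytest.mark.parametrize("slopes,expected", [((200, 100), 2.0), ((100, 100), 1.0)])
    def test_ratio_of_slopes(self, slopes, expected):
        assert bb.pairwise_ratio(_comparison(slopes)) == pytest.approx(expected)

    def test_affinity_cancels_for_known_amounts(self):
        # amounts 3:1 seen through one antibody with affinity 7.3
        affinity = 7.3
        comp = _comparison((affinity * 3.0, affinity * 1.0))
        assert bb.pairwise_ratio(comp) == pytest.approx(3.0, rel=1e-12)

    def test_mismatched_lane_antibody_rejected(self):
        good = _comparison()
        bad_lane = bb.BandRecord(
            experiment_id="e1", blot_id="b1", lane=9, condition="WT",
            analyte="A", antibody="anti-other", dilution=1.0, intensity=5.0,
        )
        with pytest.raises(ValueError, match="antibody"):
            bb.PairwiseComparison(
                antibody="anti-X", analyte_a="A", analyte_b="B",
                lanes_a=(bad_lane,), lanes_b=good.lanes_b,
            )


def _chain(r1=0.5, r2=1.0, r3=7.12):
    return bb.BridgeExperiment(
        experiment_id="e1",
        comp1=_comparison((100.0 * r1, 100.0), "anti-AXIN1", ("AXIN1", "GFP-AXIN1")),
        comp2=_comparison((100.0 * r2, 100.0), "anti-GFP", ("GFP-AXIN1", "GFP-AXIN2")),
        comp3=_comparison((100.0 * r3, 100.0), "anti-AXIN2", ("GFP-AXIN2", "AXIN2")),
    )


class TestChainedRatio:
    def test_product_of_pairwise_ratios(self):
        assert bb.chained_ratio(_chain(0.5, 1.0, 7.12)) == pytest.approx(3.56)

    def test_unit_chain(self):
        assert bb.chained_ratio(_chain(1, 1, 1)) == pytest.approx(1.0)

    def test_disconnected_chain_names_broken_link(self):
        with pytest.raises(ValueError, match="comparison 1 and 2"):
            bb.BridgeExperiment(
                experiment_id="e1",
                comp1=_comparison((50, 100), "anti-AXIN1", ("AXIN1", "GFP-AXIN1")),
                comp2=_comparison((100, 100), "anti-GFP", ("OTHER", "GFP-AXIN2")),
                comp3=_comparison((712, 100), "anti-AXIN2", ("GFP-AXIN2", "AXIN2")),
            )

    def test_noise_free_study_recovers_truth_for_arbitrary_affinities(
        self, noise_free_truth
    ):
        experiments = simulate_bridge_study(3.56, 3, noise_free_truth)
        for exp in experiments:
            assert bb.chained_ratio(exp) == pytest.approx(3.56, abs=1e-9)

    @given(
        a1=st.floats(0.01, 100.0),
        ag=st.floats(0.01, 100.0),
        a2=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, max_examples=40)
    def test_affinity_invariance(self, a1, ag, a2):
        truth = bb.SyntheticTruth(
            abundances={("SW480", "AXIN2"): 10.0},
            affinities={"anti-AXIN1": a1, "anti-GFP": ag, "anti-AXIN2": a2},
            lane_loading_cv=0.0, noise_sigma=0.0, seed=11,
        )
        (exp,) = simulate_bridge_study(3.56, 1, truth)
        assert bb.chained_ratio(exp) == pytest.approx(3.56, rel=1e-9)

    @pytest.mark.parametrize("gfp_scale", [0.1, 0.5, 2.0, 10.0])
    def test_gfp_construct_level_invariance(self, gfp_scale, noise_free_truth):
        # the absolute amount of the tagged constructs cancels as long as
        # both comparisons sharing a construct use the same lysate
        rng = np.random.default_rng(5)

        def study(scale):
            endo_a2, ratio = 10.0, 3.56
            endo_a1 = ratio * endo_a2
            gfp_a1, gfp_a2 = 30.0 * scale, 8.0 * scale
            t = noise_free_truth
            return bb.BridgeExperiment(
                experiment_id="e",
                comp1=_comparison(
                    (t.affinities["anti-AXIN1"] * endo_a1, t.affinities["anti-AXIN1"] * gfp_a1),
                    "anti-AXIN1", ("AXIN1", "GFP-AXIN1"),
                ),
                comp2=_comparison(
                    (t.affinities["anti-GFP"] * gfp_a1, t.affinities["anti-GFP"] * gfp_a2),
                    "anti-GFP", ("GFP-AXIN1", "GFP-AXIN2"),
                ),
                comp3=_comparison(
                    (t.affinities["anti-AXIN2"] * gfp_a2, t.affinities["anti-AXIN2"] * endo_a2),
                    "anti-AXIN2", ("GFP-AXIN2", "AXIN2"),
                ),
            )

        assert bb.chained_ratio(study(gfp_scale)) == pytest.approx(3.56, rel=1e-9)

    def test_single_matched_dilution_equals_full_fit(self, noise_free_truth):
        (exp,) = simulate_bridge_study(3.56, 1, noise_free_truth)
        full = bb.chained_ratio(exp)
        for d in (0.1, 0.5, 1.0):
            prod = 1.0
            for comp in (exp.comp1, exp.comp2, exp.comp3):
                ia = next(r.intensity for r in comp.lanes_a if r.dilution == d)
                ib = next(r.intensity for r in comp.lanes_b if r.dilution == d)
                prod *= ia / ib
            assert prod == pytest.approx(full, rel=1e-9)


class TestAggregateRatio:
    def test_identical_experiments_have_zero_sem(self, noise_free_truth):
        experiments = simulate_bridge_study(3.56, 6, noise_free_truth)
        est = bb.aggregate_ratio(experiments)
        assert est.mean == pytest.approx(3.56, abs=1e-9)
        assert est.sem == pytest.approx(0.0, abs=1e-9)
        assert est.n == 6

    def test_hand_computed_mean_and_sem(self):
        est = bb.RatioEstimate(per_experiment=(3.0, 4.0), mean=3.5, sem=0.5, n=2)
        experiments = [_chain(1.0, 1.0, r) for r in (3.0, 4.0)]
        got = bb.aggregate_ratio(experiments)
        assert got.mean == pytest.approx(est.mean)
        assert got.sem == pytest.approx(est.sem)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bb.aggregate_ratio([])

    def test_log_scale_aggregation_gives_geometric_mean(self):
        experiments = [_chain(1.0, 1.0, r) for r in (2.0, 8.0)]
        got = bb.aggregate_ratio(experiments, log_scale=True)
        assert got.mean == pytest.approx(4.0)

    def test_noisy_study_mean_within_three_sem_of_truth(self):
        truth = bb.SyntheticTruth(
            abundances={("SW480", "AXIN2"): 10.0},
            affinities={"anti-AXIN1": 5.0, "anti-GFP": 0.2, "anti-AXIN2": 11.0},
            lane_loading_cv=0.0, noise_sigma=0.10, seed=123,
        )
        experiments = simulate_bridge_study(
            3.56, 6, truth, rng=np.random.default_rng(123)
        )
        est = bb.aggregate_ratio(experiments)
        assert abs(est.mean - 3.56) < 3 * est.sem + 1e-12
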