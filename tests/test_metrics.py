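import numpy as np
import pytest

import dopaq
from dopaq.flow import Condition
from dopaq.metrics import GfpIndexModel, OxidationModel

from conftest import make_gated


def sensor_pair(shift, n=500, seed=0, timepoint=24.0):
    """Gated injured/uninjured sensor populations with a planted shift."""
    base = dict(n_worms=n, true_oxidation_shift=shift)
    inj = dopaq.simulate_copas_population(
        dopaq.PopulationParams(**base, seed=seed),
        Condition(treatment="injured", timepoint_h=timepoint),
    )
    uni = dopaq.simulate_copas_population(
        dopaq.PopulationParams(n_worms=n, seed=seed + 1),
        Condition(treatment="uninjured", timepoint_h=timepoint),
    )
    gate = lambda pop: dopaq.gate_mcherry(
        pop, dopaq.estimate_gate_threshold(pop.events["mcherry_peak"])
    )
    return gate(inj), gate(uni)


class TestBackgroundCorrectedRatio:
    def test_hand_evaluated_single_event(self):
        gated = make_gated(pos_405=[30.0], pos_488=[40.0], neg_405=[10.0], neg_488=[20.0])
        ratios, mean = dopaq.background_corrected_ratio(gated)
        assert ratios.tolist() == [1.0]
        assert mean == 1.0

    def test_background_only_signal_gives_zero(self):
        gated = make_gated(pos_405=[10.0, 10.0], pos_488=[40.0, 50.0],
                           neg_405=[10.0], neg_488=[20.0])
        ratios, _ = dopaq.background_corrected_ratio(gated)
        assert np.allclose(ratios, 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        pos405, pos488 = rng.uniform(20, 60, 50), rng.uniform(100, 200, 50)
        neg405, neg488 = rng.uniform(1, 5, 30), rng.uniform(1, 5, 30)
        r1, m1 = dopaq.background_corrected_ratio(make_gated(pos405, pos488, neg405, neg488))
        r2, m2 = dopaq.background_corrected_ratio(
            make_gated(2 * pos405, 2 * pos488, 2 * neg405, 2 * neg488)
        )
        assert np.allclose(r1, r2) and m1 == pytest.approx(m2)

    def test_signal_not_above_background_is_an_error(self):
        gated = make_gated(pos_405=[5.0], pos_488=[10.0], neg_405=[10.0], neg_488=[20.0])
        with pytest.raises(ValueError, match="background"):
            dopaq.background_corrected_ratio(gated)


class TestOxidationRatio:
    def test_self_comparison_is_exactly_zero(self):
        inj, _ = sensor_pair(0.5, n=200, seed=2)
        res = dopaq.oxidation_ratio(inj, inj)
        assert res.oxidation_ratio == 0.0

    def test_hand_evaluated_difference(self):
        injured = make_gated([30.0, 30.0], [40.0, 40.0], [10.0], [20.0], treatment="injured")
        uninjured = make_gated([20.0, 20.0], [40.0, 40.0], [10.0], [20.0])
        res = dopaq.oxidation_ratio(injured, uninjured)
        assert res.injured_mean == pytest.approx(1.0)
        assert res.uninjured_mean == pytest.approx(0.5)
        assert res.oxidation_ratio == pytest.approx(0.5)

    def test_antisymmetry(self):
        inj, uni = sensor_pair(0.3, n=300, seed=4)
        forward = dopaq.oxidation_ratio(inj, uni).oxidation_ratio
        backward = dopaq.oxidation_ratio(uni, inj).oxidation_ratio
        assert forward == pytest.approx(-backward)

    def test_planted_shift_recovered(self):
        inj, uni = sensor_pair(0.5, n=500, seed=6)
        res = dopaq.oxidation_ratio(inj, uni)
        assert abs(res.oxidation_ratio - 0.5) <= 0.05

    def test_timepoint_mismatch_rejected(self):
        inj, _ = sensor_pair(0.5, n=100, seed=8, timepoint=24.0)
        _, uni = sensor_pair(0.5, n=100, seed=9, timepoint=48.0)
        with pytest.raises(ValueError, match="time-matched"):
            dopaq.oxidation_ratio(inj, uni)

    def test_model_fit_bootstraps_a_ci(self):
        inj, uni = sensor_pair(0.5, n=300, seed=10)
        res = OxidationModel(inj, uni).fit(n_boot=100, seed=0)
        lo, hi = res.ci95
        assert lo <= res.oxidation_ratio <= hi
        assert "oxidation_ratio" in res.summary().index


class TestGfpRetention:
    def test_direct_division(self):
        res = dopaq.gfp_retention([60.0], 100.0)
        assert res.retention_delta == pytest.approx(0.6)

    def test_null_injury_retention_near_one(self):
        rng = np.random.default_rng(0)
        uninjured = rng.lognormal(5, 0.4, 1000)
        injured = rng.lognormal(5, 0.4, 1000)
        res = dopaq.gfp_retention(injured, float(uninjured.mean()))
        assert abs(res.retention_delta - 1.0) <= 0.03

    def test_planted_retention_recovered(self):
        inj = dopaq.simulate_copas_population(
            dopaq.PopulationParams(n_worms=2000, mosaic_rate=1.0, true_retention=0.6, seed=1),
            Condition(treatment="injured"),
        )
        uni = dopaq.simulate_copas_population(
            dopaq.PopulationParams(n_worms=2000, mosaic_rate=1.0, seed=2)
        )
        res = dopaq.gfp_retention(inj, float(np.mean(uni.head_peaks())))
        assert abs(res.retention_delta - 0.6) <= 0.02

    def test_nonpositive_uninjured_mean(self):
        with pytest.raises(ValueError, match="positive"):
            dopaq.gfp_retention([1.0], 0.0)


class TestGfpIndex:
    @pytest.mark.parametrize("control,test,expected", [
        (0.5, 0.5, 0.0),
        (0.5, 1.0, 1.0),
        (0.5, 0.75, 0.5),
    ])
    def test_hand_evaluated_formula(self, control, test, expected):
        assert dopaq.dopaminergic_gfp_index(control, test).index == pytest.approx(expected)

    def test_undefined_when_control_shows_no_loss(self):
        with pytest.raises(ValueError, match="no loss"):
            dopaq.dopaminergic_gfp_index(1.0, 0.5)

    def test_monotone_in_test_retention(self):
        control = 0.6
        grid = np.linspace(0.0, 1.2, 25)
        values = [dopaq.dopaminergic_gfp_index(control, t).index for t in grid]
        diffs = np.diff(values)
        assert np.all(diffs > 0)
        assert np.allclose(diffs, (grid[1] - grid[0]) / (1 - control))

    def test_invariance_under_global_rescale(self):
        rng = np.random.default_rng(5)
        ci, cu = rng.lognormal(5, 0.4, 400) * 0.6, rng.lognormal(5, 0.4, 400)
        ti, tu = rng.lognormal(5, 0.4, 400) * 0.9, rng.lognormal(5, 0.4, 400)

        def index(scale):
            c = dopaq.gfp_retention(ci * scale, float((cu * scale).mean())).retention_delta
            t = dopaq.gfp_retention(ti * scale, float((tu * scale).mean())).retention_delta
            return dopaq.dopaminergic_gfp_index(c, t).index

        assert index(1.0) == pytest.approx(index(7.5))

    def test_model_end_to_end_recovery(self):
        mk = lambda ret, s, tr: dopaq.simulate_copas_population(
            dopaq.PopulationParams(n_worms=2000, mosaic_rate=1.0, true_retention=ret, seed=s),
            Condition(treatment=tr),
        )
        model = GfpIndexModel(
            control_injured=mk(0.6, 1, "injured"),
            control_uninjured=mk(1.0, 2, "uninjured"),
            test_injured=mk(0.9, 3, "injured"),
            test_uninjured=mk(1.0, 4, "uninjured"),
        )
        res = model.fit(n_boot=200, seed=0)
        assert abs(res.index - 0.75) <= 0.05
        lo, hi = res.ci95
        assert lo < res.index < hi


class TestNormalizations:
    def test_double_normalize_anchors(self):
        assert dopaq.double_normalize(20.0, 10.0, 20.0) == pytest.approx(1.0)
        assert dopaq.double_normalize(10.0, 10.0, 20.0) == pytest.approx(0.0)
        assert dopaq.double_normalize(30.0, 10.0, 20.0) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            dopaq.double_normalize(5.0, 10.0, 10.0)

    def test_aging_timecourse_reference_cell_is_one(self):
        pops = []
        for arm in ("EV", "cat-1"):
            for day, scale in [(3.0, 1.0), (5.0, 0.8)]:
                pop = dopaq.simulate_copas_population(
                    dopaq.PopulationParams(
                        n_worms=200, mosaic_rate=1.0,
                        gfp488_log_mean=5.0 + np.log(scale), seed=int(day) + len(arm),
                    ),
                    Condition(treatment="uninjured", timepoint_h=day, rnai_or_drug=arm),
                )
                pops.append(pop)
        table = dopaq.aging_timecourse_normalize(pops, reference=("EV", 3.0))
        ref = table[(table["arm"] == "EV") & (table["timepoint_h"] == 3.0)]
        assert ref["normalized"].iloc[0] == pytest.approx(1.0)

    def test_aging_timecourse_recovers_planted_decay(self):
        rate = 0.7  # per-step multiplicative decline in one arm
        pops = []
        for step, day in enumerate([3.0, 6.0, 9.0]):
            for arm, decline in (("EV", 1.0), ("cat-1", rate**step)):
                pops.append(
                    dopaq.simulate_copas_population(
                        dopaq.PopulationParams(
                            n_worms=500, mosaic_rate=1.0,
                            gfp488_log_mean=5.0 + np.log(decline), seed=step * 10 + len(arm),
                        ),
                        Condition(treatment="uninjured", timepoint_h=day, rnai_or_drug=arm),
                    )
                )
        table = dopaq.aging_timecourse_normalize(pops, reference=("EV", 3.0))
        arm = table[table["arm"] == "cat-1"].sort_values("timepoint_h")
        ratios = arm["normalized"].to_numpy()
        expected = rate ** np.arange(3)
        assert np.all(np.abs(ratios / expected - 1.0) <= 0.05)

    def test_missing_reference_cell(self):
        pop = dopaq.simulate_copas_population(dopaq.PopulationParams(n_worms=50, seed=0))
        with pytest.raises(ValueError, match="reference"):
            dopaq.aging_timecourse_normalize([pop], reference=("EV", 99.0))
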