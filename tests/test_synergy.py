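import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from combindex import (
    CIResult,
    FixedRatioSynergy,
    MixtureDesign,
    additive_signal_expected,
    classify_ci,
    combination_index,
    confidence_interval95,
    isobologram,
    loewe_excess_grid,
    loewe_expected,
    simulate_interaction_study,
    webb_expected,
)

from conftest import median_effect_fit

BAND_EDGES = [0.5, 0.7, 0.9, 1.1, 1.5, 2.0]


class TestCombinationIndex:
    def test_half_dose_additivity(self):
        design = MixtureDesign(("a", "b"), (0.5, 0.5))
        # mixture delivers each agent at half its solo equi-effective dose
        assert combination_index(4.0, 4.0, 4.0, design) == pytest.approx(1.0)

    @pytest.mark.parametrize("w1", [0.1, 1 / 3, 20 / 21, 0.9])
    def test_sham_combination(self, w1):
        design = MixtureDesign(("a", "a2"), (w1, 1 - w1))
        # both components are the same agent: D1 = D2 = Dmix at any level
        assert combination_index(7.0, 7.0, 7.0, design) == pytest.approx(1.0, abs=1e-12)

    def test_non_positive_dose_rejected(self, ratio_design):
        with pytest.raises(ValueError, match="positive"):
            combination_index(0.0, 1.0, 1.0, ratio_design)

    def test_loewe_target_recovery_noiseless(self, ratio_design):
        for target in (0.6, 1.0, 1.8):
            datasets, design, _ = simulate_interaction_study(
                seed=3, target_ci=target, noise_sd=0.0)
            res = FixedRatioSynergy(datasets["carrier"], datasets["extract"],
                                    datasets["mixture"], design).fit()
            for r in res.ci_results:
                assert r.ci == pytest.approx(target, abs=1e-6)

    def test_loewe_target_recovery_noisy(self, ratio_design):
        cis = []
        for seed in range(10):
            datasets, design, _ = simulate_interaction_study(
                seed=seed, target_ci=0.8, noise_sd=0.01)
            res = FixedRatioSynergy(datasets["carrier"], datasets["extract"],
                                    datasets["mixture"], design,
                                    effect_levels=(50,)).fit()
            cis.append(res.ci_results[0].ci)
        assert np.mean(cis) == pytest.approx(0.8, abs=0.05)


class TestClassifyCI:
    @pytest.mark.parametrize(
        "ci, label, code",
        [
            (0.3, "very strong synergism", +2),
            (0.6, "strong synergism", +2),
            (0.86, "moderate synergism", +1),
            (1.0, "nearly additive", 0),
            (1.03, "nearly additive", 0),
            (1.29, "moderate antagonism", -1),
            (1.54, "moderate to strong antagonism", -2),
            (2.4, "strong antagonism", -3),
        ],
    )
    def test_band_labels(self, ci, label, code):
        assert classify_ci(ci) == (label, code)

    @pytest.mark.parametrize("edge", BAND_EDGES)
    def test_edges_fall_in_upper_band(self, edge):
        label_at_edge = classify_ci(edge)
        just_above = classify_ci(edge + 1e-9)
        assert label_at_edge == just_above

    @given(st.floats(1e-6, 10.0))
    @settings(max_examples=500, derandomize=True)
    def test_partition_no_gaps_no_overlaps(self, ci):
        label, code = classify_ci(ci)  # never raises inside (0, ∞)
        assert code in {-3, -2, -1, 0, 1, 2}

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            classify_ci(0.0)

    def test_ci_result_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CIResult(50.0, 0.86, 0.01, "strong antagonism", -3)


class TestConfidenceInterval:
    def test_zero_spread(self):
        mean, lo, hi = confidence_interval95([10.0, 10.0, 10.0])
        assert (mean, lo, hi) == (10.0, 10.0, 10.0)

    def test_hand_evaluation(self):
        mean, lo, hi = confidence_interval95([9.0, 10.0, 11.0])
        assert mean == pytest.approx(10.0)
        assert lo == pytest.approx(8.868, abs=5e-4)
        assert hi == pytest.approx(11.132, abs=5e-4)


class TestIsobologram:
    def test_additive_mixture_lies_on_line(self, ratio_design):
        datasets, design, _ = simulate_interaction_study(seed=5, target_ci=1.0, noise_sd=0.01)
        res = FixedRatioSynergy(datasets["carrier"], datasets["extract"],
                                datasets["mixture"], design, effect_levels=(50,)).fit()
        points = {p.kind: p for p in res.isobolograms[50.0]}
        solo = [p for p in res.isobolograms[50.0] if p.kind == "solo_intercept"]
        mix = points["mixture"]
        x_int = solo[0].axis1_dose
        y_int = solo[1].axis2_dose
        # distance from the additive line x/X + y/Y = 1, in CI units
        assert mix.axis1_dose / x_int + mix.axis2_dose / y_int == pytest.approx(1.0, abs=0.1)

    def test_interval_construction(self, ratio_design):
        points = isobologram(50.0, [9, 10, 11], [1, 1, 1], [5, 5, 5], ratio_design)
        solo_x = points[0]
        assert solo_x.x_ci95_low == pytest.approx(8.868, abs=5e-4)
        assert solo_x.x_ci95_high == pytest.approx(11.132, abs=5e-4)
        mix = points[2]
        w1, w2 = ratio_design.mass_fractions
        assert mix.axis1_dose == pytest.approx(5 * w1)
        assert mix.axis2_dose == pytest.approx(5 * w2)
        assert mix.x_ci95_low == pytest.approx(mix.axis1_dose)  # zero spread


class TestWebb:
    def test_neutral_element(self):
        assert webb_expected(0.0, 37.0) == pytest.approx(37.0)

    def test_saturation(self):
        assert webb_expected(100.0, 100.0) == pytest.approx(100.0)

    def test_hand_evaluation(self):
        assert webb_expected(30.0, 50.0) == pytest.approx(65.0)

    @given(a=st.floats(0, 100), b=st.floats(0, 100), c=st.floats(0, 100))
    @settings(max_examples=200, derandomize=True)
    def test_commutative_and_monotone(self, a, b, c):
        assert webb_expected(a, b) == pytest.approx(webb_expected(b, a), abs=1e-9)
        assert webb_expected(a, b) >= max(a, b) - 1e-9
        lo, hi = sorted((b, c))
        assert webb_expected(a, lo) <= webb_expected(a, hi) + 1e-9

    def test_above_hundred_rejected(self):
        with pytest.raises(ValueError):
            webb_expected(101.0, 10.0)


class TestAdditiveSignal:
    def test_identity_and_sum(self):
        assert additive_signal_expected(0.0, 0.43) == pytest.approx(0.43)
        assert additive_signal_expected(0.31, 0.12) == pytest.approx(0.43)

    def test_additive_construction_matches_experiment(self):
        # linear-assay mixture built additively: theoretical curve overlaps it
        slope1, slope2 = 0.004, 0.09
        w1, w2 = 20 / 21, 1 / 21
        for total in np.linspace(5, 100, 5):
            experimental = slope1 * w1 * total + slope2 * w2 * total
            theoretical = additive_signal_expected(slope1 * w1 * total, slope2 * w2 * total)
            assert theoretical == pytest.approx(experimental, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            additive_signal_expected(float("inf"), 0.1)


class TestLoeweExpected:
    def test_margin_consistency(self):
        f1 = median_effect_fit(1.5, 2.0)
        f2 = median_effect_fit(0.8, 10.0)
        assert loewe_expected(3.0, 0.0, f1, f2) == pytest.approx(f1.predict_fi(3.0))
        assert loewe_expected(0.0, 3.0, f1, f2) == pytest.approx(f2.predict_fi(3.0))

    def test_sham_split(self):
        fit = median_effect_fit(1.3, 5.0)
        whole = fit.predict_fi(8.0)
        assert loewe_expected(3.0, 5.0, fit, fit) == pytest.approx(whole, abs=1e-7)

    def test_residual_solved_to_tolerance(self):
        f1 = median_effect_fit(1.5, 2.0)
        f2 = median_effect_fit(0.8, 10.0)
        f = loewe_expected(1.0, 4.0, f1, f2)
        assert 1.0 / f1.ic_at(f) + 4.0 / f2.ic_at(f) == pytest.approx(1.0, abs=1e-9)

    def test_grid_oracle_agreement(self):
        """Bisection result matches a dense effect-grid scan."""
        rng = np.random.default_rng(7)
        fgrid = np.linspace(1e-6, 100 - 1e-6, 10**5)
        lratio = np.log10(fgrid / (100 - fgrid))
        for _ in range(10):
            m1, m2 = rng.uniform(0.5, 3, 2)
            i1, i2 = rng.uniform(0.2, 50, 2)
            f1, f2 = median_effect_fit(m1, i1), median_effect_fit(m2, i2)
            d1 = rng.uniform(0.05, 2) * i1
            d2 = rng.uniform(0.05, 2) * i2
            val = loewe_expected(d1, d2, f1, f2)
            D1 = 10 ** ((lratio - f1.n) / m1)
            D2 = 10 ** ((lratio - f2.n) / m2)
            fstar = fgrid[np.argmin(np.abs(d1 / D1 + d2 / D2 - 1))]
            assert val == pytest.approx(fstar, abs=2e-3)

    def test_out_of_bracket_warns(self):
        f1 = median_effect_fit(1.5, 2.0)
        f2 = median_effect_fit(1.5, 2.0)
        with pytest.warns(UserWarning, match="boundary"):
            val = loewe_expected(1e-9, 1e-9, f1, f2)
        assert val == pytest.approx(1e-6)


class TestLoeweExcessGrid:
    def test_null_surface_under_loewe(self):
        f1, f2 = median_effect_fit(1.5, 2.0), median_effect_fit(1.0, 8.0)
        d1 = np.geomspace(0.5, 8, 4)
        d2 = np.geomspace(1, 20, 4)
        observed = np.array([[loewe_expected(a, b, f1, f2) for b in d2] for a in d1])
        excess = loewe_excess_grid(observed, d1, d2, f1, f2)
        assert np.max(np.abs(excess)) < 0.01

    def test_margin_cell(self):
        f1, f2 = median_effect_fit(1.5, 2.0), median_effect_fit(1.0, 8.0)
        observed = np.array([[60.0]])
        excess = loewe_excess_grid(observed, [3.0], [0.0], f1, f2)
        assert excess[0, 0] == pytest.approx(60.0 - f1.predict_fi(3.0))

    def test_bliss_sign_pattern(self):
        f1, f2 = median_effect_fit(0.8, 2.0), median_effect_fit(0.7, 8.0)
        d1 = np.geomspace(0.5, 8, 3)
        d2 = np.geomspace(1, 20, 3)
        observed = np.array([[webb_expected(f1.predict_fi(a), f2.predict_fi(b))
                              for b in d2] for a in d1])
        excess = loewe_excess_grid(observed, d1, d2, f1, f2)
        analytic = np.array([[webb_expected(f1.predict_fi(a), f2.predict_fi(b))
                              - loewe_expected(a, b, f1, f2) for b in d2] for a in d1])
        assert np.all(np.sign(excess) == np.sign(analytic))

    def test_shape_mismatch_rejected(self):
        f1, f2 = median_effect_fit(1.5, 2.0), median_effect_fit(1.0, 8.0)
        with pytest.raises(ValueError, match="shape"):
            loewe_excess_grid(np.zeros((2, 3)), [1.0, 2.0], [1.0, 2.0], f1, f2)
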