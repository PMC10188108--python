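"""Cosinor fitting/comparison, circular statistics, attribution, alignment."""

import numpy as np
import pytest

from zeitconflict.compare import (
    align_half_period,
    circular_homogeneity_test,
    circular_summary,
    cosinor_fit,
    cosinor_group_comparison,
    rayleigh_test,
    watson_two_sample,
    zeitgeber_phase_attribution,
)
from zeitconflict.rhythm import lsp_power
from zeitconflict.synthetic import generate_phase_sample

from conftest import make_activity


@pytest.fixture(scope="module")
def t72():
    return np.arange(72.0)


class TestCosinorFit:
    def test_closed_form_recovery(self, t72):
        y = 5 + 2 * np.cos(2 * np.pi * (t72 - 18) / 24)
        fit = cosinor_fit(t72, y)
        assert fit.mesor == pytest.approx(5.0, abs=1e-10)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-10)
        assert fit.acrophase_h == pytest.approx(18.0, abs=1e-8)

    def test_constant_series_degenerate(self, t72):
        fit = cosinor_fit(t72, np.full(72, 3.0))
        assert fit.degenerate
        assert fit.amplitude == 0.0 and fit.acrophase_h == 0.0

    def test_amplitude_nearly_unbiased(self, t72):
        rng = np.random.default_rng(0)
        est = [
            cosinor_fit(t72, 1.0 * np.cos(2 * np.pi * t72 / 24) + rng.normal(0, 0.5, 72)).amplitude
            for _ in range(300)
        ]
        assert abs(np.mean(est) - 1.0) < 0.05

    def test_parameter_rmse_shrinks_with_noise(self, t72):
        rng = np.random.default_rng(1)
        rmse = []
        for sigma in (0.5, 0.05):
            err = [
                cosinor_fit(t72, 2 * np.cos(2 * np.pi * (t72 - 6) / 24)
                            + rng.normal(0, sigma, 72)).amplitude - 2.0
                for _ in range(50)
            ]
            rmse.append(np.sqrt(np.mean(np.square(err))))
        assert rmse[1] < rmse[0] / 5

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            cosinor_fit([0, 1, 2], [1, 2, 3])


class TestCosinorComparison:
    def test_planted_12h_shift(self, t72):
        rng = np.random.default_rng(4)
        y1 = 1.0 * np.cos(2 * np.pi * (t72 - 6) / 24) + rng.normal(0, 0.3, 72)
        y2 = 1.0 * np.cos(2 * np.pi * (t72 - 18) / 24) + rng.normal(0, 0.3, 72)
        res = cosinor_group_comparison(t72, y1, t72, y2)
        assert abs(abs(res.d_phase_h) - 12) < 0.5
        assert res.p_phase < 1e-6
        assert res.p_amplitude > 0.05

    def test_identical_groups_null(self, t72):
        rng = np.random.default_rng(5)
        hits = 0
        for i in range(40):
            base = np.cos(2 * np.pi * t72 / 24)
            y1 = base + rng.normal(0, 0.3, 72)
            y2 = base + rng.normal(0, 0.3, 72)
            res = cosinor_group_comparison(t72, y1, t72, y2)
            hits += (res.p_phase < 0.05) + (res.p_amplitude < 0.05) + (res.p_mesor < 0.05)
        assert hits <= 12  # ~5% of 120 tests under the null

    def test_halved_amplitude_recovered(self, t72):
        rng = np.random.default_rng(6)
        y1 = 2.0 * np.cos(2 * np.pi * t72 / 24) + rng.normal(0, 0.2, 72)
        y2 = 1.0 * np.cos(2 * np.pi * t72 / 24) + rng.normal(0, 0.2, 72)
        res = cosinor_group_comparison(t72, y1, t72, y2)
        assert res.d_amplitude == pytest.approx(-1.0, abs=0.1)
        assert res.p_amplitude < 1e-6

    def test_constant_group_flags_phase_undefined(self, t72):
        res = cosinor_group_comparison(
            t72, np.full(72, 1.0), t72, np.cos(2 * np.pi * t72 / 24)
        )
        assert res.phase_undefined
        assert np.isnan(res.d_phase_h)


class TestCircularSummary:
    def test_identical_phases(self):
        s = circular_summary([18, 18, 18])
        assert s.mean_direction_h == pytest.approx(18.0)
        assert s.resultant_length == pytest.approx(1.0)
        assert s.circular_variance == pytest.approx(0.0)

    def test_balanced_phases_cancel(self):
        s = circular_summary([0, 6, 12, 18])
        assert s.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert s.circular_variance == pytest.approx(1.0, abs=1e-12)

    def test_two_point_hand_computation(self):
        s = circular_summary([17, 19])
        assert s.mean_direction_h == pytest.approx(18.0, abs=1e-12)
        assert s.resultant_length == pytest.approx(np.cos(np.pi / 12), abs=1e-12)

    def test_rotation_invariant_resultant(self):
        rng = np.random.default_rng(2)
        ph = rng.uniform(0, 24, 50)
        r0 = circular_summary(ph).resultant_length
        r1 = circular_summary((ph + 7.3) % 24).resultant_length
        assert r0 == pytest.approx(r1, abs=1e-12)


class TestRayleigh:
    def test_fully_concentrated(self):
        assert rayleigh_test([12.0] * 24) < 1e-9

    def test_perfectly_uniform(self):
        assert rayleigh_test(np.arange(24.0)) > 0.99

    def test_matches_monte_carlo_small_n(self):
        # n=10 sample with moderate concentration
        ph = generate_phase_sample(10, 12.0, 1.2, seed=7)
        p_approx = rayleigh_test(ph)
        p_mc = rayleigh_test(ph, monte_carlo=True, n_mc=100_000, seed=0)
        assert abs(p_approx - p_mc) <= 0.005

    def test_small_sample_errors(self):
        with pytest.raises(ValueError):
            rayleigh_test([1.0, 2.0])


class TestWatson:
    def test_identical_samples_boundary(self):
        ph = np.array([1.0, 5.0, 9.0, 13.0])
        u2, p = watson_two_sample(ph, ph, n_boot=99, seed=0)
        assert p == 1.0

    def test_separated_von_mises_detected(self):
        hits = 0
        for s in range(20):
            a = generate_phase_sample(20, 6.0, 5.0, seed=2 * s)
            b = generate_phase_sample(20, 18.0, 5.0, seed=2 * s + 1)
            _, p = watson_two_sample(a, b, n_boot=499, seed=s)
            hits += p < 0.01
        assert hits >= 19

    def test_null_p_roughly_uniform(self):
        ps = []
        for s in range(60):
            a = generate_phase_sample(15, 6.0, 2.0, seed=3 * s)
            b = generate_phase_sample(15, 6.0, 2.0, seed=3 * s + 1)
            ps.append(watson_two_sample(a, b, n_boot=199, seed=s)[1])
        assert 0.2 < np.mean(ps)
        assert np.mean(np.array(ps) < 0.05) <= 0.15


class TestHomogeneity:
    def test_rotated_sample_detected(self):
        a = generate_phase_sample(100, 6.0, 3.0, seed=1)
        _, p = circular_homogeneity_test(a, (a + 6) % 24, n_mc=999, seed=0)
        assert p < 0.01

    def test_same_distribution_not_detected(self):
        a = generate_phase_sample(100, 6.0, 3.0, seed=2)
        b = generate_phase_sample(100, 6.0, 3.0, seed=3)
        _, p = circular_homogeneity_test(a, b, n_mc=999, seed=0)
        assert p > 0.05


class TestAttribution:
    def test_arithmetic_offset12(self):
        res = zeitgeber_phase_attribution([18.0], offset_h=12)
        assert res["d_light"][0] == 0.0
        assert res["d_temp"][0] == 12.0

    def test_equidistant_symmetry(self):
        res = zeitgeber_phase_attribution([0.0] * 10, offset_h=12)
        assert np.all(res["d_light"] == 6.0)
        assert np.all(res["d_temp"] == 6.0)
        assert res["verdict"] == "equidistant"

    def test_light_tracking_cohort(self):
        wins = 0
        for s in range(20):
            ph = generate_phase_sample(15, 18.0, 10.0, seed=s)
            wins += zeitgeber_phase_attribution(ph, offset_h=8)["verdict"] == "light-closer"
        assert wins >= 18

    def test_distance_bounds(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(0, 24, 200)
        res = zeitgeber_phase_attribution(ph, offset_h=6)
        assert np.all((res["d_light"] >= 0) & (res["d_light"] <= 12))
        assert np.all((res["d_temp"] >= 0) & (res["d_temp"] <= 12))


class TestAlignHalfPeriod:
    def _cohort(self, phases, t):
        out = []
        for i, ph in enumerate(phases):
            v = 0.5 + 0.5 * np.cos(2 * np.pi * (t - ph) / 24)
            out.append(make_activity(f"a{i}", v))
        return out

    def test_antiphase_cohort_aligns_to_24h(self):
        t = np.arange(72)
        series = self._cohort([6, 6, 6, 18, 18, 18], t)
        prof, res, asg = align_half_period(series, n_perm=199, seed=0)
        powers, peak, power = lsp_power(prof.zt_hours.astype(float), prof.mean,
                                        np.arange(6, 30.1, 0.25))
        assert peak == pytest.approx(24.0, abs=0.3)
        assert power == pytest.approx(1.0, abs=1e-6)
        assert sorted(asg["window"]) == [0, 0, 0, 1, 1, 1]

    def test_same_window_cohort_is_identity(self):
        t = np.arange(72)
        series = self._cohort([6, 7, 5], t)
        prof, _, asg = align_half_period(series, n_perm=99, seed=0)
        plain = np.mean([s.norm_distance for s in series], axis=0)
        assert np.allclose(prof.mean, plain)
        assert (asg["window"] == 0).all()

    def test_idempotent(self):
        t = np.arange(72)
        series = self._cohort([4, 16, 5, 17], t)
        prof1, _, _ = align_half_period(series, n_perm=99, seed=0)
        aligned_series = self._cohort([4, 4, 5, 5], t)
        prof2, _, asg2 = align_half_period(aligned_series, n_perm=99, seed=0)
        assert (asg2["window"] == 0).all()

    def test_12h_waveform_keeps_12h_peak(self):
        t = np.arange(72)
        series = []
        for i in range(6):
            v = 0.5 + 0.5 * np.cos(2 * np.pi * t / 12)
            series.append(make_activity(f"a{i}", v))
        prof, _, asg = align_half_period(series, n_perm=99, seed=0)
        assert asg["tie"].all()
        powers, peak, _ = lsp_power(prof.zt_hours.astype(float), prof.mean,
                                    np.arange(6, 30.1, 0.25))
        assert abs(peak - 12.0) < 0.3
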