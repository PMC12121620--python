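"""Noise-model fitting, pseudo p-values, coverage drop and peak calls."""

import math

import numpy as np
import pytest

from riboterm.calls import (
    NoiseModel,
    call_peak,
    coverage_drop,
    fit_noise_model,
    noise_region,
    pseudo_p_value,
)
from riboterm.coverage import CoverageProfile
from riboterm.edges import Peak


def make_peak(summit=1110, left=1100, right=1120, amplitude=2.0, sign=None):
    return Peak(
        locus_id="locus",
        readset_id="rs",
        condition_id="A",
        summit=summit,
        left_bound=left,
        right_bound=right,
        amplitude=amplitude,
        sign=sign or ("+" if amplitude > 0 else "-"),
    )


def peak_with_shape(width, amplitude):
    return make_peak(left=0, summit=0, right=width, amplitude=amplitude)


class TestNoiseRegion:
    def test_default_extensions(self):
        assert noise_region(1000, 1100, (-0.3, 1.0)) == (1030, 1200)

    def test_zero_extensions_give_riboswitch_itself(self):
        assert noise_region(1000, 1100, (0.0, 0.0)) == (1000, 1100)

    def test_degenerate_region_raises(self):
        with pytest.raises(ValueError):
            noise_region(1000, 1100, (-1.0, 0.0))

    def test_clipped_to_window(self):
        assert noise_region(1000, 1100, (-0.3, 1.0), window_length=1150) == (1030, 1150)


class TestNoiseModel:
    def test_mean_is_sample_mean(self):
        peaks = [
            peak_with_shape(4, 0.2),
            peak_with_shape(5, 0.25),
            peak_with_shape(6, 0.3),
        ]
        model = fit_noise_model(peaks)
        assert np.allclose(model.mean, [5.0, 0.25])
        assert model.n_peaks == 3

    def test_too_small_noise_set_returns_none(self):
        peaks = [peak_with_shape(4, 0.2), peak_with_shape(5, 0.25)]
        assert fit_noise_model(peaks) is None
        assert fit_noise_model(peaks + [peak_with_shape(6, 0.3)], exclude=peaks[0]) is None

    def test_identical_peaks_regularized_not_fatal(self):
        peaks = [peak_with_shape(5, 0.3) for _ in range(4)]
        model = fit_noise_model(peaks)
        assert model is not None
        assert np.linalg.det(model.covariance) > 0

    def test_recovers_known_mvn_moments(self, rng):
        mean = np.array([8.0, 1.2])
        cov = np.array([[4.0, 0.8], [0.8, 0.5]])
        draws = rng.multivariate_normal(mean, cov, size=200)
        peaks = [peak_with_shape(max(int(round(w)), 1), abs(a)) for w, a in draws]
        model = fit_noise_model(peaks)
        assert np.allclose(model.mean, mean, atol=0.4)
        assert np.allclose(model.covariance, cov, atol=1.0)


class TestPseudoP:
    def make_model(self):
        return NoiseModel(
            mean=np.array([5.0, 0.3]),
            covariance=np.array([[2.0, 0.0], [0.0, 0.05]]),
            n_peaks=10,
        )

    def test_peak_at_mean_has_p_one(self):
        model = self.make_model()
        assert pseudo_p_value(peak_with_shape(5, 0.3), model) == pytest.approx(1.0)

    def test_boundary_mahalanobis_gives_p_005(self):
        model = NoiseModel(np.array([1.0, 0.0]), np.eye(2), 10)
        d = math.sqrt(5.9915)
        p = pseudo_p_value(peak_with_shape(1, d), model)  # distance d on one axis
        assert p == pytest.approx(math.exp(-5.9915 / 2), rel=1e-6)
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_far_outlier_is_tiny(self):
        model = NoiseModel(np.array([1.0, 0.0]), np.eye(2), 10)
        p = pseudo_p_value(peak_with_shape(1, math.sqrt(50.0)), model)
        assert p == pytest.approx(math.exp(-25.0), rel=1e-9)

    def test_monotone_decreasing_in_mahalanobis_distance(self):
        model = self.make_model()
        widths = [5, 6, 8, 12, 20]
        ps = [pseudo_p_value(peak_with_shape(w, 0.3), model) for w in widths]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_monte_carlo_density_ranking(self, rng):
        """exp(-d^2/2) equals the probability a draw has lower density than the point."""
        mean = np.array([2.0, 1.0])
        cov = np.array([[1.5, 0.4], [0.4, 0.8]])
        model = NoiseModel(mean, cov, 10)
        point = np.array([3.5, 0.2])
        diff = point - mean
        d2 = float(diff @ np.linalg.solve(cov, diff))
        draws = rng.multivariate_normal(mean, cov, size=100_000)
        dd = draws - mean
        d2_draws = np.einsum("ij,ij->i", dd, np.linalg.solve(cov, dd.T).T)
        mc = (d2_draws > d2).mean()
        assert math.exp(-d2 / 2) == pytest.approx(mc, abs=0.004)

    def test_null_calibration_five_percent(self, rng):
        """Fitted on null draws, ~5% of fresh null peaks are significant."""
        mean = np.array([6.0, 0.5])
        cov = np.array([[3.0, 0.2], [0.2, 0.1]])
        fit_draws = rng.multivariate_normal(mean, cov, size=10_000)
        model = NoiseModel(fit_draws.mean(axis=0), np.cov(fit_draws, rowvar=False), 10_000)
        test_draws = rng.multivariate_normal(mean, cov, size=10_000)
        dd = test_draws - model.mean
        d2 = np.einsum("ij,ij->i", dd, np.linalg.solve(model.covariance, dd.T).T)
        frac = (np.exp(-d2 / 2) < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.01)


def uniform_profile(depth=100, window=2600, rs=1000, re=1100):
    p = CoverageProfile.empty("locus", "rs", "A", window, rs, re)
    p.read_coverage[:] = depth
    return p


class TestCoverageDrop:
    def test_drop_fraction_arithmetic(self):
        p = uniform_profile(100)
        p.read_coverage[1112:] = 70  # step down inside the peak
        peak = make_peak(summit=1110, left=1100, right=1120)
        # left bound coverage 100, exclusive right bound coverage 70, mean 100
        assert coverage_drop(peak, p) == pytest.approx(-0.30)

    def test_flat_coverage_gives_zero(self):
        p = uniform_profile(50)
        assert coverage_drop(make_peak(), p) == 0.0

    def test_zero_mean_coverage_is_an_error(self):
        p = uniform_profile(0)
        with pytest.raises(ValueError):
            coverage_drop(make_peak(), p)

    def test_termination_efficiency_recovered_in_simulation(self):
        """A locus where 40% of transcripts stop shows a ~-0.4 drop across the stop."""
        from riboterm.config import PipelineConfig
        from riboterm.coverage import build_profile
        from riboterm.edges import convolve_signed_termini, detect_peaks, make_kernel
        from riboterm.simulate import ConditionSpec, SimulationSpec, generate_dataset

        spec = SimulationSpec(
            seed=11,
            conditions={
                "A": ConditionSpec(n_readsets=1, n_transcripts=400,
                                   termination_efficiency=0.4)
            },
            terminator_jitter_sd=0.0,
            min_frag=1,  # no size selection, so coverage steps cleanly at the stop
        )
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            ds = generate_dataset(spec, td)
            profile = build_profile(
                ds.sam_paths["A_r0"], ds.window, "A_r0", "A", PipelineConfig()
            )
            conv = convolve_signed_termini(profile.signed_termini, make_kernel())
            peaks = detect_peaks(conv)
            term = max(
                (p for p in peaks if abs(p.summit - spec.terminator_position) < 10),
                key=lambda p: p.amplitude,
            )
            drop = coverage_drop(term, profile)
        assert drop == pytest.approx(-0.4, abs=0.06)


class TestCallPeak:
    def region_and_noise(self):
        region = (1030, 1200)
        rng = np.random.default_rng(5)
        noise = [
            make_peak(
                summit=int(s),
                left=int(s) - 4,
                right=int(s) + 5,
                amplitude=0.25 + 0.05 * rng.standard_normal(),
            )
            for s in rng.integers(1030, 1200, size=12)
        ]
        return region, noise

    def call(self, peak, depth_right=None, **kw):
        region, noise = self.region_and_noise()
        profile = uniform_profile(100)
        if depth_right is not None:
            profile.read_coverage[peak.summit + 2 :] = depth_right
        return call_peak(peak, noise + [peak], profile, region, **kw)

    def test_sharp_tall_peak_with_big_drop_passes(self):
        peak = make_peak(summit=1110, left=1100, right=1120, amplitude=8.0)
        call = self.call(peak, depth_right=40)
        assert call.decision == "pass"
        assert call.fail_reason == "none"
        assert call.pseudo_p < 0.05
        assert call.coverage_drop_fraction <= -0.20

    def test_significant_peak_with_small_drop_fails_on_drop(self):
        peak = make_peak(summit=1110, left=1100, right=1120, amplitude=8.0)
        call = self.call(peak, depth_right=90)
        assert call.decision == "fail"
        assert call.fail_reason == "insufficient_drop"

    def test_noise_like_peak_fails_significance_despite_drop(self):
        peak = make_peak(summit=1110, left=1106, right=1115, amplitude=0.25)
        call = self.call(peak, depth_right=40)
        assert call.decision == "fail"
        assert call.fail_reason == "not_significant"

    def test_negative_peak_fails_on_sign(self):
        peak = make_peak(summit=1110, left=1100, right=1120, amplitude=-3.0)
        assert self.call(peak).fail_reason == "wrong_sign"

    def test_peak_outside_region_fails_on_region(self):
        peak = make_peak(summit=500, left=490, right=510, amplitude=8.0)
        assert self.call(peak).fail_reason == "outside_region"

    def test_tiny_noise_set_fails_gracefully(self):
        peak = make_peak(summit=1110, left=1100, right=1120, amplitude=8.0)
        profile = uniform_profile(100)
        call = call_peak(peak, [peak], profile, (1030, 1200))
        assert call.fail_reason == "insufficient_noise_set"
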