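"""Equatorial WAXS inference chain: shapes, breadths, fits, size/disorder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from fibrilscatter.errors import ConfigurationError
from fibrilscatter.lattice import d_spacing
from fibrilscatter.profiles import AzimuthalProfile, RadialProfile
from fibrilscatter.simulate import (
    GroundTruth,
    generate_azimuthal,
    generate_equatorial_waxs,
    generate_pattern_grid,
)
from fibrilscatter.waxs import (
    PeakComponent,
    analyze_equatorial,
    asymmetric_200,
    fit_azimuthal,
    fit_equatorial,
    gaussian_peak,
    integral_breadth,
    reconstruct_equatorial,
    separate_size_disorder,
    size_disorder_from_fit,
    subtract_background,
)


class TestAsymmetric200:
    def test_height_at_maximum(self):
        for q0, sigma, h in [(15.59, 0.73, 100.0), (10.0, 2.0, 5.0)]:
            assert asymmetric_200(q0, q0, sigma, h) == pytest.approx(h, rel=1e-14)

    def test_low_q_side_augmented_by_printed_factor(self):
        q0, sigma, h = 15.59, 0.73, 100.0
        gauss = h * math.exp(-1.0 / (2 * sigma**2))
        assert asymmetric_200(q0 - 1.0, q0, sigma, h) == pytest.approx(gauss * 1.1, rel=1e-12)
        assert asymmetric_200(q0 + 1.0, q0, sigma, h) == pytest.approx(gauss, rel=1e-12)

    def test_asymmetric_area_exceeds_gaussian(self):
        for sigma in (0.3, 0.73, 1.5):
            f, _ = quad(lambda q: asymmetric_200(q, 15.59, sigma, 1.0), 5, 35)
            f0, _ = quad(lambda q: gaussian_peak(q, 15.59, sigma, 1.0), 5, 35)
            assert f > f0

    @settings(max_examples=50, derandomize=True)
    @given(
        sigma=st.floats(min_value=0.2, max_value=3.0),
        dq=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_never_below_symmetric_part(self, sigma, dq):
        q0 = 15.59
        f = asymmetric_200(q0 + dq, q0, sigma, 1.0)
        f0 = gaussian_peak(q0 + dq, q0, sigma, 1.0)
        if dq < 0:
            assert f >= f0
        else:
            assert f == pytest.approx(f0, rel=1e-14)


class TestIntegralBreadth:
    def test_unit_sigma(self):
        c = PeakComponent((2, 0, 0), "gaussian", 15.59, 1.0, 1.0)
        assert integral_breadth(c) == pytest.approx(2.5066, abs=1e-4)

    @pytest.mark.parametrize("sigma", [0.3, 0.73, 1.5])
    def test_matches_quadrature(self, sigma):
        c = PeakComponent((2, 0, 0), "gaussian", 15.59, 7.0, sigma)
        area, _ = quad(lambda q: gaussian_peak(q, 15.59, sigma, 7.0),
                       15.59 - 15 * sigma, 15.59 + 15 * sigma, epsabs=1e-13)
        assert integral_breadth(c) == pytest.approx(area / 7.0, abs=1e-10)
        assert integral_breadth(c) == pytest.approx(sigma * math.sqrt(2 * math.pi), rel=1e-14)

    def test_asymmetric_defined_on_symmetric_part(self):
        # the low-q augmentation is excluded from the breadth by definition
        g = PeakComponent((2, 0, 0), "gaussian", 15.59, 1.0, 0.73)
        a = PeakComponent((2, 0, 0), "asymmetric200", 15.59, 1.0, 0.73, 0.1)
        assert integral_breadth(a) == integral_breadth(g) == pytest.approx(1.830, abs=1e-3)


class TestSubtractBackground:
    def test_zero_baseline_roundtrip(self):
        q = np.linspace(5, 35, 800)
        inten = gaussian_peak(q, 15.59, 0.73, 100.0)
        prof = RadialProfile(q, inten)
        out = subtract_background(prof)
        assert np.max(np.abs(out.intensity - inten)) < 0.5

    def test_known_power_law_recovered(self):
        q = np.linspace(5, 35, 1500)
        peak = gaussian_peak(q, 15.59, 0.73, 100.0)
        bg = 200.0 * q**-1.5 + 2.0
        prof = RadialProfile(q, peak + bg)
        out = subtract_background(prof)
        true_area = 100.0 * 0.73 * math.sqrt(2 * math.pi)
        got_area = np.trapezoid(out.intensity[(q > 13) & (q < 18)], q[(q > 13) & (q < 18)])
        assert got_area == pytest.approx(true_area, rel=0.02)

    def test_near_idempotent(self):
        q = np.linspace(5, 35, 1500)
        bg = 200.0 * q**-1.5 + 2.0
        prof = RadialProfile(q, gaussian_peak(q, 15.59, 0.73, 100.0) + bg)
        once = subtract_background(prof)
        twice = subtract_background(once)
        assert np.max(np.abs(twice.intensity - once.intensity)) < 0.01 * np.max(bg)

    def test_single_window_rejected(self, simple_profile):
        with pytest.raises(ConfigurationError):
            subtract_background(simple_profile, anchor_windows=[(1.0, 4.0)])

    def test_empty_window_rejected(self):
        q = np.linspace(5, 35, 100)
        prof = RadialProfile(q, np.ones_like(q))
        with pytest.raises(ConfigurationError):
            subtract_background(prof, anchor_windows=[(5, 6.5), (40, 42)])


class TestFitAzimuthal:
    def test_single_gaussian_degenerate(self):
        truth = GroundTruth.bamboo(seed=0, noise_fraction=0.0,
                                   orientation_widths=(15.0, 60.0, 1.0))
        az = generate_azimuthal(truth)
        fit = fit_azimuthal(az)
        assert fit.narrow[1] == pytest.approx(15.0, rel=0.01)
        assert fit.wide[2] <= 0.01 * fit.narrow[2]

    def test_mixture_recovery_over_seeds(self):
        hits = 0
        for seed in range(20):
            truth = GroundTruth.bamboo(seed=seed)
            fit = fit_azimuthal(generate_azimuthal(truth))
            ok = (abs(fit.narrow[1] - 15.0) / 15.0 < 0.05
                  and abs(fit.wide[1] - 60.0) / 60.0 < 0.05)
            hits += ok
        assert hits >= 18

    def test_flat_profile_zero_area_components(self):
        ang = np.linspace(-90, 90, 181)
        fit = fit_azimuthal(AzimuthalProfile(ang, np.full_like(ang, 3.0)))
        total = fit.narrow[2] + fit.wide[2]
        assert total < 1e-6 or fit.residual_rms < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_azimuthal(AzimuthalProfile(np.arange(10.0), np.ones(10)))


class TestReconstructEquatorial:
    def test_noiseless_grid_matches_oriented_component(self, noiseless_truth):
        q = np.arange(5.0, 35.0, 0.1)
        grid = generate_pattern_grid(noiseless_truth, q_grid=q)
        rec = reconstruct_equatorial(grid)
        # oriented part = narrow fraction of the reflections, no background
        from fibrilscatter.simulate import _equatorial_peaks

        oriented = _equatorial_peaks(noiseless_truth, q, noiseless_truth.peak_heights)
        corr = np.corrcoef(rec.intensity, oriented)[0, 1]
        assert corr > 0.995

    def test_downstream_size_recovery_with_noise(self):
        truth = GroundTruth.bamboo(seed=3)
        q = np.arange(5.0, 35.0, 0.1)
        grid = generate_pattern_grid(truth, q_grid=q)
        rec = reconstruct_equatorial(grid)
        fit = fit_equatorial(rec, with_100=True)
        broad = size_disorder_from_fit(fit)
        assert broad.L == pytest.approx(truth.column_length_200, rel=0.05)


class TestFitEquatorial:
    def test_noiseless_recovery(self):
        # exactly background-free signal: the fit's contract assumes the
        # background has been removed cleanly
        truth = GroundTruth.bamboo(seed=0, noise_fraction=0.0, background=(0.0, 1.5, 0.0))
        prof = generate_equatorial_waxs(truth)
        fit = fit_equatorial(prof, with_100=True)
        for comp in fit.components:
            q0_true = 2 * math.pi / d_spacing(truth.cell, comp.hkl[0], comp.hkl[1])
            assert comp.q0 == pytest.approx(q0_true, rel=0.002)
        assert fit.d_spacings[(2, 0, 0)] == pytest.approx(0.403, abs=5e-4)

    def test_missing_400_gives_zero_area(self, noiseless_truth):
        truth = GroundTruth.bamboo(seed=0, noise_fraction=0.0)
        truth.peak_heights = dict(truth.peak_heights)
        truth.peak_heights[(4, 0, 0)] = 0.0
        prof = generate_equatorial_waxs(truth, q_grid=np.arange(5.0, 35.0, 0.02))
        ref = fit_equatorial(subtract_background(
            generate_equatorial_waxs(noiseless_truth)), with_100=True)
        fit = fit_equatorial(subtract_background(prof), with_100=True)
        c400 = fit.component((4, 0, 0))
        assert c400.height * c400.sigma < 0.01 * fit.component((2, 0, 0)).height
        for hkl in [(1, -1, 0), (1, 1, 0), (2, 0, 0)]:
            assert fit.component(hkl).q0 == pytest.approx(ref.component(hkl).q0, rel=0.01)

    def test_ordering_constraint_holds(self):
        for seed in range(3):
            prof = generate_equatorial_waxs(GroundTruth.bamboo(seed=seed))
            fit = fit_equatorial(subtract_background(prof), with_100=True)
            q0s = [fit.component(h).q0 for h in [(1, -1, 0), (1, 1, 0), (2, 0, 0), (4, 0, 0)]]
            assert q0s == sorted(q0s)

    def test_narrow_coverage_rejected(self):
        q = np.linspace(9.0, 20.0, 200)
        prof = RadialProfile(q, np.ones_like(q))
        with pytest.raises(ConfigurationError):
            fit_equatorial(prof)


class TestSeparateSizeDisorder:
    # forward-constructed oracle: delta_q = 2 pi / L + (pi/2) g^2 q0^2 d
    L_TRUE, G_TRUE, D200 = 3.84, 0.036, 0.403

    def _law(self, q0):
        return 2 * math.pi / self.L_TRUE + (math.pi / 2) * self.G_TRUE**2 * q0**2 * self.D200

    def test_two_point_exact_solve(self):
        q200 = 2 * math.pi / self.D200
        points = [(q200, self.D200, self._law(q200)), (2 * q200, self.D200, self._law(2 * q200))]
        fit = separate_size_disorder(points)
        assert fit.L == pytest.approx(3.84, rel=1e-9)
        assert fit.g == pytest.approx(0.036, rel=1e-9)
        assert fit.L == 2 * math.pi / fit.delta_q0
        assert fit.slope == pytest.approx((math.pi / 2) * 0.036**2, rel=1e-9)

    def test_equal_breadths_zero_disorder(self):
        fit = separate_size_disorder([(15.59, 0.403, 1.7), (31.18, 0.403, 1.7)])
        assert fit.g == pytest.approx(0.0, abs=1e-6)
        assert fit.L == pytest.approx(2 * math.pi / 1.7, rel=1e-6)

    def test_negative_slope_warns_and_zeroes_disorder(self):
        with pytest.warns(UserWarning, match="negative broadening slope"):
            fit = separate_size_disorder([(15.59, 0.403, 2.0), (31.18, 0.403, 1.5)])
        assert fit.g == 0.0
        assert fit.delta_q0 == pytest.approx(1.75, rel=1e-9)

    def test_collinear_triple_matches_pair(self):
        q200 = 2 * math.pi / self.D200
        qs = [q200, 1.5 * q200, 2 * q200]
        points = [(q, self.D200, self._law(q)) for q in qs]
        three = separate_size_disorder(points)
        two = separate_size_disorder([points[0], points[2]])
        assert three.L == pytest.approx(two.L, rel=1e-9)
        assert three.g == pytest.approx(two.g, rel=1e-9)

    def test_matches_brute_force_grid_search(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            npts = rng.integers(2, 6)
            q0s = np.sort(rng.uniform(10, 35, npts))
            d = 0.403
            dq0_true = rng.uniform(1.0, 2.5)
            slope_true = rng.uniform(1e-4, 4e-3)
            pts = [(q0, d, dq0_true + slope_true * q0**2 * d) for q0 in q0s]
            pts = [(q0, d, dq + rng.normal(0, 1e-3)) for q0, d, dq in pts]
            fit = separate_size_disorder(pts)
            # independent oracle: zooming grid search over (dq0, slope)
            x = np.array([q0**2 * d for q0, _, _ in pts])
            y = np.array([dq for _, _, dq in pts])
            lo = np.array([0.5, 0.0])
            hi = np.array([3.5, 8e-3])
            for _ in range(12):
                dq0g = np.linspace(lo[0], hi[0], 41)
                slg = np.linspace(lo[1], hi[1], 41)
                dd, ss = np.meshgrid(dq0g, slg, indexing="ij")
                cost = ((dd[..., None] + ss[..., None] * x - y) ** 2).sum(axis=-1)
                i, j = np.unravel_index(np.argmin(cost), cost.shape)
                span = (hi - lo) / 8
                centre = np.array([dq0g[i], slg[j]])
                lo = np.maximum(centre - span, [1e-6, 0.0])
                hi = centre + span
            assert fit.delta_q0 == pytest.approx(centre[0], abs=1e-6)
            assert fit.slope == pytest.approx(centre[1], abs=1e-6)

    def test_degenerate_negative_intercept(self):
        with pytest.raises(ConfigurationError, match="Scherrer"):
            separate_size_disorder([(10.0, 0.4, 0.5), (30.0, 0.4, 8.0)])

    def test_too_few_points(self):
        with pytest.raises(ConfigurationError):
            separate_size_disorder([(15.59, 0.403, 1.8)])


class TestAnalyzeEquatorial:
    def test_noiseless_end_to_end_within_one_percent(self, noiseless_truth):
        prof = generate_equatorial_waxs(noiseless_truth)
        res = analyze_equatorial(prof)
        assert res.broadening.L == pytest.approx(noiseless_truth.column_length_200, rel=0.01)
        assert res.broadening.g == pytest.approx(noiseless_truth.disorder_g, rel=0.01)
        assert res.fit.d_spacings[(2, 0, 0)] == pytest.approx(noiseless_truth.d200(), rel=0.01)
        assert res.cell.gamma == pytest.approx(noiseless_truth.cell.gamma, abs=0.1)

    def test_noisy_size_recovery_majority(self):
        # mirrors the reported +/-0.13 nm uncertainty on L = 3.84 nm
        hits = 0
        for seed in range(8):
            res = analyze_equatorial(generate_equatorial_waxs(GroundTruth.bamboo(seed=100 + seed)))
            hits += abs(res.broadening.L - 3.84) <= 0.13
        assert hits >= 7
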