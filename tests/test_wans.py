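"""Absorption correction, H/D differencing and meridional detection."""

import math

import numpy as np
import pytest

from fibrilscatter.errors import ConfigurationError, UnsupportedGeometryError
from fibrilscatter.profiles import RadialProfile, q_to_two_theta
from fibrilscatter.simulate import GroundTruth, generate_wans_pair
from fibrilscatter.wans import (
    CuboidSample,
    absorption_factor,
    check_equatorial_consistency,
    correct_absorption,
    detect_meridional,
    difference_profile,
    fit_difference_lobe,
    fit_hd_pair,
)

Q_1M10_TRUE = 2 * math.pi / 0.5849379742541144  # bamboo-cell 1-10 position


def mc_absorption(sample, two_theta, n_paths=10**6, seed=0):
    """Monte-Carlo path-sampling oracle for the cuboid transmission factor."""
    rng = np.random.default_rng(seed)
    t = sample.thickness_along_beam
    x = rng.uniform(0.0, t, n_paths)
    sec = 1.0 / math.cos(math.radians(two_theta))
    return float(np.mean(np.exp(-sample.mu * (x + (t - x) * sec))))


class TestAbsorptionFactor:
    def test_straight_through_limit(self):
        sample = CuboidSample(thickness_along_beam=0.1, width=2.0, height=1.0, mu=1.0)
        assert absorption_factor(sample, 0.0) == pytest.approx(math.exp(-0.1), rel=1e-9)

    def test_transparent_sample(self):
        sample = CuboidSample(0.1, 2.0, 1.0, mu=0.0)
        for tt in (0.0, 20.0, 60.0):
            assert absorption_factor(sample, tt) == 1.0

    def test_monotone_in_mu_and_thickness(self):
        factors = [absorption_factor(CuboidSample(0.1, 5.0, 1.0, mu), 30.0)
                   for mu in (0.5, 1.0, 2.0, 5.0)]
        assert all(b < a for a, b in zip(factors, factors[1:]))
        factors = [absorption_factor(CuboidSample(t, 5.0, 1.0, 2.0), 30.0)
                   for t in (0.05, 0.1, 0.2)]
        assert all(b < a for a, b in zip(factors, factors[1:]))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sample = CuboidSample(rng.uniform(0.02, 0.3), 10.0, 1.0, rng.uniform(0.1, 8.0))
            f = absorption_factor(sample, rng.uniform(0.0, 60.0))
            assert 0.0 < f <= 1.0

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            sample = CuboidSample(
                thickness_along_beam=rng.uniform(0.05, 0.3),
                width=20.0,
                height=1.0,
                mu=rng.uniform(0.5, 5.0),
            )
            tt = rng.uniform(0.0, 70.0)
            quad_val = absorption_factor(sample, tt)
            mc_val = mc_absorption(sample, tt, n_paths=2 * 10**6, seed=rng.integers(2**31))
            assert quad_val == pytest.approx(mc_val, abs=5e-4)

    def test_wide_cuboid_example(self):
        sample = CuboidSample(0.5, 50.0, 1.0, mu=1.0)  # mu*t = 0.5
        assert absorption_factor(sample, 60.0) == pytest.approx(
            mc_absorption(sample, 60.0), abs=1e-3)

    def test_side_face_exit_unsupported(self):
        narrow = CuboidSample(1.0, 0.5, 1.0, mu=1.0)
        with pytest.raises(UnsupportedGeometryError):
            absorption_factor(narrow, 60.0)

    def test_angle_range_enforced(self):
        sample = CuboidSample(0.1, 2.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            absorption_factor(sample, 95.0)


class TestCorrectAbsorption:
    def _profile(self):
        q = np.linspace(5.0, 30.0, 200)
        return RadialProfile(q, np.full_like(q, 10.0),
                             meta={"radiation": "neutron", "wavelength_nm": 0.242})

    def test_transparent_is_identity(self):
        prof = self._profile()
        out = correct_absorption(prof, CuboidSample(0.1, 5.0, 1.0, mu=0.0))
        np.testing.assert_allclose(out.intensity, prof.intensity, rtol=1e-12)

    def test_recovers_premultiplied_profile(self):
        prof = self._profile()
        sample = CuboidSample(0.1, 5.0, 1.0, mu=3.0)
        tts = q_to_two_theta(prof.q, 0.242)
        factors = np.array([absorption_factor(sample, tt) for tt in tts])
        attenuated = RadialProfile(prof.q, prof.intensity * factors, meta=dict(prof.meta))
        out = correct_absorption(attenuated, sample)
        np.testing.assert_allclose(out.intensity, prof.intensity, rtol=1e-6)

    def test_double_correction_refused(self):
        prof = self._profile()
        sample = CuboidSample(0.1, 5.0, 1.0, mu=1.0)
        once = correct_absorption(prof, sample)
        with pytest.raises(ConfigurationError, match="already"):
            correct_absorption(once, sample)

    def test_missing_wavelength_rejected(self):
        q = np.linspace(5.0, 30.0, 50)
        prof = RadialProfile(q, np.ones_like(q))
        with pytest.raises(ConfigurationError, match="wavelength"):
            correct_absorption(prof, CuboidSample(0.1, 5.0, 1.0, 1.0))


class TestDifferenceProfile:
    def test_identical_inputs_give_zeros(self, noiseless_truth):
        h, _, _, _ = generate_wans_pair(noiseless_truth)
        diff = difference_profile(h, h, normalisation="none")
        np.testing.assert_allclose(diff.delta_intensity, 0.0, atol=1e-12)

    def test_antisymmetric_under_swap(self, bamboo_truth):
        h, d, _, _ = generate_wans_pair(bamboo_truth)
        ab = difference_profile(d, h, normalisation="none")
        ba = difference_profile(h, d, normalisation="none")
        np.testing.assert_allclose(ab.delta_intensity, -ba.delta_intensity, rtol=1e-12)

    def test_lobe_signs_match_deuteration_scales(self, noiseless_truth):
        h, d, _, _ = generate_wans_pair(noiseless_truth)
        diff = difference_profile(d, h, normalisation="window")
        j_1m10 = np.argmin(np.abs(diff.q - Q_1M10_TRUE))
        j_200 = np.argmin(np.abs(diff.q - 2 * math.pi / 0.403))
        assert diff.delta_intensity[j_1m10] < 0
        assert diff.delta_intensity[j_200] > 0

    def test_disjoint_ranges_rejected(self):
        a = RadialProfile(np.linspace(1, 5, 10), np.ones(10))
        b = RadialProfile(np.linspace(10, 20, 10), np.ones(10))
        with pytest.raises(ConfigurationError):
            difference_profile(a, b)

    def test_resampling_flagged(self, noiseless_truth):
        h, d, _, _ = generate_wans_pair(noiseless_truth)
        h2 = RadialProfile(h.q[::2], h.intensity[::2], meta=dict(h.meta))
        diff = difference_profile(d, h2, normalisation="none")
        assert diff.resampled

    def test_lobe_fit_localises_blended_dip(self, noiseless_truth):
        h, d, _, _ = generate_wans_pair(noiseless_truth)
        diff = difference_profile(d, h, normalisation="window")
        lobe = fit_difference_lobe(diff, window=(9.2, 12.2), sign=-1)
        assert lobe["amplitude"] < 0
        # single-lobe centroid sits between the 1-10 and 110 dips, within ~1%
        assert lobe["q0"] == pytest.approx(Q_1M10_TRUE, rel=0.012)


class TestHDPairFit:
    def test_noiseless_localises_1m10_exactly(self, noiseless_truth):
        h, d, _, _ = generate_wans_pair(noiseless_truth)
        pair = fit_hd_pair(h, d)
        assert pair.q_1m10 == pytest.approx(Q_1M10_TRUE, rel=0.005)
        assert pair.q_110 == pytest.approx(2 * math.pi / 0.564870758525772, rel=0.005)

    def test_noisy_localisation_within_realistic_scatter(self):
        h, d, _, _ = generate_wans_pair(GroundTruth.bamboo(seed=0))
        pair = fit_hd_pair(h, d)
        assert pair.q_1m10 == pytest.approx(Q_1M10_TRUE, rel=0.015)

    def test_mismatched_grids_rejected(self, noiseless_truth):
        h, d, _, _ = generate_wans_pair(noiseless_truth)
        d2 = RadialProfile(d.q[::2], d.intensity[::2], meta=dict(d.meta))
        with pytest.raises(ConfigurationError):
            fit_hd_pair(h, d2)


class TestConsistency:
    def test_identical_fits_pass(self, noiseless_truth):
        h, d, _, _ = generate_wans_pair(noiseless_truth)
        pair = fit_hd_pair(h, d)
        report = check_equatorial_consistency(pair.h_fit, pair.h_fit)
        assert report["pass"]
        assert all(v == 0.0 for v in report["relative_differences"].values())

    def test_shifted_200_fails_and_names_offender(self, noiseless_truth):
        h, d, _, _ = generate_wans_pair(noiseless_truth)
        pair = fit_hd_pair(h, d)
        shifted = pair.d_fit
        comp = shifted.component((2, 0, 0))
        comp.q0 *= 1.02
        shifted.d_spacings = {c.hkl: c.d for c in shifted.components}
        report = check_equatorial_consistency(pair.h_fit, shifted)
        assert not report["pass"]
        assert (2, 0, 0) in report["offenders"]

    def test_synthetic_pair_shares_lattice(self, bamboo_truth):
        h, d, _, _ = generate_wans_pair(bamboo_truth)
        pair = fit_hd_pair(h, d)
        report = check_equatorial_consistency(pair.h_fit, pair.d_fit)
        assert report["pass"]


def test_end_to_end_absorption_difference_localisation(noiseless_truth):
    """Attenuated H/D pair -> absorption correction -> joint fit pins 1-10.

    The corrected profiles must localise the 1-10 reflection to better than
    0.5% of the generative position even though the raw patterns cannot
    separate it from 110.
    """
    h, d, _, _ = generate_wans_pair(noiseless_truth)
    sample = CuboidSample(0.1, 5.0, 1.0, mu=2.5)
    tts = q_to_two_theta(h.q, 0.242)
    factors = np.array([absorption_factor(sample, tt) for tt in tts])
    h_att = RadialProfile(h.q, h.intensity * factors, meta=dict(h.meta))
    d_att = RadialProfile(d.q, d.intensity * factors, meta=dict(d.meta))
    h_corr = correct_absorption(h_att, sample)
    d_corr = correct_absorption(d_att, sample)
    diff = difference_profile(d_corr, h_corr, normalisation="window")
    j = np.argmin(diff.delta_intensity)
    assert diff.q[j] == pytest.approx(Q_1M10_TRUE, rel=0.02)  # blended dip
    pair = fit_hd_pair(h_corr, d_corr)
    assert pair.q_1m10 == pytest.approx(Q_1M10_TRUE, rel=0.005)


class TestDetectMeridional:
    def test_00l_detected_in_difference(self, bamboo_truth):
        _, _, h_mer, d_mer = generate_wans_pair(bamboo_truth)
        diff = difference_profile(d_mer, h_mer, normalisation="none")
        hits = {r["l"]: r for r in detect_meridional(diff, fibre_repeat_c=1.038)}
        assert hits[1]["detected"] and hits[1]["q"] == pytest.approx(6.05, abs=0.1)
        assert hits[2]["detected"] and hits[2]["q"] == pytest.approx(12.11, abs=0.1)

    def test_h_form_alone_detects_nothing(self, bamboo_truth):
        _, _, h_mer, _ = generate_wans_pair(bamboo_truth)
        zero = difference_profile(h_mer, h_mer, normalisation="none")
        # add the generator's own noise level so the noise estimate is honest
        rng = np.random.default_rng(0)
        noisy = type(zero)(zero.q, rng.normal(0.0, 0.02, len(zero.q)), 1.0)
        results = detect_meridional(noisy, fibre_repeat_c=1.038)
        assert not any(r["detected"] for r in results)

    def test_threshold_above_peak_detects_nothing(self, bamboo_truth):
        _, _, h_mer, d_mer = generate_wans_pair(bamboo_truth)
        diff = difference_profile(d_mer, h_mer, normalisation="none")
        results = detect_meridional(diff, fibre_repeat_c=1.038, threshold_sigma=1e9)
        assert not any(r["detected"] for r in results)
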