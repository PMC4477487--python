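"""Seeded synthetic-pattern generator with known ground truth.

No instrument data ship with the package; every analysis stage is instead
exercised on synthetic profiles whose generative parameters (the
``GroundTruth``) are known exactly, enabling parameter-recovery tests.  The
generator emulates the observable structure of well-oriented cellulose
fibre patterns:

* equatorial WAXS/WANS profiles — 1-10/110/200/400 (and an optional weak
  100) reflections at monoclinic hk0 lattice positions over a power-law
  background, the 200 carrying the asymmetric low-q tail and the 200/400
  breadths following the size + disorder broadening law
  delta-q = 2 pi / L + (pi/2) g^2 q0^2 d200;
* azimuthal orientation profiles — a narrow plus a wide Gaussian over a
  constant background;
* 2D q x azimuth grids with the oriented reflections modulated by the dual
  orientation distribution and an isotropic background;
* SANS profiles — one broad Bragg peak whose amplitude scales with the
  squared solvent contrast (delta-rho)^2, vanishing at the match point;
* paired H/D WANS profiles — deuteration rescales reflection intensities
  without moving them, and meridional 00l peaks appear only in the D form.

Noise is multiplicative Gaussian (sd = noise_fraction x local intensity) by
default, with a Poisson option; identical GroundTruth (including the seed)
regenerates bit-identical arrays.  The default parameter values are the
bamboo reference conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dataclass_fields

import numpy as np

from .errors import ConfigurationError
from .lattice import MonoclinicCell, d_spacing
from .profiles import AzimuthalProfile, PatternGrid, RadialProfile
from .sans import contrast_factor
from .waxs import FWHM_PER_SIGMA, asymmetric_200, gaussian_peak

__all__ = ["GroundTruth", "WAVELENGTHS_NM",
           "generate_equatorial_waxs", "generate_azimuthal",
           "generate_pattern_grid", "generate_sans", "generate_wans_pair"]

WAVELENGTHS_NM = {"x-ray-Cu": 0.15406, "x-ray-Mo": 0.07071, "neutron": 0.242}

# per-technique stream tags so each generator draws an independent,
# reproducible noise stream from one seed
_STREAM = {"waxs": 1, "azimuthal": 2, "grid": 3, "sans": 4,
           "wans_h": 5, "wans_d": 6, "wans_h_mer": 7, "wans_d_mer": 8}


def _default_cell() -> MonoclinicCell:
    # a chosen so that d200 = (a/2) sin(gamma) = 0.403 nm at gamma = 92 deg
    return MonoclinicCell(a=2.0 * 0.403 / math.sin(math.radians(92.0)), b=0.820, gamma=92.0)


@dataclass
class GroundTruth:
    """Full generative parameter set; defaults are the bamboo reference conditions.

    Lengths in nm, q in nm^-1, angles in degrees.  ``peak_heights`` maps hk0
    tuples to relative heights; ``orientation_widths`` is (narrow FWHM, wide
    FWHM, narrow area fraction); ``sans_spacing`` maps D2O volume fraction to
    interfibril spacing (linearly interpolated between entries);
    ``deuteration_scale`` multiplies reflection heights in the D form;
    ``background`` is (power-law amplitude, exponent, constant) for the
    wide-angle profiles.
    """

    cell: MonoclinicCell = field(default_factory=_default_cell)
    fibre_repeat_c: float = 1.038
    column_length_200: float = 3.84
    disorder_g: float = 0.036
    peak_heights: dict = field(default_factory=lambda: {
        (1, -1, 0): 35.0, (1, 1, 0): 50.0, (2, 0, 0): 100.0,
        (4, 0, 0): 8.0, (1, 0, 0): 5.0,
    })
    orientation_widths: tuple = (15.0, 60.0, 0.6)
    sans_spacing: dict = field(default_factory=lambda: {0.0: 2.96, 0.25: 3.19})
    sans_breadth: float = 0.35
    deuteration_scale: dict = field(default_factory=lambda: {
        (2, 0, 0): 1.1, (1, -1, 0): 0.5, (1, 1, 0): 0.9,
    })
    background: tuple = (200.0, 1.5, 2.0)
    noise_fraction: float = 0.01
    seed: int = 0
    # secondary generator knobs
    overlap_width_factor: float = 1.5  # 1-10/110/100 breadth vs the 200 breadth
    sans_amplitude: float = 50.0
    sans_background: tuple = (0.5, 3.0, 0.5)
    azimuthal_area: float = 100.0
    azimuthal_background: float = 2.0
    meridional_heights: dict = field(default_factory=lambda: {1: 20.0, 2: 10.0})
    meridional_sigma: float = 0.4
    meridional_background: float = 2.0
    noise_model: str = "relative"  # "relative" | "poisson"

    def __post_init__(self):
        if self.column_length_200 <= 0:
            raise ValueError("column_length_200 must be positive")
        if not 0.0 <= self.disorder_g < 0.2:
            raise ValueError("disorder_g must be in [0, 0.2)")
        narrow, wide, frac = self.orientation_widths
        if not 0.0 < frac <= 1.0:  # 1.0 = degenerate single-component case
            raise ValueError("narrow_fraction must be in (0, 1]")
        if narrow >= wide:
            raise ConfigurationError(
                "narrow_fwhm must be smaller than wide_fwhm (the labels would lie)"
            )
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be non-negative")
        if self.noise_model not in ("relative", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @classmethod
    def bamboo(cls, seed: int = 0, **overrides) -> "GroundTruth":
        """The bamboo conditions with a chosen seed (and optional overrides)."""
        return cls(seed=seed, **overrides)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def key(hkl):
            return ",".join(str(i) for i in hkl) if isinstance(hkl, tuple) else str(hkl)

        out = {}
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, MonoclinicCell):
                v = {"a": v.a, "b": v.b, "gamma": v.gamma}
            elif isinstance(v, dict):
                v = {key(k): val for k, val in v.items()}
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        def unkey(s):
            if isinstance(s, str) and "," in s:
                return tuple(int(p) for p in s.split(","))
            try:
                return int(s)
            except (TypeError, ValueError):
                return float(s)

        kwargs = dict(data)
        if "cell" in kwargs and isinstance(kwargs["cell"], dict):
            kwargs["cell"] = MonoclinicCell(**kwargs["cell"])
        for name in ("peak_heights", "sans_spacing", "deuteration_scale", "meridional_heights"):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = {unkey(k): float(v) for k, v in kwargs[name].items()}
        for name in ("orientation_widths", "background", "sans_background"):
            if name in kwargs and isinstance(kwargs[name], list):
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)

    # -- derived quantities -------------------------------------------------

    def d200(self) -> float:
        return d_spacing(self.cell, 2, 0)

    def sigma_for(self, hkl: tuple) -> float:
        """Generative Gaussian width (nm^-1) of a reflection.

        200 and 400 follow the broadening law evaluated at their own q0 with
        the family spacing d200; the other equatorial reflections are wider
        than the 200 by ``overlap_width_factor``.
        """
        d2 = self.d200()
        q0_200 = 2.0 * math.pi / d2

        def law(q0):
            dq = 2.0 * math.pi / self.column_length_200 \
                + (math.pi / 2.0) * self.disorder_g**2 * q0**2 * d2
            return dq / math.sqrt(2.0 * math.pi)

        if tuple(hkl) in ((2, 0, 0), (4, 0, 0)):
            return law(2.0 * math.pi / d_spacing(self.cell, hkl[0], hkl[1]))
        return self.overlap_width_factor * law(q0_200)


def _rng(truth: GroundTruth, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(truth.seed) % (2**31), _STREAM[stream], extra])


def _apply_noise(intensity: np.ndarray, truth: GroundTruth, rng) -> np.ndarray:
    if truth.noise_model == "poisson":
        return rng.poisson(np.clip(intensity, 0.0, None)).astype(float)
    if truth.noise_fraction == 0.0:
        return intensity
    return intensity * (1.0 + truth.noise_fraction * rng.standard_normal(len(intensity)))


def _wide_angle_background(truth: GroundTruth, q: np.ndarray) -> np.ndarray:
    amp, exponent, const = truth.background
    return amp * np.power(q, -exponent) + const


def _equatorial_peaks(truth: GroundTruth, q: np.ndarray, heights: dict) -> np.ndarray:
    total = np.zeros_like(q)
    for hkl, height in heights.items():
        if height == 0.0:
            continue
        q0 = 2.0 * math.pi / d_spacing(truth.cell, hkl[0], hkl[1])
        sigma = truth.sigma_for(hkl)
        if tuple(hkl) == (2, 0, 0):
            total += asymmetric_200(q, q0, sigma, height)
        else:
            total += gaussian_peak(q, q0, sigma, height)
    return total


def _check_wide_angle_grid(truth: GroundTruth, q: np.ndarray) -> None:
    if (4, 0, 0) in truth.peak_heights and truth.peak_heights[(4, 0, 0)] != 0.0:
        q400 = 2.0 * math.pi / d_spacing(truth.cell, 4, 0)
        if q400 > q[-1] or q400 < q[0]:
            raise ConfigurationError(
                f"q grid [{q[0]:.2f}, {q[-1]:.2f}] does not contain the 400 "
                f"reflection at q = {q400:.2f} nm^-1"
            )


def default_waxs_grid() -> np.ndarray:
    """5-35 nm^-1 at 0.02 nm^-1 spacing."""
    return np.arange(5.0, 35.0 + 1e-9, 0.02)


def default_sans_grid() -> np.ndarray:
    """0.4-2.8 nm^-1 at 0.01 nm^-1 spacing."""
    return np.arange(0.4, 2.8 + 1e-9, 0.01)


def generate_equatorial_waxs(
    truth: GroundTruth, q_grid=None, radiation: str = "x-ray-Cu"
) -> RadialProfile:
    """Noisy equatorial wide-angle profile: background + reflections."""
    q = default_waxs_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    _check_wide_angle_grid(truth, q)
    clean = _wide_angle_background(truth, q) + _equatorial_peaks(truth, q, truth.peak_heights)
    noisy = _apply_noise(clean, truth, _rng(truth, "waxs"))
    return RadialProfile(q, noisy, meta={
        "radiation": radiation,
        "wavelength_nm": WAVELENGTHS_NM[radiation],
        "axis": "equatorial",
    })


def generate_azimuthal(truth: GroundTruth, angle_grid=None) -> AzimuthalProfile:
    """Azimuthal orientation profile: narrow + wide Gaussian over a constant."""
    ang = (np.arange(-90.0, 90.0 + 1e-9, 0.5) if angle_grid is None
           else np.asarray(angle_grid, dtype=float))
    if ang[-1] - ang[0] < 180.0 - 1e-9:
        raise ConfigurationError("angle grid must cover at least 180 degrees")
    narrow_fwhm, wide_fwhm, frac = truth.orientation_widths
    if narrow_fwhm >= wide_fwhm:
        raise ConfigurationError("narrow_fwhm must be smaller than wide_fwhm")
    sig_n = narrow_fwhm / FWHM_PER_SIGMA
    sig_w = wide_fwhm / FWHM_PER_SIGMA
    kern = (frac * np.exp(-ang**2 / (2 * sig_n**2)) / (sig_n * math.sqrt(2 * math.pi))
            + (1 - frac) * np.exp(-ang**2 / (2 * sig_w**2)) / (sig_w * math.sqrt(2 * math.pi)))
    clean = truth.azimuthal_area * kern + truth.azimuthal_background
    noisy = _apply_noise(clean, truth, _rng(truth, "azimuthal"))
    return AzimuthalProfile(ang, noisy)


def generate_pattern_grid(truth: GroundTruth, q_grid=None, angle_grid=None) -> PatternGrid:
    """2D q x azimuth grid: oriented reflections times the dual-Gaussian
    orientation kernel, plus an isotropic background."""
    q = default_waxs_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ang = (np.arange(-90.0, 90.0 + 1e-9, 1.0) if angle_grid is None
           else np.asarray(angle_grid, dtype=float))
    _check_wide_angle_grid(truth, q)
    narrow_fwhm, wide_fwhm, frac = truth.orientation_widths
    if narrow_fwhm >= wide_fwhm:
        raise ConfigurationError("narrow_fwhm must be smaller than wide_fwhm")
    sig_n = narrow_fwhm / FWHM_PER_SIGMA
    sig_w = wide_fwhm / FWHM_PER_SIGMA
    kern = (frac * np.exp(-ang**2 / (2 * sig_n**2)) / (sig_n * math.sqrt(2 * math.pi))
            + (1 - frac) * np.exp(-ang**2 / (2 * sig_w**2)) / (sig_w * math.sqrt(2 * math.pi)))
    peaks = _equatorial_peaks(truth, q, truth.peak_heights)
    iso = _wide_angle_background(truth, q) / (ang[-1] - ang[0])
    clean = np.outer(peaks, kern) + iso[:, None]
    rng = _rng(truth, "grid")
    if truth.noise_model == "poisson":
        noisy = rng.poisson(np.clip(clean, 0.0, None)).astype(float)
    elif truth.noise_fraction == 0.0:
        noisy = clean
    else:
        noisy = clean * (1.0 + truth.noise_fraction * rng.standard_normal(clean.shape))
    return PatternGrid(q, ang, noisy)


def interfibril_spacing(truth: GroundTruth, d2o_fraction: float) -> float:
    """Ground-truth interfibril spacing at a D2O fraction (linear interpolation)."""
    fracs = np.array(sorted(truth.sans_spacing))
    vals = np.array([truth.sans_spacing[f] for f in fracs])
    return float(np.interp(d2o_fraction, fracs, vals))


def generate_sans(truth: GroundTruth, d2o_fraction: float, q_grid=None) -> RadialProfile:
    """SANS profile: decaying background + one contrast-scaled Bragg peak.

    The peak amplitude is proportional to (delta-rho)^2 between cellulose
    and the D2O/H2O mixture, normalised to the pure-D2O contrast, so it
    vanishes exactly at the contrast-match fraction.
    """
    if not 0.0 <= d2o_fraction <= 1.0:
        raise ValueError("d2o_fraction must be in [0, 1]")
    q = default_sans_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    amp_bg, exponent, const = truth.sans_background
    clean = amp_bg * np.power(q, -exponent) + const
    scale = contrast_factor(d2o_fraction) / contrast_factor(1.0)
    if truth.sans_amplitude * scale > 0.0:
        q_pk = 2.0 * math.pi / interfibril_spacing(truth, d2o_fraction)
        clean = clean + truth.sans_amplitude * scale * np.exp(
            -((q - q_pk) ** 2) / (2.0 * truth.sans_breadth**2)
        )
    rng = _rng(truth, "sans", extra=int(round(d2o_fraction * 10000)))
    noisy = _apply_noise(clean, truth, rng)
    return RadialProfile(q, noisy, meta={
        "radiation": "neutron",
        "wavelength_nm": 0.35,
        "axis": "equatorial",
        "d2o_fraction": float(d2o_fraction),
    })


def generate_wans_pair(truth: GroundTruth, q_grid=None, meridional_q_grid=None):
    """Paired H/D wide-angle neutron profiles.

    Returns (H equatorial, D equatorial, H meridional, D meridional).  The D
    equatorial profile is the H profile with per-reflection heights
    multiplied by ``deuteration_scale`` (positions unchanged); meridional
    00l peaks at q = 2 pi l / c are present only in the D form.
    """
    for hkl in ((1, -1, 0), (2, 0, 0)):
        if hkl not in truth.deuteration_scale:
            raise ConfigurationError(f"deuteration_scale lacks an entry for {hkl}")
    q = default_waxs_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    qm = (np.arange(3.0, 16.0 + 1e-9, 0.02) if meridional_q_grid is None
          else np.asarray(meridional_q_grid, dtype=float))
    _check_wide_angle_grid(truth, q)

    meta = {"radiation": "neutron", "wavelength_nm": WAVELENGTHS_NM["neutron"]}
    bg = _wide_angle_background(truth, q)
    h_clean = bg + _equatorial_peaks(truth, q, truth.peak_heights)
    d_heights = {hkl: h * truth.deuteration_scale.get(hkl, 1.0)
                 for hkl, h in truth.peak_heights.items()}
    d_clean = bg + _equatorial_peaks(truth, q, d_heights)

    mer_bg = np.full_like(qm, truth.meridional_background)
    mer_d_clean = mer_bg.copy()
    for l, height in truth.meridional_heights.items():
        q0 = 2.0 * math.pi * l / truth.fibre_repeat_c
        mer_d_clean = mer_d_clean + gaussian_peak(qm, q0, truth.meridional_sigma, height)

    h_eq = RadialProfile(q, _apply_noise(h_clean, truth, _rng(truth, "wans_h")),
                         meta={**meta, "axis": "equatorial", "form": "H"})
    d_eq = RadialProfile(q, _apply_noise(d_clean, truth, _rng(truth, "wans_d")),
                         meta={**meta, "axis": "equatorial", "form": "D"})
    h_mer = RadialProfile(qm, _apply_noise(mer_bg, truth, _rng(truth, "wans_h_mer")),
                          meta={**meta, "axis": "meridional", "form": "H"})
    d_mer = RadialProfile(qm, _apply_noise(mer_d_clean, truth, _rng(truth, "wans_d_mer")),
                          meta={**meta, "axis": "meridional", "form": "D"})
    return h_eq, d_eq, h_mer, d_mer
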