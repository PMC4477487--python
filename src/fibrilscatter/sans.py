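"""SANS Bragg-peak analysis and neutron contrast-variation arithmetic.

Regularly aggregated cellulose microfibrils give a broad small-angle Bragg
peak near q = 2 nm^-1 whose position tracks the centre-to-centre spacing
d = 2 pi / q_peak.  Soaking the sample in D2O/H2O mixtures scales the peak
amplitude with the squared contrast (delta-rho)^2 between cellulose and the
liquid; at the contrast-match composition the peak vanishes.  This module
fits the peak over a power-law + constant background, assembles hydration
series, and computes scattering length densities (SLD) and match fractions
from tabulated coherent scattering lengths.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, FitError
from .profiles import RadialProfile

__all__ = [
    "SANSFit",
    "HydrationSeries",
    "SLDSpec",
    "COHERENT_SCATTERING_LENGTHS_FM",
    "ATOMIC_MASSES",
    "WATER_H",
    "WATER_D",
    "CELLULOSE",
    "sld",
    "contrast_match_fraction",
    "contrast_factor",
    "fit_bragg_peak",
    "analyze_hydration_series",
]

# Bound coherent scattering lengths, fm (standard neutron data tables;
# isotope-aware: H is 1H, D is 2H).
COHERENT_SCATTERING_LENGTHS_FM = {
    "H": -3.739,
    "D": 6.671,
    "C": 6.646,
    "N": 9.36,
    "O": 5.803,
}

# Standard atomic masses, g/mol (D is the 2H isotope mass).
ATOMIC_MASSES = {
    "H": 1.00794,
    "D": 2.014102,
    "C": 12.011,
    "N": 14.0067,
    "O": 15.9994,
}

AVOGADRO = 6.02214076e23  # 1/mol
_FM_TO_NM = 1.0e-6
_CM3_TO_NM3 = 1.0e21


@dataclass(frozen=True)
class SLDSpec:
    """Material composition (atoms per formula unit) and mass density, g/cm^3."""

    composition: dict
    mass_density: float

    def __post_init__(self):
        if not self.composition:
            raise ValueError("empty composition")
        for el, n in self.composition.items():
            if n <= 0:
                raise ValueError(f"count for {el} must be positive")
        if self.mass_density <= 0:
            raise ValueError("mass_density must be positive")

    @property
    def sld(self) -> float:
        return sld(self)


def sld(spec: SLDSpec) -> float:
    """Coherent neutron scattering length density in nm^-2.

    sld = (sum_i n_i b_i) * rho * N_A / M  with b in fm converted to nm and
    the molecular number density in nm^-3.
    """
    b_sum = 0.0
    mass = 0.0
    for el, n in spec.composition.items():
        try:
            b_sum += n * COHERENT_SCATTERING_LENGTHS_FM[el]
            mass += n * ATOMIC_MASSES[el]
        except KeyError:
            raise ConfigurationError(
                f"element {el!r} not in the bundled scattering-length table"
            ) from None
    number_density_nm3 = spec.mass_density * AVOGADRO / mass / _CM3_TO_NM3
    return b_sum * _FM_TO_NM * number_density_nm3


#: Light water at ambient density.
WATER_H = SLDSpec({"H": 2, "O": 1}, 0.997)
#: Heavy water at ambient density.
WATER_D = SLDSpec({"D": 2, "O": 1}, 1.105)
#: Crystalline cellulose, C6H10O5 per anhydroglucose unit.
CELLULOSE = SLDSpec({"C": 6, "H": 10, "O": 5}, 1.6)


def contrast_match_fraction(
    particle: SLDSpec = CELLULOSE,
    solvent_h: SLDSpec = WATER_H,
    solvent_d: SLDSpec = WATER_D,
) -> float:
    """D2O volume fraction at which the solvent SLD matches the particle's.

    f solves f*sld_D + (1-f)*sld_H = sld_particle; a value outside [0, 1]
    is returned as computed with a warning (the particle cannot be matched
    by this solvent pair).
    """
    sld_h, sld_d, sld_p = sld(solvent_h), sld(solvent_d), sld(particle)
    if sld_d == sld_h:
        raise ZeroDivisionError("solvent SLDs are identical; no match fraction")
    f = (sld_p - sld_h) / (sld_d - sld_h)
    if not 0.0 <= f <= 1.0:
        warnings.warn(
            f"match fraction {f:.3f} outside [0, 1]: particle SLD not reachable",
            stacklevel=2,
        )
    return f


def contrast_factor(
    fraction: float,
    particle: SLDSpec = CELLULOSE,
    solvent_h: SLDSpec = WATER_H,
    solvent_d: SLDSpec = WATER_D,
) -> float:
    """(delta-rho)^2 in nm^-4 between particle and a linear D2O/H2O mixture."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    mix = fraction * sld(solvent_d) + (1.0 - fraction) * sld(solvent_h)
    return (sld(particle) - mix) ** 2


# ---------------------------------------------------------------------------
# peak fitting


@dataclass
class SANSFit:
    """Power-law + constant + single-Gaussian fit of a SANS profile."""

    q_peak: float
    breadth: float  # Gaussian sigma, nm^-1
    amplitude: float
    background: dict
    detected: bool
    residual_rms: float = 0.0

    @property
    def d(self) -> float:
        """Nominal centre-to-centre spacing 2 pi / q_peak, nm."""
        return 2.0 * math.pi / self.q_peak


@dataclass
class HydrationSeries:
    """Per-D2O-fraction fits and the spacing trend from detected peaks."""

    points: list  # (fraction, SANSFit)
    spacing_trend: list = field(default_factory=list)  # (fraction, d nm)

    def __post_init__(self):
        fractions = [f for f, _ in self.points]
        if len(set(fractions)) != len(fractions):
            raise ValueError("fractions must be unique")
        self.points = sorted(self.points, key=lambda p: p[0])
        if not self.spacing_trend:
            self.spacing_trend = [(f, fit.d) for f, fit in self.points if fit.detected]


def _sans_model(q, amp_bg, exponent, const, amp_pk, q_pk, sig_pk):
    return (
        amp_bg * np.power(q, -exponent)
        + const
        + amp_pk * np.exp(-((q - q_pk) ** 2) / (2.0 * sig_pk**2))
    )


def fit_bragg_peak(
    profile: RadialProfile,
    detection_threshold_sigma: float = 3.0,
    exponent_bounds=(2.0, 4.5),
    boundary_margin: float = 0.1,
    max_breadth: float = 0.8,
) -> SANSFit:
    """Joint fit of background and one Gaussian Bragg peak.

    Detection requires (a) the fitted amplitude to exceed
    ``detection_threshold_sigma`` times the fit-residual standard deviation,
    (b) the peak centre to sit at least ``boundary_margin`` nm^-1 inside the
    measured q range (a peak pinned at the boundary is flagged
    not-detected), and (c) the fitted width to stay below ``max_breadth``
    nm^-1 — a component spanning a third of the window is residual
    background curvature, not a Bragg peak.
    """
    q, inten = profile.q, profile.intensity
    if q[0] > 0.45 or q[-1] < 2.7:
        raise ConfigurationError("SANS fit needs coverage of about [0.4, 2.8] nm^-1")

    # crude initial background from the low-q rise
    const0 = float(np.percentile(inten, 5))
    amp_bg0 = max(float((inten[0] - const0) * q[0] ** 3), 1e-9)
    resid0 = inten - (amp_bg0 * q**-3.0 + const0)
    win = (q > 1.2) & (q < 2.7)
    j = int(np.argmax(np.where(win, resid0, -np.inf)))
    q_pk0 = float(q[j])
    amp_pk0 = max(float(resid0[j]), 1e-6)

    x0 = np.array([amp_bg0, 3.0, const0, amp_pk0, q_pk0, 0.3])
    lb = [0.0, exponent_bounds[0], -np.inf, 0.0, q[0], 0.02]
    ub = [np.inf, exponent_bounds[1], np.inf, np.inf, q[-1], 1.5]
    x0 = np.clip(x0, lb, ub)
    res = least_squares(
        lambda p: _sans_model(q, *p) - inten, x0=x0, bounds=(lb, ub), x_scale="jac"
    )
    if not res.success:
        raise FitError(
            "SANS peak fit did not converge",
            residual=float(np.sqrt(np.mean(res.fun**2))),
        )
    amp_bg, exponent, const, amp_pk, q_pk, sig_pk = res.x
    resid_sd = float(np.std(res.fun))
    inside = q[0] + boundary_margin <= q_pk <= q[-1] - boundary_margin
    shape_ok = sig_pk < max_breadth
    detected = bool(amp_pk > detection_threshold_sigma * resid_sd and inside and shape_ok)
    return SANSFit(
        q_peak=float(q_pk),
        breadth=float(sig_pk),
        amplitude=float(amp_pk),
        background={
            "amplitude": float(amp_bg),
            "exponent": float(exponent),
            "constant": float(const),
        },
        detected=detected,
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
    )


def analyze_hydration_series(profiles: dict, detection_threshold_sigma: float = 3.0) -> HydrationSeries:
    """Fit every D2O fraction of a hydration series.

    ``profiles`` maps D2O volume fraction (0..1) to a RadialProfile.  The
    spacing trend contains only fractions whose peak was detected; if none
    is, an empty-trend warning is emitted.
    """
    if len(profiles) < 1:
        raise ConfigurationError("empty hydration series")
    points = []
    for frac in sorted(profiles):
        fit = fit_bragg_peak(profiles[frac], detection_threshold_sigma)
        points.append((float(frac), fit))
    series = HydrationSeries(points=points)
    if not series.spacing_trend:
        warnings.warn("no Bragg peak detected at any fraction; empty trend", stacklevel=2)
    return series
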