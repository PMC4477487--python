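"""Equatorial WAXS inference: background, azimuthal decomposition, peak
fitting with an asymmetric 200 model, and size/disorder separation.

The chain of operations mirrors how well-oriented cellulose fibre patterns
are reduced in practice:

1.  A smooth background (power-law + constant by default) is fitted through
    user-chosen anchor windows free of reflections and subtracted.
2.  The azimuthal orientation distribution is decomposed into a narrow and a
    wide Gaussian component; on a full 2D pattern the narrow component's
    area per q-column reconstructs an equatorial profile containing only the
    well-oriented fraction.
3.  The equatorial reflections are fitted: Gaussians for the strongly
    overlapped 1-10 and 110 pair (ordering constraint enforced, one shared
    width by default), a deliberately asymmetric profile for 200, Gaussians
    for 400 and the optional weak 100 shoulder.  The 200 shape is
    F(q) = F0(q) for q >= q0 and F0(q)*(1 + 0.1 (q - q0)^2) for q < q0,
    with F0 a Gaussian and the asymmetry constant fixed at 0.1 nm^2.
4.  Integral breadths delta-q = area/height of the symmetric part F0
    (sigma * sqrt(2 pi) in closed form) are regressed against q0^2 d: the
    broadening law delta-q = delta-q0 + (pi/2) g^2 q^2 d separates the
    size-only intercept, giving the Scherrer dimension (mean column length)
    L = 2 pi / delta-q0, from the paracrystalline disorder parameter
    g = sqrt(2 * slope / pi).

FWHM and Gaussian sigma are related by FWHM = sigma * 2 sqrt(2 ln 2)
wherever widths are reported in degrees.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, FitError
from .profiles import AzimuthalProfile, PatternGrid, RadialProfile

__all__ = [
    "PeakComponent",
    "EquatorialFit",
    "BroadeningFit",
    "AzimuthalFit",
    "FWHM_PER_SIGMA",
    "ASYMMETRY_COEFF",
    "asymmetric_200",
    "gaussian_peak",
    "integral_breadth",
    "subtract_background",
    "fit_azimuthal",
    "reconstruct_equatorial",
    "fit_equatorial",
    "separate_size_disorder",
    "size_disorder_from_fit",
    "EquatorialAnalysis",
    "analyze_equatorial",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Fixed low-q asymmetry coefficient of the 200 profile, nm^2.
ASYMMETRY_COEFF = 0.1


def gaussian_peak(q, q0: float, sigma: float, height: float):
    """Plain Gaussian peak, height at the maximum."""
    q = np.asarray(q, dtype=float)
    return height * np.exp(-((q - q0) ** 2) / (2.0 * sigma**2))


def asymmetric_200(q, q0: float, sigma: float, height: float, asym_coeff: float = ASYMMETRY_COEFF):
    """Asymmetric 200 reflection profile.

    Gaussian F0 on the high-q side of the maximum; on the low-q side the
    Gaussian is augmented by the factor (1 + asym_coeff * (q - q0)^2),
    broadening the tail toward small q.  Continuous at q0 with value
    ``height``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    q = np.asarray(q, dtype=float)
    f0 = height * np.exp(-((q - q0) ** 2) / (2.0 * sigma**2))
    out = np.where(q < q0, f0 * (1.0 + asym_coeff * (q - q0) ** 2), f0)
    return float(out) if out.ndim == 0 else out


@dataclass
class PeakComponent:
    """One fitted reflection: position, height and Gaussian width in q."""

    hkl: tuple
    shape: str  # "gaussian" | "asymmetric200"
    q0: float
    height: float
    sigma: float
    asym_coeff: float = 0.0

    def __post_init__(self):
        if self.shape not in ("gaussian", "asymmetric200"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.q0 <= 0 or self.sigma <= 0:
            raise ValueError("q0 and sigma must be positive")
        if self.shape == "gaussian" and self.asym_coeff != 0.0:
            raise ValueError("gaussian components carry no asymmetry")

    @property
    def d(self) -> float:
        return 2.0 * math.pi / self.q0

    def evaluate(self, q):
        if self.shape == "gaussian":
            return gaussian_peak(q, self.q0, self.sigma, self.height)
        return asymmetric_200(q, self.q0, self.sigma, self.height, self.asym_coeff)


@dataclass
class EquatorialFit:
    """Result of the multi-peak equatorial fit."""

    components: list
    background: dict
    residual_rms: float
    converged: bool
    d_spacings: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.d_spacings:
            self.d_spacings = {c.hkl: c.d for c in self.components}

    def component(self, hkl) -> PeakComponent:
        for c in self.components:
            if tuple(c.hkl) == tuple(hkl):
                return c
        raise KeyError(f"no component {hkl}")


@dataclass
class BroadeningFit:
    """Size/disorder separation from the integral-width regression."""

    delta_q0: float  # intercept, nm^-1
    slope: float  # nm^-1 per (nm^-2 nm) abscissa unit; equals (pi/2) g^2
    g: float  # dimensionless disorder parameter
    L: float  # Scherrer dimension 2 pi / delta_q0, nm
    reflections_used: list = field(default_factory=list)


@dataclass
class AzimuthalFit:
    """Dual-Gaussian + constant decomposition of an orientation profile."""

    narrow: tuple  # (centre deg, fwhm deg, area)
    wide: tuple
    background: float
    narrow_fraction: float
    converged: bool = True
    residual_rms: float = 0.0


def integral_breadth(component: PeakComponent) -> float:
    """Integral breadth delta-q = area/height of the symmetric part F0.

    For a Gaussian this is sigma * sqrt(2 pi) in closed form; the asymmetric
    low-q augmentation of the 200 shape is excluded by definition, so the
    same closed form applies to asymmetric components.
    """
    return component.sigma * math.sqrt(2.0 * math.pi)


# ---------------------------------------------------------------------------
# background subtraction


def _power_law_background(q, amplitude, exponent, constant):
    return amplitude * np.power(q, -exponent) + constant


def subtract_background(
    profile: RadialProfile,
    anchor_windows=((5.0, 6.5), (32.0, 35.0)),
    model: str = "power-law",
) -> RadialProfile:
    """Fit a smooth background through anchor windows and subtract it.

    ``anchor_windows`` are (qmin, qmax) intervals positioned away from
    reflections; each must contain at least 3 profile points and at least
    two windows are required.  ``model`` is "power-law" (A q^-p + c) or
    "linear".
    """
    windows = [tuple(w) for w in anchor_windows]
    if len(windows) < 2:
        raise ConfigurationError("need at least 2 anchor windows")
    mask = np.zeros(len(profile.q), dtype=bool)
    for lo, hi in windows:
        wmask = (profile.q >= lo) & (profile.q <= hi)
        if wmask.sum() < 3:
            raise ConfigurationError(
                f"anchor window [{lo}, {hi}] contains {int(wmask.sum())} points (need >= 3)"
            )
        mask |= wmask
    qa, ia = profile.q[mask], profile.intensity[mask]

    if model == "linear":
        coeffs = np.polyfit(qa, ia, 1)
        bg = np.polyval(coeffs, profile.q)
        bg_params = {"model": "linear", "slope": float(coeffs[0]), "intercept": float(coeffs[1])}
    elif model == "power-law":
        c0 = float(min(ia.min(), 0.0))
        a0 = max((ia[0] - c0) * qa[0] ** 1.5, 1e-6)
        res = least_squares(
            lambda p: _power_law_background(qa, *p) - ia,
            x0=[a0, 1.5, c0],
            bounds=([0.0, 0.0, -np.inf], [np.inf, 6.0, np.inf]),
        )
        bg = _power_law_background(profile.q, *res.x)
        bg_params = {
            "model": "power-law",
            "amplitude": float(res.x[0]),
            "exponent": float(res.x[1]),
            "constant": float(res.x[2]),
        }
    else:
        raise ConfigurationError(f"unknown background model {model!r}")

    meta = dict(profile.meta)
    meta["background_model"] = bg_params["model"]
    meta["background_anchors"] = ";".join(f"{lo}-{hi}" for lo, hi in windows)
    return RadialProfile(profile.q.copy(), profile.intensity - bg, profile.sigma, meta)


# ---------------------------------------------------------------------------
# azimuthal decomposition


def _dual_gaussian(angle, centre_n, sig_n, h_n, centre_w, sig_w, h_w, const):
    return (
        h_n * np.exp(-((angle - centre_n) ** 2) / (2.0 * sig_n**2))
        + h_w * np.exp(-((angle - centre_w) ** 2) / (2.0 * sig_w**2))
        + const
    )


def fit_azimuthal(az: AzimuthalProfile, max_restarts: int = 3) -> AzimuthalFit:
    """Least-squares dual-Gaussian + constant fit of an orientation profile.

    Components are labelled narrow/wide by fitted width after the fit.  A
    flat profile converges to (near-)zero-area components rather than
    raising.  Raises :class:`FitError` carrying the last residual if the
    optimiser fails after bounded restarts.
    """
    if len(az) < 20:
        raise ConfigurationError("need at least 20 azimuthal points")
    ang, inten = az.angle, az.intensity
    span = ang[-1] - ang[0]
    const0 = float(np.percentile(inten, 10))
    peak = float(inten.max() - const0)
    centre0 = float(ang[np.argmax(inten)])
    sig_n0 = max(span / 30.0, 1e-3)
    sig_w0 = max(span / 6.0, 5e-3)
    x0 = np.array([centre0, sig_n0, 0.6 * peak, centre0, sig_w0, 0.4 * peak, const0])
    lb = [ang[0], 1e-4, 0.0, ang[0], 1e-4, 0.0, -np.inf]
    ub = [ang[-1], span, np.inf, ang[-1], span, np.inf, np.inf]

    rng = np.random.default_rng(0)
    last_res = None
    for attempt in range(max_restarts + 1):
        start = x0.copy()
        if attempt > 0:
            jitter = 1.0 + 0.3 * rng.standard_normal(len(x0))
            start = np.clip(x0 * jitter, lb, ub)
        res = least_squares(
            lambda p: _dual_gaussian(ang, *p) - inten, x0=start, bounds=(lb, ub)
        )
        last_res = res
        if res.success:
            break
    else:
        raise FitError(
            "azimuthal dual-Gaussian fit did not converge",
            residual=float(np.sqrt(np.mean(last_res.fun**2))),
        )

    centre_a, sig_a, h_a, centre_b, sig_b, h_b, const = res.x
    comp_a = (float(centre_a), float(sig_a * FWHM_PER_SIGMA), float(h_a * sig_a * math.sqrt(2 * math.pi)))
    comp_b = (float(centre_b), float(sig_b * FWHM_PER_SIGMA), float(h_b * sig_b * math.sqrt(2 * math.pi)))
    narrow, wide = (comp_a, comp_b) if comp_a[1] <= comp_b[1] else (comp_b, comp_a)
    total = narrow[2] + wide[2]
    frac = narrow[2] / total if total > 0 else 0.0
    return AzimuthalFit(
        narrow=narrow,
        wide=wide,
        background=float(const),
        narrow_fraction=float(frac),
        converged=bool(res.success),
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
    )


def reconstruct_equatorial(grid: PatternGrid, max_failed_fraction: float = 0.2) -> RadialProfile:
    """Narrow-component equatorial reconstruction from a 2D pattern.

    Each q-column's tangential (azimuthal) profile is decomposed into a
    narrow and a wide Gaussian; the narrow component's area becomes the
    equatorial intensity at that q.  Columns whose fit fails are
    interpolated from neighbours and counted; more than
    ``max_failed_fraction`` failures aborts.
    """
    nq = len(grid.q)
    areas = np.full(nq, np.nan)
    for i in range(nq):
        col = AzimuthalProfile(grid.angle, grid.intensity[i])
        try:
            fit = fit_azimuthal(col, max_restarts=1)
            areas[i] = fit.narrow[2]
        except (FitError, ConfigurationError):
            continue
    failed = np.isnan(areas)
    if failed.mean() > max_failed_fraction:
        raise FitError(
            f"{int(failed.sum())}/{nq} azimuthal column fits failed "
            f"(> {max_failed_fraction:.0%})"
        )
    if failed.any():
        areas[failed] = np.interp(grid.q[failed], grid.q[~failed], areas[~failed])
    return RadialProfile(
        grid.q.copy(),
        areas,
        meta={"axis": "equatorial", "reconstructed": 1, "failed_columns": int(failed.sum())},
    )


# ---------------------------------------------------------------------------
# equatorial multi-peak fit

_DEFAULT_Q0_BOUNDS = {
    (1, -1, 0): (9.0, 12.0),
    (2, 0, 0): (14.0, 17.5),
    (4, 0, 0): (28.0, 34.5),
    (1, 0, 0): (7.2, 9.0),
}
_GAP_BOUNDS = (0.02, 2.5)  # q0(110) - q0(1-10), nm^-1
_SIGMA_BOUNDS = (0.15, 4.0)
_SIGMA_BOUNDS_100 = (0.15, 2.0)  # the 100 is a weak shoulder, not a broad hump


def _equatorial_model(q, params, with_400, with_100, shared_overlap_width):
    i = 0
    b0, b1, b2 = params[i], params[i + 1], params[i + 2]
    i += 3
    q0_a, gap, h_a, h_b = params[i : i + 4]
    i += 4
    if shared_overlap_width:
        sig_a = sig_b = params[i]
        i += 1
    else:
        sig_a, sig_b = params[i], params[i + 1]
        i += 2
    q0_200, h_200, sig_200 = params[i : i + 3]
    i += 3
    model = (
        b0
        + b1 * (q - np.mean(q))
        + b2 * np.power(q, -2.0)
        + gaussian_peak(q, q0_a, sig_a, h_a)
        + gaussian_peak(q, q0_a + gap, sig_b, h_b)
        + asymmetric_200(q, q0_200, sig_200, h_200)
    )
    if with_400:
        q0_400, h_400, sig_400 = params[i : i + 3]
        i += 3
        model = model + gaussian_peak(q, q0_400, sig_400, h_400)
    if with_100:
        q0_100, h_100, sig_100 = params[i : i + 3]
        model = model + gaussian_peak(q, q0_100, sig_100, h_100)
    return model


def fit_equatorial(
    profile: RadialProfile,
    init: dict | None = None,
    with_400: bool = True,
    with_100: bool = False,
    shared_overlap_width: bool = True,
    max_restarts: int = 3,
) -> EquatorialFit:
    """Fit the background-subtracted equatorial profile.

    The model is a smooth residual baseline (constant + linear + q^-2 term,
    absorbing imperfections of the anchor-window background subtraction)
    plus Gaussians for 1-10 and 110
    (position ordering enforced by fitting the 110 position as
    q0(1-10) + gap with gap > 0; one shared width by default, since the
    strongly overlapped pair cannot support independent widths), the
    asymmetric 200 profile, a 400 Gaussian and optionally the weak 100
    shoulder near q = 8 nm^-1.

    ``init`` may map hkl tuples to dicts with any of q0/height/sigma to
    override the data-driven initial guesses.
    """
    q, inten = profile.q, profile.intensity
    if q[0] > 7.0 or q[-1] < 33.0:
        raise ConfigurationError(
            "equatorial fit needs coverage of at least [7, 33] nm^-1"
        )
    init = init or {}

    def guess(hkl, key, default):
        return float(init.get(tuple(hkl), {}).get(key, default))

    def local_height(q0):
        j = int(np.argmin(np.abs(q - q0)))
        return max(float(inten[j]), 1e-3)

    win = (q >= 14.0) & (q <= 17.5)
    q0_200_0 = guess((2, 0, 0), "q0", float(q[win][np.argmax(inten[win])]))
    q0_a0 = guess((1, -1, 0), "q0", 10.6)
    gap0 = guess((1, 1, 0), "q0", q0_a0 + 0.4) - q0_a0

    x0 = [0.0, 0.0, 0.0, q0_a0, gap0]
    lb = [-np.inf, -np.inf, -np.inf, *_DEFAULT_Q0_BOUNDS[(1, -1, 0)][:1], _GAP_BOUNDS[0]]
    ub = [np.inf, np.inf, np.inf, _DEFAULT_Q0_BOUNDS[(1, -1, 0)][1], _GAP_BOUNDS[1]]
    x0 += [
        guess((1, -1, 0), "height", 0.6 * local_height(q0_a0)),
        guess((1, 1, 0), "height", 0.6 * local_height(q0_a0 + gap0)),
    ]
    lb += [0.0, 0.0]
    ub += [np.inf, np.inf]
    if shared_overlap_width:
        x0 += [guess((1, -1, 0), "sigma", 1.1)]
        lb += [_SIGMA_BOUNDS[0]]
        ub += [_SIGMA_BOUNDS[1]]
    else:
        x0 += [guess((1, -1, 0), "sigma", 1.1), guess((1, 1, 0), "sigma", 1.1)]
        lb += [_SIGMA_BOUNDS[0]] * 2
        ub += [_SIGMA_BOUNDS[1]] * 2
    x0 += [q0_200_0, guess((2, 0, 0), "height", local_height(q0_200_0)), guess((2, 0, 0), "sigma", 0.75)]
    lb += [*_DEFAULT_Q0_BOUNDS[(2, 0, 0)][:1], 0.0, _SIGMA_BOUNDS[0]]
    ub += [_DEFAULT_Q0_BOUNDS[(2, 0, 0)][1], np.inf, _SIGMA_BOUNDS[1]]
    if with_400:
        q0_400_0 = guess((4, 0, 0), "q0", 2.0 * q0_200_0)
        x0 += [q0_400_0, guess((4, 0, 0), "height", local_height(q0_400_0)), guess((4, 0, 0), "sigma", 1.0)]
        lb += [*_DEFAULT_Q0_BOUNDS[(4, 0, 0)][:1], 0.0, _SIGMA_BOUNDS[0]]
        ub += [_DEFAULT_Q0_BOUNDS[(4, 0, 0)][1], np.inf, _SIGMA_BOUNDS[1]]
    if with_100:
        q0_100_0 = guess((1, 0, 0), "q0", 8.0)
        x0 += [q0_100_0, guess((1, 0, 0), "height", 0.3 * local_height(q0_100_0)), guess((1, 0, 0), "sigma", 1.0)]
        lb += [*_DEFAULT_Q0_BOUNDS[(1, 0, 0)][:1], 0.0, _SIGMA_BOUNDS_100[0]]
        ub += [_DEFAULT_Q0_BOUNDS[(1, 0, 0)][1], np.inf, _SIGMA_BOUNDS_100[1]]

    x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)
    rng = np.random.default_rng(0)
    last_res = None
    for attempt in range(max_restarts + 1):
        start = x0.copy()
        if attempt > 0:
            jitter = 1.0 + 0.05 * rng.standard_normal(len(x0))
            start = np.clip(x0 * jitter, lb, ub)
        res = least_squares(
            lambda p: _equatorial_model(q, p, with_400, with_100, shared_overlap_width) - inten,
            x0=start,
            bounds=(lb, ub),
            x_scale="jac",
        )
        last_res = res
        if res.success:
            break
    else:
        raise FitError(
            "equatorial multi-peak fit did not converge",
            residual=float(np.sqrt(np.mean(last_res.fun**2))),
        )

    p = res.x
    i = 3
    q0_a, gap, h_a, h_b = p[i : i + 4]
    i += 4
    if shared_overlap_width:
        sig_a = sig_b = p[i]
        i += 1
    else:
        sig_a, sig_b = p[i], p[i + 1]
        i += 2
    comps = [
        PeakComponent((1, -1, 0), "gaussian", float(q0_a), float(h_a), float(sig_a)),
        PeakComponent((1, 1, 0), "gaussian", float(q0_a + gap), float(h_b), float(sig_b)),
        PeakComponent((2, 0, 0), "asymmetric200", float(p[i]), float(p[i + 1]), float(p[i + 2]), ASYMMETRY_COEFF),
    ]
    i += 3
    if with_400:
        comps.append(PeakComponent((4, 0, 0), "gaussian", float(p[i]), float(p[i + 1]), float(p[i + 2])))
        i += 3
    if with_100:
        comps.append(PeakComponent((1, 0, 0), "gaussian", float(p[i]), float(p[i + 1]), float(p[i + 2])))

    ordered = {tuple(c.hkl): c.q0 for c in comps}
    chain = [(1, -1, 0), (1, 1, 0), (2, 0, 0)] + ([(4, 0, 0)] if with_400 else [])
    for first, second in zip(chain, chain[1:]):
        if not ordered[first] < ordered[second]:
            raise FitError(
                f"component ordering violated after fit: q0{first} >= q0{second}"
            )

    return EquatorialFit(
        components=comps,
        background={
            "baseline_const": float(p[0]),
            "baseline_slope": float(p[1]),
            "baseline_inv_q2": float(p[2]),
        },
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# size/disorder separation


def separate_size_disorder(points, reflections_used=None) -> BroadeningFit:
    """Separate size and disorder broadening by the integral-width regression.

    ``points`` is a sequence of (q0, d, delta_q) triples from one reflection
    family — q0 the peak position in nm^-1, d the family's fundamental
    lattice spacing in nm, delta_q the integral breadth in nm^-1.  The
    regression delta_q = delta_q0 + slope * (q0^2 d) is solved exactly for
    two points and by least squares otherwise; the intercept gives
    L = 2 pi / delta_q0 and the slope gives g = sqrt(2 slope / pi).
    """
    pts = [tuple(map(float, p)) for p in points]
    if len(pts) < 2:
        raise ConfigurationError("need at least 2 (q0, d, delta_q) points")
    x = np.array([q0**2 * d for q0, d, _ in pts])
    y = np.array([dq for _, _, dq in pts])
    slope, intercept = np.polyfit(x, y, 1)
    if slope < 0:
        warnings.warn(
            "negative broadening slope: disorder indistinguishable from zero; "
            "setting g = 0",
            stacklevel=2,
        )
        slope = 0.0
        intercept = float(np.mean(y))
    if intercept <= 0:
        raise ConfigurationError(
            "non-positive intercept delta_q0: disorder broadening dominates and "
            "the Scherrer dimension is undefined for these points"
        )
    g = math.sqrt(2.0 * slope / math.pi)
    return BroadeningFit(
        delta_q0=float(intercept),
        slope=float(slope),
        g=float(g),
        L=2.0 * math.pi / float(intercept),
        reflections_used=list(reflections_used or []),
    )


@dataclass
class EquatorialAnalysis:
    """Full equatorial WAXS inference result."""

    fit: EquatorialFit
    cell: "object"  # MonoclinicCell; avoids a hard import cycle in type position
    broadening: BroadeningFit | None
    background: dict


def _lattice_pair_q(q0_200: float, gamma_deg: float, b: float):
    """1-10/110 positions implied by (gamma, b) and the fitted 200 position.

    Inlines the oblique-lattice formula so gamma may roam below 90 deg during
    optimisation (the fold gamma -> 180 - gamma relabels the pair afterwards).
    """
    g = math.radians(gamma_deg)
    d200 = 2.0 * math.pi / q0_200
    a = 2.0 * d200 / math.sin(g)
    s2 = math.sin(g) ** 2

    def q_of(h, k):
        inv_d2 = (h * h / a**2 + k * k / b**2 - 2.0 * h * k * math.cos(g) / (a * b)) / s2
        return 2.0 * math.pi * math.sqrt(inv_d2)

    return q_of(1, -1), q_of(1, 1)


def analyze_equatorial(
    profile: RadialProfile,
    anchor_windows=((5.0, 6.5), (32.0, 35.0)),
    b_reference: float = 0.820,
    with_100: bool = True,
    weighted: bool = True,
    gamma_starts=(89.0, 91.0, 93.0, 95.0),
    size_reflections=((2, 0, 0), (4, 0, 0)),
) -> EquatorialAnalysis:
    """Full equatorial inference on a raw (not background-subtracted) profile.

    Two stages.  First the anchor-window background subtraction and the
    free-position multi-peak fit provide initial estimates.  Then background
    and peaks are refitted jointly, with the 1-10/110 positions tied to one
    monoclinic cell: the intersheet edge a follows from the fitted 200
    position and the monoclinic angle gamma, while the intrasheet repeat b is
    held at ``b_reference`` (0.820 nm, the literature cellulose I-beta value)
    because the strongly overlapped pair cannot constrain a free b.  Residuals
    are weighted by 1/intensity by default, matching a relative
    (multiplicative) noise model.  gamma is optimised from several starts and
    folded onto the gamma >= 90 deg reporting convention (gamma < 90 is the
    same lattice with the pair labels swapped).

    Returns the fit, the recovered cell, and the 200-family size/disorder
    separation.
    """
    from .lattice import MonoclinicCell  # local import: lattice does not import waxs

    sub = subtract_background(profile, anchor_windows=anchor_windows)
    free_fit = fit_equatorial(sub, with_100=with_100)
    c = {tuple(cc.hkl): cc for cc in free_fit.components}

    q, y = profile.q, profile.intensity
    w = 1.0 / np.clip(y, 1e-3, None) if weighted else np.ones_like(y)

    def joint_model(p):
        amp, expo, cst, gamma, h_a, h_b, sig_ab, q200, h200, s200, q400, h400, s400 = p[:13]
        qa, qb = _lattice_pair_q(q200, gamma, b_reference)
        m = (
            amp * np.power(q, -expo)
            + cst
            + gaussian_peak(q, qa, sig_ab, h_a)
            + gaussian_peak(q, qb, sig_ab, h_b)
            + asymmetric_200(q, q200, s200, h200)
            + gaussian_peak(q, q400, s400, h400)
        )
        if with_100:
            m = m + gaussian_peak(q, p[13], p[15], p[14])
        return m

    lb = [0.0, 0.0, -np.inf, 82.0, 0.0, 0.0, _SIGMA_BOUNDS[0],
          *_DEFAULT_Q0_BOUNDS[(2, 0, 0)][:1], 0.0, _SIGMA_BOUNDS[0],
          *_DEFAULT_Q0_BOUNDS[(4, 0, 0)][:1], 0.0, _SIGMA_BOUNDS[0]]
    ub = [np.inf, 6.0, np.inf, 108.0, np.inf, np.inf, _SIGMA_BOUNDS[1],
          _DEFAULT_Q0_BOUNDS[(2, 0, 0)][1], np.inf, _SIGMA_BOUNDS[1],
          _DEFAULT_Q0_BOUNDS[(4, 0, 0)][1], np.inf, _SIGMA_BOUNDS[1]]
    if with_100:
        lb += [*_DEFAULT_Q0_BOUNDS[(1, 0, 0)][:1], 0.0, _SIGMA_BOUNDS_100[0]]
        ub += [_DEFAULT_Q0_BOUNDS[(1, 0, 0)][1], np.inf, _SIGMA_BOUNDS_100[1]]

    c400 = c[(4, 0, 0)]
    base = [150.0, 1.5, 2.0, None,
            c[(1, -1, 0)].height, c[(1, 1, 0)].height, c[(1, -1, 0)].sigma,
            c[(2, 0, 0)].q0, c[(2, 0, 0)].height, c[(2, 0, 0)].sigma,
            c400.q0, c400.height, c400.sigma]
    if with_100:
        c100 = c[(1, 0, 0)]
        base += [c100.q0, c100.height, c100.sigma]

    best = None
    for g0 in gamma_starts:
        x0 = list(base)
        x0[3] = g0
        res = least_squares(
            lambda p: (joint_model(p) - y) * w,
            np.clip(x0, lb, ub),
            bounds=(lb, ub),
            x_scale="jac",
            ftol=1e-12,
            xtol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise FitError("joint lattice-constrained equatorial fit did not converge")

    p = best.x
    gamma_raw = float(p[3])
    qa, qb = _lattice_pair_q(float(p[7]), gamma_raw, b_reference)
    if gamma_raw < 90.0:  # fold onto the reporting convention; relabel the pair
        gamma = 180.0 - gamma_raw
        qa, qb = qb, qa
        h_1m10, h_110 = float(p[5]), float(p[4])
    else:
        gamma = gamma_raw
        h_1m10, h_110 = float(p[4]), float(p[5])
    sig_ab = float(p[6])

    comps = [
        PeakComponent((1, -1, 0), "gaussian", float(min(qa, qb)), h_1m10, sig_ab),
        PeakComponent((1, 1, 0), "gaussian", float(max(qa, qb)), h_110, sig_ab),
        PeakComponent((2, 0, 0), "asymmetric200", float(p[7]), float(p[8]), float(p[9]), ASYMMETRY_COEFF),
        PeakComponent((4, 0, 0), "gaussian", float(p[10]), float(p[11]), float(p[12])),
    ]
    if with_100:
        comps.append(PeakComponent((1, 0, 0), "gaussian", float(p[13]), float(p[14]), float(p[15])))

    background = {
        "model": "power-law",
        "amplitude": float(p[0]),
        "exponent": float(p[1]),
        "constant": float(p[2]),
    }
    fit = EquatorialFit(
        components=comps,
        background=background,
        residual_rms=float(np.sqrt(np.mean((joint_model(p) - y) ** 2))),
        converged=True,
    )
    d200 = fit.component((2, 0, 0)).d
    cell = MonoclinicCell(a=2.0 * d200 / math.sin(math.radians(gamma)), b=b_reference, gamma=gamma)
    broadening = size_disorder_from_fit(fit, reflections=size_reflections)
    return EquatorialAnalysis(fit=fit, cell=cell, broadening=broadening, background=background)


def size_disorder_from_fit(fit: EquatorialFit, reflections=((2, 0, 0), (4, 0, 0))) -> BroadeningFit:
    """Build the (q0, d, delta_q) points from a fitted equatorial profile.

    By default only the 200/400 family enters the regression (the overlapped
    1-10/110 pair broadens off the 200-family line); the family's
    fundamental spacing d200 = 2 pi / q0(200) is the abscissa d for every
    point.
    """
    d_fund = fit.component((2, 0, 0)).d
    points = []
    for hkl in reflections:
        c = fit.component(hkl)
        points.append((c.q0, d_fund, integral_breadth(c)))
    return separate_size_disorder(points, reflections_used=[tuple(r) for r in reflections])
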