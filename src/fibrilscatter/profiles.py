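"""Core 1D/2D scattering-profile containers and plain-text I/O.

The common currency of the package is the radial profile: intensity sampled
on a strictly increasing grid of scattering-vector magnitudes q (nm^-1),
optionally with per-point uncertainties.  Azimuthal profiles (intensity vs
angle in degrees) and 2D q x azimuth grids complete the set.  All files are
plain text: two-column (or three-column, with sigma) whitespace/comma
separated values with a '#'-prefixed key=value metadata header, and a CSV
matrix layout for grids (first row = angles, first column = q).

Units are canonical throughout: q and breadths in nm^-1, lengths in nm,
angles in degrees at every interface.  Angstrom input is accepted via a unit
flag and converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, ProfileFormatError

__all__ = [
    "RadialProfile",
    "AzimuthalProfile",
    "PatternGrid",
    "two_theta_to_q",
    "q_to_two_theta",
    "read_profile",
    "write_profile",
    "crop_q",
    "read_grid",
    "write_grid",
]

_RADIATION_LABELS = ("x-ray-Cu", "x-ray-Mo", "neutron")
_AXIS_LABELS = ("equatorial", "meridional", "isotropic")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class RadialProfile:
    """Intensity vs scattering-vector magnitude q.

    Parameters
    ----------
    q : array-like
        Scattering vector magnitudes in nm^-1, strictly increasing, length >= 4.
    intensity : array-like
        Arbitrary counts; may be negative after background subtraction.
    sigma : array-like, optional
        Per-point uncertainty in the same (arbitrary) units as intensity.
    meta : dict
        Free-form metadata.  Recognised keys: ``radiation`` (one of
        ``x-ray-Cu``, ``x-ray-Mo``, ``neutron``), ``wavelength_nm`` (> 0),
        ``axis`` (``equatorial`` | ``meridional`` | ``isotropic``).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = _as_float_array(self.q, "q")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if self.sigma is not None:
            self.sigma = _as_float_array(self.sigma, "sigma")
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma and q must have equal length")
        if len(self.q) != len(self.intensity):
            raise ValueError("q and intensity must have equal length")
        if len(self.q) < 4:
            raise ValueError("profile needs at least 4 samples")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        rad = self.meta.get("radiation")
        if rad is not None:
            if rad not in _RADIATION_LABELS:
                raise ValueError(f"unknown radiation label {rad!r}")
            wl = self.meta.get("wavelength_nm")
            if wl is not None and float(wl) <= 0:
                raise ValueError("wavelength_nm must be positive")
        ax = self.meta.get("axis")
        if ax is not None and ax not in _AXIS_LABELS:
            raise ValueError(f"unknown axis label {ax!r}")

    def __len__(self) -> int:
        return len(self.q)

    @property
    def wavelength_nm(self) -> float | None:
        wl = self.meta.get("wavelength_nm")
        return None if wl is None else float(wl)

    def copy(self) -> "RadialProfile":
        return RadialProfile(
            self.q.copy(),
            self.intensity.copy(),
            None if self.sigma is None else self.sigma.copy(),
            dict(self.meta),
        )


@dataclass
class AzimuthalProfile:
    """Intensity vs azimuthal angle (degrees), strictly increasing grid."""

    angle: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.angle = _as_float_array(self.angle, "angle")
        self.intensity = _as_float_array(self.intensity, "intensity")
        if len(self.angle) != len(self.intensity):
            raise ValueError("angle and intensity must have equal length")
        if np.any(np.diff(self.angle) <= 0):
            raise ValueError("angle must be strictly increasing")

    def __len__(self) -> int:
        return len(self.angle)


@dataclass
class PatternGrid:
    """2D intensity on a q (rows) x azimuth (columns) grid."""

    q: np.ndarray
    angle: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.q = _as_float_array(self.q, "q")
        self.angle = _as_float_array(self.angle, "angle")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(np.diff(self.angle) <= 0):
            raise ValueError("angle must be strictly increasing")
        if self.intensity.shape != (len(self.q), len(self.angle)):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match "
                f"({len(self.q)}, {len(self.angle)})"
            )


def two_theta_to_q(two_theta, wavelength: float):
    """Convert scattering angle 2-theta (degrees) to q = 4 pi sin(theta)/lambda.

    Parameters
    ----------
    two_theta : float or array
        Scattering angle in degrees, 0 <= 2theta < 180.
    wavelength : float
        Radiation wavelength in nm, > 0.

    Returns
    -------
    q in nm^-1 (same shape as input).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    tt = np.asarray(two_theta, dtype=float)
    if np.any(tt < 0) or np.any(tt >= 180):
        raise ValueError("two_theta must be in [0, 180) degrees")
    q = 4.0 * math.pi * np.sin(np.radians(tt) / 2.0) / wavelength
    return float(q) if np.isscalar(two_theta) else q


def q_to_two_theta(q, wavelength: float):
    """Inverse of :func:`two_theta_to_q`; returns degrees."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    qa = np.asarray(q, dtype=float)
    s = qa * wavelength / (4.0 * math.pi)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("q out of representable range for this wavelength")
    tt = 2.0 * np.degrees(np.arcsin(s))
    return float(tt) if np.isscalar(q) else tt


_Q_UNIT_SCALE = {"nm^-1": 1.0, "angstrom^-1": 10.0, "A^-1": 10.0}


def _format_meta_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_meta_value(s: str):
    try:
        f = float(s)
    except ValueError:
        return s
    if f.is_integer() and "." not in s and "e" not in s.lower():
        return int(f)
    return f


def write_profile(profile: RadialProfile, path) -> None:
    """Write a profile as two/three-column text with a '#' metadata header."""
    lines = []
    for key, val in profile.meta.items():
        lines.append(f"# {key} = {_format_meta_value(val)}")
    cols = [profile.q, profile.intensity]
    if profile.sigma is not None:
        cols.append(profile.sigma)
    for row in zip(*cols):
        lines.append(" ".join(repr(float(v)) for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_profile(path, dialect: str = "two-column", q_unit: str = "nm^-1") -> RadialProfile:
    """Read a radial profile from plain text.

    Parameters
    ----------
    path : str or Path
        File with numeric rows ``q intensity [sigma]``; '#' lines are
        comments, and ``# key = value`` pairs populate ``meta``.
    dialect : {"two-column", "csv"}
        Column separator convention; "two-column" accepts any whitespace or
        commas, "csv" requires commas.
    q_unit : {"nm^-1", "angstrom^-1"}
        Unit of the q column in the file; converted to nm^-1 on read.
    """
    if dialect not in ("two-column", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        scale = _Q_UNIT_SCALE[q_unit]
    except KeyError:
        raise ValueError(f"unknown q unit {q_unit!r}") from None

    meta: dict = {}
    rows: list[tuple[float, ...]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = _parse_meta_value(val.strip())
                continue
            parts = line.split(",") if dialect == "csv" else line.replace(",", " ").split()
            try:
                values = tuple(float(p) for p in parts if p != "")
            except ValueError:
                raise ProfileFormatError(
                    f"{path}: non-numeric row at line {lineno}: {line!r}"
                ) from None
            if len(values) not in (2, 3):
                raise ProfileFormatError(
                    f"{path}: expected 2 or 3 columns at line {lineno}, got {len(values)}"
                )
            if rows and values[0] * scale <= rows[-1][0] * scale:
                raise ProfileFormatError(
                    f"{path}: q not strictly increasing at line {lineno}"
                )
            rows.append(values)
    if len(rows) < 4:
        raise ProfileFormatError(f"{path}: needs at least 4 numeric rows, got {len(rows)}")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise ProfileFormatError(f"{path}: inconsistent column count across rows")
    arr = np.array(rows, dtype=float)
    sigma = arr[:, 2] if arr.shape[1] == 3 else None
    return RadialProfile(arr[:, 0] * scale, arr[:, 1], sigma, meta)


def crop_q(profile: RadialProfile, qmin: float, qmax: float) -> RadialProfile:
    """Return the sub-profile with qmin <= q <= qmax; metadata preserved."""
    if qmin >= qmax:
        raise ValueError("qmin must be < qmax")
    mask = (profile.q >= qmin) & (profile.q <= qmax)
    if not np.any(mask):
        raise ConfigurationError(f"crop [{qmin}, {qmax}] selects no samples")
    return replace(
        profile,
        q=profile.q[mask],
        intensity=profile.intensity[mask],
        sigma=None if profile.sigma is None else profile.sigma[mask],
        meta=dict(profile.meta),
    )


def write_grid(grid: PatternGrid, path) -> None:
    """CSV matrix: first row = angles (blank corner), first column = q."""
    with open(path, "w") as fh:
        fh.write("," + ",".join(repr(float(a)) for a in grid.angle) + "\n")
        for qi, row in zip(grid.q, grid.intensity):
            fh.write(repr(float(qi)) + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_grid(path) -> PatternGrid:
    """Read the CSV matrix layout written by :func:`write_grid`."""
    with open(path) as fh:
        header = fh.readline().strip()
        parts = header.split(",")
        angle = np.array([float(p) for p in parts[1:]])
        q_rows, data = [], []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            cells = line.split(",")
            try:
                q_rows.append(float(cells[0]))
                data.append([float(c) for c in cells[1:]])
            except ValueError:
                raise ProfileFormatError(
                    f"{path}: non-numeric entry at line {lineno}"
                ) from None
    return PatternGrid(np.array(q_rows), angle, np.array(data))
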