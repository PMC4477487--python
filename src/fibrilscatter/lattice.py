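"""Monoclinic hk0 lattice arithmetic and microfibril chain counting.

Cellulose I-beta packs its chains on an oblique 2D lattice in projection
down the chain axis: cell edges a (intersheet direction) and b, with
monoclinic angle gamma between them.  Equatorial hk0 spacings follow

    1/d^2 = [h^2/a^2 + k^2/b^2 - 2 h k cos(gamma)/(a b)] / sin^2(gamma)

so that d(200) = (a/2) sin(gamma) is the sheet-to-sheet distance.  The
module inverts fitted (d_1-10, d_110, d_200) triples back to a unique cell
on the reporting convention gamma >= 90 deg (equivalently d(1-10) >=
d(110)), and counts how many chain cross-sections fit in a microfibril
envelope given the per-chain area of the crystal structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InversionError

__all__ = [
    "MonoclinicCell",
    "MicrofibrilEnvelope",
    "ChainPacking",
    "CELLULOSE_IBETA",
    "d_spacing",
    "invert_cell",
    "chain_area",
    "scale_chain_area",
    "count_chains",
]


@dataclass(frozen=True)
class MonoclinicCell:
    """2D oblique lattice: edges a, b in nm, monoclinic angle gamma in degrees."""

    a: float
    b: float
    gamma: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("cell edges must be positive")
        if not (80.0 < self.gamma < 110.0):
            raise ValueError("gamma must lie in (80, 110) degrees")


@dataclass(frozen=True)
class MicrofibrilEnvelope:
    """Cross-section envelope: height perpendicular to [200], width across sheets."""

    height: float
    width: float
    shape: str = "rectangle"

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("envelope dimensions must be positive")
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown envelope shape {self.shape!r}")

    @property
    def area(self) -> float:
        if self.shape == "rectangle":
            return self.height * self.width
        return math.pi * self.height * self.width / 4.0


@dataclass(frozen=True)
class ChainPacking:
    """Cross-sectional area occupied by one cellulose chain, nm^2."""

    area_per_chain: float
    source: str

    def __post_init__(self):
        if not (0.25 < self.area_per_chain < 0.45):
            raise ValueError(
                f"area_per_chain {self.area_per_chain:.3f} nm^2 outside the "
                "plausible 0.25-0.45 nm^2 range for cellulose"
            )


#: Literature cellulose I-beta reference cell (hk0 projection), nm / degrees.
CELLULOSE_IBETA = MonoclinicCell(a=0.778, b=0.820, gamma=96.5)


def d_spacing(cell: MonoclinicCell, h: int, k: int) -> float:
    """hk0 lattice spacing in nm for Miller indices (h, k)."""
    if h == 0 and k == 0:
        raise ValueError("(0, 0) has no spacing")
    g = math.radians(cell.gamma)
    inv_d2 = (
        h * h / cell.a**2
        + k * k / cell.b**2
        - 2.0 * h * k * math.cos(g) / (cell.a * cell.b)
    ) / math.sin(g) ** 2
    return 1.0 / math.sqrt(inv_d2)


def invert_cell(d_1m10: float, d_110: float, d_200: float) -> MonoclinicCell:
    """Recover the unique (a, b, gamma) from three equatorial spacings.

    Inputs are the (1,-1,0), (1,1,0) and (2,0,0) spacings in nm on the
    convention d_1m10 >= d_110 (gamma >= 90 deg).  The round trip through
    :func:`d_spacing` reproduces the inputs to better than 1e-9 relative.
    """
    if min(d_1m10, d_110, d_200) <= 0:
        raise ValueError("spacings must be positive")
    if d_1m10 < d_110 * (1.0 - 1e-12):
        raise InversionError(
            "d(1-10) < d(110) violates the gamma >= 90 deg convention"
        )
    A = 1.0 / d_1m10**2  # (1,-1,0)
    B = 1.0 / d_110**2  # (1,1,0)

    def params_at(gamma_deg: float):
        g = math.radians(gamma_deg)
        s2 = math.sin(g) ** 2
        a = 2.0 * d_200 / math.sin(g)
        inv_b2 = (A + B) * s2 / 2.0 - 1.0 / a**2
        return g, s2, a, inv_b2

    def mismatch(gamma_deg: float) -> float:
        g, s2, a, inv_b2 = params_at(gamma_deg)
        if inv_b2 <= 0:
            # b diverges before this gamma; push the root finder back
            return float("inf")
        b = 1.0 / math.sqrt(inv_b2)
        return -4.0 * math.cos(g) / (a * b * s2) - (B - A)

    if abs(B - A) / B < 1e-14:
        gamma = 90.0
    else:
        lo, hi = 90.0, 109.999
        f_lo = mismatch(lo)
        f_hi = mismatch(hi)
        if not math.isfinite(f_hi):
            # shrink until b is real
            while hi - lo > 1e-9:
                mid = (lo + hi) / 2.0
                if math.isfinite(mismatch(mid)):
                    lo2 = mid
                    break
                hi = mid
            else:
                raise InversionError("no real b for any gamma in [90, 110)")
            hi = lo2
            f_hi = mismatch(hi)
        if f_lo * f_hi > 0:
            raise InversionError(
                "inconsistent spacing triple: no monoclinic angle in "
                "[90, 110) reproduces d(110) - d(1-10) splitting"
            )
        gamma = brentq(mismatch, lo, hi, xtol=1e-13, rtol=8.9e-16)
    _, _, a, inv_b2 = params_at(gamma)
    if inv_b2 <= 0:
        raise InversionError("inconsistent spacing triple: b is not real")
    return MonoclinicCell(a=a, b=1.0 / math.sqrt(inv_b2), gamma=gamma)


def chain_area(cell: MonoclinicCell) -> ChainPacking:
    """Cross-section per chain: a*b*sin(gamma)/2 (two chains per hk0 cell)."""
    area = cell.a * cell.b * math.sin(math.radians(cell.gamma)) / 2.0
    return ChainPacking(area_per_chain=area, source="reference-cell")


def scale_chain_area(reference_cell: MonoclinicCell, observed_d200: float) -> ChainPacking:
    """Reference per-chain area scaled by the observed/reference d200 ratio."""
    if observed_d200 <= 0:
        raise ValueError("observed_d200 must be positive")
    ref = chain_area(reference_cell)
    scaled = ref.area_per_chain * observed_d200 / d_spacing(reference_cell, 2, 0)
    return ChainPacking(area_per_chain=scaled, source="scaled")


def count_chains(envelope: MicrofibrilEnvelope, packing: ChainPacking) -> int:
    """Whole chain cross-sections fitting in the envelope (floor)."""
    return int(np.floor(envelope.area / packing.area_per_chain))
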