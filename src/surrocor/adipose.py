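"""Adipose tissue quantification on a single axial CT slice at L4.

Adipose tissue is delineated by Hounsfield-unit thresholding in the
standard fat window, -150 to -20 HU (bounds inclusive), within the body
mask.  Total adipose tissue (TAT) is split into visceral (VAT, pixels
whose centres fall inside a supplied inner-abdominal-wall polygon) and
subcutaneous (SAT, the remainder).  Areas are pixel counts times pixel
area; percentages are relative to the body cross-section by default, with
the full image frame available as an alternative reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

HU_FAT_LOW = -150.0
HU_FAT_HIGH = -20.0

__all__ = [
    "HU_FAT_LOW",
    "HU_FAT_HIGH",
    "HUSlice",
    "AdiposeResult",
    "adipose_mask",
    "split_sat_vat",
    "adipose_percentages",
]


@dataclass
class HUSlice:
    """A 2-D Hounsfield grid with pixel spacing (mm) and a body mask."""

    hu: np.ndarray
    pixel_spacing: tuple[float, float]
    body_mask: np.ndarray
    origin: tuple[float, float] | None = None  # (x, y) of pixel [0, 0] centre

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        if self.hu.shape != self.body_mask.shape:
            raise ValueError("hu and body_mask shapes differ")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def pixel_area(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) grids of pixel-centre coordinates in mm.

        If ``origin`` is unset the grid is centred on (0, 0), matching the
        phantom convention.
        """
        ny, nx = self.hu.shape
        px, py = self.pixel_spacing
        if self.origin is None:
            x = (np.arange(nx) - (nx - 1) / 2.0) * px
            y = (np.arange(ny) - (ny - 1) / 2.0) * py
        else:
            x = self.origin[0] + np.arange(nx) * px
            y = self.origin[1] + np.arange(ny) * py
        return np.meshgrid(x, y)


@dataclass
class AdiposeResult:
    """SAT/VAT/TAT areas (mm^2) and percentages of the reference surface."""

    sat_area: float
    vat_area: float
    tat_area: float
    sat_pct: float
    vat_pct: float
    tat_pct: float
    reference_area: float
    reference_kind: str

    def __post_init__(self) -> None:
        if abs(self.tat_area - (self.sat_area + self.vat_area)) > 1e-9:
            raise ValueError("tat_area must equal sat_area + vat_area")
        for p in (self.sat_pct, self.vat_pct, self.tat_pct):
            if not (0.0 <= p <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")


def adipose_mask(sl: HUSlice) -> np.ndarray:
    """Binary adipose mask: body pixels with HU in [-150, -20], inclusive."""
    return sl.body_mask & (sl.hu >= HU_FAT_LOW) & (sl.hu <= HU_FAT_HIGH)


def split_sat_vat(
    adipose: np.ndarray, inner_wall: np.ndarray, sl: HUSlice
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the adipose mask into (SAT, VAT) by the inner abdominal wall.

    VAT pixels are adipose pixels whose centres fall inside the inner-wall
    polygon (boundary inclusive); SAT is the rest.  The masks are disjoint
    and their union is exactly the input mask.
    """
    wall = np.asarray(inner_wall, dtype=float)
    if wall.ndim != 2 or wall.shape[1] != 2 or wall.shape[0] < 3:
        raise ValueError("inner wall must be a closed polygon of >= 3 vertices")
    poly = shapely.Polygon(wall)
    if not poly.is_valid:
        raise ValueError("inner wall polygon is not simple")
    X, Y = sl.pixel_centers()
    body_hull = sl.body_mask
    # the wall must lie inside the body: every vertex over a body pixel
    iy = np.clip(np.round((wall[:, 1] - Y[0, 0]) / sl.pixel_spacing[1]).astype(int), 0, body_hull.shape[0] - 1)
    ix = np.clip(np.round((wall[:, 0] - X[0, 0]) / sl.pixel_spacing[0]).astype(int), 0, body_hull.shape[1] - 1)
    if not body_hull[iy, ix].all():
        raise ValueError("inner wall polygon extends outside the body mask")
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    inside |= shapely.intersects_xy(poly.exterior, X.ravel(), Y.ravel()).reshape(X.shape)
    adipose = np.asarray(adipose, dtype=bool)
    vat = adipose & inside
    sat = adipose & ~inside
    return sat, vat


def adipose_percentages(
    sat: np.ndarray, vat: np.ndarray, sl: HUSlice, reference_kind: str = "body"
) -> AdiposeResult:
    """Compartment areas and their percentages of the reference surface.

    ``reference_kind`` is "body" (body cross-section area, default) or
    "frame" (full image area).
    """
    if reference_kind == "body":
        ref_pixels = int(sl.body_mask.sum())
    elif reference_kind == "frame":
        ref_pixels = int(sl.hu.size)
    else:
        raise ValueError(f"unknown reference_kind {reference_kind!r}")
    ref_area = ref_pixels * sl.pixel_area
    if ref_area <= 0:
        raise ValueError("zero reference area")
    sat_area = float(np.count_nonzero(sat)) * sl.pixel_area
    vat_area = float(np.count_nonzero(vat)) * sl.pixel_area
    tat_area = sat_area + vat_area
    return AdiposeResult(
        sat_area=sat_area,
        vat_area=vat_area,
        tat_area=tat_area,
        sat_pct=100.0 * sat_area / ref_area,
        vat_pct=100.0 * vat_area / ref_area,
        tat_pct=100.0 * tat_area / ref_area,
        reference_area=ref_area,
        reference_kind=reference_kind,
    )
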