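"""Contour geometry: centroids, the central craniocaudal axis, and radial beam casting.

The torso skin on each axial CT slice is a closed simple polygon in
millimetre coordinates.  A central craniocaudal axis is fitted through the
per-slice contour centroids by least squares, and from the fixed axis point
of every slice a fan of 180 radial beams (1 degree apart, half-open
[0deg, 180deg)) is cast to the skin.  The beam length, phase by phase, is the
surrogate signal for skin respiratory motion.

Coordinate convention (declared, loaders must map onto it): x increases
toward the patient's left, y toward anterior, z toward cranial.  Beam angle
theta = 0deg points to the patient's right lateral side, 90deg anterior,
179deg one degree short of left lateral; the axial direction vector is
d(theta) = (-cos theta, sin theta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

N_BEAMS = 180
BEAM_ANGLES_DEG = np.arange(N_BEAMS, dtype=float)

__all__ = [
    "N_BEAMS",
    "BEAM_ANGLES_DEG",
    "ContourSlice",
    "PhaseContourSet",
    "BodyAxis",
    "BeamLengthField",
    "TSTrajectory",
    "beam_direction",
    "polygon_centroid",
    "polygon_area",
    "fit_axis",
    "cast_beam",
    "cast_rays",
    "build_beam_length_field",
    "ts_centroid_z",
]


def beam_direction(angle_deg):
    """Unit direction of a radial beam in the axial plane.

    theta=0 -> (-1, 0) (patient right), theta=90 -> (0, 1) (anterior).
    Accepts scalars or arrays; returns shape (..., 2).
    """
    theta = np.deg2rad(np.asarray(angle_deg, dtype=float))
    return np.stack([-np.cos(theta), np.sin(theta)], axis=-1)


def _signed_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class ContourSlice:
    """A closed simple skin polygon on one axial slice.

    Vertices are ordered (x, y) pairs in mm; the closing edge from the last
    vertex back to the first is implicit.  Orientation is normalised to
    counter-clockwise on construction.
    """

    z: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("contour needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite vertex in contour at z={self.z}")
        area = _signed_area(v)
        if area == 0.0:
            raise ValueError(f"degenerate zero-area contour at z={self.z}")
        if area < 0.0:  # normalise to CCW
            v = v[::-1].copy()
        self.vertices = v

    @property
    def area(self) -> float:
        return _signed_area(self.vertices)


@dataclass
class PhaseContourSet:
    """All skin contour slices of one respiratory phase, sorted by z."""

    phase: int
    slices: list[ContourSlice]

    def __post_init__(self) -> None:
        self.slices = sorted(self.slices, key=lambda s: s.z)
        zs = self.slice_zs
        if len(zs) != len(set(zs.tolist())):
            raise ValueError(f"duplicate slice z in phase {self.phase}")

    @property
    def slice_zs(self) -> np.ndarray:
        return np.array([s.z for s in self.slices], dtype=float)


@dataclass
class BodyAxis:
    """Central craniocaudal axis: two OLS lines, x(z) and y(z)."""

    x_intercept: float
    x_slope: float
    y_intercept: float
    y_slope: float

    def point_at(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return np.stack(
            [self.x_intercept + self.x_slope * z, self.y_intercept + self.y_slope * z],
            axis=-1,
        )


@dataclass
class TSTrajectory:
    """Tracking-structure craniocaudal centroid coordinate per phase, mm."""

    z_per_phase: np.ndarray

    def __post_init__(self) -> None:
        self.z_per_phase = np.asarray(self.z_per_phase, dtype=float).ravel()

    @property
    def n_phases(self) -> int:
        return self.z_per_phase.size


@dataclass
class BeamLengthField:
    """Beam lengths indexed (phase, slice, angle) in mm with validity flags.

    Invalid entries (a ray that failed to intersect the contour) are NaN in
    ``lengths`` and False in ``valid`` -- never silently zero.
    """

    lengths: np.ndarray  # (P, S, 180)
    valid: np.ndarray  # bool, same shape
    slice_zs: np.ndarray  # (S,)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.slice_zs = np.asarray(self.slice_zs, dtype=float)
        if self.lengths.shape != self.valid.shape:
            raise ValueError("lengths and valid shapes differ")
        if self.lengths.ndim != 3 or self.lengths.shape[2] != N_BEAMS:
            raise ValueError(f"field must be (phases, slices, {N_BEAMS})")
        if np.any(self.lengths[self.valid] <= 0):
            raise ValueError("valid beam lengths must be positive")

    @property
    def n_phases(self) -> int:
        return self.lengths.shape[0]

    @property
    def n_slices(self) -> int:
        return self.lengths.shape[1]


def polygon_area(contour: ContourSlice) -> float:
    """Enclosed area of the contour polygon, mm^2 (positive)."""
    return abs(_signed_area(contour.vertices))


def polygon_centroid(contour: ContourSlice) -> tuple[float, float]:
    """Area-weighted centroid of the closed polygon (shoelace construction).

    Independent of vertex ordering direction and starting vertex, and robust
    to uneven vertex density (unlike the plain vertex mean).
    """
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return cx, cy


def fit_axis(centroids: list[tuple[tuple[float, float], float]]) -> BodyAxis:
    """Fit the central craniocaudal axis through slice centroids.

    Two independent ordinary least-squares lines, x on z and y on z.
    Recovers collinear centroids exactly.  Raises if fewer than two distinct
    z values are given.
    """
    if len(centroids) < 2:
        raise ValueError("axis fit needs >= 2 centroids")
    xy = np.array([c[0] for c in centroids], dtype=float)
    z = np.array([c[1] for c in centroids], dtype=float)
    if np.allclose(z, z[0]):
        raise ValueError("axis fit needs >= 2 distinct z values")
    A = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(A, xy, rcond=None)
    (x0, y0), (sx, sy) = coef[0], coef[1]
    if not np.all(np.isfinite(coef)):
        raise ValueError("axis fit produced non-finite coefficients")
    return BodyAxis(float(x0), float(sx), float(y0), float(sy))


def cast_rays(origin, angles_deg, contour: ContourSlice) -> np.ndarray:
    """Cast many rays from ``origin`` against one contour; vectorised.

    For each angle the parametric ray origin + t*d(theta), t > 0, is
    intersected with every polygon edge and the LARGEST t is returned: when
    a ray crosses the skin more than once (folds), the outermost crossing is
    the surface an optical camera sees.  Rays with no forward intersection
    return NaN.
    """
    o = np.asarray(origin, dtype=float)
    d = beam_direction(angles_deg)  # (K, 2)
    if d.ndim == 1:
        d = d[None, :]
    v = contour.vertices
    p1 = v  # (E, 2)
    e = np.roll(v, -1, axis=0) - v  # edge vectors
    # Solve o + t d = p1 + s e  =>  [d, -e] [t, s]^T = p1 - o
    w = p1 - o  # (E, 2)
    # 2x2 cramer per (ray, edge): denom = d x (-e) -> use d x e
    denom = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]  # (K, E)
    wxe = w[None, :, 0] * e[None, :, 1] - w[None, :, 1] * e[None, :, 0]  # (1->K, E)
    dxw = d[:, None, 0] * w[None, :, 1] - d[:, None, 1] * w[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = wxe / denom
        s = -dxw / denom  # t*d - s*e = w  =>  s = (w x d) / (d x e)
    eps = 1e-12
    hit = (np.abs(denom) > eps) & (s >= -1e-9) & (s <= 1.0 + 1e-9) & (t > eps)
    t = np.where(hit, t, -np.inf)
    tmax = t.max(axis=1)
    return np.where(np.isfinite(tmax), tmax, np.nan)


def cast_beam(origin, angle_deg: float, contour: ContourSlice) -> float:
    """Length of one radial beam from origin to the outermost skin crossing, mm.

    Raises ValueError when the ray does not intersect the contour (origin
    outside, or degenerate geometry).
    """
    length = float(cast_rays(origin, [angle_deg], contour)[0])
    if np.isnan(length):
        raise ValueError(
            f"beam at {angle_deg} deg from {tuple(np.asarray(origin))} does not "
            f"intersect the contour at z={contour.z}"
        )
    return length


def build_beam_length_field(
    phase_sets: list[PhaseContourSet], axis: BodyAxis
) -> BeamLengthField:
    """Beam lengths for every (phase, slice, angle) from the fixed axis.

    The beam origin on each slice is the axis point (x(z), y(z)) and is held
    identical across phases, so length variation reflects skin motion rather
    than centroid drift.  Slices with more than 5% invalid beams are logged
    as warnings; a slice invalid at every beam in some phase is an error.
    """
    if not phase_sets:
        raise ValueError("no phases given")
    zs = phase_sets[0].slice_zs
    for ps in phase_sets[1:]:
        if not np.array_equal(ps.slice_zs, zs):
            raise ValueError(f"phase {ps.phase} has a different z grid")
    P, S = len(phase_sets), len(zs)
    lengths = np.full((P, S, N_BEAMS), np.nan)
    for pi, ps in enumerate(phase_sets):
        for si, sl in enumerate(ps.slices):
            origin = axis.point_at(sl.z)
            lengths[pi, si] = cast_rays(origin, BEAM_ANGLES_DEG, sl)
    valid = np.isfinite(lengths)
    for si in range(S):
        n_invalid = int((~valid[:, si]).sum())
        if n_invalid:
            logger.warning(
                "slice %d (z=%.1f mm): %d invalid beams", si, zs[si], n_invalid
            )
        if np.any((~valid[:, si]).all(axis=1)):
            raise ValueError(f"slice {si} (z={zs[si]}) has no valid beams in a phase")
        if n_invalid > 0.05 * P * N_BEAMS:
            logger.warning(
                "slice %d: more than 5%% of beams invalid (%d)", si, n_invalid
            )
    return BeamLengthField(lengths=lengths, valid=valid, slice_zs=zs)


def ts_centroid_z(ts_contours_per_phase: list[list[ContourSlice]]) -> TSTrajectory:
    """Craniocaudal centroid of the tracking structure, one value per phase.

    The TS centroid z is the area-weighted mean of its slice heights
    (a discrete volume centroid; only the craniocaudal direction is used).
    """
    out = []
    for pi, stack in enumerate(ts_contours_per_phase):
        if not stack:
            raise ValueError(f"tracking structure empty in phase {pi}")
        areas = np.array([polygon_area(s) for s in stack])
        zvals = np.array([s.z for s in stack])
        out.append(float(np.sum(areas * zvals) / np.sum(areas)))
    return TSTrajectory(np.array(out))
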