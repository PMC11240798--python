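"""Per-beam correlation and magnitude maps.

For every beam (slice, angle) the Pearson correlation between its length
across the respiratory phases and the tracking structure's craniocaudal
coordinate gives the skin-to-TS correlation map; the peak-to-peak beam
length excursion gives the respiratory magnitude map.  Beams whose length
series has zero variance (motionless skin) are flagged undefined rather
than set to zero: a motionless beam is not "uncorrelated", it carries no
correlation at all.  Beams invalid in any phase are likewise flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import BeamLengthField, TSTrajectory

UNDEFINED_REASONS = {
    0: "",
    1: "invalid beam in some phase",
    2: "zero variance in beam lengths",
    3: "zero variance in TS trajectory",
}

__all__ = [
    "CorrelationMap",
    "MagnitudeMap",
    "pearson_map",
    "magnitude_map",
    "ts_magnitude",
    "maps_to_frame",
    "render_maps",
]


@dataclass
class CorrelationMap:
    """Per-(slice, angle) Pearson R; NaN + reason code where undefined."""

    r: np.ndarray  # (S, 180)
    valid: np.ndarray  # bool
    reason: np.ndarray  # uint8 codes into UNDEFINED_REASONS
    slice_zs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.abs(self.r[self.valid]) > 1 + 1e-12):
            raise ValueError("|R| must be <= 1 where defined")


@dataclass
class MagnitudeMap:
    """Per-(slice, angle) peak-to-peak excursion, mm; NaN where undefined."""

    m: np.ndarray  # (S, 180)
    valid: np.ndarray
    slice_zs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.m[self.valid] < 0):
            raise ValueError("magnitudes must be >= 0")


def pearson_map(field: BeamLengthField, ts: TSTrajectory) -> CorrelationMap:
    """Sample Pearson R between each beam's lengths and the TS coordinate.

    Requires the field's phase count to match the trajectory and at least
    3 phases.  Raises if every beam ends up undefined.
    """
    if field.n_phases != ts.n_phases:
        raise ValueError("phase count of field and TS trajectory differ")
    if field.n_phases < 3:
        raise ValueError("need >= 3 phases for a correlation")
    L = field.lengths  # (P, S, K)
    beam_ok = field.valid.all(axis=0)  # (S, K)
    z = ts.z_per_phase - ts.z_per_phase.mean()
    ts_var = float(z @ z)
    Lc = L - L.mean(axis=0, keepdims=True)
    num = np.einsum("psk,p->sk", np.nan_to_num(Lc), z)
    den_beam = np.sqrt(np.nan_to_num(Lc**2).sum(axis=0))
    reason = np.zeros(beam_ok.shape, dtype=np.uint8)
    reason[~beam_ok] = 1
    # a motionless beam is detected on the exact value span so rounding in
    # the demeaning step cannot let a constant series through
    Ln = np.nan_to_num(L)
    zero_var = beam_ok & (Ln.max(axis=0) == Ln.min(axis=0))
    reason[zero_var] = 2
    if ts.z_per_phase.max() == ts.z_per_phase.min():
        reason[beam_ok & ~zero_var] = 3
    den_beam = np.where(den_beam > 0, den_beam, 1.0)
    valid = reason == 0
    r = np.full(beam_ok.shape, np.nan)
    rv = num / (den_beam * np.sqrt(ts_var if ts_var > 0 else 1.0))
    r[valid] = np.clip(rv[valid], -1.0, 1.0)
    if not valid.any():
        raise ValueError("every beam is undefined in the correlation map")
    return CorrelationMap(r=r, valid=valid, reason=reason, slice_zs=field.slice_zs)


def magnitude_map(field: BeamLengthField) -> MagnitudeMap:
    """Peak-to-peak beam length excursion (max - min over phases), mm."""
    if field.n_phases < 2:
        raise ValueError("need >= 2 phases for a magnitude")
    beam_ok = field.valid.all(axis=0)
    m = np.full(beam_ok.shape, np.nan)
    L = np.nan_to_num(field.lengths)
    m_all = L.max(axis=0) - L.min(axis=0)
    m[beam_ok] = m_all[beam_ok]
    return MagnitudeMap(m=m, valid=beam_ok, slice_zs=field.slice_zs)


def ts_magnitude(ts: TSTrajectory) -> float:
    """Respiratory magnitude of the tracking structure: max - min, mm."""
    if ts.n_phases < 2:
        raise ValueError("need >= 2 phases")
    return float(ts.z_per_phase.max() - ts.z_per_phase.min())


def maps_to_frame(cmap: CorrelationMap, mmap: MagnitudeMap) -> pd.DataFrame:
    """Long-format table: slice_index, z_mm, angle_deg, pearson_r,
    magnitude_mm, valid_flag."""
    S, K = cmap.r.shape
    si, ai = np.meshgrid(np.arange(S), np.arange(K), indexing="ij")
    return pd.DataFrame(
        {
            "slice_index": si.ravel(),
            "z_mm": cmap.slice_zs[si.ravel()],
            "angle_deg": ai.ravel().astype(float),
            "pearson_r": cmap.r.ravel(),
            "magnitude_mm": mmap.m.ravel(),
            "valid_flag": (cmap.valid & mmap.valid).ravel(),
        }
    )


def render_maps(cmap: CorrelationMap, mmap: MagnitudeMap, out_dir) -> list[Path]:
    """Write the angle x slice heat images as PNG; best-effort.

    The correlation image is binned with anchors at R < 0.5 (black) and
    R > 0.95 (deep blue); the magnitude image uses a green-to-red ramp.
    Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    bounds = [-1.0, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 1.0]
    colors = ["black", "#7f0000", "#d95f02", "#e6c800", "#66a61e", "#1f78b4", "#08306b"]
    cmap_r = LinearSegmentedColormap.from_list("skin_r", colors, N=len(colors))
    norm = BoundaryNorm(bounds, cmap_r.N)
    for name, data, kw in [
        ("correlation_map.png", cmap.r, {"cmap": cmap_r, "norm": norm}),
        ("magnitude_map.png", mmap.m, {"cmap": "RdYlGn_r"}),
    ]:
        fig, ax = plt.subplots(figsize=(6, 4))
        im = ax.imshow(
            data.T,
            origin="lower",
            aspect="auto",
            extent=(cmap.slice_zs[0], cmap.slice_zs[-1], 0, 180),
            **kw,
        )
        ax.set_xlabel("slice z (mm)")
        ax.set_ylabel("beam angle (deg)")
        fig.colorbar(im, ax=ax)
        p = out_dir / name
        fig.savefig(p, dpi=110)
        plt.close(fig)
        paths.append(p)
    return paths
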