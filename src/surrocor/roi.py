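"""Nine-ROI partition of the torso surface and per-ROI map summaries.

The torso skin is divided into a 3 x 3 grid of regions of interest:
columns by beam angle (right [30, 75) deg, central [75, 105) deg, left
[105, 150) deg, roughly the regions right of, between and left of the
parasternal lines) and rows by craniocaudal landmarks (row A above the
xipho-sternal line, row B between the xipho-sternal line and the subcostal
plane, row C from the subcostal plane down to the inferior limit near
L4/umbilicus).  Beams lateral of the 30-150 deg span, or outside the z
limits, belong to no ROI.  Angular bins are half-open, so each boundary
beam belongs to exactly one region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maps import CorrelationMap, MagnitudeMap

ROI_LABELS = ["A", "A_R", "A_L", "B", "B_R", "B_L", "C", "C_R", "C_L"]

_ANGULAR_BANDS = {  # suffix -> [lo, hi) in degrees
    "_R": (30.0, 75.0),
    "": (75.0, 105.0),
    "_L": (105.0, 150.0),
}

__all__ = ["ROI_LABELS", "ROIPartition", "label_beams", "summarize_roi"]


@dataclass
class ROIPartition:
    """Craniocaudal landmark heights (mm) bounding the three ROI rows.

    Rows: A in [z_xiphosternal, z_superior_limit), B in
    [z_subcostal, z_xiphosternal), C in [z_inferior_limit, z_subcostal).
    Landmarks are per-patient inputs located anatomically on the CT.
    """

    z_xiphosternal: float
    z_subcostal: float
    z_inferior_limit: float
    z_superior_limit: float

    def __post_init__(self) -> None:
        if not (
            self.z_inferior_limit
            < self.z_subcostal
            < self.z_xiphosternal
            < self.z_superior_limit
        ):
            raise ValueError(
                "landmarks must satisfy inferior < subcostal < xiphosternal < superior"
            )


def _row_of(z: np.ndarray, part: ROIPartition) -> np.ndarray:
    """Row letter per slice z, '' where outside the row limits."""
    row = np.full(z.shape, "", dtype=object)
    row[(z >= part.z_xiphosternal) & (z < part.z_superior_limit)] = "A"
    row[(z >= part.z_subcostal) & (z < part.z_xiphosternal)] = "B"
    row[(z >= part.z_inferior_limit) & (z < part.z_subcostal)] = "C"
    return row


def label_beams(partition: ROIPartition, slice_zs, n_angles: int = 180) -> np.ndarray:
    """ROI label per beam: (n_slices, n_angles) object array, '' = unassigned."""
    zs = np.asarray(slice_zs, dtype=float)
    rows = _row_of(zs, partition)
    angles = np.arange(n_angles, dtype=float)
    cols = np.full(angles.shape, None, dtype=object)
    for suffix, (lo, hi) in _ANGULAR_BANDS.items():
        cols[(angles >= lo) & (angles < hi)] = suffix
    labels = np.full((zs.size, n_angles), "", dtype=object)
    for si in range(zs.size):
        if not rows[si]:
            continue
        for ai in range(n_angles):
            if cols[ai] is not None:
                labels[si, ai] = rows[si] + cols[ai]
    missing = [lab for lab in ROI_LABELS if not np.any(labels == lab)]
    if missing:
        raise ValueError(f"ROIs with zero beams: {', '.join(missing)}")
    return labels


def summarize_roi(
    cmap: CorrelationMap,
    mmap: MagnitudeMap,
    labels: np.ndarray,
    aggregator: str = "mean",
) -> pd.DataFrame:
    """Aggregate the maps over each of the nine ROIs.

    ``aggregator`` is "mean" (default) or "median".  Undefined beams are
    excluded and counted; an ROI whose beams are all undefined is an error.
    Returns a DataFrame indexed by ROI label with columns magnitude_mm,
    pearson_r, n_beams_magnitude, n_beams_r, aggregator.
    """
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    if labels.shape != cmap.r.shape or labels.shape != mmap.m.shape:
        raise ValueError("label grid shape must match the maps")
    agg = np.mean if aggregator == "mean" else np.median
    records = []
    for lab in ROI_LABELS:
        in_roi = labels == lab
        m_ok = in_roi & mmap.valid
        r_ok = in_roi & cmap.valid
        if not m_ok.any() or not r_ok.any():
            raise ValueError(f"ROI {lab} has no defined beams")
        records.append(
            {
                "roi": lab,
                "magnitude_mm": float(agg(mmap.m[m_ok])),
                "pearson_r": float(agg(cmap.r[r_ok])),
                "n_beams_magnitude": int(m_ok.sum()),
                "n_beams_r": int(r_ok.sum()),
                "aggregator": aggregator,
            }
        )
    return pd.DataFrame.from_records(records).set_index("roi")
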