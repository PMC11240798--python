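"""End-to-end pipeline: per-patient maps, ROI summaries and adiposity,
assembled into the cohort table and the cohort statistics reports.

Each patient lives in one directory::

    patient_dir/
      contours.json     skin contour set, all phases (io schema)
      ts.csv            tracking-structure trajectory (phase, z_mm)
      patient.json      covariates + ROI landmarks
      hu_l4.csv         L4 HU grid (optional together with inner_wall.json)
      inner_wall.json   inner abdominal wall polygon

A failing patient is recorded in the run manifest and skipped; the cohort
stage runs over the survivors and requires at least two of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from . import maps as maps_mod
from .adipose import adipose_mask, adipose_percentages, split_sat_vat
from .geometry import build_beam_length_field, fit_axis, polygon_centroid
from .roi import label_beams, summarize_roi
from .stats import build_reports

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_patient", "run_pipeline"]


@dataclass
class RunConfig:
    patient_dirs: list[Path]
    out_dir: Path
    aggregator: str = "mean"
    reference_kind: str = "body"
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        self.patient_dirs = [Path(p) for p in self.patient_dirs]
        self.out_dir = Path(self.out_dir)
        if self.aggregator not in ("mean", "median"):
            raise ValueError("aggregator must be 'mean' or 'median'")
        missing = [str(p) for p in self.patient_dirs if not p.is_dir()]
        if missing:
            raise ValueError(f"patient directories not found: {', '.join(missing)}")


def run_patient(
    patient_dir: Path,
    out_dir: Path,
    aggregator: str = "mean",
    reference_kind: str = "body",
) -> dict:
    """Analyse one patient directory; writes its CSVs and returns the
    cohort-table row."""
    patient_dir = Path(patient_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    meta, partition = sio.read_patient_meta(patient_dir / "patient.json")
    phase_sets = sio.read_contour_set(patient_dir / "contours.json")
    ts = sio.read_ts_trajectory(patient_dir / "ts.csv")

    centroids = [(polygon_centroid(sl), sl.z) for sl in phase_sets[0].slices]
    axis = fit_axis(centroids)
    fieldd = build_beam_length_field(phase_sets, axis)
    cmap = maps_mod.pearson_map(fieldd, ts)
    mmap = maps_mod.magnitude_map(fieldd)
    n_undefined = int((~(cmap.valid & mmap.valid)).sum())
    if n_undefined:
        logger.info("%s: %d undefined beams excluded", meta["patient_id"], n_undefined)
    maps_mod.maps_to_frame(cmap, mmap).to_csv(out_dir / "maps.csv", index=False)

    labels = label_beams(partition, fieldd.slice_zs)
    summary = summarize_roi(cmap, mmap, labels, aggregator=aggregator)
    summary.assign(patient_id=meta["patient_id"]).to_csv(out_dir / "roi_summary.csv")

    row = {
        **meta,
        "ts_magnitude_mm": maps_mod.ts_magnitude(ts),
    }
    hu_path = patient_dir / "hu_l4.csv"
    if hu_path.exists():
        hu = sio.read_hu_slice(hu_path)
        wall = sio.read_polygon(patient_dir / "inner_wall.json")
        fat = adipose_mask(hu)
        sat, vat = split_sat_vat(fat, wall, hu)
        adip = adipose_percentages(sat, vat, hu, reference_kind=reference_kind)
        row.update(
            sat_pct=adip.sat_pct, vat_pct=adip.vat_pct, tat_pct=adip.tat_pct
        )
        pd.DataFrame(
            [{
                "patient_id": meta["patient_id"],
                "sat_pct": adip.sat_pct,
                "vat_pct": adip.vat_pct,
                "tat_pct": adip.tat_pct,
                "reference_kind": adip.reference_kind,
            }]
        ).to_csv(out_dir / "adipose.csv", index=False)
    for lab in summary.index:
        row[f"mag_{lab}"] = summary.loc[lab, "magnitude_mm"]
        row[f"r_{lab}"] = summary.loc[lab, "pearson_r"]
    return row


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every patient, then the cohort stage; returns the manifest.

    Writes per-patient outputs under ``out/<patient_dir_name>/``, the
    assembled ``cohort.csv``, the statistics reports and ``manifest.csv``.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    rows, manifest = [], []
    for pdir in config.patient_dirs:
        try:
            row = run_patient(
                pdir, config.out_dir / pdir.name, config.aggregator,
                config.reference_kind,
            )
            rows.append(row)
            manifest.append({"patient_dir": str(pdir), "status": "ok", "error": ""})
        except Exception as exc:  # record and continue with the others
            logger.error("patient %s failed: %s", pdir, exc)
            manifest.append(
                {"patient_dir": str(pdir), "status": "failed", "error": str(exc)}
            )
    manifest_df = pd.DataFrame(manifest)
    manifest_df.to_csv(config.out_dir / "manifest.csv", index=False)
    if len(rows) >= 2:
        cohort = pd.DataFrame(rows)
        cohort.to_csv(config.out_dir / "cohort.csv", index=False)
        if {"sat_pct", "vat_pct", "tat_pct"}.issubset(cohort.columns) and not (
            cohort[["sat_pct", "vat_pct", "tat_pct"]].isna().any().any()
        ):
            build_reports(cohort, out_dir=config.out_dir / "reports",
                          aggregator=config.aggregator)
    else:
        logger.warning("cohort stage skipped: fewer than 2 successful patients")
    return manifest_df
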