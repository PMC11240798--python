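"""File formats: contour-set JSON, trajectory/HU/map CSVs, landmark JSON.

Contour sets travel as human-diffable JSON (schema below); everything
tabular is CSV.  All coordinates are millimetres in the package convention
(x to the patient's left, y anterior, z cranial); loaders for other frames
must remap before writing these files.

Contour-set schema (version 1)::

    {
      "format": "surrocor-contours", "version": 1, "units": "mm",
      "n_phases": 10,
      "phases": [
        {"phase": 0,
         "slices": [{"z": 0.0, "vertices": [[x, y], ...]}, ...]},
        ...
      ]
    }

Vertices may be clockwise or counter-clockwise; orientation is normalised
on load.  All phases must share an identical z grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .adipose import HUSlice
from .geometry import ContourSlice, PhaseContourSet, TSTrajectory
from .roi import ROIPartition

SCHEMA_FORMAT = "surrocor-contours"
SCHEMA_VERSION = 1

__all__ = [
    "write_contour_set",
    "read_contour_set",
    "write_ts_trajectory",
    "read_ts_trajectory",
    "write_hu_slice",
    "read_hu_slice",
    "write_polygon",
    "read_polygon",
    "read_patient_meta",
]


def write_contour_set(path, phase_sets: list[PhaseContourSet]) -> None:
    doc = {
        "format": SCHEMA_FORMAT,
        "version": SCHEMA_VERSION,
        "units": "mm",
        "n_phases": len(phase_sets),
        "phases": [
            {
                "phase": ps.phase,
                "slices": [
                    {"z": sl.z, "vertices": sl.vertices.tolist()} for sl in ps.slices
                ],
            }
            for ps in phase_sets
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_contour_set(path, check_simple: bool = True) -> list[PhaseContourSet]:
    """Load and validate a contour-set JSON file.

    Checks the schema header, the declared phase count, identical z grids
    across phases, and (optionally) polygon simplicity; raises with the
    offending phase/slice identified.
    """
    doc = json.loads(Path(path).read_text())
    for key in ("format", "version", "n_phases", "phases", "units"):
        if key not in doc:
            raise ValueError(f"{path}: missing schema key {key!r}")
    if doc["format"] != SCHEMA_FORMAT or doc["version"] != SCHEMA_VERSION:
        raise ValueError(f"{path}: not a {SCHEMA_FORMAT} v{SCHEMA_VERSION} file")
    if doc["units"] != "mm":
        raise ValueError(f"{path}: units must be mm")
    if len(doc["phases"]) != doc["n_phases"]:
        raise ValueError(
            f"{path}: file declares {doc['n_phases']} phases but holds "
            f"{len(doc['phases'])}"
        )
    phase_sets = []
    for pdoc in doc["phases"]:
        slices = []
        for sdoc in pdoc.get("slices", []):
            try:
                sl = ContourSlice(z=float(sdoc["z"]), vertices=np.asarray(sdoc["vertices"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: phase {pdoc.get('phase')}, slice z={sdoc.get('z')}: {exc}"
                ) from exc
            if check_simple and not shapely.LinearRing(sl.vertices).is_simple:
                raise ValueError(
                    f"{path}: phase {pdoc.get('phase')}, slice z={sl.z}: "
                    "self-intersecting contour"
                )
            slices.append(sl)
        if not slices:
            raise ValueError(f"{path}: phase {pdoc.get('phase')} has no slices")
        phase_sets.append(PhaseContourSet(phase=int(pdoc["phase"]), slices=slices))
    zs0 = phase_sets[0].slice_zs
    for ps in phase_sets[1:]:
        if not np.array_equal(ps.slice_zs, zs0):
            raise ValueError(f"{path}: phase {ps.phase} z grid differs from phase 0")
    return phase_sets


def write_ts_trajectory(path, ts: TSTrajectory) -> None:
    pd.DataFrame(
        {"phase": np.arange(ts.n_phases), "z_mm": ts.z_per_phase}
    ).to_csv(path, index=False)


def read_ts_trajectory(path) -> TSTrajectory:
    df = pd.read_csv(path)
    for col in ("phase", "z_mm"):
        if col not in df.columns:
            raise ValueError(f"{path}: trajectory CSV needs a {col!r} column")
    return TSTrajectory(df.sort_values("phase")["z_mm"].to_numpy())


def write_hu_slice(path, sl: HUSlice) -> None:
    """HU grid as CSV; pixel spacing in a leading comment line."""
    px, py = sl.pixel_spacing
    with open(path, "w") as fh:
        fh.write(f"# pixel_spacing_mm={px},{py}\n")
        np.savetxt(fh, sl.hu, fmt="%.1f", delimiter=",")


def read_hu_slice(path, body_threshold: float = -200.0) -> HUSlice:
    """Read an HU CSV grid; the body mask is HU >= ``body_threshold``."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# pixel_spacing_mm="):
            raise ValueError(f"{path}: missing pixel_spacing_mm header")
        px, py = (float(v) for v in header.split("=", 1)[1].split(","))
        hu = np.loadtxt(fh, delimiter=",")
    return HUSlice(hu=hu, pixel_spacing=(px, py), body_mask=hu >= body_threshold)


def write_polygon(path, vertices: np.ndarray) -> None:
    Path(path).write_text(
        json.dumps({"units": "mm", "vertices": np.asarray(vertices).tolist()})
    )


def read_polygon(path) -> np.ndarray:
    doc = json.loads(Path(path).read_text())
    v = np.asarray(doc["vertices"], dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError(f"{path}: polygon needs >= 3 (x, y) vertices")
    return v


def read_patient_meta(path) -> tuple[dict, ROIPartition]:
    """Per-patient JSON: covariates + ROI landmark heights.

    Expected keys: patient_id, sex, height_cm, bmi and a ``landmarks``
    object with z_xiphosternal, z_subcostal, z_inferior_limit,
    z_superior_limit (mm).
    """
    doc = json.loads(Path(path).read_text())
    missing = [k for k in ("patient_id", "sex", "height_cm", "bmi", "landmarks") if k not in doc]
    if missing:
        raise ValueError(f"{path}: missing keys {', '.join(missing)}")
    lm = doc["landmarks"]
    part = ROIPartition(
        z_xiphosternal=float(lm["z_xiphosternal"]),
        z_subcostal=float(lm["z_subcostal"]),
        z_inferior_limit=float(lm["z_inferior_limit"]),
        z_superior_limit=float(lm["z_superior_limit"]),
    )
    meta = {k: doc[k] for k in ("patient_id", "sex", "height_cm", "bmi")}
    return meta, part
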