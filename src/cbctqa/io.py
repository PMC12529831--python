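"""Volume, mask and table I/O.

Volumes are 3-D Hounsfield-unit grids stored as NIfTI-1; voxel spacing is
carried in the affine (diagonal, mm).  Scan-level metadata (modality,
fraction, patient) has no standard NIfTI slot and therefore travels in a
sidecar manifest CSV, one row per scan.  Ratings and metric outputs are
plain UTF-8 CSV with a header row.

Conventions: voxel indices are 0-based; physical coordinates are
``index * spacing`` (voxel-center, mm); the axial slice is a fixed
third-axis index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("cbctqa")

PLANNING_CT = "planning-CT"
CBCT = "CBCT"
MODALITIES = (PLANNING_CT, CBCT)

#: Columns every ratings table must carry.  ``time_s`` is optional.
RATING_COLUMNS = ("observer", "patient", "scan", "parameter", "score")


@dataclasses.dataclass
class Volume:
    """A 3-D attenuation grid (HU) with spacing and scan metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Attenuation values in Hounsfield units.
    spacing : tuple of float
        Voxel spacing in mm per axis; all entries must be positive.
    modality : str
        ``"planning-CT"`` or ``"CBCT"``.
    fraction : int
        0 for the planning scan, 1..k for treatment fractions.
    patient_id : str
    scan_id : str
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: str = CBCT
    fraction: int = 1
    patient_id: str = "NA"
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError(
                f"volume must be a non-empty 3-D grid, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if self.fraction < 0:
            raise ValueError("fraction index must be >= 0")
        # Study convention: fraction 0 is the planning scan.
        if (self.fraction == 0) != (self.modality == PLANNING_CT):
            raise ValueError(
                f"fraction {self.fraction} is inconsistent with modality "
                f"{self.modality!r}: fraction 0 <=> planning-CT"
            )
        if not self.scan_id:
            self.scan_id = f"{self.patient_id}_fx{self.fraction}"

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclasses.dataclass(frozen=True)
class RatingRecord:
    """One observer x scan x parameter Likert score."""

    observer: str
    patient: str
    scan: str
    parameter: str
    score: int
    time_s: float | None = None

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3, 4, 5):
            raise ValueError(f"score must be an integer in 1..5, got {self.score}")
        if self.time_s is not None and self.time_s < 0:
            raise ValueError("assessment time must be >= 0")


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(volume: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (spacing in the affine, float32 data)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), _affine(volume.spacing))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, meta: Mapping[str, object] | None = None) -> Volume:
    """Read a NIfTI-1 volume; ``meta`` supplies manifest metadata.

    ``meta`` must provide ``modality``, ``fraction`` and ``patient`` (a
    manifest row works directly); a missing field raises naming it.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar volume, got {data.ndim}-D data")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = dict(meta or {})
    for field in ("modality", "fraction", "patient"):
        if field not in meta or meta[field] is None or (
            isinstance(meta[field], float) and np.isnan(meta[field])
        ):
            raise ValueError(f"{path}: manifest metadata missing required field {field!r}")
    return Volume(
        data=data,
        spacing=spacing,
        modality=str(meta["modality"]),
        fraction=int(meta["fraction"]),  # type: ignore[arg-type]
        patient_id=str(meta["patient"]),
        scan_id=str(meta.get("scan_id") or ""),
    )


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> Path:
    """Write an integer label mask as NIfTI-1 (int16)."""
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3-D, got shape {mask.shape}")
    img = nib.Nifti1Image(mask.astype(np.int16), _affine(tuple(spacing)))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Read an integer label mask; optionally check it matches ``shape``."""
    img = nib.load(str(path))
    mask = np.asanyarray(img.dataobj)
    if mask.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label mask, got {mask.ndim}-D data")
    if not np.issubdtype(mask.dtype, np.integer):
        rounded = np.rint(mask)
        if not np.array_equal(rounded, mask):
            raise ValueError(f"{path}: mask contains non-integer labels")
        mask = rounded
    mask = mask.astype(np.int32)
    if shape is not None and tuple(mask.shape) != tuple(shape):
        raise ValueError(
            f"{path}: mask shape {mask.shape} does not match volume shape {tuple(shape)}"
        )
    return mask


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read a ratings CSV into a validated table of Likert records.

    Required columns: observer, patient, scan, parameter, score; ``time_s``
    is optional.  An empty file (header only) yields an empty table.
    Malformed rows are rejected together, citing 1-based data row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ratings table missing columns {missing}")
    if df.empty:
        return df
    bad_rows: list[str] = []
    scores = pd.to_numeric(df["score"], errors="coerce")
    ok = scores.isin([1, 2, 3, 4, 5])
    for idx in df.index[~ok]:
        bad_rows.append(f"row {idx + 1}: score {df.loc[idx, 'score']!r} outside 1..5")
    if "time_s" in df.columns:
        times = pd.to_numeric(df["time_s"], errors="coerce")
        neg = times < 0
        for idx in df.index[neg.fillna(False)]:
            bad_rows.append(f"row {idx + 1}: negative time {df.loc[idx, 'time_s']!r}")
    if bad_rows:
        raise ValueError(f"{path}: malformed ratings rows: " + "; ".join(bad_rows))
    df = df.copy()
    df["score"] = scores.astype(int)
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy table as UTF-8 CSV with a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def config_hash(config_dict: Mapping) -> str:
    """Stable short hash of a configuration mapping, for run provenance."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
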