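"""Readers and writers for SUV volumes, masks, lesion tables and survival tables.

Volumes and integer label maps travel as NIfTI-1 with voxel spacing (mm)
in the header; lesion and survival tables as UTF-8 CSV with a header
row; metric reports as JSON.  Array axis order is (x, y, z) and matches
the spacing triple; voxel coordinates are 0-based.  All volumes are in
ml (1 ml = 1000 mm^3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .anatomy import validate_labels

#: null token for absent subregion labels in CSV (absent != empty string)
NULL_TOKEN = "NA"

LESION_REQUIRED_COLUMNS = ("patient_id", "focus_id", "classification")
LESION_OPTIONAL_COLUMNS = (
    "measurable",
    "mtv_ml",
    "volume_ml",
    "suvmax",
    "suvpeak",
    "body_part",
    "region",
    "subregion",
)


class DimensionalityError(ValueError):
    """Volume is not 3-D."""


class ValidationError(ValueError):
    """Input violates a declared invariant."""


@dataclass
class SUVVolume:
    """A 3-D grid of body-weight SUV values.

    Parameters
    ----------
    data
        SUV values, shape (nx, ny, nz); dimensionless, non-negative.
    spacing
        Voxel edge lengths in mm for the (x, y, z) axes.
    patient_id
        Identifier of the scanned patient.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (3.18, 3.18, 5.0)
    patient_id: str = "anonymous"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"SUV volume must be 3-D, got {self.data.ndim}-D"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")
        n_neg = int(np.sum(self.data < 0))
        if n_neg:
            raise ValidationError(f"SUV volume contains {n_neg} negative voxel(s)")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def write_suv_volume(volume: SUVVolume, path: str | Path) -> None:
    """Write an SUV volume as NIfTI-1 with spacing in the header."""
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_suv_volume(path: str | Path, patient_id: str | None = None) -> SUVVolume:
    """Read an SUV volume from NIfTI-1; spacing taken from the header.

    Raises
    ------
    DimensionalityError
        If the image is not 3-D.
    ValidationError
        If the image contains negative voxels.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3-D volume, got {data.ndim}-D at {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if patient_id is None:
        patient_id = Path(path).name.split(".")[0]
    return SUVVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing,
                     patient_id=patient_id)


def write_mask(mask: np.ndarray, spacing: tuple[float, float, float],
               path: str | Path) -> None:
    """Write an integer label map as NIfTI-1."""
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read an integer label map; returns (array, spacing in mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3-D label map, got {data.ndim}-D at {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.int64), spacing


def _validate_lesion_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LESION_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"lesion table missing columns: {missing}")
    dup = df.duplicated(subset=["patient_id", "focus_id"])
    if dup.any():
        keys = df.loc[dup, ["patient_id", "focus_id"]].itertuples(index=False)
        raise ValidationError(
            "duplicate (patient_id, focus_id) keys: " + ", ".join(map(str, keys))
        )
    bad_class = ~df["classification"].isin(["suspicious", "unsuspicious"])
    if bad_class.any():
        raise ValidationError(
            f"unknown classification values: {sorted(df.loc[bad_class, 'classification'].unique())}"
        )
    if {"body_part", "region"} <= set(df.columns):
        for row in df.itertuples(index=False):
            sub = getattr(row, "subregion", None)
            if pd.isna(sub):
                sub = None
            validate_labels(row.body_part, row.region, sub)
    if "mtv_ml" in df.columns and (pd.to_numeric(df["mtv_ml"]) <= 0).any():
        raise ValidationError("retained foci must have MTV > 0 ml")
    return df


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    """Read a lesion table CSV; absent subregions come back as <NA>."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[NULL_TOKEN])
    if "subregion" in df.columns:
        df["subregion"] = df["subregion"].astype("object")
        df["subregion"] = df["subregion"].where(df["subregion"].notna(), pd.NA)
    if "measurable" in df.columns:
        df["measurable"] = df["measurable"].astype(bool)
    return _validate_lesion_table(df)


def write_lesion_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a lesion table CSV (round-trip stable with read_lesion_table)."""
    _validate_lesion_table(df)
    df.to_csv(path, index=False, na_rep=NULL_TOKEN)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival table: patient_id, time_months, event, covariates."""
    df = pd.read_csv(path)
    for col in ("patient_id", "time_months", "event"):
        if col not in df.columns:
            raise ValidationError(f"survival table missing column {col!r}")
    if (df["time_months"] <= 0).any():
        raise ValidationError("survival times must be > 0 months")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")
    return df


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    """Write a metric report as indented JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
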