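"""Volumetric mask and subject-table I/O.

Masks live on a regular 3-D grid with anisotropic voxel spacing in mm and
carry integer labels: 0 = background, 1 = artery, 2 = vein.  A plain binary
segmentation is represented with all foreground as label 1 (treated as
all-artery downstream unless the caller states otherwise).

All computation in this package happens in index/spacing space: world
position = origin + index * spacing.  Direction cosines are not modelled;
volumes with a non-identity orientation are accepted with a warning because
radii and volumes are purely metric quantities.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import (
    DimensionalityError,
    LabelError,
    MaskFormatError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

VALID_LABELS = frozenset({0, 1, 2})

#: label meanings used throughout the package
BACKGROUND, ARTERY, VEIN = 0, 1, 2

SUBJECT_COLUMNS = ["id", "group", "age", "sex", "height_cm", "weight_kg"]


@dataclass
class VoxelMask:
    """A labelled voxel grid with physical spacing.

    Parameters
    ----------
    labels
        3-D integer array; values must be in {0, 1, 2}.
    spacing
        (sx, sy, sz) voxel edge lengths in mm, each strictly positive.
    origin
        World coordinate of voxel (0, 0, 0) in mm.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got {self.labels.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValidationError("spacing must have three components")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive and finite, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        self.validate_labels()

    def validate_labels(self) -> None:
        present = np.unique(self.labels)
        bad = [int(v) for v in present if int(v) not in VALID_LABELS]
        if bad:
            raise LabelError(
                f"mask contains label(s) {bad} outside the 0/1/2 "
                "(background/artery/vein) convention; pass a remap table"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def foreground(self, compartment: str = "all") -> np.ndarray:
        """Boolean foreground for a compartment ('artery', 'vein' or 'all')."""
        if compartment == "all":
            return self.labels > 0
        if compartment == "artery":
            return self.labels == ARTERY
        if compartment == "vein":
            return self.labels == VEIN
        raise ValueError(f"unknown compartment {compartment!r}")

    def foreground_count(self, compartment: str = "all") -> int:
        return int(self.foreground(compartment).sum())


@dataclass
class Subject:
    """Demographics for one study subject; BSA is computed, never read."""

    id: str
    group: str  # 'patient' or 'control'
    age: float
    sex: str  # 'male' or 'female'
    height_cm: float
    weight_kg: float
    bsa_m2: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValidationError(f"subject {self.id}: group must be patient/control, got {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"subject {self.id}: sex must be male/female, got {self.sex!r}")
        if not self.height_cm > 0:
            raise ValidationError(f"subject {self.id}: height must be positive, got {self.height_cm}")
        if not self.weight_kg > 0:
            raise ValidationError(f"subject {self.id}: weight must be positive, got {self.weight_kg}")


def _infer_dialect(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if name.endswith(".nrrd") or name.endswith(".nhdr"):
        return "nrrd"
    raise MaskFormatError(f"cannot infer volume format from filename {path.name!r}")


def read_mask(
    path: str | Path,
    dialect: str | None = None,
    remap: Mapping[int, int] | None = None,
) -> VoxelMask:
    """Read a NIfTI or NRRD label volume into a :class:`VoxelMask`.

    Spacing is taken from the file header (mm).  Nonzero labels outside
    {1, 2} raise :class:`LabelError` unless `remap` maps them onto the
    canonical scheme.
    """
    path = Path(path)
    if not path.exists():
        raise MaskFormatError(f"no such file: {path}")
    dialect = dialect or _infer_dialect(path)

    if dialect == "nifti":
        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises a zoo of types
            raise MaskFormatError(f"could not read {path} as NIfTI: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise DimensionalityError(f"{path}: expected 3-D volume, got {data.ndim}-D")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        affine = img.affine
        origin = tuple(float(v) for v in affine[:3, 3])
        rot = affine[:3, :3] / np.asarray(spacing)
        if not np.allclose(np.abs(rot), np.eye(3), atol=1e-3):
            warnings.warn(
                f"{path.name}: non-identity orientation; computing in index/spacing space",
                stacklevel=2,
            )
    elif dialect == "nrrd":
        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise MaskFormatError(f"could not read {path} as NRRD: {exc}") from exc
        if img.GetDimension() != 3:
            raise DimensionalityError(f"{path}: expected 3-D volume, got {img.GetDimension()}-D")
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
    else:
        raise MaskFormatError(f"unknown dialect {dialect!r}; use 'nifti' or 'nrrd'")

    labels = np.rint(data).astype(np.int64)
    if remap:
        out = labels.copy()
        for src, dst in remap.items():
            if dst not in VALID_LABELS:
                raise LabelError(f"remap target {dst} is not in {{0,1,2}}")
            out[labels == src] = dst
        labels = out
    return VoxelMask(labels=labels.astype(np.uint8, casting="unsafe"), spacing=spacing, origin=origin)


def write_mask(mask: VoxelMask, path: str | Path, dialect: str | None = None) -> Path:
    """Write a :class:`VoxelMask` to NIfTI or NRRD; round-trips through read_mask."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    data = np.ascontiguousarray(mask.labels.astype(np.uint8))
    try:
        if dialect == "nifti":
            affine = np.diag(list(mask.spacing) + [1.0])
            affine[:3, 3] = mask.origin
            nib.save(nib.Nifti1Image(data, affine), str(path))
        elif dialect == "nrrd":
            img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
            img.SetSpacing(mask.spacing)
            img.SetOrigin(mask.origin)
            sitk.WriteImage(img, str(path))
        else:
            raise MaskFormatError(f"unknown dialect {dialect!r}; use 'nifti' or 'nrrd'")
    except OSError as exc:
        raise MaskFormatError(f"could not write {path}: {exc}") from exc
    return path


def write_volume(
    data: np.ndarray,
    spacing: Sequence[float],
    path: str | Path,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> Path:
    """Write an arbitrary scalar volume (e.g. a radius field) to NIfTI/NRRD."""
    path = Path(path)
    dialect = _infer_dialect(path)
    if dialect == "nifti":
        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(np.ascontiguousarray(data), affine), str(path))
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(data).transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o) for o in origin))
        sitk.WriteImage(img, str(path))
    return path


def _subject_from_row(row: Mapping, where: str) -> Subject:
    try:
        return Subject(
            id=str(row["id"]),
            group=str(row["group"]).strip().lower(),
            age=float(row["age"]),
            sex=str(row["sex"]).strip().lower(),
            height_cm=float(row["height_cm"]),
            weight_kg=float(row["weight_kg"]),
        )
    except ValidationError as exc:
        raise ValidationError(f"{where}: {exc}") from exc


def read_subjects(path: str | Path) -> list[Subject]:
    """Read a subject table (CSV with header, or a JSON list of records).

    Required columns: id, group, age, sex, height_cm, weight_kg.
    BSA is left unset; fill it with :func:`vesselrad.quantify.compute_bsa`.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return [_subject_from_row(row, f"{path} row {i}") for i, row in df.iterrows()]


def subjects_to_frame(subjects: Sequence[Subject]) -> pd.DataFrame:
    """Tabulate subjects (one row each), including BSA where computed."""
    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "height_cm": [s.height_cm for s in subjects],
            "weight_kg": [s.weight_kg for s in subjects],
            "bsa": [s.bsa_m2 for s in subjects],
        }
    )
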