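"""Diameter-binned intrapulmonary vessel volume (IPVV) quantification.

Given a per-voxel radius field, each foreground voxel contributes its voxel
volume to the diameter bin containing d = 2r.  The five supra-threshold
bins are (0.8, 1.6], (1.6, 2.4], (2.4, 3.2], (3.2, 4.0] and (4.0, inf) mm
— strict lower bound, inclusive upper bound — with a sub-threshold bin
(0, 0.8] reported separately.  Headline totals exclude sub-threshold
voxels by default, treating 0.8 mm as the minimum reliable diameter on CT:

* IPVVa — arterial vessel volume (label 1),
* IPVVv — venous vessel volume (label 2),
* TIPVV = IPVVa + IPVVv.

Volumes are voxel-count based (vessel wall + lumen) in mL and, once a
subject's DuBois body surface area is attached, in mL·m⁻².
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError, VesselradError
from .io import ARTERY, VEIN, Subject, VoxelMask
from .radius import RadiusField

DEFAULT_EDGES = (0.8, 1.6, 2.4, 3.2, 4.0)

SUBTHRESHOLD = "<=0.8"
COMPARTMENTS = ("artery", "vein", "all")


@dataclass(frozen=True)
class DiameterBins:
    """Ordered diameter thresholds (mm) with strict-lower/inclusive-upper bins.

    ``edges = (0.8, 1.6, 2.4, 3.2, 4.0)`` defines the intervals
    (0.8, 1.6], (1.6, 2.4], (2.4, 3.2], (3.2, 4.0], (4.0, inf), plus the
    implicit sub-threshold interval (0, 0.8].
    """

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 1 or any(b <= a for a, b in zip(e, e[1:])) or e[0] <= 0:
            raise ValidationError(f"bin edges must be positive and strictly increasing, got {e}")

    @property
    def labels(self) -> list[str]:
        """Sub-threshold label followed by the supra-threshold interval labels."""

        def fmt(x: float) -> str:
            s = f"{x:g}"
            return s if "." in s else s + ".0"

        e = self.edges
        out = [f"<={fmt(e[0])}"]
        out += [f"{fmt(a)}-{fmt(b)}" for a, b in zip(e, e[1:])]
        out.append(f">{fmt(e[-1])}")
        return out

    @property
    def supra_labels(self) -> list[str]:
        return self.labels[1:]

    def assign(self, diameters: np.ndarray) -> np.ndarray:
        """Bin index per diameter: 0 = sub-threshold, 1..n the supra bins.

        A diameter exactly at an edge belongs to the lower interval
        (inclusive upper bound), e.g. d = 1.6 -> (0.8, 1.6].
        """
        return np.searchsorted(np.asarray(self.edges), diameters, side="left")


@dataclass
class VolumeReport:
    """Per-compartment, per-diameter-bin vessel volumes.

    ``counts`` holds integer voxel counts (rows 'artery'/'vein', one column
    per bin label, sub-threshold first); all volumes derive from these
    counts, so conservation holds exactly at the count level.  Totals
    exclude the sub-threshold bin unless ``include_subthreshold`` is set.
    """

    counts: pd.DataFrame
    voxel_volume_mm3: float
    bins: DiameterBins
    fallback_fraction: float = 0.0
    include_subthreshold: bool = False
    subject: Subject | None = None
    roi_applied: bool = False

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def volumes_ml(self) -> pd.DataFrame:
        """Volumes (mL) per compartment x bin, with a derived 'all' row."""
        df = self.counts.astype(np.float64) * self.voxel_volume_ml
        df.loc["all"] = df.loc["artery"] + df.loc["vein"]
        return df

    def _total(self, compartment: str) -> float:
        labels = self.bins.labels if self.include_subthreshold else self.bins.supra_labels
        return float(
            int(self.counts.loc[compartment, labels].sum()) * self.voxel_volume_ml
        )

    @property
    def ipvva_ml(self) -> float:
        return self._total("artery")

    @property
    def ipvvv_ml(self) -> float:
        return self._total("vein")

    @property
    def tipvv_ml(self) -> float:
        return self.ipvva_ml + self.ipvvv_ml

    @property
    def foreground_count(self) -> int:
        return int(self.counts.to_numpy().sum())

    def normalized(self) -> pd.DataFrame:
        """Volumes in mL·m⁻² (requires an attached subject with BSA)."""
        if self.subject is None or self.subject.bsa_m2 is None:
            raise VesselradError("no subject with computed BSA attached; call normalize_report")
        return self.volumes_ml() / self.subject.bsa_m2

    def to_dict(self) -> dict:
        vols = self.volumes_ml()
        out = {
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "bin_edges_mm": list(self.bins.edges),
            "include_subthreshold": self.include_subthreshold,
            "roi_applied": self.roi_applied,
            "fallback_voxel_fraction": self.fallback_fraction,
            "counts": {c: {b: int(self.counts.loc[c, b]) for b in self.counts.columns}
                       for c in self.counts.index},
            "volumes_ml": {c: {b: float(vols.loc[c, b]) for b in vols.columns}
                           for c in vols.index},
            "IPVVa_ml": self.ipvva_ml,
            "IPVVv_ml": self.ipvvv_ml,
            "TIPVV_ml": self.tipvv_ml,
        }
        if self.subject is not None and self.subject.bsa_m2 is not None:
            norm = self.normalized()
            out["subject_id"] = self.subject.id
            out["bsa_m2"] = self.subject.bsa_m2
            out["volumes_ml_per_m2"] = {
                c: {b: float(norm.loc[c, b]) for b in norm.columns} for c in norm.index
            }
            out["IPVVa_ml_per_m2"] = self.ipvva_ml / self.subject.bsa_m2
            out["IPVVv_ml_per_m2"] = self.ipvvv_ml / self.subject.bsa_m2
            out["TIPVV_ml_per_m2"] = self.tipvv_ml / self.subject.bsa_m2
        return out

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


DUBOIS_COEFF = 0.007184
DUBOIS_W_EXP = 0.425
DUBOIS_H_EXP = 0.725


def compute_bsa(subject: Subject) -> Subject:
    """Fill in body surface area with the DuBois formula.

    BSA (m²) = weight(kg)^0.425 × height(cm)^0.725 × 0.007184.
    """
    if not (subject.height_cm > 0 and subject.weight_kg > 0):
        raise ValidationError(f"subject {subject.id}: height/weight must be positive")
    bsa = DUBOIS_COEFF * subject.weight_kg**DUBOIS_W_EXP * subject.height_cm**DUBOIS_H_EXP
    return dataclasses.replace(subject, bsa_m2=float(bsa))


def bin_volumes(
    fieldmap: RadiusField,
    mask: VoxelMask,
    bins: DiameterBins | None = None,
    roi: VoxelMask | None = None,
    include_subthreshold: bool = False,
) -> VolumeReport:
    """Accumulate per-bin, per-compartment vessel volumes from a radius field.

    Each foreground voxel (intersected with ``roi`` when given, e.g. a lung
    mask excluding the hilum) contributes the voxel volume to the bin
    containing its diameter d = 2·radius.  Totals sum the supra-threshold
    bins only unless ``include_subthreshold``.
    """
    bins = bins or DiameterBins()
    if roi is not None:
        if roi.shape != mask.shape:
            raise GeometryError(f"ROI grid {roi.shape} does not match mask grid {mask.shape}")
        keep = roi.labels > 0
    else:
        keep = np.ones(mask.shape, dtype=bool)

    n_bins = len(bins.labels)
    counts = pd.DataFrame(
        np.zeros((2, n_bins), dtype=np.int64), index=["artery", "vein"], columns=bins.labels
    )
    for comp, label_value in (("artery", ARTERY), ("vein", VEIN)):
        sel = (mask.labels == label_value) & keep & fieldmap.foreground
        if not sel.any():
            continue
        d = 2.0 * fieldmap.radius[sel]
        which = bins.assign(d)
        counts.loc[comp] = np.bincount(which, minlength=n_bins)

    return VolumeReport(
        counts=counts,
        voxel_volume_mm3=mask.voxel_volume_mm3,
        bins=bins,
        fallback_fraction=fieldmap.fallback_fraction,
        include_subthreshold=include_subthreshold,
        roi_applied=roi is not None,
    )


def normalize_report(report: VolumeReport, subject: Subject) -> VolumeReport:
    """Attach a subject so volumes can be expressed per m² of body surface.

    The subject must already carry a computed BSA (see :func:`compute_bsa`).
    """
    if subject.bsa_m2 is None:
        raise VesselradError(
            f"subject {subject.id}: BSA not computed; call compute_bsa first"
        )
    return dataclasses.replace(report, subject=subject)


#: label -> color for the diameter scheme (labels 1/2/3/4)
DIAMETER_COLOR_MAP = {1: "red", 2: "yellow", 3: "blue", 4: "unclassified"}
COMPARTMENT_COLOR_MAP = {1: "red", 2: "blue"}


def color_code(
    fieldmap: RadiusField,
    mask: VoxelMask,
    scheme: str = "by_diameter",
) -> tuple[VoxelMask, dict[int, str]]:
    """Produce a display label volume plus its label->color map.

    ``by_diameter``: 1 = red (0.8 < d <= 3.2 mm, subsegmental vessels),
    2 = yellow (3.2 < d <= 4.0 mm), 3 = blue (d > 4.0 mm), 4 = sub-threshold
    (d <= 0.8 mm).  ``by_compartment``: 1 = artery (red), 2 = vein (blue).
    """
    if scheme == "by_compartment":
        return (
            VoxelMask(mask.labels.copy(), mask.spacing, mask.origin),
            dict(COMPARTMENT_COLOR_MAP),
        )
    if scheme != "by_diameter":
        raise ValidationError(f"unknown color scheme {scheme!r}")

    out = np.zeros(mask.shape, dtype=np.uint8)
    fg = (mask.labels > 0) & fieldmap.foreground
    d = 2.0 * fieldmap.radius[fg]
    # inclusive upper bound at each edge, matching the bin convention
    codes = np.where(
        d <= 0.8, 4, np.where(d <= 3.2, 1, np.where(d <= 4.0, 2, 3))
    ).astype(np.uint8)
    out[fg] = codes
    labeled = VoxelMask.__new__(VoxelMask)  # bypass 0/1/2 validation: display labels 1..4
    labeled.labels = out
    labeled.spacing = mask.spacing
    labeled.origin = mask.origin
    return labeled, dict(DIAMETER_COLOR_MAP)


def write_color_map(colormap: dict[int, str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({str(k): v for k, v in colormap.items()}, indent=2))
    return path
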