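"""Synthetic vessel phantoms with analytically known radii.

Every downstream stage (distance transform, centerline extraction, radius
propagation, diameter binning) is validated against tubes whose radius is
known by construction: straight cylinders, 90-degree bent tubes and
stochastic bifurcating trees.  The rasterization rule is "voxel center
inside the tube" (world-space distance from the voxel center to the
centerline polyline <= radius), matching the binary nature of segmentation
masks — no partial-volume modelling.

A separate cohort simulator draws per-subject diameter-binned vessel
volumes from log-normal distributions so the statistics workflow can be
exercised and calibrated without patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .io import ARTERY, Subject, VoxelMask

MARGIN_VOXELS = 2  # background margin around every phantom


@dataclass
class Segment:
    """One straight tube segment of the generating geometry.

    Free ends are capped flat (the tube stops at the endpoint plane) so a
    lone segment is a true cylinder of volume pi*r^2*L; ends that meet
    another segment keep a rounded (capsule) cap so junctions are filled.
    """

    start: np.ndarray  # world mm
    end: np.ndarray
    radius: float
    flat_start: bool = True
    flat_end: bool = True


@dataclass
class GroundTruth:
    """Analytic truth for a phantom: per-foreground-voxel radius + centerline.

    ``radius`` is 0 on background and equals the radius of the generating
    segment that claims the voxel (nearest segment; ties take the larger
    radius).  ``segments`` is the generating polyline set.
    """

    radius: np.ndarray
    segments: list[Segment] = field(default_factory=list)

    def centerline_points(self, step_mm: float = 0.25) -> np.ndarray:
        """Densely sampled points (world mm) along the analytic centerline."""
        pts = []
        for seg in self.segments:
            length = float(np.linalg.norm(seg.end - seg.start))
            n = max(2, int(math.ceil(length / step_mm)) + 1)
            t = np.linspace(0.0, 1.0, n)[:, None]
            pts.append(seg.start[None, :] * (1 - t) + seg.end[None, :] * t)
        return np.concatenate(pts, axis=0)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic tube phantom.

    radius_mm must be >= the largest spacing component (sub-voxel tubes are
    rejected).  ``seed`` fixes the tree topology and geometry exactly;
    deterministic kinds (cylinder, bent tube) ignore it.
    """

    kind: str = "cylinder"  # cylinder | bent_tube | tree
    radius_mm: float = 3.0
    length_mm: float = 40.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    depth: int = 2  # tree only
    child_scale: float = 0.7  # tree only: child radius = parent radius * scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cylinder", "bent_tube", "tree"):
            raise ValidationError(f"unknown phantom kind {self.kind!r}")
        if not 0 < self.child_scale <= 1:
            raise ValidationError("child_scale must be in (0, 1]")
        if self.radius_mm < max(self.spacing):
            raise GeometryError(
                f"radius {self.radius_mm} mm is below the largest voxel spacing "
                f"{max(self.spacing)} mm; sub-voxel tubes cannot be rasterized"
            )


def _point_segment_sqdist(points: np.ndarray, seg: Segment) -> tuple[np.ndarray, np.ndarray]:
    """Squared distance to the segment and the raw axial parameter t."""
    d = seg.end - seg.start
    len2 = float(d @ d)
    if len2 == 0.0:
        diff = points - seg.start
        return (diff * diff).sum(axis=-1), np.zeros(len(points))
    t_raw = (points - seg.start) @ d / len2
    t = np.clip(t_raw, 0.0, 1.0)
    proj = seg.start + t[:, None] * d
    diff = points - proj
    return (diff * diff).sum(axis=-1), t_raw


def _segment_membership(d2: np.ndarray, t_raw: np.ndarray, seg: Segment) -> np.ndarray:
    """Voxel-center-in-tube rule, honoring flat caps at free ends."""
    inside = d2 <= seg.radius * seg.radius
    if seg.flat_start:
        inside &= t_raw >= 0.0
    if seg.flat_end:
        inside &= t_raw <= 1.0
    return inside


def _rasterize(segments: list[Segment], spacing) -> tuple[VoxelMask, GroundTruth]:
    """Voxelize a set of tube segments on a grid with a 2-voxel margin."""
    spacing = np.asarray(spacing, dtype=np.float64)
    pts = np.concatenate([[s.start, s.end] for s in segments])
    rmax = max(s.radius for s in segments)
    lo = pts.min(axis=0) - rmax - MARGIN_VOXELS * spacing
    hi = pts.max(axis=0) + rmax + MARGIN_VOXELS * spacing
    # shift geometry so world = index * spacing with origin 0; the shift is an
    # integer number of voxels, keeping axis endpoints on voxel centers
    shift = np.floor(lo / spacing) * spacing
    shape = np.ceil((hi - shift) / spacing).astype(int) + 1
    if np.any(shape > 512):
        raise GeometryError(f"phantom grid {tuple(shape)} exceeds the 512^3 safety bound")
    segs = [
        Segment(s.start - shift, s.end - shift, s.radius, s.flat_start, s.flat_end)
        for s in segments
    ]

    idx = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    world = idx * spacing
    best_d2 = np.full(len(world), np.inf)
    best_r = np.zeros(len(world))
    inside = np.zeros(len(world), dtype=bool)
    for seg in segs:
        d2, t_raw = _point_segment_sqdist(world, seg)
        inside |= _segment_membership(d2, t_raw, seg)
        # nearest generating segment claims the voxel; ties -> larger radius
        closer = (d2 < best_d2) | ((d2 == best_d2) & (seg.radius > best_r))
        best_d2 = np.where(closer, d2, best_d2)
        best_r = np.where(closer, seg.radius, best_r)

    labels = inside.reshape(tuple(shape)).astype(np.uint8) * ARTERY
    truth = np.where(inside, best_r, 0.0).reshape(tuple(shape))
    mask = VoxelMask(labels=labels, spacing=tuple(spacing))
    return mask, GroundTruth(radius=truth, segments=segs)


def make_cylinder(spec: PhantomSpec) -> tuple[VoxelMask, GroundTruth]:
    """A straight tube of constant radius along ``spec.direction``.

    A voxel is foreground iff its center lies within ``radius_mm`` of the
    axis segment; the ground-truth radius is ``radius_mm`` everywhere.
    Deterministic: the seed is ignored.
    """
    d = np.asarray(spec.direction, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise GeometryError("cylinder direction must be nonzero")
    d = d / norm
    start = np.zeros(3)
    seg = Segment(start, start + d * spec.length_mm, spec.radius_mm)
    return _rasterize([seg], spec.spacing)


def make_bent_tube(spec: PhantomSpec) -> tuple[VoxelMask, GroundTruth]:
    """Two equal-length perpendicular segments joined at a 90-degree elbow."""
    half = spec.length_mm / 2.0
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([0.0, 0.0, half])
    c = np.array([half, 0.0, half])
    segs = [
        Segment(a, b, spec.radius_mm, flat_end=False),  # rounded elbow
        Segment(b, c, spec.radius_mm, flat_start=False),
    ]
    return _rasterize(segs, spec.spacing)


def _tree_segments(spec: PhantomSpec) -> list[Segment]:
    leaf_radius = spec.radius_mm * spec.child_scale**spec.depth
    if leaf_radius < max(spec.spacing):
        raise GeometryError(
            f"leaf radius {leaf_radius:.3f} mm would fall below the largest voxel "
            f"spacing {max(spec.spacing)} mm; reduce depth or raise the root radius"
        )
    rng = np.random.default_rng(spec.seed)
    segs: list[Segment] = []

    def grow(start: np.ndarray, direction: np.ndarray, radius: float, length: float, level: int):
        end = start + direction * length
        is_leaf = level >= spec.depth
        segs.append(
            Segment(start.copy(), end.copy(), radius,
                    flat_start=(level == 0), flat_end=is_leaf)
        )
        if is_leaf:
            return
        # two children splayed around the parent direction
        for sign in (-1.0, 1.0):
            angle = math.radians(rng.uniform(20.0, 40.0)) * sign
            azimuth = rng.uniform(0.0, 2.0 * math.pi)
            child_dir = _rotate_about(direction, angle, azimuth)
            grow(end, child_dir, radius * spec.child_scale, length * 0.75, level + 1)

    grow(np.zeros(3), np.array([0.0, 0.0, 1.0]), spec.radius_mm, spec.length_mm, 0)
    return segs


def _rotate_about(direction: np.ndarray, polar: float, azimuth: float) -> np.ndarray:
    """Tilt ``direction`` by ``polar`` radians toward an azimuthal bearing."""
    d = direction / np.linalg.norm(direction)
    # build an orthonormal frame around d
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    axis = math.cos(azimuth) * u + math.sin(azimuth) * v
    out = math.cos(polar) * d + math.sin(polar) * np.cross(axis, d)
    return out / np.linalg.norm(out)


def make_tree(spec: PhantomSpec) -> tuple[VoxelMask, GroundTruth]:
    """A bifurcating tapering tube tree; depth 0 degenerates to a cylinder.

    Child radii scale by ``child_scale`` per generation; branch directions
    are drawn from the seeded generator, so a fixed seed gives bit-identical
    masks.  Each foreground voxel's ground-truth radius is the radius of the
    nearest generating segment (ties take the larger radius).
    """
    return _rasterize(_tree_segments(spec), spec.spacing)


def make_phantom(spec: PhantomSpec) -> tuple[VoxelMask, GroundTruth]:
    """Dispatch on ``spec.kind``."""
    maker = {"cylinder": make_cylinder, "bent_tube": make_bent_tube, "tree": make_tree}
    return maker[spec.kind](spec)


# --------------------------------------------------------------------------
# cohort simulator
# --------------------------------------------------------------------------

BIN_LABELS = ["0.8-1.6", "1.6-2.4", "2.4-3.2", "3.2-4.0", ">4.0"]

#: control-group per-bin medians (mL·m⁻²) and log-normal sigmas; sigma is
#: derived from the interquartile ratio, sigma = ln(Q3/Q1) / (2 * 0.6745)
COHORT_BASELINE = {
    "IPVVa": {
        "0.8-1.6": (5.14, (4.15, 6.03)),
        "1.6-2.4": (9.40, (7.78, 11.97)),
        "2.4-3.2": (12.93, (11.00, 15.03)),
        "3.2-4.0": (6.49, (5.44, 7.98)),
        ">4.0": (12.34, (9.18, 15.86)),
    },
    "IPVVv": {
        "0.8-1.6": (4.24, (3.67, 4.96)),
        "1.6-2.4": (9.08, (7.58, 11.75)),
        "2.4-3.2": (15.40, (12.0, 19.2)),  # reported as mean±sd; quartiles approximated
        "3.2-4.0": (8.85, (7.34, 10.89)),
        ">4.0": (17.52, (13.95, 23.02)),
    },
}

#: demographic medians and dispersions per group (normal draws, truncated)
_DEMOGRAPHICS = {
    "control": {"height": (164.0, 9.6), "weight": (66.0, 12.6), "age": (45.0, 15.0), "p_female": 0.63},
    "patient": {"height": (163.0, 5.9), "weight": (59.0, 9.6), "age": (34.0, 12.0), "p_female": 0.86},
}


def _lognormal_sigma(q1: float, q3: float) -> float:
    return math.log(q3 / q1) / (2.0 * 0.6745)


def make_cohort(
    n_per_group: int,
    effect: float | dict[str, float] = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-group cohort of BSA-normalized vessel-volume measurements.

    Per-bin per-compartment volumes are drawn from log-normal distributions
    whose control-group medians and spreads follow :data:`COHORT_BASELINE`.
    ``effect`` multiplies the patient-group medians: a scalar applies to all
    bins, a dict maps measurement names (e.g. ``"IPVVa_0.8-1.6"``) to
    per-bin factors; 1.0 makes the groups exchangeable.  Totals are sums of
    the bins, so IPVVa + IPVVv = TIPVV by construction.

    Returns a tidy table with one row per subject: demographics, BSA and
    measurement columns ``IPVVa_<bin>``, ``IPVVv_<bin>``, ``IPVVa``,
    ``IPVVv``, ``TIPVV`` (all volumes in mL·m⁻²).  Deterministic given seed.
    """
    from .quantify import compute_bsa  # local import to avoid a cycle

    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("control", "patient"):
        demo = _DEMOGRAPHICS[group]
        for i in range(n_per_group):
            height = max(140.0, rng.normal(*demo["height"]))
            weight = max(35.0, rng.normal(*demo["weight"]))
            age = float(np.clip(rng.normal(*demo["age"]), 18.0, 90.0))
            sex = "female" if rng.random() < demo["p_female"] else "male"
            subj = Subject(
                id=f"{group[:3]}{i:04d}", group=group, age=age, sex=sex,
                height_cm=float(height), weight_kg=float(weight),
            )
            subj = compute_bsa(subj)
            row = {
                "id": subj.id, "group": group, "age": age, "sex": sex,
                "height_cm": float(height), "weight_kg": float(weight),
                "bsa": subj.bsa_m2,
            }
            for comp, bins in COHORT_BASELINE.items():
                for bin_label, (median, (q1, q3)) in bins.items():
                    name = f"{comp}_{bin_label}"
                    mult = effect.get(name, 1.0) if isinstance(effect, dict) else float(effect)
                    med = median * (mult if group == "patient" else 1.0)
                    sigma = _lognormal_sigma(q1, q3)
                    row[name] = float(rng.lognormal(mean=math.log(med), sigma=sigma))
            rows.append(row)
    df = pd.DataFrame(rows)
    for comp in ("IPVVa", "IPVVv"):
        df[comp] = df[[f"{comp}_{b}" for b in BIN_LABELS]].sum(axis=1)
    df["TIPVV"] = df["IPVVa"] + df["IPVVv"]
    return df


def cohort_subjects(table: pd.DataFrame) -> list[Subject]:
    """Extract :class:`Subject` records from a cohort table."""
    return [
        Subject(
            id=str(r["id"]), group=str(r["group"]), age=float(r["age"]), sex=str(r["sex"]),
            height_cm=float(r["height_cm"]), weight_kg=float(r["weight_kg"]),
            bsa_m2=float(r["bsa"]) if "bsa" in r else None,
        )
        for _, r in table.iterrows()
    ]
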