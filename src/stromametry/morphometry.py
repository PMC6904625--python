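"""Per-object 3D morphometry on instance-labeled stacks.

Measurements follow the manual protocol for stromal vesicles: for each
object the longest extent along each of the three block axes (X, Y, Z) is
taken; the largest of the three is the *length*, the mean of the two
shorter ones is the *width*, and the *ratio* is width/length (1 for a
sphere, < 1 for ovoids). Extents are axis-aligned by definition — rotated
principal-axis diameters are deliberately not computed.

Voxel spans convert to physical units per axis *before* the axes are
ordered, so anisotropic stacks (coarse z, fine x/y) order correctly. The
extent convention is ``(max_index - min_index + 1) * spacing``: voxel
centers plus one voxel width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage, stats as sps

from .io import InstanceMap
from .sampling import PointRecord

__all__ = [
    "VesicleMeasurement",
    "SizeSummary",
    "measure_object",
    "measure_category",
    "summarize_sizes",
    "select_systematic_vesicles",
    "select_targeted_vesicles",
]


@dataclass(frozen=True)
class VesicleMeasurement:
    """Axis extents (nm) and derived length/width/ratio for one object."""

    instance_id: int
    extent_z: float
    extent_y: float
    extent_x: float
    length: float
    width: float
    ratio: float
    selection_mode: str = "systematic"
    boundary_clipped: bool = False

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError("length >= width > 0 violated")
        if not (0 < self.ratio <= 1 + 1e-12):
            raise ValueError("ratio must lie in (0, 1]")

    @property
    def length_um(self) -> float:
        return self.length / 1000.0

    @property
    def width_um(self) -> float:
        return self.width / 1000.0


@dataclass(frozen=True)
class SizeSummary:
    """n, median, min, max and adjusted Fisher-Pearson sample skewness."""

    n: int
    median: float
    min: float
    max: float
    skewness: float
    selection_mode: str = ""

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("min <= median <= max violated")


def measure_object(
    instances: InstanceMap,
    instance_id: int,
    selection_mode: str = "systematic",
) -> VesicleMeasurement:
    """Measure one instance's axis-aligned extents in physical units.

    ``boundary_clipped`` is set when the object's bounding box touches the
    volume edge, i.e. the measurement is a truncation of the real object.
    """
    mask = instances.voxels == instance_id
    # Per-axis occupancy profiles: spans and edge contact without ever
    # materializing the (possibly huge) coordinate list.
    profiles = [
        mask.any(axis=(1, 2)),
        mask.any(axis=(0, 2)),
        mask.any(axis=(0, 1)),
    ]
    if not profiles[0].any():
        raise ValueError(f"instance {instance_id} is empty or absent")
    lo = [int(np.argmax(p)) for p in profiles]
    hi = [len(p) - 1 - int(np.argmax(p[::-1])) for p in profiles]
    spans = np.array([h - l + 1 for l, h in zip(lo, hi)])
    extents = spans * np.asarray(instances.spacing)  # nm, per-axis conversion first
    ordered = np.sort(extents)  # ascending
    length = float(ordered[2])
    width = float((ordered[0] + ordered[1]) / 2.0)
    clipped = any(l == 0 for l in lo) or any(
        h == len(p) - 1 for h, p in zip(hi, profiles)
    )
    return VesicleMeasurement(
        instance_id=int(instance_id),
        extent_z=float(extents[0]),
        extent_y=float(extents[1]),
        extent_x=float(extents[2]),
        length=length,
        width=width,
        ratio=width / length,
        selection_mode=selection_mode,
        boundary_clipped=clipped,
    )


def measure_category(
    instances: InstanceMap,
    category: str = "vesicle",
    ids: Optional[Iterable[int]] = None,
    selection_mode: str = "systematic",
) -> list[VesicleMeasurement]:
    """Measure every instance of a category (or an explicit ID subset).

    Uses one labeled-array pass to find bounding boxes, then measures each
    object, so it stays fast on stacks with hundreds of instances.
    """
    if ids is None:
        ids = instances.ids_of_category(category)
    ids = sorted(int(i) for i in ids)
    if not ids:
        return []
    objects = ndimage.find_objects(instances.voxels, max_label=max(ids))
    out = []
    spacing = np.asarray(instances.spacing)
    nz, ny, nx = instances.shape
    for iid in ids:
        sl = objects[iid - 1] if iid - 1 < len(objects) else None
        if sl is None:
            raise ValueError(f"instance {iid} is empty or absent")
        spans = np.array([s.stop - s.start for s in sl])
        extents = spans * spacing
        ordered = np.sort(extents)
        clipped = any(s.start == 0 for s in sl) or any(
            s.stop == dim for s, dim in zip(sl, (nz, ny, nx))
        )
        out.append(
            VesicleMeasurement(
                instance_id=iid,
                extent_z=float(extents[0]),
                extent_y=float(extents[1]),
                extent_x=float(extents[2]),
                length=float(ordered[2]),
                width=float((ordered[0] + ordered[1]) / 2.0),
                ratio=float((ordered[0] + ordered[1]) / 2.0 / ordered[2]),
                selection_mode=selection_mode,
                boundary_clipped=bool(clipped),
            )
        )
    return out


def summarize_sizes(
    measurements: Sequence[VesicleMeasurement],
    attribute: str = "length",
    selection_mode: Optional[str] = None,
    include_clipped: bool = False,
) -> SizeSummary:
    """Median / range / skewness of one measured attribute.

    ``attribute`` is ``length`` or ``width`` (summarised in μm) or
    ``ratio`` (dimensionless). Boundary-clipped objects are excluded by
    default because their extents are truncated; pass
    ``include_clipped=True`` to keep them. Skewness is the adjusted
    Fisher-Pearson sample coefficient.
    """
    pool = [
        m
        for m in measurements
        if (selection_mode is None or m.selection_mode == selection_mode)
        and (include_clipped or not m.boundary_clipped)
    ]
    if not pool:
        raise ValueError("no measurements to summarize")
    if attribute == "length":
        vals = np.array([m.length_um for m in pool])
    elif attribute == "width":
        vals = np.array([m.width_um for m in pool])
    elif attribute == "ratio":
        vals = np.array([m.ratio for m in pool])
    else:
        raise ValueError(f"unknown attribute {attribute!r}")
    skew = float(sps.skew(vals, bias=False)) if vals.size >= 3 else float("nan")
    return SizeSummary(
        n=int(vals.size),
        median=float(np.median(vals)),
        min=float(vals.min()),
        max=float(vals.max()),
        skewness=skew,
        selection_mode=selection_mode or "",
    )


def select_systematic_vesicles(
    records: Iterable[PointRecord],
    instances: Optional[InstanceMap] = None,
) -> set[int]:
    """Vesicle instances hit by at least one grid point (duplicates
    collapsed). This is size-biased sampling: a vesicle's hit probability
    is proportional to its volume, exactly as in manual point counting."""
    hits: set[int] = set()
    for rec in records:
        if rec.category == "vesicle" and rec.instance_id != 0:
            if instances is not None:
                info = instances.id_table.get(rec.instance_id)
                if info is None or info.category != "vesicle":
                    continue
            hits.add(rec.instance_id)
    return hits


def select_targeted_vesicles(
    lengths_by_id: Mapping[int, float],
    groups_by_id: Mapping[int, str],
    size_window: tuple[float, float] = (0.0, 300.0),
    per_group: int = 3,
    seed: int = 0,
) -> list[int]:
    """Pick up to ``per_group`` vesicles per placenta whose length falls in
    ``size_window`` (nm) — the by-eye selection of typical-size (< 300 nm)
    vesicles. May return fewer than requested; returns an empty list when
    nothing qualifies."""
    rng = np.random.default_rng(seed)
    lo, hi = size_window
    chosen: list[int] = []
    groups: dict[str, list[int]] = {}
    for iid, length in lengths_by_id.items():
        if lo <= length < hi:
            groups.setdefault(groups_by_id.get(iid, ""), []).append(iid)
    for group in sorted(groups):
        pool = sorted(groups[group])
        k = min(per_group, len(pool))
        picked = rng.choice(pool, size=k, replace=False)
        chosen.extend(int(i) for i in picked)
    return sorted(chosen)
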