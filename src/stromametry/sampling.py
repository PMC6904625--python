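"""Systematic uniform random sampling (SURS) and point counting.

The sampling design mirrors the manual stereology protocol: a random
starting slice is drawn from the first ``start_window`` slices, every
``slice_period``-th slice after it is sampled until the end of the stack,
and a randomly offset rectangular point grid (rows x cols intersections)
is overlaid on each sampled slice. Each grid point is assigned the tissue
category of the voxel it lands in; the tally of points per category is the
raw statistic from which all volume fractions are estimated.

SURS is unbiased by design: the random start within the first period makes
every slice equally likely to be sampled, and the random grid offset makes
every pixel equally likely to be hit, so the expected point fraction for a
category equals its true volume fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import InstanceMap, LabelVolume

__all__ = [
    "SamplingDesign",
    "PointRecord",
    "PointCountTable",
    "select_slices",
    "make_grid",
    "classify_points",
    "sample_volume",
]


@dataclass(frozen=True)
class SamplingDesign:
    """SURS parameters: slice period/start window and grid dimensions.

    Defaults follow the protocol used throughout this package: every 50th
    slice from a random start in the first 50, with a randomly offset
    4 x 4 grid giving 16 points per sampled slice.
    """

    slice_period: int = 50
    start_window: int = 50
    grid_rows: int = 4
    grid_cols: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slice_period < 1:
            raise ValueError("slice_period must be >= 1")
        if not (1 <= self.start_window <= self.slice_period):
            raise ValueError("start_window must be in [1, slice_period]")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def points_per_slice(self) -> int:
        return self.grid_rows * self.grid_cols

    def rng_for_stack(self, stack_index: int = 0) -> np.random.Generator:
        """Deterministic per-stack generator split from the design seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stack_index]))


@dataclass(frozen=True)
class PointRecord:
    """One classified grid point, with the instance it hit (0 = none)."""

    slice_index: int
    row: float
    col: float
    category: str
    instance_id: int = 0


@dataclass
class PointCountTable:
    """Per-stack tally of grid points by category.

    Invariant: the counts sum to ``n_points_total`` which equals
    ``n_slices_sampled * grid_rows * grid_cols``.
    """

    counts: dict[str, int]
    n_slices_sampled: int
    n_points_total: int
    stack_id: str = ""
    placenta_id: str = ""
    records: list[PointRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_points_total:
            raise ValueError(
                f"counts sum {sum(self.counts.values())} != n_points_total {self.n_points_total}"
            )

    @staticmethod
    def merge(tables: Iterable["PointCountTable"], placenta_id: str = "") -> "PointCountTable":
        """Pool point counts across stacks (e.g. all stacks of one placenta)."""
        tables = list(tables)
        if not tables:
            raise ValueError("no tables to merge")
        counts: dict[str, int] = {}
        n_slices = 0
        n_points = 0
        records: list[PointRecord] = []
        for t in tables:
            for k, v in t.counts.items():
                counts[k] = counts.get(k, 0) + v
            n_slices += t.n_slices_sampled
            n_points += t.n_points_total
            records.extend(t.records)
        return PointCountTable(counts, n_slices, n_points, "merged", placenta_id, records)


def select_slices(
    n_slices: int, design: SamplingDesign, rng: Optional[np.random.Generator] = None
) -> list[int]:
    """SURS slice selection: random start in the first ``start_window``
    slices, then every ``slice_period``-th slice until the end of the stack.

    The start is clamped to the stack so at least one slice is always
    returned.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if rng is None:
        rng = design.rng_for_stack(0)
    window = min(design.start_window, n_slices)
    start = int(rng.integers(0, window))
    return list(range(start, n_slices, design.slice_period))


def make_grid(
    height: int,
    width: int,
    design: SamplingDesign,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One randomly offset point grid on a ``height x width`` image.

    Grid spacing is ``height / grid_rows`` by ``width / grid_cols``; the
    offset of the first point is uniform on ``[0, spacing)`` per axis, so
    every point lies strictly inside the image. Returns an array of
    ``(row, col)`` continuous coordinates, shape ``(rows * cols, 2)``.
    A fresh offset is drawn on every call (one per sampled slice).
    """
    if height < design.grid_rows or width < design.grid_cols:
        raise ValueError(
            f"image {height}x{width} smaller than grid {design.grid_rows}x{design.grid_cols}"
        )
    if rng is None:
        rng = design.rng_for_stack(0)
    dr = height / design.grid_rows
    dc = width / design.grid_cols
    off_r = rng.uniform(0.0, dr)
    off_c = rng.uniform(0.0, dc)
    rows = off_r + dr * np.arange(design.grid_rows)
    cols = off_c + dc * np.arange(design.grid_cols)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def classify_points(
    volume: LabelVolume,
    slices: Sequence[int],
    grids: Sequence[np.ndarray],
    instances: Optional[InstanceMap] = None,
    stack_id: str = "",
    placenta_id: str = "",
    keep_records: bool = True,
) -> PointCountTable:
    """Assign each grid point the category of the voxel it lands in.

    A point at continuous coordinate ``(r, c)`` is assigned the voxel
    ``(floor(r), floor(c))``; since grid offsets are drawn on ``[0,
    spacing)`` every point maps to a valid pixel. When ``instances`` is
    given, the instance ID under each point is recorded too, which is what
    systematic vesicle selection consumes.
    """
    if len(slices) != len(grids):
        raise ValueError("one grid per sampled slice is required")
    nz, ny, nx = volume.shape
    counts: dict[str, int] = {}
    records: list[PointRecord] = []
    n_points = 0
    for z, grid in zip(slices, grids):
        if not (0 <= z < nz):
            raise IndexError(f"slice index {z} outside stack of {nz} slices")
        rows = np.floor(grid[:, 0]).astype(int)
        cols = np.floor(grid[:, 1]).astype(int)
        if rows.min() < 0 or rows.max() >= ny or cols.min() < 0 or cols.max() >= nx:
            raise IndexError("grid point outside slice bounds (grid/volume mismatch)")
        codes = volume.voxels[z, rows, cols]
        iids = instances.voxels[z, rows, cols] if instances is not None else np.zeros_like(codes)
        for (r, c), code, iid in zip(grid, codes, iids):
            name = volume.category_map[int(code)]
            counts[name] = counts.get(name, 0) + 1
            n_points += 1
            if keep_records:
                records.append(PointRecord(int(z), float(r), float(c), name, int(iid)))
    return PointCountTable(counts, len(slices), n_points, stack_id, placenta_id, records)


def sample_volume(
    volume: LabelVolume,
    design: SamplingDesign,
    stack_index: int = 0,
    instances: Optional[InstanceMap] = None,
    stack_id: str = "",
    placenta_id: str = "",
) -> PointCountTable:
    """Run the full SURS design on one stack: select slices, draw a fresh
    grid offset per slice, classify the points."""
    rng = design.rng_for_stack(stack_index)
    nz, ny, nx = volume.shape
    slices = select_slices(nz, design, rng)
    grids = [make_grid(ny, nx, design, rng) for _ in slices]
    return classify_points(
        volume, slices, grids, instances, stack_id or f"stack{stack_index}", placenta_id
    )
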