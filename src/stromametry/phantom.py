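"""Synthetic labeled villus phantoms with exact, known ground truth.

The phantom emulates a serial block-face EM stack of a terminal villus:
an intervillous background, a syncytiotrophoblast border band with a
cytotrophoblast layer beneath it, fetal capillaries (lumen, endothelial
sleeve, pericyte sleeve) running along the slicing axis, and a stromal
region filled with extracellular matrix into which stellate-cell
networks, macrophages and ellipsoidal extracellular vesicles are packed
by rejection sampling. Every voxel's category and every object's identity
are known exactly, so the stereology, morphometry, contact and network
stages can all be validated against ground truth that is *measured from
the emitted volume* (placement error is thereby captured), never copied
from the request.

Scale: the default 192x192x192 grid at (50, 14, 14) nm spacing is a
desk-scale *model* of a villus, not a physically true-size one (a real
terminal villus is tens of μm across, this field of view is ~2.7 μm), so
the cells and vesicles inside it are proportionally miniaturized. The
separate vesicle-field generator (:func:`generate_vesicle_field`) renders
vesicles at their true micron-scale sizes for morphometry validation.

Composition control: trophoblast bands and capillary sleeves are assigned
by ordering pixels on distance fields and cutting at exact quotas, so
those category counts are exact; stellate cells, macrophages and vesicles
are packed until their voxel quotas are met (granularity: a fraction of
one object). Exactly ``round(contact_fraction * n_vesicles)`` vesicles
are placed sharing a face-adjacent voxel pair with a stellate cell and
the remainder are kept out of the full 26-neighbourhood of stellate
cells and macrophages, so detected contact fractions reproduce the
ground truth exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import categories as cat
from ._raster import (
    ellipsoid_offsets,
    random_unit_vector,
    rasterize_spheroid_volume,
    spheroid_offsets,
)
from .io import InstanceInfo, InstanceMap, LabelVolume
from .morphometry import VesicleMeasurement, measure_object

__all__ = [
    "LogNormalLength",
    "LogitNormalRatio",
    "ShiftedPoissonNetworkSize",
    "PhantomSpec",
    "PhantomGroundTruth",
    "PackingError",
    "default_target_fractions",
    "generate_phantom",
    "sample_vesicle_geometry",
    "generate_vesicle_field",
    "measure_vesicle_field",
]

# ---------------------------------------------------------------------------
# Distributions

@dataclass(frozen=True)
class LogNormalLength:
    """Log-normal vesicle length model: ``median_nm * exp(sigma * N(0,1))``.

    The median is the natural location parameter because the reported
    size summaries are medians; the log-scale sigma controls the skew.
    """

    median_nm: float
    sigma_log: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median_nm * np.exp(self.sigma_log * rng.standard_normal(n))


@dataclass(frozen=True)
class LogitNormalRatio:
    """Width:length ratio on (0, 1]: logistic of a normal on the logit
    scale, so the stated median maps through exactly."""

    median: float = 0.71
    sigma_logit: float = 0.97

    def __post_init__(self) -> None:
        if not (0.0 < self.median <= 1.0):
            raise ValueError("ratio median must lie in (0, 1]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.median >= 1.0:  # degenerate: every vesicle is a sphere
            rng.normal(0.0, 1.0, n)  # keep the stream advancing uniformly
            return np.ones(n)
        mu = math.log(self.median / (1.0 - self.median))
        z = rng.normal(mu, self.sigma_logit, n)
        return np.clip(1.0 / (1.0 + np.exp(-z)), 1e-6, 1.0)


@dataclass(frozen=True)
class ShiftedPoissonNetworkSize:
    """Nuclei per stellate network: ``1 + Poisson(mean - 1)``, support >= 1."""

    mean: float = 3.3

    def __post_init__(self) -> None:
        if self.mean < 1.0:
            raise ValueError("network size mean must be >= 1")

    def sample_one(self, rng: np.random.Generator) -> int:
        return 1 + int(rng.poisson(self.mean - 1.0))


# ---------------------------------------------------------------------------
# Spec and ground truth

#: Stromal compartment share of villous tissue and its internal split.
STROMA_OF_VILLOUS = 0.192
STROMAL_SHARES = {
    "stroma_ecm": 0.710,
    "stellate_cell": 0.216,
    "vesicle": 0.039,
    "macrophage": 0.035,
}

#: Non-stromal villous split (not tabulated in the source material; a
#: realistic terminal-villus choice summing to 1 - STROMA_OF_VILLOUS).
NON_STROMAL_VILLOUS = {
    "syncytiotrophoblast": 0.490,
    "cytotrophoblast": 0.078,
    "endothelial_cell": 0.070,
    "capillary_lumen": 0.120,
    "pericyte": 0.050,
}


def default_target_fractions() -> dict[str, float]:
    """Villous-tissue category fractions used by the reference phantom."""
    fractions = dict(NON_STROMAL_VILLOUS)
    for name, share in STROMAL_SHARES.items():
        fractions[name] = STROMA_OF_VILLOUS * share
    return fractions


# Geometry constants for the scaled reference phantom (nm unless noted).
VILLUS_FILL = 0.62           # fraction of the field of view that is villus
ARC_RADIUS_FACTOR = 1.5      # villus boundary curvature, in image widths
N_CAPILLARIES = 4
# Stellate cells are modeled as thin horizontal process sheets (stellate
# processes form sheet-like sails in the stroma) stacked along the
# slicing axis: a cell is a 2-slice-thick patch of exact pixel area, a
# network is a run of patches on consecutive slab levels joined by short
# vertical process tubes, and the 2-slice inter-level gaps plus in-plane
# carving margins guarantee that different networks are never 26-adjacent.
# Sheets tile the crowded cross-section efficiently, which is what makes
# the 21.6%-of-stroma stellate quota reachable at this scale.
SLAB_PERIOD = 3              # slices per level (sheet + gap)
SLAB_THICKNESS = 2           # slices occupied by the sheet
SHEET_AREA_PX = (350, 1000, 1600)  # (min, mean, max) patch area, pixels
SHEET_AREA_SD = 180.0
PATCH_MARGIN_PX = 2          # in-plane keep-apart between networks
# Vertical connecting process: a single-pixel column (1 voxel thick), so
# tubes of different networks inherit the full patch keep-apart margin.
TUBE_RADIUS_PX = 0
#: Longest in-plane "nub" process grown from a sheet to guarantee a
#: planned vesicle contact the carving did not produce naturally, pixels.
NUB_MAX_PX = 90
MACROPHAGE_SEMI_NM = (110.0, 140.0, 140.0)
#: Placement cap on drawn vesicle lengths (multiples of the median), so a
#: rare extreme draw cannot make packing infeasible; the capped value is
#: what ground truth records.
VESICLE_LENGTH_CAP = 6.0
#: Default in-phantom vesicle median length, calibrated so that 100
#: vesicles fill the vesicle quota of the reference 192^3 phantom.
PHANTOM_VESICLE_MEDIAN_NM = 196.0
PHANTOM_VESICLE_SIGMA = 0.35


class PackingError(RuntimeError):
    """Raised when rejection packing cannot reach a category's target."""

    def __init__(self, category: str, message: str):
        super().__init__(f"[{category}] {message}")
        self.category = category


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic villus stack.

    ``target_fractions`` maps every villous category to its target
    fraction of villous tissue (they must sum to 1); the stromal split is
    implied by the four stromal entries. ``contact_fraction`` of the
    ``n_vesicles`` vesicles end up touching a stellate process.
    """

    shape: tuple[int, int, int] = (192, 192, 192)
    spacing: tuple[float, float, float] = (50.0, 14.0, 14.0)
    target_fractions: dict[str, float] = field(default_factory=default_target_fractions)
    vesicle_length_dist: LogNormalLength = LogNormalLength(
        PHANTOM_VESICLE_MEDIAN_NM, PHANTOM_VESICLE_SIGMA
    )
    vesicle_ratio_dist: LogitNormalRatio = LogitNormalRatio()
    n_vesicles: int = 100
    contact_fraction: float = 0.59
    network_size_dist: ShiftedPoissonNetworkSize = ShiftedPoissonNetworkSize(3.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 16 for s in self.shape):
            raise ValueError("shape must be 3 axes of at least 16 voxels")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        fr = self.target_fractions
        unknown = set(fr) - cat.VILLOUS_CATEGORIES
        if unknown:
            raise ValueError(f"unknown categories in target_fractions: {sorted(unknown)}")
        if any(not (0.0 <= v <= 1.0) for v in fr.values()):
            raise ValueError("target fractions must lie in [0, 1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"villous target fractions sum to {sum(fr.values())}, expected 1")
        if not (0.0 <= self.contact_fraction <= 1.0):
            raise ValueError("contact_fraction must lie in [0, 1]")
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be >= 0")
        if self.vesicle_length_dist.median_nm <= 0:
            raise ValueError("vesicle median length must be positive")

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=seed)


@dataclass
class PhantomGroundTruth:
    """Exact composition and object-level truth measured from the emitted
    volume (so placement and rasterization error are included)."""

    category_counts: dict[str, int]
    villous_fractions: dict[str, float]
    stromal_fractions: dict[str, float]
    vesicles: pd.DataFrame  # instance_id, true_length_nm, true_width_nm, true_ratio, contact_partner
    network_sizes: dict[int, int]  # network_id -> nuclei
    n_voxels_total: int

    @property
    def stromal_compartment_of_villous(self) -> float:
        return sum(
            v for k, v in self.villous_fractions.items() if k in cat.STROMAL_CATEGORIES
        )

    @property
    def n_contact_vesicles(self) -> int:
        if len(self.vesicles) == 0:
            return 0
        return int((self.vesicles["contact_partner"] == "stellate_cell").sum())


# ---------------------------------------------------------------------------
# Geometry construction

def _villus_mask_2d(
    ny: int, nx: int, fill: float, rng: np.random.Generator
) -> np.ndarray:
    """Villus cross-section: the region left of a gently curved boundary
    arc (the field of view catches one side of a large villus), sized by
    bisection to cover ``fill`` of the image."""
    target = fill * ny * nx
    cy = ny / 2.0 + rng.uniform(-0.05, 0.05) * ny
    radius = ARC_RADIUS_FACTOR * nx * rng.uniform(0.9, 1.2)
    yy = np.arange(ny, dtype=float)
    sag = radius - np.sqrt(np.maximum(radius**2 - (yy - cy) ** 2, 0.0))
    xx = np.arange(nx, dtype=float)

    def count(xcut: float) -> tuple[float, np.ndarray]:
        bound = xcut - sag  # boundary bulges toward the villus mid-height
        mask = xx[None, :] < bound[:, None]
        return float(mask.sum()), mask

    lo, hi = 0.0, nx + radius
    for _ in range(40):
        mid = (lo + hi) / 2.0
        c, _m = count(mid)
        if c < target:
            lo = mid
        else:
            hi = mid
    _, mask = count((lo + hi) / 2.0)
    return mask


def _ordered_flat_indices(key: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Flat indices of ``mask`` pixels sorted ascending by ``key`` with a
    deterministic (index) tie-break."""
    flat = np.flatnonzero(mask)
    order = np.argsort(key.ravel()[flat], kind="stable")
    return flat[order]


def _paint_2d(labels3d: np.ndarray, flat_indices: np.ndarray, shape2d, code: int) -> None:
    mask = np.zeros(shape2d, dtype=bool)
    mask.ravel()[flat_indices] = True
    labels3d[:, mask] = code


class _Packer:
    """Shared state for rejection placement of 3D objects in the stroma."""

    def __init__(self, labels, inst, spacing, stroma_pixels, rng):
        self.labels = labels
        self.inst = inst
        self.spacing = spacing
        self.stroma_pixels = stroma_pixels  # (K, 2) array of (y, x)
        self.rng = rng
        self.shape = labels.shape

    def random_stroma_voxel(self) -> np.ndarray:
        k = self.rng.integers(0, len(self.stroma_pixels))
        z = self.rng.integers(0, self.shape[0])
        y, x = self.stroma_pixels[k]
        return np.array([z, y, x], dtype=int)

    def coords_ok(self, coords: np.ndarray) -> bool:
        return bool(
            np.all(coords >= 0) and np.all(coords < np.asarray(self.shape))
        )

    def all_ecm(self, coords: np.ndarray) -> bool:
        return bool(
            np.all(self.labels[coords[:, 0], coords[:, 1], coords[:, 2]] == cat.STROMA_ECM)
        )

    def neighbourhood_clear(self, coords, forbidden_codes) -> bool:
        """True when the 26-dilation of ``coords`` contains no voxel of a
        forbidden category."""
        lo = np.maximum(coords.min(axis=0) - 1, 0)
        hi = np.minimum(coords.max(axis=0) + 2, np.asarray(self.shape))
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub = np.zeros(tuple(hi - lo), dtype=bool)
        rel = coords - lo
        sub[rel[:, 0], rel[:, 1], rel[:, 2]] = True
        dil = ndimage.binary_dilation(sub, structure=np.ones((3, 3, 3), bool))
        lab_sub = self.labels[box]
        shell = dil & ~sub
        return not np.isin(lab_sub[shell], list(forbidden_codes)).any()

    def paint(self, coords: np.ndarray, code: int, instance_id: int):
        z, y, x = coords[:, 0], coords[:, 1], coords[:, 2]
        self.labels[z, y, x] = code
        self.inst[z, y, x] = instance_id


def _place_stellate_sheets(
    labels: np.ndarray,
    inst: np.ndarray,
    stroma2d: np.ndarray,
    quota: int,
    size_dist: ShiftedPoissonNetworkSize,
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
    first_instance_id: int,
    body_mask: np.ndarray,
    protected_mask: np.ndarray,
) -> tuple[dict[int, int], dict[int, InstanceInfo], int, int]:
    """Carve stellate networks as stacked process sheets with exact areas.

    The stack is divided into slab levels of :data:`SLAB_PERIOD` slices; a
    cell occupies :data:`SLAB_THICKNESS` slices of one level as an
    exact-pixel-area patch grown inside the free stroma cross-section, a
    network occupies consecutive levels (patches overlapping in-plane so a
    single-voxel vertical process tube through the inter-level gap
    connects consecutive cells), and carving keeps a
    :data:`PATCH_MARGIN_PX` ring around every patch so different networks
    are never 26-adjacent. ``body_mask`` marks voxels of already-placed
    objects (vesicles, macrophages) that sheets must not overlap;
    ``protected_mask`` marks the subset (non-contact vesicles) whose full
    26-neighbourhood must stay stellate-free.

    Returns (network sizes, instance table entries, painted voxel count,
    next free instance id).
    """
    nz, ny, nx = labels.shape
    sz, sy, sx = spacing
    a_min, a_mean, a_max = SHEET_AREA_PX

    phase = 1 + int(rng.integers(0, SLAB_PERIOD))
    level_z = [z for z in range(phase, nz - SLAB_THICKNESS, SLAB_PERIOD)]
    n_levels = len(level_z)
    if n_levels < 2:
        raise PackingError("stellate_cell", "stack too shallow for sheet levels")

    struct4 = ndimage.generate_binary_structure(2, 1)
    struct8 = ndimage.generate_binary_structure(2, 2)
    margin_struct = ndimage.iterate_structure(struct8, PATCH_MARGIN_PX)

    free: list[np.ndarray] = []
    tube_ok: list[np.ndarray] = []
    for li, z0 in enumerate(level_z):
        body2d = body_mask[z0 : z0 + SLAB_THICKNESS].any(axis=0)
        prot2d = protected_mask[max(z0 - 1, 0) : z0 + SLAB_THICKNESS + 1].any(axis=0)
        prot2d = ndimage.binary_dilation(prot2d, structure=struct8)
        free.append(stroma2d & ~body2d & ~prot2d)
        if li == 0:
            tube_ok.append(np.ones_like(stroma2d))
        else:
            gap_lo = level_z[li - 1] + SLAB_THICKNESS
            tb = body_mask[gap_lo:z0].any(axis=0)
            pr = protected_mask[max(gap_lo - 1, 0) : z0 + 1].any(axis=0)
            tb |= ndimage.binary_dilation(pr, structure=struct8)
            tube_ok.append(~tb)

    def grow_patch(level: int, seed_yx: np.ndarray, area: int) -> Optional[np.ndarray]:
        """Grow a connected patch of exactly ``area`` pixels from the seed
        inside the level's free mask (trimming the last ring by distance
        to the seed); None when the reachable region is below the minimum
        cell area."""
        f = free[level]
        if not f[seed_yx[0], seed_yx[1]]:
            return None
        patch = np.zeros_like(f)
        patch[seed_yx[0], seed_yx[1]] = True
        count = 1
        while count < area:
            grown = ndimage.binary_dilation(patch, structure=struct4) & f
            ring = grown & ~patch
            n_ring = int(ring.sum())
            if n_ring == 0:
                break
            need = area - count
            if n_ring > need:
                ridx = np.argwhere(ring)
                d = ((ridx[:, 0] - seed_yx[0]) * sy) ** 2 + (
                    (ridx[:, 1] - seed_yx[1]) * sx
                ) ** 2
                keep = ridx[np.argsort(d, kind="stable")[:need]]
                ring = np.zeros_like(f)
                ring[keep[:, 0], keep[:, 1]] = True
                n_ring = need
            patch |= ring
            count += n_ring
        if count < a_min:
            return None
        return patch

    network_sizes: dict[int, int] = {}
    id_table: dict[int, InstanceInfo] = {}
    painted = 0
    next_id = first_instance_id
    network_id = 0
    cell_cost = SLAB_THICKNESS * a_mean
    stall = 0
    while painted < quota - cell_cost * size_dist.mean / 2:
        stall += 1
        if stall > 500:
            raise PackingError(
                "stellate_cell", "sheet carving stalled before reaching its target"
            )
        size = min(size_dist.sample_one(rng), n_levels)
        remaining = quota - painted
        areas = np.clip(
            rng.normal(a_mean, SHEET_AREA_SD, size), a_min, a_max
        ).astype(int)
        projected = SLAB_THICKNESS * int(areas.sum())
        if projected > remaining:
            areas = np.clip(
                (areas * remaining / projected).astype(int), a_min, a_max
            )

        feasible_l0 = [
            l0
            for l0 in range(0, n_levels - size + 1)
            if all(free[l0 + j].sum() >= 1.25 * areas[j] for j in range(size))
        ]
        if not feasible_l0:
            continue
        placed_ok = False
        for l0 in rng.permutation(feasible_l0)[:8]:
            cells: list[tuple[int, np.ndarray, np.ndarray]] = []
            prev_patch = None
            failed = False
            for j in range(size):
                level = int(l0) + j
                for _try in range(12):
                    if prev_patch is None:
                        pool = np.argwhere(free[level])
                    else:
                        pool = np.argwhere(prev_patch & free[level] & tube_ok[level])
                    if len(pool) == 0:
                        failed = True
                        break
                    seed = pool[rng.integers(0, len(pool))]
                    patch = grow_patch(level, seed, int(areas[j]))
                    if patch is not None:
                        cells.append((level, patch, seed))
                        prev_patch = patch
                        break
                else:
                    failed = True
                if failed:
                    break
            if failed:
                continue
            # Commit: paint sheets and tubes, update the free masks.
            for j, (level, patch, seed) in enumerate(cells):
                z0 = level_z[level]
                cell_id = next_id + j
                for dz in range(SLAB_THICKNESS):
                    zsl = z0 + dz
                    sel = patch & (labels[zsl] == cat.STROMA_ECM)
                    labels[zsl][sel] = cat.STELLATE_CELL
                    inst[zsl][sel] = cell_id
                    painted += int(sel.sum())
                free[level] &= ~ndimage.binary_dilation(patch, structure=margin_struct)
                if j > 0:
                    prev_level = cells[j - 1][0]
                    gap_lo = level_z[prev_level] + SLAB_THICKNESS
                    ty, tx = int(seed[0]), int(seed[1])
                    for zsl in range(gap_lo, z0):
                        if labels[zsl, ty, tx] == cat.STROMA_ECM:
                            labels[zsl, ty, tx] = cat.STELLATE_CELL
                            inst[zsl, ty, tx] = cell_id
                            painted += 1
                id_table[cell_id] = InstanceInfo("stellate_cell", network_id + 1)
            network_id += 1
            network_sizes[network_id] = size
            next_id += size
            placed_ok = True
            stall = 0
            break
        if not placed_ok:
            continue
    return network_sizes, id_table, painted, next_id


def _bresenham(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """8-connected in-plane pixel path from p to q, inclusive."""
    n = int(max(abs(q[0] - p[0]), abs(q[1] - p[1]))) + 1
    ys = np.round(np.linspace(p[0], q[0], n)).astype(int)
    xs = np.round(np.linspace(p[1], q[1], n)).astype(int)
    path = np.column_stack([ys, xs])
    keep = np.ones(len(path), dtype=bool)
    keep[1:] = np.any(path[1:] != path[:-1], axis=1)
    return path[keep]


def _geodesic_path(
    allowed: np.ndarray,
    starts: np.ndarray,
    goals: np.ndarray,
    max_steps: int,
) -> Optional[np.ndarray]:
    """Shortest 8-connected in-plane path from any start to any goal pixel
    through the allowed mask (BFS wavefront + greedy traceback); None when
    no goal is reachable within ``max_steps``."""
    struct8 = ndimage.generate_binary_structure(2, 2)
    reach = starts & allowed
    if not reach.any():
        return None
    dist = np.full(allowed.shape, -1, dtype=np.int32)
    dist[reach] = 0
    for step in range(1, max_steps + 1):
        if (reach & goals).any():
            break
        new = ndimage.binary_dilation(reach, structure=struct8) & allowed & (dist < 0)
        if not new.any():
            break
        dist[new] = step
        reach |= new
    hits = np.argwhere(reach & goals)
    if len(hits) == 0:
        return None
    order = np.argsort(dist[hits[:, 0], hits[:, 1]], kind="stable")
    cur = hits[order[0]]
    path = [cur]
    while dist[cur[0], cur[1]] > 0:
        d = dist[cur[0], cur[1]]
        found = None
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy, xx = cur[0] + dy, cur[1] + dx
                if (
                    0 <= yy < allowed.shape[0]
                    and 0 <= xx < allowed.shape[1]
                    and dist[yy, xx] == d - 1
                ):
                    found = np.array([yy, xx])
                    break
            if found is not None:
                break
        if found is None:
            return None
        cur = found
        path.append(cur)
    return np.array(path[::-1])


def _relocate_vesicle_to_contact(
    labels: np.ndarray,
    inst: np.ndarray,
    packer: "_Packer",
    vid: int,
    length: float,
    width: float,
    rng: np.random.Generator,
) -> bool:
    """Last-resort contact creation: move vesicle ``vid`` from its pocket
    to a site flush against a stellate sheet edge.

    Used only when no process nub can reach the vesicle where it lies
    (e.g. it sits in an isolated crevice). The vesicle keeps its drawn
    size; it is re-rasterized with its long axis in-plane (or upright
    when too thick for the sheet gaps) so its contact face sits at the
    chosen site. Returns True on success; on failure the vesicle stays
    where it was.
    """
    sp = packer.spacing
    sz = sp[0]
    lat_struct = np.zeros((1, 3, 3), dtype=bool)
    lat_struct[0] = [[False, True, False], [True, True, True], [False, True, False]]
    stellate_mask = labels == cat.STELLATE_CELL
    surf = ndimage.binary_dilation(stellate_mask, structure=lat_struct) & (
        labels == cat.STROMA_ECM
    )
    surf_coords = np.argwhere(surf)
    if len(surf_coords) == 0:
        return False
    old = np.argwhere(inst == vid)
    labels[old[:, 0], old[:, 1], old[:, 2]] = cat.STROMA_ECM
    inst[old[:, 0], old[:, 1], old[:, 2]] = 0
    inplane_dirs = np.array([[0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for _try in range(800):
        v = surf_coords[rng.integers(0, len(surf_coords))]
        if labels[v[0], v[1], v[2]] != cat.STROMA_ECM:
            continue
        dirs = [
            d
            for d in inplane_dirs
            if packer.coords_ok((v - d)[None])
            and labels[tuple(v - d)] == cat.STELLATE_CELL
        ]
        if not dirs:
            continue
        n_dir = dirs[rng.integers(0, len(dirs))]
        if width >= 3.5 * sz:
            u = np.array([1.0, 0.0, 0.0])  # upright: thread between sheets
        else:
            phi = rng.uniform(0.0, 2.0 * math.pi)
            u = np.array([0.0, math.sin(phi), math.cos(phi)])
        offs = spheroid_offsets(length, width, u, sp)
        proj = offs @ n_dir
        extreme = offs[proj == proj.min()]
        e = extreme[rng.integers(0, len(extreme))]
        coords = offs + (v - e)
        if not packer.coords_ok(coords) or not packer.all_ecm(coords):
            continue
        packer.paint(coords, cat.VESICLE, vid)
        return True
    # restore the original placement
    labels[old[:, 0], old[:, 1], old[:, 2]] = cat.VESICLE
    inst[old[:, 0], old[:, 1], old[:, 2]] = vid
    return False


def _grow_contact_nub(
    labels: np.ndarray,
    inst: np.ndarray,
    id_table: dict[int, InstanceInfo],
    spacing: tuple[float, float, float],
    vid: int,
    vesicle_lut: np.ndarray,
    bbox,
    rng: np.random.Generator,
) -> bool:
    """Grow a one-voxel-thick stellate process "nub" from a nearby sheet to
    touch vesicle ``vid``, assigned to that sheet's cell.

    The nub is an in-plane geodesic path at one slice of the vesicle's
    z-range, from the vesicle's surface to the nearest reachable sheet of
    one network; it threads around other vesicles (whose 26-neighbourhood
    must stay stellate-free) and around other networks' cells (contact
    would merge networks). A sheet directly above or below the path end
    also qualifies — the nub hooks under or over it. Returns True when a
    contact was created.
    """
    nz, ny, nx = labels.shape
    sz, sy, sx = spacing
    struct4 = ndimage.generate_binary_structure(2, 1)
    struct8 = ndimage.generate_binary_structure(2, 2)

    net_lut = np.zeros(int(inst.max()) + 1, dtype=np.int32)
    for iid, info in id_table.items():
        if info.category == "stellate_cell" and info.network_id:
            net_lut[iid] = info.network_id

    z_range = list(range(bbox[0].start, bbox[0].stop))
    rng.shuffle(z_range)
    for z in z_range:
        own2d = inst[z] == vid
        if not own2d.any():
            continue
        zlo, zhi = max(z - 1, 0), min(z + 1, nz - 1)

        # stellate pixels visible from this slice, with their networks
        stell_nets = []
        for zz in {zlo, z, zhi}:
            m = labels[zz] == cat.STELLATE_CELL
            if m.any():
                stell_nets.append(net_lut[inst[zz]] * m)
        if not stell_nets:
            continue
        near_nets = np.unique(np.concatenate([s[s > 0] for s in stell_nets]))
        if len(near_nets) == 0:
            continue

        # other vesicles around these slices: their 26-halo is off limits
        other2d = np.zeros((ny, nx), dtype=bool)
        for zz in range(zlo, zhi + 1):
            other2d |= vesicle_lut[inst[zz]] & (inst[zz] != vid)
        other2d = ndimage.binary_dilation(other2d, structure=struct8)

        ring = ndimage.binary_dilation(own2d, structure=struct4) & ~own2d
        ring &= labels[z] == cat.STROMA_ECM

        rng.shuffle(near_nets)
        for net in near_nets[:3]:
            own_net = np.zeros((ny, nx), dtype=bool)      # target network's pixels
            foreign = np.zeros((ny, nx), dtype=bool)      # everyone else's
            for zz in range(zlo, zhi + 1):
                m = labels[zz] == cat.STELLATE_CELL
                nets = net_lut[inst[zz]]
                own_net |= m & (nets == net)
                foreign |= m & (nets != net)
            allowed = (
                (labels[z] == cat.STROMA_ECM)
                & ~other2d
                & ~ndimage.binary_dilation(foreign, structure=struct8)
            )
            goals = ndimage.binary_dilation(own_net, structure=struct8) & allowed
            path = _geodesic_path(allowed, ring, goals, NUB_MAX_PX)
            if path is None:
                continue
            # receiving cell: a stellate voxel of this network 26-adjacent
            # to the path end
            ey, ex = int(path[-1][0]), int(path[-1][1])
            tid = 0
            for zz in (z, zlo, zhi):
                sub = inst[zz, max(ey - 1, 0) : ey + 2, max(ex - 1, 0) : ex + 2]
                cand = sub[(net_lut[sub] == net) & (sub > 0)]
                if len(cand):
                    tid = int(cand[0])
                    break
            if tid == 0:
                continue
            labels[z, path[:, 0], path[:, 1]] = cat.STELLATE_CELL
            inst[z, path[:, 0], path[:, 1]] = tid
            return True
    return False


# ---------------------------------------------------------------------------
# Public generators

def sample_vesicle_geometry(
    spec: PhantomSpec, n: int, seed: Optional[int | np.random.Generator] = None
) -> list[tuple[float, float]]:
    """Draw ``n`` (length, width) pairs in nm from the spec's vesicle
    distributions: log-normal lengths, widths = length x ratio with the
    ratio clipped to (0, 1]. Reproducible under the given seed (defaults
    to the spec seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    lengths = spec.vesicle_length_dist.sample(rng, n)
    ratios = spec.vesicle_ratio_dist.sample(rng, n)
    widths = lengths * ratios
    return list(zip(lengths.tolist(), widths.tolist()))


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[LabelVolume, InstanceMap, PhantomGroundTruth]:
    """Build one labeled villus phantom; see the module docstring for the
    construction. Deterministic: the same spec (including seed) yields a
    bit-identical volume.

    Raises :class:`PackingError` naming the category that could not reach
    its target when rejection packing runs out of attempts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2869]))
    nz, ny, nx = spec.shape
    sp = spec.spacing
    sz, sy, sx = sp

    # Feasibility of the requested vesicle load.
    med_offs = len(
        spheroid_offsets(
            spec.vesicle_length_dist.median_nm,
            spec.vesicle_length_dist.median_nm * spec.vesicle_ratio_dist.median,
            np.array([0.0, 0.0, 1.0]),
            sp,
        )
    )
    stroma_quota_est = (
        STROMA_OF_VILLOUS * VILLUS_FILL * nz * ny * nx
        if "stroma_ecm" not in spec.target_fractions
        else sum(
            spec.target_fractions.get(c, 0.0) for c in cat.STROMAL_CATEGORIES
        )
        * VILLUS_FILL
        * nz
        * ny
        * nx
    )
    if spec.n_vesicles * med_offs > 0.35 * stroma_quota_est:
        raise PackingError(
            "vesicle",
            f"{spec.n_vesicles} vesicles of median size ({med_offs} voxels each) "
            "cannot fit the stromal compartment of this shape",
        )

    # ---- 2D layout: villus, trophoblast bands, capillaries -----------------
    villus2d = _villus_mask_2d(ny, nx, VILLUS_FILL, rng)
    n2_villous = int(villus2d.sum())
    quota3 = {
        c: int(round(f * n2_villous * nz)) for c, f in spec.target_fractions.items()
    }
    quota2 = {c: int(round(q / nz)) for c, q in quota3.items()}

    edt2 = ndimage.distance_transform_edt(villus2d, sampling=(sy, sx))
    ordered = _ordered_flat_indices(edt2, villus2d)
    k_syn = quota2.get("syncytiotrophoblast", 0)
    k_cyt = quota2.get("cytotrophoblast", 0)
    syn_idx = ordered[:k_syn]
    cyt_idx = ordered[k_syn : k_syn + k_cyt]
    pocket_flat = ordered[k_syn + k_cyt :]
    pocket2d = np.zeros((ny, nx), dtype=bool)
    pocket2d.ravel()[pocket_flat] = True

    k_lum = quota2.get("capillary_lumen", 0)
    k_end = quota2.get("endothelial_cell", 0)
    k_per = quota2.get("pericyte", 0)
    k_cap = k_lum + k_end + k_per
    r_est_nm = math.sqrt(max(k_cap, 1) * sy * sx / (N_CAPILLARIES * math.pi))
    # The stroma pocket must at least be wide enough somewhere for a
    # median vesicle and a sheet patch around it.
    pocket_need_nm = 15 * max(sy, sx)

    pocket_edt = ndimage.distance_transform_edt(pocket2d, sampling=(sy, sx))
    cand = np.argwhere(pocket2d)
    # Deepest pocket point: the stroma reserve grows around it, so the
    # capillary bundle is pushed toward the far side of the pocket (it may
    # hug the trophoblast band; real capillaries do) to keep the reserve
    # compact instead of web-like.
    reserve = np.array(np.unravel_index(int(np.argmax(pocket_edt)), pocket_edt.shape))

    def _dist_nm(a, b) -> float:
        return math.hypot((a[0] - b[0]) * sy, (a[1] - b[1]) * sx)

    cand_dist = np.array([_dist_nm(c, reserve) for c in cand])
    far_order = np.argsort(-cand_dist, kind="stable")

    stroma2d = None
    cap_order = None
    for _attempt in range(80):
        if k_cap == 0:
            stroma2d = pocket2d.copy()
            cap_order = np.array([], dtype=int)
            break
        # Greedy: centers as far from the reserve as possible, clustered,
        # with random jitter in the pick so retries explore layouts.
        centers = []
        pool = far_order[: max(len(far_order) // 3, N_CAPILLARIES * 50)]
        for _ in range(800):
            c = cand[pool[rng.integers(0, len(pool))]]
            if centers and _dist_nm(c, centers[0]) > 3.0 * r_est_nm:
                continue  # keep the bundle clustered
            if all(_dist_nm(c, o) >= 1.4 * r_est_nm for o in centers):
                centers.append(c)
            if len(centers) == N_CAPILLARIES:
                break
        if len(centers) < N_CAPILLARIES:
            continue
        yy, xx = np.mgrid[0:ny, 0:nx]
        dist = np.full((ny, nx), np.inf)
        for c in centers:
            d = np.sqrt(((yy - c[0]) * sy) ** 2 + ((xx - c[1]) * sx) ** 2)
            dist = np.minimum(dist, d)
        cap_order = _ordered_flat_indices(dist, pocket2d)
        trial = np.zeros((ny, nx), dtype=bool)
        trial.ravel()[cap_order[k_cap:]] = True
        trial_edt = ndimage.distance_transform_edt(trial, sampling=(sy, sx))
        if trial_edt.max() >= pocket_need_nm:
            stroma2d = trial
            break
    if stroma2d is None:
        raise PackingError(
            "stellate_cell",
            "could not reserve a stromal pocket wide enough for stellate "
            "sheets around the capillaries",
        )

    # ---- paint the static 3D structure ------------------------------------
    labels = np.full(spec.shape, cat.INTERVILLOUS_SPACE, dtype=np.int16)
    _paint_2d(labels, np.flatnonzero(villus2d), (ny, nx), cat.STROMA_ECM)
    _paint_2d(labels, syn_idx, (ny, nx), cat.SYNCYTIOTROPHOBLAST)
    _paint_2d(labels, cyt_idx, (ny, nx), cat.CYTOTROPHOBLAST)
    if k_cap > 0:
        _paint_2d(labels, cap_order[:k_lum], (ny, nx), cat.CAPILLARY_LUMEN)
        _paint_2d(labels, cap_order[k_lum : k_lum + k_end], (ny, nx), cat.ENDOTHELIAL_CELL)
        _paint_2d(labels, cap_order[k_lum + k_end : k_cap], (ny, nx), cat.PERICYTE)

    inst = np.zeros(spec.shape, dtype=np.int32)
    stroma_pixels = np.argwhere(stroma2d)
    packer = _Packer(labels, inst, sp, stroma_pixels, rng)

    # ---- vesicles (placed first; sheets are carved around them) -----------
    n_ves = spec.n_vesicles
    n_contact = int(math.floor(spec.contact_fraction * n_ves + 0.5))
    quota_stellate = quota3.get("stellate_cell", 0)
    if n_contact > 0 and quota_stellate == 0:
        raise PackingError(
            "vesicle", "contact vesicles requested but the stellate target is zero"
        )
    id_table: dict[int, InstanceInfo] = {}
    next_id = 1
    vesicle_rows = []
    vesicle_ids: list[int] = []
    if n_ves > 0:
        geoms = sample_vesicle_geometry(spec, n_ves, rng)
        cap = VESICLE_LENGTH_CAP * spec.vesicle_length_dist.median_nm
        capped = []
        for length, width in geoms:
            if length > cap:
                width *= cap / length
                length = cap
            capped.append((length, width))
        # Normalize the cohort by a common factor so the total vesicle
        # volume lands on the vesicle quota: composition is controlled
        # while the (scale-free) shape distribution is preserved.
        quota_ves_nm3 = quota3.get("vesicle", 0) * sz * sy * sx
        total_nm3 = sum(math.pi / 6.0 * l * w * w for l, w in capped)
        if quota_ves_nm3 > 0 and total_nm3 > 0:
            f = (quota_ves_nm3 / total_nm3) ** (1.0 / 3.0)
            capped = [(l * f, w * f) for l, w in capped]
        for i, (length, width) in enumerate(capped):
            placed = False
            for _attempt in range(3000):
                u = random_unit_vector(rng)
                offs = spheroid_offsets(length, width, u, sp)
                center = packer.random_stroma_voxel()
                coords = offs + center
                if not packer.coords_ok(coords) or not packer.all_ecm(coords):
                    continue
                packer.paint(coords, cat.VESICLE, next_id)
                id_table[next_id] = InstanceInfo("vesicle")
                vesicle_rows.append(
                    {
                        "instance_id": next_id,
                        "true_length_nm": float(length),
                        "true_width_nm": float(width),
                        "true_ratio": float(width / length),
                        "contact_partner": "",
                    }
                )
                vesicle_ids.append(next_id)
                next_id += 1
                placed = True
                break
            if not placed:
                raise PackingError(
                    "vesicle",
                    f"could not place vesicle {i} (length {length:.0f} nm) in the stroma",
                )

    # ---- macrophages (kept out of vesicle neighbourhoods) ------------------
    quota_mac = quota3.get("macrophage", 0)
    blob_est = len(ellipsoid_offsets(MACROPHAGE_SEMI_NM, sp))
    painted_mac = 0
    fails = 0
    while painted_mac < quota_mac - blob_est / 2:
        scale = 1.0 + rng.uniform(-0.2, 0.2)
        offs = ellipsoid_offsets(tuple(s * scale for s in MACROPHAGE_SEMI_NM), sp)
        center = packer.random_stroma_voxel()
        coords = offs + center
        if (
            packer.coords_ok(coords)
            and packer.all_ecm(coords)
            and packer.neighbourhood_clear(coords, (cat.VESICLE,))
        ):
            packer.paint(coords, cat.MACROPHAGE, next_id)
            id_table[next_id] = InstanceInfo("macrophage")
            next_id += 1
            painted_mac += len(coords)
            fails = 0
        else:
            fails += 1
            if fails > 5000:
                raise PackingError("macrophage", "macrophage packing stalled")

    # ---- stellate sheets carved around the placed objects ------------------
    # Every vesicle is halo-protected during carving; stellate contacts are
    # then created deliberately, so the detected contact fraction equals
    # the requested one exactly.
    network_sizes: dict[int, int] = {}
    if quota_stellate > 0:
        vesicle_lut = np.zeros(next_id, dtype=bool)
        if vesicle_ids:
            vesicle_lut[np.array(vesicle_ids)] = True
        protected = vesicle_lut[inst]
        body = protected | (labels == cat.MACROPHAGE)
        network_sizes, stell_table, _painted, next_id = _place_stellate_sheets(
            labels,
            inst,
            stroma2d,
            quota_stellate,
            spec.network_size_dist,
            sp,
            rng,
            next_id,
            body,
            protected,
        )
        id_table.update(stell_table)

    # ---- contact designation: grow nubs until the quota is met -------------
    contact_ids: set[int] = set()
    if n_contact > 0:
        vesicle_lut = np.zeros(next_id, dtype=bool)
        vesicle_lut[np.array(vesicle_ids)] = True
        objects = ndimage.find_objects(inst)
        for vid in rng.permutation(vesicle_ids):
            if len(contact_ids) == n_contact:
                break
            vid = int(vid)
            if _grow_contact_nub(
                labels, inst, id_table, sp, vid, vesicle_lut, objects[vid - 1], rng
            ):
                contact_ids.add(vid)
        if len(contact_ids) < n_contact:
            # second pass: nubs may now run beside vesicles that are
            # already designated contacts (extra stellate adjacency is
            # harmless for them), which opens paths through clusters
            for vid in rng.permutation(sorted(set(vesicle_ids) - contact_ids)):
                if len(contact_ids) == n_contact:
                    break
                vid = int(vid)
                relaxed = vesicle_lut.copy()
                relaxed[np.array(sorted(contact_ids), dtype=int)] = False
                if _grow_contact_nub(
                    labels, inst, id_table, sp, vid, relaxed, objects[vid - 1], rng
                ):
                    contact_ids.add(vid)
        if len(contact_ids) < n_contact:
            # final pass: relocate still-unreachable vesicles flush
            # against a sheet edge (their pockets are isolated crevices)
            size_by_id = {
                row["instance_id"]: (row["true_length_nm"], row["true_width_nm"])
                for row in vesicle_rows
            }
            for vid in rng.permutation(sorted(set(vesicle_ids) - contact_ids)):
                if len(contact_ids) == n_contact:
                    break
                vid = int(vid)
                length_nm, width_nm = size_by_id[vid]
                if _relocate_vesicle_to_contact(
                    labels, inst, packer, vid, length_nm, width_nm, rng
                ):
                    contact_ids.add(vid)
        if len(contact_ids) < n_contact:
            raise PackingError(
                "vesicle",
                f"only {len(contact_ids)} of {n_contact} stellate contacts "
                "could be realized",
            )
        for row in vesicle_rows:
            row["contact_partner"] = (
                "stellate_cell" if row["instance_id"] in contact_ids else ""
            )

    # ---- verify the contact bookkeeping is exact ---------------------------
    if n_ves > 0:
        struct26 = np.ones((3, 3, 3), dtype=bool)
        objects = ndimage.find_objects(inst)
        for vid in vesicle_ids:
            slc = objects[vid - 1]
            box = tuple(
                slice(max(s.start - 1, 0), min(s.stop + 1, d))
                for s, d in zip(slc, spec.shape)
            )
            own = inst[box] == vid
            shell = ndimage.binary_dilation(own, structure=struct26) & ~own
            touches = bool((labels[box][shell] == cat.STELLATE_CELL).any())
            if touches != (vid in contact_ids):
                raise PackingError(
                    "vesicle",
                    f"vesicle {vid} contact state inconsistent with its plan",
                )

    # ---- ground truth from the emitted volume ------------------------------
    volume = LabelVolume(labels, sp, dict(cat.CATEGORY_MAP))
    counts = volume.category_counts()
    n_villous = sum(v for k, v in counts.items() if k in cat.VILLOUS_CATEGORIES)
    villous_fractions = {
        k: counts.get(k, 0) / n_villous for k in sorted(cat.VILLOUS_CATEGORIES)
    }
    n_stromal = sum(v for k, v in counts.items() if k in cat.STROMAL_CATEGORIES)
    stromal_fractions = {
        k: counts.get(k, 0) / n_stromal for k in sorted(cat.STROMAL_CATEGORIES)
    }
    for c, f in spec.target_fractions.items():
        if abs(villous_fractions.get(c, 0.0) - f) > 0.015:
            raise PackingError(
                c,
                f"achieved villous fraction {villous_fractions.get(c, 0.0):.4f} "
                f"deviates from target {f:.4f} by more than 1.5 percentage points",
            )

    truth = PhantomGroundTruth(
        category_counts=counts,
        villous_fractions=villous_fractions,
        stromal_fractions=stromal_fractions,
        vesicles=pd.DataFrame(
            vesicle_rows,
            columns=[
                "instance_id",
                "true_length_nm",
                "true_width_nm",
                "true_ratio",
                "contact_partner",
            ],
        ),
        network_sizes=network_sizes,
        n_voxels_total=int(np.prod(spec.shape)),
    )
    instances = InstanceMap(inst, sp, id_table)
    return volume, instances, truth


# ---------------------------------------------------------------------------
# Vesicle field for morphometry validation

def generate_vesicle_field(
    n: int,
    length_dist: LogNormalLength = LogNormalLength(2750.0, 0.70),
    ratio_dist: LogitNormalRatio = LogitNormalRatio(0.71, 0.97),
    spacing: tuple[float, float, float] = (50.0, 25.0, 25.0),
    orientation: str = "axis_aligned",
    seed: int = 0,
):
    """Yield ``n`` single-vesicle instance maps at true (unscaled) sizes.

    Each vesicle is an ovoid (prolate spheroid) rendered in its own tight
    volume; defaults reproduce the macrovesicle population (log-normal
    lengths, median 2.75 μm; ratio median 0.71) on an anisotropic grid.

    ``orientation='axis_aligned'`` puts each long axis along a randomly
    chosen grid axis, so the axis-extent measurement protocol can recover
    the generative parameters; ``'uniform'`` rotates freely, which is
    physically realistic but systematically inflates measured ratios (the
    bounding-box extents of a tilted ovoid are all between width and
    length). Yields ``(InstanceMap, truth_row_dict)`` pairs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if orientation not in ("axis_aligned", "uniform"):
        raise ValueError("orientation must be 'axis_aligned' or 'uniform'")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 997]))
    lengths = length_dist.sample(rng, n)
    ratios = ratio_dist.sample(rng, n)
    for i in range(n):
        length = float(lengths[i])
        width = float(length * ratios[i])
        if orientation == "axis_aligned":
            axis = int(rng.integers(0, 3))
            u = np.zeros(3)
            u[axis] = 1.0
        else:
            u = random_unit_vector(rng)
        mask = rasterize_spheroid_volume(length, width, u, spacing)
        imap = InstanceMap(
            mask.view(np.int8), spacing, {1: InstanceInfo("vesicle")}
        )
        yield imap, {
            "instance_id": i + 1,
            "true_length_nm": length,
            "true_width_nm": width,
            "true_ratio": width / length,
        }


def measure_vesicle_field(
    n: int,
    length_dist: LogNormalLength = LogNormalLength(2750.0, 0.70),
    ratio_dist: LogitNormalRatio = LogitNormalRatio(0.71, 0.97),
    spacing: tuple[float, float, float] = (50.0, 25.0, 25.0),
    orientation: str = "axis_aligned",
    seed: int = 0,
    selection_mode: str = "systematic",
) -> tuple[list[VesicleMeasurement], pd.DataFrame]:
    """Generate a vesicle field and measure every vesicle, returning the
    measurements and the generative ground truth side by side."""
    measurements = []
    rows = []
    for k, (imap, truth_row) in enumerate(
        generate_vesicle_field(n, length_dist, ratio_dist, spacing, orientation, seed)
    ):
        m = measure_object(imap, 1, selection_mode=selection_mode)
        measurements.append(
            VesicleMeasurement(
                instance_id=k + 1,
                extent_z=m.extent_z,
                extent_y=m.extent_y,
                extent_x=m.extent_x,
                length=m.length,
                width=m.width,
                ratio=m.ratio,
                selection_mode=selection_mode,
                boundary_clipped=m.boundary_clipped,
            )
        )
        rows.append(truth_row)
    return measurements, pd.DataFrame(rows)
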