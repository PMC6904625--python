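"""Vesicle-cell contact classification and stellate-network analysis.

Contact is defined by voxel adjacency: a vesicle is in contact with a
partner category when some vesicle voxel is 26-adjacent (faces, edges and
corners) to a voxel of that category belonging to a different instance.
The permissive 26-neighbourhood is the digital analogue of counting any
visible touching during manual inspection. Adjacency to the
syncytiotrophoblast stands in for contact with the trophoblast basal
lamina, which has no separate label.

Stellate networks are connected components of a graph whose vertices are
stellate cells (one nucleus each) with an edge whenever two cells' voxels
are 26-adjacent; the summary statistic is the mean number of nuclei per
network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .categories import CONTACT_PARTNER_CATEGORIES, STROMAL_CELL_CATEGORIES
from .io import InstanceMap, LabelVolume
from .morphometry import VesicleMeasurement
from .stats import TestResult, mann_whitney

__all__ = [
    "ContactRecord",
    "NetworkSummary",
    "ContactSizeComparison",
    "detect_contacts",
    "contact_summary",
    "compare_contact_sizes",
    "stellate_networks",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ContactRecord:
    """Contact partners of one vesicle.

    ``any_stromal_cell_contact`` is true iff a stellate cell or a
    macrophage is among the partners.
    """

    vesicle_id: int
    partners: frozenset[str]
    any_stromal_cell_contact: bool

    def __post_init__(self) -> None:
        expected = bool(self.partners & STROMAL_CELL_CATEGORIES)
        if self.any_stromal_cell_contact != expected:
            raise ValueError("any_stromal_cell_contact inconsistent with partners")


@dataclass(frozen=True)
class NetworkSummary:
    """Connected-component sizes (nuclei per network) and their mean/SEM."""

    sizes: tuple[int, ...]
    mean: float
    sem: Optional[float]
    n_networks: int

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.sizes):
            raise ValueError("network sizes must be >= 1")
        if self.sizes and abs(self.mean - float(np.mean(self.sizes))) > 1e-9:
            raise ValueError("mean inconsistent with sizes")


@dataclass(frozen=True)
class ContactSizeComparison:
    """Contact vs no-contact vesicle lengths: medians, ranges and the
    rank-test result."""

    median_contact_um: float
    range_contact_um: tuple[float, float]
    n_contact: int
    median_no_contact_um: float
    range_no_contact_um: tuple[float, float]
    n_no_contact: int
    test: TestResult


def _bbox_with_margin(mask_coords, shape, margin=1):
    lo = [max(int(c.min()) - margin, 0) for c in mask_coords]
    hi = [min(int(c.max()) + margin + 1, s) for c, s in zip(mask_coords, shape)]
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def detect_contacts(
    labels: LabelVolume,
    instances: InstanceMap,
    vesicle_ids: Optional[Sequence[int]] = None,
    connectivity: int = 26,
) -> list[ContactRecord]:
    """Record, for each vesicle, every partner category with a voxel
    26-adjacent to the vesicle (6-adjacent if ``connectivity=6``), always
    excluding the vesicle's own voxels.

    Contact with another vesicle is recorded as partner ``"vesicle"`` only
    when the adjacent voxel belongs to a *different* instance.
    """
    if labels.shape != instances.shape:
        raise ValueError("label volume and instance map shapes differ")
    if connectivity == 26:
        struct = _STRUCT26
    elif connectivity == 6:
        struct = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    if vesicle_ids is None:
        vesicle_ids = instances.ids_of_category("vesicle")
    code_to_name = dict(labels.category_map)

    # Precompute bounding boxes in one pass.
    max_id = int(instances.voxels.max()) if len(vesicle_ids) else 0
    objects = ndimage.find_objects(instances.voxels, max_label=max_id)

    records: list[ContactRecord] = []
    for vid in vesicle_ids:
        info = instances.id_table.get(int(vid))
        if info is None or info.category != "vesicle":
            raise ValueError(f"unknown vesicle ID {vid}")
        sl = objects[int(vid) - 1] if int(vid) - 1 < len(objects) else None
        if sl is None:
            raise ValueError(f"vesicle {vid} has no voxels")
        region = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, instances.shape)
        )
        inst_sub = instances.voxels[region]
        lab_sub = labels.voxels[region]
        own = inst_sub == vid
        shell = ndimage.binary_dilation(own, structure=struct) & ~own
        partners: set[str] = set()
        for code in np.unique(lab_sub[shell]):
            name = code_to_name[int(code)]
            if name in CONTACT_PARTNER_CATEGORIES:
                partners.add(name)
        records.append(
            ContactRecord(
                vesicle_id=int(vid),
                partners=frozenset(partners),
                any_stromal_cell_contact=bool(
                    frozenset(partners) & STROMAL_CELL_CATEGORIES
                ),
            )
        )
    return records


def _round_percent(x: float) -> int:
    """Round half away from zero, matching hand-rounded report percentages."""
    return int(np.floor(x + 0.5))


def contact_summary(records: Sequence[ContactRecord]) -> dict[str, float]:
    """Percentages of vesicles with stellate contact and with any
    stromal-cell (stellate or macrophage) contact, rounded to the nearest
    integer percent for reporting; exact values are returned alongside."""
    if not records:
        raise ValueError("no contact records")
    n = len(records)
    n_stellate = sum(1 for r in records if "stellate_cell" in r.partners)
    n_stromal = sum(1 for r in records if r.any_stromal_cell_contact)
    return {
        "n_vesicles": n,
        "n_stellate_contact": n_stellate,
        "n_any_stromal_contact": n_stromal,
        "pct_stellate_contact": _round_percent(100.0 * n_stellate / n),
        "pct_any_stromal_contact": _round_percent(100.0 * n_stromal / n),
        "frac_stellate_contact": n_stellate / n,
        "frac_any_stromal_contact": n_stromal / n,
    }


def compare_contact_sizes(
    measurements: Sequence[VesicleMeasurement],
    records: Sequence[ContactRecord],
) -> ContactSizeComparison:
    """Mann-Whitney comparison of vesicle lengths split by stromal-cell
    contact. Every measured vesicle must have a contact record; each group
    must be non-empty."""
    by_id = {r.vesicle_id: r for r in records}
    contact, no_contact = [], []
    for m in measurements:
        rec = by_id.get(m.instance_id)
        if rec is None:
            raise ValueError(f"vesicle {m.instance_id} has no contact record")
        (contact if rec.any_stromal_cell_contact else no_contact).append(m.length_um)
    if not contact or not no_contact:
        raise ValueError("both contact and no-contact groups must be non-empty")
    test = mann_whitney(contact, no_contact)
    return ContactSizeComparison(
        median_contact_um=float(np.median(contact)),
        range_contact_um=(float(min(contact)), float(max(contact))),
        n_contact=len(contact),
        median_no_contact_um=float(np.median(no_contact)),
        range_no_contact_um=(float(min(no_contact)), float(max(no_contact))),
        n_no_contact=len(no_contact),
        test=test,
    )


def stellate_networks(instances: InstanceMap, connectivity: int = 26) -> NetworkSummary:
    """Partition stellate cells into networks by voxel adjacency.

    Each stellate cell carries one nucleus, so component sizes are nuclei
    per network. Components partition the cells: sizes sum to the total
    cell count.
    """
    ids = instances.ids_of_category("stellate_cell")
    if not ids:
        raise ValueError("no stellate-cell instances")
    if connectivity == 26:
        struct = _STRUCT26
    elif connectivity == 6:
        struct = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")

    id_to_idx = {iid: k for k, iid in enumerate(ids)}
    stellate_set = set(ids)
    objects = ndimage.find_objects(instances.voxels, max_label=max(ids))
    edges_i, edges_j = [], []
    for iid in ids:
        sl = objects[iid - 1]
        if sl is None:
            raise ValueError(f"stellate instance {iid} has no voxels")
        region = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, instances.shape)
        )
        sub = instances.voxels[region]
        own = sub == iid
        shell = ndimage.binary_dilation(own, structure=struct) & ~own
        for other in np.unique(sub[shell]):
            other = int(other)
            if other != 0 and other in stellate_set:
                edges_i.append(id_to_idx[iid])
                edges_j.append(id_to_idx[other])
    n = len(ids)
    graph = coo_matrix(
        (np.ones(len(edges_i)), (edges_i, edges_j)), shape=(n, n)
    )
    n_comp, labels_ = connected_components(graph, directed=False)
    sizes = tuple(sorted(int(c) for c in np.bincount(labels_, minlength=n_comp)))
    mean = float(np.mean(sizes))
    sem = (
        float(np.std(sizes, ddof=1) / np.sqrt(len(sizes))) if len(sizes) >= 2 else None
    )
    return NetworkSummary(sizes=sizes, mean=mean, sem=sem, n_networks=n_comp)
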