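"""Labeled-stack and table I/O with explicit physical spacing.

Volumes are held as ``(z, y, x)`` arrays, 0-based, with ``z`` the slicing
direction; spacing is nanometres per axis in the same order and the z step
may legitimately differ from the in-plane pixel size (serial block-face
stacks are anisotropic: pixels of a few nm, slices of tens of nm). All
physical quantities are kept in nm internally and converted to μm only at
the reporting layer.

On disk a volume is a multi-page 16-bit grayscale TIFF, one page per
slice; tables are CSV. The category map is mandatory on read — codes are
never inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .categories import CATEGORY_MAP

__all__ = [
    "LabelVolume",
    "InstanceInfo",
    "InstanceMap",
    "read_label_stack",
    "write_label_stack",
    "read_instance_stack",
    "write_instance_stack",
    "write_tables",
]


@dataclass
class LabelVolume:
    """A 3D grid of tissue-category codes with anisotropic voxel spacing.

    Parameters
    ----------
    voxels
        Integer category codes, shape ``(nz, ny, nx)``.
    spacing
        Physical voxel size in nm per axis, ``(z, y, x)``; all positive.
    category_map
        Mapping from every code present in ``voxels`` to a category name.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    category_map: Mapping[int, str] = field(default_factory=lambda: dict(CATEGORY_MAP))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        codes = np.unique(self.voxels)
        unknown = sorted(int(c) for c in codes if int(c) not in self.category_map)
        if unknown:
            raise ValueError(f"voxel codes missing from category_map: {unknown}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_nm3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def category_counts(self) -> dict[str, int]:
        """Exhaustive per-category voxel tally (the stereology oracle)."""
        counts = np.bincount(self.voxels.ravel(), minlength=max(self.category_map) + 1)
        return {
            name: int(counts[code]) if code < len(counts) else 0
            for code, name in self.category_map.items()
        }


@dataclass(frozen=True)
class InstanceInfo:
    """Metadata for one labeled object: its tissue category and, for
    stellate cells, the ground-truth network it belongs to."""

    category: str
    network_id: Optional[int] = None


@dataclass
class InstanceMap:
    """Per-object ID grid aligned voxel-for-voxel with a :class:`LabelVolume`.

    ID 0 is reserved for background. ``id_table`` maps every nonzero ID to
    its :class:`InstanceInfo`.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    id_table: dict[int, InstanceInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        present = set(int(i) for i in np.unique(self.voxels)) - {0}
        missing = sorted(present - set(self.id_table))
        if missing:
            raise ValueError(f"instance IDs missing from id_table: {missing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def ids_of_category(self, category: str) -> list[int]:
        return sorted(i for i, info in self.id_table.items() if info.category == category)

    def check_consistent(self, labels: LabelVolume) -> None:
        """Verify every instance's voxels carry its category in ``labels``."""
        from .categories import NAME_TO_CODE

        if labels.shape != self.shape:
            raise ValueError("label volume and instance map shapes differ")
        for iid, info in self.id_table.items():
            mask = self.voxels == iid
            if not mask.any():
                continue
            codes = np.unique(labels.voxels[mask])
            want = NAME_TO_CODE[info.category]
            if codes.size != 1 or int(codes[0]) != want:
                raise ValueError(
                    f"instance {iid} ({info.category}) overlaps label codes {codes.tolist()}"
                )


def _read_stack(path: Path | str) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:  # single-page stack
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multi-page 2D stack, got shape {arr.shape}")
    return arr


def read_label_stack(
    path: Path | str,
    spacing: Sequence[float],
    category_map: Mapping[int, str],
) -> LabelVolume:
    """Read a multi-page TIFF of category codes.

    ``spacing`` and ``category_map`` are mandatory: the file stores only
    raster data. Unknown codes raise with the offending codes listed.
    """
    arr = _read_stack(path)
    return LabelVolume(arr.astype(np.int64), tuple(spacing), dict(category_map))


def write_label_stack(volume: LabelVolume, path: Path | str) -> Path:
    """Write as 16-bit multi-page TIFF; round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = volume.voxels
    if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
        raise ValueError("category codes outside the 16-bit range")
    tifffile.imwrite(path, data.astype(np.uint16), photometric="minisblack")
    return path


def write_instance_stack(instances: InstanceMap, path: Path | str) -> Path:
    """Write the ID raster as 16-bit TIFF and the ID table as a sibling CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = instances.voxels
    if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
        raise ValueError("instance IDs outside the 16-bit range")
    tifffile.imwrite(path, data.astype(np.uint16), photometric="minisblack")
    rows = [
        {
            "instance_id": iid,
            "category": info.category,
            "network_id": "" if info.network_id is None else info.network_id,
        }
        for iid, info in sorted(instances.id_table.items())
    ]
    pd.DataFrame(rows, columns=["instance_id", "category", "network_id"]).to_csv(
        path.with_suffix(".instances.csv"), index=False
    )
    return path


def read_instance_stack(path: Path | str, spacing: Sequence[float]) -> InstanceMap:
    arr = _read_stack(path)
    table_path = Path(path).with_suffix(".instances.csv")
    id_table: dict[int, InstanceInfo] = {}
    if table_path.exists():
        df = pd.read_csv(table_path)
        for _, row in df.iterrows():
            net = row.get("network_id")
            net_id = None if pd.isna(net) or net == "" else int(net)
            id_table[int(row["instance_id"])] = InstanceInfo(str(row["category"]), net_id)
    else:
        id_table = {int(i): InstanceInfo("unknown") for i in np.unique(arr) if i != 0}
    return InstanceMap(arr.astype(np.int64), tuple(spacing), id_table)


def write_tables(results: Mapping[str, pd.DataFrame], path: Path | str) -> list[Path]:
    """Write each named DataFrame as ``<path>/<name>.csv``.

    Column order is preserved; float columns keep full precision and each
    gains a ``<col>_display`` companion rounded for human reading.
    """
    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        df = df.copy()
        for col in list(df.columns):
            if pd.api.types.is_float_dtype(df[col]):
                df[f"{col}_display"] = df[col].round(4)
        target = out_dir / f"{name}.csv"
        df.to_csv(target, index=False)
        written.append(target)
    return written
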