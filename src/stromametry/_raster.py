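"""Voxelization helpers for the phantom generator.

All geometry is done in physical units (nm) and converted to voxel
offsets per axis, so anisotropic spacing (coarse z, fine x/y) is handled
uniformly. Rasterization uses the voxel-center-inside rule, which is
close to volume-preserving for the object sizes used here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "spheroid_offsets",
    "ellipsoid_offsets",
    "rasterize_spheroid_volume",
    "random_unit_vector",
]


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform random direction on the sphere, as a (z, y, x) unit vector."""
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def spheroid_offsets(
    length_nm: float,
    width_nm: float,
    direction: np.ndarray,
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Voxel offsets (relative to a center voxel) inside a prolate spheroid.

    The spheroid has one long axis ``length_nm`` along ``direction`` (a
    physical-space unit vector) and two equal short axes ``width_nm`` —
    an ovoid with a single longest dimension, matching a width defined as
    the mean of the two shorter extents.

    Returns an ``(N, 3)`` int array; always contains at least the center
    voxel so every object occupies >= 1 voxel.
    """
    a = length_nm / 2.0
    b = width_nm / 2.0
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    sp = np.asarray(spacing, dtype=float)
    # Half-extent of the bounding box along each grid axis.
    h = np.sqrt(a * a * u * u + b * b * (1.0 - u * u))
    rad = np.maximum(np.ceil(h / sp).astype(int), 0)
    zz, yy, xx = np.mgrid[
        -rad[0] : rad[0] + 1, -rad[1] : rad[1] + 1, -rad[2] : rad[2] + 1
    ]
    offs = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    p = offs * sp  # physical offsets of voxel centers
    t = p @ u  # component along the long axis
    r2 = np.einsum("ij,ij->i", p, p) - t * t
    inside = (t / a) ** 2 + r2 / (b * b) <= 1.0
    if not inside.any():
        return np.zeros((1, 3), dtype=int)
    return offs[inside]


def ellipsoid_offsets(
    semi_axes_nm: tuple[float, float, float],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Axis-aligned ellipsoid voxel offsets (semi-axes in nm, (z, y, x))."""
    s = np.asarray(semi_axes_nm, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    rad = np.maximum(np.ceil(s / sp).astype(int), 0)
    zz, yy, xx = np.mgrid[
        -rad[0] : rad[0] + 1, -rad[1] : rad[1] + 1, -rad[2] : rad[2] + 1
    ]
    offs = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    q = offs * sp / s
    inside = np.einsum("ij,ij->i", q, q) <= 1.0
    if not inside.any():
        return np.zeros((1, 3), dtype=int)
    return offs[inside]


def rasterize_spheroid_volume(
    length_nm: float,
    width_nm: float,
    direction: np.ndarray,
    spacing: tuple[float, float, float],
    pad: int = 1,
) -> np.ndarray:
    """Boolean volume of one spheroid in its own tight bounding box.

    Slice-wise evaluation keeps the memory footprint to one 2D plane of
    temporaries, so even very large objects (hundreds of voxels across)
    rasterize without materializing a 3D coordinate grid.
    """
    a = length_nm / 2.0
    b = width_nm / 2.0
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    sp = np.asarray(spacing, dtype=float)
    h = np.sqrt(a * a * u * u + b * b * (1.0 - u * u))
    rad = np.maximum(np.ceil(h / sp).astype(int), 0)
    shape = tuple(2 * r + 1 + 2 * pad for r in rad)
    out = np.zeros(shape, dtype=bool)
    py = ((np.arange(shape[1]) - rad[1] - pad) * sp[1]).astype(np.float32)
    px = ((np.arange(shape[2]) - rad[2] - pad) * sp[2]).astype(np.float32)
    yy, xx = np.meshgrid(py, px, indexing="ij")
    inv_a2 = 1.0 / (a * a)
    inv_b2 = 1.0 / (b * b)
    for iz in range(shape[0]):
        pz = (iz - rad[0] - pad) * sp[0]
        t = pz * u[0] + yy * u[1] + xx * u[2]
        r2 = pz * pz + yy * yy + xx * xx - t * t
        out[iz] = t * t * inv_a2 + r2 * inv_b2 <= 1.0
    if not out.any():
        out[tuple(r + pad for r in rad)] = True
    return out
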