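"""Voxel-grid geometry helpers shared by all volume types.

World coordinates are millimetres in the right-handed space defined by each
volume's voxel-to-world affine; voxel indices are 0-based and a voxel's
center sits at ``affine @ (i, j, k, 1)``.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates


def check_affine(affine: np.ndarray) -> np.ndarray:
    """Validate a 4x4 voxel-to-world affine with orthogonal grid axes.

    The linear part must decompose into rotation times positive scaling
    (columns mutually orthogonal, non-zero). Returns the affine as float64.
    """
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite entries")
    if not np.allclose(affine[3], [0, 0, 0, 1]):
        raise ValueError("affine bottom row must be [0, 0, 0, 1]")
    lin = affine[:3, :3]
    if abs(np.linalg.det(lin)) < 1e-12:
        raise ValueError("affine is singular")
    gram = lin.T @ lin
    off = gram - np.diag(np.diag(gram))
    if np.max(np.abs(off)) > 1e-6 * np.max(np.diag(gram)):
        raise ValueError("grid axes are not orthogonal in world space")
    return affine


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (..., 3) to world mm coordinates (..., 3)."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Map world mm coordinates (..., 3) to continuous voxel indices."""
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def grid_world_coords(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World coordinates of every voxel center, shape (*shape, 3)."""
    idx = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape[:3]), indexing="ij"), axis=-1
    )
    return voxel_to_world(affine, idx)


def sample_trilinear(data: np.ndarray, affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinearly sample a scalar or multi-channel grid at world points.

    ``data`` has shape (nx, ny, nz) or (nx, ny, nz, K). Points outside the
    grid contribute 0. Returns shape (npts,) or (npts, K).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("sample points must be finite")
    vox = world_to_voxel(affine, points).T  # (3, npts)
    if data.ndim == 3:
        return map_coordinates(data, vox, order=1, mode="grid-constant", cval=0.0)
    out = np.empty((points.shape[0], data.shape[3]), dtype=float)
    for k in range(data.shape[3]):
        out[:, k] = map_coordinates(data[..., k], vox, order=1, mode="grid-constant", cval=0.0)
    return out


def sample_nearest_inside(mask: np.ndarray, affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Nearest-voxel mask membership for world points; outside grid -> False."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    vox = np.rint(world_to_voxel(affine, points)).astype(int)
    inside = np.all((vox >= 0) & (vox < np.array(mask.shape)), axis=1)
    out = np.zeros(points.shape[0], dtype=bool)
    if np.any(inside):
        v = vox[inside]
        out[inside] = mask[v[:, 0], v[:, 1], v[:, 2]].astype(bool)
    return out
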