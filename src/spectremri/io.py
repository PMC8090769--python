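"""NIfTI / TCK / gradient-table / config file handling.

Conventions:
  * all volumes are NIfTI-1, data written as float32, affines preserved;
  * multi-channel volumes (colors, SPECTRE maps, deformation fields) put
    the channel on the 4th dimension;
  * tensors travel as 6-component volumes in lower-triangular row order
    (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz);
  * streamlines are written as TCK in world mm (RAS); TRK is accepted on
    read;
  * gradient tables are FSL-style whitespace-separated bval / bvec text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .colorfield import ColorVolume, DeformationField
from .spectre import SpectreMap, TargetRegion
from .tracking import Mask, Streamline, TensorField

_LT = ((0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2))


def _load(path) -> tuple[np.ndarray, np.ndarray]:
    try:
        img = nib.load(str(path))
        return np.asanyarray(img.dataobj), img.affine
    except Exception as e:  # re-raise with the offending path
        raise IOError(f"cannot read NIfTI volume '{path}': {e}") from e


def _save(path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def write_colorvolume(path, cv: ColorVolume) -> None:
    _save(path, cv.data, cv.affine)


def read_colorvolume(path, space_tag: str = "template") -> ColorVolume:
    data, affine = _load(path)
    return ColorVolume(data, affine, space_tag)


def write_mask(path, mask: Mask | TargetRegion) -> None:
    data = mask.data if isinstance(mask, Mask) else mask.mask
    _save(path, data.astype(np.float32), mask.affine)


def read_mask(path) -> Mask:
    data, affine = _load(path)
    return Mask(data > 0.5, affine)


def read_target_region(path) -> TargetRegion:
    data, affine = _load(path)
    return TargetRegion(data > 0.5, affine)


def write_deformation(path, warp: DeformationField) -> None:
    _save(path, warp.mapping, warp.affine)


def read_deformation(path) -> DeformationField:
    data, affine = _load(path)
    if data.ndim == 5:  # some tools insert a singleton time axis
        data = data[:, :, :, 0, :]
    return DeformationField(data, affine)


def write_tensorfield(path, field: TensorField, mask_path=None) -> None:
    six = np.stack([field.tensors[..., i, j] for i, j in _LT], axis=-1)
    _save(path, six, field.affine)
    if mask_path is not None:
        _save(mask_path, field.mask.astype(np.float32), field.affine)


def read_tensorfield(path, mask_path=None) -> TensorField:
    six, affine = _load(path)
    if six.ndim != 4 or six.shape[3] != 6:
        raise IOError(f"'{path}': expected a 6-component tensor volume, got {six.shape}")
    t = np.zeros(six.shape[:3] + (3, 3))
    for k, (i, j) in enumerate(_LT):
        t[..., i, j] = six[..., k]
        t[..., j, i] = six[..., k]
    mask = None
    if mask_path is not None:
        mask = _load(mask_path)[0] > 0.5
    return TensorField(t, affine, mask)


def write_spectremap(path, smap: SpectreMap, for_display: bool = False) -> None:
    """Absent voxels are NaN in float outputs, 0 in display exports."""
    data = smap.data
    if for_display:
        data = np.nan_to_num(data, nan=0.0)
    _save(path, data, smap.affine)


def read_spectremap(path) -> SpectreMap:
    data, affine = _load(path)
    if data.ndim == 3:
        data = data[..., None]
    region = ~np.isnan(data).any(axis=3)
    return SpectreMap(data, affine, region)


def read_gradient_table(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape[1] == len(bvals):
        bvecs = bvecs.T
    if bvecs.shape != (len(bvals), 3):
        raise IOError("bvec table does not match the number of b-values")
    return bvals, bvecs


def write_gradient_table(bval_path, bvec_path, bvals, bvecs) -> None:
    np.savetxt(str(bval_path), np.atleast_2d(np.asarray(bvals).ravel()), fmt="%.6g")
    np.savetxt(str(bvec_path), np.asarray(bvecs).T, fmt="%.8g")


def write_streamlines(path, streamlines: list[Streamline]) -> None:
    """Write TCK with points in world mm."""
    tract = nib.streamlines.Tractogram(
        [s.points.astype(np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tract, str(path))


def read_streamlines(path) -> list[Streamline]:
    """Read TCK or TRK; points come back in world mm."""
    tf = nib.streamlines.load(str(path))
    out = []
    for pts in tf.tractogram.streamlines:
        pts = np.asarray(pts, dtype=float)
        out.append(Streamline(pts, pts[len(pts) // 2]))
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise IOError(f"config '{path}' must be a mapping")
    return cfg


def config_digest(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_provenance(path, cfg: dict, extra: dict | None = None) -> None:
    """Record config hash, seed and library versions next to run outputs."""
    import scipy

    record = {
        "config_digest": config_digest(cfg),
        "seed": cfg.get("seed"),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "nibabel": nib.__version__,
        },
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2) + "\n")
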