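"""Test-retest reproducibility of SPECTRE maps: the intraclass-distance index.

Maps from repeated scans of the same subjects are brought onto one common
grid and compared by squared Euclidean distance over all region voxels and
channels, with no channel weighting and no intensity pre-normalization.
The index

    icd = 100% * (1 - N * sum_n d(s_n1, s_n2) / sum_j sum_n d(s_j1, s_n2))

is 100% when every subject's two scans coincide while subjects differ, and
shrinks as within-subject differences approach between-subject differences.
The double sum in the denominator keeps the j = n diagonal terms.  The
index is not algebraically confined to [0, 100]% for adversarial inputs;
negative values are reported as computed rather than clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .colorfield import DeformationField
from .grids import sample_trilinear
from .spectre import SpectreMap


@dataclass
class RescanSet:
    """Per-subject scan pairs on one common grid plus an analysis mask.

    ``scan1`` and ``scan2`` list one SpectreMap per subject; the shared
    analysis mask is the intersection of the given mask (or every map's
    region) with the voxels present (non-NaN) in all maps.
    """

    scan1: list[SpectreMap]
    scan2: list[SpectreMap]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.scan1) != len(self.scan2) or not self.scan1:
            raise ValueError("need the same non-zero number of maps per scan")
        ref = self.scan1[0]
        for m in self.scan1 + self.scan2:
            if m.data.shape != ref.data.shape or not np.allclose(m.affine, ref.affine):
                raise ValueError("all maps must share one grid and affine")
        shared = np.ones(ref.data.shape[:3], dtype=bool)
        if self.mask is not None:
            shared &= np.asarray(self.mask).astype(bool)
        for m in self.scan1 + self.scan2:
            shared &= m.region_mask & ~np.isnan(m.data).any(axis=3)
        if not shared.any():
            raise ValueError("shared analysis mask is empty")
        self.mask = shared

    @property
    def n_subjects(self) -> int:
        return len(self.scan1)


@dataclass
class IcdResult:
    icd: float  # percent
    intra_sum: float
    inter_sum: float
    n_subjects: int
    per_subject_intra: np.ndarray | None = None


def map_distance(s_a: SpectreMap, s_b: SpectreMap, mask: np.ndarray) -> float:
    """Squared Euclidean distance over masked voxels and all channels."""
    if s_a.data.shape != s_b.data.shape or not np.allclose(s_a.affine, s_b.affine):
        raise ValueError("maps are not on the same grid")
    mask = np.asarray(mask).astype(bool)
    if mask.shape != s_a.data.shape[:3]:
        raise ValueError("mask is not on the maps' grid")
    diff = s_a.data[mask] - s_b.data[mask]
    return float(np.sum(diff**2))


def compute_icd(rescans: RescanSet, include_diagonal: bool = True) -> IcdResult:
    """Intraclass-distance index over a set of scan pairs.

    ``include_diagonal`` keeps the j = n terms in the between-subject sum
    (the printed definition); the exclusion variant is exposed for
    sensitivity analysis only.
    """
    n = rescans.n_subjects
    intra = np.array(
        [map_distance(a, b, rescans.mask) for a, b in zip(rescans.scan1, rescans.scan2)]
    )
    inter = 0.0
    for j, sj1 in enumerate(rescans.scan1):
        for i, si2 in enumerate(rescans.scan2):
            if not include_diagonal and i == j:
                continue
            inter += map_distance(sj1, si2, rescans.mask)
    if inter == 0:
        warnings.warn("all maps identical: icd undefined, reporting 100%")
        return IcdResult(100.0, float(intra.sum()), inter, n, intra)
    icd = 100.0 * (1.0 - n * intra.sum() / inter)
    return IcdResult(float(icd), float(intra.sum()), float(inter), n, intra)


def warp_map_to_common(
    smap: SpectreMap, warp: DeformationField, common_mask: np.ndarray | None = None
) -> SpectreMap:
    """Resample a subject-space map onto the common grid through a warp.

    ``warp.mapping`` gives, per common-grid voxel, the subject-space
    coordinate to sample (pull-back); channels are trilinearly
    interpolated. Voxels mapped outside the map's region become absent.
    """
    if warp is None:
        raise ValueError("a deformation field is required")
    pts = warp.mapping.reshape(-1, 3)
    filled = np.nan_to_num(smap.data, nan=0.0)
    data = sample_trilinear(filled, smap.affine, pts)
    present = (
        sample_trilinear(smap.region_mask.astype(float), smap.affine, pts) > 0.999
    )
    shape = warp.mapping.shape[:3]
    data = data.reshape(shape + (smap.n_channels,))
    present = present.reshape(shape)
    if common_mask is not None:
        present &= np.asarray(common_mask).astype(bool)
    data[~present] = np.nan
    return SpectreMap(data, warp.affine, present, smap.n_seeds, smap.params, smap.normalized)


def group_average(maps: list[SpectreMap]) -> SpectreMap:
    """Voxel- and channel-wise mean over maps, where present in all."""
    if not maps:
        raise ValueError("need at least one map")
    ref = maps[0]
    for m in maps:
        if m.data.shape != ref.data.shape or not np.allclose(m.affine, ref.affine):
            raise ValueError("maps are not on a shared grid")
    present = np.ones(ref.data.shape[:3], dtype=bool)
    for m in maps:
        present &= m.region_mask & ~np.isnan(m.data).any(axis=3)
    stack = np.stack([m.data for m in maps])
    data = stack.mean(axis=0)
    data[~present] = np.nan
    return SpectreMap(data, ref.affine, present, ref.n_seeds, ref.params, ref.normalized)
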