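"""Track-weighted color aggregation onto a super-resolved target grid.

For every voxel r of the target region, N streamlines are emitted and the
subject-space color field c_k is summed along all of their points:

    C_k(r) = sum_f sum_n c_k(x_n^{r,f})

with trilinear interpolation at the fractional positions x_n and no
normalization by streamline length — longer streamlines deliberately
contribute more.  The target grid may be finer than the diffusion grid
(typically half the acquisition voxel size); jittered sub-voxel seeding is
what makes this super-resolution meaningful.  Display normalization divides
by the 80th percentile of the brightness (channel sum) over the region and
clips to [0, 1]; quantitative analyses use the raw, un-normalized maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorfield import ColorVolume
from .grids import check_affine, grid_world_coords, sample_trilinear
from .tracking import DirectionModel, Mask, StreamlineBundle, TrackingParams, seed_bundle


@dataclass
class TargetRegion:
    """Binary region mask on the output grid, with its resolution in mm."""

    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("region mask must be 3D")
        if not self.mask.any():
            raise ValueError("target region is empty")
        self.affine = check_affine(self.affine)

    @property
    def resolution(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of the region's voxel centers, (nvox, 3)."""
        idx = np.argwhere(self.mask)
        return grid_world_coords(self.mask.shape, self.affine).reshape(-1, 3)[
            np.ravel_multi_index(idx.T, self.mask.shape)
        ]


@dataclass
class SpectreMap:
    """K-channel aggregated color map on the target grid.

    Voxels outside the target region are absent, encoded as NaN; inside the
    region values are >= 0 whenever the color field is. ``normalized``
    flags display scaling (quantitative paths keep it False).
    """

    data: np.ndarray
    affine: np.ndarray
    region_mask: np.ndarray
    n_seeds: int = 0
    params: TrackingParams | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("map data must be (nx, ny, nz, K)")
        self.region_mask = np.asarray(self.region_mask).astype(bool)
        if self.region_mask.shape != self.data.shape[:3]:
            raise ValueError("region mask must match map grid")
        self.affine = check_affine(self.affine)

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    def values_in_region(self) -> np.ndarray:
        """(nvox, K) array of the region voxels' channel values."""
        return self.data[self.region_mask]


def trilinear_sample(cv: ColorVolume, points: np.ndarray) -> np.ndarray:
    """Sample the color volume at world points; out-of-bounds yields 0."""
    return sample_trilinear(cv.data, cv.affine, points)


def aggregate_seed(bundle: StreamlineBundle, cv: ColorVolume) -> np.ndarray:
    """Sum the color field over every point of every streamline of a bundle.

    No per-streamline or per-length normalization is applied.
    """
    if cv.space_tag != "subject":
        raise ValueError("color volume must be in subject space for aggregation")
    if len(bundle) == 0 or bundle.total_points == 0:
        import warnings

        warnings.warn("empty bundle: aggregation yields a zero vector")
        return np.zeros(cv.n_channels)
    pts = np.concatenate([s.points for s in bundle.streamlines], axis=0)
    return trilinear_sample(cv, pts).sum(axis=0)


def compute_spectre(
    region: TargetRegion,
    model: DirectionModel,
    cv: ColorVolume,
    params: TrackingParams,
    n_seeds: int = 500,
    tracking_mask: Mask | None = None,
    jitter: bool = True,
) -> SpectreMap:
    """Build the full map: one jittered N-streamline bundle per region voxel.

    Deterministic given ``params.seed``: each region voxel derives its own
    random substream from (seed, flat voxel index), so results do not
    depend on iteration order.
    """
    if tracking_mask is None:
        raise ValueError("a tracking mask is required")
    shape = region.mask.shape
    data = np.full(shape + (cv.n_channels,), np.nan)
    jit = region.affine[:3, :3] if jitter else None
    flat_index = np.ravel_multi_index(np.argwhere(region.mask).T, shape)
    centers = region.voxel_centers()
    for center, fi in zip(centers, flat_index):
        ss = np.random.SeedSequence([params.seed, int(fi)])
        if tracking_mask.contains(center[None])[0]:
            bundle = seed_bundle(
                center, n_seeds, model, params, tracking_mask,
                seed_sequence=ss, jitter_linear=jit,
            )
            value = aggregate_seed(bundle, cv)
        else:  # region voxel outside trackable tissue: present but zero
            value = np.zeros(cv.n_channels)
        data[np.unravel_index(fi, shape)] = value
    return SpectreMap(data, region.affine, region.mask, n_seeds, params)


def normalize_for_display(smap: SpectreMap, region: TargetRegion | None = None) -> SpectreMap:
    """Scale by the 80th percentile of region brightness, then clip to [0, 1].

    Brightness is the per-voxel channel sum; the percentile uses linear
    interpolation between order statistics. Display-only: quantitative
    comparisons operate on un-normalized maps.
    """
    if smap.normalized:
        raise ValueError("map is already display-normalized")
    mask = region.mask if region is not None else smap.region_mask
    if mask.shape != smap.data.shape[:3]:
        raise ValueError("region grid does not match map grid")
    values = smap.data[mask]
    brightness = values.sum(axis=1)
    if not np.any(brightness > 0):
        raise ValueError("all-zero map: display scale is undefined")
    p80 = np.percentile(brightness, 80)
    if p80 <= 0:
        raise ValueError("80th-percentile brightness is zero: scale is undefined")
    data = np.clip(smap.data / p80, 0.0, 1.0)
    data[~smap.region_mask] = np.nan
    return SpectreMap(
        data, smap.affine, smap.region_mask, smap.n_seeds, smap.params, normalized=True
    )
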