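"""Template-space color gradients and their warp into subject space.

The shipped contrast is a sum of three isotropic Gaussians in template (MNI)
coordinates, each feeding one RGB channel, producing a smooth fronto-occipital
gradient: green over prefrontal cortex, blue over sensorimotor regions, red
occipitally.  The field is rasterized on a template grid, optionally
restricted to a tissue or lobe mask, and pulled back into subject space
through a dense deformation field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import (
    check_affine,
    grid_world_coords,
    sample_trilinear,
    voxel_to_world,
)

#: Default gradient: amplitudes (color weights), centers (MNI mm), width (mm).
DEFAULT_AMPLITUDES = np.array([[0.5, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
DEFAULT_CENTERS = np.array([[0.0, -60.0, 70.0], [0.0, 70.0, 0.0], [0.0, 20.0, 70.0]])
DEFAULT_SIGMA = 50.0


@dataclass(frozen=True)
class GradientSpec:
    """Three-Gaussian color gradient defined in template space.

    Each Gaussian i contributes ``a_i * exp(-|r_i - r|^2 / (2 sigma^2))``
    to the K-channel color at template position r (mm).
    """

    amplitudes: np.ndarray = field(default_factory=lambda: DEFAULT_AMPLITUDES.copy())
    centers: np.ndarray = field(default_factory=lambda: DEFAULT_CENTERS.copy())
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        r = np.asarray(self.centers, dtype=float)
        if a.ndim != 2 or a.shape[0] != 3:
            raise ValueError("amplitudes must be three K-vectors")
        if r.shape != (3, 3):
            raise ValueError("centers must be three 3D coordinates")
        if np.any(a < 0):
            raise ValueError("amplitude components must be >= 0")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(r))):
            raise ValueError("gradient parameters must be finite")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "centers", r)

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[1]


@dataclass
class ColorVolume:
    """Multi-channel scalar field on a regular grid.

    ``data`` has shape (nx, ny, nz, K); values are unitless, finite and
    non-negative. ``space_tag`` records whether the grid lives in template
    or subject space.
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = "template"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise ValueError("color data must be (nx, ny, nz, K)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("color values must be finite")
        if np.any(self.data < 0):
            raise ValueError("color values must be >= 0")
        if self.space_tag not in ("template", "subject"):
            raise ValueError("space_tag must be 'template' or 'subject'")
        self.affine = check_affine(self.affine)

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class DeformationField:
    """Dense subject-to-template coordinate mapping.

    ``mapping`` has shape (nx, ny, nz, 3) and stores, for each subject-grid
    voxel, the corresponding absolute template-space coordinate in mm (not a
    displacement). The identity field maps every voxel to its own world
    coordinate.
    """

    mapping: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=float)
        if self.mapping.ndim != 4 or self.mapping.shape[3] != 3:
            raise ValueError("deformation mapping must be (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.mapping)):
            raise ValueError("deformation vectors must be finite")
        self.affine = check_affine(self.affine)

    @classmethod
    def identity(cls, shape: tuple[int, int, int], affine: np.ndarray) -> "DeformationField":
        return cls(grid_world_coords(shape, affine), affine)

    @classmethod
    def translation(cls, shape, affine, offset) -> "DeformationField":
        """Field that samples the template at subject position + offset (mm)."""
        return cls(grid_world_coords(shape, affine) + np.asarray(offset, float), affine)


def evaluate_gradient(spec: GradientSpec, points: np.ndarray) -> np.ndarray:
    """Evaluate the Gaussian color mixture at template coordinates (mm).

    Returns one K-vector per point: ``c(r) = sum_i a_i exp(-|r_i - r|^2 /
    (2 sigma^2))``, channel-wise and un-normalized.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[-1] != 3:
        raise ValueError("points must be 3D coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    d2 = np.sum((pts[:, None, :] - spec.centers[None, :, :]) ** 2, axis=2)
    weights = np.exp(-d2 / (2.0 * spec.sigma**2))  # (npts, 3)
    out = weights @ spec.amplitudes  # (npts, K)
    return out if np.asarray(points).ndim > 1 else out[0]


def rasterize_gradient(
    spec: GradientSpec, shape: tuple[int, int, int], affine: np.ndarray
) -> ColorVolume:
    """Evaluate the gradient at every voxel center of a template grid."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ValueError("grid shape must be three positive integers")
    affine = check_affine(affine)
    coords = grid_world_coords(shape, affine).reshape(-1, 3)
    data = evaluate_gradient(spec, coords).reshape(shape + (spec.n_channels,))
    return ColorVolume(data, affine, space_tag="template")


def restrict_to_mask(cv: ColorVolume, mask: np.ndarray) -> ColorVolume:
    """Zero the color channels outside a binary mask on the same grid."""
    mask = np.asarray(mask)
    if mask.shape != cv.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match color grid {cv.shape}; "
            "no implicit resampling"
        )
    data = cv.data * mask.astype(bool)[..., None]
    return ColorVolume(data, cv.affine, cv.space_tag)


def warp_colorvolume(cv_template: ColorVolume, warp: DeformationField) -> ColorVolume:
    """Pull a template-space color volume back onto the subject grid.

    For each subject voxel the template volume is sampled at the mapped
    template coordinate by trilinear interpolation; coordinates outside the
    template grid yield 0.
    """
    if warp is None:
        raise ValueError("deformation field is required; identity is never assumed")
    if cv_template.space_tag != "template":
        raise ValueError("input color volume must be in template space")
    pts = warp.mapping.reshape(-1, 3)
    data = sample_trilinear(cv_template.data, cv_template.affine, pts)
    data = data.reshape(warp.mapping.shape[:3] + (cv_template.n_channels,))
    return ColorVolume(data, warp.affine, space_tag="subject")
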