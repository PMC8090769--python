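"""Synthetic phantoms with known ground truth for every pipeline stage.

Tensor corridors (straight, curved, crossing) embedded in an isotropic
background play the role of white-matter pathways; ramp or end-cap color
fields stand in for the template gradient; controlled tensor perturbations
emulate a re-scan session.  Diffusivities are in mm^2/s with white-matter-like
defaults (axial 1.7e-3, radial 0.3e-3, i.e. corridor FA ~ 0.80, isotropic
background 0.7e-3); grids default to 2 mm voxels, matching a clinical
single-shell acquisition, with the finer 1.25 mm research-grade mode one
parameter away.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .colorfield import ColorVolume
from .grids import grid_world_coords
from .spectre import SpectreMap, TargetRegion, compute_spectre
from .tracking import Mask, TendModel, TensorField, TrackingParams
from .reproducibility import RescanSet

GEOMETRIES = ("straight", "curved", "crossing")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material parameters of a synthetic tensor phantom."""

    geometry: str = "straight"
    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_mm: float = 2.0
    corridor_halfwidth_mm: float = 5.0
    axial_diffusivity: float = 1.7e-3
    radial_diffusivity: float = 0.3e-3
    background_diffusivity: float = 0.7e-3
    tilt_deg: float = 0.0  # in-plane rotation of the corridor axis
    seed: int = 0
    rescan_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.axial_diffusivity <= self.radial_diffusivity:
            raise ValueError("corridor must be anisotropic (axial > radial)")
        if self.rescan_noise < 0:
            raise ValueError("rescan noise must be >= 0")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] *= self.voxel_mm
        return a

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.shape) * self.voxel_mm

    @property
    def center_mm(self) -> np.ndarray:
        return (np.array(self.shape) - 1) * self.voxel_mm / 2.0


def _prolate(direction: np.ndarray, axial: float, radial: float) -> np.ndarray:
    """Tensor with the given principal axis; works on (..., 3) directions."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    outer = d[..., :, None] * d[..., None, :]
    return radial * np.eye(3) + (axial - radial) * outer


def make_tensor_phantom(spec: PhantomSpec) -> TensorField:
    """Build the phantom tensor field; tracking mask covers the whole grid.

    straight: one corridor along the (tilted) y axis spanning the grid.
    curved: quarter-circle corridor in the x-y plane, tangent-aligned.
    crossing: straight corridors along x and y, tensors averaged where
    they overlap (oblate, degenerate leading eigenspace at the crossing).
    """
    coords = grid_world_coords(spec.shape, spec.affine)
    center = spec.center_mm
    rel = coords - center
    t = np.deg2rad(spec.tilt_deg)
    # corridor axis in the x-y plane, default +y
    axis = np.array([np.sin(t), np.cos(t), 0.0])
    perp = np.array([np.cos(t), -np.sin(t), 0.0])
    iso = spec.background_diffusivity * np.eye(3)
    tensors = np.broadcast_to(iso, spec.shape + (3, 3)).copy()
    hw = spec.corridor_halfwidth_mm

    def corridor_mask(direction_perp: np.ndarray) -> np.ndarray:
        lateral = np.abs(rel @ direction_perp)
        vertical = np.abs(rel[..., 2])
        return (lateral <= hw) & (vertical <= hw)

    if spec.geometry == "straight":
        m = corridor_mask(perp)
        if not m.any():
            raise ValueError("corridor lies outside the grid")
        tensors[m] = _prolate(axis, spec.axial_diffusivity, spec.radial_diffusivity)
    elif spec.geometry == "crossing":
        my = corridor_mask(np.array([1.0, 0.0, 0.0]))
        mx = corridor_mask(np.array([0.0, 1.0, 0.0]))
        ty = _prolate(np.array([0.0, 1.0, 0.0]), spec.axial_diffusivity, spec.radial_diffusivity)
        tx = _prolate(np.array([1.0, 0.0, 0.0]), spec.axial_diffusivity, spec.radial_diffusivity)
        tensors[my] = ty
        tensors[mx] = tx
        both = mx & my
        tensors[both] = 0.5 * (tx + ty)
        if not (mx.any() and my.any()):
            raise ValueError("corridor lies outside the grid")
    else:  # curved: quarter circle around the grid's lower corner
        radius = 0.45 * min(spec.extent_mm[0], spec.extent_mm[1])
        origin = np.array([0.0, 0.0, center[2]])
        d = coords - origin
        rho = np.hypot(d[..., 0], d[..., 1])
        m = (np.abs(rho - radius) <= hw) & (np.abs(d[..., 2]) <= hw)
        m &= (d[..., 0] >= 0) & (d[..., 1] >= 0)
        if not m.any():
            raise ValueError("corridor lies outside the grid")
        tang = np.stack(
            [-d[..., 1][m] / rho[m], d[..., 0][m] / rho[m], np.zeros(m.sum())], axis=-1
        )
        tensors[m] = _prolate(tang, spec.axial_diffusivity, spec.radial_diffusivity)
    return TensorField(tensors, spec.affine, np.ones(spec.shape, dtype=bool))


def analytic_tangent(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Ground-truth corridor direction at world points (curved geometry)."""
    if spec.geometry != "curved":
        raise ValueError("analytic tangent is defined for the curved geometry")
    d = np.atleast_2d(points) - np.array([0.0, 0.0, spec.center_mm[2]])
    rho = np.hypot(d[:, 0], d[:, 1])
    return np.stack([-d[:, 1] / rho, d[:, 0] / rho, np.zeros(len(d))], axis=-1)


def make_ramp_colorfield(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    axis: int = 1,
    gain: float = 0.01,
    offset: float = 0.0,
    space_tag: str = "subject",
) -> ColorVolume:
    """Three-channel field whose first channel ramps linearly along one axis.

    c1(r) = gain * r[axis] + offset (must stay >= 0 on the grid);
    channels 2 and 3 are zero.
    """
    if not np.isfinite(gain):
        raise ValueError("gain must be finite")
    coords = grid_world_coords(shape, affine)
    data = np.zeros(tuple(shape) + (3,))
    data[..., 0] = gain * coords[..., axis] + offset
    return ColorVolume(data, affine, space_tag)


def make_end_colorfield(
    spec: PhantomSpec, axis: int = 1, cap_mm: float = 6.0
) -> ColorVolume:
    """Green cap at the corridor's low end, blue cap at the high end.

    Emulates a cortical destination coloring: the contrast only exists at
    the two ends a streamline can reach, so mid-corridor seeds pick up a
    green/blue mixture whose balance reflects tracking symmetry.
    """
    coords = grid_world_coords(spec.shape, spec.affine)
    a = coords[..., axis]
    data = np.zeros(spec.shape + (3,))
    data[..., 1] = a <= a.min() + cap_mm
    data[..., 2] = a >= a.max() - cap_mm
    return ColorVolume(data, spec.affine, "subject")


def make_rescan_pair(
    tensors: TensorField, noise: float, rng: np.random.Generator
) -> tuple[TensorField, TensorField]:
    """Scan 1 is the input; scan 2 adds symmetric tensor perturbations.

    Perturbation scale is ``noise`` times the mean diffusivity of the
    field; the perturbed tensors are re-projected onto the PSD cone by
    clamping negative eigenvalues.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    scan1 = TensorField(tensors.tensors.copy(), tensors.affine, tensors.mask.copy())
    if noise == 0:
        scan2 = TensorField(tensors.tensors.copy(), tensors.affine, tensors.mask.copy())
        return scan1, scan2
    scale = noise * np.trace(tensors.tensors, axis1=3, axis2=4).mean() / 3.0
    eps = rng.standard_normal(tensors.tensors.shape)
    sym = 0.5 * (eps + np.swapaxes(eps, 3, 4))
    perturbed = tensors.tensors + scale * sym
    lam, vec = np.linalg.eigh(perturbed)
    lam = np.clip(lam, 0.0, None)
    perturbed = np.einsum("...ij,...j,...kj->...ik", vec, lam, vec)
    scan2 = TensorField(perturbed, tensors.affine, tensors.mask.copy())
    return scan1, scan2


def _mid_corridor_region(spec: PhantomSpec, half_extent_vox: int = 1) -> TargetRegion:
    mask = np.zeros(spec.shape, dtype=bool)
    c = np.array(spec.shape) // 2
    lo = c - half_extent_vox
    hi = c + half_extent_vox + 1
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return TargetRegion(mask, spec.affine)


def simulate_rescan_study(
    n_subjects: int = 8,
    tracking_noise: float = 0.05,
    rescan_noise: float = 0.05,
    n_seeds: int = 60,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    max_tilt_deg: float = 15.0,
) -> RescanSet:
    """Synthetic test-retest cohort on straight-corridor phantoms.

    Each subject gets an individual corridor tilt (its 'anatomy'); scan 2
    perturbs the subject's tensors at ``rescan_noise``.  Both scans are
    mapped with TEND at the given direction-noise factor ``tracking_noise``
    onto a mid-corridor target region shared by all subjects, so the maps
    live on a common grid and feed the icd index directly.
    """
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    tilts = rng.uniform(-max_tilt_deg, max_tilt_deg, size=n_subjects)
    region = _mid_corridor_region(base)
    color = make_end_colorfield(base)
    scan1_maps: list[SpectreMap] = []
    scan2_maps: list[SpectreMap] = []
    for n, tilt in enumerate(tilts):
        spec = replace(base, tilt_deg=float(tilt), seed=base.seed + n)
        field = make_tensor_phantom(spec)
        t1, t2 = make_rescan_pair(field, rescan_noise, np.random.default_rng(seed + 1000 + n))
        for k, tf in enumerate((t1, t2)):
            params = TrackingParams(
                step=1.0, noise=tracking_noise, max_steps=60,
                seed=int(seed + 17 * n + 7 * k),
            )
            smap = compute_spectre(
                region, TendModel(tf), color, params,
                n_seeds=n_seeds, tracking_mask=tf.tracking_mask(),
            )
            (scan1_maps if k == 0 else scan2_maps).append(smap)
    return RescanSet(scan1_maps, scan2_maps)
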