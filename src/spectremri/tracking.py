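"""Diffusion-tensor estimation and streamline propagation.

Two direction models are provided: the principal tensor direction (DTI) and
tensor deflection (TEND), in which the incoming direction v is deflected by
the local tensor, ``v_out = normalize(D v)``.  Both consume a trilinearly
interpolated tensor field, optionally perturb each proposed direction with
isotropic Gaussian noise of magnitude ``s`` (the noise factor), and march
bidirectionally from the seed with a fixed step of ``alpha`` millimetres.
Externally estimated peak fields plug in through the same DirectionModel
contract, so FOD-based trackers can drive the pipeline without being
implemented here.

Propagation is vectorized across the streamlines of a bundle; per-streamline
random substreams keep results bit-reproducible regardless of batching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .grids import check_affine, sample_nearest_inside, world_to_voxel

TERMINATION_REASONS = (
    "mask_exit",
    "max_steps",
    "angle",
    "low_fa",
    "undefined",
    "seed_outside",
)

#: Relative eigenvalue gap below which the leading eigenspace counts as tied.
DEGENERACY_TOL = 1e-9


class DegenerateTensorError(ValueError):
    """Leading eigenspace of the tensor is (numerically) degenerate."""


@dataclass
class Mask:
    """Binary mask on a regular grid (nearest-voxel membership)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3D grid")
        self.affine = check_affine(self.affine)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return sample_nearest_inside(self.data, self.affine, points)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors with a validity mask.

    ``tensors`` has shape (nx, ny, nz, 3, 3); absolute scale is irrelevant
    to tracking. Eigenvalues are expected >= 0 (fitting clamps them).
    """

    tensors: np.ndarray
    affine: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must be (nx, ny, nz, 3, 3)")
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, 3, 4), atol=1e-8):
            raise ValueError("tensors must be symmetric")
        self.affine = check_affine(self.affine)
        if self.mask is None:
            self.mask = np.ones(self.tensors.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.tensors.shape[:3]:
                raise ValueError("mask shape must match tensor grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Component-wise trilinear interpolation of the tensor at world points."""
        points = np.atleast_2d(points)
        vox = world_to_voxel(self.affine, points).T
        out = np.zeros((points.shape[0], 3, 3))
        for i, j in ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)):
            val = map_coordinates(
                self.tensors[..., i, j], vox, order=1, mode="grid-constant", cval=0.0
            )
            out[:, i, j] = val
            out[:, j, i] = val
        return out

    def fa_volume(self) -> np.ndarray:
        """Fractional anisotropy per voxel."""
        lam = np.linalg.eigvalsh(self.tensors)
        return fractional_anisotropy(lam)

    def tracking_mask(self) -> Mask:
        return Mask(self.mask, self.affine)


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from eigenvalue arrays of shape (..., 3)."""
    lam = np.asarray(eigenvalues, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam**2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters.

    step: step width alpha in mm. noise: unitless perturbation factor s.
    max_steps: cap per propagation half. angle_threshold: maximum turning
    angle between consecutive steps, degrees. anisotropy_floor: FA below
    which propagation stops. seed: root RNG seed.
    """

    step: float = 1.0
    noise: float = 0.05
    max_steps: int = 250
    angle_threshold: float = 60.0
    anisotropy_floor: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError("step must be > 0")
        if self.noise < 0:
            raise ValueError("noise factor must be >= 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not 0 < self.angle_threshold <= 180:
            raise ValueError("angle_threshold must be in (0, 180] degrees")


@dataclass
class Streamline:
    """Ordered world-space points of one trace, with the seed interior.

    Consecutive points are exactly one step apart. ``reasons`` records why
    each end (backward, forward) terminated.
    """

    points: np.ndarray
    seed: np.ndarray
    reasons: tuple[str, str] = ("max_steps", "max_steps")

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.seed = np.asarray(self.seed, dtype=float)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class StreamlineBundle:
    """All streamlines emitted from one seed voxel."""

    seed: np.ndarray
    streamlines: list[Streamline]
    params: TrackingParams

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def total_points(self) -> int:
        return sum(len(s) for s in self.streamlines)


# ---------------------------------------------------------------------------
# Elementary direction operations


def tend_step(v_in: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Deflect a unit direction by the tensor: normalize(D v), sign-aligned.

    Raises DegenerateTensorError when D v vanishes (undefined direction).
    """
    v_in = np.asarray(v_in, dtype=float)
    w = np.asarray(D, dtype=float) @ v_in
    n = np.linalg.norm(w)
    if n == 0:
        raise DegenerateTensorError("tensor annihilates the incoming direction")
    w = w / n
    if np.dot(w, v_in) < 0:
        w = -w
    return w


def principal_direction(D: np.ndarray, v_in: np.ndarray | None = None) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue, sign-aligned with v_in.

    A (near-)tied leading eigenspace is degenerate: with an incoming
    direction the incoming direction is kept (graceful tie-break), without
    one DegenerateTensorError is raised.
    """
    D = np.asarray(D, dtype=float)
    lam, vec = np.linalg.eigh(D)
    gap = lam[2] - lam[1]
    if gap < DEGENERACY_TOL * max(abs(np.trace(D)), 1e-300):
        if v_in is not None:
            return np.asarray(v_in, dtype=float)
        raise DegenerateTensorError("leading eigenspace is degenerate")
    e1 = vec[:, 2]
    if v_in is not None and np.dot(e1, v_in) < 0:
        e1 = -e1
    return e1


def perturb_direction(v: np.ndarray, s: float, rng: np.random.Generator) -> np.ndarray:
    """normalize(v + s * eps) with eps ~ N(0, I_3); s = 0 returns v."""
    v = np.asarray(v, dtype=float)
    if s < 0:
        raise ValueError("noise factor must be >= 0")
    if s == 0:
        return v
    while True:
        w = v + s * rng.standard_normal(3)
        n = np.linalg.norm(w)
        if n > 0:  # re-draw on the measure-zero cancellation event
            return w / n


def _perturb_batch(v: np.ndarray, s: float, eps: np.ndarray) -> np.ndarray:
    if s == 0:
        return v
    w = v + s * eps
    n = np.linalg.norm(w, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return w / n


# ---------------------------------------------------------------------------
# Direction models


class DirectionModel:
    """Contract: propose a unit propagation direction at world points.

    Implementations return, for a batch of points with incoming unit
    directions, the proposed (unperturbed) outgoing directions, a validity
    flag, and the local anisotropy used for termination.
    """

    def initial_directions(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(directions, valid) at seed points where no incoming direction exists."""
        raise NotImplementedError

    def propose(
        self, points: np.ndarray, v_in: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(directions, valid) given incoming unit directions."""
        raise NotImplementedError

    def anisotropy(self, points: np.ndarray) -> np.ndarray:
        """Scalar anisotropy (FA-like) at world points, for the floor test."""
        raise NotImplementedError


class _TensorModel(DirectionModel):
    def __init__(self, field: TensorField):
        self.field = field

    def _eig(self, points: np.ndarray):
        D = self.field.interpolate(points)
        lam, vec = np.linalg.eigh(D)
        return D, lam, vec

    def _degenerate(self, D: np.ndarray, lam: np.ndarray) -> np.ndarray:
        tr = np.abs(np.trace(D, axis1=1, axis2=2))
        return (lam[:, 2] - lam[:, 1]) < DEGENERACY_TOL * np.maximum(tr, 1e-300)

    def initial_directions(self, points: np.ndarray):
        D, lam, vec = self._eig(np.atleast_2d(points))
        valid = ~self._degenerate(D, lam) & (lam[:, 2] > 0)
        return vec[:, :, 2], valid

    def anisotropy(self, points: np.ndarray) -> np.ndarray:
        D = self.field.interpolate(points)
        return fractional_anisotropy(np.linalg.eigvalsh(D))


class DtiModel(_TensorModel):
    """Principal-tensor-direction propagation."""

    def propose(self, points: np.ndarray, v_in: np.ndarray):
        D, lam, vec = self._eig(points)
        e1 = vec[:, :, 2]
        flip = np.sum(e1 * v_in, axis=1) < 0
        e1[flip] = -e1[flip]
        degen = self._degenerate(D, lam)
        # graceful tie-break: keep the incoming direction
        e1[degen] = v_in[degen]
        valid = lam[:, 2] > 0
        return e1, valid


class TendModel(_TensorModel):
    """Tensor-deflection propagation: v_out = normalize(D v_in)."""

    def propose(self, points: np.ndarray, v_in: np.ndarray):
        D = self.field.interpolate(points)
        w = np.einsum("nij,nj->ni", D, v_in)
        n = np.linalg.norm(w, axis=1)
        valid = n > 0
        w[valid] /= n[valid, None]
        flip = np.sum(w * v_in, axis=1) < 0
        w[flip] = -w[flip]
        w[~valid] = v_in[~valid]
        return w, valid


class PeaksModel(DirectionModel):
    """Plug-in point for externally supplied peak / FOD-peak fields.

    ``peaks`` is an (nx, ny, nz, 3) vector volume; an optional scalar
    ``anisotropy`` volume feeds the termination floor (defaults to 1
    inside the non-zero peak support).
    """

    def __init__(self, peaks: np.ndarray, affine: np.ndarray, anisotropy: np.ndarray | None = None):
        self.peaks = np.asarray(peaks, dtype=float)
        if self.peaks.ndim != 4 or self.peaks.shape[3] != 3:
            raise ValueError("peaks must be (nx, ny, nz, 3)")
        self.affine = check_affine(affine)
        self._aniso = anisotropy

    def _sample(self, points: np.ndarray) -> np.ndarray:
        vox = world_to_voxel(self.affine, np.atleast_2d(points)).T
        out = np.stack(
            [
                map_coordinates(self.peaks[..., k], vox, order=1, mode="grid-constant", cval=0.0)
                for k in range(3)
            ],
            axis=1,
        )
        return out

    def initial_directions(self, points: np.ndarray):
        p = self._sample(points)
        n = np.linalg.norm(p, axis=1)
        valid = n > 0
        p[valid] /= n[valid, None]
        return p, valid

    def propose(self, points: np.ndarray, v_in: np.ndarray):
        p, valid = self.initial_directions(points)
        flip = np.sum(p * v_in, axis=1) < 0
        p[flip] = -p[flip]
        p[~valid] = v_in[~valid]
        return p, valid

    def anisotropy(self, points: np.ndarray) -> np.ndarray:
        if self._aniso is not None:
            vox = world_to_voxel(self.affine, np.atleast_2d(points)).T
            return map_coordinates(self._aniso, vox, order=1, mode="grid-constant", cval=0.0)
        return (np.linalg.norm(self._sample(points), axis=1) > 0).astype(float)


def make_direction_model(name: str, field: TensorField | None = None, **kw) -> DirectionModel:
    name = name.lower()
    if name == "dti":
        return DtiModel(field)
    if name == "tend":
        return TendModel(field)
    if name == "peaks":
        return PeaksModel(**kw)
    raise ValueError(f"unknown direction model '{name}'")


# ---------------------------------------------------------------------------
# Tensor fitting


def fit_tensors(
    dwi: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray, affine: np.ndarray
) -> TensorField:
    """Log-linear least-squares tensor fit per voxel.

    Requires at least six distinct non-zero-b directions and one b~0 volume.
    Negative eigenvalues are clamped to zero; the validity mask keeps voxels
    with positive b0 signal.
    """
    dwi = np.asarray(dwi, dtype=float)
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    if bvecs.shape == (3, len(bvals)):
        bvecs = bvecs.T
    if dwi.ndim != 4 or dwi.shape[3] != len(bvals) or bvecs.shape != (len(bvals), 3):
        raise ValueError("dwi, bvals and bvecs have inconsistent shapes")
    b0 = bvals < 50
    if b0.sum() < 1:
        raise ValueError("need at least one b~0 volume")
    g = bvecs[~b0]
    g = g / np.linalg.norm(g, axis=1, keepdims=True)
    if len(np.unique(np.round(np.abs(g), 6), axis=0)) < 6:
        raise ValueError("need at least six distinct non-zero-b directions")

    gn = np.zeros_like(bvecs)
    nz = ~b0
    gn[nz] = bvecs[nz] / np.linalg.norm(bvecs[nz], axis=1, keepdims=True)
    b = bvals
    # unknowns: [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * gn[:, 0] ** 2,
            -b * gn[:, 1] ** 2,
            -b * gn[:, 2] ** 2,
            -2 * b * gn[:, 0] * gn[:, 1],
            -2 * b * gn[:, 0] * gn[:, 2],
            -2 * b * gn[:, 1] * gn[:, 2],
        ]
    )
    shape = dwi.shape[:3]
    signal = dwi.reshape(-1, len(bvals))
    mask = signal[:, b0].mean(axis=1) > 0
    logs = np.log(np.clip(signal, 1e-12, None))
    coeffs = np.linalg.pinv(X) @ logs.T  # (7, nvox)
    d = coeffs[1:].T
    tensors = np.zeros((signal.shape[0], 3, 3))
    tensors[:, 0, 0] = d[:, 0]
    tensors[:, 1, 1] = d[:, 1]
    tensors[:, 2, 2] = d[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = d[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = d[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = d[:, 5]
    tensors[~mask] = 0.0
    lam, vec = np.linalg.eigh(tensors)
    lam = np.clip(lam, 0.0, None)
    tensors = np.einsum("nij,nj,nkj->nik", vec, lam, vec)
    return TensorField(
        tensors.reshape(shape + (3, 3)), affine, mask.reshape(shape)
    )


# ---------------------------------------------------------------------------
# Propagation


def _march_half(
    seeds: np.ndarray,
    dirs0: np.ndarray,
    alive0: np.ndarray,
    model: DirectionModel,
    params: TrackingParams,
    mask: Mask,
    noise: np.ndarray,
) -> tuple[list[list[np.ndarray]], np.ndarray]:
    """March one half for a batch of streamlines; returns per-streamline
    point lists (beyond the seed) and termination reasons."""
    m = seeds.shape[0]
    cos_thr = np.cos(np.deg2rad(params.angle_threshold))
    pts: list[list[np.ndarray]] = [[] for _ in range(m)]
    reasons = np.array(["max_steps"] * m, dtype=object)
    x = seeds.copy()
    d_prev = dirs0.copy()
    alive = alive0.copy()
    reasons[~alive0] = "undefined"
    for n in range(params.max_steps):
        if not np.any(alive):
            break
        idx = np.flatnonzero(alive)
        prop, valid = model.propose(x[idx], d_prev[idx])
        dead = idx[~valid]
        reasons[dead] = "undefined"
        alive[dead] = False
        keep = idx[valid]
        if keep.size == 0:
            continue
        d = _perturb_batch(prop[valid], params.noise, noise[keep, n])
        turn = np.sum(d * d_prev[keep], axis=1) < cos_thr
        reasons[keep[turn]] = "angle"
        alive[keep[turn]] = False
        keep = keep[~turn]
        d = d[~turn]
        if keep.size == 0:
            continue
        x_new = x[keep] + params.step * d
        inside = mask.contains(x_new)
        reasons[keep[~inside]] = "mask_exit"
        alive[keep[~inside]] = False
        keep = keep[inside]
        d = d[inside]
        x_new = x_new[inside]
        if keep.size == 0:
            continue
        fa = model.anisotropy(x_new)
        low = fa < params.anisotropy_floor
        reasons[keep[low]] = "low_fa"
        alive[keep[low]] = False
        keep = keep[~low]
        d = d[~low]
        x_new = x_new[~low]
        for i, k in enumerate(keep):
            pts[k].append(x_new[i])
        x[keep] = x_new
        d_prev[keep] = d
    return pts, reasons


def _propagate_batch(
    seeds: np.ndarray,
    model: DirectionModel,
    params: TrackingParams,
    mask: Mask,
    noise_fwd: np.ndarray,
    noise_bwd: np.ndarray,
) -> list[Streamline]:
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    inside = mask.contains(seeds)
    v0, valid0 = model.initial_directions(seeds)
    alive = inside & valid0
    fwd, reason_f = _march_half(seeds, v0, alive, model, params, mask, noise_fwd)
    bwd, reason_b = _march_half(seeds, -v0, alive, model, params, mask, noise_bwd)
    out = []
    for i in range(seeds.shape[0]):
        back = bwd[i][::-1]
        points = np.array(back + [seeds[i]] + fwd[i])
        rb, rf = reason_b[i], reason_f[i]
        if not inside[i]:
            rb = rf = "seed_outside"
        out.append(Streamline(points, seeds[i], (str(rb), str(rf))))
    return out


def propagate(
    seed: np.ndarray,
    model: DirectionModel,
    params: TrackingParams,
    mask: Mask,
    rng: np.random.Generator | None = None,
) -> Streamline:
    """Bidirectional march from a single seed point.

    From the model's direction v0 at the seed, one half tracks along +v0 and
    the other along -v0; the halves are concatenated with the seed interior.
    Each half stops on mask exit, step cap, turning angle above threshold,
    anisotropy below the floor, or an undefined direction.
    """
    seed = np.asarray(seed, dtype=float)
    if not mask.contains(seed[None])[0]:
        raise ValueError("seed lies outside the tracking mask")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal((2, params.max_steps, 3))
    return _propagate_batch(seed[None], model, params, mask, noise[0][None], noise[1][None])[0]


def seed_bundle(
    seed: np.ndarray,
    n_streamlines: int,
    model: DirectionModel,
    params: TrackingParams,
    mask: Mask,
    seed_sequence: np.random.SeedSequence | None = None,
    jitter_linear: np.ndarray | None = None,
) -> StreamlineBundle:
    """Emit N streamlines from one seed voxel.

    Each streamline gets its own random substream (spawned from
    ``seed_sequence``), used first for a uniform jitter of the start
    position inside the seed's output voxel (``jitter_linear`` maps the
    unit cube to world mm; None disables jitter) and then for the
    per-step direction perturbations, so bundles are bit-reproducible.
    """
    seed = np.asarray(seed, dtype=float)
    if not mask.contains(seed[None])[0]:
        raise ValueError("seed lies outside the tracking mask")
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(params.seed)
    gens = [np.random.default_rng(s) for s in seed_sequence.spawn(n_streamlines)]
    starts = np.empty((n_streamlines, 3))
    noise_fwd = np.empty((n_streamlines, params.max_steps, 3))
    noise_bwd = np.empty((n_streamlines, params.max_steps, 3))
    for i, g in enumerate(gens):
        if jitter_linear is not None:
            starts[i] = seed + np.asarray(jitter_linear) @ g.uniform(-0.5, 0.5, 3)
        else:
            starts[i] = seed
        block = g.standard_normal((2, params.max_steps, 3))
        noise_fwd[i] = block[0]
        noise_bwd[i] = block[1]
    streamlines = _propagate_batch(starts, model, params, mask, noise_fwd, noise_bwd)
    return StreamlineBundle(seed, streamlines, replace(params))
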