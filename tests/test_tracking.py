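"""Tensor fitting, direction rules and streamline propagation."""

import numpy as np
import pytest

from spectremri import (
    DtiModel,
    Mask,
    PeaksModel,
    PhantomSpec,
    TendModel,
    TensorField,
    TrackingParams,
    fit_tensors,
    make_tensor_phantom,
    perturb_direction,
    principal_direction,
    propagate,
    seed_bundle,
    tend_step,
)
from spectremri.tracking import DegenerateTensorError


def uniform_field(direction, shape=(12, 30, 12), voxel=1.0, axial=1.7e-3, radial=0.3e-3):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    D = radial * np.eye(3) + (axial - radial) * np.outer(d, d)
    tensors = np.broadcast_to(D, tuple(shape) + (3, 3)).copy()
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return TensorField(tensors, affine)


class TestFitTensors:
    def _scheme(self):
        rng = np.random.default_rng(4)
        g = rng.standard_normal((30, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        bvals = np.r_[0.0, np.full(30, 1000.0)]
        bvecs = np.vstack([[0, 0, 0], g])
        return bvals, bvecs

    def test_noiseless_refit_recovers_tensor(self):
        bvals, bvecs = self._scheme()
        rng = np.random.default_rng(11)
        a = rng.standard_normal((3, 3)) * 1e-3
        D = a @ a.T + 1e-4 * np.eye(3)  # random SPD tensor
        s0 = 800.0
        signal = s0 * np.exp(-bvals * np.einsum("ni,ij,nj->n", bvecs, D, bvecs))
        dwi = np.broadcast_to(signal, (3, 3, 3, len(bvals))).copy()
        field = fit_tensors(dwi, bvals, bvecs, np.eye(4))
        rel = np.abs(field.tensors[1, 1, 1] - D).max() / np.abs(D).max()
        assert rel <= 1e-6

    def test_isotropic_signal_gives_zero_fa(self):
        bvals, bvecs = self._scheme()
        signal = 500.0 * np.exp(-bvals * 1e-3)
        dwi = np.broadcast_to(signal, (2, 2, 2, len(bvals))).copy()
        field = fit_tensors(dwi, bvals, bvecs, np.eye(4))
        assert np.allclose(field.fa_volume(), 0.0, atol=1e-9)

    def test_zero_signal_voxel_excluded_from_mask(self):
        bvals, bvecs = self._scheme()
        signal = 500.0 * np.exp(-bvals * 1e-3)
        dwi = np.broadcast_to(signal, (2, 2, 2, len(bvals))).copy()
        dwi[0, 0, 0] = 0.0
        field = fit_tensors(dwi, bvals, bvecs, np.eye(4))
        assert not field.mask[0, 0, 0]
        assert field.mask[1, 1, 1]

    def test_insufficient_directions_rejected(self):
        bvals = np.array([0.0, 1000.0, 1000.0, 1000.0])
        bvecs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        with pytest.raises(ValueError, match="six"):
            fit_tensors(np.ones((2, 2, 2, 4)), bvals, bvecs, np.eye(4))


class TestDirectionOps:
    def test_tend_identity_tensor_keeps_direction(self, rng):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        assert np.allclose(tend_step(v, np.eye(3)), v, atol=1e-12)

    def test_tend_deflects_toward_principal_axis(self):
        v = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        out = tend_step(v, np.diag([4.0, 1.0, 1.0]))
        assert np.allclose(out, np.array([4.0, 1.0, 0.0]) / np.sqrt(17), atol=1e-12)

    def test_tend_sign_alignment(self):
        out = tend_step(np.array([-1.0, 0, 0]), np.diag([1.0, 0.1, 0.1]))
        assert np.allclose(out, [-1.0, 0, 0])

    def test_tend_annihilated_direction_flagged(self):
        with pytest.raises(DegenerateTensorError):
            tend_step(np.array([0.0, 0, 1.0]), np.diag([1.0, 1.0, 0.0]))

    def test_principal_direction_and_sign(self):
        e = principal_direction(np.diag([3.0, 2.0, 1.0]), v_in=np.array([1.0, 0, 0]))
        assert np.allclose(e, [1.0, 0, 0])
        assert abs(principal_direction(np.diag([3.0, 2.0, 1.0]))[0]) == pytest.approx(1.0)

    def test_principal_direction_rotated_matches_eigh_oracle(self, rng):
        for _ in range(20):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            D = q @ np.diag([3.0, 2.0, 1.0]) @ q.T
            e = principal_direction(D)
            lam, vec = np.linalg.eigh(D)
            oracle = vec[:, np.argmax(lam)]
            assert min(np.linalg.norm(e - oracle), np.linalg.norm(e + oracle)) < 1e-9

    def test_isotropic_tensor_is_degenerate(self):
        with pytest.raises(DegenerateTensorError):
            principal_direction(np.eye(3))
        # graceful with an incoming direction
        v = np.array([0.0, 1.0, 0.0])
        assert np.array_equal(principal_direction(np.eye(3), v_in=v), v)

    def test_perturb_zero_noise_is_identity(self, rng):
        v = np.array([0.0, 0.0, 1.0])
        assert np.array_equal(perturb_direction(v, 0.0, rng), v)

    def test_perturb_output_is_unit(self, rng):
        v = np.array([1.0, 0.0, 0.0])
        for s in (0.05, 0.2, 2.0):
            assert np.linalg.norm(perturb_direction(v, s, rng)) == pytest.approx(1.0)

    def test_perturb_mean_direction_preserved(self):
        rng = np.random.default_rng(99)
        v = np.array([0.0, 1.0, 0.0])
        draws = np.array([perturb_direction(v, 0.1, rng) for _ in range(10_000)])
        mean = draws.mean(axis=0)
        mean /= np.linalg.norm(mean)
        angle = np.degrees(np.arccos(np.clip(np.dot(mean, v), -1, 1)))
        assert angle < 1.0


class TestPropagate:
    def test_straight_corridor_exact_steps(self):
        field = uniform_field([0, 1, 0])
        params = TrackingParams(step=1.0, noise=0.0, max_steps=5)
        seed = np.array([5.0, 15.0, 5.0])
        s = propagate(seed, TendModel(field), params, field.tracking_mask())
        assert len(s) == 11  # 5 per half plus the interior seed
        steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        assert np.allclose(steps, 1.0, atol=1e-9)
        # collinearity: no spread off the corridor axis
        assert np.ptp(s.points[:, 0]) < 1e-6 and np.ptp(s.points[:, 2]) < 1e-6
        assert s.points[0, 1] == pytest.approx(10.0) and s.points[-1, 1] == pytest.approx(20.0)

    def test_abrupt_turn_terminates_on_angle(self):
        # +y corridor that switches to +x beyond y=20
        field = uniform_field([0, 1, 0], shape=(40, 40, 8))
        other = np.array([1.0, 0, 0])
        D = 0.3e-3 * np.eye(3) + 1.4e-3 * np.outer(other, other)
        field.tensors[:, 22:, :] = D
        params = TrackingParams(step=1.0, noise=0.0, max_steps=100, angle_threshold=60.0)
        s = propagate(np.array([20.0, 10.0, 4.0]), DtiModel(field), params, field.tracking_mask())
        assert "angle" in s.reasons
        assert s.points[:, 1].max() < 25.0  # stopped at the interface

    def test_tend_crosses_orthogonal_crossing(self):
        spec = PhantomSpec(geometry="crossing", shape=(24, 24, 8), voxel_mm=2.0)
        field = make_tensor_phantom(spec)
        params = TrackingParams(step=1.0, noise=0.0, max_steps=200, anisotropy_floor=0.05)
        seed = spec.center_mm - np.array([0.0, 12.0, 0.0])
        s = propagate(seed, TendModel(field), params, field.tracking_mask())
        # direction on the far side of the crossing within 5 degrees of +-y
        v = s.points[-1] - s.points[-2]
        v /= np.linalg.norm(v)
        angle = np.degrees(np.arccos(min(abs(v[1]), 1.0)))
        assert angle < 5.0
        assert s.points[:, 1].max() > spec.center_mm[1] + 8  # actually crossed

    def test_seed_outside_mask_rejected(self):
        field = uniform_field([0, 1, 0])
        with pytest.raises(ValueError, match="outside"):
            propagate(np.array([-50.0, 0, 0]), TendModel(field),
                      TrackingParams(), field.tracking_mask())

    def test_rotation_invariance(self):
        angle = np.deg2rad(33.0)
        c, s_ = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s_, 0], [s_, c, 0], [0, 0, 1.0]])
        field = uniform_field([0, 1, 0], shape=(16, 16, 16))
        rot_aff = np.eye(4)
        rot_aff[:3, :3] = R @ field.affine[:3, :3]
        rot = TensorField(
            np.einsum("ij,...jk,lk->...il", R, field.tensors, R), rot_aff
        )
        params = TrackingParams(step=1.0, noise=0.0, max_steps=4)
        seed = np.array([7.0, 7.0, 7.0])
        base = propagate(seed, TendModel(field), params, field.tracking_mask())
        rotated = propagate(R @ seed, TendModel(rot), params, rot.tracking_mask())
        assert np.allclose(rotated.points, base.points @ R.T, atol=1e-9)


class TestSeedBundle:
    def test_bundle_is_deterministic(self):
        field = uniform_field([0, 1, 0])
        params = TrackingParams(noise=0.1, max_steps=10, seed=42)
        mask = field.tracking_mask()
        seed = np.array([5.0, 15.0, 5.0])
        b1 = seed_bundle(seed, 8, TendModel(field), params, mask,
                         jitter_linear=field.affine[:3, :3])
        b2 = seed_bundle(seed, 8, TendModel(field), params, mask,
                         jitter_linear=field.affine[:3, :3])
        assert len(b1) == 8
        for s1, s2 in zip(b1.streamlines, b2.streamlines):
            assert np.array_equal(s1.points, s2.points)

    def test_single_streamline_matches_propagate(self):
        field = uniform_field([0, 1, 0])
        params = TrackingParams(noise=0.1, max_steps=10, seed=7)
        mask = field.tracking_mask()
        seed = np.array([5.0, 15.0, 5.0])
        ss = np.random.SeedSequence(123)
        bundle = seed_bundle(seed, 1, TendModel(field), params, mask, seed_sequence=ss)
        direct = propagate(seed, TendModel(field), params, mask,
                           rng=np.random.default_rng(np.random.SeedSequence(123).spawn(1)[0]))
        assert np.array_equal(bundle.streamlines[0].points, direct.points)

    def test_straight_phantom_streamlines_exit_through_ends(self, straight_phantom):
        spec, field = straight_phantom
        params = TrackingParams(noise=0.05, max_steps=60, seed=5)
        bundle = seed_bundle(spec.center_mm, 100, TendModel(field), params,
                             field.tracking_mask(), jitter_linear=spec.affine[:3, :3])
        ylo, yhi = 0.0, spec.extent_mm[1]
        for s in bundle.streamlines:
            assert s.points[0, 1] < ylo + 4.0
            assert s.points[-1, 1] > yhi - 4.0

    def test_step_length_invariant_with_noise(self, straight_phantom):
        spec, field = straight_phantom
        params = TrackingParams(step=1.0, noise=0.2, max_steps=40, seed=3)
        bundle = seed_bundle(spec.center_mm, 20, TendModel(field), params,
                             field.tracking_mask())
        for s in bundle.streamlines:
            steps = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
            assert np.allclose(steps, 1.0, atol=1e-6)


class TestPeaksModel:
    def test_peaks_track_like_uniform_field(self):
        peaks = np.zeros((10, 20, 10, 3))
        peaks[..., 1] = 1.0
        model = PeaksModel(peaks, np.eye(4))
        mask = Mask(np.ones((10, 20, 10)), np.eye(4))
        params = TrackingParams(step=1.0, noise=0.0, max_steps=5, anisotropy_floor=0.5)
        s = propagate(np.array([5.0, 10.0, 5.0]), model, params, mask)
        assert len(s) == 11
        assert np.ptp(s.points[:, 0]) < 1e-9
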