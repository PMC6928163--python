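"""Kabsch superposition, trajectory alignment, average structures, and the
per-residue displacement statistic."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinfield import (
    Selection,
    align_trajectory,
    average_structure,
    displacement_profile,
    kabsch_fit,
    rmsf,
)
from kinfield.alignment import DegenerateGeometryError
from conftest import random_rotation_matrices, toy_structure, trajectory_from_frames

REF4 = np.array(
    [[0.0, 0, 0], [3.0, 0, 0], [0, 2.0, 0], [0.5, 0.5, 4.0]]
)  # non-coplanar


def _rmsd(a, b):
    return np.sqrt(((a - b) ** 2).sum() / len(a))


class TestKabschFit:
    def test_exact_recovery_of_planted_transform(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([5.0, -2.0, 1.0])
        mobile = REF4 @ R.T + t
        tf = kabsch_fit(mobile, REF4)
        assert tf.rmsd_fit <= 1e-9
        np.testing.assert_allclose(tf.apply(mobile), REF4, atol=1e-9)
        # recovered transform inverts the planted one
        np.testing.assert_allclose(tf.rotation, R.T, atol=1e-9)

    def test_identity_on_equal_inputs(self):
        tf = kabsch_fit(REF4, REF4)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)
        assert tf.rmsd_fit == pytest.approx(0.0, abs=1e-12)

    def test_mirror_image_grid_search_oracle(self):
        """A chiral set and its mirror cannot be superimposed by a proper
        rotation; the Kabsch residual must match a brute-force minimum
        over a coarse Euler-angle grid (the RMSD landscape is quadratic
        near its optimum, so a 10-degree grid sits within 2%)."""
        mirror = REF4 * np.array([1.0, 1.0, -1.0])
        tf = kabsch_fit(mirror, REF4)
        assert tf.rmsd_fit > 0.1
        assert abs(np.linalg.det(tf.rotation) - 1.0) < 1e-9

        angles = np.arange(0, 360, 10.0)
        beta = np.arange(0, 181, 10.0)
        grid = np.stack(
            np.meshgrid(angles, beta, angles, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        Rs = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
        mob_c = mirror - mirror.mean(axis=0)
        ref_c = REF4 - REF4.mean(axis=0)
        rot = np.einsum("rij,kj->rki", Rs, mob_c)
        rmsds = np.sqrt(((rot - ref_c) ** 2).sum(axis=(1, 2)) / len(REF4))
        assert tf.rmsd_fit <= rmsds.min() + 1e-12
        assert tf.rmsd_fit == pytest.approx(rmsds.min(), rel=0.02)

    def test_matches_scipy_align_vectors(self, rng):
        """Independent oracle: scipy's Wahba solver reaches the same
        residual on noisy instances."""
        for _ in range(5):
            ref = rng.normal(size=(6, 3))
            R = Rotation.random(rng=np.random.default_rng(1)).as_matrix()
            mobile = (ref + rng.normal(scale=0.3, size=ref.shape)) @ R.T + rng.normal(size=3)
            tf = kabsch_fit(mobile, ref)
            rot, _ = Rotation.align_vectors(
                ref - ref.mean(axis=0), mobile - mobile.mean(axis=0)
            )
            assert tf.rmsd_fit == pytest.approx(
                _rmsd(rot.apply(mobile - mobile.mean(axis=0)), ref - ref.mean(axis=0)),
                rel=1e-6,
            )

    def test_optimality_against_random_rotations(self, rng):
        """Property: the fitted RMSD never exceeds the raw RMSD nor the
        RMSD under any of 1,000 random proper rotations."""
        ref = rng.normal(size=(8, 3))
        mobile = ref + rng.normal(scale=0.5, size=ref.shape)
        tf = kabsch_fit(mobile, ref)
        assert tf.rmsd_fit <= _rmsd(mobile, ref) + 1e-12
        mob_c = mobile - mobile.mean(axis=0)
        ref_c = ref - ref.mean(axis=0)
        Rs = random_rotation_matrices(1000, rng)
        rmsds = np.sqrt(
            ((np.einsum("rij,kj->rki", Rs, mob_c) - ref_c) ** 2).sum(axis=(1, 2))
            / len(ref)
        )
        assert tf.rmsd_fit <= rmsds.min() + 1e-12

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(REF4[:2], REF4[:2])

    def test_collinear_points(self):
        line = np.outer(np.arange(4.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(line, line)


class TestAlignTrajectory:
    def _rigid_traj(self, rng, base, n=8):
        Rs = random_rotation_matrices(n, rng)
        shifts = rng.normal(scale=10, size=(n, 3))
        frames = np.einsum("fij,kj->fki", Rs, base) + shifts[:, None, :]
        s = toy_structure(len(base)).with_coordinates(base)
        return s, trajectory_from_frames(s, frames)

    def test_rigid_motions_collapse_to_reference(self, rng):
        base = rng.normal(scale=3, size=(6, 3))
        s, traj = self._rigid_traj(rng, base)
        aligned = align_trajectory(traj, s, Selection.all(s))
        assert np.abs(aligned.frames - base).max() < 1e-6

    def test_idempotence(self, rng):
        base = rng.normal(scale=3, size=(6, 3))
        s, traj = self._rigid_traj(rng, base)
        once = align_trajectory(traj, s, Selection.all(s))
        twice = align_trajectory(once, s, Selection.all(s))
        assert np.abs(twice.frames - once.frames).max() < 1e-9

    def test_rmsf_equals_internal_motion_only(self, rng):
        """Internal displacements plus random rigid motions must give the
        same RMSF, after alignment, as the internal stream alone."""
        base = rng.normal(scale=4, size=(7, 3))
        internal = rng.normal(scale=0.3, size=(40, 7, 3))
        internal -= internal.mean(axis=0)
        s = toy_structure(7).with_coordinates(base)
        pure = trajectory_from_frames(s, base + internal)
        Rs = random_rotation_matrices(40, rng)
        shifts = rng.normal(scale=8, size=(40, 3))
        moved = np.einsum("fij,fkj->fki", Rs, base + internal) + shifts[:, None, :]
        contaminated = trajectory_from_frames(s, moved)
        sel = Selection.all(s)
        r_pure = rmsf(align_trajectory(pure, s, sel), sel, window=None)
        r_cont = rmsf(align_trajectory(contaminated, s, sel), sel, window=None)
        np.testing.assert_allclose(r_cont.rmsf, r_pure.rmsf, atol=1e-6)

    def test_invariance_to_global_rigid_transform(self, rng):
        base = rng.normal(scale=4, size=(6, 3))
        frames = base + rng.normal(scale=0.5, size=(10, 6, 3))
        s = toy_structure(6).with_coordinates(base)
        sel = Selection.all(s)
        a1 = align_trajectory(trajectory_from_frames(s, frames), s, sel)
        R = random_rotation_matrices(1, rng)[0]
        moved = frames @ R.T + np.array([3.0, -7.0, 2.0])
        a2 = align_trajectory(trajectory_from_frames(s, moved), s, sel)
        assert np.abs(a1.frames - a2.frames).max() < 1e-6


class TestAverageStructure:
    def test_two_frames(self):
        s = toy_structure(1)
        frames = np.array([[[0.0, 0, 0]], [[2.0, 0, 0]]])
        avg = average_structure([trajectory_from_frames(s, frames)])
        np.testing.assert_allclose(avg.coordinates, [[1.0, 0, 0]])

    def test_identical_frames(self, rng):
        s = toy_structure(4)
        frame = rng.normal(size=(4, 3))
        avg = average_structure(
            [trajectory_from_frames(s, np.repeat(frame[None], 5, axis=0))]
        )
        np.testing.assert_allclose(avg.coordinates, frame)

    def test_recovers_planted_mean_clt_bound(self):
        """4,500 pooled frames of unit Gaussian scatter recover the planted
        mean within 5·sigma/sqrt(n) per coordinate."""
        g = np.random.default_rng(99)
        s = toy_structure(5)
        mean = g.normal(scale=6, size=(5, 3))
        trajs = [
            trajectory_from_frames(s, mean + g.normal(size=(1500, 5, 3)), rep=r)
            for r in (1, 2, 3)
        ]
        avg = average_structure(trajs)
        assert np.abs(avg.coordinates - mean).max() < 5.0 / np.sqrt(4500)

    def test_empty_pool_error(self):
        with pytest.raises(ValueError):
            average_structure([])


class TestDisplacementProfile:
    def _setup(self, rng, n=6):
        s = toy_structure(n)
        ref = s
        return s, ref

    def test_zero_when_frames_equal_reference(self, rng):
        s, ref = self._setup(rng)
        frames = np.repeat(ref.coordinates[None], 8, axis=0)
        prof = displacement_profile(
            [trajectory_from_frames(s, frames)], ref, Selection.all(s), "x"
        )
        np.testing.assert_allclose(prof.mean, 0.0, atol=1e-12)
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-12)

    def test_uniform_shift_along_x(self, rng):
        s, ref = self._setup(rng)
        frames = np.repeat(ref.coordinates[None], 8, axis=0)
        frames[:, :, 0] += 1.0
        prof = displacement_profile(
            [trajectory_from_frames(s, frames)], ref, Selection.all(s), "x"
        )
        np.testing.assert_allclose(prof.mean, 1.0, atol=1e-12)
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-12)
        assert prof.n_frames == 8

    def test_recovers_planted_drift(self):
        """750 pooled frames with per-residue drift + 0.5 Å noise recover
        the drift within 4·sigma/sqrt(750)."""
        g = np.random.default_rng(7)
        s = toy_structure(6)
        drift = g.normal(scale=0.8, size=6)
        trajs = []
        for rep in range(3):
            frames = np.repeat(s.coordinates[None], 250, axis=0)
            frames[:, :, 1] += drift[None, :] + g.normal(
                scale=0.5, size=(250, 6)
            )
            trajs.append(trajectory_from_frames(s, frames, rep=rep))
        prof = displacement_profile(trajs, s, Selection.all(s), "y")
        assert prof.n_frames == 750
        assert np.abs(prof.mean - drift).max() < 4 * 0.5 / np.sqrt(750)

    def test_antisymmetry_under_negated_shift(self, rng):
        s, ref = self._setup(rng)
        shift = rng.normal(size=6)
        plus = np.repeat(ref.coordinates[None], 5, axis=0)
        plus[:, :, 2] += shift
        minus = np.repeat(ref.coordinates[None], 5, axis=0)
        minus[:, :, 2] -= shift
        sel = Selection.all(s)
        p = displacement_profile([trajectory_from_frames(s, plus)], ref, sel, "z")
        m = displacement_profile([trajectory_from_frames(s, minus)], ref, sel, "z")
        np.testing.assert_allclose(p.mean, -m.mean, atol=1e-12)

    def test_empty_window_error(self, rng):
        s, ref = self._setup(rng)
        frames = np.repeat(ref.coordinates[None], 4, axis=0)
        with pytest.raises(ValueError):
            displacement_profile(
                [trajectory_from_frames(s, frames)],
                ref,
                Selection.all(s),
                "x",
                window=(1e6, 2e6),
            )
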