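"""SASA sphere-point sampling and contact surface area: closed forms,
convergence, invariances, and an independent Shrake–Rupley oracle."""

import numpy as np
import pytest

from kinfield import Selection, Trajectory, contact_surface_area, csa_series, sasa
from kinfield.surface import _neighbor_lists, golden_spiral_points
from conftest import toy_structure, trajectory_from_frames

PROBE = 1.4


def two_sphere_cap_area(r, d, probe):
    """Closed form: two equal spheres of expanded radius R = r + probe at
    distance d bury a cap of height h = R − d/2 on each; accessible area
    per sphere is 4πR² − 2πRh."""
    R = r + probe
    h = R - d / 2.0
    return 2 * (4 * np.pi * R**2 - 2 * np.pi * R * h)


class TestSASA:
    def test_single_sphere_closed_form(self):
        res = sasa(np.zeros((1, 3)), np.array([1.4]), PROBE, 960)
        assert res.per_atom[0] == pytest.approx(4 * np.pi * 2.8**2, rel=0.005)
        assert res.total == pytest.approx(res.per_atom[0] / 100.0)

    def test_buried_atom_zero(self):
        coords = np.zeros((2, 3))
        radii = np.array([0.5, 5.0])
        res = sasa(coords, radii, PROBE, 480)
        assert res.per_atom[0] == 0.0

    def test_two_equal_spheres_cap_formula_and_convergence(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        radii = np.array([2.0, 2.0])
        total_960 = sasa(coords, radii, PROBE, 960).per_atom.sum()
        total_10k = sasa(coords, radii, PROBE, 10_000).per_atom.sum()
        analytic = two_sphere_cap_area(2.0, 3.0, PROBE)
        assert total_960 == pytest.approx(total_10k, rel=0.01)
        assert total_960 == pytest.approx(analytic, rel=0.01)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(scale=4, size=(20, 3))
        radii = rng.uniform(1.2, 2.2, size=20)
        base = sasa(coords, radii, PROBE, 960).per_atom.sum()
        R = Rotation.random(rng=np.random.default_rng(0)).as_matrix()
        moved = sasa(coords @ R.T + np.array([10.0, -3, 2]), radii, PROBE, 960)
        assert moved.per_atom.sum() == pytest.approx(base, rel=0.005)

    def test_adding_atoms_never_increases_existing_area(self, rng):
        coords = rng.normal(scale=3, size=(12, 3))
        radii = np.full(12, 1.8)
        before = sasa(coords, radii, PROBE, 480).per_atom
        for _ in range(5):
            extra = rng.normal(scale=3, size=(1, 3))
            after = sasa(
                np.vstack([coords, extra]), np.append(radii, 1.8), PROBE, 480
            ).per_atom[:12]
            assert np.all(after <= before + 1e-9)

    def test_convergence_on_random_clusters(self, rng):
        """|SASA(960) − SASA(10,000)| / SASA(10,000) ≤ 1% on random
        50-atom clusters."""
        for _ in range(3):
            coords = rng.normal(scale=6, size=(50, 3))
            radii = rng.uniform(1.2, 2.4, size=50)
            s960 = sasa(coords, radii, PROBE, 960).per_atom.sum()
            s10k = sasa(coords, radii, PROBE, 10_000).per_atom.sum()
            assert abs(s960 - s10k) / s10k <= 0.01

    def test_kdtree_neighbors_match_all_pairs_exactly(self, rng):
        coords = rng.normal(scale=5, size=(40, 3))
        radii = rng.uniform(1.0, 2.5, size=40)
        fast = sasa(coords, radii, PROBE, 480, all_pairs=False).per_atom
        brute = sasa(coords, radii, PROBE, 480, all_pairs=True).per_atom
        np.testing.assert_array_equal(fast, brute)

    def test_matches_independent_shrake_rupley(self):
        """Cross-check against mdtraj's Shrake–Rupley on a carbon cluster,
        feeding mdtraj's own radius table into our implementation."""
        mdtraj = pytest.importorskip("mdtraj")
        from mdtraj.geometry.sasa import _ATOMIC_RADII

        g = np.random.default_rng(8)
        n = 15
        coords = g.normal(scale=4, size=(n, 3))
        r_c = _ATOMIC_RADII["C"] * 10.0  # nm → Å
        top = mdtraj.Topology()
        chain = top.add_chain()
        res = top.add_residue("LIG", chain)
        for i in range(n):
            top.add_atom(f"C{i}", mdtraj.element.carbon, res)
        t = mdtraj.Trajectory(coords[None] / 10.0, top)  # Å → nm
        ref = mdtraj.shrake_rupley(t, probe_radius=0.14, n_sphere_points=960)
        ours = sasa(coords, np.full(n, r_c), PROBE, 960)
        assert ours.per_atom.sum() / 100.0 == pytest.approx(
            float(ref.sum()), rel=0.02
        )

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="32"):
            sasa(np.zeros((1, 3)), np.array([1.0]), PROBE, 16)

    def test_zero_radius_atoms_excluded(self):
        res = sasa(np.zeros((2, 3)) + np.arange(2)[:, None], np.array([0.0, 1.0]), PROBE, 480)
        assert res.per_atom[0] == 0.0
        assert res.per_atom[1] > 0

    def test_golden_spiral_points_unit_norm(self):
        pts = golden_spiral_points(500)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        # roughly isotropic: centroid near origin
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01


class TestContactSurfaceArea:
    def _complex(self, separation):
        g = np.random.default_rng(12)
        a = g.normal(scale=2.5, size=(10, 3))
        b = g.normal(scale=2.5, size=(10, 3)) + np.array([separation, 0, 0])
        coords = np.vstack([a, b])
        radii = np.full(20, 1.8)
        return coords, radii, Selection(np.arange(10)), Selection(np.arange(10, 20))

    def test_distant_domains_zero(self):
        coords, radii, A, B = self._complex(200.0)
        assert contact_surface_area(coords, radii, A, B, PROBE, 480) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_coincident_copy_is_half_sasa(self):
        g = np.random.default_rng(3)
        a = g.normal(scale=2, size=(6, 3))
        coords = np.vstack([a, a])  # B atom-on-atom coincident with A
        radii = np.full(12, 1.5)
        A, B = Selection(np.arange(6)), Selection(np.arange(6, 12))
        csa = contact_surface_area(coords, radii, A, B, PROBE, 480)
        half = 0.5 * sasa(a, radii[:6], PROBE, 480).total
        assert csa == pytest.approx(half, rel=1e-9)

    def test_contact_exceeds_pulled_and_converges(self):
        c1, r1, A, B = self._complex(5.0)
        c2, _, _, _ = self._complex(10.0)
        csa_contact = contact_surface_area(c1, r1, A, B, PROBE, 960)
        csa_pulled = contact_surface_area(c2, r1, A, B, PROBE, 960)
        assert csa_contact > csa_pulled
        hi = contact_surface_area(c1, r1, A, B, PROBE, 10_000)
        assert csa_contact == pytest.approx(hi, rel=0.02)

    def test_symmetry_and_nonnegativity(self):
        coords, radii, A, B = self._complex(4.0)
        ab = contact_surface_area(coords, radii, A, B, PROBE, 480)
        ba = contact_surface_area(coords, radii, B, A, PROBE, 480)
        assert ab == pytest.approx(ba, abs=1e-12)
        assert ab >= -1e-6

    def test_overlapping_selections_rejected(self):
        coords, radii, A, _ = self._complex(4.0)
        with pytest.raises(ValueError, match="overlap"):
            contact_surface_area(coords, radii, A, Selection(np.arange(5, 15)), PROBE, 480)


class TestCSASeries:
    def _structure(self):
        g = np.random.default_rng(2)
        coords = np.vstack(
            [g.normal(scale=2, size=(6, 3)), g.normal(scale=2, size=(6, 3)) + [5, 0, 0]]
        )
        s = toy_structure(12, radii=np.full(12, 1.8))
        return s.with_coordinates(coords), Selection(np.arange(6)), Selection(np.arange(6, 12))

    def test_static_trajectory_constant_series(self):
        s, A, B = self._structure()
        frames = np.repeat(s.coordinates[None], 10, axis=0)
        cs = csa_series(trajectory_from_frames(s, frames, dt=10.0), A, B, n_points=240, block=50.0)
        assert np.ptp(cs.csa) == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(cs.block_sds, 0.0, atol=1e-12)
        assert cs.n_per_block.sum() == 10

    def test_alternating_frames_block_mean_is_midpoint(self):
        s, A, B = self._structure()
        far = s.coordinates.copy()
        far[6:, 0] += 50.0
        frames = np.stack([s.coordinates, far] * 4)
        cs = csa_series(trajectory_from_frames(s, frames, dt=10.0), A, B, n_points=240, block=80.0)
        vals = sorted(set(np.round(cs.csa, 12)))
        assert cs.block_means[0] == pytest.approx(np.mean(cs.csa[:8]))
        assert len(vals) == 2

    def test_planted_separation_monotone_blocks(self):
        """Gradually pulling the domains apart must give monotonically
        non-increasing block means (sign test on successive blocks)."""
        s, A, B = self._structure()
        n = 24
        frames = np.repeat(s.coordinates[None], n, axis=0)
        frames[:, 6:, 0] += np.linspace(0, 12, n)[:, None]
        cs = csa_series(trajectory_from_frames(s, frames, dt=10.0), A, B, n_points=480, block=60.0)
        diffs = np.diff(cs.block_means)
        assert np.all(diffs <= 1e-9)
        assert diffs.min() < 0

    def test_replicates_pooled_per_block(self):
        s, A, B = self._structure()
        frames = np.repeat(s.coordinates[None], 6, axis=0)
        trajs = [
            trajectory_from_frames(s, frames, dt=10.0, label="c", rep=r)
            for r in (1, 2, 3)
        ]
        cs = csa_series(trajs, A, B, n_points=240, block=30.0)
        assert np.all(cs.n_per_block == 9)  # 3 frames per block × 3 replicates
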