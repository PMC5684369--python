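"""Objective contracts: landscapes, conformations, distances, gradients."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from widedock import (DofLayout, InvalidArgumentError, SearchPoint,
                      apply_conformation, conformation_with_jacobian,
                      distance, make_gaussian_landscape,
                      make_toy_docking_objective, make_two_well_landscape,
                      normalize_angles, pair_potential)
from widedock.objectives import PAIR_R0, PAIR_R_CUT, distance_many

from conftest import make_chain_tree


def finite_difference_gradient(objective, coords, eps=1e-6):
    g = np.zeros_like(coords)
    for j in range(coords.size):
        hi, lo = coords.copy(), coords.copy()
        hi[j] += eps
        lo[j] -= eps
        g[j] = (objective.evaluate(hi)[0] - objective.evaluate(lo)[0]) / (2 * eps)
    return g


# ---------------------------------------------------------------------------
# Gaussian landscapes
# ---------------------------------------------------------------------------

class TestGaussianLandscape:
    def test_single_well_stationary_point(self):
        land = make_gaussian_landscape(dim=2, n_wells=1, seed=5)
        center, depth = land.deepest_well
        score, grad = land.evaluate(center)
        assert score == pytest.approx(-depth)
        assert np.allclose(grad, 0.0)

    def test_seeded_determinism(self):
        a = make_gaussian_landscape(dim=3, n_wells=5, seed=7)
        b = make_gaussian_landscape(dim=3, n_wells=5, seed=7)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.depths, b.depths)
        assert np.array_equal(a.widths, b.widths)

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            make_gaussian_landscape(dim=0, n_wells=1, seed=0)
        with pytest.raises(InvalidArgumentError):
            make_gaussian_landscape(dim=2, n_wells=0, seed=0)

    def test_gradient_matches_finite_differences(self, rng):
        land = make_gaussian_landscape(dim=2, n_wells=3, seed=1)
        for _ in range(100):
            x = rng.uniform(0, 30, size=2)
            _, grad = land.evaluate(x)
            fd = finite_difference_gradient(land, x)
            assert np.allclose(grad, fd, rtol=1e-5, atol=1e-9)

    def test_two_well_separation_and_depths(self):
        clean = make_two_well_landscape(seed=3, n_rough=0, texture_amp=0)
        assert np.linalg.norm(clean.centers[0] - clean.centers[1]) >= 30.0
        truth = clean.ground_truth_minimum()
        assert truth.score == pytest.approx(-10.0, abs=1e-3)

    def test_two_well_rugged_keeps_deep_well_global(self):
        land = make_two_well_landscape(seed=3)
        truth = land.ground_truth_minimum()
        # texture and decoys perturb but never displace the deep well
        assert -13.0 < truth.score <= -10.0
        assert np.linalg.norm(truth.coords - land.centers[0]) < 2.0
        # textured gradient still matches finite differences
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 75, size=3)
            _, grad = land.evaluate(x)
            fd = finite_difference_gradient(land, x)
            assert np.allclose(grad, fd, rtol=1e-4, atol=1e-7)


# ---------------------------------------------------------------------------
# Conformations
# ---------------------------------------------------------------------------

class TestApplyConformation:
    def test_zero_point_is_identity(self, chain_tree):
        out = apply_conformation(chain_tree, np.zeros(9))
        assert np.allclose(out, chain_tree.coords)

    def test_pure_translation_shifts_every_atom(self, chain_tree):
        pt = np.zeros(9)
        pt[0] = 3.25
        out = apply_conformation(chain_tree, pt)
        assert np.allclose(out - chain_tree.coords,
                           [[3.25, 0.0, 0.0]] * chain_tree.n_atoms)

    def test_dimension_mismatch_rejected(self, chain_tree):
        with pytest.raises(InvalidArgumentError):
            apply_conformation(chain_tree, np.zeros(5))

    def test_torsion_pi_flips_dihedral(self):
        # 4-atom chain, one rotatable bond moving the last atom
        from widedock import Branch, LigandAtom, TorsionTree
        coords = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0],
                           [1.5, 0.0, 0.0], [2.0, 1.2, 0.0]])
        atoms = [LigandAtom("C", c) for c in coords]
        tree = TorsionTree(atoms=atoms, root_atoms=[0, 1, 2],
                           branches=[Branch(parent=1, child=2, moved=[2, 3])])
        # this branch bond is atoms 1->2; atom 3 rotates about it
        pt = np.zeros(7)
        pt[6] = math.pi

        def dihedral(p):
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            m1 = np.cross(n1, b2 / np.linalg.norm(b2))
            return math.atan2(m1 @ n2, n1 @ n2)

        before = dihedral(coords)
        after = dihedral(apply_conformation(tree, pt))
        delta = (after - before + math.pi) % (2 * math.pi) - math.pi
        assert abs(abs(delta) - math.pi) < 1e-9

    def test_rigid_body_distances_preserved(self, chain_tree, rng):
        bodies = chain_tree.rigid_bodies()
        ref = chain_tree.coords
        for _ in range(25):
            pt = rng.normal(0, 1.0, 9)
            out = apply_conformation(chain_tree, pt)
            for body in bodies:
                for i in body:
                    for j in body:
                        d_ref = np.linalg.norm(ref[i] - ref[j])
                        d_out = np.linalg.norm(out[i] - out[j])
                        assert d_out == pytest.approx(d_ref, abs=1e-9)

    def test_jacobian_matches_finite_differences(self, chain_tree, rng):
        for _ in range(10):
            pt = rng.normal(0, 0.8, 9)
            _, jac = conformation_with_jacobian(chain_tree, pt)
            eps = 1e-6
            for j in range(9):
                hi, lo = pt.copy(), pt.copy()
                hi[j] += eps
                lo[j] -= eps
                fd = (apply_conformation(chain_tree, hi)
                      - apply_conformation(chain_tree, lo)) / (2 * eps)
                assert np.allclose(jac[:, :, j], fd, atol=1e-7)


# ---------------------------------------------------------------------------
# Toy docking objective
# ---------------------------------------------------------------------------

class TestToyDockingObjective:
    def _objective(self, rng, n_receptor=12):
        tree = make_chain_tree(6, 3)
        receptor = rng.uniform(-2.0, 9.0, size=(n_receptor, 3))
        return make_toy_docking_objective(receptor, tree,
                                          [-15.0, -15.0, -15.0],
                                          [20.0, 20.0, 20.0])

    def test_pair_potential_shape(self):
        u0, du0 = pair_potential(np.array([PAIR_R0]))
        assert u0[0] == pytest.approx(-1.0)
        assert du0[0] == pytest.approx(0.0, abs=1e-12)
        uc, duc = pair_potential(np.array([PAIR_R_CUT, PAIR_R_CUT + 1]))
        assert np.allclose(uc, 0.0) and np.allclose(duc, 0.0)
        uw, _ = pair_potential(np.array([2.0]))
        assert uw[0] > 50.0     # steep short-range repulsion

    def test_out_of_range_scores_zero(self, rng):
        obj = self._objective(rng)
        pt = np.zeros(obj.dim)
        pt[:3] = [300.0, 300.0, 300.0] - obj.tree.root_centroid
        score, grad = obj.evaluate(pt)
        assert score == 0.0
        assert np.allclose(grad[:3], 0.0)

    def test_single_pair_minimum_has_zero_translation_gradient(self):
        from widedock import LigandAtom, TorsionTree
        atom = LigandAtom("C", [0.0, 0.0, 0.0])
        tree = TorsionTree(atoms=[atom], root_atoms=[0])
        obj = make_toy_docking_objective(np.array([[PAIR_R0, 0.0, 0.0]]),
                                         tree, [-10] * 3, [10] * 3)
        score, grad = obj.evaluate(np.zeros(6))
        assert score == pytest.approx(-1.0)
        assert np.allclose(grad[:3], 0.0, atol=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        obj = self._objective(rng)
        checked = 0
        while checked < 100:
            pt = rng.normal(0.0, 1.0, obj.dim)
            score, grad = obj.evaluate(pt)
            fd = finite_difference_gradient(obj, pt)
            # FD floor: central differences carry ~|f| * eps_mach / h noise,
            # so components below ~1e-5 |f| are not resolvable at rtol 1e-4
            floor = max(1e-4, abs(score) * 1e-5)
            scale = np.maximum(np.abs(fd), floor)
            assert np.all(np.abs(grad - fd) / scale < 1e-4)
            checked += 1

    def test_empty_receptor_rejected(self, chain_tree):
        with pytest.raises(InvalidArgumentError):
            make_toy_docking_objective(np.empty((0, 3)), chain_tree,
                                       [0, 0, 0], [1, 1, 1])


# ---------------------------------------------------------------------------
# Normalization and distance
# ---------------------------------------------------------------------------

class TestNormalizeAngles:
    def test_already_normalized_untouched(self):
        layout = DofLayout.for_ligand(2)
        pt = np.zeros(8)
        assert np.array_equal(normalize_angles(pt, layout), pt)

    def test_torsion_periodicity(self):
        layout = DofLayout.for_ligand(1)
        pt = np.zeros(7)
        pt[6] = 3 * math.pi
        out = normalize_angles(pt, layout)
        assert out[6] == pytest.approx(-math.pi)

    def test_wide_mode_range(self, rng):
        layout = DofLayout.for_ligand(2)
        for _ in range(50):
            pt = rng.normal(0, 10.0, 8)
            out = normalize_angles(pt, layout, mode="wide")
            assert np.all(np.abs(out[6:]) < 2 * math.pi)

    def test_score_invariant_under_normalization(self):
        rng = np.random.default_rng(11)
        tree = make_chain_tree(6, 3)
        obj = make_toy_docking_objective(rng.uniform(-2, 9, (10, 3)), tree,
                                         [-15] * 3, [20] * 3)
        for _ in range(1000):
            pt = rng.normal(0.0, 6.0, obj.dim)
            before = obj.evaluate(pt)[0]
            after = obj.evaluate(normalize_angles(pt, obj.layout))[0]
            assert after == pytest.approx(before, abs=1e-9)

    def test_spatial_components_untouched(self, rng):
        layout = DofLayout.for_ligand(3)
        pt = rng.normal(0, 10, 9)
        out = normalize_angles(pt, layout)
        assert np.array_equal(out[:3], pt[:3])


class TestDistance:
    def test_identity(self, rng):
        layout = DofLayout.for_ligand(2)
        pt = rng.normal(0, 2, 8)
        assert distance(pt, pt, "all", layout) == 0.0

    def test_spatial_filter_ignores_torsions(self, rng):
        layout = DofLayout.for_ligand(4)
        a = np.zeros(10)
        b = np.zeros(10)
        b[:3] = [3.0, 4.0, 0.0]
        b[6:] = rng.uniform(-3, 3, 4)
        assert distance(a, b, "spatial") == pytest.approx(5.0)

    def test_full_distance_matches_bruteforce(self, rng):
        layout = DofLayout.for_ligand(3)
        for _ in range(50):
            a = rng.normal(0, 3, 9)
            b = rng.normal(0, 3, 9)
            expect = 0.0
            for k in range(9):
                d = a[k] - b[k]
                if 3 <= k:      # angular dims: minimal angular difference
                    d = (d + math.pi) % (2 * math.pi) - math.pi
                expect += d * d
            expect = math.sqrt(expect)
            assert distance(a, b, "all", layout) == pytest.approx(
                expect, abs=1e-12)
            got = distance_many(a, b[None, :], layout)
            assert got[0] == pytest.approx(expect, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            distance(np.zeros(3), np.zeros(4))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        layout = DofLayout.for_ligand(2)
        a, b, c = (rng.normal(0, 4, 8) for _ in range(3))
        dab = distance(a, b, "all", layout)
        dba = distance(b, a, "all", layout)
        dac = distance(a, c, "all", layout)
        dcb = distance(c, b, "all", layout)
        assert dab >= 0
        assert dab == pytest.approx(dba, abs=1e-12)
        assert dab <= dac + dcb + 1e-9
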