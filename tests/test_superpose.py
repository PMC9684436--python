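"""Kabsch superposition: exact cases, brute-force oracle, refinement."""

import numpy as np
import pytest

from qtyshift import (
    ProteinRecord,
    generate_helix_coords,
    kabsch,
    map_sequence_to_structure,
    model_from_arrays,
    perturb_structure,
    superpose_models,
)
from qtyshift.errors import RefinementCollapseError, UnderdeterminedError
from qtyshift.superpose import TrimPolicy, trim_outside_tm
from qtyshift.synthetic import random_rotation


def brute_force_min_rmsd(a, b, coarse_deg=8.0, fine_deg=0.25):
    """Oracle: minimum RMSD over a rotation grid (coarse scan + local refine).

    Independent of the SVD path: enumerates rotations from Euler angles,
    scoring centred coordinates (the optimal translation at fixed rotation
    matches centroids exactly).
    """
    from scipy.spatial.transform import Rotation

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def scan(alphas, betas, gammas):
        angles = np.stack(np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1)
        angles = angles.reshape(-1, 3)
        mats = Rotation.from_euler("zyz", angles).as_matrix()
        moved = np.einsum("rij,nj->rni", mats, b)
        rmsd = np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=2), axis=1))
        k = int(np.argmin(rmsd))
        return float(rmsd[k]), angles[k]

    step = np.radians(coarse_deg)
    best, ang = scan(
        np.arange(0, 2 * np.pi, step), np.arange(0, np.pi + step, step),
        np.arange(0, 2 * np.pi, step),
    )
    # refine around the coarse optimum
    w = np.radians(coarse_deg)
    fine = np.radians(fine_deg)
    best, ang = scan(
        np.arange(ang[0] - w, ang[0] + w, fine),
        np.arange(ang[1] - w, ang[1] + w, fine),
        np.arange(ang[2] - w, ang[2] + w, fine),
    )
    return best


class TestKabsch:
    def test_identical_sets_zero_rmsd_identity_rotation(self, rng):
        x = rng.normal(size=(20, 3))
        res = kabsch(x, x)
        assert res.rmsd_all < 1e-9
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9

    def test_exact_rigid_case_recovers_rotation(self, rng):
        x = rng.normal(size=(30, 3)) * 10
        for seed in range(20):
            r = np.random.default_rng(seed)
            rot = random_rotation(r)
            t = r.uniform(-50, 50, size=3)
            y = x @ rot.T + t
            res = kabsch(x, y)
            assert res.rmsd_all < 1e-9
            # fitted rotation must undo the applied one
            assert np.allclose(res.rotation, rot.T, atol=1e-9)

    def test_rotation_always_proper(self, rng):
        # near-planar sets tempt the unconstrained solution into a reflection
        x = rng.normal(size=(10, 3)) * [10, 10, 0.01]
        y = -x[:, [1, 0, 2]]
        res = kabsch(x, y)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_points", [4, 5, 8])
    def test_matches_brute_force_rotation_grid(self, n_points):
        rng = np.random.default_rng(n_points)
        a = rng.normal(size=(n_points, 3)) * 3
        b = rng.normal(size=(n_points, 3)) * 3
        res = kabsch(a, b)
        oracle = brute_force_min_rmsd(a, b)
        assert res.rmsd_all <= oracle + 1e-9  # SVD optimum can only be better
        assert res.rmsd_all == pytest.approx(oracle, abs=0.02)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UnderdeterminedError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_warns_but_returns(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.warns(UserWarning):
            res = kabsch(line, line)
        assert res.rmsd_all < 1e-9

    def test_rmsd_invariant_under_rigid_transforms(self, rng):
        a = rng.normal(size=(40, 3)) * 5
        b = a + rng.normal(scale=1.0, size=(40, 3))
        base = kabsch(a, b).rmsd_all
        for seed in range(100):
            r = np.random.default_rng(seed + 1000)
            rot = random_rotation(r)
            t = r.uniform(-30, 30, 3)
            assert kabsch(a @ rot.T + t, b).rmsd_all == pytest.approx(base, abs=1e-9)
            assert kabsch(a, b @ rot.T + t).rmsd_all == pytest.approx(base, abs=1e-9)

    def test_rmsd_symmetric(self, rng):
        a = rng.normal(size=(25, 3))
        b = rng.normal(size=(25, 3))
        assert kabsch(a, b).rmsd_all == pytest.approx(kabsch(b, a).rmsd_all, abs=1e-9)


class TestSuperposeModels:
    def test_rigid_decoy_zero_refined_rmsd(self, helix100):
        decoy = perturb_structure(helix100, noise_sd=0.0, seed=17)
        res = superpose_models(helix100, decoy)
        assert res.rmsd_refined < 1e-9
        assert res.n_pairs_retained == res.n_pairs_initial == 100

    def test_constructed_outliers_are_the_rejected_set(self, helix100):
        coords = helix100.coords.copy()
        displaced = [10, 30, 50, 70, 90]
        coords[displaced] += [10.0, 0.0, 0.0]
        broken = model_from_arrays("broken", helix100.sequence, coords)
        res = superpose_models(helix100, broken, cycles=5, reject_cutoff=2.0)
        assert res.n_pairs_retained == 95
        rejected = set(range(100)) - set(res.retained_indices)
        assert rejected == set(displaced)
        assert res.rmsd_refined < 1e-6

    def test_refined_rmsd_never_exceeds_initial(self, helix100):
        for seed in range(10):
            decoy = perturb_structure(helix100, noise_sd=1.2, seed=seed)
            res = superpose_models(helix100, decoy, cycles=5, reject_cutoff=2.0)
            assert res.rmsd_refined <= res.rmsd_all + 1e-9
            assert res.n_pairs_retained <= res.n_pairs_initial

    def test_refinement_collapse_raises(self, helix100):
        far = model_from_arrays(
            "far", helix100.sequence,
            helix100.coords + np.random.default_rng(0).normal(scale=30, size=(100, 3)),
        )
        with pytest.raises(RefinementCollapseError):
            superpose_models(helix100, far, cycles=5, reject_cutoff=0.01)

    def test_pairing_through_sequence_structure_map(self, helix100):
        # mobile model has 10 extra leading residues relative to the reference
        seq = "G" * 10 + helix100.sequence
        coords = np.vstack([np.random.default_rng(5).normal(size=(10, 3)) + [50, 50, 50],
                            helix100.coords])
        mob = model_from_arrays("mob", seq, coords)
        record = ProteinRecord(id="r", sequence=seq)
        pair_map = map_sequence_to_structure(record, helix100)
        res = superpose_models(helix100, mob, pair_map=pair_map)
        assert res.n_pairs_initial == 100
        assert res.rmsd_refined < 1e-9

    def test_trim_policy_drops_terminal_pairs(self, helix100):
        decoy = perturb_structure(helix100, noise_sd=0.0, seed=3)
        res = superpose_models(
            helix100, decoy, trim=TrimPolicy(drop_n_terminal=10, drop_c_terminal=5)
        )
        assert res.n_pairs_initial == 85

    def test_trim_outside_tm_counts(self):
        seq = "G" * 10 + "L" * 20 + "G" * 5 + "L" * 20 + "G" * 8
        rec = ProteinRecord(id="r", sequence=seq, tm_segments=((11, 30), (36, 55)))
        model = model_from_arrays("m", seq, generate_helix_coords(len(seq)).coords)
        pair_map = map_sequence_to_structure(rec, model)
        trim = trim_outside_tm(rec, pair_map)
        assert trim.drop_n_terminal == 10
        assert trim.drop_c_terminal == 8
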