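import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mutmovie import (
    LddtParams,
    MetricError,
    PerturbationSpec,
    Residue,
    StructureModel,
    align_variant,
    kabsch_superpose,
    lddt_score,
    make_helix_structure,
    perturb,
)

from conftest import make_random_structure
from oracles import brute_force_lddt, random_rigid_transform


def ca_only_model(coords):
    residues = [
        Residue(index=i + 1, aa="A", atoms={"CA": np.asarray(c, dtype=float)})
        for i, c in enumerate(coords)
    ]
    return StructureModel(residues, confidence=np.full(len(coords), 90.0))


class TestLddt:
    def test_identical_structures_score_exactly_one(self, helix10):
        res = lddt_score(helix10, helix10)
        assert res.global_score == 1.0
        valid = res.per_residue[~np.isnan(res.per_residue)]
        assert np.all(valid == 1.0)

    def test_three_residue_toy_against_frozen_oracle_value(self):
        # CA-only toy: one preserved pair, one off by 0.544 A, one off by
        # exactly 1.0 A; brute-force enumeration gives per-residue scores
        # 0.875 / 0.75 / 0.625 and a global mean of 0.75.
        ref = ca_only_model([(0, 0, 0), (4, 0, 0), (8, 0, 0)])
        mod = ca_only_model([(0, 0, 0), (4, 0, 0), (8, 3, 0)])
        params = LddtParams(atom_set="CA")
        res = lddt_score(ref, mod, params)
        assert res.global_score == pytest.approx(0.75, abs=1e-12)
        assert res.per_residue.tolist() == pytest.approx([0.875, 0.75, 0.625], abs=1e-12)
        oracle_global, oracle_per = brute_force_lddt(ref, mod, atom_set="CA")
        assert res.global_score == pytest.approx(oracle_global, abs=1e-12)

    def test_translation_invariance(self, helix10):
        shifted = helix10.transformed(np.eye(3), np.array([10.0, 10.0, 10.0]))
        assert lddt_score(helix10, shifted).global_score == 1.0

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("atom_set", ["CA", "backbone", "all"])
    def test_oracle_equivalence_small_structures(self, seed, atom_set):
        # brute-force pair enumeration must agree to 1e-12 on <=5 residues
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        ref = make_random_structure(rng, n)
        mod = make_random_structure(rng, n)
        res = lddt_score(ref, mod, LddtParams(atom_set=atom_set))
        oracle_global, oracle_per = brute_force_lddt(ref, mod, atom_set=atom_set)
        assert res.global_score == pytest.approx(oracle_global, abs=1e-12)
        for got, want in zip(res.per_residue, oracle_per):
            if want is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_rigid_motion_invariance(self, helix10):
        rng = np.random.default_rng(42)
        mod = perturb(helix10, PerturbationSpec("gaussian_noise", 1.0, 1, 3))
        base = lddt_score(helix10, mod).global_score
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            moved = mod.transformed(rot, trans)
            assert lddt_score(helix10, moved).global_score == pytest.approx(
                base, abs=1e-12
            )

    def test_threshold_preserved_fraction_monotone(self, helix10):
        mod = perturb(helix10, PerturbationSpec("gaussian_noise", 1.0, 1, 5))
        fracs = []
        for t in (0.5, 1.0, 2.0, 4.0):
            res = lddt_score(helix10, mod, LddtParams(thresholds=(t,)))
            fracs.append(res.global_score)
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_noise_monotonicity_over_seeds(self, helix10):
        sigmas = [0.1, 0.5, 1.0, 2.0, 5.0]
        means = []
        for sigma in sigmas:
            scores = [
                lddt_score(
                    helix10,
                    perturb(helix10, PerturbationSpec("gaussian_noise", sigma, 1, s)),
                ).global_score
                for s in range(20)
            ]
            means.append(np.mean(scores))
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_missing_model_atom_counts_as_not_preserved(self, helix10):
        stripped = helix10.transformed(np.eye(3), np.zeros(3))
        del stripped.residues[4].atoms["O"]
        res = lddt_score(helix10, stripped)
        assert res.global_score < 1.0

    def test_residue_count_mismatch_is_error(self, helix10):
        other = make_helix_structure("MKV")
        with pytest.raises(MetricError, match="mismatch"):
            lddt_score(helix10, other)

    def test_zero_qualifying_pairs_is_error(self):
        ref = ca_only_model([(0, 0, 0), (100.0, 0, 0)])
        with pytest.raises(MetricError, match="pair"):
            lddt_score(ref, ref, LddtParams(atom_set="CA"))

    def test_score_bounds(self, helix10):
        mod = perturb(helix10, PerturbationSpec("gaussian_noise", 10.0, 1, 9))
        res = lddt_score(helix10, mod)
        assert 0.0 <= res.global_score <= 1.0


class TestKabsch:
    def test_identity_fit(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        t = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-10)
        assert t.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(1)
        target = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = target @ rot.T + np.array([5.0, 0.0, 0.0])
        t = kabsch_superpose(mobile, target)
        assert t.rmsd < 1e-6
        np.testing.assert_allclose(t.apply(mobile), target, atol=1e-6)

    def test_never_beaten_by_random_rigid_transforms(self):
        # optimality via random-search oracle: 1000 random proper rotations
        # (each with its own optimal translation) never yield a lower rmsd
        rng = np.random.default_rng(2)
        target = rng.normal(scale=5.0, size=(10, 3))
        mobile = target + rng.normal(scale=0.5, size=(10, 3))
        opt = kabsch_superpose(mobile, target)
        cm, ct = mobile.mean(axis=0), target.mean(axis=0)
        for _ in range(1000):
            rot, _ = random_rigid_transform(rng)
            trans = ct - rot @ cm
            rmsd = np.sqrt(((mobile @ rot.T + trans - target) ** 2).sum(axis=1).mean())
            assert rmsd >= opt.rmsd - 1e-9

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        target = rng.normal(scale=5.0, size=(12, 3))
        mobile = target + rng.normal(scale=0.8, size=(12, 3))
        ours = kabsch_superpose(mobile, target)
        rot, rssd = Rotation.align_vectors(
            target - target.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        np.testing.assert_allclose(ours.rotation, rot.as_matrix(), atol=1e-8)
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(mobile)), abs=1e-8)

    def test_rmsd_invariant_under_rigid_pre_transform(self):
        rng = np.random.default_rng(4)
        target = rng.normal(scale=5.0, size=(8, 3))
        mobile = target + rng.normal(scale=0.5, size=(8, 3))
        base = kabsch_superpose(mobile, target).rmsd
        for _ in range(5):
            rot, trans = random_rigid_transform(rng)
            assert kabsch_superpose(mobile @ rot.T + trans, target).rmsd == pytest.approx(
                base, abs=1e-9
            )

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        cloud = np.random.default_rng(5).normal(size=(4, 3))
        with pytest.raises(MetricError, match="collinear"):
            kabsch_superpose(line, cloud)
        with pytest.raises(MetricError, match="mismatch"):
            kabsch_superpose(cloud, cloud[:3])
        with pytest.raises(MetricError, match="3 points"):
            kabsch_superpose(cloud[:2], cloud[:2])

    def test_proper_rotation_enforced(self):
        # mirror-image target must be fit with a rotation, not a reflection
        rng = np.random.default_rng(6)
        mobile = rng.normal(size=(10, 3))
        target = mobile * np.array([1.0, 1.0, -1.0])
        t = kabsch_superpose(mobile, target)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-10)


class TestAlignVariant:
    def test_self_alignment_is_identity(self, helix10):
        aligned = align_variant(helix10, helix10)
        np.testing.assert_allclose(aligned.all_coords, helix10.all_coords, atol=1e-6)

    def test_prerotated_copy_recovers_wildtype(self, helix10):
        rng = np.random.default_rng(7)
        rot, trans = random_rigid_transform(rng)
        moved = helix10.transformed(rot, trans)
        aligned = align_variant(moved, helix10)
        np.testing.assert_allclose(aligned.all_coords, helix10.all_coords, atol=1e-6)

    def test_alignment_never_increases_ca_rmsd(self, helix10):
        pert = perturb(helix10, PerturbationSpec("hinge", 45.0, 5, 11))
        rng = np.random.default_rng(8)
        rot, trans = random_rigid_transform(rng)
        moved = pert.transformed(rot, trans)
        before = np.sqrt(((moved.ca_coords - helix10.ca_coords) ** 2).sum(axis=1).mean())
        aligned = align_variant(moved, helix10)
        after = np.sqrt(((aligned.ca_coords - helix10.ca_coords) ** 2).sum(axis=1).mean())
        assert after <= before + 1e-12

    def test_confidence_untouched(self, helix10):
        pert = perturb(helix10, PerturbationSpec("hinge", 45.0, 5, 11))
        aligned = align_variant(pert, helix10)
        np.testing.assert_array_equal(aligned.confidence, pert.confidence)
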