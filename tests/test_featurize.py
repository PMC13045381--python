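"""Distance features, contacts, centroids, superposition, membrane clash."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from openmsm import (
    DistancePairSet,
    FeatureTrajectory,
    StructureFrame,
    ToyComplexSpec,
    build_toy_complex,
    com_distance,
    count_lipid_contacts,
    membrane_clash,
    pairwise_distances,
    reward_sum,
    superimpose,
)


def make_frame(coords, **kw):
    n = len(coords)
    defaults = dict(
        residue_id=np.arange(1, n + 1),
        residue_name=np.array(["GLY"] * n, dtype=object),
        molecule_id=np.zeros(n, dtype=int),
        molecule_class=np.array(["MpD"] * n, dtype=object),
    )
    defaults.update(kw)
    return StructureFrame(coords=np.asarray(coords, dtype=float), **defaults)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestPairwiseDistances:
    def test_simple_triangle(self):
        frame = make_frame([[0, 0, 0], [3, 4, 0]])
        feats = pairwise_distances(frame, DistancePairSet([[0, 1]]))
        assert feats.values[0, 0] == pytest.approx(5.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=10, size=(12, 3))
        p = rng.choice(12, size=(8, 2), replace=True)
        p[:, 1] = (p[:, 0] + 1 + p[:, 1] % 11) % 12  # distinct within a pair
        pairs = DistancePairSet(p)
        frame = make_frame(coords)
        moved = frame.transformed(random_rotation(rng), rng.normal(size=3))
        a = pairwise_distances(frame, pairs).values
        b = pairwise_distances(moved, pairs).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matches_brute_force_distance_matrix(self, rng):
        coords = rng.normal(scale=8, size=(20, 3))
        idx = rng.choice(20, size=(30, 2))
        idx[:, 1] = (idx[:, 0] + 1 + idx[:, 1] % 19) % 20
        pairs = DistancePairSet(idx)
        frame = make_frame(coords)
        full = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        got = pairwise_distances(frame, pairs).values[0]
        np.testing.assert_allclose(got, full[idx[:, 0], idx[:, 1]], rtol=1e-12)

    def test_index_out_of_range(self):
        frame = make_frame([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(IndexError):
            pairwise_distances(frame, DistancePairSet([[0, 5]]))

    def test_pair_file_roundtrip(self, tmp_path):
        pairs = DistancePairSet([[0, 3], [1, 4]], interface_tags=["MpD-CrD", "MpD-StD"])
        path = tmp_path / "pairs.txt"
        pairs.to_file(path)
        back = DistancePairSet.from_file(path)
        assert np.array_equal(back.pairs, pairs.pairs)
        assert list(back.interface_tags) == list(pairs.interface_tags)


class TestRewardSum:
    def test_sum_in_nanometres(self):
        feats = FeatureTrajectory(np.array([[30.0, 40.0, 50.0]]), 1.0, list("abc"))
        assert reward_sum(feats)[0] == pytest.approx(12.0)

    def test_homogeneous_under_scaling(self, rng):
        vals = rng.uniform(10, 90, size=(5, 7))
        a = reward_sum(FeatureTrajectory(vals, 1.0, [str(i) for i in range(7)]))
        b = reward_sum(FeatureTrajectory(2 * vals, 1.0, [str(i) for i in range(7)]))
        np.testing.assert_allclose(b, 2 * a)

    def test_open_complex_scores_higher_than_closed(self):
        closed = make_frame([[0, 0, 0], [0, 0, 10], [0, 0, 20]])
        opened = make_frame([[0, 0, 0], [0, 0, 30], [0, 0, 60]])
        pairs = DistancePairSet([[0, 1], [0, 2], [1, 2]])
        r_closed = reward_sum(pairwise_distances(closed, pairs))[0]
        r_open = reward_sum(pairwise_distances(opened, pairs))[0]
        assert r_open > r_closed

    def test_empty_subset_rejected(self):
        feats = FeatureTrajectory(np.ones((2, 3)), 1.0, list("abc"))
        with pytest.raises(ValueError):
            reward_sum(feats, pair_subset=[])


class TestLipidContacts:
    def base_frame(self, lipids):
        return build_toy_complex(
            ToyComplexSpec(lipid_counts={}, explicit_lipids=lipids, atoms_per_lipid=1), seed=4
        )

    @staticmethod
    def outermost_crd_atom(frame):
        crd = frame.coords[frame.select(molecule_class="CrD")]
        return crd[np.argmax(crd[:, 0])]

    def test_molecule_not_atom_counting(self):
        ref = self.base_frame([])
        crd_atom = ref.coords[ref.select(molecule_class="CrD")][0]
        # one lipid, two of its atoms within 3 A of the CrD (heads stacked at -4 A steps)
        frame = build_toy_complex(
            ToyComplexSpec(
                lipid_counts={},
                atoms_per_lipid=2,
                explicit_lipids=[("POPC", crd_atom + np.array([0.0, 0.0, 3.0]))],
            ),
            seed=4,
        )
        assert count_lipid_contacts(frame, "CrD") == 1
        assert count_lipid_contacts(frame, "CrD", count_atom_pairs=True) >= 2

    def test_cutoff_is_exclusive_above_four(self):
        ref = self.base_frame([])
        crd_atom = self.outermost_crd_atom(ref)
        frame = self.base_frame([("POPC", crd_atom + np.array([4.1, 0, 0]))])
        # nearest lipid atom sits exactly 4.1 A away
        assert count_lipid_contacts(frame, "CrD") == 0
        assert count_lipid_contacts(frame, "CrD", cutoff=4.2) == 1

    def test_matches_brute_force_oracle_both_modes(self):
        frame = build_toy_complex(
            ToyComplexSpec(lipid_counts={"POPC": 35, "POPS": 15}, slab=(0.0, 25.0)), seed=8
        )
        for domain in ("CrD", "StD", "TmD"):
            dom = frame.select(molecule_class=domain)
            lip = frame.select(molecule_class=("POPC", "POPS"))
            d = np.linalg.norm(
                frame.coords[dom][:, None, :] - frame.coords[lip][None, :, :], axis=2
            )
            touched = (d <= 4.0).any(axis=0)
            expect_mol = len(np.unique(frame.molecule_id[lip][touched]))
            assert count_lipid_contacts(frame, domain) == expect_mol
            assert count_lipid_contacts(frame, domain, count_atom_pairs=True) == int(
                (d <= 4.0).sum()
            )
            per_res = count_lipid_contacts(frame, domain, per_residue=True)
            for rid, cnt in per_res.items():
                sel = dom & (frame.residue_id == rid)
                dr = np.linalg.norm(
                    frame.coords[sel][:, None, :] - frame.coords[lip][None, :, :], axis=2
                )
                expect = len(np.unique(frame.molecule_id[lip][(dr <= 4.0).any(axis=0)]))
                assert cnt == expect

    def test_monotone_in_cutoff(self):
        frame = build_toy_complex(ToyComplexSpec(slab=(0.0, 30.0)), seed=9)
        counts = [count_lipid_contacts(frame, "TmD", cutoff=c) for c in (2.0, 4.0, 8.0, 16.0)]
        assert counts == sorted(counts)

    def test_unknown_species_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            count_lipid_contacts(toy_complex, "CrD", species_filter="CHOL")


class TestComDistance:
    def test_two_single_atoms(self):
        frame = make_frame([[0, 0, 0], [0, 3, 4]])
        assert com_distance(frame, [1], [2]) == pytest.approx(5.0)

    def test_mirrored_groups(self):
        frame = make_frame([[1, 2, 0], [3, 2, 0], [-1, -2, 0], [-3, -2, 0]])
        d = com_distance(frame, [1, 2], [3, 4])
        centroid = np.array([2.0, 2.0, 0.0])
        assert d == pytest.approx(2 * np.linalg.norm(centroid))

    def test_mass_weights_match_oracle(self, rng):
        coords = rng.normal(size=(6, 3))
        masses = rng.uniform(1, 16, size=6)
        frame = make_frame(coords, masses=masses)
        d = com_distance(frame, [1, 2, 3], [4, 5, 6], weights="mass")
        ca = np.average(coords[:3], axis=0, weights=masses[:3])
        cb = np.average(coords[3:], axis=0, weights=masses[3:])
        assert d == pytest.approx(np.linalg.norm(ca - cb))

    def test_empty_selection_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            com_distance(toy_complex, [99999], [1])


class TestSuperimpose:
    def test_identity(self, toy_complex):
        ids = np.unique(toy_complex.residue_id)[:10]
        moved, rmsd = superimpose(toy_complex, toy_complex, ids)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(moved.coords, toy_complex.coords, atol=1e-9)

    def test_recovers_known_rotation(self, toy_complex, rng):
        R = random_rotation(rng)
        t = np.array([5.0, -3.0, 8.0])
        mobile = toy_complex.transformed(R, t)
        ids = np.unique(toy_complex.residue_id)
        moved, rmsd = superimpose(mobile, toy_complex, ids)
        assert rmsd < 1e-6
        np.testing.assert_allclose(moved.coords, toy_complex.coords, atol=1e-6)

    def test_rmsd_not_worse_than_unaligned(self, toy_complex, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            mobile = toy_complex.transformed(random_rotation(r), r.normal(size=3) * 4)
            jitter = mobile.coords + r.normal(scale=0.3, size=mobile.coords.shape)
            mobile = make_frame(
                jitter,
                residue_id=mobile.residue_id,
                residue_name=mobile.residue_name,
                molecule_id=mobile.molecule_id,
                molecule_class=mobile.molecule_class,
            )
            ids = np.unique(toy_complex.residue_id)
            sel = toy_complex.select(residue_ids=ids)
            before = np.sqrt(np.mean(np.sum((mobile.coords[sel] - toy_complex.coords[sel]) ** 2, -1)))
            _, after = superimpose(mobile, toy_complex, ids)
            assert after <= before + 1e-9

    def test_mismatched_and_degenerate_selections(self, toy_complex):
        with pytest.raises(ValueError):
            superimpose(toy_complex, toy_complex, [])
        line = make_frame([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError):
            superimpose(line, line, [1, 2, 3])

    def test_agrees_with_scipy_rotation_align(self, rng):
        from scipy.spatial.transform import Rotation

        X = rng.normal(size=(8, 3))
        R = random_rotation(rng)
        Y = X @ R.T + np.array([1.0, 2.0, 3.0])
        fx = make_frame(X)
        fy = make_frame(Y)
        moved, rmsd = superimpose(fx, fy, np.arange(1, 9))
        est, _ = Rotation.align_vectors(Y - Y.mean(0), X - X.mean(0))
        np.testing.assert_allclose(moved.coords, Y, atol=1e-8)
        np.testing.assert_allclose(est.as_matrix(), R, atol=1e-8)


class TestMembraneClash:
    def test_atom_at_midplane_clashes(self):
        coords = [[0, 0, 20.0], [0, 0, 100.0]]
        frame = make_frame(
            coords,
            molecule_class=np.array(["FabH", "FabH"], dtype=object),
            membrane_slab=(0.0, 40.0, 100.0),
        )
        flag, count = membrane_clash(frame, "fab")
        assert flag is True and count == 1

    def test_grazing_penetration_not_counted(self):
        frame = make_frame(
            [[0, 0, 39.5]],
            molecule_class=np.array(["FabL"], dtype=object),
            membrane_slab=(0.0, 40.0, 100.0),
        )
        flag, count = membrane_clash(frame, "fab", penetration_min=1.0)
        assert flag is False and count == 0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_depth_oracle(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.uniform(-20, 60, size=15)
        coords = np.column_stack([rng.normal(size=(15, 2)), z])
        frame = make_frame(
            coords,
            molecule_class=np.array(["FabH"] * 15, dtype=object),
            membrane_slab=(0.0, 40.0, 100.0),
        )
        depth = np.minimum(z - 0.0, 40.0 - z)
        expect = int((depth > 1.0).sum())
        flag, count = membrane_clash(frame, "fab")
        assert count == expect and flag == (expect > 0)

    def test_inverted_slab_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            membrane_clash(toy_complex, "fab", slab=(40.0, 0.0))
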