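"""Superposition: pairing, the Kabsch fit against two oracles, rejection."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from foldability.errors import DegenerateGeometryError, ValidationError
from foldability.superpose import (
    AtomPairing,
    align_iterative,
    align_sequences,
    kabsch,
    pair_by_alignment,
    pair_by_map,
)
from foldability.synthetic import make_toy_structure
from oracles import (
    brute_force_rotation_rmsd,
    nw_linear_gap_score,
    pairing_score,
    quaternion_rmsd,
    random_rigid_transform,
)


def make_pairing(P, Q):
    return AtomPairing(P, Q, [((i + 1, "CA"), (i + 1, "CA")) for i in range(len(P))],
                       "residue_map", ("CA",))


class TestPairing:
    def test_identical_models_pair_count_with_glycine(self):
        # 5 residues, one Gly: 4 atoms each except Gly (no CB) -> 4*4 + 3 = 19
        m = make_toy_structure("AKVGL", "CCCCC", seed=1)
        pairing = pair_by_map(m, m, [1, 2, 3, 4, 5], ("CA", "CB", "C", "O"))
        assert len(pairing) == 19

    def test_all_none_map_gives_empty_pairing(self, helix20):
        pairing = pair_by_map(helix20, helix20, [None] * 20)
        assert len(pairing) == 0
        with pytest.raises(DegenerateGeometryError):
            align_iterative(pairing)

    def test_permutant_map_pairs_as_many_as_identity(self):
        # glycine-free so every residue offers the same atom set
        m = make_toy_structure("MKVLEAIRKQ", "H" * 10, seed=5)
        identity = pair_by_map(m, m, list(range(1, 11)))
        shifted = list(range(4, 11)) + list(range(1, 4))  # circular shift
        permuted = pair_by_map(m, m, shifted)
        assert len(permuted) == len(identity)

    def test_map_to_absent_residue_rejected(self, helix20):
        with pytest.raises(ValidationError):
            pair_by_map(helix20, helix20, [99] + [None] * 19)

    def test_identical_sequences_align_to_identity(self, helix20):
        pairing = pair_by_alignment(helix20, helix20)
        identity = pair_by_map(helix20, helix20, list(range(1, 21)))
        assert pairing.pairs == identity.pairs

    @given(
        a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
        b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12),
    )
    @settings(max_examples=60)
    def test_alignment_pairs_reach_dp_optimum(self, a, b):
        """With a linear gap penalty the score reconstructed from the aligned
        columns must equal the plain-DP global optimum."""
        gap = -1.0
        sub = substitution_matrices.load("BLOSUM62")
        pairs = align_sequences(a, b, open_gap=gap, extend_gap=gap)
        assert pairing_score(a, b, pairs, sub, gap) == pytest.approx(
            nw_linear_gap_score(a, b, sub, gap)
        )

    def test_disjoint_alphabets_follow_dp(self):
        gap = -1.0
        sub = substitution_matrices.load("BLOSUM62")
        pairs = align_sequences("AAAA", "WWWW", open_gap=gap, extend_gap=gap)
        assert pairing_score("AAAA", "WWWW", pairs, sub, gap) == pytest.approx(
            nw_linear_gap_score("AAAA", "WWWW", sub, gap)
        )


class TestKabsch:
    def test_self_superposition(self, rng):
        P = rng.normal(size=(10, 3))
        res = kabsch(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_rigid_transform(self, rng):
        for _ in range(20):
            P = rng.normal(size=(int(rng.integers(3, 30)), 3))
            R, t = random_rigid_transform(rng)
            res = kabsch(P, P @ R.T + t)
            assert res.rmsd < 1e-9
            assert np.allclose(res.rotation, R, atol=1e-8)

    def test_rotation_is_proper_orthonormal(self, rng):
        for _ in range(20):
            P = rng.normal(size=(8, 3))
            Q = rng.normal(size=(8, 3))
            R = kabsch(P, Q).rotation
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-8)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_symmetry(self, rng):
        for _ in range(20):
            P = rng.normal(size=(12, 3))
            Q = rng.normal(size=(12, 3))
            assert kabsch(P, Q).rmsd == pytest.approx(kabsch(Q, P).rmsd, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        P = rng.normal(size=(15, 3))
        Q = rng.normal(size=(15, 3))
        base = kabsch(P, Q).rmsd
        for _ in range(10):
            R1, t1 = random_rigid_transform(rng)
            R2, t2 = random_rigid_transform(rng)
            moved = kabsch(P @ R1.T + t1, Q @ R2.T + t2).rmsd
            assert moved == pytest.approx(base, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_point_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 31))
            P = rng.normal(size=(n, 3))
            Q = rng.normal(size=(n, 3))
            assert abs(kabsch(P, Q).rmsd - quaternion_rmsd(P, Q)) < 1e-9

    def test_matches_brute_force_rotation_search_on_distorted_square(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        Q = P.copy()
        Q[2, 2] = 1.0  # one corner lifted 1 A out of plane
        kb = kabsch(P, Q).rmsd
        assert abs(kb - brute_force_rotation_rmsd(P, Q)) <= 1e-3
        assert abs(kb - quaternion_rmsd(P, Q)) <= 1e-9

    def test_too_few_points_rejected(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch(P, P)

    def test_collinear_points_rejected(self):
        P = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch(P, P)


class TestIterativeRejection:
    def test_perfect_superposition_no_rejection(self, rng):
        P = rng.normal(size=(10, 3))
        R, t = random_rigid_transform(rng)
        res = align_iterative(make_pairing(P, P @ R.T + t))
        assert res.rmsd < 1e-9
        assert res.cycles_run == 0
        assert res.n_pairs_retained == 10

    def test_gross_outliers_rejected_to_clean_fit(self, rng):
        P = rng.normal(size=(20, 3)) * 3.0
        R, t = random_rigid_transform(rng)
        Q = P @ R.T + t
        noise = rng.normal(scale=0.1, size=(20, 3))
        Q += noise
        Q[[4, 17]] += 10.0  # two gross outliers
        res = align_iterative(make_pairing(P, Q))
        assert res.n_pairs_retained == 18
        rejected = {i for cycle in res.rejected for i in cycle}
        assert rejected == {4, 17}
        clean = kabsch(np.delete(P, [4, 17], axis=0), np.delete(Q, [4, 17], axis=0))
        assert res.rmsd == pytest.approx(clean.rmsd, abs=1e-9)

    def test_rmsd_never_increases_across_cycles(self, rng):
        for _ in range(20):
            P = rng.normal(size=(30, 3)) * 2
            Q = P + rng.normal(scale=1.0, size=(30, 3))
            res = align_iterative(make_pairing(P, Q), cycles=5, reject_factor=1.2)
            diffs = np.diff(res.rmsd_per_cycle)
            assert (diffs <= 1e-12).all()

    def test_never_drops_below_three_pairs(self, rng):
        P = rng.normal(size=(4, 3)) * 5
        Q = P + rng.normal(scale=2.0, size=(4, 3))
        res = align_iterative(make_pairing(P, Q), cycles=10, reject_factor=0.1)
        assert res.n_pairs_retained >= 3
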