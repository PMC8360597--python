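import numpy as np
import pytest
from hypothesis import given, strategies as st

from tdavine import (
    TaskDesign,
    ValidationError,
    group_statistic,
    permutation_test,
    permute_labels_blockwise,
    wasserstein,
)
from tdavine.synthetic import make_design

from _oracles import bruteforce_wasserstein


def diags(points_list):
    return [np.asarray(p, dtype=float).reshape(-1, 2) for p in points_list]


class TestWasserstein:
    def test_identity(self):
        P = [[0.0, 2.0], [1.0, 3.0]]
        assert wasserstein(P, P) == 0.0

    def test_single_point_to_empty_pays_diagonal(self):
        for q in (1.0, 2.0, 3.0):
            assert wasserstein([[0.0, 2.0]], np.empty((0, 2)), q=q) == pytest.approx(1.0)

    def test_direct_match_beats_diagonal_route(self):
        # match cost 2 < diagonal route 1 + 2 = 3
        assert wasserstein([[0.0, 2.0]], [[0.0, 4.0]], q=1.0) == pytest.approx(2.0)

    def test_empty_vs_empty_is_zero(self):
        assert wasserstein(np.empty((0, 2)), np.empty((0, 2))) == 0.0

    def test_q_below_one_rejected(self):
        with pytest.raises(ValidationError):
            wasserstein([[0, 1.0]], [[0, 1.0]], q=0.5)

    def test_adding_a_feature_strictly_increases_distance(self):
        base = [[0.0, 2.0]]
        other = [[0.0, 2.0], [1.0, 3.0]]
        assert wasserstein(base, other) > wasserstein(base, base)

    @pytest.mark.parametrize("q", [1.0, 2.0])
    def test_matches_exhaustive_matching_oracle(self, q):
        rng = np.random.default_rng(99)
        for _ in range(60):
            def mk():
                k = int(rng.integers(0, 5))
                b = rng.uniform(0, 3, k)
                return np.column_stack([b, b + rng.uniform(0, 2, k)])
            P1, P2 = mk(), mk()
            assert wasserstein(P1, P2, q=q) == pytest.approx(
                bruteforce_wasserstein(P1, P2, q=q), abs=1e-9
            )

    @given(st.data())
    def test_metric_axioms(self, data):
        pts = st.lists(
            st.tuples(
                st.floats(0, 3, allow_nan=False), st.floats(0, 2, allow_nan=False)
            ).map(lambda bd: (bd[0], bd[0] + bd[1])),
            min_size=0,
            max_size=4,
        )
        A = np.array(data.draw(pts)).reshape(-1, 2)
        B = np.array(data.draw(pts)).reshape(-1, 2)
        C = np.array(data.draw(pts)).reshape(-1, 2)
        dab = wasserstein(A, B)
        assert dab == pytest.approx(wasserstein(B, A))
        assert dab <= wasserstein(A, C) + wasserstein(C, B) + 1e-9


class TestGroupStatistic:
    def test_identical_diagrams_give_zero(self):
        d = diags([[[0, 2.0]]] * 4)
        assert group_statistic(d, ["a", "a", "b", "b"]) == 0.0

    def test_internally_identical_groups_give_zero(self):
        d = diags([[[0, 2.0]], [[0, 2.0]], [], []])
        assert group_statistic(d, ["a", "a", "b", "b"]) == 0.0

    def test_hand_computed_sum(self):
        # group a: {(0,2)} vs {(0,4)} -> W=2; group b: {} vs {(0,2)} -> W=1
        d = diags([[[0, 2.0]], [[0, 4.0]], [], [[0, 2.0]]])
        s = group_statistic(d, ["a", "a", "b", "b"], q=2.0)
        assert s == pytest.approx(2.0**2 + 1.0**2)

    def test_group_of_one_rejected(self):
        d = diags([[[0, 2.0]]] * 3)
        with pytest.raises(ValidationError):
            group_statistic(d, ["a", "a", "b"])


class TestBlockPermutation:
    def test_blocks_derived_from_labels(self):
        design = TaskDesign.from_labels(["e", "e", "c", "c", "r", "r"])
        assert design.blocks == (("e", 0, 2), ("c", 2, 4), ("r", 4, 6))

    def test_full_design_has_8_encoding_blocks_of_9(self):
        design = make_design()
        assert design.T == 288
        enc = [b for b in design.blocks if b[0] == "encoding"]
        assert len(enc) == 8
        assert all(stop - start == 9 for _, start, stop in enc)

    def test_permutation_preserves_block_structure(self):
        design = make_design(trs_per_block=3, n_cycles=2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            new = permute_labels_blockwise(design, ("encoding", "retrieval"), rng)
            perm = TaskDesign.from_labels(new)
            # same number of blocks per condition, same block lengths
            assert sorted(b[0] for b in perm.blocks) == sorted(
                b[0] for b in design.blocks
            )
            # untested conditions never move
            for t, lab in enumerate(design.labels):
                if lab == "consolidation":
                    assert new[t] == "consolidation"

    def test_uniform_over_block_assignments(self):
        # 2 encoding + 2 retrieval blocks -> C(4,2)=6 equally likely assignments
        design = make_design(trs_per_block=2, n_cycles=2)
        rng = np.random.default_rng(123)
        counts: dict[tuple, int] = {}
        n = 6000
        for _ in range(n):
            key = tuple(
                permute_labels_blockwise(design, ("encoding", "retrieval"), rng)
            )
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        for c in counts.values():
            assert abs(c - n / 6) < 5 * np.sqrt(n / 6)

    def test_full_design_supports_12870_assignments(self):
        from math import comb

        design = make_design()
        enc = sum(1 for b in design.blocks if b[0] == "encoding")
        ret = sum(1 for b in design.blocks if b[0] == "retrieval")
        assert comb(enc + ret, enc) == 12870

    def test_too_few_blocks_rejected(self):
        design = make_design(trs_per_block=2, n_cycles=1)
        with pytest.raises(ValidationError):
            permute_labels_blockwise(
                design, ("encoding", "retrieval"), np.random.default_rng(0)
            )


class TestPermutationTest:
    def test_label_independent_diagrams_give_p_one(self):
        design = make_design(trs_per_block=2, n_cycles=2)
        d = diags([[[0, 2.0]]] * design.T)
        res = permutation_test(d, design, n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_seed_reproducibility(self):
        design = make_design(trs_per_block=2, n_cycles=3)
        rng = np.random.default_rng(5)
        d = [
            np.array([[0.0, 2.0 + rng.normal(0, 0.3)]]) for _ in range(design.T)
        ]
        a = permutation_test(d, design, n_perm=199, seed=7)
        b = permutation_test(d, design, n_perm=199, seed=7)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_statistics, b.null_statistics)

    def test_p_invariant_to_group_order(self):
        design = make_design(trs_per_block=2, n_cycles=3)
        rng = np.random.default_rng(5)
        d = [np.array([[0.0, 2.0 + rng.normal(0, 0.3)]]) for _ in range(design.T)]
        a = permutation_test(d, design, ("encoding", "retrieval"), n_perm=199, seed=7)
        b = permutation_test(d, design, ("retrieval", "encoding"), n_perm=199, seed=7)
        assert a.p_value == b.p_value

    def test_presence_absence_signal_detected(self):
        # loop present at encoding indices only -> tiny p
        design = make_design(trs_per_block=3, n_cycles=8)
        d = [
            np.array([[0.5, 2.0]]) if lab == "encoding" else np.empty((0, 2))
            for lab in design.labels
        ]
        res = permutation_test(d, design, n_perm=999, seed=1)
        assert res.p_value <= 0.01

    def test_plus_one_estimator_and_invariants(self):
        design = make_design(trs_per_block=2, n_cycles=2)
        d = diags([[[0, 2.0]]] * design.T)
        res = permutation_test(d, design, n_perm=99, seed=3)
        ties = int(np.sum(res.null_statistics <= res.observed_statistic))
        assert res.p_value == (1 + ties) / (1 + res.n_permutations)
        assert 0 < res.p_value <= 1

    def test_super_uniform_under_null(self):
        """P(p <= alpha) <= alpha + eps when labels are independent of diagrams."""
        design = make_design(trs_per_block=2, n_cycles=3)
        rng = np.random.default_rng(2)
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            d = [
                np.array([[0.0, 1.0 + rng.uniform(0, 1)]]) for _ in range(design.T)
            ]
            res = permutation_test(d, design, n_perm=99, seed=1000 + rep)
            hits += res.p_value <= 0.10
        assert hits / n_rep <= 0.10 + 0.07  # 3-sigma slack at alpha=0.10
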