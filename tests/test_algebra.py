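"""Subject-stack algebra: group matrices, decomposition, mediated paths."""

import itertools

import numpy as np
import pytest

from conftest import random_binary_cm
from mibca import algebra
from mibca.types import ConnectivityMatrix, SubjectStack


def _stack(matrices):
    ids = [f"s{i}" for i in range(len(matrices))]
    return SubjectStack(subject_ids=ids, matrices=dict(zip(ids, matrices)))


def _cm(values, **kw):
    values = np.asarray(values, dtype=float)
    kw.setdefault("roi_ids", list(range(1, len(values) + 1)))
    return ConnectivityMatrix(values=values, **kw)


class TestBinarize:
    def test_positive_count_rule(self):
        cm = _cm([[0, 3, 0], [3, 0, 17], [0, 17, 0]], weight_kind="count")
        b = algebra.binarize(cm)
        np.testing.assert_array_equal(
            b.values, [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        )

    def test_p_threshold_all_ones_empty(self):
        cm = _cm(np.zeros((4, 4)), weight_kind="correlation")
        b = algebra.binarize(cm, rule="p_threshold", p_matrix=np.ones((4, 4)))
        assert b.values.sum() == 0

    def test_matches_elementwise_bruteforce(self, rng):
        vals = rng.integers(0, 5, size=(6, 6)).astype(float)
        vals = np.triu(vals, 1) + np.triu(vals, 1).T
        cm = _cm(vals, weight_kind="count")
        np.testing.assert_array_equal(
            algebra.binarize(cm).values, (vals > 0).astype(float)
        )

    def test_p_rule_without_p_matrix_rejected(self):
        with pytest.raises(ValueError, match="p_matrix"):
            algebra.binarize(_cm(np.zeros((3, 3))), rule="p_threshold")


class TestMeanRobustness:
    def test_mean_of_two(self):
        a = _cm([[0, 4], [4, 0]])
        b = _cm([[0, 6], [6, 0]])
        assert algebra.mean_cm(_stack([a, b])).values[0, 1] == pytest.approx(5.0)

    def test_single_subject_identity(self, rng):
        cm = random_binary_cm(rng)
        np.testing.assert_array_equal(algebra.mean_cm(_stack([cm])).values, cm.values)

    def test_mean_matches_bruteforce_loop(self, rng):
        mats = [random_binary_cm(rng, n=5) for _ in range(10)]
        got = algebra.mean_cm(_stack(mats)).values
        expect = sum(m.values for m in mats) / 10
        np.testing.assert_allclose(got, expect)

    def test_robustness_fraction_of_subjects(self):
        # edge present in exactly 1 of 10 -> 0.1; in 9 of 10 -> 0.9
        base = np.zeros((3, 3))
        rare = base.copy()
        rare[0, 1] = rare[1, 0] = 1
        common = base.copy()
        common[1, 2] = common[2, 1] = 1
        mats = [_cm(rare if i == 0 else base, weight_kind="binary")
                for i in range(10)]
        rob = algebra.robustness_cm(_stack(mats))
        assert rob.values[0, 1] == pytest.approx(0.1)
        mats = [_cm(common if i < 9 else base, weight_kind="binary")
                for i in range(10)]
        rob = algebra.robustness_cm(_stack(mats))
        assert rob.values[1, 2] == pytest.approx(0.9)

    def test_robustness_idempotent_on_identical_stacks(self, rng):
        cm = random_binary_cm(rng)
        rob = algebra.robustness_cm(_stack([cm] * 7))
        np.testing.assert_array_equal(rob.values, cm.values)

    def test_robustness_rejects_weighted_input(self):
        with pytest.raises(ValueError, match="not binary"):
            algebra.robustness_cm(_stack([_cm([[0, 2.0], [2.0, 0]])]))


class TestCombined:
    def test_strict_threshold_formula(self):
        mean = _cm([[0, 12.0], [12.0, 0]])
        for rob_val, expected in ((0.9, 12.0), (0.7, 0.0), (0.8, 0.0)):
            rob = _cm([[0, rob_val], [rob_val, 0]], weight_kind="probability")
            comb = algebra.combined_cm(mean, rob, tau=0.8)
            assert comb.values[0, 1] == pytest.approx(expected)

    def test_contraction_of_mean(self, rng):
        m = np.abs(rng.normal(size=(5, 5)))
        mean = _cm(m + m.T)
        r = np.round(np.triu(rng.random((5, 5)), 1), 2)
        rob = _cm(r + r.T, weight_kind="probability")
        comb = algebra.combined_cm(mean, rob)
        assert np.all(np.abs(comb.values) <= np.abs(mean.values) + 1e-12)


class TestHybridSF:
    def test_elementwise_product(self):
        s = _cm([[0, 3.0], [3.0, 0]], modality="s")
        f = _cm([[0, 0.5], [0.5, 0]], modality="f")
        sf = algebra.hybrid_sf(s, f)
        assert sf.values[0, 1] == pytest.approx(1.5)
        assert sf.modality == "sf"

    def test_zero_functional_annihilates(self, rng):
        s = random_binary_cm(rng, n=5)
        f = s.copy_with(np.zeros((5, 5)), modality="f")
        assert algebra.hybrid_sf(s, f).values.sum() == 0

    def test_matches_bruteforce_loop(self, rng):
        s = random_binary_cm(rng, n=5)
        fv = rng.uniform(-1, 1, size=(5, 5))
        fv = (fv + fv.T) / 2
        np.fill_diagonal(fv, 0)
        f = s.copy_with(fv, modality="f", weight_kind="correlation")
        sf = algebra.hybrid_sf(s, f)
        for i in range(5):
            for j in range(5):
                assert sf.values[i, j] == pytest.approx(s.values[i, j] * f.values[i, j])


class TestDecomposition:
    def test_edge_classification(self):
        s = _cm([[0, 1, 0], [1, 0, 0], [0, 0, 0]], weight_kind="binary")
        f = _cm([[0, 1, 1], [1, 0, 0], [1, 0, 0]], weight_kind="binary")
        direct, mediated = algebra.decompose_direct_mediated(s, f)
        assert direct.values[0, 1] == 1 and mediated.values[0, 1] == 0
        assert direct.values[0, 2] == 0 and mediated.values[0, 2] == 1

    def test_structural_only_edge_in_neither(self):
        s = _cm([[0, 1], [1, 0]], weight_kind="binary")
        f = _cm(np.zeros((2, 2)), weight_kind="binary")
        direct, mediated = algebra.decompose_direct_mediated(s, f)
        assert direct.values.sum() == 0 and mediated.values.sum() == 0

    def test_partition_law_on_random_pairs(self, rng):
        for _ in range(500):
            s = random_binary_cm(rng, n=6)
            f = random_binary_cm(rng, n=6)
            direct, mediated = algebra.decompose_direct_mediated(s, f)
            np.testing.assert_array_equal(
                direct.values + mediated.values, f.values
            )
            assert np.all(direct.values * mediated.values == 0)


def bruteforce_shortest(adj, src, dst):
    """Exhaustive enumeration of simple paths; minimal length or None."""
    n = len(adj)
    best = None
    for length in range(2, n + 1):
        for mid in itertools.permutations(
            [k for k in range(n) if k not in (src, dst)], length - 2
        ):
            path = (src, *mid, dst)
            if all(adj[path[i], path[i + 1]] for i in range(len(path) - 1)):
                best = len(path)
                break
        if best:
            break
    return best


class TestMediatedPath:
    def _chain_cm(self):
        # rMFG_R - SFG_R - SFG_L - rMFG_L chain plus unrelated edges
        names = ["rMFG_L", "rMFG_R", "SFG_L", "SFG_R", "other1", "other2"]
        ids = list(range(1, len(names) + 1))
        idx = {n: names.index(n) for n in names}
        vals = np.zeros((6, 6))
        for a, b in (("rMFG_R", "SFG_R"), ("SFG_R", "SFG_L"),
                     ("SFG_L", "rMFG_L"), ("other1", "other2"),
                     ("other1", "SFG_R")):
            vals[idx[a], idx[b]] = vals[idx[b], idx[a]] = 1
        cm = ConnectivityMatrix(values=vals, roi_ids=ids, weight_kind="binary")
        return cm, idx, ids

    def test_printed_four_region_path(self):
        cm, idx, ids = self._chain_cm()
        path = algebra.mediated_path(cm, ids[idx["rMFG_R"]], ids[idx["rMFG_L"]])
        assert len(path) == 4
        assert path == [ids[idx[n]] for n in ("rMFG_R", "SFG_R", "SFG_L", "rMFG_L")]

    def test_adjacent_pair_two_region_path(self):
        cm, idx, ids = self._chain_cm()
        path = algebra.mediated_path(cm, ids[idx["SFG_R"]], ids[idx["SFG_L"]])
        assert path == [ids[idx["SFG_R"]], ids[idx["SFG_L"]]]

    def test_disconnected_returns_none(self):
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = 1
        cm = ConnectivityMatrix(values=vals, roi_ids=[1, 2, 3, 4],
                                weight_kind="binary")
        assert algebra.mediated_path(cm, 1, 3) is None

    def test_length_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 11))
            cm = random_binary_cm(rng, n=n, p=0.25)
            src, dst = 0, n - 1
            path = algebra.mediated_path(cm, cm.roi_ids[src], cm.roi_ids[dst])
            expect = bruteforce_shortest(cm.values, src, dst)
            if expect is None:
                assert path is None
            else:
                assert path is not None and len(path) == expect

    def test_all_shortest_mode_contains_greedy_path(self, rng):
        cm = random_binary_cm(rng, n=8, p=0.4)
        greedy = algebra.mediated_path(cm, 1, 8)
        if greedy is not None:
            everything = algebra.mediated_path(cm, 1, 8, all_shortest=True)
            assert greedy in everything
            assert all(len(p) == len(greedy) for p in everything)

    def test_unknown_roi_rejected(self, rng):
        cm = random_binary_cm(rng)
        with pytest.raises(KeyError):
            algebra.mediated_path(cm, 1, 99)


def test_variance_cm_matches_numpy(rng):
    mats = [random_binary_cm(rng, n=4) for _ in range(6)]
    stack = _stack(mats)
    got = algebra.variance_cm(stack).values
    np.testing.assert_allclose(got, np.stack([m.values for m in mats]).var(axis=0))
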