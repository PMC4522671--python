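"""Beta-metric tests against an independent brute-force implementation.

The oracle below computes every statistic with explicit double loops over
species, straight from the definitions, sharing no code with the
vectorized engine under test.
"""

import numpy as np
import pandas as pd
import pytest

from forestbeta import beta
from forestbeta.grid import CommunityMatrix, subdivide_plot
from forestbeta.io import DistanceMatrix, ValidationError

from conftest import random_delta


@pytest.fixture
def chain_delta():
    """Three species along a chain: d(A,B)=d(B,C)=2, d(A,C)=4."""
    return DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0.0, 2.0, 4.0],
                  [2.0, 0.0, 2.0],
                  [4.0, 2.0, 0.0]]),
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_dbar(i, target, delta):
    return sum(delta.loc(i, s) for s in target) / len(target)


def brute_dpw(k1, k2, delta):
    total = sum(brute_dbar(i, k2, delta) for i in k1)
    total += sum(brute_dbar(j, k1, delta) for j in k2)
    return total / (len(k1) + len(k2))


def brute_dnn(k1, k2, delta):
    total = sum(min(delta.loc(i, s) for s in k2) for i in k1)
    total += sum(min(delta.loc(j, s) for s in k1) for j in k2)
    return total / (len(k1) + len(k2))


def brute_dpw_w(k1, k2, ab1, ab2, delta):
    t1 = sum(ab1[i] * brute_dbar(i, k2, delta) for i in k1) / sum(ab1.values())
    t2 = sum(ab2[j] * brute_dbar(j, k1, delta) for j in k2) / sum(ab2.values())
    return (t1 + t2) / 2


def brute_dnn_w(k1, k2, ab1, ab2, delta):
    t1 = sum(ab1[i] * min(delta.loc(i, s) for s in k2)
             for i in k1) / sum(ab1.values())
    t2 = sum(ab2[j] * min(delta.loc(j, s) for s in k1)
             for j in k2) / sum(ab2.values())
    return (t1 + t2) / 2


# ---------------------------------------------------------------------------


class TestMeanCrossDistance:
    def test_self_only_target(self, toy_delta):
        assert beta.mean_cross_distance("A", ["A"], toy_delta) == 0.0

    def test_hand_example(self, toy_delta):
        assert beta.mean_cross_distance("A", ["B", "C"], toy_delta) == 3.0

    def test_conspecific_zero_included(self, chain_delta):
        # B -> {B, C}: (0 + 2) / 2
        assert beta.mean_cross_distance("B", ["B", "C"], chain_delta) == 1.0

    def test_unknown_species_named_in_error(self, toy_delta):
        with pytest.raises(ValidationError, match="Z"):
            beta.mean_cross_distance("Z", ["A"], toy_delta)


class TestHandExamples:
    """Worked examples, verified against the brute-force oracle."""

    def test_single_species_pair(self, toy_delta):
        assert beta.d_pw(["A"], ["B"], toy_delta) == 2.0

    def test_identical_communities_dpw(self, toy_delta):
        # mean intra-community pairwise distance, not zero
        val = beta.d_pw(["A", "B"], ["A", "B"], toy_delta)
        assert val == pytest.approx(1.0)
        assert val == pytest.approx(
            brute_dpw(["A", "B"], ["A", "B"], toy_delta))

    def test_overlapping_communities_dpw(self, chain_delta):
        val = beta.d_pw(["A", "B"], ["B", "C"], chain_delta)
        assert val == pytest.approx(2.0)

    def test_identical_communities_dnn_zero(self, toy_delta):
        assert beta.d_nn(["A", "B"], ["A", "B"], toy_delta) == 0.0

    def test_overlapping_communities_dnn(self, chain_delta):
        assert beta.d_nn(["A", "B"], ["B", "C"], chain_delta) \
            == pytest.approx(1.0)

    def test_asymmetric_sizes_dnn(self, toy_delta):
        assert beta.d_nn(["A"], ["B", "C"], toy_delta) \
            == pytest.approx(8.0 / 3.0)

    def test_weighted_dpw(self, chain_delta):
        val = beta.d_pw_weighted(["A", "B"], ["B", "C"],
                                 {"A": 3, "B": 1}, {"B": 1, "C": 1},
                                 chain_delta)
        assert val == pytest.approx(2.25)

    def test_weighted_dnn(self, chain_delta):
        val = beta.d_nn_weighted(["A", "B"], ["B", "C"],
                                 {"A": 3, "B": 1}, {"B": 1, "C": 1},
                                 chain_delta)
        assert val == pytest.approx(1.25)

    def test_equal_abundances_collapse_to_unweighted_dnn(self, chain_delta):
        w = beta.d_nn_weighted(["A", "B"], ["B", "C"],
                               {"A": 1, "B": 1}, {"B": 1, "C": 1}, chain_delta)
        assert w == pytest.approx(beta.d_nn(["A", "B"], ["B", "C"],
                                            chain_delta))

    def test_abundance_rescaling_invariance(self, chain_delta):
        a = beta.d_pw_weighted(["A", "B"], ["B", "C"],
                               {"A": 3, "B": 1}, {"B": 2, "C": 2}, chain_delta)
        b = beta.d_pw_weighted(["A", "B"], ["B", "C"],
                               {"A": 30, "B": 10}, {"B": 5, "C": 5},
                               chain_delta)
        assert a == pytest.approx(b)

    def test_empty_community_rejected(self, toy_delta):
        with pytest.raises(ValidationError):
            beta.d_pw([], ["A"], toy_delta)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_sp = int(rng.integers(2, 7))
        delta = random_delta(n_sp, rng)
        labels = delta.labels
        k1 = list(rng.choice(labels, size=rng.integers(1, n_sp + 1),
                             replace=False))
        k2 = list(rng.choice(labels, size=rng.integers(1, n_sp + 1),
                             replace=False))
        ab1 = {s: float(rng.integers(1, 9)) for s in k1}
        ab2 = {s: float(rng.integers(1, 9)) for s in k2}
        assert beta.d_pw(k1, k2, delta) == pytest.approx(
            brute_dpw(k1, k2, delta), abs=1e-12)
        assert beta.d_nn(k1, k2, delta) == pytest.approx(
            brute_dnn(k1, k2, delta), abs=1e-12)
        assert beta.d_pw_weighted(k1, k2, ab1, ab2, delta) == pytest.approx(
            brute_dpw_w(k1, k2, ab1, ab2, delta), abs=1e-12)
        assert beta.d_nn_weighted(k1, k2, ab1, ab2, delta) == pytest.approx(
            brute_dnn_w(k1, k2, ab1, ab2, delta), abs=1e-12)

    def test_monotone_response_to_delta_scaling(self, toy_delta):
        c = 3.7
        scaled = DistanceMatrix(toy_delta.labels, c * toy_delta.values)
        args = (["A", "B"], ["B", "C"])
        assert beta.d_pw(*args, scaled) == pytest.approx(
            c * beta.d_pw(*args, toy_delta))
        assert beta.d_nn(*args, scaled) == pytest.approx(
            c * beta.d_nn(*args, toy_delta))


def _community_matrix(counts, species):
    grid = subdivide_plot(10.0 * len(counts), 10.0, 10.0)
    return CommunityMatrix(grid, pd.DataFrame(
        counts, index=grid.cell_ids, columns=species))


class TestAllPairs:
    def test_three_nonempty_cells_give_three_pairs(self, toy_delta):
        cm = _community_matrix(
            [[2, 1, 0], [0, 3, 1], [1, 0, 2]], ["A", "B", "C"])
        table = beta.all_pairs(cm, toy_delta)
        assert len(table) == 3

    def test_matches_per_pair_calls(self, toy_delta):
        counts = [[2, 1, 0], [0, 3, 1]]
        cm = _community_matrix(counts, ["A", "B", "C"])
        table = beta.all_pairs(cm, toy_delta, weighted=True)
        row = table.iloc[0]
        expected_pw = beta.d_pw_weighted(["A", "B"], ["B", "C"],
                                         {"A": 2, "B": 1}, {"B": 3, "C": 1},
                                         toy_delta)
        expected_nn = beta.d_nn_weighted(["A", "B"], ["B", "C"],
                                         {"A": 2, "B": 1}, {"B": 3, "C": 1},
                                         toy_delta)
        assert row["dpw"] == pytest.approx(expected_pw, abs=1e-12)
        assert row["dnn"] == pytest.approx(expected_nn, abs=1e-12)

    def test_empty_subplots_excluded(self, toy_delta):
        cm = _community_matrix([[1, 0, 0], [0, 0, 0], [0, 2, 0]],
                               ["A", "B", "C"])
        table = beta.all_pairs(cm, toy_delta)
        assert len(table) == 1
        assert set(table[["k1", "k2"]].iloc[0]) == {"c0000", "c0002"}

    def test_engine_matrix_is_symmetric(self, rng):
        delta = random_delta(5, rng)
        counts = rng.integers(0, 4, size=(6, 5))
        counts[0] += 1  # ensure at least one non-empty
        mats = beta.pair_beta_matrices(counts, delta.values, weighted=True)
        for m in mats.values():
            ok = np.isfinite(m)
            np.testing.assert_allclose(m[ok & ok.T], m.T[ok & ok.T])
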