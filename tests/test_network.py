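"""Spearman matrices, partial correlations, connectivity, edge thresholds."""

from __future__ import annotations

import math

import numpy as np
import pytest

from symptomnet.network import (
    DegenerateColumnError,
    connectivity,
    edge_vector,
    estimate_network,
    partial_from_correlation,
    repair_correlation,
    spearman_matrix,
    threshold_edges,
)

from conftest import matrix_from_array, network_from_weights, random_pd_correlation


def residualization_partial(r: np.ndarray, i: int, j: int) -> float:
    """Independent oracle: correlate the residuals of i and j after
    least-squares projection on all remaining variables, using only the
    correlation matrix (population regression algebra)."""
    k = r.shape[0]
    rest = [m for m in range(k) if m not in (i, j)]
    if not rest:
        return r[i, j]
    r_rr = r[np.ix_(rest, rest)]
    b_i = np.linalg.solve(r_rr, r[rest, i])
    b_j = np.linalg.solve(r_rr, r[rest, j])
    var_i = 1.0 - r[rest, i] @ b_i
    var_j = 1.0 - r[rest, j] @ b_j
    cov_ij = r[i, j] - r[rest, i] @ b_j
    return cov_ij / math.sqrt(var_i * var_j)


class TestSpearmanMatrix:
    def test_identical_columns_give_one(self, rng):
        x = rng.integers(0, 7, size=(30, 9))
        x[:, 3] = x[:, 5]
        r = spearman_matrix(x)
        assert r[3, 5] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        x = np.tile(np.arange(10)[:, None], (1, 9))
        x[:, 2] = x[::-1, 0]
        r = spearman_matrix(x)
        assert r[0, 2] == pytest.approx(-1.0)

    def test_tied_ranks_hand_oracle(self):
        # columns [1,2,2,4,5] and [2,1,3,3,3]: average ranks give
        # cov 11/2, variances 19/2 and 8 => r = 5.5/sqrt(76)
        x = np.tile(np.array([[1], [2], [2], [4], [5]]), (1, 9))
        x[:, 1] = [2, 1, 3, 3, 3]
        r = spearman_matrix(x)
        assert r[0, 1] == pytest.approx(5.5 / math.sqrt(76), abs=1e-12)

    def test_constant_column_rejected(self):
        x = np.ones((10, 9), dtype=int)
        x[:, 1:] = np.arange(10)[:, None] % 7
        with pytest.raises(DegenerateColumnError, match="concentration"):
            spearman_matrix(matrix_from_array(x))


class TestPartialFromCorrelation:
    def test_identity_gives_zero_partials(self):
        p, repaired = partial_from_correlation(np.eye(5))
        assert not repaired
        assert np.allclose(p, 0.0)

    def test_equicorrelated_closed_form(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        p, _ = partial_from_correlation(r)
        off = p[np.triu_indices(3, k=1)]
        # (r - r^2) / (1 - r^2) = 1/3 exactly
        assert np.allclose(off, 1.0 / 3.0, atol=1e-12)

    def test_matches_residualization_oracle(self, rng):
        for _ in range(100):
            k = rng.integers(3, 10)
            r = random_pd_correlation(rng, k)
            p, _ = partial_from_correlation(r)
            i, j = sorted(rng.choice(k, size=2, replace=False))
            assert p[i, j] == pytest.approx(
                residualization_partial(r, i, j), abs=1e-10
            )

    def test_precision_construction_inverts(self, rng):
        # rebuilding the precision from the partials and the precision
        # diagonal recovers the original correlation matrix
        r = random_pd_correlation(rng, 6)
        p, _ = partial_from_correlation(r)
        k = np.linalg.inv(r)
        d = np.sqrt(np.diag(k))
        k_rebuilt = np.outer(d, d) * (np.eye(6) - p)
        assert np.allclose(np.linalg.inv(k_rebuilt), r, atol=1e-10)

    def test_pd_repair_flags_and_bounds(self, rng):
        # rank-deficient correlation (duplicated variable) needs repair
        a = rng.standard_normal((6, 4))
        a[:, 3] = a[:, 2]
        r = np.corrcoef(a, rowvar=False)
        p, repaired = partial_from_correlation(r)
        assert repaired
        assert np.isfinite(p).all()
        assert np.abs(p).max() <= 1.0

    def test_repair_leaves_pd_inputs_untouched(self, rng):
        r = random_pd_correlation(rng, 5)
        fixed, repaired = repair_correlation(r)
        assert not repaired
        assert fixed is r


class TestEstimateNetwork:
    def test_duplicated_sample_gives_identical_network(self, rng):
        x = rng.integers(0, 7, size=(40, 9))
        net1 = estimate_network(matrix_from_array(x))
        net2 = estimate_network(matrix_from_array(np.vstack([x, x])))
        assert np.allclose(net1.weights, net2.weights, atol=1e-12)

    def test_records_metadata(self, rng):
        x = rng.integers(0, 7, size=(25, 9))
        net = estimate_network(matrix_from_array(x, timepoint="end"))
        assert net.n == 25
        assert net.timepoint == "end"
        assert net.node_labels[0] == "concentration"

    def test_weights_bounded_and_symmetric(self, rng):
        x = rng.integers(0, 7, size=(50, 9))
        net = estimate_network(matrix_from_array(x))
        assert np.allclose(net.weights, net.weights.T)
        assert np.allclose(np.diag(net.weights), 0.0)
        assert np.abs(net.weights).max() <= 1.0
        assert not net.pd_repaired


class TestConnectivity:
    def test_zero_network(self):
        assert connectivity(network_from_weights(np.zeros((9, 9)))) == 0.0

    def test_three_node_toy(self):
        w = np.full((3, 3), 1.0 / 3.0)
        np.fill_diagonal(w, 0.0)
        assert connectivity(network_from_weights(w)) == pytest.approx(1.0, abs=1e-12)

    def test_half_sum_of_strengths(self, rng):
        w = rng.uniform(-0.3, 0.3, size=(9, 9))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = network_from_weights(w)
        assert connectivity(net) == pytest.approx(np.abs(w).sum() / 2.0)

    def test_invariant_under_relabeling(self, rng):
        w = rng.uniform(-0.3, 0.3, size=(6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        perm = rng.permutation(6)
        assert connectivity(network_from_weights(w)) == pytest.approx(
            connectivity(network_from_weights(w[np.ix_(perm, perm)]))
        )


class TestThresholdEdges:
    @pytest.mark.parametrize(
        "weight,displayed", [(0.09, False), (0.10, True), (-0.09, False), (-0.2, True)]
    )
    def test_display_boundary(self, weight, displayed):
        w = np.zeros((9, 9))
        w[0, 1] = w[1, 0] = weight
        edges = threshold_edges(network_from_weights(w), display_min=0.1)
        row = edges.table[(edges.table.node_i == "A") & (edges.table.node_j == "B")]
        assert bool(row["displayed"].iloc[0]) is displayed
        assert row["weight"].iloc[0] == weight  # thresholding never alters weights

    def test_zero_threshold_displays_all(self, rng):
        w = rng.uniform(0.01, 0.3, size=(9, 9))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        edges = threshold_edges(network_from_weights(w), display_min=0.0)
        assert len(edges.table) == 36
        assert edges.table["displayed"].all()


class TestEdgeVector:
    def test_matches_upper_triangle(self, rng):
        w = rng.uniform(-0.4, 0.4, size=(4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        v = edge_vector(network_from_weights(w))
        assert v == pytest.approx([w[0, 1], w[0, 2], w[0, 3], w[1, 2], w[1, 3], w[2, 3]])
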