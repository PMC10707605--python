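"""Validity indices against brute-force oracles; selection and vote logic."""

import math

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

from helpers_naive import NAIVE_INDEX_FUNCS, random_clustered_instance
from stainclust.clustering_eval import (
    ClusteredPoints,
    ValidityTable,
    agreement,
    c_index,
    calinski_harabasz,
    dunn,
    hartigan,
    mclain_rao,
    reference_table,
    select_optimal,
    validity_scores,
    vote,
    xie_beni,
)

TOY = ClusteredPoints(np.array([[0.0], [1.0], [10.0], [11.0]]), np.array([0, 0, 1, 1]))


class TestToyValues:
    """Hand-enumerable two-cluster line: {0,1} vs {10,11}."""

    def test_xie_beni(self):
        # compactness 4*0.25 = 1; min centroid separation^2 = 100
        assert xie_beni(TOY) == pytest.approx(1.0 / 400.0, abs=1e-12)

    def test_calinski_harabasz(self):
        assert calinski_harabasz(TOY) == pytest.approx(200.0, abs=1e-9)

    def test_c_index(self):
        # S = 2, n_w = 2, sorted distances (1,1,9,10,10,11) -> S_min=2, S_max=21
        assert c_index(TOY) == pytest.approx(0.0, abs=1e-12)

    def test_hartigan(self):
        assert hartigan(TOY) == pytest.approx(math.log(100.0), abs=1e-9)

    def test_dunn(self):
        assert dunn(TOY) == pytest.approx(9.0, abs=1e-12)

    def test_mclain_rao(self):
        assert mclain_rao(TOY) == pytest.approx(0.1, abs=1e-12)


class TestInvariances:
    def test_translation_invariance(self):
        shifted = ClusteredPoints(TOY.X + 57.0, TOY.labels)
        assert xie_beni(shifted) == pytest.approx(xie_beni(TOY), rel=1e-9)
        assert mclain_rao(shifted) == pytest.approx(mclain_rao(TOY), rel=1e-9)

    def test_scale_invariance_of_ratios(self):
        scaled = ClusteredPoints(TOY.X * 3.0, TOY.labels)
        assert calinski_harabasz(scaled) == pytest.approx(calinski_harabasz(TOY), rel=1e-9)
        assert dunn(scaled) == pytest.approx(dunn(TOY), rel=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        X, labels = random_clustered_instance(rng)
        if X.shape[1] < 2:
            X = np.column_stack([X, np.zeros(len(X))])
        theta = 0.83
        rot = np.eye(X.shape[1])
        rot[:2, :2] = [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        cp1 = ClusteredPoints(X, labels)
        cp2 = ClusteredPoints(X @ rot.T, labels)
        for fn in (xie_beni, calinski_harabasz, c_index, hartigan, dunn, mclain_rao):
            assert fn(cp2) == pytest.approx(fn(cp1), rel=1e-9)


def test_all_indices_match_naive_oracles():
    """50 random small instances, every index to 1e-9 relative."""
    rng = np.random.default_rng(123)
    for _ in range(50):
        X, labels = random_clustered_instance(rng)
        scores = validity_scores(X, labels)
        for name, fn in NAIVE_INDEX_FUNCS.items():
            assert scores[name] == pytest.approx(fn(X, labels), rel=1e-9), name


def test_calinski_harabasz_cross_check_sklearn():
    rng = np.random.default_rng(7)
    X, labels = random_clustered_instance(rng)
    assert calinski_harabasz(ClusteredPoints(X, labels)) == pytest.approx(
        calinski_harabasz_score(X, labels), rel=1e-9
    )


class TestDegenerateInputs:
    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ClusteredPoints(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ClusteredPoints(np.zeros((4, 2)), np.array([0, 0, 2, 2]))

    def test_coincident_centroids(self):
        cp = ClusteredPoints(
            np.array([[0.0, 1], [0, -1], [0, 1], [0, -1]]), np.array([0, 0, 1, 1])
        )
        with pytest.raises(ValueError):
            xie_beni(cp)

    def test_zero_within_scatter(self):
        cp = ClusteredPoints(np.array([[0.0], [0.0], [5.0], [5.0]]), np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError):
            calinski_harabasz(cp)
        with pytest.raises(ValueError):
            hartigan(cp)
        with pytest.raises(ValueError):
            dunn(cp)

    def test_duplicate_point_across_clusters_gives_zero_dunn(self):
        cp = ClusteredPoints(
            np.array([[0.0], [1.0], [1.0], [5.0]]), np.array([0, 0, 1, 1])
        )
        assert dunn(cp) == 0.0


def test_fuzzy_xie_beni_uses_squared_memberships():
    soft = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
    cp = ClusteredPoints(TOY.X, TOY.labels, soft)
    crisp = xie_beni(cp)
    fuzzy = xie_beni(cp, use_soft=True)
    assert fuzzy != pytest.approx(crisp)
    # brute-force fuzzy compactness with crisp centroids
    v = cp.centroids()
    compact = sum(
        soft[i, k] ** 2 * (TOY.X[i, 0] - v[k, 0]) ** 2
        for i in range(4)
        for k in range(2)
    )
    assert fuzzy == pytest.approx(compact / (4 * 100.0), rel=1e-9)


class TestSelectionAndVote:
    def test_reference_per_index_choices(self):
        opt = select_optimal(reference_table())
        expected = {
            "xie_beni:128": 14, "calinski_harabasz:128": 14, "c_index:128": 14,
            "hartigan:128": 15, "dunn:128": 13, "mclain_rao:128": 15,
            "xie_beni:64": 13, "calinski_harabasz:64": 11, "c_index:64": 17,
            "hartigan:64": 14, "dunn:64": 14, "mclain_rao:64": 14,
        }
        assert opt["optimum"].to_dict() == expected
        assert not opt["tied"].any()

    def test_reference_vote_is_fourteen(self):
        mode, counts = vote(select_optimal(reference_table()))
        assert mode == 14
        assert counts[14] == 6
        assert sum(counts.values()) == 12

    def test_single_row_table(self):
        t = ValidityTable.from_scores({5: {"dunn": 1.0, "c_index": 0.4}})
        opt = select_optimal(t)
        assert (opt["optimum"] == 5).all()

    def test_ties_go_to_smallest_and_are_flagged(self):
        t = ValidityTable.from_scores({3: {"dunn": 1.0}, 4: {"dunn": 1.0}})
        opt = select_optimal(t)
        assert opt.loc["dunn", "optimum"] == 3
        assert bool(opt.loc["dunn", "tied"])

    def test_vote_counts_conserved(self):
        t = ValidityTable.from_scores(
            {3: {"dunn": 1.0, "c_index": 0.1}, 4: {"dunn": 2.0, "c_index": 0.5}}
        )
        _, counts = vote(select_optimal(t))
        assert sum(counts.values()) == 2

    def test_unknown_index_column_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            ValidityTable(pd.DataFrame({"bogus": [1.0]}, index=[3]))


class TestAgreement:
    def test_identical_labelings(self):
        labels = np.array([0, 1, 2, 0, 1, 2])
        ari, nmi = agreement(labels, labels)
        assert ari == 1.0 and nmi == pytest.approx(1.0)

    def test_permutation_invariance(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        permuted = np.array([2, 2, 0, 0, 1, 1])
        ari, nmi = agreement(permuted, truth)
        assert ari == 1.0 and nmi == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 4, size=3000)
        rand = rng.integers(0, 4, size=3000)
        ari, _ = agreement(rand, truth)
        assert abs(ari) < 0.05
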