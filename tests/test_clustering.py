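"""Longitudinal K-means: Lloyd correctness, quality scores, profiling."""
import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from actitraj.clustering import (assignment_agreement, kmeans_longitudinal,
                                 partition_quality, profile_clusters, select_k)


def _mat(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(ids, name="participant_id"),
                      columns=range(1, values.shape[1] + 1))
    df.columns.name = "day"
    return df


def brute_force_wcss(x: np.ndarray, k: int) -> float:
    """Exhaustive minimum within-cluster SS over all k-labelings."""
    n = x.shape[0]
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        if len(np.unique(labels)) < k:
            continue
        w = 0.0
        for j in range(k):
            m = x[labels == j]
            w += ((m - m.mean(axis=0)) ** 2).sum()
        best = min(best, w)
    return best


class TestKmeans:
    def test_k1_centroid_is_grand_mean(self):
        mat = _mat(np.arange(12).reshape(4, 3))
        m = kmeans_longitudinal(mat, 1, n_starts=3, seed=0)
        np.testing.assert_allclose(m.centroids[0], mat.to_numpy().mean(axis=0))
        assert m.wcss == pytest.approx(
            ((mat.to_numpy() - mat.to_numpy().mean(0)) ** 2).sum())

    def test_separable_levels_recovered_exactly(self):
        rng = np.random.default_rng(0)
        x = np.vstack([np.full((5, 10), 5.0), np.full((5, 10), 50.0)])
        x += rng.normal(0, 0.1, x.shape)
        m = kmeans_longitudinal(_mat(x), 2, n_starts=5, seed=1)
        assert list(m.assignments[:5]) == [0] * 5
        assert list(m.assignments[5:]) == [1] * 5
        assert m.within_dispersion < 1.0

    def test_labels_ordered_by_activity_level(self):
        rng = np.random.default_rng(1)
        levels = [40.0, 5.0, 20.0]
        x = np.vstack([np.full((4, 8), lv) + rng.normal(0, 0.2, (4, 8))
                       for lv in levels])
        m = kmeans_longitudinal(_mat(x), 3, n_starts=10, seed=2)
        grand = m.centroids.mean(axis=1)
        assert np.all(np.diff(grand) > 0)
        assert set(m.assignments[:4]) == {2}   # the 40-level block is highest
        assert set(m.assignments[4:8]) == {0}  # the 5-level block is lowest

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_longitudinal(_mat(np.ones((3, 4))), 4)

    def test_matches_bruteforce_partition_optimum(self):
        rng = np.random.default_rng(7)
        hits = 0
        for seed in range(20):
            x = rng.normal(0, 1, (8, 5)) + rng.choice([0.0, 4.0], (8, 1))
            mat = _mat(x)
            m = kmeans_longitudinal(mat, 2, n_starts=20, seed=seed)
            assert m.wcss >= brute_force_wcss(x, 2) - 1e-9
            hits += abs(m.wcss - brute_force_wcss(x, 2)) < 1e-6
        assert hits >= 19  # multi-start Lloyd attains the global optimum

    def test_available_case_distance_ignores_missing(self):
        x = np.vstack([np.full((4, 6), 5.0), np.full((4, 6), 50.0)])
        x[0, :3] = np.nan
        x[5, 4] = np.nan
        m = kmeans_longitudinal(_mat(x), 2, n_starts=5, seed=3)
        assert list(m.assignments[:4]) == [0] * 4
        assert list(m.assignments[4:]) == [1] * 4

    def test_wcss_agrees_with_sklearn_on_complete_data(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (40, 12)) + rng.choice([0, 6], (40, 1))
        ours = kmeans_longitudinal(_mat(x), 2, n_starts=20, seed=4)
        sk = KMeans(n_clusters=2, n_init=20, random_state=0).fit(x)
        assert ours.wcss == pytest.approx(sk.inertia_, rel=1e-6)


class TestQuality:
    def test_perfect_separation_gives_infinite_criterion(self):
        x = np.vstack([np.full((3, 4), 1.0), np.full((3, 4), 9.0)])
        m = kmeans_longitudinal(_mat(x), 2, n_starts=2, seed=0)
        b, w, ch = partition_quality(m, _mat(x))
        assert w == 0.0 and np.isinf(ch) and b > 0

    def test_identical_participants_zero_between(self):
        x = np.full((6, 4), 3.0)
        m = kmeans_longitudinal(_mat(x), 2, n_starts=2, seed=0)
        b, w, ch = partition_quality(m, _mat(x))
        assert b == pytest.approx(0.0)

    def test_k1_criterion_undefined(self):
        m = kmeans_longitudinal(_mat(np.arange(8).reshape(4, 2)), 1)
        assert m.calinski_harabasz is None

    def test_matches_sklearn_calinski_harabasz(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (30, 6)) + rng.choice([0, 5], (30, 1))
        m = kmeans_longitudinal(_mat(x), 2, n_starts=10, seed=1)
        ours = m.calinski_harabasz
        theirs = calinski_harabasz_score(x, m.assignments.to_numpy())
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_three_separated_classes_peak_at_k3(self):
        # Three equally spaced, well-populated, tight trajectory levels:
        # the canonical situation in which the criterion recovers k=3.
        # (With a dominant single gap, or a near-empty class, the ratio
        # legitimately prefers the two-cluster split.)
        from actitraj.synthetic import CohortSpec, simulate_daily_features
        from actitraj.patterns import impute_missing_days
        wins = 0
        for rep in range(5):
            spec = CohortSpec(n_participants=120,
                              class_proportions=(1 / 3, 1 / 3, 1 / 3),
                              class_mvpa_means=(5.0, 30.0, 55.0),
                              mvpa_log_sd=0.1, mvpa_daily_log_sd=0.1,
                              dropout_prob=0.0, seed=100 + rep)
            day, _ = simulate_daily_features(spec)
            piv = day.pivot(index="participant_id", columns="day",
                            values="mvpa_minutes").reindex(columns=range(1, 91))
            imp = impute_missing_days(piv)
            _, tbl = select_k(imp, [2, 3, 4], n_starts=5, seed=rep)
            best = tbl.loc[tbl.calinski_harabasz.idxmax(), "k"]
            wins += best == 3
        assert wins >= 4


class TestSelectK:
    def test_single_k1_returned_by_default(self):
        m, tbl = select_k(_mat(np.arange(10).reshape(5, 2)), [1])
        assert m.k == 1 and m.calinski_harabasz is None

    def test_separable_two_level_selects_k2(self):
        rng = np.random.default_rng(3)
        x = np.vstack([np.full((6, 8), 5.0), np.full((6, 8), 50.0)])
        x += rng.normal(0, 0.5, x.shape)
        m, _ = select_k(_mat(x), range(1, 5), n_starts=10, seed=0)
        assert m.k == 2

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_k(_mat(np.ones((3, 3))), [])


class TestProfilesAndAgreement:
    def _cov(self, ids):
        return pd.DataFrame({
            "participant_id": ids,
            "group": ["RA" if i % 2 else "axSpA" for i in range(len(ids))],
            "ptga": np.linspace(1, 5, len(ids)),
            "bmi": np.linspace(22, 30, len(ids)),
        })

    def test_sizes_and_proportions(self):
        x = np.vstack([np.full((6, 5), 2.0), np.full((4, 5), 30.0)])
        mat = _mat(x)
        m = kmeans_longitudinal(mat, 2, n_starts=3, seed=0)
        summary = pd.DataFrame({"participant_id": mat.index,
                                "mvpa_minutes": x.mean(axis=1)})
        prof = profile_clusters(m, summary, self._cov(list(mat.index)))
        assert prof["n"].tolist() == [6, 4]
        assert prof["proportion"].sum() == pytest.approx(1.0)
        assert prof.loc[0, "label"] == "low"

    def test_single_cluster_proportion_one(self):
        mat = _mat(np.ones((5, 4)))
        m = kmeans_longitudinal(mat, 1)
        summary = pd.DataFrame({"participant_id": mat.index, "mvpa_minutes": 1.0})
        prof = profile_clusters(m, summary, self._cov(list(mat.index)))
        assert prof["proportion"].tolist() == [1.0]

    def test_missing_covariate_participant_named(self):
        mat = _mat(np.ones((4, 3)))
        m = kmeans_longitudinal(mat, 1)
        summary = pd.DataFrame({"participant_id": mat.index, "mvpa_minutes": 1.0})
        with pytest.raises(KeyError, match="P3"):
            profile_clusters(m, summary, self._cov(["P0", "P1", "P2"]))

    def test_agreement_invariant_to_label_permutation(self):
        ids = [f"P{i}" for i in range(10)]
        a = pd.Series([0] * 5 + [1] * 5, index=ids)
        b = pd.Series([1] * 5 + [0] * 5, index=ids)
        assert assignment_agreement(a, b) == 1.0
        c = pd.Series([1] * 5 + [0] * 4 + [1], index=ids)
        assert assignment_agreement(a, c) == pytest.approx(0.9)
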