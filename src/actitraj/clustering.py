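"""K-means for longitudinal trajectories (kml-style).

Each participant contributes one 90-day trajectory of a daily activity
feature; trajectories are partitioned by Lloyd's algorithm with plain
Euclidean distance on the whole vector, multi-started, and the partition
count can be chosen by the Calinski-Harabasz criterion (highest
between-cluster dispersion relative to within-cluster dispersion).

Matrices with missing days are handled kml-fashion: distances average
over the observed entries of each trajectory and centroids are per-day
means over the members observed that day, so the same code clusters both
imputed (complete) and available-case matrices.

Cluster labels are canonical: clusters are relabelled by ascending
centroid grand mean, so cluster 0 is always the lowest-activity cluster.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    """A fitted longitudinal K-means partition."""

    k: int
    assignments: pd.Series        # participant_id -> label 0..k-1 (0 = lowest)
    centroids: np.ndarray         # (k, n_days)
    wcss: float                   # total within-cluster sum of squares
    between_dispersion: float
    within_dispersion: float
    calinski_harabasz: float | None
    n_starts: int
    seed: int | None
    n_iterations: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "assignments": {k: int(v) for k, v in self.assignments.items()},
            "centroids": self.centroids.tolist(),
            "wcss": self.wcss,
            "between_dispersion": self.between_dispersion,
            "within_dispersion": self.within_dispersion,
            "calinski_harabasz": self.calinski_harabasz,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "n_iterations": self.n_iterations,
        }


def _distances(x: np.ndarray, obs: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Mean squared deviation over observed entries, participants x k."""
    d = np.empty((x.shape[0], centroids.shape[0]))
    n_obs = obs.sum(axis=1)
    xz = np.where(obs, x, 0.0)
    for j, c in enumerate(centroids):
        diff = np.where(obs, xz - c, 0.0)
        d[:, j] = (diff * diff).sum(axis=1) / n_obs
    return d


def _lloyd(
    x: np.ndarray, obs: np.ndarray, init: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One Lloyd run; returns (labels, centroids, wcss, n_iter)."""
    k = init.shape[0]
    centroids = init.copy()
    labels = np.full(x.shape[0], -1)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = _distances(x, obs, centroids)
        new_labels = d.argmin(axis=1)  # ties -> lowest index
        for j in range(k):
            members = new_labels == j
            if not members.any():
                far = d.min(axis=1).argmax()
                logger.info("empty cluster %d reseeded from farthest trajectory %d", j, far)
                new_labels[far] = j
                members = new_labels == j
            cnt = obs[members].sum(axis=0)
            csum = np.where(obs[members], x[members], 0.0).sum(axis=0)
            with np.errstate(invalid="ignore"):
                c = np.where(cnt > 0, csum / np.maximum(cnt, 1), np.nan)
            if np.isnan(c).any():  # no member observed on some day
                c = np.where(np.isnan(c), np.nanmean(np.where(obs[members], x[members], np.nan)), c)
            centroids[j] = c
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    d = _distances(x, obs, centroids)
    wcss = float((d[np.arange(len(labels)), labels] * obs.sum(axis=1)).sum())
    return labels, centroids, wcss, n_iter


def kmeans_longitudinal(
    matrix: pd.DataFrame,
    k: int,
    n_starts: int = 20,
    max_iter: int = 200,
    seed: int | None = None,
) -> ClusterModel:
    """Multi-start Lloyd K-means on whole trajectories.

    ``matrix`` is participants x days; NaN cells are treated as
    unobserved (available-case distances).  The best of ``n_starts``
    random initialisations (distinct participants as seed centroids) by
    total within-cluster sum of squares is kept; deterministic for a
    fixed ``seed``.
    """
    x = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} participants available")
    if n == 0:
        raise ValueError("cannot cluster an empty matrix")
    if (obs.sum(axis=1) == 0).any():
        bad = matrix.index[obs.sum(axis=1) == 0][0]
        raise ValueError(f"participant {bad!r} has no observed days")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, int] | None = None
    for _ in range(n_starts):
        idx = rng.choice(n, size=k, replace=False)
        init = np.where(obs[idx], x[idx], np.nanmean(x))
        labels, centroids, wcss, n_iter = _lloyd(x, obs, init, max_iter)
        if best is None or wcss < best[0] - 1e-12:
            best = (wcss, labels, centroids, n_iter)
    wcss, labels, centroids, n_iter = best

    order = np.argsort(centroids.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centroids = centroids[order]

    model = ClusterModel(
        k=k,
        assignments=pd.Series(labels, index=matrix.index, name="cluster"),
        centroids=centroids,
        wcss=wcss,
        between_dispersion=0.0,
        within_dispersion=0.0,
        calinski_harabasz=None,
        n_starts=n_starts,
        seed=seed,
        n_iterations=n_iter,
    )
    b, w, ch = partition_quality(model, matrix)
    model.between_dispersion, model.within_dispersion, model.calinski_harabasz = b, w, ch
    return model


def partition_quality(
    model: ClusterModel, matrix: pd.DataFrame
) -> tuple[float, float, float | None]:
    """Between- and within-cluster dispersion and the Calinski-Harabasz ratio.

    B = sum_c n_c ||c_c - grand||^2, W = total within-cluster sum of
    squares; the criterion is (B/(k-1)) / (W/(n-k)), higher meaning
    better-separated, more compact clusters.  Undefined (None) at k=1,
    and infinite when W = 0 with k > 1.
    """
    x = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    labels = model.assignments.to_numpy()
    n, k = x.shape[0], model.k
    grand = np.nanmean(np.where(obs, x, np.nan), axis=0)
    b = 0.0
    w = 0.0
    for j in range(k):
        members = labels == j
        if not members.any():
            continue
        b += members.sum() * float(np.nansum((model.centroids[j] - grand) ** 2))
        diff = np.where(obs[members], x[members] - model.centroids[j], 0.0)
        w += float((diff * diff).sum())
    if k == 1 or n <= k:
        return b, w, None
    if w == 0.0:
        return b, w, float("inf")
    return b, w, (b / (k - 1)) / (w / (n - k))


def select_k(
    matrix: pd.DataFrame,
    k_range: Sequence[int],
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 200,
) -> tuple[ClusterModel, pd.DataFrame]:
    """Fit each k in ``k_range`` and keep the Calinski-Harabasz maximiser.

    Returns (best model, score table).  k values whose criterion is
    undefined (k=1) only win when no other candidate exists.
    """
    if len(k_range) == 0:
        raise ValueError("k_range must be non-empty")
    rows = []
    models = {}
    for k in sorted(set(int(k) for k in k_range)):
        m = kmeans_longitudinal(matrix, k, n_starts=n_starts, max_iter=max_iter, seed=seed)
        models[k] = m
        rows.append({"k": k, "wcss": m.wcss, "between": m.between_dispersion,
                     "within": m.within_dispersion,
                     "calinski_harabasz": m.calinski_harabasz})
    table = pd.DataFrame(rows)
    defined = table.dropna(subset=["calinski_harabasz"])
    if len(defined) == 0:
        best_k = int(table["k"].iloc[0])
    else:
        best_k = int(defined.loc[defined["calinski_harabasz"].idxmax(), "k"])
    logger.info("select_k chose k=%d\n%s", best_k, table.to_string(index=False))
    return models[best_k], table


def profile_clusters(
    model: ClusterModel,
    summary: pd.DataFrame,
    covariates: pd.DataFrame,
    feature: str = "mvpa_minutes",
) -> pd.DataFrame:
    """Per-cluster sizes, proportions, feature mean (SD) and covariate summaries.

    ``summary`` is the participant_summary table; ``covariates`` the
    cohort covariate table.  Disease-activity style covariates present in
    the table (``ptga``) are summarised per cluster.  Cluster 0 is the
    low-activity cluster by construction.
    """
    assigned = model.assignments
    missing = assigned.index.difference(pd.Index(covariates["participant_id"]))
    if len(missing) > 0:
        raise KeyError(f"participant {missing[0]!r} missing from covariate table")
    df = (summary.set_index("participant_id")
          .join(assigned, how="inner")
          .join(covariates.set_index("participant_id"), how="left"))
    rows = []
    n_total = len(df)
    for j in range(model.k):
        sub = df[df["cluster"] == j]
        row = {
            "cluster": j,
            "label": "low" if j == 0 else ("high" if j == model.k - 1 and model.k > 1 else f"level_{j}"),
            "n": len(sub),
            "proportion": len(sub) / n_total if n_total else np.nan,
            f"{feature}_mean": sub[feature].mean(),
            f"{feature}_sd": sub[feature].std(ddof=1),
        }
        if "group" in sub.columns:
            row["n_RA"] = int((sub["group"] == "RA").sum())
            row["n_axSpA"] = int((sub["group"] == "axSpA").sum())
        if "ptga" in sub.columns:
            row["ptga_mean"] = sub["ptga"].mean()
            row["ptga_sd"] = sub["ptga"].std(ddof=1)
        if "bmi" in sub.columns:
            row["bmi_mean"] = sub["bmi"].mean()
            row["bmi_sd"] = sub["bmi"].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def assignment_agreement(a: pd.Series, b: pd.Series) -> float:
    """Fraction of participants on which two partitions agree, after
    matching b's labels to a's by greedy maximum overlap."""
    common = a.index.intersection(b.index)
    av, bv = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    labels_a, labels_b = np.unique(av), np.unique(bv)
    overlap = np.array([[np.sum((bv == lb) & (av == la)) for lb in labels_b]
                        for la in labels_a])
    mapping = {}
    used = set()
    for _ in range(min(len(labels_a), len(labels_b))):
        i, j = np.unravel_index(np.argmax(overlap), overlap.shape)
        mapping[labels_b[j]] = labels_a[i]
        overlap[i, :] = -1
        overlap[:, j] = -1
    mapped = np.array([mapping.get(v, -999) for v in bv])
    return float((mapped == av).mean())
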