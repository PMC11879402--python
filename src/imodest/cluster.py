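"""Cluster genes on their 63 per-spec PRESS R² scores and label clusters
by their dominant regulator classes.

Genes are clustered per cohort with Ward-linkage agglomerative clustering
on Euclidean distance (deterministic; a seeded k-means mode exists behind
a flag).  Candidate cluster counts are scored by the Dunn index (higher is
better: smallest between-cluster distance over largest within-cluster
diameter) and connectivity (lower is better: for each gene, its L nearest
neighbors assigned to a different cluster contribute 1/rank).  Each
cluster is labeled with every class whose mean predictive gain over member
genes reaches at least half of the top class's mean gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .regulators import CLASS_ORDER, class_index, enumerate_models

DIAMETER_FLOOR = np.finfo(float).eps


def cluster_features(ensembles_by_cohort: dict, score: str = "deflated"
                     ) -> tuple[dict, list]:
    """Per cohort: genes x 63 matrix of per-spec scores, restricted to
    genes modelable (all specs fitted) in every cohort.

    Returns (cohort -> DataFrame, excluded gene list).
    """
    specs = enumerate_models()
    labels = [s.label for s in specs]
    usable = None
    per_cohort_scores = {}
    for cohort, ensembles in ensembles_by_cohort.items():
        scores = {}
        for ens in ensembles:
            vals = [ens.press(s, score) for s in specs]
            if any(v is None for v in vals):
                continue
            scores[ens.gene] = vals
        per_cohort_scores[cohort] = scores
        genes = set(scores)
        usable = genes if usable is None else usable & genes
    if not usable:
        raise ValueError("no gene is modelable in every cohort")
    all_genes = set()
    for scores in per_cohort_scores.values():
        all_genes |= set(scores)
    excluded = sorted(all_genes - usable)
    out = {}
    for cohort, scores in per_cohort_scores.items():
        genes = sorted(usable)
        out[cohort] = pd.DataFrame([scores[g] for g in genes],
                                   index=genes, columns=labels)
    return out, excluded


def connectivity(X: np.ndarray, labels: np.ndarray, L: int = 10) -> float:
    """clValid-style connectivity: sum over items of 1/j for each of its
    L nearest neighbors (rank j) lying in a different cluster."""
    X = np.asarray(X, float)
    n = len(X)
    L = min(L, n - 1)
    D = squareform(pdist(X))
    total = 0.0
    for i in range(n):
        order = np.argsort(D[i], kind="stable")
        order = order[order != i][:L]
        for j, nb in enumerate(order, start=1):
            if labels[nb] != labels[i]:
                total += 1.0 / j
    return total


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """min between-cluster point distance / max within-cluster diameter
    (singleton diameters floored at machine epsilon)."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    D = squareform(pdist(X))
    min_between = np.inf
    max_diam = DIAMETER_FLOOR
    for a in range(len(uniq)):
        ia = np.where(labels == uniq[a])[0]
        if len(ia) > 1:
            max_diam = max(max_diam, D[np.ix_(ia, ia)].max())
        for b in range(a + 1, len(uniq)):
            ib = np.where(labels == uniq[b])[0]
            min_between = min(min_between, D[np.ix_(ia, ib)].min())
    return float(min_between / max_diam)


def cluster_genes(features: pd.DataFrame, k: int, method: str = "ward",
                  seed: int = 0) -> pd.Series:
    """Cluster genes into k groups; Ward hierarchical by default (fully
    deterministic), seeded k-means behind method='kmeans'."""
    n = len(features)
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} genes")
    X = features.to_numpy(float)
    if method == "ward":
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif method == "kmeans":
        from scipy.cluster.vq import kmeans2
        _, labels = kmeans2(X, k, seed=seed, minit="++")
        labels = labels + 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return pd.Series(labels, index=features.index, name="cluster")


def select_k(features: pd.DataFrame, k_candidates, method: str = "ward",
             L: int = 10, seed: int = 0):
    """Evaluate candidate cluster counts; the chosen k maximizes the Dunn
    index with minimum connectivity as the tie-breaker.

    Returns (metrics DataFrame, chosen k).  Candidates < 2 or > n-1 are
    skipped with a reason.
    """
    X = features.to_numpy(float)
    n = len(features)
    rows = []
    for k in k_candidates:
        if k < 2 or k > n - 1:
            rows.append((k, np.nan, np.nan, "skipped: k out of range"))
            continue
        labels = cluster_genes(features, k, method, seed).to_numpy()
        rows.append((k, connectivity(X, labels, L), dunn_index(X, labels),
                     ""))
    metrics = pd.DataFrame(rows, columns=["k", "connectivity", "dunn",
                                          "note"])
    ok = metrics.dropna(subset=["dunn"])
    if ok.empty:
        raise ValueError("no evaluable k candidate")
    best = ok.sort_values(["dunn", "connectivity"],
                          ascending=[False, True]).iloc[0]
    return metrics, int(best["k"])


@dataclass
class ClusterResult:
    """Assignments plus per-cluster regulator labels for one cohort."""

    cohort_id: str
    k: int
    assignments: pd.Series            # gene -> cluster id
    labels: dict                      # cluster id -> tuple of classes
    metrics: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cohort": self.cohort_id,
            "gene": self.assignments.index,
            "cluster": self.assignments.to_numpy(),
            "label": [";".join(self.labels[c])
                      for c in self.assignments.to_numpy()],
        })


def label_clusters(assignments: pd.Series, gains: pd.DataFrame,
                   cohort_id: str = "cohort", half_fraction: float = 0.5,
                   metrics: pd.DataFrame | None = None) -> ClusterResult:
    """Label each cluster with the classes driving its genes.

    Per cluster: mean gain per class over member genes; the label contains
    the top class and every class whose mean gain is positive and at least
    ``half_fraction`` of the top's, ordered by descending mean gain (ties
    broken by canonical class order).  Clusters whose every mean gain is
    <= 0 get the label ("none",).
    """
    if {"class", "gain"} <= set(gains.columns):      # long format
        gm = gains.pivot_table(index="gene", columns="class", values="gain",
                               aggfunc="first")
    else:                                            # already genes x classes
        gm = gains
    gm = gm.reindex(columns=[c for c in CLASS_ORDER if c in gm.columns])
    labels = {}
    for cid in sorted(assignments.unique()):
        members = assignments.index[assignments == cid]
        means = gm.loc[gm.index.intersection(members)].mean()
        if means.empty or (means <= 0).all() or means.isna().all():
            labels[cid] = ("none",)
            continue
        top = means.max()
        chosen = [c for c in means.index
                  if means[c] > 0 and means[c] >= half_fraction * top]
        chosen.sort(key=lambda c: (-means[c], class_index(c)))
        labels[cid] = tuple(chosen)
    k = assignments.nunique()
    return ClusterResult(cohort_id=cohort_id, k=k, assignments=assignments,
                         labels=labels, metrics=metrics)


def merge_across_cohorts(results) -> pd.DataFrame:
    """Group labeled clusters across cohorts by their (unordered) label
    set: per (label set, cohort) gene counts, log10 counts, and the
    per-label mean count over cohorts."""
    rows = []
    for res in results:
        counts = res.assignments.value_counts()
        for cid, cnt in counts.items():
            label_set = ";".join(sorted(res.labels[cid]))
            rows.append((label_set, res.cohort_id, int(cnt)))
    df = pd.DataFrame(rows, columns=["label", "cohort", "n_genes"])
    df = df.groupby(["label", "cohort"], as_index=False)["n_genes"].sum()
    df["log10_n_genes"] = np.log10(df["n_genes"])
    mean_per_label = df.groupby("label")["n_genes"].mean() \
        .rename("mean_n_genes")
    return df.merge(mean_per_label, on="label")
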