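"""Scoring of phenotypic distance metrics.

All evaluations treat smaller distance as "more similar": the positive
class is the same-drug pair and the ranking score is the negated distance,
so AUROC equals the probability that a random positive pair has smaller
distance than a random negative pair (ties counted half — the normalized
Mann-Whitney U statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import precision_recall_curve, roc_curve

from .distances import DistanceMatrix

__all__ = [
    "PairScoreSet",
    "ReplicateIDCurve",
    "mann_whitney_auroc",
    "roc_auc",
    "prc_auc",
    "knn_classify",
    "replicate_identification",
    "behaviorome_map",
    "mean_traces_by_treatment",
]


@dataclass
class PairScoreSet:
    """Distances and same/different labels for a set of scored pairs."""

    distances: np.ndarray
    labels: np.ndarray        # 1 = same (positive), 0 = different
    metric: str = ""

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.distances.shape != self.labels.shape:
            raise ValueError("one score per pair required")
        if not np.all(np.isfinite(self.distances)):
            raise ValueError("non-finite pair distances")


@dataclass
class ReplicateIDCurve:
    """counts[k-1] = number of drugs with >= k same-drug replicates found
    in the top-N neighbor lists (max over the drug's own wells)."""

    counts: np.ndarray
    top_n: int
    metric: str = ""


def _check_two_classes(labels: np.ndarray):
    if len(np.unique(labels)) < 2:
        raise ValueError("need both positive and negative pairs")


def mann_whitney_auroc(distances: np.ndarray, labels: np.ndarray) -> float:
    """AUROC of −distance as a score for the positive (same) class.

    Computed from the rank-sum form of the Mann-Whitney U statistic with
    midranks for ties.
    """
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    ranks = rankdata(-distances)          # higher score = smaller distance
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: PairScoreSet) -> tuple[pd.DataFrame, float]:
    """(ROC curve as a DataFrame with fpr/tpr/threshold, AUROC)."""
    _check_two_classes(scores.labels)
    fpr, tpr, thr = roc_curve(scores.labels, -scores.distances)
    auc = mann_whitney_auroc(scores.distances, scores.labels)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def prc_auc(scores: PairScoreSet) -> tuple[pd.DataFrame, float]:
    """(PR curve, area by the step interpolation sum_i (R_i - R_{i-1}) P_i)."""
    _check_two_classes(scores.labels)
    precision, recall, thr = precision_recall_curve(scores.labels, -scores.distances)
    # precision_recall_curve returns decreasing recall; step-integrate
    area = float(-np.sum(np.diff(recall) * precision[:-1]))
    curve = pd.DataFrame({"precision": precision, "recall": recall})
    return curve, area


def knn_classify(dmat: DistanceMatrix, drug_labels: dict[str, str] | list[str],
                 k: int = 15, replicate_split: tuple[int, int] = (8, 2),
                 seed: int = 0) -> dict:
    """k-nearest-neighbor drug identification over a replicate distance matrix.

    Per drug, ``replicate_split`` wells go to train/validation (seeded).
    Each validation well is assigned the majority drug among its k nearest
    training wells; ties break by smaller summed distance, then by
    lexicographic drug id.  Note k may exceed a drug's training replicate
    count, in which case neighbors necessarily pool across drugs.
    """
    if isinstance(drug_labels, dict):
        labels = np.array([drug_labels[i] for i in dmat.ids])
    else:
        labels = np.asarray(drug_labels)
    n_train, n_val = replicate_split
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for drug in np.unique(labels):
        idxs = np.flatnonzero(labels == drug)
        if len(idxs) < n_train + n_val:
            raise ValueError(f"drug {drug!r} has {len(idxs)} replicates, "
                             f"needs >= {n_train + n_val}")
        perm = rng.permutation(idxs)
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:n_train + n_val])
    train_idx = np.array(sorted(train_idx))
    val_idx = np.array(sorted(val_idx))
    if k > len(train_idx):
        raise ValueError(f"k={k} exceeds training set size {len(train_idx)}")

    per_drug_hits: dict[str, list[int]] = {d: [] for d in np.unique(labels)}
    for v in val_idx:
        dists = dmat.values[v, train_idx]
        order = np.argsort(dists, kind="stable")[:k]
        neigh_labels = labels[train_idx[order]]
        neigh_dists = dists[order]
        votes: dict[str, tuple[int, float]] = {}
        for lab, dist in zip(neigh_labels, neigh_dists):
            cnt, s = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, s + dist)
        best = sorted(votes.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))[0][0]
        per_drug_hits[labels[v]].append(int(best == labels[v]))
    per_drug = {d: float(np.mean(h)) if h else np.nan for d, h in per_drug_hits.items()}
    overall = float(np.mean([x for h in per_drug_hits.values() for x in h]))
    return {"per_drug_accuracy": per_drug, "overall_accuracy": overall,
            "k": k, "replicate_split": replicate_split}


def replicate_identification(dmat: DistanceMatrix, wells: pd.DataFrame,
                             top_n: int = 50, aggregate: str = "max") -> ReplicateIDCurve:
    """Cumulative curve of drugs by number of replicates recovered in the
    top-N most similar wells (self excluded).

    Per drug the per-well counts are aggregated with ``max`` (default) or
    ``mean`` (rounded down) over the drug's own wells.
    """
    n = dmat.values.shape[0]
    if top_n >= n:
        raise ValueError(f"top_n={top_n} must be smaller than well count {n}")
    treatments = wells["treatment_id"].to_numpy()
    roles = wells["role"].to_numpy()
    drug_mask = roles == "drug"
    drugs = sorted(np.unique(treatments[drug_mask]))
    per_drug = {}
    for drug in drugs:
        idxs = np.flatnonzero((treatments == drug) & drug_mask)
        counts = []
        for i in idxs:
            d = dmat.values[i].copy()
            d[i] = np.inf
            top = np.argsort(d, kind="stable")[:top_n]
            counts.append(int(np.sum((treatments[top] == drug) & drug_mask[top])))
        if aggregate == "max":
            per_drug[drug] = max(counts)
        elif aggregate == "mean":
            per_drug[drug] = int(np.floor(np.mean(counts)))
        else:
            raise ValueError(f"unknown aggregate {aggregate!r}")
    max_rep = max(per_drug.values()) if per_drug else 0
    ks = np.arange(1, max(max_rep, 1) + 1)
    counts = np.array([sum(v >= k for v in per_drug.values()) for k in ks])
    return ReplicateIDCurve(counts=counts, top_n=top_n, metric=dmat.metric)


def mean_traces_by_treatment(traces: np.ndarray, wells: pd.DataFrame,
                             roles: tuple[str, ...] = ("drug",)) -> tuple[np.ndarray, list[str]]:
    """Element-wise mean trace per treatment for the given roles."""
    mask = wells["role"].isin(roles).to_numpy()
    treatments = wells["treatment_id"].to_numpy()
    ids = sorted(np.unique(treatments[mask]))
    means = np.stack([traces[(treatments == t) & mask].mean(axis=0) for t in ids])
    return means, ids


def plot_pair_separation(scores: PairScoreSet, path, bins: int = 40):
    """Histogram of positive vs. negative pair distances (PNG/SVG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(scores.distances[scores.labels == 1], bins=bins, alpha=0.6,
            label="same drug", density=True)
    ax.hist(scores.distances[scores.labels == 0], bins=bins, alpha=0.6,
            label="different drugs", density=True)
    ax.set_xlabel(f"{scores.metric or 'phenotypic'} distance")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_curve(curve: pd.DataFrame, x: str, y: str, path, label: str = "",
               baseline: str | None = None):
    """Line plot for ROC/PRC, replicate-ID or enrichment curve tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(curve[x], curve[y], label=label or y)
    if baseline is not None and baseline in curve:
        ax.plot(curve[x], curve[baseline], "--", color="gray", label="baseline")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def behaviorome_map(dmat: DistanceMatrix, n_neighbors: int = 10,
                    min_dist: float = 0.1, seed: int = 0,
                    embedder=None) -> pd.DataFrame:
    """2-D layout of compounds from a precomputed phenotypic distance matrix.

    Defaults to UMAP on the precomputed matrix; any callable with signature
    ``(distance_values, seed) -> (n, 2) array`` may be plugged in instead.
    """
    n = dmat.values.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need >= {n_neighbors + 1} compounds, got {n}")
    if embedder is not None:
        coords = np.asarray(embedder(dmat.values, seed))
    else:
        import warnings
        from umap import UMAP
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            um = UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                      metric="precomputed", random_state=seed)
            coords = um.fit_transform(dmat.values)
    return pd.DataFrame({"id": dmat.ids, "x": coords[:, 0], "y": coords[:, 1]})
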