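"""Integration benchmarking metrics.

Omics-mixing metrics (GC, SAS, ASW-O) measure how thoroughly the two
modalities interleave in the joint embedding; cell-type conservation metrics
(MAP, ASW, NMI) measure how well biological identity survives integration.
The two aggregates are unweighted means of their three components.  LTA and
FOSCTTM measure cross-modal label transfer and, for paired data, how close
each cell lands to its true counterpart.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.metrics import normalized_mutual_info_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors, kneighbors_graph

from .data import EmbeddingSet, MetricReport

DEFAULT_K_GC = 15
DEFAULT_K_SAS = 10
DEFAULT_K_MAP = 30
DEFAULT_K_LTA = 5


def _labels_array(labels) -> np.ndarray:
    return np.asarray(list(labels))


def graph_connectivity(emb: np.ndarray, types, k: int = DEFAULT_K_GC) -> float:
    """Mean over cell types of |largest connected component| / n_t on per-type kNN graphs."""
    emb = np.asarray(emb, dtype=float)
    types = _labels_array(types)
    scores = []
    for t in np.unique(types):
        idx = np.nonzero(types == t)[0]
        n_t = len(idx)
        if n_t == 1:
            warnings.warn(f"cell type {t!r} has a single cell; connectivity contributes 1")
            scores.append(1.0)
            continue
        g = kneighbors_graph(emb[idx], n_neighbors=min(k, n_t - 1), mode="connectivity")
        g = g.maximum(g.T)  # undirected
        n_comp, memb = connected_components(g, directed=False)
        largest = np.bincount(memb).max()
        scores.append(largest / n_t)
    return float(np.mean(scores))


def seurat_alignment_score(emb: np.ndarray, omics_labels, k: int = DEFAULT_K_SAS,
                           n_repeats: int = 3, seed: int = 0) -> float:
    """1 - (xbar - k/V)/(k - k/V) where xbar is the mean same-omics neighbor count.

    Each omics layer is subsampled to the size of the smallest layer before
    the kNN search; the subsampling is repeated ``n_repeats`` times and the
    mean score reported.  Perfect mixing (xbar = k/V) gives 1; full
    modality separation (xbar = k) gives 0.
    """
    emb = np.asarray(emb, dtype=float)
    omics = _labels_array(omics_labels)
    layers = np.unique(omics)
    V = len(layers)
    n_min = min(int((omics == o).sum()) for o in layers)
    if k >= n_min * V:
        raise ValueError(f"k={k} must be smaller than the subsampled total {n_min * V}")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_repeats):
        idx = np.concatenate([rng.choice(np.nonzero(omics == o)[0], size=n_min, replace=False)
                              for o in layers])
        sub, sub_omics = emb[idx], omics[idx]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(sub)
        _, nbrs = nn.kneighbors(sub)
        same = (sub_omics[nbrs[:, 1:]] == sub_omics[:, None]).sum(axis=1)
        xbar = same.mean()
        score = 1.0 - (xbar - k / V) / (k - k / V)
        scores.append(min(max(score, 0.0), 1.0))
    return float(np.mean(scores))


def asw_omics(emb: np.ndarray, types, omics_labels) -> float:
    """Within each cell type, mean of 1 - |silhouette| with omics layer as cluster label."""
    emb = np.asarray(emb, dtype=float)
    types = _labels_array(types)
    omics = _labels_array(omics_labels)
    per_type = []
    for t in np.unique(types):
        idx = np.nonzero(types == t)[0]
        present = np.unique(omics[idx])
        if len(present) < 2:
            warnings.warn(f"cell type {t!r} present in only one omics layer; excluded from ASW-O")
            continue
        s = silhouette_samples(emb[idx], omics[idx])
        per_type.append(float(np.mean(1.0 - np.abs(s))))
    if not per_type:
        raise ValueError("no cell type is present in both omics layers")
    return float(np.mean(per_type))


def mean_average_precision(emb: np.ndarray, types, k: int = DEFAULT_K_MAP) -> float:
    """Mean over cells of average precision of the k nearest neighbors' type labels."""
    emb = np.asarray(emb, dtype=float)
    types = _labels_array(types)
    n = len(emb)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, nbrs = nn.kneighbors(emb)
    correct = types[nbrs[:, 1:]] == types[:, None]  # n x k
    ranks = np.arange(1, k + 1)
    precision_at = np.cumsum(correct, axis=1) / ranks
    m = correct.sum(axis=1)
    ap = np.where(m > 0, (precision_at * correct).sum(axis=1) / np.maximum(m, 1), 0.0)
    return float(ap.mean())


def asw_celltype(emb: np.ndarray, types) -> float:
    """Mean silhouette width over cells with cell-type labels (raw scale, in [-1, 1])."""
    types = _labels_array(types)
    if len(np.unique(types)) < 2:
        raise ValueError("silhouette requires at least two cell types")
    return float(np.mean(silhouette_samples(np.asarray(emb, dtype=float), types)))


def nmi_score(emb: np.ndarray, types, clusterer: str = "kmeans", seed: int = 0) -> float:
    """NMI (2I / (H_pred + H_true)) between a k-means clustering of the embedding and the labels."""
    types = _labels_array(types)
    n_types = len(np.unique(types))
    if clusterer != "kmeans":
        raise ValueError(f"unknown clusterer {clusterer!r}")
    pred = KMeans(n_clusters=n_types, random_state=seed, n_init=10).fit_predict(
        np.asarray(emb, dtype=float))
    return float(normalized_mutual_info_score(types, pred, average_method="arithmetic"))


def _knn_vote(train_emb, train_labels, test_emb, k):
    nn = NearestNeighbors(n_neighbors=k).fit(train_emb)
    _, nbrs = nn.kneighbors(test_emb)
    preds = []
    for row in nbrs:
        votes = {}
        for rank, t in enumerate(train_labels[row]):
            if t not in votes:
                votes[t] = [0, rank]  # count, first (nearest) occurrence
            votes[t][0] += 1
        # majority; ties broken by the nearest neighbor's label
        preds.append(min(votes, key=lambda t: (-votes[t][0], votes[t][1])))
    return np.asarray(preds)


def label_transfer_accuracy(Z_train: np.ndarray, labels_train, Z_test: np.ndarray,
                            labels_test, k: int = DEFAULT_K_LTA) -> float:
    """Accuracy of a k-NN classifier transferring labels from one modality to the other."""
    labels_train = _labels_array(labels_train)
    labels_test = _labels_array(labels_test)
    preds = _knn_vote(np.asarray(Z_train, dtype=float), labels_train,
                      np.asarray(Z_test, dtype=float), min(k, len(labels_train)))
    return float(np.mean(preds == labels_test))


def foscttm(Z1: np.ndarray, Z2: np.ndarray, true_pairs) -> float:
    """Fraction of opposite-modality cells strictly closer than the true match.

    Averaged over both directions and all paired cells; Euclidean distance;
    ties count as not closer.  0 means every cell is nearest its match.
    """
    pairs = list(true_pairs)
    if not pairs:
        raise ValueError("FOSCTTM requires true cell pairings; omit this metric for unpaired data")
    Z1 = np.asarray(Z1, dtype=float)
    Z2 = np.asarray(Z2, dtype=float)
    i_idx = np.asarray([p[0] for p in pairs], dtype=int)
    j_idx = np.asarray([p[1] for p in pairs], dtype=int)

    def _one_direction(a, b, ai, bj):
        # for each paired cell a[ai], fraction of all rows of b strictly closer than b[bj]
        d = np.sqrt(((a[ai][:, None, :] - b[None, :, :]) ** 2).sum(-1))
        d_true = d[np.arange(len(ai)), bj]
        return (d < d_true[:, None]).sum(axis=1) / b.shape[0]

    f12 = _one_direction(Z1, Z2, i_idx, j_idx)
    f21 = _one_direction(Z2, Z1, j_idx, i_idx)
    return float(np.mean((f12 + f21) / 2.0))


def report(emb: EmbeddingSet, labels1, labels2, true_pairs=None,
           k_gc: int = DEFAULT_K_GC, k_sas: int = DEFAULT_K_SAS,
           k_map: int = DEFAULT_K_MAP, k_lta: int = DEFAULT_K_LTA,
           seed: int = 0) -> MetricReport:
    """Compute every applicable metric plus the two aggregates.

    FOSCTTM is included only when ``true_pairs`` is given.  LTA trains on the
    larger modality and predicts the smaller one.
    """
    joint, omics = emb.joint_cells()
    types = np.concatenate([_labels_array(labels1), _labels_array(labels2)])

    if len(labels1) >= len(labels2):
        lta = label_transfer_accuracy(emb.Z1, labels1, emb.Z2, labels2, k=k_lta)
    else:
        lta = label_transfer_accuracy(emb.Z2, labels2, emb.Z1, labels1, k=k_lta)

    return MetricReport(
        gc=graph_connectivity(joint, types, k=k_gc),
        sas=seurat_alignment_score(joint, omics, k=k_sas, seed=seed),
        asw_o=asw_omics(joint, types, omics),
        map=mean_average_precision(joint, types, k=min(k_map, len(joint) - 1)),
        asw=asw_celltype(joint, types),
        nmi=nmi_score(joint, types, seed=seed),
        lta=lta,
        foscttm=foscttm(emb.Z1, emb.Z2, true_pairs) if true_pairs else None,
        k_neighbors={"gc": k_gc, "sas": k_sas, "map": k_map, "lta": k_lta},
    )
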