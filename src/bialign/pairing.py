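"""Cross-modal anchor construction: MNN cell pairs and one-to-one feature pairs.

Cell anchors are mutual nearest neighbors under cosine distance computed in
the shared feature space (never in PCA space): cells i and j form an anchor
iff i is among the k1 nearest modality-1 cells of x2_j *and* j is among the
k2 nearest modality-2 cells of x1_i.  Distance ties break toward the smaller
cell index so the pair set is fully deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import CellAnchorSet, FeatureCorrespondence

DEFAULT_K_MNN_ATAC = 100   # RNA + gene-activity integration
DEFAULT_K_MNN_PROTEIN = 500  # RNA + protein integration


def _row_normalize(x: np.ndarray, which: str) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero cell rows in {which} (cosine undefined): indices {zero[:5].tolist()}")
    return x / norms[:, None]


def _topk_mask(sim: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Boolean mask of the k largest similarities along ``axis``, ties to smaller index."""
    if axis == 0:
        return _topk_mask(sim.T, k, 1).T
    n_rows, n_cols = sim.shape
    idx = np.arange(n_cols)
    mask = np.zeros_like(sim, dtype=bool)
    for i in range(n_rows):
        # stable order: descending similarity, then ascending index
        order = np.lexsort((idx, -sim[i]))[:k]
        mask[i, order] = True
    return mask


def build_mnn_pairs(shared1: np.ndarray, shared2: np.ndarray,
                    k_mnn: int = DEFAULT_K_MNN_ATAC,
                    k1: int | None = None, k2: int | None = None) -> CellAnchorSet:
    """Exact mutual-nearest-neighbor cell pairs under cosine distance.

    ``k1``/``k2`` default to ``k_mnn``; both matrices must share identical
    column ordering over the shared feature space.
    """
    shared1 = np.asarray(shared1, dtype=float)
    shared2 = np.asarray(shared2, dtype=float)
    if shared1.shape[1] != shared2.shape[1]:
        raise ValueError("shared-space matrices must have identical columns")
    k1 = k_mnn if k1 is None else k1
    k2 = k_mnn if k2 is None else k2
    n1, n2 = shared1.shape[0], shared2.shape[0]
    if k1 >= n1 or k2 >= n2:
        raise ValueError(f"k_mnn=({k1},{k2}) must be smaller than both cell counts ({n1},{n2})")
    u1 = _row_normalize(shared1, "modality 1")
    u2 = _row_normalize(shared2, "modality 2")
    sim = u1 @ u2.T  # n1 x n2 cosine similarity
    # j among the k2 nearest modality-2 cells of x1_i
    near2 = _topk_mask(sim, k2, axis=1)
    # i among the k1 nearest modality-1 cells of x2_j
    near1 = _topk_mask(sim, k1, axis=0)
    ii, jj = np.nonzero(near1 & near2)
    pairs = sorted(zip(ii.tolist(), jj.tolist()))
    return CellAnchorSet(pairs, k1=k1, k2=k2, metric="cosine")


def match_rate(anchors: CellAnchorSet, labels1, labels2) -> float:
    """Fraction of anchor pairs whose two cells share a cell-type label."""
    if len(anchors) == 0:
        warnings.warn("empty anchor set: match_rate defined as 0")
        return 0.0
    same = sum(1 for i, j in anchors.pairs if labels1[i] == labels2[j])
    return same / len(anchors)


def build_feature_pairs(ids1: list[str], ids2: list[str],
                        mapping: list[tuple[str, str]] | None = None) -> FeatureCorrespondence:
    """One-to-one feature correspondences between the two modalities.

    Gene mode (``mapping=None``): identity matches on shared feature ids.
    Protein mode: ``mapping`` rows are (feature-id in modality 2, feature-id
    in modality 1), e.g. (protein, gene symbol); rows are restricted to
    features present in both matrices, and any feature appearing in more than
    one surviving row is dropped entirely to enforce one-to-one pairs.
    """
    set1, set2 = set(ids1), set(ids2)
    if mapping is None:
        shared = sorted(set1 & set2)
        if not shared:
            raise ValueError("no shared feature ids and no mapping supplied")
        return FeatureCorrespondence([(f, f) for f in shared])

    present = [(gene, prot) for prot, gene in mapping if gene in set1 and prot in set2]
    from collections import Counter
    gene_counts = Counter(g for g, _ in present)
    prot_counts = Counter(p for _, p in present)
    pairs = sorted((g, p) for g, p in present if gene_counts[g] == 1 and prot_counts[p] == 1)
    if not pairs:
        raise ValueError("no one-to-one feature pairs after restricting the mapping")
    return FeatureCorrespondence(pairs)


def anchors_from_true_pairs(true_pairs: list[tuple[int, int]],
                            n1: int | None = None, n2: int | None = None) -> CellAnchorSet:
    """Use known cell correspondences directly as anchors, bypassing MNN search."""
    seen = set()
    pairs = []
    for i, j in true_pairs:
        i, j = int(i), int(j)
        if n1 is not None and not 0 <= i < n1:
            raise ValueError(f"pair index {i} out of range for modality 1")
        if n2 is not None and not 0 <= j < n2:
            raise ValueError(f"pair index {j} out of range for modality 2")
        if (i, j) not in seen:
            seen.add((i, j))
            pairs.append((i, j))
    n_dup = len(true_pairs) - len(pairs)
    if n_dup:
        warnings.warn(f"deduplicated {n_dup} repeated true pairs")
    return CellAnchorSet(pairs, k1=0, k2=0, metric="true")
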