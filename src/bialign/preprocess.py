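"""Per-modality preprocessing: HVG selection, union space, normalization, PCA.

The pipeline mirrors standard single-cell practice: per-cell total-count
normalization to a fixed target sum, log1p, per-feature z-scoring with
clipping, highly-variable-gene selection by binned normalized dispersion, and
a rank-q PCA whose cell scores and feature loadings become the encoder
inputs.  Continuous (already real-valued, possibly negative) matrices skip
the count-specific normalization/log steps and are z-scored directly.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .data import FeatureCorrespondence, ModalityMatrix, PreprocessedModality

TARGET_SUM = 1e4
DEFAULT_CLIP = 10.0
DEFAULT_N_HVG = 2000
DEFAULT_Q = 100


def _is_count_like(m: ModalityMatrix) -> bool:
    data = m.values.data if sp.issparse(m.values) else m.values
    return data.size == 0 or float(np.min(data)) >= 0.0


def _cell_totals(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.sum(axis=1)).ravel()
    return values.sum(axis=1)


def _zscore_clip(x: np.ndarray, clip: float) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return np.clip(out, -clip, clip)


def normalize_log_zscore(m: ModalityMatrix, clip: float = DEFAULT_CLIP,
                         target_sum: float = TARGET_SUM) -> np.ndarray:
    """Total-count normalize, log1p, z-score per feature, truncate to [-clip, clip].

    Zero-variance features map to 0.  Continuous matrices (negative entries)
    skip the count-specific steps and are only z-scored and clipped.
    """
    x = m.dense()
    if _is_count_like(m):
        totals = _cell_totals(x)
        if np.any(totals == 0):
            bad = [m.cell_ids[i] for i in np.nonzero(totals == 0)[0][:5]]
            raise ValueError(f"cells with zero total counts (e.g. {bad}); filter empty cells first")
        x = np.log1p(x * (target_sum / totals[:, None]))
    return _zscore_clip(x, clip)


def select_hvg(m: ModalityMatrix, n_hvg: int, strategy: str = "auto") -> list[str]:
    """Rank features by variability and return the top ``n_hvg`` ids.

    ``strategy="dispersion"`` uses the classic mean-binned normalized
    dispersion on normalized log counts (the scanpy/Seurat statistic);
    ``"variance"`` ranks by plain variance of the (z-score-input) values and
    is used for continuous matrices.  Ties break by lexical feature id.
    """
    if n_hvg > m.n_features:
        raise ValueError(f"n_hvg={n_hvg} exceeds feature count {m.n_features}")
    if strategy == "auto":
        strategy = "dispersion" if _is_count_like(m) else "variance"
    if m.n_features > 1 and not np.any(m.dense().var(axis=0) > 0):
        raise ValueError("constant matrix: no variable features to rank")

    if strategy == "dispersion":
        totals = _cell_totals(m.values)
        if np.any(totals == 0):
            bad = [m.cell_ids[i] for i in np.nonzero(totals == 0)[0][:5]]
            raise ValueError(f"cells with zero total counts (e.g. {bad}); filter empty cells first")
        import anndata as ad
        import scanpy as sc

        adata = ad.AnnData(sp.csr_matrix(m.values, dtype=np.float32) if not sp.issparse(m.values)
                           else m.values.astype(np.float32))
        adata.var_names = m.feature_ids
        sc.pp.normalize_total(adata, target_sum=TARGET_SUM)
        sc.pp.log1p(adata)
        sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=min(n_hvg, m.n_features))
        stat = np.nan_to_num(adata.var["dispersions_norm"].to_numpy(dtype=float), nan=-np.inf)
    elif strategy == "variance":
        stat = m.dense().var(axis=0)
    else:
        raise ValueError(f"unknown HVG strategy {strategy!r}")

    if np.all(stat == stat[0]) and m.n_features > 1 and np.all(m.dense().var(axis=0) == 0):
        raise ValueError("constant matrix: no variable features to rank")
    order = sorted(range(m.n_features), key=lambda j: (-stat[j], m.feature_ids[j]))
    return [m.feature_ids[j] for j in order[:n_hvg]]


def build_union_space(
    m1: ModalityMatrix,
    m2: ModalityMatrix,
    hvg1: list[str] | None = None,
    hvg2: list[str] | None = None,
    n_hvg: int = DEFAULT_N_HVG,
    correspondence: FeatureCorrespondence | None = None,
) -> tuple[list[str], ModalityMatrix, ModalityMatrix]:
    """Define the shared feature space and restrict both matrices to it.

    Gene mode (both modalities gene-indexed): the union of per-modality HVG
    lists, intersected with the features present in *both* matrices, ordered
    lexically.  Protein mode: the shared space is exactly the mapped
    gene-protein pairs; the returned matrices are column-ordered so that
    column j of one corresponds to column j of the other.
    """
    if correspondence is not None:
        present = [(a, b) for a, b in correspondence.pairs
                   if a in set(m1.feature_ids) and b in set(m2.feature_ids)]
        if not present:
            raise ValueError("no mapped feature pairs present in both matrices")
        ids1 = [a for a, _ in present]
        ids2 = [b for _, b in present]
        return ids1, m1.subset_features(ids1), m2.subset_features(ids2)

    if hvg1 is None:
        hvg1 = select_hvg(m1, min(n_hvg, m1.n_features))
    if hvg2 is None:
        hvg2 = select_hvg(m2, min(n_hvg, m2.n_features))
    union = set(hvg1) | set(hvg2)
    shared = sorted(union & set(m1.feature_ids) & set(m2.feature_ids))
    if not shared:
        raise ValueError("empty shared feature space: HVG union has no features present in both matrices")
    return shared, m1.subset_features(shared), m2.subset_features(shared)


def pca_embed(matrix: np.ndarray, q: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-q PCA returning cell scores, feature loadings and explained variance.

    The matrix is column-centered (a no-op on z-scored input); loadings are
    the right singular vectors, scores the centered data projected onto them.
    The sign of each component is fixed so its largest-magnitude loading is
    positive, which makes results reproducible across LAPACK backends.
    """
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if q > min(n, p):
        raise ValueError(f"q={q} exceeds min(cells, features)={min(n, p)}")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    v = vt[:q].T  # p x q loadings
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(q)])
    flip[flip == 0] = 1.0
    v = v * flip
    scores = xc @ v
    variance = (s[:q] ** 2) / max(n - 1, 1)
    return scores, v, variance


def preprocess_modality(
    m: ModalityMatrix,
    shared_ids: list[str],
    hvg_ids: list[str] | None = None,
    n_hvg: int = DEFAULT_N_HVG,
    clip: float = DEFAULT_CLIP,
    q: int = DEFAULT_Q,
    seed: int = 0,
) -> PreprocessedModality:
    """Run the full per-modality pipeline against a precomputed shared space.

    Protein modalities keep all measured features (no HVG selection); other
    modalities use ``hvg_ids`` or select ``n_hvg`` themselves.  ``q`` shrinks
    to ``min(cells, HVGs) - 1`` when the matrix is smaller than requested.
    """
    if hvg_ids is None:
        if m.modality == "protein":
            hvg_ids = list(m.feature_ids)
        else:
            hvg_ids = select_hvg(m, min(n_hvg, m.n_features))
    hvg_sub = m.subset_features(hvg_ids)
    hvg_matrix = normalize_log_zscore(hvg_sub, clip=clip)
    shared_matrix = normalize_log_zscore(m.subset_features(shared_ids), clip=clip)
    q_eff = min(q, min(hvg_matrix.shape) - 1) if min(hvg_matrix.shape) > 1 else 1
    cell_pcs, feature_pcs, variance = pca_embed(hvg_matrix, q_eff, seed=seed)
    return PreprocessedModality(
        hvg_matrix=hvg_matrix,
        shared_space_matrix=shared_matrix,
        cell_pcs=cell_pcs,
        feature_pcs=feature_pcs,
        hvg_ids=list(hvg_ids),
        shared_ids=list(shared_ids),
        cell_ids=list(m.cell_ids),
        pca_variance=variance,
        modality=m.modality,
        labels=list(m.labels) if m.labels is not None else None,
    )
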