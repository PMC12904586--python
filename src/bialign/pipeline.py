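"""End-to-end orchestration: preprocess -> pair -> train."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CellAnchorSet, EmbeddingSet, FeatureCorrespondence, ModalityMatrix, PreprocessedModality
from .model import LossWeights, TrainConfig, TrainingLog, train
from .pairing import (
    DEFAULT_K_MNN_ATAC,
    DEFAULT_K_MNN_PROTEIN,
    build_feature_pairs,
    build_mnn_pairs,
)
from .preprocess import DEFAULT_CLIP, DEFAULT_N_HVG, DEFAULT_Q, build_union_space, preprocess_modality, select_hvg


@dataclass
class IntegrationResult:
    prep1: PreprocessedModality
    prep2: PreprocessedModality
    anchors: CellAnchorSet
    fpairs: FeatureCorrespondence
    embeddings: EmbeddingSet
    log: TrainingLog


def integrate(
    mod1: ModalityMatrix,
    mod2: ModalityMatrix,
    mapping: list[tuple[str, str]] | None = None,
    n_hvg: int = DEFAULT_N_HVG,
    clip: float = DEFAULT_CLIP,
    q: int = DEFAULT_Q,
    k_mnn: int | None = None,
    anchors: CellAnchorSet | None = None,
    weights: LossWeights | None = None,
    cfg: TrainConfig | None = None,
) -> IntegrationResult:
    """Run the full integration pipeline on two modality matrices.

    Gene mode (both modalities gene-indexed) uses the HVG-union shared space
    and identity feature pairs; protein mode (``mapping`` of (protein, gene)
    rows) restricts the shared space to mapped gene-protein pairs.  Pass
    ``anchors`` to bypass MNN search (e.g. known cell pairings).
    """
    cfg = cfg or TrainConfig()
    weights = weights or LossWeights()

    if mapping is not None or "protein" in (mod1.modality, mod2.modality):
        if mapping is None:
            raise ValueError("protein-mode integration requires a gene-protein mapping table")
        fpairs = build_feature_pairs(mod1.feature_ids, mod2.feature_ids, mapping)
        shared1 = [a for a, _ in fpairs.pairs]
        shared2 = [b for _, b in fpairs.pairs]
        # keep mapped genes in the RNA HVG space so feature pairs survive selection
        hvg1 = select_hvg(mod1, min(n_hvg, mod1.n_features))
        hvg1 = sorted(set(hvg1) | set(shared1))
        prep1 = preprocess_modality(mod1, shared1, hvg_ids=hvg1, clip=clip, q=q, seed=cfg.seed)
        prep2 = preprocess_modality(mod2, shared2, hvg_ids=list(mod2.feature_ids), clip=clip,
                                    q=q, seed=cfg.seed)
        default_k = DEFAULT_K_MNN_PROTEIN
    else:
        hvg1 = select_hvg(mod1, min(n_hvg, mod1.n_features))
        hvg2 = select_hvg(mod2, min(n_hvg, mod2.n_features))
        shared, _, _ = build_union_space(mod1, mod2, hvg1, hvg2)
        prep1 = preprocess_modality(mod1, shared, hvg_ids=hvg1, clip=clip, q=q, seed=cfg.seed)
        prep2 = preprocess_modality(mod2, shared, hvg_ids=hvg2, clip=clip, q=q, seed=cfg.seed)
        fpairs = build_feature_pairs(hvg1, hvg2)
        default_k = DEFAULT_K_MNN_ATAC

    if anchors is None:
        if k_mnn is None:
            k_mnn = min(default_k, min(mod1.n_cells, mod2.n_cells) - 1)
        anchors = build_mnn_pairs(prep1.shared_space_matrix, prep2.shared_space_matrix, k_mnn)
        if len(anchors) == 0:
            raise ValueError("MNN search produced no anchors; increase k_mnn")

    embeddings, log = train(prep1, prep2, anchors, fpairs, weights, cfg)
    return IntegrationResult(prep1, prep2, anchors, fpairs, embeddings, log)


def unintegrated_baseline(prep1: PreprocessedModality, prep2: PreprocessedModality,
                          d: int | None = None) -> EmbeddingSet:
    """PCA-only joint embedding (no training): the pre-integration reference point.

    Cell scores of both modalities truncated to a common dimension; feature
    loadings likewise.  Used to quantify how much integration improves over
    raw per-modality PCA.
    """
    d = d or min(prep1.cell_pcs.shape[1], prep2.cell_pcs.shape[1])
    d = min(d, prep1.cell_pcs.shape[1], prep2.cell_pcs.shape[1])
    return EmbeddingSet(
        prep1.cell_pcs[:, :d], prep2.cell_pcs[:, :d],
        prep1.feature_pcs[:, :d].T, prep2.feature_pcs[:, :d].T,
    )
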