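"""Desk-scale evaluation studies on synthetic data.

Each study generates its own data, runs the full pipeline and measures the
result, so the numbers it reports are always recomputed from scratch.  The
problem sizes (two modalities of 500-800 cells, 4 types, ~120 features) and
the scaled-down training configuration (latent dimension 16, hidden widths
(64, 32), learning rate 1e-3, a few hundred epochs, k_mnn at ~5% of the
smaller modality) are the package's fixed study conditions for this data
regime; larger data should use the library defaults instead.
"""

from __future__ import annotations

import numpy as np

from .metrics import report
from .model import LossWeights, TrainConfig
from .pairing import anchors_from_true_pairs, match_rate
from .pipeline import integrate, unintegrated_baseline
from .synthetic import SyntheticSpec, generate, split_paired_dataset

STUDY_N_HVG = 100
STUDY_Q = 30
STUDY_K_MNN = 25  # ~5% of 500 cells, inside the method's recommended 0.1-5% band


def study_train_config(seed: int, max_epochs: int = 500) -> TrainConfig:
    return TrainConfig(latent_dim=16, hidden_widths=(64, 32), max_epochs=max_epochs,
                       early_stop_patience=max_epochs, learning_rate=1e-3, seed=seed)


def _run(ds, seed: int, max_epochs: int = 500, weights: LossWeights | None = None,
         anchors=None, k_mnn: int | None = STUDY_K_MNN):
    return integrate(ds.mod1, ds.mod2, n_hvg=STUDY_N_HVG, q=STUDY_Q, k_mnn=k_mnn,
                     anchors=anchors, weights=weights,
                     cfg=study_train_config(seed, max_epochs))


def parameter_recovery_study(seed: int = 0) -> dict:
    """Unpaired integration (pairing_ratio 0): LTA, mixing, conservation vs PCA baseline."""
    ds = generate(SyntheticSpec(pairing_ratio=0.0, seed=seed))
    res = _run(ds, seed)
    rep = report(res.embeddings, ds.true_types_1, ds.true_types_2, seed=seed)
    base = unintegrated_baseline(res.prep1, res.prep2, d=16)
    base_rep = report(base, ds.true_types_1, ds.true_types_2, seed=seed)
    return {
        "lta": rep.lta,
        "omics_mixing": rep.omics_mixing,
        "celltype_conservation": rep.celltype_conservation,
        "baseline_celltype_conservation": base_rep.celltype_conservation,
        "baseline_omics_mixing": base_rep.omics_mixing,
        "mnn_match_rate": match_rate(res.anchors, ds.true_types_1, ds.true_types_2),
        "report": rep,
    }


def paired_alignment_study(seed: int = 0) -> dict:
    """Fully paired data with true-correspondence anchors: FOSCTTM of the result."""
    ds = generate(SyntheticSpec(pairing_ratio=1.0, seed=seed))
    anchors = anchors_from_true_pairs(ds.true_pairs, ds.mod1.n_cells, ds.mod2.n_cells)
    res = _run(ds, seed, anchors=anchors, k_mnn=None)
    rep = report(res.embeddings, ds.true_types_1, ds.true_types_2,
                 true_pairs=ds.true_pairs, seed=seed)
    return {"foscttm": rep.foscttm, "lta": rep.lta, "omics_mixing": rep.omics_mixing}


def ablation_study(seed: int = 0, n_seeds: int = 5, max_epochs: int = 250) -> dict:
    """Drop the cell (alpha=0) or feature (beta=0) contrastive term on matched seeds.

    Returns per-seed omics-mixing scores and the number of seeds on which
    removing the cell term hurts mixing more than removing the feature term.
    """
    mix_a0, mix_b0 = [], []
    for s in range(n_seeds):
        ds = generate(SyntheticSpec(seed=seed + 100 + s))
        for target, (a, b) in ((mix_a0, (0.0, 1e4)), (mix_b0, (1e4, 0.0))):
            res = _run(ds, seed + s, max_epochs=max_epochs,
                       weights=LossWeights(alpha=a, beta=b))
            rep = report(res.embeddings, ds.true_types_1, ds.true_types_2, seed=seed)
            target.append(rep.omics_mixing)
    wins = sum(a < b for a, b in zip(mix_a0, mix_b0))
    return {"omics_mixing_alpha0": mix_a0, "omics_mixing_beta0": mix_b0,
            "alpha_worse_count": wins, "n_seeds": n_seeds}


def pairing_ratio_study(seed: int = 0, ratios=(0.0, 0.1, 0.3, 0.5, 0.8),
                        n_pairs: int = 800, max_epochs: int = 250) -> dict:
    """Split a fully paired dataset at several pairing ratios and track LTA stability."""
    base = generate(SyntheticSpec(n_cells_1=n_pairs, n_cells_2=n_pairs,
                                  pairing_ratio=1.0, seed=seed + 42))
    ltas = {}
    for p in ratios:
        ds = split_paired_dataset(base, p, seed=seed + 7)
        k = max(10, round(0.05 * min(ds.mod1.n_cells, ds.mod2.n_cells)))
        res = _run(ds, seed, max_epochs=max_epochs, k_mnn=k)
        rep = report(res.embeddings, ds.true_types_1, ds.true_types_2, seed=seed)
        ltas[p] = rep.lta
    values = list(ltas.values())
    return {"lta_by_ratio": ltas, "lta_spread": max(values) - min(values)}
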