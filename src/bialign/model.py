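"""Bilateral contrastive autoencoder: encoders, bilinear decoder, losses, training.

Each modality v has a cell encoder g_v and a feature encoder f_v (two hidden
blocks of linear -> batchnorm -> LeakyReLU(0.2) -> dropout(0.2), then a
linear head to the latent dimension d).  The decoder reconstructs the
z-scored cell-by-feature matrix through a low-rank interaction,

    X_hat = softplus(scale) * (Z Y) + bias,

with per-feature learnable scale and bias.  Training minimizes

    L_total = L_rec + alpha * L_cell + beta * L_feat,

where L_rec is the gamma-weighted reconstruction error and the two
contrastive terms are InfoNCE losses over MNN cell anchors and one-to-one
feature pairs (cosine similarity, temperature tau).  Both contrastive losses
are symmetrized (modality 1->2 and 2->1 averaged); negatives are the other
cross-modal samples of the current mini-batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CellAnchorSet, EmbeddingSet, FeatureCorrespondence, PreprocessedModality
from .nn import Adam, MLPEncoder, Parameter, Tensor


@dataclass
class LossWeights:
    """Trade-off parameters of the total loss; defaults follow the method's paper-grade settings."""

    alpha: float = 1e4
    beta: float = 1e4
    gamma_a: float = 1.0
    gamma_b: float = 1.0
    tau_c: float = 0.5
    tau_f: float = 0.5

    def __post_init__(self) -> None:
        if self.tau_c <= 0 or self.tau_f <= 0:
            raise ValueError("temperatures must be positive")
        if min(self.alpha, self.beta, self.gamma_a, self.gamma_b) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class TrainConfig:
    latent_dim: int = 50
    hidden_widths: tuple[int, int] = (512, 256)
    negative_slope: float = 0.2
    dropout: float = 0.2
    batch_size_cells: int = 256
    batch_size_features: int = 256
    learning_rate: float = 1e-4
    weight_decay: float = 5e-5
    max_epochs: int = 1000
    early_stop_patience: int = 30
    early_stop_rel_tol: float = 1e-4
    decoder: str = "bilinear_softplus"  # alternative architectures are a config hook only
    normalize_embeddings: bool = True  # L2-normalize cell embeddings on output (cosine objective)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim <= 0 or self.max_epochs <= 0:
            raise ValueError("latent_dim and max_epochs must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.batch_size_cells <= 1 or self.batch_size_features <= 1:
            raise ValueError("batch sizes must exceed 1")
        if self.decoder != "bilinear_softplus":
            raise NotImplementedError(f"decoder variant {self.decoder!r} is a config hook only")


@dataclass
class DecoderParams:
    """Modality-specific learnable scale and bias (scalar or per-feature)."""

    scale: np.ndarray | float = 0.0
    bias: np.ndarray | float = 0.0


def _softplus(x):
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))


def decode(Z: np.ndarray, Y: np.ndarray, params: DecoderParams) -> np.ndarray:
    """Reconstruct an n x p matrix as softplus(scale) * (Z @ Y) + bias."""
    Z = np.asarray(Z, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Z.shape[1] != Y.shape[0]:
        raise ValueError(f"latent dims differ: Z is {Z.shape}, Y is {Y.shape}")
    return _softplus(params.scale) * (Z @ Y) + params.bias


def loss_reconstruction(X1, X1_hat, X2, X2_hat, w: LossWeights) -> float:
    """Literal weighted squared-Frobenius reconstruction error."""
    X1, X1_hat, X2, X2_hat = (np.asarray(a, dtype=float) for a in (X1, X1_hat, X2, X2_hat))
    if X1.shape != X1_hat.shape or X2.shape != X2_hat.shape:
        raise ValueError("reconstruction shapes do not match inputs")
    return float(w.gamma_a * np.sum((X1 - X1_hat) ** 2) + w.gamma_b * np.sum((X2 - X2_hat) ** 2))


def _unit_rows(x: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"zero-norm {what} embedding: cosine similarity undefined")
    return x / norms[:, None]


def _infonce(emb_a: np.ndarray, emb_b: np.ndarray, pairs: list[tuple[int, int]],
             tau: float, negatives: dict[int, list[int]] | None) -> float:
    """Mean InfoNCE over positives (a_i, b_j); denominator = positive + negatives.

    ``negatives`` maps a positive-pair index to candidate indices in ``emb_b``;
    ``None`` means all other rows of ``emb_b``.  One-directional (a -> b).
    """
    ua = _unit_rows(np.asarray(emb_a, dtype=float), "first")
    ub = _unit_rows(np.asarray(emb_b, dtype=float), "second")
    total = 0.0
    all_b = np.arange(len(ub))
    for t, (i, j) in enumerate(pairs):
        if negatives is None:
            neg = all_b[all_b != j]
        else:
            neg = np.asarray(negatives.get(t, []), dtype=int)
        cand = np.concatenate([[j], neg])
        logits = (ua[i] @ ub[cand].T) / tau
        m = logits.max()
        total += float(np.log(np.sum(np.exp(logits - m))) + m - logits[0])
    return total / len(pairs)


def loss_cell_contrastive(Z1: np.ndarray, Z2: np.ndarray, anchors: CellAnchorSet,
                          tau_c: float = 0.5,
                          negatives: dict[int, list[int]] | None = None) -> float:
    """InfoNCE over MNN cell anchors (modality 1 -> 2 direction).

    The denominator includes the positive plus the negative candidates, so
    the loss is nonnegative and equals ln 2 for one equal-similarity negative.
    """
    if len(anchors) == 0:
        raise ValueError("anchor set is empty")
    return _infonce(Z1, Z2, anchors.pairs, tau_c, negatives)


def loss_feature_contrastive(Y1: np.ndarray, Y2: np.ndarray, fpairs: FeatureCorrespondence | list,
                             ids1: list[str] | None = None, ids2: list[str] | None = None,
                             tau_f: float = 0.5,
                             negatives: dict[int, list[int]] | None = None) -> float:
    """InfoNCE over one-to-one feature pairs on feature embedding columns.

    ``Y1``/``Y2`` are d x p matrices (features are columns).  ``fpairs`` may
    be a :class:`FeatureCorrespondence` (resolved through ``ids1``/``ids2``)
    or an explicit list of (column in Y1, column in Y2) index pairs.
    """
    if isinstance(fpairs, FeatureCorrespondence):
        if ids1 is None or ids2 is None:
            raise ValueError("ids1/ids2 required to resolve feature ids to columns")
        ix1 = {f: i for i, f in enumerate(ids1)}
        ix2 = {f: i for i, f in enumerate(ids2)}
        pairs = [(ix1[a], ix2[b]) for a, b in fpairs.pairs if a in ix1 and b in ix2]
    else:
        pairs = [(int(a), int(b)) for a, b in fpairs]
    if not pairs:
        raise ValueError("no feature pairs to contrast")
    return _infonce(np.asarray(Y1, dtype=float).T, np.asarray(Y2, dtype=float).T, pairs, tau_f, negatives)


def total_loss(l_rec: float, l_cell: float, l_feat: float, w: LossWeights) -> float:
    """L_total = L_rec + alpha * L_cell + beta * L_feat."""
    return float(l_rec + w.alpha * l_cell + w.beta * l_feat)


# ---------------------------------------------------------------------------
# trainable model


class BilateralModel:
    """The trainable network: four encoders plus two decoder parameter sets."""

    def __init__(self, q1: int, q2: int, p1: int, p2: int, cfg: TrainConfig,
                 rng: np.random.Generator):
        hw = tuple(cfg.hidden_widths)
        d = cfg.latent_dim
        mk = lambda n_in: MLPEncoder(n_in, hw, d, rng, cfg.negative_slope, cfg.dropout)
        self.cell_enc = [mk(q1), mk(q2)]
        self.feat_enc = [mk(q1), mk(q2)]
        self.scale = [Parameter(np.zeros(p1)), Parameter(np.zeros(p2))]
        self.bias = [Parameter(np.zeros(p1)), Parameter(np.zeros(p2))]
        self.cfg = cfg

    def parameters(self):
        out = []
        for enc in self.cell_enc + self.feat_enc:
            out += enc.parameters()
        return out + self.scale + self.bias

    def encode_cells(self, v: int, x: np.ndarray, training: bool, rng) -> Tensor:
        return self.cell_enc[v](Tensor(x), training, rng)

    def encode_features(self, v: int, x: np.ndarray, training: bool, rng) -> Tensor:
        return self.feat_enc[v](Tensor(x), training, rng)

    def reconstruct(self, v: int, z: Tensor, y: Tensor, feat_idx: np.ndarray) -> Tensor:
        """softplus(scale_f) * (Z @ Y^T) + bias_f on a cell x feature sub-block."""
        scale = self.scale[v].take_rows(feat_idx).softplus()
        bias = self.bias[v].take_rows(feat_idx)
        return scale * (z @ y.T) + bias


def _contrastive_batch(za: Tensor, zb: Tensor, n_pos: int, tau: float) -> Tensor:
    """Symmetric in-batch InfoNCE: positives on the diagonal of the first n_pos rows/cols."""
    ua = za.normalize_rows()
    ub = zb.normalize_rows()
    sim = (ua @ ub.T) * (1.0 / tau)
    pos_idx = np.arange(n_pos)
    diag = sim.gather(pos_idx, pos_idx)
    fwd = (sim.take_rows(pos_idx).logsumexp(axis=1) - diag).mean()
    bwd = (sim.T.take_rows(pos_idx).logsumexp(axis=1) - diag).mean()
    return (fwd + bwd) * 0.5


def _mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def _resolve_feature_pairs(fpairs: FeatureCorrespondence, ids1: list[str], ids2: list[str]) -> np.ndarray:
    ix1 = {f: i for i, f in enumerate(ids1)}
    ix2 = {f: i for i, f in enumerate(ids2)}
    pairs = [(ix1[a], ix2[b]) for a, b in fpairs.pairs if a in ix1 and b in ix2]
    dropped = len(fpairs) - len(pairs)
    if dropped:
        warnings.warn(f"{dropped} feature pairs fall outside the HVG spaces and were dropped")
    if not pairs:
        raise ValueError("no feature pairs overlap the HVG spaces")
    return np.asarray(pairs, dtype=int)


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.epochs.append(kwargs)

    @property
    def total(self) -> list[float]:
        return [e["total"] for e in self.epochs]


def _sample_batch(rng, n_total: int, anchor_side: np.ndarray, batch: int):
    """First part anchors (positions align across modalities), rest random fill."""
    n_anchor = min(batch // 2, len(anchor_side)) if len(anchor_side) else 0
    take = rng.choice(len(anchor_side), size=n_anchor, replace=False) if n_anchor else np.empty(0, int)
    fill = rng.integers(0, n_total, size=max(batch - n_anchor, 0))
    return take, fill


def batch_loss(model: BilateralModel, prep1: PreprocessedModality, prep2: PreprocessedModality,
               cells1: np.ndarray, cells2: np.ndarray, n_pos_cells: int,
               feats1: np.ndarray, feats2: np.ndarray, n_pos_feats: int,
               w: LossWeights, training: bool, rng: np.random.Generator) -> tuple[Tensor, dict]:
    """Differentiable total loss on one mini-batch (also used by gradient checks)."""
    z1 = model.encode_cells(0, prep1.cell_pcs[cells1], training, rng)
    z2 = model.encode_cells(1, prep2.cell_pcs[cells2], training, rng)
    y1 = model.encode_features(0, prep1.feature_pcs[feats1], training, rng)
    y2 = model.encode_features(1, prep2.feature_pcs[feats2], training, rng)

    rec1 = _mse(model.reconstruct(0, z1, y1, feats1), prep1.hvg_matrix[np.ix_(cells1, feats1)])
    rec2 = _mse(model.reconstruct(1, z2, y2, feats2), prep2.hvg_matrix[np.ix_(cells2, feats2)])
    l_rec = rec1 * w.gamma_a + rec2 * w.gamma_b

    parts = {"rec": l_rec.item()}
    total = l_rec
    if w.alpha > 0 and n_pos_cells > 0:
        l_cell = _contrastive_batch(z1, z2, n_pos_cells, w.tau_c)
        total = total + l_cell * w.alpha
        parts["cell"] = l_cell.item()
    else:
        parts["cell"] = 0.0
    if w.beta > 0 and n_pos_feats > 0:
        l_feat = _contrastive_batch(y1, y2, n_pos_feats, w.tau_f)
        total = total + l_feat * w.beta
        parts["feat"] = l_feat.item()
    else:
        parts["feat"] = 0.0
    parts["total"] = total.item()
    return total, parts


def train(prep1: PreprocessedModality, prep2: PreprocessedModality,
          anchors: CellAnchorSet, fpairs: FeatureCorrespondence,
          weights: LossWeights | None = None, cfg: TrainConfig | None = None,
          ) -> tuple[EmbeddingSet, TrainingLog]:
    """Mini-batch training of the bilateral contrastive autoencoder.

    Cell batches interleave sampled anchor pairs (aligned across modalities)
    with random fill cells; feature batches cycle through all positive
    feature pairs each epoch so sparse correspondences are never starved.
    Embeddings are extracted in deterministic evaluation mode.
    """
    weights = weights or LossWeights()
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)

    n1, n2 = prep1.cell_pcs.shape[0], prep2.cell_pcs.shape[0]
    p1, p2 = len(prep1.hvg_ids), len(prep2.hvg_ids)
    q1, q2 = prep1.cell_pcs.shape[1], prep2.cell_pcs.shape[1]

    anchor_arr = np.asarray(anchors.pairs, dtype=int).reshape(-1, 2)
    fpair_arr = _resolve_feature_pairs(fpairs, prep1.hvg_ids, prep2.hvg_ids)

    model = BilateralModel(q1, q2, p1, p2, cfg, rng)
    opt = Adam(model.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    log = TrainingLog()

    bc, bf = cfg.batch_size_cells, cfg.batch_size_features
    steps = max(1, int(np.ceil(max(n1, n2) / bc)))
    best = np.inf
    best_epoch = 0
    smoothed = None

    for epoch in range(cfg.max_epochs):
        fq = rng.permutation(len(fpair_arr))  # feature-pair queue for this epoch
        fq_pos = 0
        epoch_parts = {"total": 0.0, "rec": 0.0, "cell": 0.0, "feat": 0.0}
        for _ in range(steps):
            take, fill1 = _sample_batch(rng, n1, anchor_arr, bc)
            _, fill2 = _sample_batch(rng, n2, anchor_arr, bc)
            n_pos_c = len(take)
            cells1 = np.concatenate([anchor_arr[take, 0], fill1]) if n_pos_c else fill1
            cells2 = np.concatenate([anchor_arr[take, 1], fill2]) if n_pos_c else fill2

            n_pos_f = min(bf // 2, len(fpair_arr))
            if fq_pos + n_pos_f > len(fq):
                fq = rng.permutation(len(fpair_arr))
                fq_pos = 0
            ftake = fq[fq_pos:fq_pos + n_pos_f]
            fq_pos += n_pos_f
            ffill1 = rng.integers(0, p1, size=max(min(bf, p1) - n_pos_f, 0))
            ffill2 = rng.integers(0, p2, size=max(min(bf, p2) - n_pos_f, 0))
            feats1 = np.concatenate([fpair_arr[ftake, 0], ffill1])
            feats2 = np.concatenate([fpair_arr[ftake, 1], ffill2])

            opt.zero_grad()
            loss, parts = batch_loss(model, prep1, prep2, cells1, cells2, n_pos_c,
                                     feats1, feats2, n_pos_f, weights, True, rng)
            if not np.isfinite(parts["total"]):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: total loss {parts['total']}; "
                    "reduce the learning rate or the contrastive weights")
            loss.backward()
            opt.step()
            for k in epoch_parts:
                epoch_parts[k] += parts[k] / steps

        log.append(epoch=epoch, **epoch_parts)
        smoothed = epoch_parts["total"] if smoothed is None else 0.7 * smoothed + 0.3 * epoch_parts["total"]
        if smoothed < best * (1 - cfg.early_stop_rel_tol):
            best = smoothed
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.early_stop_patience:
            break

    eval_rng = np.random.default_rng(cfg.seed + 1)  # unused in eval mode (no dropout)
    Z1 = model.encode_cells(0, prep1.cell_pcs, False, eval_rng).data
    Z2 = model.encode_cells(1, prep2.cell_pcs, False, eval_rng).data
    if cfg.normalize_embeddings:
        # the contrastive objective is angular, so the unit sphere is the
        # natural output geometry for downstream Euclidean-distance metrics
        Z1 = Z1 / np.linalg.norm(Z1, axis=1, keepdims=True)
        Z2 = Z2 / np.linalg.norm(Z2, axis=1, keepdims=True)
    Y1 = model.encode_features(0, prep1.feature_pcs, False, eval_rng).data.T
    Y2 = model.encode_features(1, prep2.feature_pcs, False, eval_rng).data.T
    emb = EmbeddingSet(Z1, Z2, Y1, Y2)
    return emb, log
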