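"""Synthetic two-modality datasets with known ground truth.

The generator emulates the data regimes the integration method is designed
for: two cell-by-feature matrices that share a latent cell-type structure but
are observed through modality-specific linear loadings and noise.  A
controllable fraction of cells (``pairing_ratio``) carries identical latent
vectors in both modalities and is recorded as ground-truth pairs, so anchor
construction, training and every evaluation metric can be tested end to end
without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ModalityMatrix


class SyntheticSpecError(ValueError):
    """Raised when a synthetic-data specification is invalid; names the field."""


@dataclass
class SyntheticSpec:
    """Parameters of the two-modality generative model.

    Cells of each type sit around a centroid in a ``latent_dim_true``-dim
    latent space; centroids are placed so their minimum pairwise distance
    equals ``type_separation``.  Each modality observes the latent vectors
    through its own loading matrix; the ``n_shared_features`` loading columns
    are identical across modalities so that feature correspondences carry
    signal.  ``count_model="negative_binomial"`` exponentiates the latent
    means and draws overdispersed counts (fixed dispersion
    ``nb_dispersion``), emulating the sparsity of expression/activity data.
    """

    n_cells_1: int = 500
    n_cells_2: int = 500
    n_types: int = 4
    n_shared_features: int = 80
    n_private_features_1: int = 20
    n_private_features_2: int = 20
    latent_dim_true: int = 10
    noise_sd: float = 0.5
    type_separation: float = 6.0
    pairing_ratio: float = 0.0
    count_model: str = "gaussian"
    nb_dispersion: float = 0.5
    seed: int = 0
    modality_1: str = "rna"
    modality_2: str = "atac_activity"

    def validate(self) -> None:
        for name in ("n_cells_1", "n_cells_2", "n_shared_features", "latent_dim_true"):
            if int(getattr(self, name)) <= 0:
                raise SyntheticSpecError(f"{name} must be positive")
        for name in ("n_private_features_1", "n_private_features_2"):
            if int(getattr(self, name)) < 0:
                raise SyntheticSpecError(f"{name} must be nonnegative")
        if self.n_types < 2:
            raise SyntheticSpecError("n_types must be >= 2")
        if not 0.0 <= self.pairing_ratio <= 1.0:
            raise SyntheticSpecError("pairing_ratio must lie in [0, 1]")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be nonnegative")
        if self.type_separation < 0:
            raise SyntheticSpecError("type_separation must be nonnegative")
        if self.count_model not in ("gaussian", "negative_binomial"):
            raise SyntheticSpecError("count_model must be 'gaussian' or 'negative_binomial'")
        if self.nb_dispersion <= 0:
            raise SyntheticSpecError("nb_dispersion must be positive")

    @property
    def n_pairs(self) -> int:
        return int(round(self.pairing_ratio * min(self.n_cells_1, self.n_cells_2)))


@dataclass
class SyntheticDataset:
    mod1: ModalityMatrix
    mod2: ModalityMatrix
    true_types_1: list[str]
    true_types_2: list[str]
    true_pairs: list[tuple[int, int]]
    feature_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n1, n2 = self.mod1.n_cells, self.mod2.n_cells
        for i, j in self.true_pairs:
            if not (0 <= i < n1 and 0 <= j < n2):
                raise ValueError(f"true pair ({i},{j}) out of range")
            if self.true_types_1[i] != self.true_types_2[j]:
                raise ValueError(f"paired cells ({i},{j}) have different type labels")
        left = [i for i, _ in self.true_pairs]
        right = [j for _, j in self.true_pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("true_pairs must be injective on both sides")


def _centroids(rng: np.random.Generator, n_types: int, dim: int, separation: float) -> np.ndarray:
    """Random centroids rescaled so the minimum pairwise distance equals ``separation``."""
    c = rng.standard_normal((n_types, dim))
    c -= c.mean(axis=0, keepdims=True)
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    dmin = d.min()
    if dmin <= 0:  # coincident draw; nudge deterministically
        c += 1e-6 * np.arange(n_types)[:, None]
        d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        dmin = d.min()
    return c * (separation / dmin)


def _observe(rng: np.random.Generator, latent: np.ndarray, loading: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    signal = latent @ loading
    if spec.count_model == "gaussian":
        return signal + spec.noise_sd * rng.standard_normal(signal.shape)
    # counts: exponentiated latent means, fixed-dispersion negative binomial
    log_mu = np.clip(signal / max(1.0, spec.type_separation / 2.0), -8.0, 8.0)
    mu = np.exp(log_mu)
    theta = spec.nb_dispersion
    return rng.negative_binomial(theta, theta / (theta + mu)).astype(float)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a two-modality dataset from ``spec``; same spec+seed is bit-identical."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dim = spec.latent_dim_true
    centroids = _centroids(rng, spec.n_types, dim, spec.type_separation)

    n_pairs = spec.n_pairs
    types_paired = np.arange(n_pairs) % spec.n_types
    latent_paired = centroids[types_paired] + spec.noise_sd * rng.standard_normal((n_pairs, dim))

    def _extra(n_extra: int):
        t = np.arange(n_extra) % spec.n_types
        z = centroids[t] + spec.noise_sd * rng.standard_normal((n_extra, dim))
        return t, z

    t1x, z1x = _extra(spec.n_cells_1 - n_pairs)
    t2x, z2x = _extra(spec.n_cells_2 - n_pairs)
    types1 = np.concatenate([types_paired, t1x]).astype(int)
    types2 = np.concatenate([types_paired, t2x]).astype(int)
    latent1 = np.vstack([latent_paired, z1x])
    latent2 = np.vstack([latent_paired, z2x])

    scale = 1.0 / np.sqrt(dim)
    w_shared = scale * rng.standard_normal((dim, spec.n_shared_features))
    w_priv1 = scale * rng.standard_normal((dim, spec.n_private_features_1))
    w_priv2 = scale * rng.standard_normal((dim, spec.n_private_features_2))

    x1 = _observe(rng, latent1, np.hstack([w_shared, w_priv1]), spec)
    x2 = _observe(rng, latent2, np.hstack([w_shared, w_priv2]), spec)

    shared_ids = [f"gene{j}" for j in range(spec.n_shared_features)]
    feats1 = shared_ids + [f"mod1_feat{j}" for j in range(spec.n_private_features_1)]
    feats2 = shared_ids + [f"mod2_feat{j}" for j in range(spec.n_private_features_2)]
    labels1 = [f"type{t}" for t in types1]
    labels2 = [f"type{t}" for t in types2]

    mod1 = ModalityMatrix(x1, [f"mod1_cell{i}" for i in range(spec.n_cells_1)], feats1, spec.modality_1, labels1)
    mod2 = ModalityMatrix(x2, [f"mod2_cell{i}" for i in range(spec.n_cells_2)], feats2, spec.modality_2, labels2)

    return SyntheticDataset(
        mod1=mod1,
        mod2=mod2,
        true_types_1=labels1,
        true_types_2=labels2,
        true_pairs=[(i, i) for i in range(n_pairs)],
        feature_map={g: g for g in shared_ids},
    )


def split_paired_dataset(ds: SyntheticDataset, p: float, seed: int = 0) -> SyntheticDataset:
    """Down-sample a fully paired dataset to a pairing fraction ``p``.

    A random fraction ``p`` of the pairs is retained in both modalities; the
    remaining pairs are split evenly, each cell kept in exactly one modality.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    n = len(ds.true_pairs)
    if n != ds.mod1.n_cells or n != ds.mod2.n_cells:
        raise ValueError("split_paired_dataset requires a fully paired dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_keep = int(round(p * n))
    kept = perm[:n_keep]
    rest = perm[n_keep:]
    half = len(rest) // 2
    only1 = rest[:half + len(rest) % 2]
    only2 = rest[half + len(rest) % 2:]

    idx1 = np.concatenate([kept, only1]).astype(int)
    idx2 = np.concatenate([kept, only2]).astype(int)
    pair_idx1 = {int(ds.true_pairs[k][0]): pos for pos, k in enumerate(kept)}

    mod1 = ds.mod1.subset_cells(idx1)
    mod2 = ds.mod2.subset_cells(idx2)
    types1 = [ds.true_types_1[i] for i in idx1]
    types2 = [ds.true_types_2[i] for i in idx2]
    new_pairs = [(pos, pos) for pos in range(n_keep)]
    assert all(pair_idx1[int(ds.true_pairs[k][0])] == pos for pos, k in enumerate(kept))

    return SyntheticDataset(mod1, mod2, types1, types2, new_pairs, dict(ds.feature_map))
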