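"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

MODALITIES = ("rna", "atac_activity", "protein")


def _as_2d(values):
    if sp.issparse(values):
        return values.tocsr()
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


def _check_finite(values, name: str) -> None:
    data = values.data if sp.issparse(values) else values
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{name} contains NaN or Inf values")


def _check_unique(ids: Sequence[str], name: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{name} are not unique")


@dataclass
class ModalityMatrix:
    """One modality's cell-by-feature matrix with identifiers.

    Parameters
    ----------
    values
        cells x features matrix (dense ndarray or scipy sparse).
    cell_ids, feature_ids
        Unique string identifiers for rows / columns.
    modality
        One of ``"rna"``, ``"atac_activity"``, ``"protein"``.
    labels
        Optional per-cell type labels, same length as ``cell_ids``.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values)
        self.cell_ids = list(self.cell_ids)
        self.feature_ids = list(self.feature_ids)
        _check_finite(self.values, "values")
        n, p = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {p} columns")
        _check_unique(self.cell_ids, "cell_ids")
        _check_unique(self.feature_ids, "feature_ids")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length does not match cell count")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def subset_features(self, feature_ids: Sequence[str]) -> "ModalityMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        vals = self.values[:, cols]
        return ModalityMatrix(vals, self.cell_ids, list(feature_ids), self.modality, self.labels)

    def subset_cells(self, rows: Sequence[int]) -> "ModalityMatrix":
        rows = list(rows)
        vals = self.values[rows, :]
        labels = [self.labels[i] for i in rows] if self.labels is not None else None
        return ModalityMatrix(vals, [self.cell_ids[i] for i in rows], self.feature_ids, self.modality, labels)


@dataclass
class PreprocessedModality:
    """Output of the per-modality preprocessing pipeline.

    ``hvg_matrix`` is the normalized, log1p-transformed, z-scored and clipped
    cells x HVG matrix that the decoder reconstructs; ``shared_space_matrix``
    is the same transform restricted to the cross-modality shared feature
    space and is the only input ever used for MNN anchor construction;
    ``cell_pcs`` / ``feature_pcs`` are the PCA scores and loadings fed to the
    cell and feature encoders.
    """

    hvg_matrix: np.ndarray
    shared_space_matrix: np.ndarray
    cell_pcs: np.ndarray
    feature_pcs: np.ndarray
    hvg_ids: list[str]
    shared_ids: list[str]
    cell_ids: list[str]
    pca_variance: np.ndarray
    modality: str
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pca_variance) > 1e-8):
            raise ValueError("pca_variance must be non-increasing")


@dataclass
class CellAnchorSet:
    """Cross-modal cell anchor pairs (index in modality 1, index in modality 2)."""

    pairs: list[tuple[int, int]]
    k1: int = 0
    k2: int = 0
    metric: str = "cosine"

    def __post_init__(self) -> None:
        self.pairs = [(int(i), int(j)) for i, j in self.pairs]
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate anchor pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.asarray(self.pairs, dtype=int)
        return arr[:, 0], arr[:, 1]

    def transpose(self) -> "CellAnchorSet":
        return CellAnchorSet([(j, i) for i, j in self.pairs], self.k2, self.k1, self.metric)


@dataclass
class FeatureCorrespondence:
    """One-to-one cross-modal feature pairs (feature id in mod1, feature id in mod2)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("feature correspondence must be one-to-one in both coordinates")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class EmbeddingSet:
    """Learned cell embeddings Z_v (n_v x d) and feature embeddings Y_v (d x p_v)."""

    Z1: np.ndarray
    Z2: np.ndarray
    Y1: np.ndarray
    Y2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("Z1", "Z2", "Y1", "Y2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        d = self.Z1.shape[1]
        if self.Z2.shape[1] != d or self.Y1.shape[0] != d or self.Y2.shape[0] != d:
            raise ValueError("inconsistent latent dimension across embeddings")

    @property
    def d(self) -> int:
        return self.Z1.shape[1]

    def joint_cells(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack cell embeddings; return (embedding, omics indicator array)."""
        emb = np.vstack([self.Z1, self.Z2])
        omics = np.array(["mod1"] * len(self.Z1) + ["mod2"] * len(self.Z2))
        return emb, omics


@dataclass
class MetricReport:
    """The eight individual integration metrics plus the two aggregates."""

    gc: float
    sas: float
    asw_o: float
    map: float
    asw: float
    nmi: float
    lta: float
    foscttm: float | None = None
    k_neighbors: dict = field(default_factory=dict)

    @property
    def omics_mixing(self) -> float:
        return (self.gc + self.sas + self.asw_o) / 3.0

    @property
    def celltype_conservation(self) -> float:
        return (self.map + self.asw + self.nmi) / 3.0

    def to_dict(self) -> dict:
        out = {
            "gc": self.gc,
            "sas": self.sas,
            "asw_o": self.asw_o,
            "map": self.map,
            "asw": self.asw,
            "nmi": self.nmi,
            "omics_mixing": self.omics_mixing,
            "celltype_conservation": self.celltype_conservation,
            "lta": self.lta,
        }
        if self.foscttm is not None:
            out["foscttm"] = self.foscttm
        return out
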