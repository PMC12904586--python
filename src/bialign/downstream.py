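"""Embedding-based downstream analyses.

Gene embeddings feed three analyses: (1) gene modules from a cosine kNN
gene-gene graph partitioned by greedy modularity maximization, (2) regulator
(e.g. transcription-factor) enrichment of those modules by one-sided
hypergeometric tests with Benjamini-Hochberg FDR control, and (3) per-type
marker genes ranked by gene-cell embedding similarity.  Cell embeddings feed
a cell-type interaction network: a cosine kNN cell graph aggregated to the
type level, row-normalized and thresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

DEFAULT_K_MODULES = 5
DEFAULT_K_INTERACTION = 100
DEFAULT_INTERACTION_THRESHOLD = 0.005
DEFAULT_TOP_N_MARKERS = 50


@dataclass
class GeneModuleSet:
    modules: list[set]
    graph: nx.Graph
    k: int


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # module, regulator, overlap, module_size, target_set_size, universe_size, p, adj_p
    significant_regulators: list[str] = field(default_factory=list)


@dataclass
class InteractionMatrix:
    types: list[str]
    row_normalized: np.ndarray  # pre-mask, rows sum to 1
    masked: np.ndarray          # post-mask symmetrized upper triangle
    threshold: float
    k: int


def _cosine_knn_graph(emb: np.ndarray, ids, k: int) -> nx.Graph:
    """Undirected union-symmetrized kNN graph with cosine-similarity edge weights."""
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = emb / norms
    sim = u @ u.T
    np.fill_diagonal(sim, -np.inf)
    g = nx.Graph()
    g.add_nodes_from(ids)
    order = np.argsort(-sim, axis=1, kind="stable")[:, :k]
    for i in range(len(ids)):
        for j in order[i]:
            g.add_edge(ids[i], ids[int(j)], weight=float(sim[i, int(j)]))
    return g


def gene_modules(gene_embeddings: np.ndarray, gene_ids: list[str],
                 k: int = DEFAULT_K_MODULES) -> GeneModuleSet:
    """Partition genes into modules by greedy modularity on a cosine kNN graph.

    ``gene_embeddings`` is genes x d.  Requires at least 2k genes; with all
    embeddings identical the graph is degenerate and a single module is
    returned with a warning.
    """
    emb = np.asarray(gene_embeddings, dtype=float)
    n = len(gene_ids)
    if emb.shape[0] != n:
        raise ValueError("gene_ids length does not match embedding rows")
    if k >= n - 1:
        raise ValueError(f"k={k} too large for {n} genes (need k < n - 1)")
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} genes, got {n}")
    if np.allclose(emb, emb[0]):
        warnings.warn("all gene embeddings identical; returning a single module")
        g = nx.complete_graph(0)
        g.add_nodes_from(gene_ids)
        return GeneModuleSet([set(gene_ids)], g, k)
    g = _cosine_knn_graph(emb, list(gene_ids), k)
    communities = nx.algorithms.community.greedy_modularity_communities(g, weight="weight")
    return GeneModuleSet([set(c) for c in communities], g, k)


def regulator_sets_from_table(rows, max_confidence: str | None = None) -> dict[str, set]:
    """Build regulator -> target-set mapping from (regulator, target[, confidence]) rows.

    ``max_confidence`` keeps only rows whose confidence letter is <= the given
    letter (cumulative A, AB, ABC, ... stratification).
    """
    sets: dict[str, set] = {}
    for row in rows:
        reg, target = row[0], row[1]
        if max_confidence is not None and len(row) > 2 and str(row[2]) > max_confidence:
            continue
        sets.setdefault(reg, set()).add(target)
    return sets


def module_enrichment(modules: GeneModuleSet | list, regulator_sets: dict[str, set],
                      universe: set | None = None, fdr: float = 0.05) -> EnrichmentResult:
    """Hypergeometric over-representation of regulator targets in each module.

    For each (module, regulator) pair the upper-tail hypergeometric p-value of
    the target overlap is computed against ``universe`` (defaults to the union
    of module genes); p-values are BH-adjusted across all tests, and the
    regulators significant (adjusted p < ``fdr``) in at least one module form
    ``significant_regulators``.
    """
    module_list = modules.modules if isinstance(modules, GeneModuleSet) else [set(m) for m in modules]
    if not regulator_sets:
        raise ValueError("empty regulator sets")
    if universe is None:
        universe = set().union(*module_list)
    universe = set(universe)
    for m in module_list:
        if not m <= universe:
            raise ValueError("universe must contain all module genes")
    N = len(universe)
    rows = []
    for mi, module in enumerate(module_list):
        n = len(module)
        for reg, targets in regulator_sets.items():
            targets_in = set(targets) & universe
            K = len(targets_in)
            overlap = len(module & targets_in)
            # P(X >= overlap) for X ~ Hypergeom(N, K, n)
            p = float(hypergeom.sf(overlap - 1, N, K, n)) if K else 1.0
            rows.append((mi, reg, overlap, n, K, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["module", "regulator", "overlap", "module_size",
                                        "target_set_size", "universe_size", "p"])
    table["adj_p"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    sig = sorted(table.loc[table["adj_p"] < fdr, "regulator"].unique())
    return EnrichmentResult(table=table, significant_regulators=list(sig))


def marker_genes(gene_embeddings: np.ndarray, gene_ids: list[str],
                 cell_embeddings: np.ndarray, types,
                 top_n: int = DEFAULT_TOP_N_MARKERS,
                 statistic: str = "mean") -> dict[str, list[str]]:
    """Per-type top-``top_n`` genes by gene-cell cosine similarity.

    The gene-cell similarity matrix is aggregated per cell type by ``mean``
    (default), ``max`` or ``rank-sum`` of each gene's similarities to that
    type's cells; scale-invariant because cosine similarity is used.
    """
    genes = np.asarray(gene_embeddings, dtype=float)
    cells = np.asarray(cell_embeddings, dtype=float)
    if genes.shape[1] != cells.shape[1]:
        raise ValueError("gene and cell embeddings must share the latent dimension")
    if top_n > len(gene_ids):
        raise ValueError(f"top_n={top_n} exceeds gene count {len(gene_ids)}")
    gn = genes / np.maximum(np.linalg.norm(genes, axis=1, keepdims=True), 1e-12)
    cn = cells / np.maximum(np.linalg.norm(cells, axis=1, keepdims=True), 1e-12)
    sim = gn @ cn.T  # genes x cells
    types = np.asarray(list(types))
    out: dict[str, list[str]] = {}
    for t in np.unique(types):
        cols = types == t
        if statistic == "mean":
            score = sim[:, cols].mean(axis=1)
        elif statistic == "max":
            score = sim[:, cols].max(axis=1)
        elif statistic == "rank-sum":
            ranks = sim.argsort(axis=0).argsort(axis=0)  # per-cell gene ranks
            score = ranks[:, cols].sum(axis=1).astype(float)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        order = sorted(range(len(gene_ids)), key=lambda g: (-score[g], gene_ids[g]))
        out[str(t)] = [gene_ids[g] for g in order[:top_n]]
    return out


def interaction_network(cell_embeddings: np.ndarray, types,
                        k: int = DEFAULT_K_INTERACTION,
                        threshold: float = DEFAULT_INTERACTION_THRESHOLD) -> InteractionMatrix:
    """Cell-type interaction propensities from a cosine kNN cell graph.

    Edge weights (cosine similarities, clipped at 0) are summed between every
    pair of cell types, the type x type matrix is row-normalized, symmetrized
    for masking, and only upper-triangle entries >= ``threshold`` retained.
    """
    emb = np.asarray(cell_embeddings, dtype=float)
    types = np.asarray(list(types))
    n = len(emb)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    uniq = sorted(np.unique(types).tolist())
    if any((types == t).sum() == 0 for t in uniq):
        raise ValueError("every cell type must have at least one cell")
    tix = {t: i for i, t in enumerate(uniq)}

    g = _cosine_knn_graph(emb, list(range(n)), k)
    agg = np.zeros((len(uniq), len(uniq)))
    for a, b, data in g.edges(data=True):
        w = max(float(data["weight"]), 0.0)
        ta, tb = tix[types[a]], tix[types[b]]
        agg[ta, tb] += w
        if ta != tb:
            agg[tb, ta] += w
    row_sums = agg.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    norm = agg / row_sums
    sym = (norm + norm.T) / 2.0
    masked = np.triu(sym)
    masked[masked < threshold] = 0.0
    return InteractionMatrix(types=[str(t) for t in uniq], row_normalized=norm,
                             masked=masked, threshold=threshold, k=k)
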