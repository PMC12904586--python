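"""File round-tripping: MTX bundles, delimited tables, anchors, embeddings, reports.

A modality on disk is either an MTX bundle (``<prefix>.mtx`` plus
``<prefix>.cells.txt`` / ``<prefix>.features.txt`` identifier files and an
optional ``<prefix>.labels.tsv``) or a single delimited table with a header
row of feature ids and a first column of cell ids.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .data import CellAnchorSet, EmbeddingSet, ModalityMatrix
from .synthetic import SyntheticDataset


def write_modality_mtx(m: ModalityMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    values = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    sio.mmwrite(str(prefix) + ".mtx", values)
    Path(str(prefix) + ".cells.txt").write_text("\n".join(m.cell_ids) + "\n")
    Path(str(prefix) + ".features.txt").write_text("\n".join(m.feature_ids) + "\n")
    meta = {"modality": m.modality}
    Path(str(prefix) + ".meta.json").write_text(json.dumps(meta))
    if m.labels is not None:
        pd.DataFrame({"cell_id": m.cell_ids, "label": m.labels}).to_csv(
            str(prefix) + ".labels.tsv", sep="\t", index=False
        )


def read_modality_mtx(prefix: str | Path) -> ModalityMatrix:
    prefix = str(prefix)
    values = sio.mmread(prefix + ".mtx").tocsr()
    cells = Path(prefix + ".cells.txt").read_text().splitlines()
    feats = Path(prefix + ".features.txt").read_text().splitlines()
    modality = json.loads(Path(prefix + ".meta.json").read_text())["modality"]
    labels = None
    labels_path = Path(prefix + ".labels.tsv")
    if labels_path.exists():
        df = pd.read_csv(labels_path, sep="\t", dtype=str)
        labels = df.set_index("cell_id").loc[cells, "label"].tolist()
    return ModalityMatrix(values, cells, feats, modality, labels)


def write_modality_table(m: ModalityMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.feature_ids)
    df.to_csv(path, sep=sep, index_label="cell_id")


def read_modality_table(
    path: str | Path, modality: str, sep: str = "\t", labels: list[str] | None = None
) -> ModalityMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ModalityMatrix(df.to_numpy(dtype=float), df.index.astype(str).tolist(),
                          df.columns.astype(str).tolist(), modality, labels)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_modality_mtx(ds.mod1, outdir / "mod1")
    write_modality_mtx(ds.mod2, outdir / "mod2")
    pd.DataFrame(ds.true_pairs, columns=["idx1", "idx2"]).to_csv(
        outdir / "true_pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(sorted(ds.feature_map.items()), columns=["feature1", "feature2"]).to_csv(
        outdir / "feature_map.tsv", sep="\t", index=False
    )


def read_dataset(outdir: str | Path) -> SyntheticDataset:
    outdir = Path(outdir)
    mod1 = read_modality_mtx(outdir / "mod1")
    mod2 = read_modality_mtx(outdir / "mod2")
    pairs_df = pd.read_csv(outdir / "true_pairs.tsv", sep="\t")
    pairs = [(int(i), int(j)) for i, j in pairs_df.itertuples(index=False)]
    fmap_df = pd.read_csv(outdir / "feature_map.tsv", sep="\t", dtype=str)
    fmap = dict(zip(fmap_df["feature1"], fmap_df["feature2"]))
    return SyntheticDataset(mod1, mod2, list(mod1.labels), list(mod2.labels), pairs, fmap)


def write_anchors(anchors: CellAnchorSet, cell_ids1: list[str], cell_ids2: list[str], path: str | Path) -> None:
    rows = [(cell_ids1[i], cell_ids2[j]) for i, j in anchors.pairs]
    pd.DataFrame(rows, columns=["cell1", "cell2"]).to_csv(path, sep="\t", index=False)


def read_anchors(path: str | Path, cell_ids1: list[str], cell_ids2: list[str]) -> CellAnchorSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    ix1 = {c: i for i, c in enumerate(cell_ids1)}
    ix2 = {c: i for i, c in enumerate(cell_ids2)}
    return CellAnchorSet([(ix1[a], ix2[b]) for a, b in zip(df["cell1"], df["cell2"])])


def read_mapping_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV (protein id, gene symbol) -> list of (protein, gene) rows."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False)]


def write_embeddings(emb: EmbeddingSet, cell_ids1, cell_ids2, hvg_ids1, hvg_ids2, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, ids, mat in (
        ("Z1", cell_ids1, emb.Z1),
        ("Z2", cell_ids2, emb.Z2),
        ("Y1", hvg_ids1, emb.Y1.T),
        ("Y2", hvg_ids2, emb.Y2.T),
    ):
        pd.DataFrame(mat, index=ids).to_csv(outdir / f"{name}.tsv", sep="\t", header=False)


def read_embeddings(outdir: str | Path) -> tuple[EmbeddingSet, dict]:
    outdir = Path(outdir)
    mats, ids = {}, {}
    for name in ("Z1", "Z2", "Y1", "Y2"):
        df = pd.read_csv(outdir / f"{name}.tsv", sep="\t", header=None, index_col=0)
        mats[name] = df.to_numpy(dtype=float)
        ids[name] = df.index.astype(str).tolist()
    emb = EmbeddingSet(mats["Z1"], mats["Z2"], mats["Y1"].T, mats["Y2"].T)
    return emb, ids


def write_report(report_dict: dict, path_prefix: str | Path) -> None:
    prefix = str(path_prefix)
    Path(prefix + ".json").write_text(json.dumps(report_dict, indent=2, sort_keys=True))
    pd.Series(report_dict).to_csv(prefix + ".tsv", sep="\t", header=False)
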