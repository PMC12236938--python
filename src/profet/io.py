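"""Reading and writing snapshot series, embeddings and result tables.

On-disk conventions: expression matrices are cells x genes delimited text
with a gene-name header (optionally an index column of cell ids), or a
MatrixMarket triplet (``.mtx`` plus ``genes``/``barcodes`` sidecars, cells
as columns as in 10x exports).  A snapshot series is described by a
manifest — a two-column delimited file of ``time`` and ``path`` entries.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .preprocess import LatentEmbedding, SnapshotSeries

__all__ = [
    "load_matrix",
    "load_snapshots",
    "save_snapshots",
    "save_embedding",
    "load_embedding",
]


def load_matrix(path) -> tuple[np.ndarray, list[str], list[str] | None]:
    """Read one cells x genes matrix; returns (values, gene_names, cell_ids).

    ``.mtx`` paths are read as a MatrixMarket triplet with ``genes.tsv`` and
    ``barcodes.tsv`` (or ``<stem>_genes.tsv`` / ``<stem>_barcodes.tsv``)
    sidecars, genes as matrix rows; anything else as delimited text with a
    header row.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes_file = _sidecar(path, "genes")
        barcodes_file = _sidecar(path, "barcodes")
        genes = [ln.split("\t")[0].strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
        cells = None
        if barcodes_file is not None:
            cells = [ln.strip() for ln in barcodes_file.read_text().splitlines() if ln.strip()]
        if mat.shape[0] != len(genes):
            raise ValueError(f"{path}: matrix has {mat.shape[0]} rows but {len(genes)} genes")
        return np.asarray(mat, dtype=float).T, genes, cells
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    cells = None
    first = df.columns[0]
    if df[first].dtype == object:  # index column of cell ids
        cells = df[first].astype(str).tolist()
        df = df.drop(columns=[first])
    return df.to_numpy(dtype=float), [str(c) for c in df.columns], cells


def _sidecar(mtx_path: Path, kind: str) -> Path | None:
    for cand in (mtx_path.with_name(f"{kind}.tsv"),
                 mtx_path.with_name(f"{mtx_path.stem}_{kind}.tsv")):
        if cand.exists():
            return cand
    if kind == "genes":
        raise FileNotFoundError(f"no gene sidecar next to {mtx_path}")
    return None


def load_snapshots(manifest_or_entries, strict: bool = False) -> SnapshotSeries:
    """Assemble a validated SnapshotSeries from a manifest file or entries.

    Entries are ``(time, path)`` pairs.  Columns are realigned by gene name;
    if the files' gene sets differ the intersection is used with a warning,
    or an error is raised in strict mode.
    """
    if isinstance(manifest_or_entries, (str, Path)):
        man = Path(manifest_or_entries)
        df = pd.read_csv(man, sep=None, engine="python")
        entries = [(float(t), man.parent / p) for t, p in zip(df.iloc[:, 0], df.iloc[:, 1])]
    else:
        entries = [(float(t), Path(p)) for t, p in manifest_or_entries]
    entries.sort(key=lambda e: e[0])
    loaded = [(t, *load_matrix(p)) for t, p in entries]
    gene_sets = [genes for _, _, genes, _ in loaded]
    shared = gene_sets[0]
    if any(set(g) != set(shared) for g in gene_sets[1:]):
        common = set(shared)
        for g in gene_sets[1:]:
            common &= set(g)
        if strict:
            raise ValueError("gene sets differ between snapshot files (strict mode)")
        if not common:
            raise ValueError("snapshot files share no genes")
        warnings.warn(f"gene sets differ; using the {len(common)}-gene intersection",
                      RuntimeWarning)
        shared = [g for g in shared if g in common]
    matrices, cell_ids = [], []
    for t, values, genes, cells in loaded:
        col = {g: i for i, g in enumerate(genes)}
        matrices.append(values[:, [col[g] for g in shared]])
        cell_ids.append(cells if cells is not None
                        else [f"t{t:g}_c{j}" for j in range(values.shape[0])])
    return SnapshotSeries(times=[t for t, *_ in loaded], matrices=matrices,
                          gene_names=list(shared), cell_ids=cell_ids)


def save_snapshots(series: SnapshotSeries, out_dir, stem: str = "snapshot") -> Path:
    """Write one TSV per time point, a combined long table, and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    combined = []
    for i, (t, mat, cells) in enumerate(zip(series.times, series.matrices, series.cell_ids)):
        fname = f"{stem}_{i}.tsv"
        df = pd.DataFrame(mat, columns=series.gene_names)
        df.insert(0, "cell_id", cells)
        df.to_csv(out_dir / fname, sep="\t", index=False)
        rows.append({"time": t, "path": fname})
        combined.append(df.assign(time=t))
    pd.DataFrame(rows).to_csv(out_dir / f"{stem}_manifest.tsv", sep="\t", index=False)
    pd.concat(combined, ignore_index=True).to_csv(
        out_dir / f"{stem}_combined.tsv", sep="\t", index=False)
    return out_dir / f"{stem}_manifest.tsv"


def save_embedding(embedding: LatentEmbedding, path) -> None:
    """Serialize the fitted embedding to a single .npz archive."""
    np.savez(path, loadings=embedding.loadings, center=embedding.center,
             explained_variance_ratio=embedding.explained_variance_ratio,
             d=embedding.d)


def load_embedding(path) -> LatentEmbedding:
    with np.load(path) as z:
        return LatentEmbedding(loadings=z["loadings"], center=z["center"],
                               explained_variance_ratio=z["explained_variance_ratio"],
                               d=int(z["d"]))
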