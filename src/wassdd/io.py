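"""Readers and writers for expression matrices, metadata and results.

Matrices are always genes x cells (rows x columns) in every supported
format; no auto-transposition is attempted.  Input is expected to be
pre-filtered and pre-normalized — values are validated (nonnegative,
finite, no duplicate gene ids) but never transformed.

Supported encodings: dense TSV/CSV with gene ids as the index column and
cell ids as the header, and MatrixMarket (MTX) coordinate triplets with
companion ``genes.txt`` / ``cells.txt`` name files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .simulate import SimulatedDataset, SimulationConfig

__all__ = [
    "ExpressionMatrix",
    "CellMetadata",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_dataset",
    "read_dataset",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    values: np.ndarray  # genes x cells
    gene_ids: list[str] = field(repr=False)
    cell_ids: list[str] = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("expression matrix must be 2-d (genes x cells)")
        if v.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix dimensions do not match id vectors")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")
        if np.any(v < 0):
            raise ValueError("expression values must be nonnegative")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.cell_ids)


@dataclass(frozen=True)
class CellMetadata:
    cell_ids: list[str]
    condition: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self):
        cond = np.asarray(self.condition)
        if cond.size != len(self.cell_ids):
            raise ValueError("condition vector must match cell ids")
        if np.unique(cond).size != 2:
            raise ValueError("metadata must contain exactly two condition labels")
        if self.replicate is not None:
            rep = np.asarray(self.replicate)
            if rep.size != len(self.cell_ids):
                raise ValueError("replicate vector must match cell ids")
            object.__setattr__(self, "replicate", rep)
        object.__setattr__(self, "condition", cond)

    @property
    def conditions(self) -> np.ndarray:
        return np.unique(self.condition)


def _read_names(path: Path) -> list[str]:
    return path.read_text().splitlines()


def read_matrix(path: str | Path, fmt: str = "tsv") -> ExpressionMatrix:
    """Load a genes x cells matrix.

    For ``fmt="mtx_triplet"``, ``path`` is the ``.mtx`` file and the gene
    and cell names are read from ``genes.txt`` and ``cells.txt`` next to
    it.
    """
    path = Path(path)
    if fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        return ExpressionMatrix(df.to_numpy(dtype=float),
                                [str(g) for g in df.index],
                                [str(c) for c in df.columns])
    if fmt == "mtx_triplet":
        genes = _read_names(path.parent / "genes.txt")
        cells = _read_names(path.parent / "cells.txt")
        try:
            m = spio.mmread(path)
        except Exception as exc:
            raise ValueError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        if m.shape != (len(genes), len(cells)):
            raise ValueError(
                f"{path}: matrix shape {m.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells")
        dense = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=float)
        return ExpressionMatrix(dense, genes, cells)
    raise ValueError(f"unknown format {fmt!r}")


def write_matrix(matrix: ExpressionMatrix, path: str | Path,
                 fmt: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt in ("tsv", "csv"):
        matrix.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")
        return
    if fmt == "mtx_triplet":
        spio.mmwrite(path, sparse.coo_matrix(matrix.values))
        (path.parent / "genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        (path.parent / "cells.txt").write_text("\n".join(matrix.cell_ids) + "\n")
        return
    raise ValueError(f"unknown format {fmt!r}")


def read_metadata(path: str | Path) -> CellMetadata:
    """Read a cell metadata table (columns: cell_id, condition[, replicate])."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return CellMetadata([str(c) for c in df["cell_id"]],
                        df["condition"].to_numpy(), rep)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path,
                  fmt: str = "tsv") -> None:
    """Write a simulated dataset: counts, metadata, labels and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    c = dataset.config.n_cells
    cells = [f"A_cell{i + 1:04d}" for i in range(c)] + \
            [f"B_cell{i + 1:04d}" for i in range(c)]
    mat = ExpressionMatrix(
        np.hstack([dataset.counts_a, dataset.counts_b]).astype(float),
        dataset.gene_ids, cells)
    write_matrix(mat, outdir / ("counts.mtx" if fmt == "mtx_triplet"
                                else f"counts.{fmt}"), fmt)
    pd.DataFrame({
        "cell_id": cells,
        "condition": ["A"] * c + ["B"] * c,
    }).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame({
        "gene": dataset.gene_ids,
        "category": dataset.labels,
    }).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(dataset.config), fh)


def read_dataset(outdir: str | Path, fmt: str = "tsv") -> SimulatedDataset:
    """Inverse of :func:`write_dataset`."""
    outdir = Path(outdir)
    mat = read_matrix(outdir / ("counts.mtx" if fmt == "mtx_triplet"
                                else f"counts.{fmt}"), fmt)
    with open(outdir / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    for key in ("nb_mean_log_range", "nb_dispersion_range", "dp_pi"):
        raw[key] = tuple(raw[key])
    config = SimulationConfig(**raw)
    labels = pd.read_csv(outdir / "labels.tsv", sep="\t")["category"].to_numpy()
    c = config.n_cells
    return SimulatedDataset(
        counts_a=mat.values[:, :c].astype(np.int64),
        counts_b=mat.values[:, c:].astype(np.int64),
        labels=labels, gene_ids=mat.gene_ids, config=config)
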