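"""Dataset-level differential-distribution models.

These wrap the gene-wise pipelines in the familiar model/results idiom: a
model object is built from an expression matrix plus cell metadata, its
``fit()`` runs every gene through the appropriate two-stage test and
returns a :class:`DDResults` carrying the per-gene table (distance
decomposition, stage p-values, Fisher-combined p-value and BH-adjusted
versions of all three) with a ``summary()``.

``CellLevelDD`` treats cells as observations (one replicate per
condition); ``ReplicateLevelDD`` treats replicates as observations and
requires at least two replicates per condition.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .distance import QuantileGrid, default_grid
from .io import CellMetadata, ExpressionMatrix
from .pipelines import bh_adjust, variant_a, variant_b
from .zeros import detection_rate

__all__ = ["CellLevelDD", "ReplicateLevelDD", "DDResults"]

RESULT_COLUMNS = [
    "gene", "d", "location", "size", "shape",
    "frac.location", "frac.size", "frac.shape", "rho",
    "p.zero", "p.nonzero", "p.comb",
    "p.adj.zero", "p.adj.nonzero", "p.adj.comb", "flags",
]


def _gene_seed(master_seed: int, gene_id: str) -> int:
    """Stable per-gene child seed, independent of gene order."""
    h = zlib.crc32(gene_id.encode())
    return int(np.random.SeedSequence([master_seed & 0x7FFFFFFF, h])
               .generate_state(1)[0] % (2**31))


class DDResults:
    """Per-gene differential-distribution results."""

    def __init__(self, frame: pd.DataFrame, variant: str, n_cells: int,
                 alpha: float = 0.05):
        self.frame = frame
        self.variant = variant
        self.n_cells = n_cells
        self.alpha = alpha

    def significant(self, column: str = "p.adj.comb",
                    alpha: float | None = None) -> pd.DataFrame:
        alpha = self.alpha if alpha is None else alpha
        return self.frame[self.frame[column] <= alpha]

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self) -> str:
        f = self.frame
        a = self.alpha
        lines = [
            "Differential distribution test results "
            f"(variant {self.variant})",
            "=" * 58,
            f"genes tested:            {len(f)}",
            f"cells:                   {self.n_cells}",
            f"significance level:      {a} (BH-adjusted)",
            f"DD genes (p.adj.comb):   {int((f['p.adj.comb'] <= a).sum())}",
            f"DPZ genes (p.adj.zero):  {int((f['p.adj.zero'] <= a).sum())}",
            f"non-zero DD (p.adj.nonzero): "
            f"{int((f['p.adj.nonzero'] <= a).sum())}",
        ]
        det = f[f["p.adj.comb"] <= a]
        if len(det):
            lines.append(
                "median fractions among detected genes: "
                f"location {det['frac.location'].median():.2f}, "
                f"size {det['frac.size'].median():.2f}, "
                f"shape {det['frac.shape'].median():.2f}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<DDResults variant={self.variant} genes={len(self.frame)}>")


def _finalize(rows: list[dict], variant: str, n_cells: int) -> DDResults:
    frame = pd.DataFrame(rows)
    for stage in ("zero", "nonzero", "comb"):
        frame[f"p.adj.{stage}"] = bh_adjust(frame[f"p.{stage}"].to_numpy())
    return DDResults(frame[RESULT_COLUMNS], variant, n_cells)


class CellLevelDD:
    """Variant A: one replicate per condition, cells as observations.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Pre-normalized genes x cells expression values.
    metadata : CellMetadata
        Condition label per cell (exactly two labels).
    """

    def __init__(self, matrix: ExpressionMatrix, metadata: CellMetadata):
        if matrix.cell_ids != list(metadata.cell_ids):
            raise ValueError("matrix and metadata cell ids do not match")
        self.matrix = matrix
        self.metadata = metadata
        conds = metadata.conditions
        self._mask_a = np.asarray(metadata.condition) == conds[0]
        self._mask_b = ~self._mask_a
        # CDR is a per-cell covariate computed on the full matrix
        self.cdr = detection_rate(matrix.values)

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame,
                       metadata: pd.DataFrame) -> "CellLevelDD":
        mat = ExpressionMatrix(counts.to_numpy(dtype=float),
                               [str(g) for g in counts.index],
                               [str(c) for c in counts.columns])
        rep = metadata["replicate"].to_numpy() if "replicate" in metadata else None
        meta = CellMetadata([str(c) for c in metadata["cell_id"]],
                            metadata["condition"].to_numpy(), rep)
        return cls(mat, meta)

    def fit(self, n_sub: int = 1000, grid: QuantileGrid | None = None,
            seed: int = 0) -> DDResults:
        if grid is None:
            grid = default_grid()
        rows = []
        v = self.matrix.values
        for g, gene in enumerate(self.matrix.gene_ids):
            res = variant_a(
                v[g, self._mask_a], v[g, self._mask_b],
                self.cdr[self._mask_a], self.cdr[self._mask_b],
                n_sub=n_sub, grid=grid, seed=_gene_seed(seed, gene),
                gene_id=gene)
            dc = res.decomposition
            rows.append({
                "gene": gene,
                "d": dc.d if dc else np.nan,
                "location": dc.location if dc else np.nan,
                "size": dc.size if dc else np.nan,
                "shape": dc.shape if dc else np.nan,
                "frac.location": dc.frac_location if dc else np.nan,
                "frac.size": dc.frac_size if dc else np.nan,
                "frac.shape": dc.frac_shape if dc else np.nan,
                "rho": dc.rho if dc else np.nan,
                "p.zero": res.p_zero if res.p_zero is not None else np.nan,
                "p.nonzero": res.p_nonzero if res.p_nonzero is not None else np.nan,
                "p.comb": res.p_comb if res.p_comb is not None else np.nan,
                "flags": ";".join(sorted(res.flags)),
            })
        return _finalize(rows, "A", v.shape[1])


class ReplicateLevelDD:
    """Variant B: multiple replicates per condition.

    Requires a ``replicate`` column in the metadata and at least two
    replicates per condition.
    """

    def __init__(self, matrix: ExpressionMatrix, metadata: CellMetadata,
                 paired: bool = True):
        if matrix.cell_ids != list(metadata.cell_ids):
            raise ValueError("matrix and metadata cell ids do not match")
        if metadata.replicate is None:
            raise ValueError("replicate-level model needs a replicate column")
        self.matrix = matrix
        self.metadata = metadata
        self.paired = paired
        conds = metadata.conditions
        cond = np.asarray(metadata.condition)
        rep = np.asarray(metadata.replicate)
        self._groups_a = [
            (cond == conds[0]) & (rep == r)
            for r in np.unique(rep[cond == conds[0]])]
        self._groups_b = [
            (cond == conds[1]) & (rep == r)
            for r in np.unique(rep[cond == conds[1]])]
        if len(self._groups_a) < 2 or len(self._groups_b) < 2:
            raise ValueError("variant B requires replicates (>= 2 per condition)")

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, metadata: pd.DataFrame,
                       paired: bool = True) -> "ReplicateLevelDD":
        mat = ExpressionMatrix(counts.to_numpy(dtype=float),
                               [str(g) for g in counts.index],
                               [str(c) for c in counts.columns])
        meta = CellMetadata([str(c) for c in metadata["cell_id"]],
                            metadata["condition"].to_numpy(),
                            metadata["replicate"].to_numpy())
        return cls(mat, meta, paired=paired)

    def fit(self, grid: QuantileGrid | None = None,
            alternative: str = "greater") -> DDResults:
        if grid is None:
            grid = default_grid()
        rows = []
        v = self.matrix.values
        for g, gene in enumerate(self.matrix.gene_ids):
            res = variant_b(
                [v[g, m] for m in self._groups_a],
                [v[g, m] for m in self._groups_b],
                paired=self.paired, grid=grid, alternative=alternative,
                gene_id=gene)
            rows.append({
                "gene": gene,
                "d": res.mean_d if res.mean_d is not None else np.nan,
                "location": np.nan, "size": np.nan, "shape": np.nan,
                "frac.location": res.mean_frac_location
                if res.mean_frac_location is not None else np.nan,
                "frac.size": res.mean_frac_size
                if res.mean_frac_size is not None else np.nan,
                "frac.shape": res.mean_frac_shape
                if res.mean_frac_shape is not None else np.nan,
                "rho": res.mean_rho if res.mean_rho is not None else np.nan,
                "p.zero": res.p_zero if res.p_zero is not None else np.nan,
                "p.nonzero": res.p_nonzero if res.p_nonzero is not None else np.nan,
                "p.comb": res.p_comb if res.p_comb is not None else np.nan,
                "flags": ";".join(sorted(res.flags)),
            })
        return _finalize(rows, "B", v.shape[1])
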