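"""Gene-wise differential-distribution pipelines.

Two scenarios are supported:

* **variant A** — one replicate per condition, cells as observations.  A
  two-stage test per gene: (i) differential proportion of zeros (DPZ) via
  the detection-rate-adjusted logistic regression, and (ii) the SP
  permutation test on the strictly positive expression values only, with
  the location/size/shape decomposition attached.  The two p-values are
  combined with Fisher's method into an overall differential-distribution
  p-value.

* **variant B** — R >= 2 replicates per condition, replicates as
  observations.  All between-condition replicate-pair distances (D_BC) are
  compared with all within-condition pair distances (D_WC) by a one-sided
  Wilcoxon rank-sum test ("greater": a true difference in distribution
  makes between-condition distances stochastically larger).  The overall
  decomposition is the average of the D_BC decomposition fractions.  The
  zero stage is the CMH test over per-replicate 2x2 tables (paired
  setting); p-values combine as in variant A.

When one stage is not computable the combined p-value falls back to the
other stage's p-value rather than Fisher with a placeholder, and a flag
records why.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distance import QuantileGrid, WassersteinDecomposition, _as_sample, decompose, default_grid
from .sp import sp_test
from .zeros import cmh_test, dpz_logistic

__all__ = [
    "VariantAResult",
    "VariantBResult",
    "fisher_combine",
    "bh_adjust",
    "variant_a",
    "variant_b",
    "MIN_NONZERO",
]

MIN_NONZERO = 3  # quantiles of <=2 points are uninformative


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher combination of two independent p-values.

    ``X² = -2(ln p1 + ln p2)`` referred to the chi-square distribution
    with 4 degrees of freedom.
    """
    for p in (p1, p2):
        if not (0.0 < p <= 1.0):
            raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * (np.log(p1) + np.log(p2))
    return float(stats.chi2.sf(x2, df=4))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment; NaNs pass through."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if np.any((p[mask] <= 0) | (p[mask] > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class VariantAResult:
    gene_id: str
    p_zero: float | None
    p_nonzero: float | None
    p_comb: float | None
    decomposition: WassersteinDecomposition | None
    flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class VariantBResult:
    gene_id: str
    p_zero: float | None
    p_nonzero: float | None
    p_comb: float | None
    d_bc: np.ndarray
    d_wc: np.ndarray
    mean_d: float | None
    mean_frac_location: float | None
    mean_frac_size: float | None
    mean_frac_shape: float | None
    mean_rho: float | None
    flags: frozenset[str] = field(default_factory=frozenset)


def _combine(p_zero, p_nonzero):
    if p_zero is not None and p_nonzero is not None:
        return fisher_combine(p_zero, p_nonzero)
    if p_zero is not None:
        return p_zero
    return p_nonzero


def variant_a(a, b, cdr_a, cdr_b, *, n_sub: int = 1000,
              grid: QuantileGrid | None = None, seed: int = 0,
              min_nonzero: int = MIN_NONZERO,
              gene_id: str = "gene") -> VariantAResult:
    """Two-stage single-replicate DD test for one gene."""
    xa = _as_sample(a)
    xb = _as_sample(b)
    cdr_a = np.asarray(cdr_a, dtype=float).ravel()
    cdr_b = np.asarray(cdr_b, dtype=float).ravel()
    if xa.size != cdr_a.size or xb.size != cdr_b.size:
        raise ValueError("samples and CDR vectors must align")
    if grid is None:
        grid = default_grid()

    flags: set[str] = set()

    zero = np.concatenate([xa == 0, xb == 0]).astype(int)
    cond = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    cdr = np.concatenate([cdr_a, cdr_b])
    try:
        p_zero = dpz_logistic(zero, cond, cdr)
    except ValueError:
        p_zero = None
        flags.add("zero_test_skipped")

    nz_a = xa[xa > 0]
    nz_b = xb[xb > 0]
    if min(nz_a.size, nz_b.size) < min_nonzero:
        p_nonzero = None
        decomp = None
        flags.add("too_few_nonzero")
    else:
        res = sp_test(nz_a, nz_b, n_sub=n_sub, grid=grid, seed=seed)
        p_nonzero = res.p_final
        if res.method_used == "gpd":
            flags.add("gpd_used")
        decomp = decompose(nz_a, nz_b, grid)

    return VariantAResult(
        gene_id=gene_id, p_zero=p_zero, p_nonzero=p_nonzero,
        p_comb=_combine(p_zero, p_nonzero), decomposition=decomp,
        flags=frozenset(flags),
    )


def _zero_tables(samples_a, samples_b):
    tables = []
    for xa, xb in zip(samples_a, samples_b):
        tables.append([
            [int(np.sum(xa == 0)), int(np.sum(xa > 0))],
            [int(np.sum(xb == 0)), int(np.sum(xb > 0))],
        ])
    return tables


def variant_b(samples_a, samples_b, *, paired: bool = True,
              grid: QuantileGrid | None = None,
              alternative: str = "greater",
              min_nonzero: int = MIN_NONZERO,
              gene_id: str = "gene") -> VariantBResult:
    """Replicate-level DD test for one gene.

    ``samples_a`` / ``samples_b`` are lists of per-replicate expression
    vectors.  ``paired`` means replicate r of condition A matches
    replicate r of condition B (required for the CMH zero stage with
    unequal orderings handled by rank-pairing on zero fraction when the
    data are unpaired but balanced).
    """
    samples_a = [_as_sample(s) for s in samples_a]
    samples_b = [_as_sample(s) for s in samples_b]
    r_a, r_b = len(samples_a), len(samples_b)
    if r_a < 2 or r_b < 2:
        raise ValueError("variant B requires replicates (>= 2 per condition)")
    if paired and r_a != r_b:
        raise ValueError("paired variant B requires equal replicate counts")
    if grid is None:
        grid = default_grid()

    flags: set[str] = set()

    # zero stage: CMH over per-replicate strata
    p_zero = None
    if r_a == r_b:
        if paired:
            pairs_a, pairs_b = samples_a, samples_b
        else:
            # rank-pair by zero fraction so strata match comparable replicates
            zf = lambda xs: np.argsort([np.mean(x == 0) for x in xs], kind="stable")
            pairs_a = [samples_a[i] for i in zf(samples_a)]
            pairs_b = [samples_b[i] for i in zf(samples_b)]
        tables = [np.asarray(t) for t in _zero_tables(pairs_a, pairs_b)]
        if any(np.all(t.sum(axis=0) > 0) and np.all(t.sum(axis=1) > 0)
               for t in tables):
            p_zero = cmh_test(tables)
        else:
            # no zeros (or no non-zeros) anywhere: no DPZ information
            p_zero = 1.0
            flags.add("zero_test_degenerate")
    else:
        flags.add("zero_test_skipped")

    # non-zero stage: D_BC vs D_WC rank-sum test
    nz_a = [s[s > 0] for s in samples_a]
    nz_b = [s[s > 0] for s in samples_b]
    keep_a = [s for s in nz_a if s.size >= min_nonzero]
    keep_b = [s for s in nz_b if s.size >= min_nonzero]
    if len(keep_a) < len(nz_a) or len(keep_b) < len(nz_b):
        flags.add("too_few_nonzero")

    p_nonzero = None
    d_bc = np.empty(0)
    d_wc = np.empty(0)
    mean_d = mfl = mfs = mfsh = mrho = None
    if len(keep_a) >= 2 and len(keep_b) >= 2:
        decomps = [decompose(xa, xb, grid) for xa, xb in product(keep_a, keep_b)]
        d_bc = np.array([dc.d for dc in decomps])
        d_wc = np.array(
            [stats_d for xs in (keep_a, keep_b)
             for stats_d in (decompose(u, v, grid).d
                             for u, v in combinations(xs, 2))]
        )
        nondeg = [dc for dc in decomps if dc.d > 0]
        if nondeg:
            mean_d = float(np.mean([dc.d for dc in decomps]))
            mfl = float(np.mean([dc.frac_location for dc in nondeg]))
            mfs = float(np.mean([dc.frac_size for dc in nondeg]))
            mfsh = float(np.mean([dc.frac_shape for dc in nondeg]))
            mrho = float(np.mean([dc.rho for dc in nondeg]))
        if d_wc.size:
            exact = (np.unique(np.concatenate([d_bc, d_wc])).size
                     == d_bc.size + d_wc.size)
            p_nonzero = float(stats.mannwhitneyu(
                d_bc, d_wc, alternative=alternative,
                method="exact" if exact else "asymptotic").pvalue)
    else:
        flags.add("nonzero_test_skipped")

    return VariantBResult(
        gene_id=gene_id, p_zero=p_zero, p_nonzero=p_nonzero,
        p_comb=_combine(p_zero, p_nonzero),
        d_bc=d_bc, d_wc=d_wc, mean_d=mean_d,
        mean_frac_location=mfl, mean_frac_size=mfs, mean_frac_shape=mfsh,
        mean_rho=mrho, flags=frozenset(flags),
    )
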