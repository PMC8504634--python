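"""Asymptotic two-sample test (ASY) for continuous data.

For continuous, tie-free data the permutation machinery of the SP test can
be replaced by the limiting null law of the scaled statistic.  Both samples
are first mapped through the pooled empirical probability transform
(pooled mid-ranks scaled to (0, 1)), which under H0 makes them
asymptotically uniform and renders the limit parameter-free: the scaled
squared 2-Wasserstein distance

.. math::

    T = \\frac{nm}{n+m} \\; d\\big(\\tilde F_A, \\tilde F_B\\big)

converges under H0 to :math:`\\int_0^1 B(t)^2\\,dt` for a standard Brownian
bridge :math:`B` — the same limit as the two-sample Cramér-von Mises
statistic, with analytic mean ``1/6``.  The reference law is simulated once
from discretised bridge paths and cached; the p-value is the pseudo-counted
upper-tail fraction of the reference at ``T``.

This route is for continuous data only: heavy ties (e.g. scRNA-seq zeros)
break the uniform transform and such data should use the SP test instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .distance import QuantileGrid, _as_sample, default_grid, wasserstein_squared

__all__ = ["NullReference", "simulate_null_reference", "asy_test"]

_CHUNK = 2000


@dataclass(frozen=True)
class NullReference:
    """Simulated draws of the limiting null law ∫ B(t)² dt."""

    values: np.ndarray
    n_sims: int
    grid_size: int
    seed: int


def simulate_null_reference(n_sims: int = 100_000, grid_size: int = 1000,
                            seed: int = 0,
                            cache_path: str | Path | None = None) -> NullReference:
    """Simulate the squared-Brownian-bridge integral ∫₀¹ B(t)² dt.

    Bridges are built on ``grid_size`` equispaced points from cumulative
    Gaussian increments with the endpoint pinned to zero; the integral is
    the grid mean of B².  Mean 1/6 and variance 1/45 are analytic checks.
    Results are cached to ``cache_path`` (two files: .npy values + .json
    metadata) and reloaded when the metadata matches.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if grid_size < 10:
        raise ValueError("grid_size must be >= 10")

    if cache_path is not None:
        cache_path = Path(cache_path)
        meta_path = cache_path.with_suffix(".json")
        if cache_path.exists() and meta_path.exists():
            meta = json.loads(meta_path.read_text())
            if meta == {"n_sims": n_sims, "grid_size": grid_size, "seed": seed}:
                values = np.load(cache_path)
                return NullReference(values, n_sims, grid_size, seed)

    rng = np.random.default_rng(seed)
    t = np.arange(1, grid_size + 1) / grid_size
    out = np.empty(n_sims)
    done = 0
    while done < n_sims:
        m = min(_CHUNK, n_sims - done)
        w = np.cumsum(rng.standard_normal((m, grid_size)) / np.sqrt(grid_size),
                      axis=1)
        bridge = w - t * w[:, -1:]
        out[done:done + m] = np.mean(bridge**2, axis=1)
        done += m

    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.save(cache_path, out)
        cache_path.with_suffix(".json").write_text(json.dumps(
            {"n_sims": n_sims, "grid_size": grid_size, "seed": seed}))
    return NullReference(out, n_sims, grid_size, seed)


def _pooled_probability_transform(xa: np.ndarray, xb: np.ndarray):
    """Map both samples through the pooled empirical CDF via mid-ranks."""
    pooled = np.concatenate([xa, xb])
    ranks = stats.rankdata(pooled, method="average")
    u = (ranks - 0.5) / pooled.size
    return u[:xa.size], u[xa.size:]


def asy_test(a, b, reference: NullReference,
             grid: QuantileGrid | None = None) -> float:
    """P-value of the asymptotic test of H0: F_A = F_B for continuous data.

    Warns when more than 1% of pooled values are tied, since the limit is
    derived for continuous distributions.
    """
    xa = _as_sample(a)
    xb = _as_sample(b)
    pooled = np.concatenate([xa, xb])
    if np.std(pooled) == 0.0:
        raise ValueError("degenerate data for asymptotic test")
    n_ties = pooled.size - np.unique(pooled).size
    if n_ties > 0.01 * pooled.size:
        warnings.warn(
            "more than 1% of pooled values are tied; the asymptotic test "
            "assumes continuous data — consider the SP permutation test",
            stacklevel=2,
        )
    if grid is None:
        grid = default_grid()
    ua, ub = _pooled_probability_transform(xa, xb)
    n, m = xa.size, xb.size
    t_stat = (n * m / (n + m)) * wasserstein_squared(ua, ub, grid)
    return (int(np.sum(reference.values >= t_stat)) + 1) / (reference.n_sims + 1)
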