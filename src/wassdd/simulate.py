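"""Synthetic benchmark data with known differential-distribution structure.

The single-cell generator emulates the classic scDD benchmark design:
``G = 1000`` genes over two conditions with ``C`` cells each, where 100
genes are differentially distributed, split evenly over four categories
(25 genes each), and the 900 null genes split evenly between a one- and a
two-component negative-binomial model:

* **DE** — unimodal in both conditions, condition-B mean scaled by a
  drawn fold change (classic differential expression),
* **DP** — both conditions bimodal with the same two modes but mixing
  proportions pi vs 1-pi (differential proportion within modes),
* **DM** — condition A unimodal at mode 1, condition B an equal mixture
  of modes 1 and 2 (differential modality),
* **DB** — condition A unimodal at the midpoint of the two modes,
  condition B an equal mixture of the modes (differential modality and
  component means),
* **EE** — one NB component, identical in both conditions,
* **EP** — two NB components with the same mixing in both conditions.

Per gene, a baseline mean is drawn log-uniformly on [20, 500] and an NB
size (dispersion) parameter uniformly on [0.5, 5] — realistic
overdispersed count magnitudes for normalized scRNA-seq — and the second
mode sits at baseline x FC with FC ~ Normal(fc_mean, fc_sd) truncated at
1.5 to keep the modes separated.  The degree of DD is controlled by
``fc_mean`` (2 = weak, 4 = medium, 6 = strong; spread 2).  Zeros arise
naturally from the NB draws; no extra dropout layer is added.

A small continuous generator (normal / gamma pairs) supports validation
of the SP and ASY tests and of the decomposition against closed-form
population values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CATEGORIES",
    "DD_CATEGORIES",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_continuous_pair",
]

DD_CATEGORIES = ("DE", "DP", "DM", "DB")
CATEGORIES = DD_CATEGORIES + ("EE", "EP")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 1000
    n_cells: int = 100
    n_per_dd_category: int = 25
    n_ee: int = 450
    n_ep: int = 450
    fc_mean: float = 4.0
    fc_sd: float = 2.0
    fc_min: float = 1.5
    nb_mean_log_range: tuple[float, float] = (math.log(20.0), math.log(500.0))
    nb_dispersion_range: tuple[float, float] = (0.5, 5.0)
    dp_pi: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    ep_pi: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes != 4 * self.n_per_dd_category + self.n_ee + self.n_ep:
            raise ValueError(
                "n_genes must equal 4*n_per_dd_category + n_ee + n_ep")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells per condition")
        if self.fc_min <= 1.0:
            raise ValueError("fc_min must exceed 1 to separate the modes")


@dataclass(frozen=True)
class SimulatedDataset:
    counts_a: np.ndarray  # genes x cells, nonnegative integers
    counts_b: np.ndarray
    labels: np.ndarray  # per-gene category
    gene_ids: list[str] = field(repr=False)
    config: SimulationConfig = field(repr=False)

    @property
    def is_dd(self) -> np.ndarray:
        return np.isin(self.labels, DD_CATEGORIES)


def _nb(rng, mean, size_param, n):
    return rng.negative_binomial(size_param, size_param / (size_param + mean), n)


def _mixture(rng, means, weights, size_param, n):
    comp = rng.choice(len(means), size=n, p=weights)
    out = np.empty(n, dtype=np.int64)
    for i, mu in enumerate(means):
        m = comp == i
        out[m] = _nb(rng, mu, size_param, int(m.sum()))
    return out


def _truncated_fc(rng, cfg: SimulationConfig) -> float:
    while True:
        fc = rng.normal(cfg.fc_mean, cfg.fc_sd)
        if fc >= cfg.fc_min:
            return float(fc)


def _simulate_gene(rng, label: str, cfg: SimulationConfig):
    lo, hi = cfg.nb_mean_log_range
    mu1 = float(np.exp(rng.uniform(lo, hi)))
    size_param = float(rng.uniform(*cfg.nb_dispersion_range))
    fc = _truncated_fc(rng, cfg)
    mu2 = mu1 * fc
    c = cfg.n_cells

    if label == "EE":
        a = _nb(rng, mu1, size_param, c)
        b = _nb(rng, mu1, size_param, c)
    elif label == "EP":
        w = (cfg.ep_pi, 1.0 - cfg.ep_pi)
        a = _mixture(rng, (mu1, mu2), w, size_param, c)
        b = _mixture(rng, (mu1, mu2), w, size_param, c)
    elif label == "DE":
        a = _nb(rng, mu1, size_param, c)
        b = _nb(rng, mu2, size_param, c)
    elif label == "DP":
        pa, pb = cfg.dp_pi
        a = _mixture(rng, (mu1, mu2), (pa, 1.0 - pa), size_param, c)
        b = _mixture(rng, (mu1, mu2), (pb, 1.0 - pb), size_param, c)
    elif label == "DM":
        a = _nb(rng, mu1, size_param, c)
        b = _mixture(rng, (mu1, mu2), (0.5, 0.5), size_param, c)
    elif label == "DB":
        a = _nb(rng, (mu1 + mu2) / 2.0, size_param, c)
        b = _mixture(rng, (mu1, mu2), (0.5, 0.5), size_param, c)
    else:  # pragma: no cover
        raise ValueError(f"unknown category {label!r}")
    return a, b


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate a labeled two-condition count dataset.

    Per-gene RNG streams are spawned from the master seed so each gene's
    data is reproducible independently of the others.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)

    labels = np.array(
        [cat for cat in DD_CATEGORIES for _ in range(config.n_per_dd_category)]
        + ["EE"] * config.n_ee + ["EP"] * config.n_ep
    )
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_genes)

    counts_a = np.empty((config.n_genes, config.n_cells), dtype=np.int64)
    counts_b = np.empty_like(counts_a)
    for g, (label, child) in enumerate(zip(labels, children)):
        rng = np.random.default_rng(child)
        counts_a[g], counts_b[g] = _simulate_gene(rng, label, config)

    width = len(str(config.n_genes))
    gene_ids = [f"gene{g + 1:0{width}d}" for g in range(config.n_genes)]
    return SimulatedDataset(counts_a=counts_a, counts_b=counts_b,
                            labels=labels, gene_ids=gene_ids, config=config)


def simulate_continuous_pair(family: str, params_a, params_b, n: int, seed: int = 0):
    """Two i.i.d. continuous samples for test validation.

    ``family`` is ``"normal"`` (params ``(loc, scale)``) or ``"gamma"``
    (params ``(shape, scale)``).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if family == "normal":
        draw = lambda p, r: r.normal(p[0], p[1], n)
        for p in (params_a, params_b):
            if p[1] <= 0:
                raise ValueError("normal scale must be positive")
    elif family == "gamma":
        draw = lambda p, r: r.gamma(p[0], p[1], n)
        for p in (params_a, params_b):
            if p[0] <= 0 or p[1] <= 0:
                raise ValueError("gamma parameters must be positive")
    else:
        raise ValueError("family must be 'normal' or 'gamma'")
    return draw(params_a, rng), draw(params_b, rng)
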