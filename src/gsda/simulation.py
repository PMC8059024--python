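"""Synthetic-data generator and level/power harness for the distance-correlation test.

The generator reproduces the structure of a standard gene-set simulation
design:

* **Collection A** — 100 genes partitioned among 60 overlapping gene sets of
  8-10 genes each; 10 genes are "associated" and exactly 10 sets contain at
  least one of them (the other 50 sets are null).
* **Collection B** — 1000 genes, 100 sets of 10-100 genes; 10 associated
  genes, exactly 20 sets containing at least one.

Expression of null genes is iid standard normal.  A latent standard-normal
subject vector ``L`` drives both the endpoint and the associated genes:

* simple association — gene g = beta * L + noise;
* complex association — gene g = Z * beta * L + noise, where ``Z`` is a
  per-subject random sign vector shared by the associated genes.  Within the
  Z = +1 subjects the associated genes are positively inter-correlated and
  within Z = -1 negatively — a differential-correlation pattern with no mean
  shift, invisible to per-gene location tests.

Endpoints derive from ``L``: quantitative ``y = L + N(0,1)``; categorical by
a median split of ``L + N(0,1)`` into two equal groups; survival with event
times exponential at rate ``exp(L)`` under independent Uniform(0, c)
censoring, with ``c`` calibrated by quadrature to a target censoring
fraction.

Level (type I error) and power are estimated by Monte-Carlo: the fraction of
replicates in which each gene set's t-test p-value falls below the nominal
alpha, averaged over null sets (level) and associated sets (power).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform

from .distance_core import dcor, dcor_t_test, u_center
from .endpoints import Endpoint
from .exceptions import DegenerateError, InputError
from .io import GeneSet

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "build_collection",
    "generate_dataset",
    "estimate_level_power",
    "LevelPowerResult",
]

COLLECTIONS = {
    # genes, associated genes, sets, (min,max) set size, sets containing signal
    "A": dict(n_genes=100, n_associated=10, n_sets=60, size_range=(8, 10), n_assoc_sets=10),
    "B": dict(n_genes=1000, n_associated=10, n_sets=100, size_range=(10, 100), n_assoc_sets=20),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulation setting.

    ``n`` is the number of subjects per group for a categorical endpoint and
    the total number of subjects otherwise.  ``beta`` scales the latent
    variable in associated genes and ``noise_sd`` the residual, so the
    default 1.0/1.0 gives a 1:1 signal-to-noise ratio.  ``censor_frac`` is
    the target fraction of censored subjects (survival only).
    """

    collection: str = "A"
    endpoint: str = "quantitative"
    association: str = "simple"
    n: int = 50
    beta: float = 1.0
    noise_sd: float = 1.0
    censor_frac: float = 0.3
    reps: int = 500
    seed: int = 0
    shared_flip: bool = True  # one sign-flip vector per dataset (False: per gene)

    def __post_init__(self):
        if self.collection not in COLLECTIONS:
            raise InputError(f"unknown collection {self.collection!r}")
        if self.endpoint not in ("quantitative", "categorical", "survival"):
            raise InputError(f"unknown endpoint type {self.endpoint!r}")
        if self.association not in ("null", "simple", "complex"):
            raise InputError(f"unknown association {self.association!r}")
        if self.n < 4:
            raise InputError("n must be >= 4")
        if self.reps < 1:
            raise InputError("reps must be >= 1")
        if not 0 <= self.censor_frac < 1:
            raise InputError("censor_frac must be in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n if self.endpoint == "categorical" else self.n


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind one simulated dataset."""

    associated_genes: tuple[str, ...]
    associated_sets: tuple[str, ...]
    collection: tuple[GeneSet, ...]
    latent: np.ndarray = field(repr=False)
    flip: np.ndarray | None = field(default=None, repr=False)


def _gene_names(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"g{k + 1:0{width}d}" for k in range(n_genes)]


def build_collection(
    collection: str, seed: int
) -> tuple[list[GeneSet], tuple[str, ...], tuple[str, ...]]:
    """Draw the gene-set membership structure for a collection.

    Membership is a function of the master seed alone, so it is fixed across
    replicates of one configuration.  Returns (gene sets, associated gene
    names, names of sets containing at least one associated gene).
    """
    spec = COLLECTIONS[collection]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    genes = _gene_names(spec["n_genes"])
    assoc_idx = rng.choice(spec["n_genes"], size=spec["n_associated"], replace=False)
    assoc = [genes[i] for i in sorted(assoc_idx)]
    null_pool = [g for g in genes if g not in set(assoc)]
    lo, hi = spec["size_range"]
    sets: list[GeneSet] = []
    width = len(str(spec["n_sets"]))
    for k in range(spec["n_sets"]):
        name = f"{collection}{k + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if k < spec["n_assoc_sets"]:
            n_sig = int(rng.integers(1, min(3, len(assoc), size) + 1))
            members = list(rng.choice(assoc, size=n_sig, replace=False))
            members += list(rng.choice(null_pool, size=size - n_sig, replace=False))
        else:
            members = list(rng.choice(null_pool, size=size, replace=False))
        rng.shuffle(members)
        sets.append(GeneSet(name=name, genes=tuple(members), description=f"simulated {collection}"))
    assoc_sets = tuple(s.name for s in sets[: spec["n_assoc_sets"]])
    return sets, tuple(assoc), assoc_sets


@lru_cache(maxsize=32)
def _censoring_scale(censor_frac: float) -> float:
    """Upper bound c of the Uniform(0, c) censoring time giving the target
    marginal censoring fraction when T | L ~ Exp(rate = exp(L)), L ~ N(0,1).

    P(censored | L) = P(C < T | L) = (1 - exp(-lam c)) / (lam c), lam = e^L;
    the expectation over L is evaluated by Gauss-Hermite quadrature and the
    root found by Brent's method.
    """
    nodes, weights = np.polynomial.hermite.hermgauss(64)
    lam = np.exp(np.sqrt(2.0) * nodes)
    w = weights / np.sqrt(np.pi)

    def frac(c):
        return float(np.sum(w * (1.0 - np.exp(-lam * c)) / (lam * c)))

    return brentq(lambda c: frac(c) - censor_frac, 1e-9, 1e9, xtol=1e-12)


def _make_endpoint(cfg: SimulationConfig, L: np.ndarray, rng) -> Endpoint:
    N = L.size
    if cfg.endpoint == "quantitative":
        return Endpoint.quantitative(L + rng.standard_normal(N))
    if cfg.endpoint == "categorical":
        u = L + rng.standard_normal(N)
        labels = np.where(u > np.median(u), "high", "low")
        return Endpoint.categorical(labels)
    T = rng.exponential(scale=np.exp(-L))
    if cfg.censor_frac > 0:
        c = _censoring_scale(cfg.censor_frac)
        C = rng.uniform(0.0, c, size=N)
        o = np.minimum(T, C)
        s = (T <= C).astype(int)
    else:
        o, s = T, np.ones(N, dtype=int)
    return Endpoint.survival(np.maximum(o, 1e-300), s)


def generate_dataset(
    cfg: SimulationConfig, rep_index: int = 0
) -> tuple[pd.DataFrame, Endpoint, SimTruth]:
    """Generate one replicate dataset: expression frame, endpoint, ground truth.

    The same (seed, rep_index) pair always yields a bit-identical dataset;
    the gene-set membership depends on the seed only.
    """
    spec = COLLECTIONS[cfg.collection]
    sets, assoc_genes, assoc_sets = build_collection(cfg.collection, cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0, int(rep_index)]))
    N = cfg.n_subjects
    genes = _gene_names(spec["n_genes"])
    L = rng.standard_normal(N)
    X = rng.standard_normal((N, spec["n_genes"]))
    flip = None
    if cfg.association != "null":
        assoc_cols = [genes.index(g) for g in assoc_genes]
        noise = cfg.noise_sd * rng.standard_normal((N, len(assoc_cols)))
        if cfg.association == "simple":
            signal = cfg.beta * L[:, None]
        else:
            if cfg.shared_flip:
                flip = rng.choice((-1.0, 1.0), size=N)[:, None]
            else:
                flip = rng.choice((-1.0, 1.0), size=(N, len(assoc_cols)))
            signal = flip * cfg.beta * L[:, None]
            flip = flip[:, 0] if cfg.shared_flip else flip
        X[:, assoc_cols] = signal + noise
    endpoint = _make_endpoint(cfg, L, rng)
    subjects = [f"s{k + 1:04d}" for k in range(N)]
    frame = pd.DataFrame(X, index=subjects, columns=genes)
    truth = SimTruth(
        associated_genes=assoc_genes,
        associated_sets=assoc_sets,
        collection=tuple(sets),
        latent=L,
        flip=flip,
    )
    return frame, endpoint, truth


@dataclass(frozen=True)
class LevelPowerResult:
    """Per-set rejection rates with their null/associated averages."""

    table: pd.DataFrame  # columns: gene_set, truth_label, rejection_rate
    level: float  # average rejection rate over null sets
    power: float  # average rejection rate over associated sets
    alpha: float
    reps: int


def _set_pvalues(values: np.ndarray, gene_index: dict, sets, Yc: np.ndarray) -> np.ndarray:
    """t-test p for every gene set of one dataset (1.0 where degenerate)."""
    n = values.shape[0]
    out = np.empty(len(sets))
    for k, gs in enumerate(sets):
        cols = [gene_index[g] for g in gs.genes]
        D = squareform(pdist(values[:, cols]))
        try:
            out[k] = dcor_t_test(dcor(u_center(D), Yc), n).p_t
        except DegenerateError:
            out[k] = 1.0
    return out


def estimate_level_power(cfg: SimulationConfig, alpha: float = 0.05) -> LevelPowerResult:
    """Monte-Carlo level and power of the t-test over a gene-set collection.

    For each replicate every gene set is tested at the nominal ``alpha``;
    per-set rejection rates are averaged over the sets whose truth label is
    null (level) and associated (power).  Under ``association='null'`` every
    set is effectively null, but the collection's structural labels are kept
    so the level is averaged over the designated null sets.

    A warning is emitted when ``reps`` is too small for the Monte-Carlo
    standard error of a rate near ``alpha`` to stay below ``alpha / 2``.
    """
    min_reps = int(np.ceil(4 * (1 - alpha) / alpha))
    if cfg.reps < min_reps:
        warnings.warn(
            f"reps={cfg.reps} gives Monte-Carlo SE above alpha/2 at alpha={alpha}; "
            f"use at least {min_reps} replicates",
            stacklevel=2,
        )
    sets, _, assoc_sets = build_collection(cfg.collection, cfg.seed)
    gene_index = {g: i for i, g in enumerate(_gene_names(COLLECTIONS[cfg.collection]["n_genes"]))}
    rejections = np.zeros(len(sets))
    for rep in range(cfg.reps):
        X, endpoint, _ = generate_dataset(cfg, rep)
        Yc = u_center(endpoint.distance_matrix())
        pvals = _set_pvalues(X.to_numpy(), gene_index, sets, Yc)
        rejections += pvals < alpha
    rates = rejections / cfg.reps
    truth = np.array(
        ["associated" if s.name in set(assoc_sets) else "null" for s in sets]
    )
    table = pd.DataFrame(
        {"gene_set": [s.name for s in sets], "truth_label": truth, "rejection_rate": rates}
    )
    level = float(rates[truth == "null"].mean())
    power = float(rates[truth == "associated"].mean())
    return LevelPowerResult(table=table, level=level, power=power, alpha=alpha, reps=cfg.reps)
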