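"""Backward elimination of gene-set genes to isolate the empirical drivers.

A significant gene-set association may be carried by a subset of the genes.
Starting from the full matched set, each round evaluates the t-test p-value
of every leave-one-out subset of the current genes, removes the gene whose
exclusion gives the smallest p, and records the step; this repeats until one
gene remains.  The visited subsets (including the full set) form the
candidate pool, and the candidate with the smallest p-value is reported as
the empirical drivers.

The selected subset's p-value is a *selection criterion*, not a Type I error
rate: the hypothesis was chosen after looking at the data.  For strict error
control the whole elimination can be embedded in a permutation test
(:func:`eliminate_with_permutation`), which reruns the procedure on
endpoint-permuted data and compares best p-values.

Performance: squared Euclidean distances are additive over genes, so the
procedure keeps a per-gene stack of squared-difference matrices and a running
sum; dropping a gene is an O(n^2) subtraction instead of an O(n^2 m)
recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import _as_gene_set, match_genes
from .distance_core import dcor, dcor_t_test, u_center
from .endpoints import Endpoint, apply_transform
from .exceptions import DegenerateError, InputError
from .io import GeneSet

__all__ = ["EliminationTrace", "backward_eliminate", "eliminate_with_permutation"]


@dataclass(frozen=True)
class EliminationStep:
    removed_gene: str
    remaining_genes: tuple[str, ...]
    p_t: float


@dataclass(frozen=True)
class EliminationTrace:
    """Full record of one backward-elimination run.

    ``candidates`` holds every evaluated surviving subset — the original full
    set plus the subset remaining after each removal (sizes m, m-1, ..., 1) —
    with its p-value; ``best_subset``/``best_p`` select the minimum-p
    candidate, preferring the smaller subset on ties.  ``n_evaluations``
    counts leave-one-out p-value evaluations, m(m+1)/2 - 1 for m genes.
    """

    steps: tuple[EliminationStep, ...]
    candidates: tuple[tuple[tuple[str, ...], float], ...]
    best_subset: tuple[str, ...]
    best_p: float
    n_evaluations: int = 0
    best_score: float = 0.0  # -|t_d| of the best subset; orders candidates below p underflow

    def to_frame(self) -> pd.DataFrame:
        """Step table: one row per removal."""
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.steps) + 1),
                "removed_gene": [s.removed_gene for s in self.steps],
                "n_remaining": [len(s.remaining_genes) for s in self.steps],
                "remaining_genes": [",".join(s.remaining_genes) for s in self.steps],
                "p_t": [s.p_t for s in self.steps],
            }
        )


def _subset_p(S: np.ndarray, Yc: np.ndarray, n: int) -> tuple[float, float]:
    """(score, p) from a summed squared-difference matrix; (0, 1) if degenerate.

    The selection score is -|t_d|: at fixed n the two-sided p is a strictly
    increasing function of it, so ranking on the score is exactly ranking on
    p — but it stays informative where p itself underflows to 0.0 under
    strong association.
    """
    D = np.sqrt(np.clip(S, 0.0, None))
    try:
        res = dcor_t_test(dcor(u_center(D), Yc), n)
    except DegenerateError:
        return 0.0, 1.0
    return -abs(res.t_d), res.p_t


def _prepare(X: pd.DataFrame, gene_set, endpoint: Endpoint, transform: str):
    gs = _as_gene_set(gene_set)
    matched = match_genes(X, gs)
    if len(matched) < 2:
        raise InputError(
            f"backward elimination needs >= 2 matched genes; set {gs.name!r} has {len(matched)}"
        )
    if endpoint.n != X.shape[0]:
        raise InputError(
            f"endpoint has {endpoint.n} subjects but expression has {X.shape[0]}"
        )
    values = apply_transform(X[matched], transform).to_numpy()
    # per-gene squared-difference matrices: stack[g][i, j] = (x_ig - x_jg)^2
    diffs = values[:, None, :] - values[None, :, :]
    stack = np.ascontiguousarray(np.moveaxis(diffs * diffs, -1, 0))
    return matched, stack


def _eliminate(stack: np.ndarray, genes: list[str], Yc: np.ndarray) -> EliminationTrace:
    m, n = stack.shape[0], stack.shape[1]
    S = stack.sum(axis=0)
    score0, p0 = _subset_p(S, Yc, n)
    candidates: list[tuple[tuple[str, ...], float]] = [(tuple(genes), p0)]
    scores: list[float] = [score0]
    active = list(range(m))
    steps: list[EliminationStep] = []
    n_eval = 0
    while len(active) > 1:
        best_idx, best_score, best_p = None, np.inf, 1.0
        for g in active:
            score, p = _subset_p(S - stack[g], Yc, n)
            n_eval += 1
            # strict < breaks ties toward the lowest original column index
            if score < best_score:
                best_idx, best_score, best_p = g, score, p
        S = S - stack[best_idx]
        active.remove(best_idx)
        remaining = tuple(genes[g] for g in active)
        steps.append(EliminationStep(genes[best_idx], remaining, best_p))
        candidates.append((remaining, best_p))
        scores.append(best_score)
    # smallest p wins; among ties prefer the smaller (more parsimonious) subset
    order = min(range(len(candidates)), key=lambda k: (scores[k], len(candidates[k][0])))
    best_subset, best_p = candidates[order]
    return EliminationTrace(
        steps=tuple(steps),
        candidates=tuple(candidates),
        best_subset=best_subset,
        best_p=best_p,
        n_evaluations=n_eval,
        best_score=scores[order],
    )


def backward_eliminate(
    X: pd.DataFrame,
    gene_set,
    endpoint: Endpoint,
    transform: str = "none",
) -> EliminationTrace:
    """Backward-eliminate genes from a set to find the empirical drivers.

    Deterministic given the data: no randomness enters the elimination.
    Degenerate candidate subsets are assigned p = 1 and elimination
    continues.
    """
    matched, stack = _prepare(X, gene_set, endpoint, transform)
    Yc = u_center(endpoint.distance_matrix())
    return _eliminate(stack, matched, Yc)


def eliminate_with_permutation(
    X: pd.DataFrame,
    gene_set,
    endpoint: Endpoint,
    n_perm: int,
    seed=None,
    transform: str = "none",
) -> tuple[EliminationTrace, float]:
    """Selection-adjusted significance for the backward-eliminated subset.

    Reruns the entire elimination on each endpoint-permuted dataset and
    reports ``(1 + #{best_p_b <= best_p_observed}) / (n_perm + 1)`` — the
    chance that a null dataset, given the same freedom to choose its best
    subset, beats the observed best p.
    """
    if n_perm < 1:
        raise InputError("the number of permutation replicates must be >= 1")
    matched, stack = _prepare(X, gene_set, endpoint, transform)
    Yc = u_center(endpoint.distance_matrix())
    observed = _eliminate(stack, matched, Yc)
    rng = np.random.default_rng(seed)
    n = Yc.shape[0]
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        trace_b = _eliminate(stack, matched, Yc[np.ix_(p, p)])
        if trace_b.best_score <= observed.best_score:
            count += 1
    return observed, (1 + count) / (n_perm + 1)
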