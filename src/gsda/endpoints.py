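"""Endpoint variants and their pairwise distance metrics, plus expression transforms.

Three endpoint types are supported, each mapped to an n x n subject distance
matrix that feeds the distance-correlation machinery:

* quantitative — absolute difference |y_i - y_j| (Euclidean in one dimension);
* categorical — the indicator distance, 1 if the labels differ else 0;
* censored event time — a rank-like metric on (observation time o_i,
  status s_i) pairs: the number of unique *event* times falling between the
  two observation windows, counted from whichever subject actually had an
  event.  Two event-free (censored) subjects are at distance zero, and the
  metric depends on the times only through their order, so it is invariant
  under strictly monotone transformations of the time axis.

Two opt-in variance-equalising transforms of the expression matrix are also
provided (z-scoring and commensuration); they are never applied silently
because equalising gene contributions is advisable in some applications and
not in others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance_core import _check_n
from .exceptions import DegenerateEndpointError, InputError, ZeroVarianceError

__all__ = [
    "Endpoint",
    "quantitative_distance",
    "categorical_distance",
    "survival_distance",
    "zscore_transform",
    "commensurate_transform",
    "apply_transform",
]

ENDPOINT_KINDS = ("quantitative", "categorical", "survival")
TRANSFORMS = ("none", "zscore", "commensurate")


@dataclass(frozen=True)
class Endpoint:
    """A tagged endpoint variable: exactly one variant is populated.

    Construct via :meth:`quantitative`, :meth:`categorical` or
    :meth:`survival` rather than directly.
    """

    kind: str
    values: np.ndarray = field(repr=False)  # numeric values or opaque labels
    status: np.ndarray | None = field(default=None, repr=False)  # survival only
    subject_ids: tuple | None = None

    @classmethod
    def quantitative(cls, values, subject_ids=None) -> "Endpoint":
        y = np.asarray(values, dtype=float)
        if y.ndim != 1:
            raise InputError("quantitative endpoint must be a 1-D vector")
        if not np.all(np.isfinite(y)):
            raise InputError("non-finite values in quantitative endpoint")
        return cls("quantitative", y, None, _ids(subject_ids, y.size))

    @classmethod
    def categorical(cls, labels, subject_ids=None) -> "Endpoint":
        y = np.asarray(labels, dtype=object)
        if y.ndim != 1:
            raise InputError("categorical endpoint must be a 1-D vector")
        if any(pd.isna(v) for v in y):
            raise InputError("missing labels in categorical endpoint")
        return cls("categorical", y, None, _ids(subject_ids, y.size))

    @classmethod
    def survival(cls, time, status, subject_ids=None) -> "Endpoint":
        o = np.asarray(time, dtype=float)
        s = np.asarray(status)
        if o.ndim != 1 or s.shape != o.shape:
            raise InputError("survival endpoint needs matching 1-D time and status vectors")
        if not np.all(np.isfinite(o)) or np.any(o <= 0):
            raise InputError("observation times must be finite and positive")
        if not np.all(np.isin(s, (0, 1))):
            bad = sorted(set(np.asarray(s).tolist()) - {0, 1})
            raise InputError(f"status values must be 0 (censored) or 1 (event); found {bad}")
        return cls("survival", o, np.asarray(s, dtype=int), _ids(subject_ids, o.size))

    @property
    def n(self) -> int:
        return int(self.values.size)

    def subset(self, index) -> "Endpoint":
        """Endpoint restricted to positional ``index`` (preserving order)."""
        idx = np.asarray(index)
        ids = tuple(np.asarray(self.subject_ids)[idx]) if self.subject_ids else None
        status = self.status[idx] if self.status is not None else None
        return Endpoint(self.kind, self.values[idx], status, ids)

    def distance_matrix(self) -> np.ndarray:
        """Dispatch to the variant-appropriate pairwise distance."""
        if self.kind == "quantitative":
            return quantitative_distance(self.values)
        if self.kind == "categorical":
            return categorical_distance(self.values)
        return survival_distance(self.values, self.status)


def _ids(subject_ids, n):
    if subject_ids is None:
        return None
    ids = tuple(subject_ids)
    if len(ids) != n:
        raise InputError(f"{len(ids)} subject ids for {n} values")
    return ids


def quantitative_distance(y) -> np.ndarray:
    """|y_i - y_j| for a numeric endpoint (1-D Euclidean distance)."""
    y = np.asarray(y, dtype=float)
    _check_n(y.size)
    if not np.all(np.isfinite(y)):
        raise InputError("non-finite values in quantitative endpoint")
    return np.abs(y[:, None] - y[None, :])


def categorical_distance(y) -> np.ndarray:
    """Indicator distance: 1 where labels differ, 0 where they agree.

    Labels are compared by exact token equality; merging of categories is the
    caller's responsibility (the metric changes when groups are combined).
    """
    y = np.asarray(y, dtype=object)
    _check_n(y.size)
    codes = pd.factorize(y)[0]
    if codes.max() == 0:
        raise DegenerateEndpointError(
            "categorical endpoint has a single label; no association is definable"
        )
    return (codes[:, None] != codes[None, :]).astype(float)


def survival_distance(time, status) -> np.ndarray:
    """Censored event-time distance.

    With u_1 < ... < u_s the unique times of subjects that had an event, the
    distance between subjects i and j is

        sum_l I(o_j > u_l >= o_i) I(s_i = 1) + I(o_i > u_l >= o_j) I(s_j = 1)

    i.e. the number of unique event times separating the pair, counted only
    from a subject that actually experienced the event.  Computed in
    O(n log n) via cumulative counts on the sorted event-time grid.
    """
    o = np.asarray(time, dtype=float)
    s = np.asarray(status, dtype=int)
    _check_n(o.size)
    if o.ndim != 1 or s.shape != o.shape:
        raise InputError("time and status must be matching 1-D vectors")
    grid = np.unique(o[s == 1])
    if grid.size == 0:
        raise DegenerateEndpointError("no events observed; the survival distance is identically zero")
    # below[i] = number of grid times strictly below o_i; at_or_below counts <= o_i
    below = np.searchsorted(grid, o, side="left")
    # count of u_l with o_i <= u_l < o_j  =  below[j] - below[i]  (clipped at 0)
    span = np.clip(below[None, :] - below[:, None], 0, None).astype(float)
    D = span * (s[:, None] == 1) + span.T * (s[None, :] == 1)
    np.fill_diagonal(D, 0.0)
    return D


def zscore_transform(X: pd.DataFrame) -> pd.DataFrame:
    """Center each gene and scale to unit sample standard deviation (ddof=1)."""
    values = np.asarray(X, dtype=float)
    sd = values.std(axis=0, ddof=1)
    zero = sd <= 0
    if np.any(zero):
        cols = X.columns[zero] if isinstance(X, pd.DataFrame) else np.nonzero(zero)[0]
        raise ZeroVarianceError(list(cols))
    out = (values - values.mean(axis=0)) / sd
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


def commensurate_transform(X: pd.DataFrame) -> pd.DataFrame:
    """Center each gene, then scale by its sum of pairwise absolute differences.

    After the transform each gene's sum of |x_ig - x_jg| over all unordered
    subject pairs equals 1, so every gene contributes comparably to the
    Euclidean distance.  The unordered-pair convention is a pure scale choice:
    it cancels in the distance correlation.
    """
    values = np.asarray(X, dtype=float)
    n = values.shape[0]
    centered = values - values.mean(axis=0)
    # sum over unordered pairs of |x_i - x_j|, per gene, via sorting:
    # contribution of the k-th order statistic is (2k - n + 1) * x_(k)
    srt = np.sort(centered, axis=0)
    weights = 2 * np.arange(n) - n + 1
    pair_sums = np.einsum("ij,i->j", srt, weights.astype(float))
    zero = pair_sums <= 0
    if np.any(zero):
        cols = X.columns[zero] if isinstance(X, pd.DataFrame) else np.nonzero(zero)[0]
        raise ZeroVarianceError(list(cols))
    out = centered / pair_sums
    if isinstance(X, pd.DataFrame):
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out


def apply_transform(X: pd.DataFrame, transform: str) -> pd.DataFrame:
    """Apply a named expression transform ('none', 'zscore', 'commensurate')."""
    if transform not in TRANSFORMS:
        raise InputError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    if transform == "zscore":
        return zscore_transform(X)
    if transform == "commensurate":
        return commensurate_transform(X)
    return X
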