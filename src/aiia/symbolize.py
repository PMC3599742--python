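"""Symbolization of RRID series via 1-D K-Means.

Each RR-interval difference is assigned to the nearest of ``k`` cluster
centroids fitted by Lloyd's algorithm, and each cluster is mapped to one of
the first ``k`` lowercase letters, smallest centroid first.  A record's
difference series thus becomes a string over ``a..{k-th letter}`` whose
n-gram statistics characterise the record's beat-to-beat dynamics.

The fit is fully deterministic: initial centroids are data quantiles at
positions ``(i + 0.5)/k``, assignment ties break toward the lower-indexed
(smaller) centroid, and empty clusters are re-seeded at the point currently
farthest from its assigned centroid.  Determinism makes every downstream
gram count and accuracy reproducible from (data, k, seed, tol) alone.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    AlphabetOverflowError,
    InfeasibleKError,
    ParameterError,
)
from .preprocess import RRIDSeries, RRRecord, compute_rrid

__all__ = [
    "SymbolModel",
    "SymbolSequence",
    "kmeans_fit",
    "assign_symbols",
    "symbolize_record",
    "KMeansSymbolizer",
]

_ALPHABET = string.ascii_lowercase

DEFAULT_MAX_ITER = 300
DEFAULT_TOL = 1e-6  # ms; max centroid movement declaring convergence


@dataclass(frozen=True)
class SymbolModel:
    """Fitted 1-D K-Means centroids with their letter mapping.

    ``centroids`` are stored in strictly ascending order and letter ``i`` of
    the alphabet labels centroid ``i``, so 'a' always denotes the most
    negative differences (strongest acceleration) and the last letter the
    most positive (strongest deceleration).
    """

    k: int
    centroids: np.ndarray
    fit_scope: str = "per_record"
    seed: int = 0
    n_iter: int = 0
    inertia: float = float("nan")
    inertia_history: tuple = field(default=(), repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        if c.size != self.k:
            raise ParameterError(f"expected {self.k} centroids, got {c.size}")
        if np.any(np.diff(c) <= 0):
            raise ParameterError("centroids must be strictly ascending")
        object.__setattr__(self, "centroids", c)

    @property
    def letter_map(self) -> dict:
        """Centroid index -> letter, ascending centroids alphabetically."""
        return {i: _ALPHABET[i] for i in range(self.k)}

    @property
    def alphabet(self) -> str:
        return _ALPHABET[: self.k]


@dataclass(frozen=True)
class SymbolSequence:
    """A record rendered as a string over the first ``k`` letters."""

    record_id: str
    symbols: str
    label: Optional[str] = None

    def __len__(self) -> int:
        return len(self.symbols)


def _check_k(k: int) -> None:
    if k > 26:
        raise AlphabetOverflowError(f"k={k} exceeds the 26-letter alphabet")
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")


def kmeans_fit(
    values: Sequence[float],
    k: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    fit_scope: str = "per_record",
) -> SymbolModel:
    """Fit 1-D K-Means (Lloyd's algorithm) with deterministic quantile init.

    Parameters
    ----------
    values : array-like of float
        The RRID values to cluster; must contain at least ``k`` distinct
        numbers.
    k : int
        Number of clusters, 2..26.
    seed : int
        Recorded on the model for provenance; the fit itself is
        deterministic and does not consume randomness.
    max_iter, tol : int, float
        Lloyd's iteration stops when the maximum centroid movement drops
        below ``tol`` (milliseconds) or after ``max_iter`` sweeps.

    Returns
    -------
    SymbolModel
        Centroids sorted ascending, with the per-iteration within-cluster
        sum of squares recorded in ``inertia_history``.
    """
    _check_k(k)
    x = np.asarray(values, dtype=float).ravel()
    n_distinct = np.unique(x).size
    if n_distinct < k:
        raise InfeasibleKError(
            f"k={k} infeasible: only {n_distinct} distinct values"
        )
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")

    # Quantile seeding: centroids start at the (i+0.5)/k data quantiles.
    centroids = np.quantile(x, (np.arange(k) + 0.5) / k)

    history = []
    n_iter = 0
    inertia = np.nan
    for n_iter in range(1, max_iter + 1):
        # Assignment: nearest centroid, ties to the lower index (argmin
        # returns the first minimum).
        dists = np.abs(x[:, None] - centroids[None, :])
        assign = np.argmin(dists, axis=1)

        # Re-seed empty clusters at the point farthest from its centroid.
        counts = np.bincount(assign, minlength=k)
        for empty in np.flatnonzero(counts == 0):
            resid = np.abs(x - centroids[assign])
            far = int(np.argmax(resid))
            centroids[empty] = x[far]
            assign[far] = empty
            counts = np.bincount(assign, minlength=k)

        inertia = float(np.sum((x - centroids[assign]) ** 2))
        history.append(inertia)

        # Update: arithmetic mean of assigned points.
        sums = np.bincount(assign, weights=x, minlength=k)
        new_centroids = sums / counts
        move = float(np.max(np.abs(new_centroids - centroids)))
        centroids = new_centroids
        if move < tol:
            break

    order = np.argsort(centroids, kind="stable")
    return SymbolModel(
        k=k,
        centroids=centroids[order],
        fit_scope=fit_scope,
        seed=seed,
        n_iter=n_iter,
        inertia=inertia,
        inertia_history=tuple(history),
    )


def assign_symbols(diffs, model: SymbolModel) -> SymbolSequence:
    """Map each RRID value to the letter of its nearest centroid.

    Ties (a value exactly midway between two centroids) break toward the
    smaller centroid, i.e. the alphabetically earlier letter.
    """
    if isinstance(diffs, RRIDSeries):
        record_id, label, x = diffs.record_id, diffs.label, diffs.diffs
    else:
        record_id, label, x = "", None, np.asarray(diffs, dtype=float).ravel()
    idx = np.argmin(np.abs(x[:, None] - model.centroids[None, :]), axis=1)
    letters = np.frombuffer(model.alphabet.encode(), dtype=np.uint8)
    symbols = letters[idx].tobytes().decode()
    return SymbolSequence(record_id=record_id, symbols=symbols, label=label)


def symbolize_record(
    record: RRRecord,
    k: int,
    seed: int = 0,
    fit_scope: str = "per_record",
    pooled_model: Optional[SymbolModel] = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
):
    """Symbolize one record end to end; returns (sequence, model used).

    With ``fit_scope="per_record"`` the K-Means model is fitted on this
    record's own differences (the adaptive reading: each record gets its own
    partition of its RRID range).  With ``"pooled"`` a model fitted
    elsewhere — on training records only — must be supplied.
    """
    rrid = compute_rrid(record)
    if fit_scope == "per_record":
        model = kmeans_fit(rrid.diffs, k, seed=seed, max_iter=max_iter, tol=tol)
    elif fit_scope == "pooled":
        if pooled_model is None:
            raise ParameterError("pooled fit scope requires pooled_model")
        model = pooled_model
    else:
        raise ParameterError(f"unknown fit_scope {fit_scope!r}")
    return assign_symbols(rrid, model), model


class KMeansSymbolizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer: RRID series to symbol sequences.

    Parameters
    ----------
    n_clusters : int, default 10
        Alphabet size ``k`` (2..26).
    fit_scope : {"per_record", "pooled"}, default "per_record"
        ``per_record`` fits a fresh K-Means on each record's own
        differences at transform time (``fit`` only validates parameters);
        ``pooled`` fits one model on the concatenated differences of the
        records passed to ``fit`` and applies it to every record, which
        makes letters comparable across records.  Inside a pipeline the
        pooled model therefore sees training records only.
    random_state : int, default 0
        Recorded seed; the fit is deterministic.
    max_iter, tol
        Lloyd's stopping rule (see :func:`kmeans_fit`).

    Attributes
    ----------
    model_ : SymbolModel
        The pooled model (``fit_scope="pooled"`` only).
    """

    def __init__(
        self,
        n_clusters: int = 10,
        fit_scope: str = "per_record",
        random_state: int = 0,
        max_iter: int = DEFAULT_MAX_ITER,
        tol: float = DEFAULT_TOL,
    ):
        self.n_clusters = n_clusters
        self.fit_scope = fit_scope
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def _as_rrid(self, X) -> list:
        out = []
        for i, item in enumerate(X):
            if isinstance(item, RRIDSeries):
                out.append(item)
            elif isinstance(item, RRRecord):
                out.append(compute_rrid(item))
            else:
                arr = np.asarray(item, dtype=float).ravel()
                out.append(
                    RRIDSeries(
                        record_id=f"record_{i}",
                        diffs=arr,
                        source_length=arr.size + 1,
                    )
                )
        return out

    def fit(self, X, y=None) -> "KMeansSymbolizer":
        _check_k(self.n_clusters)
        if self.fit_scope not in ("per_record", "pooled"):
            raise ParameterError(f"unknown fit_scope {self.fit_scope!r}")
        if self.fit_scope == "pooled":
            series = self._as_rrid(X)
            pooled = np.concatenate([s.diffs for s in series])
            self.model_ = kmeans_fit(
                pooled,
                self.n_clusters,
                seed=self.random_state,
                max_iter=self.max_iter,
                tol=self.tol,
                fit_scope="pooled",
            )
        return self

    def transform(self, X) -> list:
        series = self._as_rrid(X)
        if self.fit_scope == "pooled":
            from sklearn.utils.validation import check_is_fitted

            check_is_fitted(self, "model_")
            return [assign_symbols(s, self.model_) for s in series]
        return [
            symbolize_record_diffs(
                s,
                self.n_clusters,
                seed=self.random_state,
                max_iter=self.max_iter,
                tol=self.tol,
            )
            for s in series
        ]


def symbolize_record_diffs(
    rrid: RRIDSeries,
    k: int,
    seed: int = 0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> SymbolSequence:
    """Per-record symbolization from an already-differenced series."""
    model = kmeans_fit(rrid.diffs, k, seed=seed, max_iter=max_iter, tol=tol)
    return assign_symbols(rrid, model)
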