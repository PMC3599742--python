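"""RR-interval records and their successive differences.

The substrate of the whole method is the RR-interval difference (RRID)
series: for an interbeat-interval series ``x_1 .. x_N`` (milliseconds), the
signed differences ``x_{i+1} - x_i`` preserve both the magnitude and the
direction (acceleration vs deceleration) of beat-to-beat variation.  No
detrending, windowing or local-mean normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import TooShortRecordError, ValidationError

__all__ = [
    "RRRecord",
    "RRIDSeries",
    "compute_rrid",
    "no_artifact_filter",
    "RRIDifferencer",
]


@dataclass(frozen=True)
class RRRecord:
    """An ordered series of interbeat intervals in milliseconds.

    Parameters
    ----------
    record_id : str
        Identifier of the recording.
    intervals : ndarray of float
        Interbeat intervals, strictly positive, length >= 2.  Always stored
        in milliseconds; unit conversion is an I/O concern.
    label : str, optional
        Class name for supervised runs (e.g. ``"AF"``, ``"CHF"``, ``"WNU"``).
    """

    record_id: str
    intervals: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise TooShortRecordError(
                f"record {self.record_id!r}: need at least 2 intervals, "
                f"got {arr.size}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(
                f"record {self.record_id!r}: non-finite interval value"
            )
        if np.any(arr <= 0):
            bad = int(np.argmax(arr <= 0))
            raise ValidationError(
                f"record {self.record_id!r}: non-positive interval "
                f"{arr[bad]} at position {bad}"
            )
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class RRIDSeries:
    """Signed successive differences of an :class:`RRRecord` (milliseconds)."""

    record_id: str
    diffs: np.ndarray
    source_length: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.diffs, dtype=float)
        if arr.size != self.source_length - 1:
            raise ValidationError(
                f"record {self.record_id!r}: {arr.size} diffs inconsistent "
                f"with source length {self.source_length}"
            )
        object.__setattr__(self, "diffs", arr)

    def __len__(self) -> int:
        return int(self.diffs.size)


def compute_rrid(record: RRRecord) -> RRIDSeries:
    """Compute the RR-interval difference series of a record.

    Returns the signed differences ``intervals[i+1] - intervals[i]`` in
    original order; the output has exactly one element fewer than the input.
    The telescoping identity ``sum(diffs) == last - first`` holds exactly up
    to floating point.
    """
    return RRIDSeries(
        record_id=record.record_id,
        diffs=np.diff(record.intervals),
        source_length=len(record),
        label=record.label,
    )


def no_artifact_filter(record: RRRecord) -> RRRecord:
    """Identity hook for ectopic-beat / artifact filtering.

    The pipeline applies no beat filtering; this hook documents where a
    filter would plug in, and returns the record unchanged.
    """
    return record


class RRIDifferencer(BaseEstimator, TransformerMixin):
    """Stateless transformer: RR records to RRID series.

    Accepts a sequence of :class:`RRRecord` (or raw 1-D interval arrays) and
    returns a list of :class:`RRIDSeries`.  ``fit`` is a no-op, present for
    scikit-learn pipeline compatibility.
    """

    def fit(self, X: Sequence, y=None) -> "RRIDifferencer":
        return self

    def transform(self, X: Sequence) -> list:
        out = []
        for i, rec in enumerate(X):
            if not isinstance(rec, RRRecord):
                rec = RRRecord(record_id=f"record_{i}", intervals=np.asarray(rec))
            out.append(compute_rrid(rec))
        return out
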