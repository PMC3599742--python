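"""Text I/O for RR records, symbol sequences and feature matrices.

RR records are plain text with one interbeat interval per line — the
format produced by ``ann2rr``-style exports of beat annotation files.
Blank lines and ``#`` comments are skipped.  Units may be milliseconds or
seconds on disk; everything is milliseconds in memory.

Feature matrices are CSV with columns ``record_id, label`` followed by one
column per gram in canonical vocabulary order, so files from identical
runs are byte-comparable.  Probabilities are printed with 12 significant
digits and round-trip losslessly through :func:`read_feature_matrix`.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, ShapeError, TooShortRecordError
from .grams import GramFeatures, GramVocabulary, build_vocabulary
from .preprocess import RRRecord
from .symbolize import SymbolSequence

__all__ = [
    "read_rr_record",
    "write_rr_record",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_symbol_fasta",
    "write_symbol_fasta",
    "read_manifest",
    "write_manifest",
]

_FLOAT_FMT = "%.12g"


def read_rr_record(
    path: Union[str, Path],
    unit: str = "ms",
    record_id: Optional[str] = None,
    label: Optional[str] = None,
) -> RRRecord:
    """Read a one-interval-per-line RR record.

    Parameters
    ----------
    path : path
        Text file; blank lines and lines starting with ``#`` are skipped.
    unit : {"ms", "s"}
        Unit of the values on disk; seconds are converted to milliseconds.
    record_id : str, optional
        Defaults to the file stem.
    label : str, optional
        Class label to attach.
    """
    if unit not in ("ms", "s"):
        raise ParameterError(f"unit must be 'ms' or 's', got {unit!r}")
    path = Path(path)
    values: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: not a number: {text!r}"
                ) from None
    if len(values) < 2:
        raise TooShortRecordError(
            f"{path}: need at least 2 intervals, found {len(values)}"
        )
    arr = np.asarray(values)
    if unit == "s":
        arr = arr * 1000.0
    return RRRecord(
        record_id=record_id if record_id is not None else path.stem,
        intervals=arr,
        label=label,
    )


def write_rr_record(record: RRRecord, path: Union[str, Path]) -> None:
    """Write a record as one millisecond value per line."""
    with open(path, "w") as fh:
        fh.write(f"# record_id={record.record_id}")
        if record.label:
            fh.write(f" label={record.label}")
        fh.write("\n")
        for v in record.intervals:
            fh.write(_FLOAT_FMT % v + "\n")


def write_feature_matrix(
    features: Sequence[GramFeatures], path: Union[str, Path],
    vocabulary: Optional[GramVocabulary] = None,
) -> None:
    """Write gram features as CSV, one row per record.

    All features must share one vocabulary (same k and n_max); columns are
    ``record_id, label`` then the grams in canonical order.  An empty
    feature list requires ``vocabulary`` to be passed for the header.
    """
    if features:
        vocab = features[0].vocabulary
        for f in features[1:]:
            if f.vocabulary.k != vocab.k or f.vocabulary.n_max != vocab.n_max:
                raise ShapeError(
                    f"record {f.record_id!r} has vocabulary "
                    f"(k={f.vocabulary.k}, n_max={f.vocabulary.n_max}); "
                    f"expected (k={vocab.k}, n_max={vocab.n_max})"
                )
    elif vocabulary is not None:
        vocab = vocabulary
    else:
        raise ShapeError("empty feature list requires an explicit vocabulary")

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "label", *vocab.grams])
        for f in features:
            row = [f.record_id, f.label if f.label is not None else ""]
            row.extend(_FLOAT_FMT % f.get(g) for g in vocab.grams)
            writer.writerow(row)


def read_feature_matrix(
    path: Union[str, Path], k: int, n_max: int
) -> List[GramFeatures]:
    """Read a feature CSV written by :func:`write_feature_matrix`."""
    vocab = build_vocabulary(k, n_max)
    df = pd.read_csv(path, dtype={"record_id": str, "label": str})
    expected = ["record_id", "label", *vocab.grams]
    if list(df.columns) != expected:
        raise ShapeError(
            f"{path}: columns do not match vocabulary k={k}, n_max={n_max}"
        )
    out = []
    for _, row in df.iterrows():
        label = row["label"]
        probs = {
            g: float(row[g]) for g in vocab.grams if float(row[g]) != 0.0
        }
        out.append(
            GramFeatures(
                record_id=row["record_id"],
                label=None if pd.isna(label) else str(label),
                vocabulary=vocab,
                probabilities=probs,
            )
        )
    return out


def write_symbol_fasta(
    sequences: Sequence[SymbolSequence], path: Union[str, Path]
) -> None:
    """Write symbol sequences in FASTA-like text for inspection."""
    with open(path, "w") as fh:
        for s in sequences:
            header = f">{s.record_id}"
            if s.label is not None:
                header += f" label={s.label}"
            fh.write(header + "\n" + s.symbols + "\n")


def read_symbol_fasta(path: Union[str, Path]) -> List[SymbolSequence]:
    """Read sequences written by :func:`write_symbol_fasta`."""
    out: List[SymbolSequence] = []
    record_id, label, chunks = None, None, []

    def flush():
        if record_id is not None:
            out.append(SymbolSequence(record_id, "".join(chunks), label))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                head = line[1:].split()
                record_id = head[0] if head else ""
                label = None
                for tok in head[1:]:
                    if tok.startswith("label="):
                        label = tok[len("label="):]
                chunks = []
            elif line:
                chunks.append(line)
    flush()
    return out


def write_manifest(
    entries: Iterable[Tuple[str, Optional[str], str]], path: Union[str, Path]
) -> None:
    """Write a record manifest CSV with columns path,label,unit."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "unit"])
        for p, label, unit in entries:
            writer.writerow([p, label if label is not None else "", unit])


def read_manifest(path: Union[str, Path]) -> List[Tuple[str, Optional[str], str]]:
    """Read a manifest CSV; relative paths resolve against the manifest."""
    base = Path(path).parent
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            out.append((str(p), row.get("label") or None, row.get("unit") or "ms"))
    return out
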