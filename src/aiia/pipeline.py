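"""End-to-end orchestration: records -> RRID -> symbols -> grams -> CV.

Two execution routes exist.  Under per-record symbolization each record is
clustered on its own differences, so features can be computed once up
front and cross-validation runs on the fixed feature matrix.  Under pooled
symbolization the K-Means model must be refitted inside every fold on
training records only; the scikit-learn Pipeline built by
:func:`make_aiia_pipeline` does exactly that when cross-validated on the
raw records.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from . import io as aio
from .classify import (
    CVConfig,
    CVReport,
    crossvalidate,
    make_classifier,
)
from .errors import ParameterError
from .grams import GramFeatures, NGramFeaturizer, build_vocabulary, featurize
from .preprocess import RRIDifferencer, RRRecord, compute_rrid
from .symbolize import KMeansSymbolizer, SymbolSequence, symbolize_record

logger = logging.getLogger("aiia")

__all__ = ["RunConfig", "make_aiia_pipeline", "extract_features",
           "run_pipeline", "run_sweep"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one end-to-end run (or sweep)."""

    k: Union[int, Sequence[int]] = 10
    n_max: Union[int, Sequence[int]] = 3
    fit_scope: str = "per_record"
    classifier_name: str = "reference_gnb"
    folds: int = 10
    stratified: bool = True
    seed: int = 0
    manifest: Optional[str] = None
    outdir: Optional[str] = None

    def k_values(self) -> List[int]:
        return [self.k] if isinstance(self.k, int) else sorted(self.k)

    def n_values(self) -> List[int]:
        return [self.n_max] if isinstance(self.n_max, int) else sorted(self.n_max)


def make_aiia_pipeline(
    k: int = 10,
    n_max: int = 3,
    fit_scope: str = "per_record",
    classifier_name: str = "reference_gnb",
    seed: int = 0,
) -> Pipeline:
    """Build the full scikit-learn pipeline over raw RR records."""
    return Pipeline(
        [
            ("rrid", RRIDifferencer()),
            (
                "symbolize",
                KMeansSymbolizer(
                    n_clusters=k, fit_scope=fit_scope, random_state=seed
                ),
            ),
            ("grams", NGramFeaturizer(n_clusters=k, n_max=n_max)),
            ("classifier", make_classifier(classifier_name, seed=seed)),
        ]
    )


def extract_features(
    records: Sequence[RRRecord],
    k: int,
    n_max: int,
    seed: int = 0,
) -> Tuple[List[SymbolSequence], List[GramFeatures], np.ndarray]:
    """Per-record symbolization and featurization of a whole corpus.

    Returns the symbol sequences, the sparse feature objects, and the dense
    matrix in canonical vocabulary order.
    """
    vocab = build_vocabulary(k, n_max)
    sequences, feats = [], []
    for rec in records:
        seq, _ = symbolize_record(rec, k=k, seed=seed, fit_scope="per_record")
        sequences.append(seq)
        feats.append(featurize(seq, vocab))
    X = np.vstack([f.to_vector() for f in feats]) if feats else np.empty((0, vocab.size))
    return sequences, feats, X


def _load_records(config: RunConfig) -> List[RRRecord]:
    if config.manifest is None:
        raise ParameterError("config.manifest is required to load records")
    records = []
    for path, label, unit in aio.read_manifest(config.manifest):
        records.append(aio.read_rr_record(path, unit=unit, label=label))
    return records


def run_pipeline(
    config: RunConfig, records: Optional[Sequence[RRRecord]] = None
) -> CVReport:
    """Execute read -> RRID -> symbolize -> featurize -> cross-validate.

    ``records`` may be passed directly (e.g. fresh from the synthetic
    generator); otherwise they are loaded from ``config.manifest``.
    Artifacts (symbol FASTA, feature CSV, JSON report) are written to
    ``config.outdir`` when set.
    """
    ks, ns = config.k_values(), config.n_values()
    if len(ks) != 1 or len(ns) != 1:
        raise ParameterError("run_pipeline takes scalar k and n_max; use run_sweep")
    k, n_max = ks[0], ns[0]
    if records is None:
        records = _load_records(config)
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise ParameterError("every record needs a label for classification")
    logger.info(
        "run: %d records, k=%d, n_max=%d, scope=%s, classifier=%s, "
        "folds=%d, seed=%d",
        len(records), k, n_max, config.fit_scope, config.classifier_name,
        config.folds, config.seed,
    )
    cv = CVConfig(
        folds=config.folds,
        stratified=config.stratified,
        seed=config.seed,
        classifier_name=config.classifier_name,
    )

    outdir = Path(config.outdir) if config.outdir else None
    if config.fit_scope == "per_record":
        sequences, feats, X = extract_features(
            records, k=k, n_max=n_max, seed=config.seed
        )
        clf = make_classifier(config.classifier_name, seed=config.seed)
        report = crossvalidate(X, labels, clf, cv)
        if outdir:
            outdir.mkdir(parents=True, exist_ok=True)
            aio.write_symbol_fasta(sequences, outdir / "symbols.fasta")
            aio.write_feature_matrix(feats, outdir / "features.csv")
    elif config.fit_scope == "pooled":
        # Symbol model refitted per fold on training records only.
        pipe = make_aiia_pipeline(
            k=k, n_max=n_max, fit_scope="pooled",
            classifier_name=config.classifier_name, seed=config.seed,
        )
        report = crossvalidate(list(records), labels, pipe, cv)
        if outdir:
            outdir.mkdir(parents=True, exist_ok=True)
    else:
        raise ParameterError(f"unknown fit_scope {config.fit_scope!r}")

    if outdir:
        (outdir / "report.json").write_text(report.to_json())
        run_log = dataclasses.asdict(config)
        run_log.update(k=k, n_max=n_max, n_records=len(records))
        (outdir / "run.json").write_text(json.dumps(run_log, indent=2))
    return report


def run_sweep(
    config: RunConfig, records: Optional[Sequence[RRRecord]] = None
) -> pd.DataFrame:
    """Run the pipeline over a (k, n_max) grid; one accuracy row per cell.

    The table behind accuracy-vs-cluster-count and gram-order-comparison
    curves: columns k, n_max, classifier, overall accuracy and per-class
    accuracies.
    """
    if records is None:
        records = _load_records(config)
    rows = []
    reports = {}
    for k in config.k_values():
        for n_max in config.n_values():
            sub = dataclasses.replace(config, k=k, n_max=n_max, outdir=None)
            report = run_pipeline(sub, records=records)
            reports[(k, n_max)] = report
            row = {
                "k": k,
                "n_max": n_max,
                "classifier": config.classifier_name,
                "accuracy": report.overall_accuracy,
                "n_total": report.n_total,
                "n_correct": report.n_correct,
            }
            for cls, acc in report.per_class_accuracy.items():
                row[f"accuracy_{cls}"] = acc
            rows.append(row)
    table = pd.DataFrame(rows)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "sweep.csv", index=False)
    return table
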