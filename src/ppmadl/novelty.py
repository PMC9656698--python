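"""Compression-factor novelty detection and the detect-then-retrain loop.

A query triplet's novelty score is its compression factor

    CF = uncompressed bits / compressed bits,

where the uncompressed size is the uniform-model cost 3·log2|A| and the
compressed size is the PPM escape-cascade code length. A triplet whose CF
exceeds a threshold ``t`` (default 2.0) is flagged as a novel activity; all
flagged triplets from a validation stream are then folded back into the model
in one retraining step, so new behaviours are learned while every count from
the original training data is preserved (no catastrophic forgetting).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .model import PPMActivityModel, _validate_triplets
from .symbolize import SymbolTable

__all__ = [
    "NoveltyResult",
    "DetectionRun",
    "CompressionNoveltyDetector",
    "compression_factor",
    "score_stream",
    "detect_and_learn",
    "write_detection_report",
]

DEFAULT_THRESHOLD = 2.0


@dataclass(frozen=True)
class NoveltyResult:
    """Score of one triplet: code length, compression factor, and decision.

    ``is_novel`` and ``threshold`` are ``None`` when only the score was
    requested. ``degenerate`` marks a zero code length (the model was certain
    of every symbol), reported as an infinite CF rather than an error.
    """

    triplet: tuple[str, str, str]
    uncompressed_bits: float
    compressed_bits: float
    compression_factor: float
    is_novel: bool | None = None
    threshold: float | None = None
    degenerate: bool = False


@dataclass
class DetectionRun:
    """Record of one detect-and-learn pass over a validation sequence."""

    sequence: list[tuple[str, str, str]]
    results: list[NoveltyResult]
    novel: list[tuple[str, str, str]]
    threshold: float
    base_model: PPMActivityModel
    model: PPMActivityModel


def compression_factor(model: PPMActivityModel, triplet) -> NoveltyResult:
    """CF of one triplet against a trained model (decision fields unset)."""
    trip = tuple(triplet)
    uncompressed = model.uniform_bits()
    compressed = model.code_length(trip).total_bits
    if compressed <= 0.0:
        return NoveltyResult(trip, uncompressed, compressed, math.inf, degenerate=True)
    return NoveltyResult(trip, uncompressed, compressed, uncompressed / compressed)


def score_stream(
    model: PPMActivityModel,
    triplets: Iterable,
    threshold: float | None = None,
) -> list[NoveltyResult]:
    """Score a stream read-only: one result per triplet, order preserved.

    If ``threshold`` is given, each result also carries the strict CF > t
    decision; the model is never modified.
    """
    results = []
    for trip in _validate_triplets(triplets):
        r = compression_factor(model, trip)
        if threshold is not None:
            r = NoveltyResult(
                r.triplet,
                r.uncompressed_bits,
                r.compressed_bits,
                r.compression_factor,
                is_novel=r.compression_factor > threshold,
                threshold=threshold,
                degenerate=r.degenerate,
            )
        results.append(r)
    return results


def detect_and_learn(
    model: PPMActivityModel,
    sequence: Iterable,
    threshold: float = DEFAULT_THRESHOLD,
    skip_known: bool = False,
    incremental: bool = False,
) -> DetectionRun:
    """Flag novel triplets in ``sequence`` and retrain the model with them.

    Every triplet is scored against the *original* base model; the novel set N
    (CF strictly above ``threshold``, duplicates preserved in order) is
    accumulated and the model is retrained once, after the loop. Retraining is
    batch by default — a fresh fit on the stored training triplets plus N —
    or an in-place count update with ``incremental=True``; the two produce
    identical models. ``skip_known`` exempts triplets whose activity is
    already a successor of their (time, location) context at order 2, for
    deployments where a fully familiar triplet should never count as novel.

    The input ``model`` is not mutated; the run record holds both the frozen
    base model and the retrained one.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    seq = _validate_triplets(sequence)
    results = score_stream(model, seq, threshold=threshold)
    novel = []
    for r in results:
        if not r.is_novel:
            continue
        if skip_known:
            c2 = model.order2_.get((r.triplet[0], r.triplet[1]))
            if c2 is not None and r.triplet[2] in c2:
                continue
        novel.append(r.triplet)

    base = copy.deepcopy(model)
    if not novel:
        retrained = copy.deepcopy(model)
    elif incremental or model.training_triplets_ is None:
        retrained = copy.deepcopy(model).partial_fit(novel)
    else:
        retrained = PPMActivityModel(store_training=model.store_training).fit(
            model.training_triplets_ + novel
        )
    return DetectionRun(
        sequence=seq,
        results=results,
        novel=novel,
        threshold=threshold,
        base_model=base,
        model=retrained,
    )


class CompressionNoveltyDetector(BaseEstimator):
    """Novelty detector over activity triplets, sklearn estimator style.

    Fits a :class:`PPMActivityModel` on a training stream; ``score_samples``
    returns each query triplet's compression factor (higher = more novel) and
    ``predict`` the boolean CF > threshold decision. :meth:`detect_and_learn`
    runs the full detect-then-retrain loop, replacing the fitted model with
    the retrained one.

    Parameters
    ----------
    threshold : float, default=2.0
        Novelty cutoff on the compression factor (strict comparison).
    skip_known : bool, default=False
        Never flag triplets whose activity is already known in their
        (time, location) context.
    incremental : bool, default=False
        Retrain by direct count update instead of a batch refit (identical
        result, no need to keep training triplets).
    store_training : bool, default=True
        Passed through to the underlying model.

    Attributes
    ----------
    model_ : PPMActivityModel
        The fitted (and possibly since-retrained) compression model.
    runs_ : list[DetectionRun]
        History of detect-and-learn passes on this detector.
    """

    def __init__(
        self,
        threshold: float = DEFAULT_THRESHOLD,
        skip_known: bool = False,
        incremental: bool = False,
        store_training: bool = True,
    ):
        self.threshold = threshold
        self.skip_known = skip_known
        self.incremental = incremental
        self.store_training = store_training

    def fit(self, X: Iterable, y=None) -> "CompressionNoveltyDetector":
        if self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        self.model_ = PPMActivityModel(store_training=self.store_training).fit(X)
        self.runs_: list[DetectionRun] = []
        return self

    def score_samples(self, X: Iterable) -> np.ndarray:
        """Compression factor of each triplet; read-only, higher = more novel."""
        check_is_fitted(self, "model_")
        return np.array(
            [r.compression_factor for r in score_stream(self.model_, X)], dtype=float
        )

    def predict(self, X: Iterable) -> np.ndarray:
        """Boolean novelty decisions (CF strictly above the threshold)."""
        check_is_fitted(self, "model_")
        return self.score_samples(X) > self.threshold

    def detect_and_learn(self, X: Iterable) -> DetectionRun:
        """Run the detect-then-retrain loop and adopt the retrained model."""
        check_is_fitted(self, "model_")
        run = detect_and_learn(
            self.model_,
            X,
            threshold=self.threshold,
            skip_known=self.skip_known,
            incremental=self.incremental,
        )
        self.model_ = run.model
        self.runs_.append(run)
        return run


def write_detection_report(
    results: Sequence[NoveltyResult],
    path,
    table: SymbolTable | None = None,
    threshold: float | None = None,
    config_echo: str | None = None,
) -> None:
    """Write a detection report: one CSV row per triplet plus a summary footer.

    Columns: the three symbols, decoded labels when a symbol table is given,
    compressed bits, CF, and the decision. Footer lines (``#``-prefixed) give
    the novel count and threshold so the run is reproducible from the report.
    """
    import pandas as pd

    rows = []
    for r in results:
        row = {
            "time_symbol": r.triplet[0],
            "location_symbol": r.triplet[1],
            "activity_symbol": r.triplet[2],
        }
        if table is not None:
            for role_key, sym in zip(("time", "location", "activity"), r.triplet):
                try:
                    row[f"{role_key}_label"] = table.label(sym)[1]
                except KeyError:
                    row[f"{role_key}_label"] = ""
        row["compressed_bits"] = round(r.compressed_bits, 4)
        row["compression_factor"] = (
            "inf" if math.isinf(r.compression_factor) else round(r.compression_factor, 4)
        )
        row["is_novel"] = "" if r.is_novel is None else str(bool(r.is_novel)).lower()
        rows.append(row)
    df = pd.DataFrame(rows)
    n_novel = sum(1 for r in results if r.is_novel)
    with open(path, "w") as fh:
        if config_echo:
            fh.write(f"# config: {config_echo}\n")
        df.to_csv(fh, index=False)
        thr = threshold if threshold is not None else (
            results[0].threshold if results else None
        )
        fh.write(f"# novel={n_novel} threshold={thr}\n")
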