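"""Day-based cross-validation protocol for the three recognition tasks.

Event streams are split by calendar day into contiguous training, validation
and test blocks, enumerated deterministically into folds. Three model variants
are compared:

* ``model1`` — trained on the training block only (baseline);
* ``model2`` — trained on the training block, then run through compression-
  factor novelty detection on the validation block, learning flagged triplets
  (the incremental-learning method under study);
* ``model3`` — trained on training + validation combined (upper baseline that
  simply sees twice the data).

Each variant is scored on the held-out test block for three prediction tasks:
time→location and location→activity (order-1 tables) and
(time, location)→activity (order-2 table). Accuracy is the percentage of
correct predictions over *all* test triplets; fallback predictions for unseen
contexts count as attempts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .model import PPMActivityModel
from .novelty import DEFAULT_THRESHOLD, detect_and_learn
from .symbolize import Event, SymbolTable, TimeBinning, build_symbol_table, encode_events

__all__ = [
    "SplitScheme",
    "Fold",
    "EvaluationReport",
    "TASKS",
    "VARIANTS",
    "SCHEME_PRESETS",
    "make_folds",
    "run_protocol",
]

TASKS = ("time_location", "location_activity", "time_location_activity")
VARIANTS = ("model1", "model2", "model3")

# Day counts (training, validation, test, folds) for the benchmark-corpus
# splits, plus the reduced small-training variants.
SCHEME_PRESETS: dict[str, tuple[int, int, int, int]] = {
    "aruba": (15, 15, 28, 6),
    "mit": (5, 5, 6, 6),
    "kasteren": (7, 7, 10, 6),
    "aruba-small": (5, 5, 48, 8),
    "mit-small": (3, 3, 10, 8),
    "kasteren-small": (5, 5, 14, 8),
}


@dataclass(frozen=True)
class SplitScheme:
    """Counts of contiguous days per block and the number of folds."""

    train_days: int
    validation_days: int
    test_days: int
    n_folds: int

    def __post_init__(self) -> None:
        if self.train_days <= 0 or self.test_days <= 0:
            raise ValueError("train_days and test_days must be positive")
        if self.validation_days < 0:
            raise ValueError("validation_days must be non-negative")
        if self.n_folds <= 0:
            raise ValueError("n_folds must be positive")

    @property
    def days_needed(self) -> int:
        return self.train_days + self.validation_days + self.test_days

    @classmethod
    def from_preset(cls, name: str) -> "SplitScheme":
        try:
            return cls(*SCHEME_PRESETS[name])
        except KeyError:
            raise ValueError(
                f"unknown scheme preset {name!r}; available: "
                f"{', '.join(sorted(SCHEME_PRESETS))}"
            ) from None

    @classmethod
    def parse(cls, text: str) -> "SplitScheme":
        """Parse a preset name or a ``train,validation,test,folds`` string."""
        if text in SCHEME_PRESETS:
            return cls.from_preset(text)
        parts = text.split(",")
        if len(parts) != 4:
            raise ValueError(
                f"scheme must be a preset ({', '.join(sorted(SCHEME_PRESETS))}) "
                "or 'train,validation,test,folds'"
            )
        return cls(*(int(p) for p in parts))


@dataclass(frozen=True)
class Fold:
    """One fold's day blocks; the three sets are pairwise disjoint."""

    train_days: tuple[int, ...]
    validation_days: tuple[int, ...]
    test_days: tuple[int, ...]


def make_folds(events_or_days, scheme: SplitScheme) -> list[Fold]:
    """Enumerate day-block folds deterministically.

    The test block slides across the observation period: its start positions
    are evenly spaced over the available days. When the scheme has a
    validation block of the same size as the training block, each test
    position yields a *pair* of folds with the train and validation blocks
    swapped (so consecutive fold pairs share a test set, and the
    train+validation union — hence any model trained on it — is identical
    within a pair). Otherwise each position yields one fold.
    """
    days = _distinct_days(events_or_days)
    n = len(days)
    if n < scheme.days_needed:
        raise ValueError(
            f"scheme needs {scheme.days_needed} distinct days "
            f"(train {scheme.train_days} + validation {scheme.validation_days} "
            f"+ test {scheme.test_days}) but only {n} are available"
        )
    tr, va, te = scheme.train_days, scheme.validation_days, scheme.test_days
    swap = va == tr and va > 0
    n_positions = (scheme.n_folds + 1) // 2 if swap else scheme.n_folds

    starts: list[int] = []
    span = n - te
    for j in range(n_positions):
        # single position: chronological split (train on the past, test on the
        # latest block); several positions: evenly spaced across the period
        s = round(j * span / (n_positions - 1)) if n_positions > 1 else span
        if s not in starts:
            starts.append(s)

    folds: list[Fold] = []
    for s in starts:
        test = tuple(days[s : s + te])
        remaining = days[:s] + days[s + te :]
        block_a = tuple(remaining[:tr])
        block_b = tuple(remaining[tr : tr + va])
        folds.append(Fold(block_a, block_b, test))
        if swap and len(folds) < scheme.n_folds:
            folds.append(Fold(block_b, block_a, test))
        if len(folds) >= scheme.n_folds:
            break
    return folds[: scheme.n_folds]


def _distinct_days(events_or_days) -> list[int]:
    seq = list(events_or_days)
    if seq and isinstance(seq[0], Event):
        return sorted({ev.day_index for ev in seq})
    return sorted({int(d) for d in seq})


@dataclass
class EvaluationReport:
    """Per-fold and mean accuracies for each task, for one model variant."""

    variant: str
    scheme: SplitScheme
    threshold: float
    fold_accuracy: list[dict[str, float]]  # one dict per fold: task -> %
    novel_counts: list[int] = field(default_factory=list)

    def mean_accuracy(self, task: str) -> float:
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
        vals = [fa[task] for fa in self.fold_accuracy]
        return sum(vals) / len(vals)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, fa in enumerate(self.fold_accuracy, start=1):
            for task in TASKS:
                rows.append(
                    {
                        "variant": self.variant,
                        "fold": i,
                        "task": task,
                        "accuracy_pct": fa[task],
                    }
                )
        for task in TASKS:
            rows.append(
                {
                    "variant": self.variant,
                    "fold": "mean",
                    "task": task,
                    "accuracy_pct": self.mean_accuracy(task),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "scheme": {
                    "train_days": self.scheme.train_days,
                    "validation_days": self.scheme.validation_days,
                    "test_days": self.scheme.test_days,
                    "n_folds": self.scheme.n_folds,
                },
                "threshold": self.threshold,
                "folds": self.fold_accuracy,
                "novel_counts": self.novel_counts,
                "mean": {task: self.mean_accuracy(task) for task in TASKS},
            },
            sort_keys=True,
        )


def _accuracy(model: PPMActivityModel, test_triplets) -> dict[str, float]:
    n = len(test_triplets)
    if n == 0:
        return {task: 0.0 for task in TASKS}
    correct = {task: 0 for task in TASKS}
    for t, l, a in test_triplets:
        if model.predict_location(t) == l:
            correct["time_location"] += 1
        if model.predict_activity(l) == a:
            correct["location_activity"] += 1
        if model.predict_activity_tl(t, l) == a:
            correct["time_location_activity"] += 1
    return {task: 100.0 * c / n for task, c in correct.items()}


def run_protocol(
    events: Sequence[Event],
    scheme: SplitScheme,
    variant: str = "model2",
    threshold: float = DEFAULT_THRESHOLD,
    binning: TimeBinning | None = None,
    table: SymbolTable | None = None,
) -> EvaluationReport:
    """Run one variant through every fold and report per-task accuracies.

    The symbol table is built once over the full stream (symbols are arbitrary
    names, so this leaks no information about which block an event is in);
    each fold's models see only their own blocks' triplets.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    binning = binning or TimeBinning()
    events = sorted(events, key=lambda e: (e.day_index, e.time_of_day))
    if table is None:
        table = build_symbol_table(events, binning)
    folds = make_folds(events, scheme)

    fold_accuracy: list[dict[str, float]] = []
    novel_counts: list[int] = []
    for fold in folds:
        blocks = {}
        for name, day_set in (
            ("train", set(fold.train_days)),
            ("validation", set(fold.validation_days)),
            ("test", set(fold.test_days)),
        ):
            block_events = [ev for ev in events if ev.day_index in day_set]
            blocks[name] = encode_events(block_events, table, binning)

        if variant == "model1":
            model = PPMActivityModel().fit(blocks["train"])
        elif variant == "model3":
            model = PPMActivityModel().fit(blocks["train"] + blocks["validation"])
        else:
            base = PPMActivityModel().fit(blocks["train"])
            run = detect_and_learn(base, blocks["validation"], threshold=threshold)
            model = run.model
            novel_counts.append(len(run.novel))

        fold_accuracy.append(_accuracy(model, blocks["test"]))

    return EvaluationReport(
        variant=variant,
        scheme=scheme,
        threshold=threshold,
        fold_accuracy=fold_accuracy,
        novel_counts=novel_counts,
    )
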