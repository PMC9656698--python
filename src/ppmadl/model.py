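"""Multi-order prediction-by-partial-matching (PPM) model over activity triplets.

The model keeps frequency-count tables at three context orders for triplets
⟨time, location, activity⟩:

* order 2 — activity conditioned on the (time, location) pair;
* order 1 — location conditioned on time, and activity conditioned on location;
* order 0 — unconditioned counts of every symbol, all roles pooled.

Escape probabilities follow PPM method C: in every context the escape count
equals the number of distinct successors seen there, so with ``n`` occurrences
over ``d`` distinct successors the context total is ``n + d`` and
``P(esc) = d / (n + d)``. Below order 0 sits the uniform order −1 model, which
assigns every symbol probability ``1/|A|`` over the training alphabet ``A``.

All probabilities are exact integer ratios (:class:`fractions.Fraction`); logs
are taken only when a code length in bits is requested, so printed counts and
probabilities can be checked against the tables by hand.
"""

from __future__ import annotations

import enum
import json
import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ESC",
    "Missing",
    "CodeStep",
    "CodeBreakdown",
    "PPMActivityModel",
    "train",
]

FORMAT_NAME = "ppmadl-model"
FORMAT_VERSION = 1


class _EscType:
    """Singleton marker for the escape pseudo-symbol."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ESC"


ESC = _EscType()


class Missing(enum.Enum):
    """Non-probability signals returned by :meth:`PPMActivityModel.prob`.

    ``CONTEXT`` — the queried context has never been seen at that order;
    ``SYMBOL`` — the context exists but the symbol is not among its successors
    (the caller should escape to a lower order rather than read this as 0).
    """

    CONTEXT = "context absent"
    SYMBOL = "symbol absent"


@dataclass(frozen=True)
class CodeStep:
    """One probability factor contributed while coding a triplet."""

    order: int
    context: tuple[str, ...] | str | None
    symbol: str | _EscType
    probability: Fraction


@dataclass(frozen=True)
class CodeBreakdown:
    """Full account of how a triplet was coded: the factors and the bit total."""

    steps: tuple[CodeStep, ...]

    @property
    def probability(self) -> Fraction:
        p = Fraction(1)
        for s in self.steps:
            p *= s.probability
        return p

    @property
    def total_bits(self) -> float:
        p = self.probability
        return math.log2(p.denominator) - math.log2(p.numerator)


def _context_total(counter: Counter) -> int:
    # PPM-C: escape count equals the number of distinct successors.
    return sum(counter.values()) + len(counter)


def _validate_triplets(X: Iterable) -> list[tuple[str, str, str]]:
    triplets = []
    for i, item in enumerate(X):
        parts = tuple(item)
        if len(parts) != 3 or not all(
            isinstance(s, str) and len(s) == 1 for s in parts
        ):
            raise ValueError(
                f"triplet {i} must be three single-character symbols, got {item!r}"
            )
        triplets.append(parts)
    return triplets


def _argmax_symbol(counter: Counter) -> str:
    # Highest count wins; ties broken by lexicographically smallest symbol.
    return min(counter, key=lambda s: (-counter[s], s))


class PPMActivityModel(BaseEstimator):
    """PPM-C model of a resident's ⟨time, location, activity⟩ triplet stream.

    The estimator is fit on a sequence of triplets (3-tuples or 3-character
    strings of single printable-ASCII symbols) and then answers three kinds of
    query: exact conditional probabilities per context order, per-triplet code
    lengths via the escape cascade, and maximum-probability predictions for
    the three recognition tasks (time→location, location→activity,
    (time, location)→activity).

    Parameters
    ----------
    store_training : bool, default=True
        Keep the training triplets on the model. Required for batch
        retraining semantics in novelty detection; switch off for a
        memory-lean model that only supports incremental updates.

    Attributes
    ----------
    order2_ : dict[(str, str), Counter]
        (time, location) context → activity successor counts.
    time_location_ : dict[str, Counter]
        time context → location successor counts (order 1).
    location_activity_ : dict[str, Counter]
        location context → activity successor counts (order 1).
    order0_ : Counter
        Pooled symbol occurrence counts over all three roles.
    alphabet_ : frozenset[str]
        Distinct symbols seen in training.
    time_symbols_, location_symbols_, activity_symbols_ : set[str]
        Role-resolved symbol sets (by triplet position).
    n_triplets_ : int
        Number of training triplets ingested.
    training_triplets_ : list[tuple] or None
        The ingested triplets, if ``store_training``.

    Examples
    --------
    >>> m = PPMActivityModel().fit(["act", "ive", "act", "ion", "ick"])
    >>> m.prob(2, ("a", "c"), "t")
    Fraction(2, 3)
    >>> round(m.uniform_bits(), 2)
    9.51
    """

    def __init__(self, store_training: bool = True):
        self.store_training = store_training

    # -- construction -------------------------------------------------------

    def fit(self, X: Iterable, y=None) -> "PPMActivityModel":
        """Build count tables from a triplet sequence (may be empty)."""
        self._init_tables()
        self._ingest(_validate_triplets(X))
        return self

    def partial_fit(self, X: Iterable, y=None) -> "PPMActivityModel":
        """Add triplets to the model's counts.

        Counts are additive and escape counts are derived, so any split of a
        stream between ``fit`` and ``partial_fit`` calls yields the same model
        as a single ``fit`` on the concatenation.
        """
        if not hasattr(self, "order0_"):
            self._init_tables()
        self._ingest(_validate_triplets(X))
        return self

    def _init_tables(self) -> None:
        self.order2_: dict[tuple[str, str], Counter] = {}
        self.time_location_: dict[str, Counter] = {}
        self.location_activity_: dict[str, Counter] = {}
        self.order0_: Counter = Counter()
        self.time_symbols_: set[str] = set()
        self.location_symbols_: set[str] = set()
        self.activity_symbols_: set[str] = set()
        self.n_triplets_: int = 0
        self.training_triplets_: list[tuple[str, str, str]] | None = (
            [] if self.store_training else None
        )

    def _ingest(self, triplets: Sequence[tuple[str, str, str]]) -> None:
        for t, l, a in triplets:
            self.order2_.setdefault((t, l), Counter())[a] += 1
            self.time_location_.setdefault(t, Counter())[l] += 1
            self.location_activity_.setdefault(l, Counter())[a] += 1
            self.order0_.update((t, l, a))
            self.time_symbols_.add(t)
            self.location_symbols_.add(l)
            self.activity_symbols_.add(a)
        self.n_triplets_ += len(triplets)
        if self.training_triplets_ is not None:
            self.training_triplets_.extend(triplets)

    # -- queries ------------------------------------------------------------

    @property
    def alphabet_(self) -> frozenset:
        check_is_fitted(self, "order0_")
        return frozenset(self.order0_)

    def prob(self, order: int, context, symbol) -> Fraction | Missing:
        """Exact probability of ``symbol`` (or ``ESC``) in a context.

        Returns ``Missing.CONTEXT`` for an unseen context and
        ``Missing.SYMBOL`` for a symbol absent from an existing context —
        never 0, because an absent symbol means "escape", not "impossible".
        At order 1 the context symbol selects the table (time→location or
        location→activity); role pools are disjoint so at most one matches.
        """
        check_is_fitted(self, "order0_")
        if order == 2:
            counter = self.order2_.get(tuple(context)) if context else None
        elif order == 1:
            key = context[0] if not isinstance(context, str) else context
            counter = self.time_location_.get(key)
            if counter is None:
                counter = self.location_activity_.get(key)
        elif order == 0:
            counter = self.order0_ if self.order0_ else None
        else:
            raise ValueError(f"order must be one of {{2, 1, 0}}, got {order}")
        if counter is None:
            return Missing.CONTEXT
        total = _context_total(counter)
        if symbol is ESC:
            return Fraction(len(counter), total)
        if symbol not in counter:
            return Missing.SYMBOL
        return Fraction(counter[symbol], total)

    def uniform_bits(self) -> float:
        """Bits to code one triplet under the uniform (order −1) model: 3·log2|A|."""
        check_is_fitted(self, "order0_")
        if not self.order0_:
            raise ValueError("model has an empty alphabet; train it first")
        return 3.0 * math.log2(len(self.order0_))

    def code_length(self, triplet) -> CodeBreakdown:
        """Code a triplet through the escape cascade; escapes cost zero bits.

        The cascade covers the triplet's symbols from the highest available
        order down. An order-2 hit (context seen and activity among its
        successors) contributes P(activity | time, location) and covers the
        activity symbol. Each order-1 transition (time→location, then
        location→activity) is evaluated unless all its symbols are already
        covered; a stored transition contributes its probability and covers
        both its symbols, a missing one contributes nothing. Any symbol still
        uncovered contributes its order-0 probability, or the order-0 escape
        probability if it was never seen in training. Total bits is
        −log2 of the product of contributed factors; each symbol's probability
        is counted at most once.
        """
        check_is_fitted(self, "order0_")
        if not self.order0_:
            raise ValueError("model has an empty alphabet; train it first")
        x, y, z = tuple(triplet)
        steps: list[CodeStep] = []
        covered: set[str] = set()

        c2 = self.order2_.get((x, y))
        if c2 is not None and z in c2:
            steps.append(
                CodeStep(2, (x, y), z, Fraction(c2[z], _context_total(c2)))
            )
            covered.add(z)

        for table, ctx, succ in (
            (self.time_location_, x, y),
            (self.location_activity_, y, z),
        ):
            if ctx in covered and succ in covered:
                continue
            counter = table.get(ctx)
            if counter is not None and succ in counter:
                steps.append(
                    CodeStep(1, ctx, succ, Fraction(counter[succ], _context_total(counter)))
                )
                covered.update((ctx, succ))

        total0 = _context_total(self.order0_)
        for sym in (x, y, z):
            if sym in covered:
                continue
            if sym in self.order0_:
                steps.append(CodeStep(0, None, sym, Fraction(self.order0_[sym], total0)))
            else:
                steps.append(CodeStep(0, None, ESC, Fraction(len(self.order0_), total0)))
            covered.add(sym)

        return CodeBreakdown(tuple(steps))

    # -- prediction ---------------------------------------------------------

    def predict_location(self, time_symbol: str) -> str:
        """Most probable location for a time symbol (order-1 argmax).

        Ties break by higher count then lexicographically smaller symbol; an
        unknown time symbol falls back to the most frequent location-role
        symbol at order 0.
        """
        check_is_fitted(self, "order0_")
        counter = self.time_location_.get(time_symbol)
        if counter:
            return _argmax_symbol(counter)
        return self._order0_argmax(self.location_symbols_)

    def predict_activity(self, location_symbol: str) -> str:
        """Most probable activity for a location symbol (order-1 argmax)."""
        check_is_fitted(self, "order0_")
        counter = self.location_activity_.get(location_symbol)
        if counter:
            return _argmax_symbol(counter)
        return self._order0_argmax(self.activity_symbols_)

    def predict_activity_tl(self, time_symbol: str, location_symbol: str) -> str:
        """Most probable activity for a (time, location) pair (order-2 argmax).

        Backs off escape-style: unseen (time, location) context → order-1
        location→activity; unseen location too → order-0 over activity symbols.
        """
        check_is_fitted(self, "order0_")
        counter = self.order2_.get((time_symbol, location_symbol))
        if counter:
            return _argmax_symbol(counter)
        return self.predict_activity(location_symbol)

    def _order0_argmax(self, role_symbols: set[str]) -> str:
        if not role_symbols:
            raise ValueError("model has no symbols for this role; train it first")
        restricted = Counter({s: self.order0_[s] for s in role_symbols})
        return _argmax_symbol(restricted)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        """Serialize to a versioned JSON document (counts as integers)."""
        check_is_fitted(self, "order0_")
        payload = {
            "format": FORMAT_NAME,
            "version": FORMAT_VERSION,
            "store_training": self.store_training,
            "n_triplets": self.n_triplets_,
            "order2": {"".join(ctx): dict(c) for ctx, c in self.order2_.items()},
            "time_location": {k: dict(c) for k, c in self.time_location_.items()},
            "location_activity": {
                k: dict(c) for k, c in self.location_activity_.items()
            },
            "order0": dict(self.order0_),
            "roles": {
                "time": "".join(sorted(self.time_symbols_)),
                "location": "".join(sorted(self.location_symbols_)),
                "activity": "".join(sorted(self.activity_symbols_)),
            },
            "training": (
                ["".join(t) for t in self.training_triplets_]
                if self.training_triplets_ is not None
                else None
            ),
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PPMActivityModel":
        """Inverse of :meth:`to_json`; probabilities are recomputed from counts."""
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed model payload: {exc}") from exc
        if not isinstance(payload, dict) or payload.get("format") != FORMAT_NAME:
            raise ValueError("payload is not a serialized PPM activity model")
        if payload.get("version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('version')!r}; "
                f"this build reads version {FORMAT_VERSION}"
            )
        model = cls(store_training=payload["store_training"])
        model._init_tables()
        try:
            model.order2_ = {
                (k[0], k[1]): Counter(v) for k, v in payload["order2"].items()
            }
            model.time_location_ = {
                k: Counter(v) for k, v in payload["time_location"].items()
            }
            model.location_activity_ = {
                k: Counter(v) for k, v in payload["location_activity"].items()
            }
            model.order0_ = Counter(payload["order0"])
            model.time_symbols_ = set(payload["roles"]["time"])
            model.location_symbols_ = set(payload["roles"]["location"])
            model.activity_symbols_ = set(payload["roles"]["activity"])
            model.n_triplets_ = int(payload["n_triplets"])
            if payload["training"] is not None:
                model.training_triplets_ = [tuple(s) for s in payload["training"]]
            else:
                model.training_triplets_ = None
        except (KeyError, TypeError, IndexError) as exc:
            raise ValueError(f"malformed model payload: {exc!r}") from exc
        return model

    def equals(self, other: "PPMActivityModel") -> bool:
        """Structural equality of all count tables, alphabet and role sets."""
        return (
            self.order2_ == other.order2_
            and self.time_location_ == other.time_location_
            and self.location_activity_ == other.location_activity_
            and self.order0_ == other.order0_
            and self.time_symbols_ == other.time_symbols_
            and self.location_symbols_ == other.location_symbols_
            and self.activity_symbols_ == other.activity_symbols_
        )


def train(triplets: Iterable, store_training: bool = True) -> PPMActivityModel:
    """Functional wrapper: build a :class:`PPMActivityModel` from triplets."""
    return PPMActivityModel(store_training=store_training).fit(triplets)
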