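"""Symbolization of annotated activity-event logs.

Raw observations (timestamp, location, activity) become role-tagged triplets of
single printable-ASCII characters: one symbol for the time-of-day bin, one for
the location, one for the activity. The triplet is the unit the compression
model trains and scores on; this module owns the bijection between human
labels and symbols, and the canonical delimited event-file format.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "Event",
    "TimeBinning",
    "SymbolTable",
    "Triplet",
    "ROLES",
    "ROLE_POOLS",
    "discretize_time",
    "build_symbol_table",
    "encode_events",
    "decode_triplets",
    "read_events",
    "write_events",
    "read_casas",
]

MINUTES_PER_DAY = 1440

ROLES = ("time", "location", "activity")

# Disjoint printable-ASCII pools, one per role, consumed in first-seen order.
# Sizes are skewed toward the time role because fine time binning can produce
# many distinct bins, while homes have few rooms and activity types.
ROLE_POOLS: Mapping[str, str] = {
    "time": "".join(chr(c) for c in range(0x21, 0x52)),      # '!'..'Q' (49)
    "location": "".join(chr(c) for c in range(0x52, 0x69)),  # 'R'..'h' (23)
    "activity": "".join(chr(c) for c in range(0x69, 0x7F)),  # 'i'..'~' (22)
}


class Triplet(NamedTuple):
    """One activity instance as three role-tagged symbols ⟨time, location, activity⟩."""

    time: str
    location: str
    activity: str


@dataclass(frozen=True)
class Event:
    """One raw observation from an annotated activity log.

    Parameters
    ----------
    day_index : int
        Zero-based day number, derived from the calendar date.
    time_of_day : int
        Minutes since midnight, in ``[0, 1440)``.
    location : str
        Room or sensor-area label, non-empty.
    activity : str
        Activity label, non-empty.
    """

    day_index: int
    time_of_day: int
    location: str
    activity: str

    def __post_init__(self) -> None:
        if self.day_index < 0:
            raise ValueError(f"day_index must be non-negative, got {self.day_index}")
        if not 0 <= self.time_of_day < MINUTES_PER_DAY:
            raise ValueError(
                f"time_of_day must be in [0, {MINUTES_PER_DAY}), got {self.time_of_day}"
            )
        if not self.location:
            raise ValueError("location label must be non-empty")
        if not self.activity:
            raise ValueError("activity label must be non-empty")


@dataclass(frozen=True)
class TimeBinning:
    """Partition of the day into half-open, equal-width minute bins.

    Bins are ``[start, start + bin_width)`` and labelled by their start time as
    ``"HH:MM"``; ``bin_width`` must divide 1440 so the bins tile the day.
    """

    bin_width: int = 30

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or MINUTES_PER_DAY % self.bin_width != 0:
            raise ValueError(
                f"bin_width must be a positive divisor of {MINUTES_PER_DAY}, "
                f"got {self.bin_width}"
            )

    @property
    def n_bins(self) -> int:
        return MINUTES_PER_DAY // self.bin_width

    def bin_start(self, time_of_day: int) -> int:
        if not 0 <= time_of_day < MINUTES_PER_DAY:
            raise ValueError(
                f"time_of_day must be in [0, {MINUTES_PER_DAY}), got {time_of_day}"
            )
        return (time_of_day // self.bin_width) * self.bin_width

    def label(self, time_of_day: int) -> str:
        start = self.bin_start(time_of_day)
        return f"{start // 60:02d}:{start % 60:02d}"


def discretize_time(time_of_day: int, binning: TimeBinning) -> str:
    """Return the label of the unique bin containing ``time_of_day``."""
    return binning.label(time_of_day)


class SymbolTable:
    """Injective mapping from (role, label) pairs to single ASCII symbols.

    Symbols are drawn from disjoint per-role pools in first-seen order, so the
    assignment is a deterministic function of the observation order. An explicit
    assignment mapping may be supplied to pin specific labels to specific
    characters (overriding the pools); injectivity is enforced globally either
    way.
    """

    def __init__(self) -> None:
        self._forward: dict[str, dict[str, str]] = {role: {} for role in ROLES}
        self._inverse: dict[str, tuple[str, str]] = {}
        self._pool_pos: dict[str, int] = {role: 0 for role in ROLES}

    def __len__(self) -> int:
        return len(self._inverse)

    def __contains__(self, key: tuple[str, str]) -> bool:
        role, label = key
        return label in self._forward.get(role, {})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SymbolTable):
            return NotImplemented
        return self._forward == other._forward

    def assign(self, role: str, label: str, symbol: str | None = None) -> str:
        """Assign a symbol to ``(role, label)``; idempotent for known pairs."""
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
        existing = self._forward[role].get(label)
        if existing is not None:
            if symbol is not None and symbol != existing:
                raise ValueError(
                    f"({role!r}, {label!r}) already mapped to {existing!r}"
                )
            return existing
        if symbol is None:
            symbol = self._next_free(role)
        if len(symbol) != 1 or not (0x21 <= ord(symbol) <= 0x7E):
            raise ValueError(f"symbol must be one printable ASCII char, got {symbol!r}")
        if symbol in self._inverse:
            raise ValueError(
                f"symbol {symbol!r} already serves {self._inverse[symbol]}"
            )
        self._forward[role][label] = symbol
        self._inverse[symbol] = (role, label)
        return symbol

    def _next_free(self, role: str) -> str:
        pool = ROLE_POOLS[role]
        pos = self._pool_pos[role]
        while pos < len(pool) and pool[pos] in self._inverse:
            pos += 1
        if pos >= len(pool):
            raise CapacityError(
                f"symbol pool for role {role!r} exhausted "
                f"({len(pool)} symbols available)"
            )
        self._pool_pos[role] = pos + 1
        return pool[pos]

    def symbol(self, role: str, label: str) -> str:
        try:
            return self._forward[role][label]
        except KeyError:
            raise KeyError(f"no symbol for ({role!r}, {label!r})") from None

    def label(self, symbol: str) -> tuple[str, str]:
        """Return the (role, label) pair a symbol stands for."""
        try:
            return self._inverse[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} is not assigned") from None

    def items(self) -> Iterable[tuple[str, str, str]]:
        for role in ROLES:
            for label, sym in self._forward[role].items():
                yield role, label, sym

    def to_dict(self) -> dict:
        return {role: dict(self._forward[role]) for role in ROLES}

    @classmethod
    def from_dict(cls, payload: Mapping[str, Mapping[str, str]]) -> "SymbolTable":
        table = cls()
        for role in ROLES:
            for label, sym in payload.get(role, {}).items():
                table.assign(role, label, sym)
        return table


class CapacityError(RuntimeError):
    """Raised when a role's symbol pool has no free symbols left."""


def build_symbol_table(
    events: Sequence[Event],
    binning: TimeBinning | None = None,
    assignments: Mapping[str, Mapping[str, str]] | None = None,
) -> SymbolTable:
    """Build a symbol table covering every (role, label) observed in ``events``.

    Assignment is deterministic: pinned ``assignments`` (role → label → symbol)
    are applied first, then remaining labels receive the next free symbol from
    their role's pool in first-seen order.
    """
    if not events:
        raise ValueError("cannot build a symbol table from an empty event list")
    binning = binning or TimeBinning()
    table = SymbolTable()
    if assignments:
        for role, mapping in assignments.items():
            for label, sym in mapping.items():
                table.assign(role, label, sym)
    for ev in events:
        table.assign("time", discretize_time(ev.time_of_day, binning))
        table.assign("location", ev.location)
        table.assign("activity", ev.activity)
    return table


def encode_events(
    events: Sequence[Event],
    table: SymbolTable,
    binning: TimeBinning | None = None,
    extend: bool = False,
) -> list[Triplet]:
    """Encode events as triplets, one per event, order preserved.

    With ``extend=False`` (frozen table) an unseen label raises ``KeyError``
    naming the offending record; with ``extend=True`` new labels are assigned
    symbols on demand (learning mode).
    """
    binning = binning or TimeBinning()
    out: list[Triplet] = []
    for i, ev in enumerate(events):
        labels = (
            ("time", discretize_time(ev.time_of_day, binning)),
            ("location", ev.location),
            ("activity", ev.activity),
        )
        symbols = []
        for role, label in labels:
            if extend:
                symbols.append(table.assign(role, label))
            else:
                try:
                    symbols.append(table.symbol(role, label))
                except KeyError:
                    raise KeyError(
                        f"event {i} (day {ev.day_index}): no symbol for "
                        f"({role!r}, {label!r}) in frozen table"
                    ) from None
        out.append(Triplet(*symbols))
    return out


def decode_triplets(
    triplets: Iterable[Sequence[str]], table: SymbolTable
) -> list[tuple[str, str, str]]:
    """Invert encoding: triplets back to (time-bin label, location, activity)."""
    decoded = []
    for trip in triplets:
        t, l, a = trip
        decoded.append((table.label(t)[1], table.label(l)[1], table.label(a)[1]))
    return decoded


# ---------------------------------------------------------------------------
# Canonical event file: delimited text, header timestamp,location,activity,
# ISO-8601 timestamps; comma or tab separated.
# ---------------------------------------------------------------------------

def read_events(path) -> list[Event]:
    """Read the canonical event file; day_index is relative to the first date."""
    df = pd.read_csv(path, sep=None, engine="python")
    expected = ["timestamp", "location", "activity"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"expected header {','.join(expected)}, got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        raise ValueError(f"event file {path} contains no events")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    day0 = ts.dt.normalize().min()
    events = []
    for i in range(len(df)):
        t = ts.iloc[i]
        events.append(
            Event(
                day_index=int((t.normalize() - day0).days),
                time_of_day=int(t.hour * 60 + t.minute),
                location=str(df["location"].iloc[i]),
                activity=str(df["activity"].iloc[i]),
            )
        )
    return events


def write_events(events: Sequence[Event], path, start_date: str = "2000-01-01") -> None:
    """Write events in the canonical CSV format, mapping day_index onto dates."""
    base = pd.Timestamp(start_date)
    rows = [
        {
            "timestamp": (
                base
                + pd.Timedelta(days=ev.day_index, minutes=ev.time_of_day)
            ).isoformat(),
            "location": ev.location,
            "activity": ev.activity,
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["timestamp", "location", "activity"]).to_csv(
        path, index=False
    )


def read_casas(path) -> list[Event]:
    """Adapter for CASAS-style whitespace-delimited annotated logs.

    Expected line shape: ``DATE TIME <location/sensor> ... <activity> [begin|end]``.
    The third field is taken as the location and the last non-marker field as
    the activity; lines with fewer than four fields are skipped. This is a
    minimal hook — site-specific logs usually need their own adapter.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if len(fields) < 4:
                continue
            date, time_s, location = fields[0], fields[1], fields[2]
            rest = fields[3:]
            if rest and rest[-1].lower() in ("begin", "end"):
                rest = rest[:-1]
            if not rest:
                continue
            records.append((f"{date} {time_s}", location, rest[-1]))
    if not records:
        raise ValueError(f"no annotated events found in {path}")
    ts = pd.to_datetime([r[0] for r in records], format="mixed")
    day0 = ts.normalize().min()
    return [
        Event(
            day_index=int((t.normalize() - day0).days),
            time_of_day=int(t.hour * 60 + t.minute),
            location=loc,
            activity=act,
        )
        for t, (_, loc, act) in zip(ts, records)
    ]
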