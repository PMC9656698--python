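"""Seeded generator of synthetic single-resident activity streams.

Emulates the statistical structure the compression model assumes: recurring
activities at characteristic times and locations, day-to-day timing jitter,
later-onset novel activities, and occasional noise events. Every event in a
generated stream carries a ground-truth tag (``baseline``, ``novel`` or
``noise``) so detection quality can be measured without external data.

The generator does *not* emulate raw binary-sensor firings, multi-resident
interleaving, sensor faults, or the long-range seasonal drift of real homes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .symbolize import MINUTES_PER_DAY, Event

__all__ = [
    "ActivitySpec",
    "NoveltyInjection",
    "ScheduleSpec",
    "SimulatedStream",
    "generate",
    "small_home_spec",
    "large_home_spec",
    "worked_example",
    "WorkedExample",
]


@dataclass(frozen=True)
class ActivitySpec:
    """One recurring activity: where it happens and when.

    ``time_distribution`` is a categorical distribution over bin-start minutes
    (probabilities summing to 1); the event time is drawn uniformly inside the
    chosen bin, so the bin is the activity's time "slot" and the within-bin
    minute is jitter. ``occurrences_per_day`` is a fixed daily count.
    """

    activity: str
    location: str
    time_distribution: Mapping[int, float]
    occurrences_per_day: int = 1
    bin_width: int = 30

    def __post_init__(self) -> None:
        if not self.activity or not self.location:
            raise ValueError("activity and location labels must be non-empty")
        if self.occurrences_per_day < 0:
            raise ValueError(
                f"occurrences_per_day must be >= 0, got {self.occurrences_per_day}"
            )
        if not self.time_distribution:
            raise ValueError("time_distribution must be non-empty")
        total = sum(self.time_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"time_distribution must sum to 1, sums to {total}")
        for start, p in self.time_distribution.items():
            if p < 0:
                raise ValueError(f"time_distribution has negative mass at {start}")
            if not 0 <= start < MINUTES_PER_DAY:
                raise ValueError(f"bin start {start} outside [0, {MINUTES_PER_DAY})")

    @classmethod
    def peaked(
        cls,
        activity: str,
        location: str,
        peak_minute: int,
        peak_mass: float = 0.8,
        bin_width: int = 30,
        occurrences_per_day: int = 1,
    ) -> "ActivitySpec":
        """Convenience builder: mass ``peak_mass`` at the peak bin, the rest
        split evenly over the two adjacent bins (wrapping at midnight)."""
        peak = (peak_minute // bin_width) * bin_width
        spill = (1.0 - peak_mass) / 2.0
        before = (peak - bin_width) % MINUTES_PER_DAY
        after = (peak + bin_width) % MINUTES_PER_DAY
        dist = {peak: peak_mass, before: spill, after: spill}
        return cls(activity, location, dist, occurrences_per_day, bin_width)


@dataclass(frozen=True)
class NoveltyInjection:
    """A new activity that first appears on ``onset_day`` (0-based)."""

    spec: ActivitySpec
    onset_day: int

    def __post_init__(self) -> None:
        if self.onset_day < 0:
            raise ValueError(f"onset_day must be >= 0, got {self.onset_day}")


@dataclass(frozen=True)
class ScheduleSpec:
    """Generative description of one synthetic resident."""

    activities: tuple[ActivitySpec, ...]
    n_days: int
    novelties: tuple[NoveltyInjection, ...] = ()
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "activities", tuple(self.activities))
        object.__setattr__(self, "novelties", tuple(self.novelties))
        if self.n_days <= 0:
            raise ValueError(f"n_days must be positive, got {self.n_days}")
        if not self.activities:
            raise ValueError("activities must be non-empty")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError(f"noise_rate must be in [0, 1], got {self.noise_rate}")
        for inj in self.novelties:
            if inj.onset_day >= self.n_days:
                raise ValueError(
                    f"onset_day {inj.onset_day} outside 0..{self.n_days - 1}"
                )

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ScheduleSpec":
        def _activity(d: Mapping) -> ActivitySpec:
            if "peak_minute" in d:
                return ActivitySpec.peaked(
                    d["activity"],
                    d["location"],
                    int(d["peak_minute"]),
                    peak_mass=float(d.get("peak_mass", 0.8)),
                    bin_width=int(d.get("bin_width", 30)),
                    occurrences_per_day=int(d.get("occurrences_per_day", 1)),
                )
            return ActivitySpec(
                d["activity"],
                d["location"],
                {int(k): float(v) for k, v in d["time_distribution"].items()},
                int(d.get("occurrences_per_day", 1)),
                int(d.get("bin_width", 30)),
            )

        return cls(
            activities=tuple(_activity(a) for a in payload["activities"]),
            n_days=int(payload["n_days"]),
            novelties=tuple(
                NoveltyInjection(_activity(n["activity_spec"]), int(n["onset_day"]))
                for n in payload.get("novelties", ())
            ),
            noise_rate=float(payload.get("noise_rate", 0.0)),
            seed=int(payload.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScheduleSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulatedStream:
    """Events sorted by (day, time) with parallel ground-truth tags."""

    events: list[Event]
    tags: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day_index": [e.day_index for e in self.events],
                "time_of_day": [e.time_of_day for e in self.events],
                "location": [e.location for e in self.events],
                "activity": [e.activity for e in self.events],
                "tag": self.tags,
            }
        )


def _draw_event(
    rng: np.random.Generator, spec: ActivitySpec, day: int
) -> Event:
    starts = sorted(spec.time_distribution)
    probs = np.array([spec.time_distribution[s] for s in starts], dtype=float)
    probs /= probs.sum()
    start = int(rng.choice(np.array(starts), p=probs))
    minute = start + int(rng.integers(0, spec.bin_width))
    return Event(day, minute % MINUTES_PER_DAY, spec.location, spec.activity)


def generate(spec: ScheduleSpec) -> SimulatedStream:
    """Generate one resident's event stream, deterministic given the seed.

    Per day, each baseline activity fires ``occurrences_per_day`` times at
    times drawn from its bin distribution; injected activities do the same
    from their onset day onward (never before); with probability
    ``noise_rate`` one noise event occurs at a uniformly random minute with a
    random (location, activity) combination from the schedule's inventory.
    """
    rng = np.random.default_rng(spec.seed)
    locations = sorted({a.location for a in spec.activities})
    activities = sorted({a.activity for a in spec.activities})
    tagged: list[tuple[Event, str]] = []
    for day in range(spec.n_days):
        for act in spec.activities:
            for _ in range(act.occurrences_per_day):
                tagged.append((_draw_event(rng, act, day), "baseline"))
        for inj in spec.novelties:
            if day >= inj.onset_day:
                for _ in range(inj.spec.occurrences_per_day):
                    tagged.append((_draw_event(rng, inj.spec, day), "novel"))
        if rng.random() < spec.noise_rate:
            minute = int(rng.integers(0, MINUTES_PER_DAY))
            loc = locations[int(rng.integers(0, len(locations)))]
            act_label = activities[int(rng.integers(0, len(activities)))]
            tagged.append((Event(day, minute, loc, act_label), "noise"))
    tagged.sort(key=lambda pair: (pair[0].day_index, pair[0].time_of_day))
    return SimulatedStream([e for e, _ in tagged], [t for _, t in tagged])


# ---------------------------------------------------------------------------
# Presets: nominal small- and larger-home inventories for fast tests.
# ---------------------------------------------------------------------------

def small_home_spec(
    n_days: int = 30,
    novelties: Sequence[NoveltyInjection] = (),
    noise_rate: float = 0.0,
    seed: int = 0,
) -> ScheduleSpec:
    """Four locations / four activities — a compact single-resident day."""
    acts = (
        ActivitySpec.peaked("Sleeping", "Bedroom", 23 * 60),
        ActivitySpec.peaked("PreparingMeal", "Kitchen", 8 * 60),
        ActivitySpec.peaked("Showering", "Bathroom", 7 * 60),
        ActivitySpec.peaked("Relaxing", "LivingRoom", 20 * 60),
    )
    return ScheduleSpec(acts, n_days, tuple(novelties), noise_rate, seed)


def large_home_spec(
    n_days: int = 60,
    novelties: Sequence[NoveltyInjection] = (),
    noise_rate: float = 0.0,
    seed: int = 0,
) -> ScheduleSpec:
    """Seven rooms / six activities for protocol-scale tests."""
    acts = (
        ActivitySpec.peaked("Sleeping", "Bedroom", 23 * 60),
        ActivitySpec.peaked("MealPreparation", "Kitchen", 8 * 60, occurrences_per_day=2),
        ActivitySpec.peaked("Eating", "DiningRoom", 12 * 60, occurrences_per_day=2),
        ActivitySpec.peaked("Working", "Office", 10 * 60, occurrences_per_day=2),
        ActivitySpec.peaked("WashingDishes", "Kitchen", 13 * 60),
        ActivitySpec.peaked("Showering", "Bathroom", 7 * 60),
        ActivitySpec.peaked("Relaxing", "LivingRoom", 20 * 60),
        ActivitySpec.peaked("Laundry", "UtilityRoom", 16 * 60),
        ActivitySpec.peaked("Reading", "Study", 21 * 60),
    )
    return ScheduleSpec(acts, n_days, tuple(novelties), noise_rate, seed)


# ---------------------------------------------------------------------------
# Hand-checkable worked example (the 'activeactionick' stream).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkedExample:
    """A tiny fully hand-checkable fixture for docs and tests.

    Five training triplets built from a morning routine (two meal
    preparations, bathing, dressing, dish washing), four query scenarios that
    differ from the routine in exactly one respect, and their expected
    compression factors (rounded to 2 d.p., verified by hand through the
    escape cascade).
    """

    training: tuple[tuple[str, str, str], ...]
    scenarios: tuple[tuple[str, str, str], ...]
    expected_cfs: tuple[float, ...]
    events: tuple[Event, ...]
    assignments: Mapping[str, Mapping[str, str]]


def worked_example() -> WorkedExample:
    """Return the packaged worked example.

    Training is the symbol stream ``act ive act ion ick`` (five triplets over
    a 9-symbol alphabet); the scenarios probe a new activity in a known
    context, a known routine at a new-to-it time, a never-seen time symbol,
    and a known activity in the wrong room.
    """
    assignments = {
        "time": {"08:00": "a", "09:30": "i"},
        "location": {"Kitchen": "c", "Bathroom": "v", "Bedroom": "o"},
        "activity": {
            "PreparingMeal": "t",
            "Bathing": "e",
            "Dressing": "n",
            "WashingDishes": "k",
        },
    }
    events = (
        Event(0, 8 * 60, "Kitchen", "PreparingMeal"),
        Event(0, 9 * 60 + 30, "Bathroom", "Bathing"),
        Event(1, 8 * 60, "Kitchen", "PreparingMeal"),
        Event(1, 9 * 60 + 30, "Bedroom", "Dressing"),
        Event(1, 9 * 60 + 45, "Kitchen", "WashingDishes"),
    )
    training = (
        ("a", "c", "t"),
        ("i", "v", "e"),
        ("a", "c", "t"),
        ("i", "o", "n"),
        ("i", "c", "k"),
    )
    scenarios = (
        ("a", "c", "k"),  # new activity at a familiar time and place
        ("a", "v", "e"),  # familiar routine at a different time
        ("s", "o", "n"),  # never-seen time symbol
        ("i", "c", "n"),  # familiar activity in the wrong room
    )
    expected_cfs = (3.27, 2.07, 3.94, 1.33)
    return WorkedExample(training, scenarios, expected_cfs, events, assignments)
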