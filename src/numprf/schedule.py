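"""Block-design stimulus schedules and the numerosity-versus-time function.

A run presents numerosities 1–5 in ascending order, a 20-item baseline
block, the same numerosities in descending order, and a second 20-item
block; this 12-block cycle repeats four times per run. Small-numerosity
blocks last 4.2 s (six stimulus events each); 20-item blocks last 16.8 s.
The resulting piecewise-constant numerosity function x(t) drives the
neuronal tuning model downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Block",
    "StimulusSchedule",
    "StimulusTimecourse",
    "CYCLE_ORDER",
    "build_cycle",
    "build_run",
    "numerosity_timecourse",
    "schedule_to_events",
    "events_to_schedule",
]

#: Fixed within-cycle presentation order (ascending, baseline, descending, baseline).
CYCLE_ORDER = (1, 2, 3, 4, 5, 20, 5, 4, 3, 2, 1, 20)

VALID_NUMEROSITIES = frozenset({1, 2, 3, 4, 5, 20})

# (event_on, event_off, n_events) per modality for small-numerosity blocks
# and for the 20-item baseline blocks. Small blocks: 6 events of 700 ms
# (visual 300 ms stimulus + 400 ms gap; auditory 500 ms + 200 ms). Baseline
# blocks last 16.8 s: 24 events visually, 8 events (2.1 s each) auditorily.
_SMALL_EVENT = {"visual": (0.3, 0.4, 6), "auditory": (0.5, 0.2, 6)}
_TWENTY_EVENT = {"visual": (0.3, 0.4, 24), "auditory": (2.0, 0.1, 8)}


@dataclass(frozen=True)
class Block:
    """One stimulation block of a single numerosity."""

    numerosity: int
    onset: float  # s from run start
    duration: float  # s
    n_events: int
    event_on: float  # s stimulus visible/audible per event
    event_off: float  # s gap following each event

    def __post_init__(self) -> None:
        if self.numerosity not in VALID_NUMEROSITIES:
            raise ValueError(f"numerosity must be one of {sorted(VALID_NUMEROSITIES)}, "
                             f"got {self.numerosity}")
        if self.onset < 0:
            raise ValueError("block onset must be non-negative")
        expected = self.n_events * (self.event_on + self.event_off)
        if not math.isclose(self.duration, expected, rel_tol=1e-9):
            raise ValueError(
                f"duration {self.duration} inconsistent with "
                f"{self.n_events} x ({self.event_on} + {self.event_off}) s"
            )

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class StimulusSchedule:
    """Complete block schedule for one run."""

    modality: str
    blocks: tuple[Block, ...]
    tr: float = 2.1
    n_volumes: int = 145
    n_cycles: int = 4
    slice_time_ref: float = 1.025

    def __post_init__(self) -> None:
        ends = [b.end for b in self.blocks]
        onsets = [b.onset for b in self.blocks]
        for prev_end, onset in zip(ends, onsets[1:]):
            if onset < prev_end - 1e-9:
                raise ValueError("blocks overlap")
        if self.blocks and ends[-1] > self.duration + 1e-9:
            raise ValueError("schedule extends beyond the run")

    @property
    def duration(self) -> float:
        """Run length in seconds (n_volumes x tr)."""
        return self.n_volumes * self.tr

    @property
    def stimulus_end(self) -> float:
        return self.blocks[-1].end if self.blocks else 0.0


@dataclass(frozen=True)
class StimulusTimecourse:
    """Numerosity-or-none sampled on a fine time grid (NaN where no stimulus)."""

    dt: float
    values: np.ndarray = field(repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


def build_cycle(modality: str, start: float = 0.0) -> list[Block]:
    """Build the 12 blocks of one stimulation cycle starting at ``start`` s.

    The cycle presents numerosities 1..5 ascending, a 20-item block, 5..1
    descending, and a second 20-item block (75.6 s total).
    """
    if modality not in _SMALL_EVENT:
        raise ValueError(f"unknown modality {modality!r}; expected 'visual' or 'auditory'")
    on_s, off_s, n_s = _SMALL_EVENT[modality]
    on_t, off_t, n_t = _TWENTY_EVENT[modality]
    blocks: list[Block] = []
    t = start
    for num in CYCLE_ORDER:
        if num == 20:
            on, off, n = on_t, off_t, n_t
        else:
            on, off, n = on_s, off_s, n_s
        dur = n * (on + off)
        blocks.append(Block(num, t, dur, n, on, off))
        t += dur
    return blocks


def cycle_duration(modality: str) -> float:
    return sum(b.duration for b in build_cycle(modality))


def build_run(
    modality: str,
    n_cycles: int = 4,
    tr: float = 2.1,
    n_volumes: int = 145,
    slice_time_ref: float = 1.025,
) -> StimulusSchedule:
    """Concatenate ``n_cycles`` cycles from t=0; trailing time is stimulus-free."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    cyc_dur = cycle_duration(modality)
    if n_volumes * tr < n_cycles * cyc_dur - 1e-9:
        raise ValueError(
            f"run of {n_volumes * tr:.1f} s too short for "
            f"{n_cycles} cycles ({n_cycles * cyc_dur:.1f} s)"
        )
    blocks: list[Block] = []
    for c in range(n_cycles):
        blocks.extend(build_cycle(modality, start=c * cyc_dur))
    return StimulusSchedule(
        modality=modality,
        blocks=tuple(blocks),
        tr=tr,
        n_volumes=n_volumes,
        n_cycles=n_cycles,
        slice_time_ref=slice_time_ref,
    )


def numerosity_timecourse(
    schedule: StimulusSchedule, dt: float, event_level: bool = False
) -> StimulusTimecourse:
    """Sample x(t) on a grid of step ``dt``.

    Block-level mode (default) holds the block's numerosity for its whole
    duration; event-level mode sets the value only within each event's "on"
    window. Absence of stimulation is encoded as NaN.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isclose(schedule.tr / dt, round(schedule.tr / dt), abs_tol=1e-9):
        raise ValueError(f"dt={dt} must divide tr={schedule.tr} evenly")
    n = math.ceil(schedule.duration / dt)
    values = np.full(n, np.nan)
    t = np.arange(n) * dt
    for b in schedule.blocks:
        if event_level:
            for e in range(b.n_events):
                e_on = b.onset + e * (b.event_on + b.event_off)
                sel = (t >= e_on - 1e-9) & (t < e_on + b.event_on - 1e-9)
                values[sel] = b.numerosity
        else:
            sel = (t >= b.onset - 1e-9) & (t < b.end - 1e-9)
            values[sel] = b.numerosity
    return StimulusTimecourse(dt=dt, values=values)


def schedule_to_events(schedule: StimulusSchedule) -> pd.DataFrame:
    """Serialize blocks as a BIDS-events-style table (onset, duration, numerosity)."""
    return pd.DataFrame(
        {
            "onset": [b.onset for b in schedule.blocks],
            "duration": [b.duration for b in schedule.blocks],
            "numerosity": [b.numerosity for b in schedule.blocks],
        }
    )


def events_to_schedule(
    events: pd.DataFrame,
    modality: str,
    tr: float = 2.1,
    n_volumes: int = 145,
) -> StimulusSchedule:
    """Rebuild a schedule from an events table written by :func:`schedule_to_events`."""
    blocks = []
    for _, row in events.iterrows():
        num = int(row["numerosity"])
        on, off, _ = (_TWENTY_EVENT if num == 20 else _SMALL_EVENT)[modality]
        n_events = round(row["duration"] / (on + off))
        blocks.append(Block(num, float(row["onset"]), float(row["duration"]),
                            n_events, on, off))
    n_cycles = max(1, sum(1 for b in blocks if b.numerosity == 20) // 2)
    return StimulusSchedule(modality=modality, blocks=tuple(blocks), tr=tr,
                            n_volumes=n_volumes, n_cycles=n_cycles)
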