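"""Sleep scoring, bout metrics, profiles, and Zeitgeber/starvation-time windows.

Fly sleep is scored with the field-standard inactivity rule: a sleep bout is
every maximal run of consecutive minutes with zero beam counts whose length
reaches the threshold (5 min by default).  Metrics (total sleep, bout number,
mean bout duration) are computed over arbitrary minute windows with bouts
clipped at window edges, so totals are conserved across adjacent windows.

Time bookkeeping uses Zeitgeber time (ZT: hours since lights-on; in a 12:12
LD cycle ZT0 = lights on, ZT12 = lights off) and starvation time (ST: hours
since food deprivation began).  The analyses here are anchored to the first
light<->dark transition after starvation starts — e.g. a ZT12 starvation start
puts the first shift at the next lights-on, so ST12-ST24 maps onto the
ZT0-ZT12 light phase of the following cycle.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .dam_io import ActivitySeries
from .errors import ValidationError

MINUTES_PER_DAY = 1440

#: Field-standard minimum inactive run length scored as sleep, in minutes.
DEFAULT_SLEEP_THRESHOLD_MIN = 5


@dataclass
class ExperimentDesign:
    """Photoperiod geometry and the starvation anchor for one experiment.

    ``lights_on_clock`` maps wall-clock time to ZT0.  ``recording_start_zt``
    is the ZT of minute 0 of every series in the experiment (recordings are
    conventionally started at lights-on, ZT0).  ``starvation_day`` indexes
    the recording cycle in which food deprivation begins, so that ST windows
    can be mapped to series minute coordinates.
    """

    lights_on_clock: dt.time = dt.time(6, 30)
    light_hours: float = 12.0
    dark_hours: float = 12.0
    starvation_start_zt: float | None = None
    starvation_day: int = 0
    recording_start_zt: float = 0.0
    n_days: int = 2

    def __post_init__(self) -> None:
        if isinstance(self.lights_on_clock, str):
            h, m = self.lights_on_clock.split(":")[:2]
            self.lights_on_clock = dt.time(int(h), int(m))
        if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
            raise ValidationError("light_hours + dark_hours must equal 24")
        if self.starvation_start_zt is not None and not 0 <= self.starvation_start_zt < 24:
            raise ValidationError("starvation_start_zt must lie in [0, 24)")
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")

    @property
    def total_minutes(self) -> int:
        return self.n_days * MINUTES_PER_DAY

    def zt_of_minute(self, minute: int | np.ndarray) -> float | np.ndarray:
        """ZT hours (mod 24) of a series minute index."""
        return (self.recording_start_zt + np.asarray(minute) / 60.0) % 24.0

    def is_light(self, zt: float | np.ndarray) -> bool | np.ndarray:
        """True during the light phase: ZT in [0, light_hours)."""
        return np.asarray(zt) % 24.0 < self.light_hours

    @property
    def starvation_start_min(self) -> int:
        """Series minute at which food deprivation begins."""
        if self.starvation_start_zt is None:
            raise ValidationError("design has no starvation start")
        rel = (self.starvation_start_zt - self.recording_start_zt) % 24.0
        return int(round(self.starvation_day * MINUTES_PER_DAY + rel * 60.0))


@dataclass
class SleepBouts:
    """Disjoint, sorted half-open sleep intervals in series minute coordinates."""

    intervals: list[tuple[int, int]]
    source_len: int

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.intervals:
            if not (0 <= s < e <= self.source_len):
                raise ValidationError(f"bout [{s}, {e}) outside [0, {self.source_len}]")
            if s < prev_end:
                raise ValidationError("bouts overlap or are unsorted")
            prev_end = e

    def __len__(self) -> int:
        return len(self.intervals)

    def asleep_mask(self) -> np.ndarray:
        """Boolean per-minute sleep indicator of length ``source_len``."""
        mask = np.zeros(self.source_len, dtype=bool)
        for s, e in self.intervals:
            mask[s:e] = True
        return mask

    def shifted(self, k: int, new_source_len: int | None = None) -> "SleepBouts":
        n = self.source_len + k if new_source_len is None else new_source_len
        return SleepBouts([(s + k, e + k) for s, e in self.intervals], n)


@dataclass
class SleepMetrics:
    """Window summary: total sleep, bout number, mean bout duration.

    ``mean_bout_duration_min`` is ``None`` (missing) when no bout overlaps
    the window — zero would conflate "no sleep" with "brief sleep".
    """

    total_sleep_min: int
    bout_number: int
    mean_bout_duration_min: float | None
    window: tuple[int, int]


@dataclass
class SleepProfile:
    """Per-bin minutes asleep, the standard published fly sleep profile."""

    bin_min: int
    values: np.ndarray
    zt_of_first_bin: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values < 0) | (self.values > self.bin_min)).any():
            raise ValidationError("profile values must lie in [0, bin_min]")

    def bin_zt(self) -> np.ndarray:
        """ZT (mod 24) of each bin's left edge."""
        return (self.zt_of_first_bin + np.arange(len(self.values)) * self.bin_min / 60.0) % 24.0


class FirstLDShift(NamedTuple):
    """The first light<->dark transition strictly after starvation start."""

    shift_zt: float   # ZT of the transition, in [0, 24)
    st_hours: float   # hours elapsed since starvation at the transition


def score_sleep(
    series: ActivitySeries | np.ndarray,
    threshold_min: int = DEFAULT_SLEEP_THRESHOLD_MIN,
) -> SleepBouts:
    """Score sleep bouts: maximal zero-count runs of length >= ``threshold_min``.

    Depends only on the zero/nonzero pattern of the counts.  Runs touching
    the series edges are truncated there and still count if long enough.
    """
    if threshold_min < 1:
        raise ValidationError("threshold_min must be >= 1")
    counts = series.counts if isinstance(series, ActivitySeries) else np.asarray(series)
    if counts.size == 0:
        raise ValidationError("empty series")
    zero = (counts == 0).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], zero, [0]))))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= threshold_min
    intervals = [(int(s), int(e)) for s, e in zip(starts[keep], ends[keep])]
    return SleepBouts(intervals=intervals, source_len=int(counts.size))


def bout_metrics(bouts: SleepBouts, window: tuple[int, int] | None = None) -> SleepMetrics:
    """Summarise bouts over a half-open minute window ``[a, b)``.

    Bouts are clipped at the window edges; a bout counts toward every window
    it overlaps, and the overlapped portions are what the mean averages, so
    totals are conserved across adjacent windows.
    """
    a, b = (0, bouts.source_len) if window is None else (int(window[0]), int(window[1]))
    if not a < b:
        raise ValidationError(f"empty window [{a}, {b})")
    if a < 0 or b > bouts.source_len:
        raise ValidationError(f"window [{a}, {b}) outside [0, {bouts.source_len})")
    overlaps = [
        min(e, b) - max(s, a) for s, e in bouts.intervals if min(e, b) > max(s, a)
    ]
    total = int(sum(overlaps))
    n = len(overlaps)
    mean = total / n if n else None
    return SleepMetrics(total_sleep_min=total, bout_number=n,
                        mean_bout_duration_min=mean, window=(a, b))


def sleep_profile(
    bouts: SleepBouts,
    design: ExperimentDesign | None = None,
    bin_min: int = 30,
) -> SleepProfile:
    """Bin per-minute sleep into a profile; bin sums conserve total sleep."""
    if bin_min < 1 or bouts.source_len % bin_min != 0:
        raise ValidationError(
            f"bin width {bin_min} must divide the series length {bouts.source_len}"
        )
    values = bouts.asleep_mask().reshape(-1, bin_min).sum(axis=1)
    zt0 = design.recording_start_zt if design is not None else 0.0
    return SleepProfile(bin_min=bin_min, values=values, zt_of_first_bin=zt0)


def first_ld_shift(design: ExperimentDesign) -> FirstLDShift:
    """First LD transition strictly after starvation start.

    Transitions happen at ZT0 (lights on) and ZT ``light_hours`` (lights
    off).  "Strictly after" means a start exactly at a transition points to
    the next one: a ZT0 start shifts at ZT12 (ST12); a ZT12 start shifts at
    the next ZT0 (ST12), so the post-shift half-day is ZT0-ZT12.
    """
    if design.starvation_start_zt is None:
        raise ValidationError("design has no starvation start")
    start = design.starvation_start_zt
    best = None
    for cand in (0.0, design.light_hours):
        st = (cand - start) % 24.0
        if st <= 0:
            st = 24.0
        if best is None or st < best[1]:
            best = (cand % 24.0, st)
    return FirstLDShift(shift_zt=best[0], st_hours=best[1])


def st_window(
    design: ExperimentDesign, st_from: float, st_to: float
) -> tuple[int, int]:
    """Map a starvation-time window ``[st_from, st_to)`` hours to series minutes."""
    if not 0 <= st_from < st_to:
        raise ValidationError("need 0 <= st_from < st_to")
    base = design.starvation_start_min
    a = base + int(round(st_from * 60.0))
    b = base + int(round(st_to * 60.0))
    if b > design.total_minutes:
        raise ValidationError(
            f"ST window [{st_from}, {st_to})h ends at minute {b}, beyond the "
            f"{design.total_minutes}-min recording"
        )
    return a, b


def is_dead(series: ActivitySeries, final_hours: float = 12.0) -> bool:
    """Dead-fly heuristic: no beam breaks at all over the final hours of record."""
    n = min(len(series), int(round(final_hours * 60)))
    return bool((series.counts[-n:] == 0).all())


def exclude_dead(
    series_list: Sequence[ActivitySeries], final_hours: float = 12.0
) -> list[ActivitySeries]:
    """Drop flies failing :func:`is_dead`; intended for fed-arm records."""
    return [s for s in series_list if not is_dead(s, final_hours)]
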