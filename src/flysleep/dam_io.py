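"""Reading, validating and slicing Drosophila Activity Monitor (DAM) records.

Trikinetics DAM systems append one tab-delimited row per minute per monitor:
a reading index, date, time, a status code, six device fields, then 32
per-channel infrared beam-break counts (one channel per fly tube).  This
module parses that layout plus a simple CSV dialect
(``timestamp,ch1,...,ch32``), enforces the one-row-per-minute contract, and
slices single channels into per-fly :class:`ActivitySeries`.

Rows whose status code differs from the "valid reading" code are retained
and flagged, never silently dropped.  Missing minutes are a hard error by
default; ``repair_gaps=True`` inserts zero-count flagged rows instead.
Timestamps are naive local clock time — the experiment design, not the file,
defines lights-on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Number of count channels per monitor.
N_CHANNELS = 32

#: Trikinetics status code for a valid reading.
VALID_STATUS = 1

#: Status code used for rows synthesised by gap repair.
REPAIRED_STATUS = 0

_DAM_DATE_FMT = "%d %b %y"
_DAM_TIME_FMT = "%H:%M:%S"
_MIN_DAM_COLUMNS = 42


@dataclass
class ActivitySeries:
    """Minute-resolution beam-count record for a single fly.

    Minute ``i`` corresponds to ``start_time + i`` minutes; there are no
    gaps or duplicates by construction.
    """

    fly_id: str
    start_time: pd.Timestamp
    counts: np.ndarray
    channel: int = 1
    monitor_id: str = ""

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time).floor("min")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValidationError(f"{self.fly_id}: counts must be a non-empty 1-D sequence")
        if (self.counts < 0).any():
            raise ValidationError(f"{self.fly_id}: negative beam counts")
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValidationError(f"{self.fly_id}: channel {self.channel} outside 1..{N_CHANNELS}")

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def end_time(self) -> pd.Timestamp:
        """Timestamp of the last recorded minute."""
        return self.start_time + pd.Timedelta(minutes=len(self) - 1)


@dataclass
class MonitorTable:
    """Validated per-monitor matrix: one row per minute, 32 count columns."""

    timestamps: pd.DatetimeIndex
    counts: np.ndarray          # shape (n_rows, 32)
    status: np.ndarray          # shape (n_rows,)
    monitor_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.status = np.asarray(self.status, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != N_CHANNELS:
            raise ValidationError(
                f"monitor {self.monitor_id!r}: counts must have {N_CHANNELS} columns"
            )
        if not (len(self.timestamps) == len(self.counts) == len(self.status)):
            raise ValidationError(f"monitor {self.monitor_id!r}: ragged table")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of rows whose status code is not the valid-reading code."""
        return self.status != VALID_STATUS

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.timestamps[0], self.timestamps[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=self.timestamps,
            columns=[f"ch{i}" for i in range(1, N_CHANNELS + 1)],
        )
        df.insert(0, "status", self.status)
        return df


def _validate_minute_spacing(timestamps: pd.DatetimeIndex, monitor_id: str) -> None:
    if len(timestamps) < 2:
        return
    deltas = np.diff(timestamps.asi8) // 60_000_000_000  # minutes
    bad = np.flatnonzero(deltas != 1)
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"monitor {monitor_id!r}: rows {i + 1} and {i + 2} are not one minute apart "
            f"({timestamps[i]} -> {timestamps[i + 1]})"
        )


def _repair_gaps(
    timestamps: pd.DatetimeIndex, counts: np.ndarray, status: np.ndarray, monitor_id: str
) -> tuple[pd.DatetimeIndex, np.ndarray, np.ndarray]:
    """Insert zero-count flagged rows for missing minutes; duplicates still fail."""
    deltas = np.diff(timestamps.asi8) // 60_000_000_000
    if (deltas < 1).any():
        i = int(np.flatnonzero(deltas < 1)[0])
        raise ValidationError(
            f"monitor {monitor_id!r}: non-monotone timestamps at rows {i + 1}/{i + 2} "
            f"({timestamps[i]} -> {timestamps[i + 1]}) cannot be repaired"
        )
    full = pd.date_range(timestamps[0], timestamps[-1], freq="min")
    pos = full.get_indexer(timestamps)
    new_counts = np.zeros((len(full), N_CHANNELS), dtype=np.int64)
    new_status = np.full(len(full), REPAIRED_STATUS, dtype=np.int64)
    new_counts[pos] = counts
    new_status[pos] = status
    return full, new_counts, new_status


def read_monitor_file(
    path, dialect: str = "dam", monitor_id: str | None = None, repair_gaps: bool = False
) -> MonitorTable:
    """Read a monitor file into a validated :class:`MonitorTable`.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"dam"``: tab-delimited Trikinetics layout with >= 42 columns
        (index, date, time, status, six device fields, 32 channel counts).
        ``"csv"``: header ``timestamp,ch1,...,ch32`` with ISO-8601 minute
        timestamps; status is taken as valid for every row.
    monitor_id
        Label for the table; defaults to the file stem.
    repair_gaps
        Insert zero-count flagged rows at missing minutes instead of failing.
    """
    import pathlib

    path = pathlib.Path(path)
    if monitor_id is None:
        monitor_id = path.stem
    if dialect == "dam":
        timestamps, counts, status = _read_dam(path)
    elif dialect == "csv":
        timestamps, counts, status = _read_csv(path)
    else:
        raise ValidationError(f"unknown monitor dialect {dialect!r}")
    if len(timestamps) == 0:
        raise ParseError(f"{path}: no data rows")
    if repair_gaps:
        timestamps, counts, status = _repair_gaps(timestamps, counts, status, monitor_id)
    _validate_minute_spacing(timestamps, monitor_id)
    return MonitorTable(timestamps=timestamps, counts=counts, status=status, monitor_id=monitor_id)


def _read_dam(path):
    stamps: list[pd.Timestamp] = []
    status: list[int] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < _MIN_DAM_COLUMNS:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {_MIN_DAM_COLUMNS} tab-separated "
                    f"columns, found {len(cols)}"
                )
            try:
                ts = pd.Timestamp.combine(
                    pd.to_datetime(cols[1], format=_DAM_DATE_FMT).date(),
                    pd.to_datetime(cols[2], format=_DAM_TIME_FMT).time(),
                )
                st = int(cols[3])
                counts = [int(c) for c in cols[10:10 + N_CHANNELS]]
            except (ValueError, TypeError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if any(c < 0 for c in counts):
                raise ParseError(f"{path}: line {lineno}: negative count")
            stamps.append(ts)
            status.append(st)
            rows.append(counts)
    return (
        pd.DatetimeIndex(stamps),
        np.asarray(rows, dtype=np.int64).reshape(len(rows), N_CHANNELS),
        np.asarray(status, dtype=np.int64),
    )


_CSV_HEADER = ["timestamp"] + [f"ch{i}" for i in range(1, N_CHANNELS + 1)]


def _read_csv(path):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != _CSV_HEADER:
        raise ParseError(f"{path}: header must be {','.join(_CSV_HEADER)}")
    try:
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: bad timestamp: {exc}") from exc
    counts = df[_CSV_HEADER[1:]].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        bad = int(np.argwhere(counts < 0)[0, 0]) + 2
        raise ParseError(f"{path}: line {bad}: negative count")
    status = np.full(len(df), VALID_STATUS, dtype=np.int64)
    return ts, counts, status


def write_monitor_file(table: MonitorTable, path, dialect: str = "dam") -> None:
    """Write a :class:`MonitorTable`; ``read_monitor_file`` inverts it exactly."""
    if len(table) == 0:
        raise ValidationError("no rows")
    if dialect == "dam":
        with open(path, "w") as fh:
            for i, ts in enumerate(table.timestamps):
                date = ts.strftime(_DAM_DATE_FMT)
                time = ts.strftime(_DAM_TIME_FMT)
                device = "\t".join(["1", "0", "0", "0", "0", "0"])
                counts = "\t".join(str(c) for c in table.counts[i])
                fh.write(f"{i + 1}\t{date}\t{time}\t{table.status[i]}\t{device}\t{counts}\n")
    elif dialect == "csv":
        df = pd.DataFrame(table.counts, columns=_CSV_HEADER[1:])
        df.insert(0, "timestamp", table.timestamps.strftime("%Y-%m-%dT%H:%M"))
        df.to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown monitor dialect {dialect!r}")


def slice_channel(
    table: MonitorTable,
    channel: int,
    window: tuple | None = None,
    fly_id: str | None = None,
) -> ActivitySeries:
    """Extract one channel over a closed timestamp interval.

    ``window`` is ``(first_minute, last_minute)``, both inclusive; ``None``
    selects the full span.  The result has one count per minute of the
    window.
    """
    if not 1 <= channel <= N_CHANNELS:
        raise ValidationError(f"channel {channel} outside 1..{N_CHANNELS}")
    lo, hi = table.span
    if window is None:
        start, stop = lo, hi
    else:
        start, stop = (pd.Timestamp(w).floor("min") for w in window)
    if start > stop:
        raise ValidationError(f"empty window {start} > {stop}")
    if start < lo or stop > hi:
        raise ValidationError(
            f"window [{start}, {stop}] outside monitor span [{lo}, {hi}]"
        )
    i0 = int((start - lo) / pd.Timedelta(minutes=1))
    i1 = int((stop - lo) / pd.Timedelta(minutes=1))
    counts = table.counts[i0:i1 + 1, channel - 1]
    if fly_id is None:
        fly_id = f"{table.monitor_id}_ch{channel:02d}"
    return ActivitySeries(
        fly_id=fly_id, start_time=start, counts=counts,
        channel=channel, monitor_id=table.monitor_id,
    )


def pack_monitor(
    series: Sequence[ActivitySeries], monitor_id: str = "Monitor1"
) -> MonitorTable:
    """Assemble up to 32 equal-length, co-started series into one monitor table.

    Channels are assigned in order; unused channels read zero.  Used by the
    simulator so synthetic data exercises the real reader/writer.
    """
    if not series:
        raise ValidationError("no series to pack")
    if len(series) > N_CHANNELS:
        raise ValidationError(f"cannot pack {len(series)} series into {N_CHANNELS} channels")
    n = len(series[0])
    t0 = series[0].start_time
    counts = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for i, s in enumerate(series):
        if len(s) != n or s.start_time != t0:
            raise ValidationError("all series must share start time and length")
        counts[:, i] = s.counts
    timestamps = pd.date_range(t0, periods=n, freq="min")
    status = np.full(n, VALID_STATUS, dtype=np.int64)
    return MonitorTable(timestamps=timestamps, counts=counts, status=status, monitor_id=monitor_id)
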