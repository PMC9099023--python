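"""Light schedules, Zeitgeber time, and activity-monitor file I/O.

A :class:`LightSchedule` is a piecewise light/dark program: repeated LD
cycles (``LD18:6`` etc.), constant darkness (``DD``) or constant light
(``LL``), optionally with short light/dark pulses overriding the base
program.  Zeitgeber time (ZT) is hours since lights-on; ZT0 is always the
lights-on instant of the entraining cycle, and in constant conditions ZT
keeps running on the 24-h phase of the preceding (or nominal) LD cycle.

Monitor files follow the tab-separated activity-monitor text convention:
index, date, time, status, then one count column per channel, one row per
bin.  All intervals are half-open ``[start, end)``: a bin belongs to the
light state at its start.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LightSchedule",
    "Pulse",
    "Segment",
    "MonitorTable",
    "ActivitySeries",
    "EnvironmentTable",
    "make_schedule",
    "zt_of",
    "read_monitor",
    "write_monitor",
    "read_environment",
]

STATUS_OK = 1


@dataclass(frozen=True)
class Segment:
    """One contiguous stretch of a light program.

    ``start_h`` is measured in hours from the schedule origin (ZT0 of the
    first cycle); ``light_on`` is the state over ``[start_h, start_h+duration_h)``.
    """

    start_h: float
    duration_h: float
    light_on: bool

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h


@dataclass(frozen=True)
class Pulse:
    """A light-state override (e.g. a 2-h dark pulse in the photophase)."""

    start_h: float  # hours from schedule origin
    duration_h: float
    light_on: bool

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h


@dataclass
class LightSchedule:
    """Piecewise light/dark program with optional pulses.

    Parameters
    ----------
    segments
        Contiguous, non-overlapping segments covering ``[0, span_h)``.
    label
        Human-readable program name, e.g. ``"LD18:6"``, ``"DD"``.
    photoperiod_h
        Light-phase duration of the underlying 24-h cycle, or ``None`` for
        constant conditions with no nominal cycle.
    pulses
        Overrides applied on top of the base segments.
    """

    segments: list[Segment]
    label: str
    photoperiod_h: float | None = None
    pulses: list[Pulse] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        t = self.segments[0].start_h
        if t != 0.0:
            raise ValueError("first segment must start at 0")
        for seg in self.segments:
            if seg.duration_h <= 0:
                raise ValueError("segment durations must be positive")
            if abs(seg.start_h - t) > 1e-9:
                raise ValueError("segments must be contiguous and ordered")
            t = seg.end_h
        for p in self.pulses:
            if p.start_h < 0 or p.end_h > self.span_h + 1e-9:
                raise ValueError(
                    f"pulse [{p.start_h}, {p.end_h}) h lies outside the "
                    f"schedule span of {self.span_h} h"
                )

    @property
    def span_h(self) -> float:
        return self.segments[-1].end_h

    @property
    def is_cyclic(self) -> bool:
        """True when the base program alternates light and dark."""
        states = {s.light_on for s in self.segments}
        return len(states) == 2

    @property
    def is_constant(self) -> bool:
        return not self.is_cyclic

    def light_at(self, t_h: float) -> bool:
        """Light state at ``t_h`` hours from origin (pulses applied)."""
        if t_h < 0 or t_h >= self.span_h:
            raise ValueError(f"time {t_h} h outside schedule span [0, {self.span_h})")
        for p in self.pulses:
            if p.start_h <= t_h < p.end_h:
                return p.light_on
        # segments are ordered; binary search on start times
        starts = [s.start_h for s in self.segments]
        i = int(np.searchsorted(starts, t_h, side="right")) - 1
        return self.segments[i].light_on

    def light_states(self, t_h: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`light_at` (bool array)."""
        t_h = np.asarray(t_h, dtype=float)
        if np.any(t_h < 0) or np.any(t_h >= self.span_h):
            raise ValueError("times outside schedule span")
        starts = np.array([s.start_h for s in self.segments])
        states = np.array([s.light_on for s in self.segments])
        out = states[np.searchsorted(starts, t_h, side="right") - 1]
        for p in self.pulses:
            out = np.where((t_h >= p.start_h) & (t_h < p.end_h), p.light_on, out)
        return out

    def transitions(self) -> list[tuple[float, bool]]:
        """Times (h from origin) at which the light state switches, with the
        new state.  Includes pulse edges; t=0 is not a transition."""
        edges: list[tuple[float, bool]] = []
        prev = self.light_at(0.0)
        # candidate edge times: segment boundaries and pulse boundaries
        cand = sorted(
            {s.start_h for s in self.segments[1:]}
            | {p.start_h for p in self.pulses}
            | {p.end_h for p in self.pulses if p.end_h < self.span_h}
        )
        for t in cand:
            st = self.light_at(t)
            if st != prev:
                edges.append((t, st))
                prev = st
        return edges

    def zt(self, t_h: float | np.ndarray) -> np.ndarray | float:
        """ZT hours in [0, 24) for time(s) ``t_h`` from origin.

        The schedule origin is ZT0 (lights-on of the first cycle); in
        constant conditions ZT continues on the 24-h phase of the prior LD
        program, so ZT is always ``t_h mod 24``.
        """
        return np.mod(t_h, 24.0)


_LD_RE = re.compile(r"^LD\s*(\d+(?:\.\d+)?)\s*:\s*(\d+(?:\.\d+)?)$", re.IGNORECASE)


def make_schedule(
    label: str,
    photoperiod_hours: float | None = None,
    pulses: Sequence[tuple[float, float, bool]] | Sequence[Pulse] = (),
    span_days: int = 1,
) -> LightSchedule:
    """Build a light schedule from a label like ``"LD18:6"``, ``"DD"`` or ``"LL"``.

    For cyclic labels the photoperiod may be encoded in the label
    (``LD18:6``) or given via ``photoperiod_hours``; the two must agree if
    both are present.  ZT0 coincides with lights-on.  Pulses are
    ``(start_h_from_origin, duration_h, light_on)`` triples.
    """
    if span_days < 1:
        raise ValueError("span_days must be >= 1")
    label = label.strip()
    m = _LD_RE.match(label)
    pulse_list = [p if isinstance(p, Pulse) else Pulse(*p) for p in pulses]
    if m:
        light_h, dark_h = float(m.group(1)), float(m.group(2))
        if abs(light_h + dark_h - 24.0) > 1e-9:
            raise ValueError(f"LD label {label!r}: light+dark must sum to 24 h")
        if photoperiod_hours is not None and abs(photoperiod_hours - light_h) > 1e-9:
            raise ValueError("photoperiod_hours conflicts with LD label")
        photoperiod_hours = light_h
    elif label.upper() in ("DD", "LL"):
        if photoperiod_hours is not None:
            # retained as the nominal prior cycle so ZT stays meaningful
            pass
        on = label.upper() == "LL"
        segs = [Segment(0.0, 24.0 * span_days, on)]
        return LightSchedule(segs, label.upper(), photoperiod_hours, pulse_list)
    elif photoperiod_hours is not None:
        if not (0.0 < photoperiod_hours < 24.0):
            raise ValueError("photoperiod_hours must lie in (0, 24)")
        label = f"LD{photoperiod_hours:g}:{24 - photoperiod_hours:g}"
    else:
        raise ValueError(f"unrecognised schedule label {label!r}")

    if not (0.0 < photoperiod_hours < 24.0):
        raise ValueError("photoperiod_hours must lie in (0, 24)")
    segs: list[Segment] = []
    for d in range(span_days):
        t0 = 24.0 * d
        segs.append(Segment(t0, photoperiod_hours, True))
        segs.append(Segment(t0 + photoperiod_hours, 24.0 - photoperiod_hours, False))
    return LightSchedule(segs, label, photoperiod_hours, pulse_list)


def concat_schedules(first: LightSchedule, second: LightSchedule, label: str | None = None) -> LightSchedule:
    """Chain two programs (e.g. 5 days LD entrainment then 12 days DD).

    ZT phase carries over: the second program's origin lands at the end of
    the first, so ZT in the constant segment continues from the LD phase.
    """
    off = first.span_h
    segs = list(first.segments) + [
        Segment(s.start_h + off, s.duration_h, s.light_on) for s in second.segments
    ]
    pulses = list(first.pulses) + [
        Pulse(p.start_h + off, p.duration_h, p.light_on) for p in second.pulses
    ]
    return LightSchedule(
        segs,
        label or f"{first.label}+{second.label}",
        first.photoperiod_h,
        pulses,
    )


def zt_of(timestamp: datetime, schedule: LightSchedule, t0: datetime) -> float:
    """ZT hours in [0, 24) of a wall-clock ``timestamp``.

    ``t0`` is the wall-clock instant of the schedule origin (the first
    lights-on).  Raises if the timestamp falls outside the schedule span.
    """
    dt_h = (timestamp - t0).total_seconds() / 3600.0
    if dt_h < 0 or dt_h >= schedule.span_h:
        raise ValueError(f"timestamp {timestamp} outside schedule span")
    return float(np.mod(dt_h, 24.0))


# ---------------------------------------------------------------------------
# monitor tables and per-animal series


@dataclass
class MonitorTable:
    """Binned counts from one activity monitor.

    ``counts`` has one row per timestamp and one column per channel; bins
    whose status flag marked a reader error are recorded in ``missing`` and
    excluded from statistics downstream.
    """

    source_id: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray  # (n_bins, n_channels) int
    bin_minutes: int
    missing: np.ndarray | None = None  # bool mask per bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] < 1:
            raise ValueError("counts must be 2-D with at least one channel")
        if len(self.timestamps) != self.counts.shape[0]:
            raise ValueError("timestamps and counts length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        step = pd.Timedelta(minutes=self.bin_minutes)
        diffs = np.diff(self.timestamps.values)
        if len(diffs) and not np.all(diffs == np.timedelta64(step.value, "ns")):
            bad = int(np.nonzero(diffs != np.timedelta64(step.value, "ns"))[0][0])
            raise ValueError(
                f"timestamps not uniformly spaced at {self.bin_minutes} min: "
                f"gap after row {bad} ({self.timestamps[bad]})"
            )
        if self.missing is None:
            self.missing = np.zeros(len(self.timestamps), dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]


@dataclass
class ActivitySeries:
    """Binned locomotor counts of one animal bound to a light schedule.

    ``t0_zt`` gives the ZT of the first bin, anchoring the series to the
    schedule; ``start_h`` is the offset (hours) of the first bin from the
    schedule origin, so ``t0_zt == start_h % 24``.
    """

    animal_id: str
    counts: np.ndarray
    bin_minutes: int
    schedule: LightSchedule
    start_h: float = 0.0
    genotype: str = ""
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if np.any(self.counts[~np.isnan(self.counts)] < 0):
            raise ValueError("negative counts")
        if self.missing is None:
            self.missing = np.isnan(self.counts)
        span_needed = self.start_h + len(self.counts) * self.bin_minutes / 60.0
        if span_needed > self.schedule.span_h + 1e-6:
            raise ValueError("series extends past its schedule span")

    @property
    def t0_zt(self) -> float:
        return float(np.mod(self.start_h, 24.0))

    @property
    def bins_per_day(self) -> int:
        bpd = 24 * 60 / self.bin_minutes
        if abs(bpd - round(bpd)) > 1e-9:
            raise ValueError("bin_minutes must divide the day")
        return int(round(bpd))

    @property
    def n_days(self) -> float:
        return len(self.counts) / self.bins_per_day

    def times_h(self) -> np.ndarray:
        """Bin start times in hours from the schedule origin."""
        return self.start_h + np.arange(len(self.counts)) * self.bin_minutes / 60.0

    def zt(self) -> np.ndarray:
        """Per-bin ZT hours in [0, 24)."""
        return np.mod(self.times_h(), 24.0)

    def light_mask(self) -> np.ndarray:
        """Per-bin light state (True = lights on), state taken at bin start."""
        return self.schedule.light_states(self.times_h())

    def slice_hours(self, start_h: float, end_h: float) -> "ActivitySeries":
        """Sub-series covering [start_h, end_h) from the schedule origin."""
        t = self.times_h()
        sel = (t >= start_h - 1e-9) & (t < end_h - 1e-9)
        idx = np.nonzero(sel)[0]
        if len(idx) == 0:
            raise ValueError("empty slice")
        return ActivitySeries(
            self.animal_id,
            self.counts[idx],
            self.bin_minutes,
            self.schedule,
            start_h=float(t[idx[0]]),
            genotype=self.genotype,
            missing=self.missing[idx],
        )


@dataclass
class EnvironmentTable:
    """Light and temperature log from an environment monitor."""

    timestamps: pd.DatetimeIndex
    light_lux: np.ndarray
    temperature_c: np.ndarray
    bin_minutes: int

    def __post_init__(self) -> None:
        self.light_lux = np.asarray(self.light_lux, dtype=float)
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        if np.any(self.light_lux < 0):
            raise ValueError("negative light readings")
        step = np.timedelta64(int(self.bin_minutes * 60e9), "ns")
        diffs = np.diff(self.timestamps.values)
        if len(diffs) and not np.all(diffs == step):
            raise ValueError("environment timestamps not uniformly spaced")


# ---------------------------------------------------------------------------
# monitor text dialect


def read_monitor(path, bin_minutes: int, source_id: str | None = None) -> MonitorTable:
    """Read a tab-separated activity-monitor text file.

    Expected columns: record index, date (``D MON YY`` or ISO), time
    (``HH:MM:SS``), status flag, then one integer count column per channel.
    Rows whose status flag is not the OK value (1) are kept with their bins
    flagged missing.  Malformed rows raise with their line number; a gap or
    non-monotone timestamp is a hard error naming the offending row.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}: line {ln}: expected >=5 tab-separated fields")
            try:
                ts = _parse_monitor_datetime(parts[1], parts[2])
                status = int(parts[3])
                counts = [int(c) for c in parts[4:]]
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: {e}") from e
            if any(c < 0 for c in counts):
                raise ValueError(f"{path}: line {ln}: negative count")
            rows.append((ts, status, counts))
    if not rows:
        raise ValueError(f"{path}: empty monitor file")
    n_chan = len(rows[0][2])
    if any(len(r[2]) != n_chan for r in rows):
        raise ValueError(f"{path}: inconsistent channel count across rows")
    ts_index = pd.DatetimeIndex([r[0] for r in rows])
    counts = np.array([r[2] for r in rows], dtype=int)
    missing = np.array([r[1] != STATUS_OK for r in rows])
    return MonitorTable(
        source_id=source_id or str(path),
        timestamps=ts_index,
        counts=counts,
        bin_minutes=bin_minutes,
        missing=missing,
    )


_MONTHS = "JAN FEB MAR APR MAY JUN JUL AUG SEP OCT NOV DEC".split()


def _parse_monitor_datetime(date_s: str, time_s: str) -> datetime:
    date_s = date_s.strip()
    try:
        if "-" in date_s and date_s[0].isdigit() and len(date_s.split("-")[0]) == 4:
            d = datetime.strptime(date_s, "%Y-%m-%d")
        else:
            day, mon, yy = date_s.split("-") if "-" in date_s else date_s.split()
            d = datetime(2000 + int(yy), _MONTHS.index(mon.upper()) + 1, int(day))
    except Exception as e:  # noqa: BLE001 - re-raised with context
        raise ValueError(f"cannot parse date {date_s!r}: {e}") from e
    t = datetime.strptime(time_s.strip(), "%H:%M:%S").time()
    return datetime.combine(d.date(), t)


def write_monitor(table: MonitorTable, path) -> None:
    """Write a :class:`MonitorTable` in the monitor text dialect (round-trips
    bit-exactly with :func:`read_monitor`)."""
    with open(path, "w") as fh:
        for i, ts in enumerate(table.timestamps):
            date_s = f"{ts.day}-{_MONTHS[ts.month - 1]}-{ts.year % 100:02d}"
            time_s = ts.strftime("%H:%M:%S")
            status = 0 if table.missing[i] else STATUS_OK
            cnts = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{i + 1}\t{date_s}\t{time_s}\t{status}\t{cnts}\n")


def read_environment(path, bin_minutes: int) -> EnvironmentTable:
    """Read an environment-monitor text file (index, date, time, status,
    light lux, temperature in deci-degrees C)."""
    tbl = read_monitor(path, bin_minutes, source_id=str(path))
    if tbl.n_channels < 2:
        raise ValueError(f"{path}: environment file needs light and temperature columns")
    return EnvironmentTable(
        timestamps=tbl.timestamps,
        light_lux=tbl.counts[:, 0].astype(float),
        temperature_c=tbl.counts[:, 1].astype(float) / 10.0,
        bin_minutes=bin_minutes,
    )


def monitor_to_series(
    table: MonitorTable,
    schedule: LightSchedule,
    t0: datetime,
    animal_ids: Sequence[str] | None = None,
    genotype: str = "",
) -> list[ActivitySeries]:
    """Split a monitor table into per-channel :class:`ActivitySeries` bound
    to ``schedule`` (``t0`` = wall-clock instant of the schedule origin)."""
    start_h = (table.timestamps[0].to_pydatetime() - t0).total_seconds() / 3600.0
    if start_h < -1e-9:
        raise ValueError("monitor starts before the schedule origin")
    ids = list(animal_ids) if animal_ids else [
        f"{table.source_id}#{c + 1}" for c in range(table.n_channels)
    ]
    if len(ids) != table.n_channels:
        raise ValueError("animal_ids length must equal channel count")
    out = []
    for c, aid in enumerate(ids):
        counts = table.counts[:, c].astype(float)
        counts = counts.copy()
        counts[table.missing] = np.nan
        out.append(
            ActivitySeries(
                aid,
                counts,
                table.bin_minutes,
                schedule,
                start_h=max(start_h, 0.0),
                genotype=genotype,
            )
        )
    return out


def to_long_frame(series_list: Sequence[ActivitySeries]) -> pd.DataFrame:
    """Normalised long-format table (animal_id, t_h, zt, light_state, counts)."""
    frames = []
    for s in series_list:
        t = s.times_h()
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": s.animal_id,
                    "genotype": s.genotype,
                    "t_h": t,
                    "zt": np.mod(t, 24.0),
                    "light_state": s.light_mask(),
                    "counts": s.counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
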