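"""Call-event / GPS data model, CSV I/O and recorder clock-drift correction.

All analyses in this package run on two tabular containers:

* a *calls* table — one row per labelled vocalization (or merged call), with
  caller identity, call category, UTC onset/offset in seconds, a focal flag
  and the caller's age class;
* a *GPS* table — per-individual 1 Hz planar positions in metres.

Times are floating-point seconds since the session's UTC midnight; calendar
dates are carried separately as ISO strings.  Typed row objects
(:class:`CallEvent`, :class:`GpsFix`, :class:`SyncPing`) validate invariants
at the I/O boundary; the analysis modules work on :class:`pandas.DataFrame`
views produced by :func:`calls_to_frame` / :func:`gps_to_frame`.

Independently worn recorders drift against true time; a periodic spoken-time
("talking clock") ping, audible to every recorder, gives paired
(device time, true time) anchors every ~90 s.  :func:`correct_clock_drift`
maps device-clock event times onto UTC through the piecewise-linear
interpolant of those anchors, per device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed call-category vocabulary: close call, short note, social, aggression,
#: move, alarm, lead, unknown.
CATEGORIES = ("cc", "sn", "soc", "agg", "mo", "al", "ld", "ukn")

AGE_CLASSES = ("adult", "juvenile")

CALL_COLUMNS = [
    "event_id",
    "individual_id",
    "group_id",
    "session_date",
    "t_start",
    "t_end",
    "category",
    "focal",
    "age_class",
    "n_notes",
]

GPS_COLUMNS = ["individual_id", "t", "x", "y", "n_satellites", "valid"]

PING_COLUMNS = ["device_id", "t_device", "t_true"]


class SchemaError(ValueError):
    """A CSV is missing a mandatory column or violates the documented schema."""


class RowParseError(ValueError):
    """A CSV row could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class CallEvent:
    """One labelled vocalization (or a merged multi-note call)."""

    event_id: str
    individual_id: str
    group_id: str
    session_date: str
    t_start: float
    t_end: float
    category: str
    focal: bool = True
    age_class: str = "adult"
    n_notes: int = 1

    def __post_init__(self):
        if self.t_end < self.t_start:
            raise ValueError(
                f"event {self.event_id}: t_end ({self.t_end}) < t_start ({self.t_start})"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"event {self.event_id}: unknown category {self.category!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"event {self.event_id}: unknown age_class {self.age_class!r}")
        if self.n_notes < 1:
            raise ValueError(f"event {self.event_id}: n_notes must be >= 1")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class GpsFix:
    """A single (nominally 1 Hz) planar GPS position for one individual."""

    individual_id: str
    t: float
    x: float
    y: float
    n_satellites: int = 99
    valid: bool = True

    def __post_init__(self):
        if self.n_satellites < 0:
            raise ValueError("n_satellites must be >= 0")


@dataclass(frozen=True)
class SyncPing:
    """A talking-clock anchor pairing one device-clock time with true UTC."""

    device_id: str
    t_device: float
    t_true: float


@dataclass
class Session:
    """One group-day of synchronized tracking.

    ``individuals`` maps individual_id -> (age_class, has_gps); ``t_window``
    is the [start, end] UTC-second window every analysed call falls inside.
    """

    group_id: str
    session_date: str
    individuals: dict[str, tuple[str, bool]] = field(default_factory=dict)
    t_window: tuple[float, float] = (0.0, 3600.0)

    def __post_init__(self):
        if self.t_window[0] >= self.t_window[1]:
            raise ValueError("session t_window must have start < end")

    @property
    def duration(self) -> float:
        return self.t_window[1] - self.t_window[0]

    def adults(self) -> list[str]:
        return [i for i, (age, _) in self.individuals.items() if age == "adult"]

    def gps_individuals(self) -> list[str]:
        return [i for i, (_, has_gps) in self.individuals.items() if has_gps]


# ---------------------------------------------------------------------------
# frame <-> object conversion


def calls_to_frame(events: Iterable[CallEvent]) -> pd.DataFrame:
    """Return a calls DataFrame (documented column order) from CallEvents."""
    rows = [{f.name: getattr(e, f.name) for f in fields(CallEvent)} for e in events]
    frame = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return frame.astype(
        {"t_start": float, "t_end": float, "focal": bool, "n_notes": int}
        if len(frame)
        else {}
    )


def frame_to_calls(frame: pd.DataFrame) -> list[CallEvent]:
    return [
        CallEvent(
            event_id=str(r.event_id),
            individual_id=str(r.individual_id),
            group_id=str(r.group_id),
            session_date=str(r.session_date),
            t_start=float(r.t_start),
            t_end=float(r.t_end),
            category=str(r.category),
            focal=bool(r.focal),
            age_class=str(r.age_class),
            n_notes=int(r.n_notes),
        )
        for r in frame.itertuples(index=False)
    ]


def gps_to_frame(fixes: Iterable[GpsFix]) -> pd.DataFrame:
    rows = [{f.name: getattr(g, f.name) for f in fields(GpsFix)} for g in fixes]
    frame = pd.DataFrame(rows, columns=GPS_COLUMNS)
    if len(frame):
        frame = frame.astype(
            {"t": float, "x": float, "y": float, "n_satellites": int, "valid": bool}
        )
    return frame


def frame_to_gps(frame: pd.DataFrame) -> list[GpsFix]:
    return [
        GpsFix(
            individual_id=str(r.individual_id),
            t=float(r.t),
            x=float(r.x),
            y=float(r.y),
            n_satellites=int(r.n_satellites),
            valid=bool(r.valid),
        )
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# CSV readers / writers


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def read_call_events(path, *, map_unknown_categories: bool = True) -> list[CallEvent]:
    """Read a calls CSV into validated :class:`CallEvent` objects.

    Events are returned sorted by (individual_id, t_start).  Category strings
    outside the closed vocabulary map to ``ukn`` with a logged warning (set
    ``map_unknown_categories=False`` to make them a hard error).  Rows whose
    times fail to parse raise :class:`RowParseError` with the CSV line number;
    rows violating ``t_end >= t_start`` raise with the offending event_id.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, [c for c in CALL_COLUMNS if c != "valid"], path)

    events: list[CallEvent] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            t_start, t_end = float(row.t_start), float(row.t_end)
            n_notes = int(row.n_notes)
        except ValueError as exc:
            raise RowParseError(f"{path}:{line}: non-numeric field ({exc})", line=line) from exc
        category = row.category.strip()
        if category not in CATEGORIES:
            if not map_unknown_categories:
                raise RowParseError(f"{path}:{line}: unknown category {category!r}", line=line)
            logger.warning("%s:%d: unknown category %r mapped to 'ukn'", path, line, category)
            category = "ukn"
        try:
            events.append(
                CallEvent(
                    event_id=row.event_id,
                    individual_id=row.individual_id,
                    group_id=row.group_id,
                    session_date=row.session_date,
                    t_start=t_start,
                    t_end=t_end,
                    category=category,
                    focal=_parse_bool(row.focal),
                    age_class=row.age_class.strip(),
                    n_notes=n_notes,
                )
            )
        except ValueError as exc:
            raise RowParseError(f"{path}:{line}: {exc}", line=line) from exc
    events.sort(key=lambda e: (e.individual_id, e.t_start, e.event_id))
    return events


def write_call_events(events: Sequence[CallEvent], path) -> None:
    """Write events to CSV in the documented schema (round-trip identity)."""
    ids = [e.event_id for e in events]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate event_id(s): {', '.join(map(str, dupes))}")
    calls_to_frame(events).to_csv(path, index=False)


def read_gps(path) -> list[GpsFix]:
    """Read a GPS CSV; fixes sorted by (individual_id, t), strictly increasing t."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, [c for c in GPS_COLUMNS if c != "valid"], path)
    has_valid = "valid" in frame.columns
    fixes: list[GpsFix] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2
        try:
            fixes.append(
                GpsFix(
                    individual_id=row.individual_id,
                    t=float(row.t),
                    x=float(row.x),
                    y=float(row.y),
                    n_satellites=int(row.n_satellites),
                    valid=_parse_bool(row.valid) if has_valid else True,
                )
            )
        except ValueError as exc:
            raise RowParseError(f"{path}:{line}: {exc}", line=line) from exc
    fixes.sort(key=lambda g: (g.individual_id, g.t))
    for a, b in zip(fixes, fixes[1:]):
        if a.individual_id == b.individual_id and b.t <= a.t:
            raise ValueError(
                f"{path}: non-increasing fix times for {a.individual_id} at t={b.t}"
            )
    return fixes


def write_gps(fixes: Sequence[GpsFix], path) -> None:
    gps_to_frame(fixes).to_csv(path, index=False)


def read_sync_pings(path) -> list[SyncPing]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, PING_COLUMNS, path)
    pings = [
        SyncPing(device_id=r.device_id, t_device=float(r.t_device), t_true=float(r.t_true))
        for r in frame.itertuples(index=False)
    ]
    pings.sort(key=lambda p: (p.device_id, p.t_device))
    return pings


def write_sync_pings(pings: Sequence[SyncPing], path) -> None:
    pd.DataFrame(
        [{"device_id": p.device_id, "t_device": p.t_device, "t_true": p.t_true} for p in pings],
        columns=PING_COLUMNS,
    ).to_csv(path, index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


# ---------------------------------------------------------------------------
# clock-drift correction


def _drift_map(t_device: np.ndarray, t_true: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Piecewise-linear device->true mapping; edge segments extrapolate."""
    idx = np.clip(np.searchsorted(t_device, times) - 1, 0, len(t_device) - 2)
    t0, t1 = t_device[idx], t_device[idx + 1]
    u0, u1 = t_true[idx], t_true[idx + 1]
    return u0 + (times - t0) * (u1 - u0) / (t1 - t0)


def correct_clock_drift(
    events: Sequence[CallEvent],
    pings: Sequence[SyncPing],
    *,
    device_of=None,
    flag_extrapolation_s: float = 90.0,
) -> list[CallEvent]:
    """Map event times from device clocks to true UTC via the sync pings.

    ``device_of`` maps an event to its recorder id (default: the caller's
    individual_id — one collar per animal).  Within each device the mapping is
    the piecewise-linear interpolant of the (t_device, t_true) anchors; times
    outside the ping span follow the nearest segment's slope.  Events more
    than ``flag_extrapolation_s`` outside the span are logged.
    """
    if device_of is None:
        device_of = lambda e: e.individual_id  # noqa: E731

    by_device: dict[str, list[SyncPing]] = {}
    for p in pings:
        by_device.setdefault(p.device_id, []).append(p)

    maps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for device, dev_pings in by_device.items():
        dev_pings = sorted(dev_pings, key=lambda p: p.t_device)
        td = np.array([p.t_device for p in dev_pings], dtype=float)
        tt = np.array([p.t_true for p in dev_pings], dtype=float)
        if len(td) < 2:
            raise ValueError(f"insufficient sync pings for device {device!r} (need >= 2)")
        if not (np.all(np.diff(td) > 0) and np.all(np.diff(tt) > 0)):
            raise ValueError(f"non-monotone sync-ping mapping for device {device!r}")
        maps[device] = (td, tt)

    corrected: list[CallEvent] = []
    for e in events:
        device = device_of(e)
        if device not in maps:
            raise ValueError(f"no sync pings for device {device!r} (event {e.event_id})")
        td, tt = maps[device]
        lo, hi = td[0], td[-1]
        if e.t_start < lo - flag_extrapolation_s or e.t_end > hi + flag_extrapolation_s:
            logger.warning(
                "event %s lies >%gs outside the ping span of device %s; extrapolating",
                e.event_id, flag_extrapolation_s, device,
            )
        new_times = _drift_map(td, tt, np.array([e.t_start, e.t_end], dtype=float))
        corrected.append(
            CallEvent(
                event_id=e.event_id,
                individual_id=e.individual_id,
                group_id=e.group_id,
                session_date=e.session_date,
                t_start=float(new_times[0]),
                t_end=float(new_times[1]),
                category=e.category,
                focal=e.focal,
                age_class=e.age_class,
                n_notes=e.n_notes,
            )
        )
    return corrected
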