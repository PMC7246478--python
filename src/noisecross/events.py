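"""Case/control event construction for the time-stratified case-crossover design.

Deaths are split by clock time into daytime (07:00–23:00) and nighttime
(23:00–07:00) deaths; all windows are half-open [start, end).

Daytime deaths receive five fixed exposure windows anchored to the night
preceding the death day:

    evening        19:00–23:00  (14400 s)
    early night    23:00–23:30  ( 1800 s, reserved for delayed flights)
    core night     23:30–06:00  (23400 s, flight ban)
    early morning  06:00–07:00  ( 3600 s)
    overall night  23:00–07:00  (28800 s)

Nighttime deaths receive a single 2-hour window ending at the death clock
time, to probe short-term triggering.

Control events are sampled time-stratified: every other date in the same
calendar month sharing the case's day of week, which yields 3 or 4 controls
per case, bidirectionally around the case date.  Control windows reuse the
case's clock times on the control date, so case and control windows have
identical duration T.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Optional

from noisecross.footprints import ReceiverPoint

STUDY_SPAN = (2000, 2015)

_ICD10_CARDIOVASCULAR = re.compile(r"^I\d\d(\.\d+)?$")

DAY_START = time(7, 0)
NIGHT_START = time(23, 0)

#: fixed Table-1 windows for daytime deaths, as (window_id, start clock,
#: end clock, starts on previous calendar day, T seconds)
_DAYTIME_WINDOWS = (
    ("evening", time(19, 0), time(23, 0), True, True, 14400),
    ("early_night", time(23, 0), time(23, 30), True, True, 1800),
    ("core_night", time(23, 30), time(6, 0), True, False, 23400),
    ("early_morning", time(6, 0), time(7, 0), False, False, 3600),
    ("overall_night", time(23, 0), time(7, 0), True, False, 28800),
)

WINDOW_IDS = ("evening", "early_night", "core_night", "early_morning", "overall_night", "last2h")


@dataclass(frozen=True)
class DeathRecord:
    """One cardiovascular death: person, geocoded residence, time, ICD-10 cause."""

    person_id: str
    geocode: ReceiverPoint
    death_dt: datetime
    icd10: str

    def __post_init__(self) -> None:
        if not _ICD10_CARDIOVASCULAR.match(self.icd10):
            raise ValueError(f"icd10 must be a cardiovascular code I00–I99, got {self.icd10!r}")


@dataclass(frozen=True)
class ExposureWindow:
    """Half-open exposure window [start_dt, end_dt) with nominal duration T."""

    window_id: str
    start_dt: datetime
    end_dt: datetime
    t_seconds: int

    def __post_init__(self) -> None:
        if self.window_id not in WINDOW_IDS:
            raise ValueError(f"unknown window_id {self.window_id!r}")
        if self.t_seconds <= 0:
            raise ValueError("t_seconds must be positive")


@dataclass(frozen=True)
class ExposureEvent:
    """One (person, case/control date, window) unit of exposure assessment."""

    person_id: str
    event_kind: str  # "case" | "control"
    event_date: date
    window: ExposureWindow
    death_class: str  # "daytime" | "nighttime"
    geocode: Optional[ReceiverPoint] = None

    def __post_init__(self) -> None:
        if self.event_kind not in ("case", "control"):
            raise ValueError(f"event_kind must be case/control, got {self.event_kind!r}")
        if self.death_class not in ("daytime", "nighttime"):
            raise ValueError(f"death_class must be daytime/nighttime, got {self.death_class!r}")


def classify_death(death_dt: datetime) -> str:
    """'daytime' iff the clock time is in [07:00, 23:00), else 'nighttime'."""
    return "daytime" if DAY_START <= death_dt.time() < NIGHT_START else "nighttime"


def windows_for(death: DeathRecord, event_date: date) -> list[ExposureWindow]:
    """Exposure windows for one (death, event date) pair.

    Daytime deaths get the five fixed windows of the night preceding
    ``event_date`` (evening through 07:00 of the event day); nighttime deaths
    get the single 2-hour window ending at the death clock time anchored to
    ``event_date``.
    """
    if classify_death(death.death_dt) == "daytime":
        prev = event_date - timedelta(days=1)
        out = []
        for wid, t_start, t_end, start_prev, end_prev, t_sec in _DAYTIME_WINDOWS:
            start = datetime.combine(prev if start_prev else event_date, t_start)
            end = datetime.combine(prev if end_prev else event_date, t_end)
            out.append(ExposureWindow(wid, start, end, t_sec))
        return out
    # nighttime: 2 h preceding the death clock time; deaths in [23:00, 24:00)
    # anchor to the evening of the event date, deaths in [00:00, 07:00) to its
    # early morning (the window then reaches back across midnight)
    end = datetime.combine(event_date, death.death_dt.time())
    start = end - timedelta(hours=2)
    return [ExposureWindow("last2h", start, end, 7200)]


def sample_controls(case_date: date) -> list[date]:
    """Time-stratified control dates: same weekday, same calendar month, case excluded.

    Always yields 3 or 4 dates, sorted ascending, lying both before and after
    the case date whenever the month permits.
    """
    first = case_date.replace(day=1)
    offset = (case_date.weekday() - first.weekday()) % 7
    d = first + timedelta(days=offset)
    controls = []
    while d.month == case_date.month:
        if d != case_date:
            controls.append(d)
        d += timedelta(days=7)
    return controls


def read_deaths(path) -> list[DeathRecord]:
    """Read a deaths CSV: ``person_id,x,y,death_dt,icd10`` (ISO-8601 datetimes)."""
    import csv

    from noisecross.errors import ParseError

    out: list[DeathRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rownum, row in enumerate(reader, start=2):
            try:
                out.append(
                    DeathRecord(
                        person_id=row["person_id"],
                        geocode=ReceiverPoint(float(row["x"]), float(row["y"])),
                        death_dt=datetime.fromisoformat(row["death_dt"]),
                        icd10=row["icd10"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: row {rownum}: {exc}") from None
    return out


def write_deaths(deaths, path) -> None:
    """Inverse of :func:`read_deaths`."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["person_id", "x", "y", "death_dt", "icd10"])
        for d in deaths:
            w.writerow(
                [d.person_id, f"{d.geocode.x:g}", f"{d.geocode.y:g}",
                 d.death_dt.isoformat(), d.icd10]
            )


def write_events(events, path) -> None:
    """Write events CSV: ``person_id,event_kind,event_date,window_id,start_dt,end_dt,death_class``."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["person_id", "event_kind", "event_date", "window_id",
             "start_dt", "end_dt", "death_class"]
        )
        for e in events:
            w.writerow(
                [e.person_id, e.event_kind, e.event_date.isoformat(), e.window.window_id,
                 e.window.start_dt.isoformat(), e.window.end_dt.isoformat(), e.death_class]
            )


def read_events(path, geocodes: dict[str, ReceiverPoint] | None = None) -> list[ExposureEvent]:
    """Read an events CSV back; ``geocodes`` (person_id -> point) re-attaches residences."""
    import csv

    from noisecross.errors import ParseError

    out: list[ExposureEvent] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rownum, row in enumerate(reader, start=2):
            try:
                start = datetime.fromisoformat(row["start_dt"])
                end = datetime.fromisoformat(row["end_dt"])
                window = ExposureWindow(
                    window_id=row["window_id"],
                    start_dt=start,
                    end_dt=end,
                    t_seconds=int((end - start).total_seconds()),
                )
                out.append(
                    ExposureEvent(
                        person_id=row["person_id"],
                        event_kind=row["event_kind"],
                        event_date=date.fromisoformat(row["event_date"]),
                        window=window,
                        death_class=row["death_class"],
                        geocode=(geocodes or {}).get(row["person_id"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: row {rownum}: {exc}") from None
    return out


def build_events(death: DeathRecord) -> list[ExposureEvent]:
    """All case and control exposure events for one death.

    One event per (date, window): a daytime death with k controls yields
    5*(1+k) events, a nighttime death 1+k.
    """
    case_date = death.death_dt.date()
    death_class = classify_death(death.death_dt)
    events: list[ExposureEvent] = []
    for kind, d in [("case", case_date)] + [("control", c) for c in sample_controls(case_date)]:
        for w in windows_for(death, d):
            events.append(
                ExposureEvent(
                    person_id=death.person_id,
                    event_kind=kind,
                    event_date=d,
                    window=w,
                    death_class=death_class,
                    geocode=death.geocode,
                )
            )
    return events
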