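"""Airport movement lists: reading, cleaning, filtering, and audibility intervals.

A movement is one departure or arrival, timestamped at brake release or touch
down.  Because a flight is audible away from the runway before touch down
(arrivals) or after brake release (departures), each movement is mapped to a
10-minute *audible interval*: [t-10 min, t] for arrivals and [t, t+10 min]
for departures.  A flight belongs to an exposure window when its audible
interval overlaps the window with positive measure (half-open semantics —
touching at a single endpoint does not count); this is the reading under
which the 19:00–07:00 night envelope expands to the 18:50–07:10 selection
band.

Cleaning steps: aircraft types missing from the movement list are recovered
from a tail-number registry keyed by validity date ranges; flights are then
restricted to large aircraft (maximum take-off weight strictly above
8618 kg) with a known air route.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

from noisecross.errors import ParseError

logger = logging.getLogger(__name__)

#: MTOW cutoff in kg; retained flights satisfy mtow > this, strictly
MIN_MTOW_KG = 8618.0

#: audibility buffer applied before landings / after departures
BUFFER = timedelta(minutes=10)

_PROCEDURE_CODES = {"D": "departure", "A": "arrival"}


@dataclass(frozen=True)
class Movement:
    """One flight movement. ``aircraft_type`` and ``route`` may be None (missing)."""

    flight_id: str
    timestamp: datetime
    aircraft_type: str | None
    tail_number: str | None
    route: str | None
    runway: str
    procedure: str  # "departure" | "arrival"
    mtow_kg: float
    aircraft_group: str | None = None

    def __post_init__(self) -> None:
        if self.procedure not in ("departure", "arrival"):
            raise ValueError(f"procedure must be departure/arrival, got {self.procedure!r}")
        if not self.mtow_kg > 0:
            raise ValueError(f"mtow_kg must be positive, got {self.mtow_kg}")

    @property
    def group(self) -> str | None:
        """Aircraft group used for footprint lookup (falls back to the raw type)."""
        return self.aircraft_group if self.aircraft_group is not None else self.aircraft_type


@dataclass(frozen=True)
class AudibleInterval:
    """Half-open time interval [start, end) during which a flight is audible."""

    start: datetime
    end: datetime

    def overlaps(self, window_start: datetime, window_end: datetime) -> bool:
        """True iff the intersection with [window_start, window_end) has positive measure."""
        return max(self.start, window_start) < min(self.end, window_end)


def audible_interval(m: Movement) -> AudibleInterval:
    """[t-10 min, t] for arrivals, [t, t+10 min] for departures."""
    if m.procedure == "arrival":
        return AudibleInterval(start=m.timestamp - BUFFER, end=m.timestamp)
    return AudibleInterval(start=m.timestamp, end=m.timestamp + BUFFER)


def read_movements(path: str | Path) -> list[Movement]:
    """Read a movements CSV.

    Columns: ``flight_id,timestamp,aircraft_type,tail_number,route,runway,
    procedure,mtow_kg``; timestamps ISO-8601 local, procedure ``D``/``A``,
    empty string meaning missing.  Rows with missing aircraft type or route
    are retained (with None), not dropped.
    """
    path = Path(path)
    out: list[Movement] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {
            "flight_id", "timestamp", "aircraft_type", "tail_number",
            "route", "runway", "procedure", "mtow_kg",
        }
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: header must contain columns {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                ts = datetime.fromisoformat(row["timestamp"])
            except ValueError:
                raise ParseError(
                    f"{path}: row {rownum}: malformed timestamp {row['timestamp']!r}"
                ) from None
            proc = _PROCEDURE_CODES.get(row["procedure"])
            if proc is None:
                raise ParseError(
                    f"{path}: row {rownum}: unknown procedure code {row['procedure']!r}"
                )
            try:
                mtow = float(row["mtow_kg"])
            except ValueError:
                raise ParseError(
                    f"{path}: row {rownum}: non-numeric mtow_kg {row['mtow_kg']!r}"
                ) from None
            out.append(
                Movement(
                    flight_id=row["flight_id"],
                    timestamp=ts,
                    aircraft_type=row["aircraft_type"] or None,
                    tail_number=row["tail_number"] or None,
                    route=row["route"] or None,
                    runway=row["runway"],
                    procedure=proc,
                    mtow_kg=mtow,
                )
            )
    return out


def write_movements(movements: Sequence[Movement], path: str | Path) -> None:
    """Inverse of :func:`read_movements`."""
    code = {"departure": "D", "arrival": "A"}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["flight_id", "timestamp", "aircraft_type", "tail_number",
             "route", "runway", "procedure", "mtow_kg"]
        )
        for m in movements:
            w.writerow(
                [m.flight_id, m.timestamp.isoformat(), m.aircraft_type or "",
                 m.tail_number or "", m.route or "", m.runway,
                 code[m.procedure], f"{m.mtow_kg:g}"]
            )


# ---------------------------------------------------------------------------
# tail-number registry and type recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryEntry:
    tail_number: str
    valid_from: date
    valid_to: date
    aircraft_type: str


def read_tail_registry(path: str | Path) -> list[RegistryEntry]:
    """Read a tail registry CSV: ``tail_number,valid_from,valid_to,aircraft_type``."""
    path = Path(path)
    entries: list[RegistryEntry] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rownum, row in enumerate(reader, start=2):
            try:
                entries.append(
                    RegistryEntry(
                        tail_number=row["tail_number"],
                        valid_from=date.fromisoformat(row["valid_from"]),
                        valid_to=date.fromisoformat(row["valid_to"]),
                        aircraft_type=row["aircraft_type"],
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: row {rownum}: {exc}") from None
    return entries


def recover_types(
    movements: Sequence[Movement], registry: Iterable[RegistryEntry]
) -> list[Movement]:
    """Fill missing aircraft types from the tail registry by (tail number, date).

    Never overwrites a type that is already present; rows that do not match
    any registry entry stay missing.  The number of recoveries is logged.
    """
    by_tail: dict[str, list[RegistryEntry]] = {}
    for e in registry:
        by_tail.setdefault(e.tail_number, []).append(e)

    out: list[Movement] = []
    recovered = 0
    for m in movements:
        if m.aircraft_type is None and m.tail_number is not None:
            d = m.timestamp.date()
            for e in by_tail.get(m.tail_number, ()):
                if e.valid_from <= d <= e.valid_to:
                    m = replace(m, aircraft_type=e.aircraft_type)
                    recovered += 1
                    break
        out.append(m)
    logger.info("recover_types: filled %d missing aircraft types", recovered)
    return out


def filter_flights(
    movements: Sequence[Movement],
    min_mtow_kg: float = MIN_MTOW_KG,
    drop_missing_route: bool = True,
    drop_missing_type: bool = False,
) -> tuple[list[Movement], dict[str, int]]:
    """Keep large aircraft (mtow strictly > cutoff) with a known route.

    ``drop_missing_type=True`` additionally removes flights whose aircraft
    type is still unknown after registry recovery (such flights cannot be
    mapped to any footprint).  Returns the retained movements and a
    per-reason exclusion count (a flight failing several tests is counted
    under each reason).
    """
    kept: list[Movement] = []
    excluded = {"light_aircraft": 0, "missing_route": 0, "missing_type": 0}
    for m in movements:
        light = not (m.mtow_kg > min_mtow_kg)
        routeless = drop_missing_route and m.route is None
        typeless = drop_missing_type and m.aircraft_type is None
        if light:
            excluded["light_aircraft"] += 1
        if routeless:
            excluded["missing_route"] += 1
        if typeless:
            excluded["missing_type"] += 1
        if not light and not routeless and not typeless:
            kept.append(m)
    logger.info(
        "filter_flights: retained %d of %d (light=%d, missing_route=%d, missing_type=%d)",
        len(kept), len(movements), excluded["light_aircraft"],
        excluded["missing_route"], excluded["missing_type"],
    )
    return kept, excluded


def assign_groups(
    movements: Sequence[Movement], group_map: dict[str, str] | None = None
) -> list[Movement]:
    """Map aircraft types to footprint groups (identity when no map is given)."""
    out = []
    for m in movements:
        if m.aircraft_type is None:
            out.append(m)
            continue
        group = (group_map or {}).get(m.aircraft_type, m.aircraft_type)
        out.append(replace(m, aircraft_group=group))
    return out
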