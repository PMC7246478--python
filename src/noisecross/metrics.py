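"""Decibel arithmetic and the three per-event exposure metrics.

For every exposure window the flights whose audible interval overlaps the
window are collected; each contributes one sound exposure level L_AE and one
maximum level L_Amax interpolated from its footprint at the residential
geocode.  The three metrics are then

* ``L_Aeq = max(0, L_AE,total - 10 log10(T / t0))`` with t0 = 1 s, where
  L_AE,total is the energetic sum ``10 log10(sum 10^(L_AE,i/10))`` over the
  n flights in the window and T the nominal window duration in seconds;
  windows with no flight, or with a negative L_Aeq, are set to 0 dB;
* the maximum L_Amax over the flights in the window (0 if none);
* NAT_55, the count of flights whose L_Amax strictly exceeds 55 dB.

All accumulation happens in the linear energy domain in double precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from noisecross.events import ExposureEvent
from noisecross.errors import MissingFootprintError
from noisecross.footprints import FootprintKey, FootprintStore, ReceiverPoint, idw_interpolate
from noisecross.movements import Movement, audible_interval

logger = logging.getLogger(__name__)

#: sentinel for "no acoustic energy" (the energetic sum of zero events);
#: maps to 0 dB under the L_Aeq zero rule
NO_ENERGY = -math.inf

NAT_THRESHOLD_DB = 55.0


@dataclass(frozen=True)
class FlightNoise:
    """Per-flight interpolated levels at one geocode."""

    flight_id: str
    lae: float
    lamax: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lae) and math.isfinite(self.lamax)):
            raise ValueError("flight noise levels must be finite")


@dataclass(frozen=True)
class ExposureRecord:
    """The three metrics for one exposure event, plus the flight count."""

    event: ExposureEvent
    laeq: float
    lamax_max: float
    nat55: int
    n_flights: int


def energetic_sum(levels: Iterable[float]) -> float:
    """Energetic (dB) sum: ``10 log10(sum_i 10^(L_i/10))``.

    An empty input returns :data:`NO_ENERGY` (-inf), which the L_Aeq zero
    rule maps to 0 dB.
    """
    energy = math.fsum(10.0 ** (L / 10.0) for L in levels)
    if energy == 0.0:
        return NO_ENERGY
    return 10.0 * math.log10(energy)


def laeq_from_lae(lae_total: float, t_seconds: float) -> float:
    """Equivalent continuous level over T seconds: ``max(0, L_AE - 10 log10(T))``.

    The reference time t0 is 1 s, so T enters as a pure number.  Negative
    results and the no-energy sentinel are floored to 0 dB.
    """
    if t_seconds <= 0:
        raise ValueError(f"t_seconds must be positive, got {t_seconds}")
    if lae_total == NO_ENERGY:
        return 0.0
    return max(0.0, lae_total - 10.0 * math.log10(t_seconds))


def lamax_of_event(flights: Sequence[FlightNoise]) -> float:
    """Highest L_Amax among the flights in a window; 0 dB when there is none."""
    if not flights:
        return 0.0
    return max(f.lamax for f in flights)


def nat(flights: Sequence[FlightNoise], threshold: float = NAT_THRESHOLD_DB,
        strict: bool = True) -> int:
    """Number Above Threshold: flights whose L_Amax exceeds ``threshold``.

    The comparison is strict (> threshold) by default; ``strict=False``
    switches to >=.
    """
    if strict:
        return sum(1 for f in flights if f.lamax > threshold)
    return sum(1 for f in flights if f.lamax >= threshold)


class MovementIndex:
    """Movements bucketed by calendar date for fast window queries.

    Window queries only touch the buckets of the dates the (buffered) window
    can reach, so per-event selection cost is independent of the study span.
    """

    def __init__(self, movements: Iterable[Movement]):
        from datetime import timedelta

        self._by_date: dict = {}
        self._margin = timedelta(minutes=10)
        for m in movements:
            self._by_date.setdefault(m.timestamp.date(), []).append(m)

    def candidates(self, start, end) -> list[Movement]:
        from datetime import timedelta

        d = (start - self._margin).date()
        last = (end + self._margin).date()
        out: list[Movement] = []
        while d <= last:
            out.extend(self._by_date.get(d, ()))
            d += timedelta(days=1)
        return out


def flights_in_window(
    movements, event: ExposureEvent, membership: str = "overlap"
) -> list[Movement]:
    """Movements belonging to the event window.

    ``movements`` may be a plain iterable or a :class:`MovementIndex`.
    ``membership='overlap'`` (default): the flight's 10-minute audible
    interval intersects the half-open window with positive measure.
    ``membership='point'``: the raw timestamp lies inside the window.
    """
    w = event.window
    if isinstance(movements, MovementIndex):
        movements = movements.candidates(w.start_dt, w.end_dt)
    if membership == "overlap":
        return [m for m in movements if audible_interval(m).overlaps(w.start_dt, w.end_dt)]
    if membership == "point":
        return [m for m in movements if w.start_dt <= m.timestamp < w.end_dt]
    raise ValueError(f"membership must be 'overlap' or 'point', got {membership!r}")


def flight_noise_at(
    m: Movement, point: ReceiverPoint, store: FootprintStore
) -> FlightNoise:
    """Resolve the flight's footprint (with fallback) and interpolate both levels."""
    if m.group is None or m.route is None:
        raise MissingFootprintError(
            f"flight {m.flight_id} has no aircraft group or route", flight_id=m.flight_id
        )
    key = FootprintKey(
        year=m.timestamp.year,
        aircraft_group=m.group,
        route=m.route,
        procedure=m.procedure,
    )
    try:
        grid = store.lookup(key)
    except MissingFootprintError as exc:
        raise MissingFootprintError(str(exc), key=key, flight_id=m.flight_id) from None
    return FlightNoise(
        flight_id=m.flight_id,
        lae=idw_interpolate(grid, point, "lae"),
        lamax=idw_interpolate(grid, point, "lamax"),
    )


def compute_exposure(
    event: ExposureEvent,
    movements: Iterable[Movement],
    store: FootprintStore,
    *,
    geocode: ReceiverPoint | None = None,
    membership: str = "overlap",
    nat_threshold: float = NAT_THRESHOLD_DB,
    nat_strict: bool = True,
) -> ExposureRecord:
    """All three metrics for one exposure event.

    ``geocode`` defaults to the event's own residence point.  Raises
    :class:`MissingFootprintError` (carrying the flight id) if any in-window
    flight has no footprint even after fallback.
    """
    point = geocode if geocode is not None else event.geocode
    if point is None:
        raise ValueError(f"no geocode for event of person {event.person_id}")
    selected = flights_in_window(movements, event, membership=membership)
    noises = [flight_noise_at(m, point, store) for m in selected]
    lae_total = energetic_sum(f.lae for f in noises)
    return ExposureRecord(
        event=event,
        laeq=laeq_from_lae(lae_total, event.window.t_seconds),
        lamax_max=lamax_of_event(noises),
        nat55=nat(noises, threshold=nat_threshold, strict=nat_strict),
        n_flights=len(noises),
    )


def write_exposures(records: Sequence[ExposureRecord], path) -> None:
    """Final output CSV, one row per event; levels rounded to 3 decimals."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["person_id", "event_kind", "event_date", "window_id",
             "laeq_db", "lamax_db", "nat55", "n_flights"]
        )
        for r in records:
            e = r.event
            w.writerow(
                [e.person_id, e.event_kind, e.event_date.isoformat(), e.window.window_id,
                 f"{r.laeq:.3f}", f"{r.lamax_max:.3f}", r.nat55, r.n_flights]
            )
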