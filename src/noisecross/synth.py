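"""Seeded synthetic study data: footprints, movement lists, tail registry, deaths.

The generators emulate the *structure* the exposure-assessment method
assumes, so the whole pipeline runs with no restricted data:

* footprints follow a toy line-source decay model — the level at a receiver
  falls off with the distance d to the route axis as
  ``L_AE = max(0, source_level - k * log10(1 + d/d0))`` with ``L_Amax`` a
  fixed offset below — which reproduces the monotone distance decay of real
  footprints, not their acoustics;
* nightly movement counts are Poisson, with a per-night "wind regime" that
  reshuffles traffic between route families so the same geocode sees
  different exposure across nights; a night-time flight ban is enforced,
  with occasional delayed flights spilling into the 23:00–23:30 slot;
* configurable fractions of movements have a missing aircraft type
  (recoverable through the generated tail registry) or a missing route;
* deaths are scattered uniformly over the study region with a configurable
  daytime/nighttime split and ICD-10 codes from the cardiovascular range.

Each generator draws from its own stream derived from the master seed, so
the three artifact sets can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np

from noisecross.events import DeathRecord
from noisecross.footprints import FootprintGrid, FootprintKey, FootprintStore, ReceiverPoint
from noisecross.movements import Movement, RegistryEntry


@dataclass(frozen=True)
class RouteSpec:
    """One air route: a straight axis segment and its procedure."""

    name: str
    start: tuple[float, float]
    end: tuple[float, float]
    procedure: str  # "departure" | "arrival"


@dataclass(frozen=True)
class GroupSpec:
    """One aircraft group: certification mass, source level, traffic share."""

    name: str
    mtow_kg: float
    source_level_db: float
    share: float


def _default_routes() -> tuple[RouteSpec, ...]:
    # rays fanning out of a runway complex at the region center, in a
    # Swiss-style projected CRS; 4 departure and 2 approach axes
    cx, cy = 670000.0, 250000.0
    return (
        RouteSpec("DEP_N", (cx, cy), (cx + 1500, cy + 9500), "departure"),
        RouteSpec("DEP_W", (cx, cy), (cx - 9500, cy + 1500), "departure"),
        RouteSpec("DEP_S", (cx, cy), (cx - 1500, cy - 9500), "departure"),
        RouteSpec("DEP_E", (cx, cy), (cx + 9500, cy - 1500), "departure"),
        RouteSpec("APP_N", (cx + 500, cy + 9500), (cx, cy), "arrival"),
        RouteSpec("APP_S", (cx - 500, cy - 9500), (cx, cy), "arrival"),
    )


def _default_groups() -> tuple[GroupSpec, ...]:
    # the LIGHT group sits below the 8618 kg cutoff and exists to exercise
    # the large-aircraft filter
    return (
        GroupSpec("HEAVY", 297500.0, 99.0, 0.25),
        GroupSpec("MEDIUM", 77000.0, 93.0, 0.60),
        GroupSpec("LIGHT", 5700.0, 78.0, 0.15),
    )


@dataclass
class SynthConfig:
    """Knobs of the synthetic study; defaults emulate a large-hub night regime."""

    seed: int = 0
    study_span: tuple[int, int] = (2000, 2015)
    #: (xmin, ymin, xmax, ymax), projected meters; 20 x 20 km around the airport
    region: tuple[float, float, float, float] = (660000.0, 240000.0, 680000.0, 260000.0)
    cell_size: float = 250.0
    routes: tuple[RouteSpec, ...] = field(default_factory=_default_routes)
    aircraft_groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)
    #: mean night flights (19:00-07:00 band) per night
    nightly_flight_rate: float = 60.0
    #: mean daytime flights per day (outside the night windows; kept for realism)
    daily_flight_rate: float = 40.0
    ban_start: time = time(23, 30)
    ban_end: time = time(6, 0)
    #: per-flight probability of spilling into the 23:00-23:30 delayed slot
    delayed_flight_prob: float = 0.05
    #: decay slope (dB per decade of distance) and reference distance of the toy model
    decay_k: float = 22.0
    decay_d0_m: float = 200.0
    lamax_offset_db: float = 8.0
    frac_missing_type: float = 0.05
    frac_missing_route: float = 0.01
    #: fraction of non-first-year footprints withheld, to exercise year fallback
    frac_missing_footprint: float = 0.05
    #: fraction of tails covered by the registry (missing types on other tails
    #: stay unrecoverable)
    registry_coverage: float = 0.75
    n_deaths: int = 200
    daytime_death_frac: float = 0.7

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.region
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("region must have positive area")
        if not 0 <= self.delayed_flight_prob <= 1:
            raise ValueError("delayed_flight_prob must be in [0, 1]")
        if self.nightly_flight_rate < 0 or self.daily_flight_rate < 0:
            raise ValueError("flight rates must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


_STREAM_FOOTPRINTS, _STREAM_MOVEMENTS, _STREAM_DEATHS = 1, 2, 3


def _segment_distance(px: np.ndarray, py: np.ndarray, a: tuple[float, float],
                      b: tuple[float, float]) -> np.ndarray:
    """Euclidean distance from points to the segment a-b."""
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    seg2 = vx * vx + vy * vy
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / seg2, 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def make_footprints(cfg: SynthConfig) -> FootprintStore:
    """One footprint per (year, group, route); deterministic per seed.

    A fraction of the combinations in non-initial years is withheld so the
    store's nearest-year fallback path is exercised on realistic inputs.
    The first study year is always complete, so every key resolves.
    """
    rng = cfg.rng(_STREAM_FOOTPRINTS)
    xmin, ymin, xmax, ymax = cfg.region
    xs = np.arange(xmin, xmax + cfg.cell_size / 2, cfg.cell_size)
    ys = np.arange(ymax, ymin - cfg.cell_size / 2, -cfg.cell_size)  # row 0 north
    px, py = np.meshgrid(xs, ys)
    y0, y1 = cfg.study_span

    store = FootprintStore()
    for group in cfg.aircraft_groups:
        for route in cfg.routes:
            d = _segment_distance(px, py, route.start, route.end)
            for year in range(y0, y1 + 1):
                withhold = year > y0 and rng.random() < cfg.frac_missing_footprint
                # small per-year fleet drift so substituted years differ measurably
                drift = float(rng.normal(0.0, 0.5))
                if withhold:
                    continue
                level = group.source_level_db + drift
                lae = np.maximum(0.0, level - cfg.decay_k * np.log10(1.0 + d / cfg.decay_d0_m))
                lamax = np.maximum(0.0, lae - cfg.lamax_offset_db)
                store.add(
                    FootprintGrid(
                        key=FootprintKey(year, group.name, route.name, route.procedure),
                        origin=(float(xs[0]), float(ys[0])),
                        cell_size=cfg.cell_size,
                        lae=lae,
                        lamax=lamax,
                    )
                )
    return store


def _draw_clock(rng: np.random.Generator, start: time, end: time) -> timedelta:
    """Uniform clock offset from midnight within [start, end) of the same day."""
    s = start.hour * 3600 + start.minute * 60
    e = end.hour * 3600 + end.minute * 60
    return timedelta(seconds=float(rng.uniform(s, e)))


def make_movements(cfg: SynthConfig) -> tuple[list[Movement], list[RegistryEntry]]:
    """Movement list plus matching tail registry over the study span.

    Night traffic is Poisson per night, placed in the evening (19:00-23:00)
    and early morning (06:00-07:00) slots; no flight falls inside the ban
    except, with ``delayed_flight_prob``, in the delayed 23:00-23:30 slot.
    Route choice follows a per-night two-state wind regime, giving
    day-to-day exposure variability at any fixed geocode.
    """
    rng = cfg.rng(_STREAM_MOVEMENTS)
    y0, y1 = cfg.study_span
    groups = cfg.aircraft_groups
    shares = np.array([g.share for g in groups], dtype=float)
    shares /= shares.sum()

    # two wind regimes: each concentrates traffic on a different half of the routes
    n_routes = len(cfg.routes)
    half = max(1, n_routes // 2)
    regime = np.empty((2, n_routes))
    regime[0, :half], regime[0, half:] = 0.8 / half, 0.2 / max(1, n_routes - half)
    regime[1, :half], regime[1, half:] = 0.2 / half, 0.8 / max(1, n_routes - half)
    regime = regime / regime.sum(axis=1, keepdims=True)

    tails = {g.name: [f"HB-{g.name[0]}{i:02d}" for i in range(20)] for g in groups}

    movements: list[Movement] = []
    fid = 0
    d = date(y0, 1, 1)
    end_date = date(y1, 12, 31)
    one_day = timedelta(days=1)
    while d <= end_date:
        probs = regime[int(rng.random() < 0.5)]
        n_night = rng.poisson(cfg.nightly_flight_rate)
        n_day = rng.poisson(cfg.daily_flight_rate)
        for is_night in ([True] * n_night + [False] * n_day):
            if is_night:
                u = rng.random()
                if u < cfg.delayed_flight_prob:
                    dt = datetime.combine(d, time(0)) + _draw_clock(rng, time(23, 0), time(23, 30))
                elif u < cfg.delayed_flight_prob + 0.2:
                    # early morning belongs to the following calendar day's clock
                    dt = datetime.combine(d + one_day, time(0)) + _draw_clock(
                        rng, cfg.ban_end, time(7, 0)
                    )
                else:
                    dt = datetime.combine(d, time(0)) + _draw_clock(rng, time(19, 0), time(23, 0))
            else:
                dt = datetime.combine(d, time(0)) + _draw_clock(rng, time(7, 0), time(19, 0))
            gi = rng.choice(len(groups), p=shares)
            g = groups[gi]
            route = cfg.routes[rng.choice(n_routes, p=probs)]
            fid += 1
            movements.append(
                Movement(
                    flight_id=f"F{fid:07d}",
                    timestamp=dt.replace(microsecond=0),
                    aircraft_type=None if rng.random() < cfg.frac_missing_type else g.name,
                    tail_number=tails[g.name][rng.integers(len(tails[g.name]))],
                    route=None if rng.random() < cfg.frac_missing_route else route.name,
                    runway=f"RW{1 + rng.integers(3)}",
                    procedure=route.procedure,
                    mtow_kg=g.mtow_kg,
                )
            )
        d += one_day

    registry = [
        RegistryEntry(
            tail_number=t,
            valid_from=date(y0, 1, 1),
            valid_to=date(y1, 12, 31),
            aircraft_type=g.name,
        )
        for g in groups
        for t in tails[g.name]
        if rng.random() < cfg.registry_coverage
    ]
    movements.sort(key=lambda m: (m.timestamp, m.flight_id))
    return movements, registry


def make_deaths(cfg: SynthConfig) -> list[DeathRecord]:
    """Deaths uniform over the region and span with a fixed day/night mix."""
    if cfg.n_deaths < 1:
        raise ValueError("n_deaths must be >= 1")
    rng = cfg.rng(_STREAM_DEATHS)
    xmin, ymin, xmax, ymax = cfg.region
    y0, y1 = cfg.study_span
    start = date(y0, 1, 1)
    n_days = (date(y1, 12, 31) - start).days + 1

    deaths: list[DeathRecord] = []
    for i in range(cfg.n_deaths):
        d = start + timedelta(days=int(rng.integers(n_days)))
        if rng.random() < cfg.daytime_death_frac:
            clock = timedelta(seconds=float(rng.uniform(7 * 3600, 23 * 3600)))
        else:
            s = float(rng.uniform(23 * 3600, 31 * 3600))  # 23:00 through 07:00 next day
            clock = timedelta(seconds=s % 86400)
        dt = (datetime.combine(d, time(0)) + clock).replace(microsecond=0)
        deaths.append(
            DeathRecord(
                person_id=f"P{i + 1:05d}",
                geocode=ReceiverPoint(
                    float(rng.uniform(xmin, xmax)), float(rng.uniform(ymin, ymax))
                ),
                death_dt=dt,
                icd10=f"I{rng.integers(100):02d}",
            )
        )
    return deaths
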