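"""Noise footprint grids: storage, file I/O, lookup with fallback, and IDW interpolation.

A *footprint* is a regular receiver grid (default 250 m spacing) of per-event
noise levels — the sound exposure level L_AE and the maximum level L_Amax —
for one combination of calendar year, aircraft group, air route, procedure
(departure or arrival) and, optionally, time of day.  The level of a single
flight at a residential geocode is obtained from the four nearest receivers
by inverse-distance weighting with exponent 1:

    L = (sum_i L_i / d_i) / (sum_i 1 / d_i),   i = 1..4,

with the degenerate case d_min = 0 returning the receiver's stored value.
Interpolation operates on dB values directly (an arithmetic weighted mean of
levels, not of energies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from noisecross.errors import (
    InvalidGridError,
    MissingFootprintError,
    OutOfExtentError,
    ParseError,
)

logger = logging.getLogger(__name__)

PROCEDURES = ("departure", "arrival")
TIMES_OF_DAY = ("day", "night")

#: distances below this (meters) are treated as "point on receiver"
ZERO_DISTANCE_TOL = 1e-6


@dataclass(frozen=True, order=True)
class FootprintKey:
    """Identifies one footprint: (year, aircraft group, route, procedure[, time of day])."""

    year: int
    aircraft_group: str
    route: str
    procedure: str
    time_of_day: str | None = None

    def __post_init__(self) -> None:
        if self.procedure not in PROCEDURES:
            raise ValueError(f"procedure must be one of {PROCEDURES}, got {self.procedure!r}")
        if self.time_of_day is not None and self.time_of_day not in TIMES_OF_DAY:
            raise ValueError(
                f"time_of_day must be one of {TIMES_OF_DAY} or None, got {self.time_of_day!r}"
            )


@dataclass(frozen=True)
class ReceiverPoint:
    """A location in the projected metric CRS of the grids."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("receiver coordinates must be finite")


@dataclass
class FootprintGrid:
    """One footprint on a regular lattice.

    ``origin`` is the *north-west* receiver; row 0 is the northernmost row,
    so the y coordinate decreases with the row index while x increases with
    the column index.  ``lae`` and ``lamax`` are (ny, nx) arrays in dB.
    """

    key: FootprintKey
    origin: tuple[float, float]
    cell_size: float
    lae: np.ndarray
    lamax: np.ndarray

    def __post_init__(self) -> None:
        self.lae = np.asarray(self.lae, dtype=float)
        self.lamax = np.asarray(self.lamax, dtype=float)
        if self.cell_size <= 0:
            raise InvalidGridError(f"cell_size must be > 0, got {self.cell_size}")
        if self.lae.ndim != 2 or self.lae.shape != self.lamax.shape:
            raise InvalidGridError(
                f"lae and lamax must be 2-D with identical shape, "
                f"got {self.lae.shape} vs {self.lamax.shape}"
            )
        if not (np.isfinite(self.lae).all() and np.isfinite(self.lamax).all()):
            raise InvalidGridError("grid levels must all be finite")

    @property
    def ny(self) -> int:
        return self.lae.shape[0]

    @property
    def nx(self) -> int:
        return self.lae.shape[1]

    def receiver_xy(self, row: int, col: int) -> tuple[float, float]:
        """Projected coordinates of the receiver at (row, col)."""
        x0, y0 = self.origin
        return (x0 + col * self.cell_size, y0 - row * self.cell_size)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the receiver lattice."""
        x0, y0 = self.origin
        return (x0, x0 + (self.nx - 1) * self.cell_size, y0 - (self.ny - 1) * self.cell_size, y0)

    def contains(self, point: ReceiverPoint) -> bool:
        xmin, xmax, ymin, ymax = self.extent
        return xmin <= point.x <= xmax and ymin <= point.y <= ymax


def nearest_four(grid: FootprintGrid, point: ReceiverPoint) -> list[tuple[tuple[int, int], float]]:
    """The 4 receivers nearest to ``point``, as ((row, col), distance), ascending.

    Ties are broken by row-major receiver index, so the result is
    deterministic for points equidistant from several receivers (e.g. cell
    centers).
    """
    if grid.ny * grid.nx < 4:
        raise InvalidGridError(f"grid has {grid.ny * grid.nx} receivers; need at least 4")
    x0, y0 = grid.origin
    # fractional lattice index of the point; the 4 nearest receivers of a
    # regular lattice always fall in a small index window around it
    fc = (point.x - x0) / grid.cell_size
    fr = (y0 - point.y) / grid.cell_size
    c_lo = max(0, int(np.floor(fc)) - 2)
    c_hi = min(grid.nx, int(np.ceil(fc)) + 3)
    r_lo = max(0, int(np.floor(fr)) - 2)
    r_hi = min(grid.ny, int(np.ceil(fr)) + 3)
    # widen if clamping left fewer than 4 candidates (narrow grids)
    while (r_hi - r_lo) * (c_hi - c_lo) < 4:
        c_lo, c_hi = max(0, c_lo - 1), min(grid.nx, c_hi + 1)
        r_lo, r_hi = max(0, r_lo - 1), min(grid.ny, r_hi + 1)

    candidates: list[tuple[float, int, int, int]] = []
    for r in range(r_lo, r_hi):
        dy = y0 - r * grid.cell_size - point.y
        for c in range(c_lo, c_hi):
            dx = x0 + c * grid.cell_size - point.x
            d = float(np.hypot(dx, dy))
            candidates.append((d, r * grid.nx + c, r, c))
    candidates.sort(key=lambda t: (t[0], t[1]))
    return [((r, c), d) for d, _, r, c in candidates[:4]]


def weighted_level(values: Sequence[float], distances: Sequence[float]) -> float:
    """Inverse-distance weighted mean of dB levels with exponent 1.

    ``L = (sum_i L_i / d_i) / (sum_i 1 / d_i)``; if the smallest distance is
    (numerically) zero the corresponding level is returned exactly.
    """
    i_min = min(range(len(distances)), key=distances.__getitem__)
    if distances[i_min] < ZERO_DISTANCE_TOL:
        return float(values[i_min])
    num = sum(v / d for v, d in zip(values, distances))
    den = sum(1.0 / d for d in distances)
    return num / den


def idw_interpolate(
    grid: FootprintGrid, point: ReceiverPoint, metric: Literal["lae", "lamax"]
) -> float:
    """Inverse-distance-weighted level (dB) at ``point`` from the 4 nearest receivers.

    Raises :class:`OutOfExtentError` if the point falls outside the bounding
    rectangle of the receiver lattice; no extrapolation is attempted.
    """
    if metric not in ("lae", "lamax"):
        raise ValueError(f"metric must be 'lae' or 'lamax', got {metric!r}")
    if not grid.contains(point):
        raise OutOfExtentError(
            f"point ({point.x}, {point.y}) outside grid extent {grid.extent} for key {grid.key}"
        )
    values = getattr(grid, metric)
    neighbors = nearest_four(grid, point)
    return weighted_level(
        [float(values[r, c]) for (r, c), _ in neighbors], [d for _, d in neighbors]
    )


@dataclass
class FallbackRecord:
    """Audit entry for one footprint substitution."""

    requested: FootprintKey
    substituted: FootprintKey


class FootprintStore:
    """Keyed collection of footprint grids with year/time-of-day fallback.

    Lookup order when the exact key is absent:

    1. same (aircraft_group, route, procedure, time_of_day) in the nearest
       other year, ties broken toward the earlier year;
    2. same (aircraft_group, route, procedure) ignoring time_of_day, again
       nearest year first, earlier on ties, and within a year the bare key
       (no time of day) before 'day' before 'night'.

    Every substitution is logged and appended to :attr:`fallback_log`.
    """

    def __init__(self, grids: Iterable[FootprintGrid] = ()):
        self._grids: dict[FootprintKey, FootprintGrid] = {}
        self.fallback_log: list[FallbackRecord] = []
        for g in grids:
            self.add(g)

    def add(self, grid: FootprintGrid) -> None:
        self._grids[grid.key] = grid

    def __len__(self) -> int:
        return len(self._grids)

    def __contains__(self, key: FootprintKey) -> bool:
        return key in self._grids

    def keys(self):
        return self._grids.keys()

    def grids(self):
        return self._grids.values()

    def lookup(self, key: FootprintKey) -> FootprintGrid:
        if not self._grids:
            raise MissingFootprintError("footprint store is empty", key=key)
        grid = self._grids.get(key)
        if grid is not None:
            return grid

        def tod_rank(t: str | None) -> int:
            return 0 if t is None else 1 + TIMES_OF_DAY.index(t)

        # pass 1: keep time_of_day, vary year; pass 2: ignore time_of_day
        for ignore_tod in (False, True):
            candidates = [
                k
                for k in self._grids
                if k.aircraft_group == key.aircraft_group
                and k.route == key.route
                and k.procedure == key.procedure
                and (ignore_tod or k.time_of_day == key.time_of_day)
            ]
            if candidates:
                best = min(
                    candidates,
                    key=lambda k: (abs(k.year - key.year), k.year, tod_rank(k.time_of_day)),
                )
                self.fallback_log.append(FallbackRecord(requested=key, substituted=best))
                logger.info("footprint fallback: %s -> %s", key, best)
                return self._grids[best]
        raise MissingFootprintError(
            f"no footprint for ({key.aircraft_group}, {key.route}, {key.procedure}) in any year",
            key=key,
        )


# ---------------------------------------------------------------------------
# file I/O — plain-text grid dialect and long-format CSV
# ---------------------------------------------------------------------------

_HEADER_FIELDS = ("key", "origin", "cell_size", "nx", "ny")


def write_grid(grid: FootprintGrid, path: str | Path) -> None:
    """Write a grid in the plain-text dialect (see :func:`read_grid`)."""
    k = grid.key
    key_str = f"{k.year}|{k.aircraft_group}|{k.route}|{k.procedure}"
    if k.time_of_day is not None:
        key_str += f"|{k.time_of_day}"
    lines = [
        f"key={key_str}",
        f"origin={grid.origin[0]!r} {grid.origin[1]!r}",
        f"cell_size={grid.cell_size!r}",
        f"nx={grid.nx}",
        f"ny={grid.ny}",
        "#LAE",
    ]
    for row in grid.lae:
        lines.append(" ".join(repr(float(v)) for v in row))
    lines.append("#LAMAX")
    for row in grid.lamax:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_key(text: str, path: Path, lineno: int) -> FootprintKey:
    parts = text.split("|")
    if len(parts) not in (4, 5):
        raise ParseError(f"{path}:{lineno}: key must have 4 or 5 '|'-separated fields")
    try:
        year = int(parts[0])
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer year {parts[0]!r}") from None
    tod = parts[4] if len(parts) == 5 else None
    try:
        return FootprintKey(year, parts[1], parts[2], parts[3], tod)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def read_grid(path: str | Path) -> FootprintGrid:
    """Read a grid from the plain-text dialect.

    Format: header lines ``key=...``, ``origin=<x> <y>``, ``cell_size=<m>``,
    ``nx=<int>``, ``ny=<int>``, then a ``#LAE`` block and a ``#LAMAX`` block
    of ny rows by nx whitespace-separated dB values; row 0 is the
    northernmost row.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    i = 0
    while i < len(lines) and "=" in lines[i] and not lines[i].startswith("#"):
        field_name, _, value = lines[i].partition("=")
        header[field_name.strip()] = value.strip()
        i += 1
    missing = [f for f in _HEADER_FIELDS if f not in header]
    if missing:
        raise ParseError(f"{path}:{i + 1}: missing header field(s): {', '.join(missing)}")
    key = _parse_key(header["key"], path, 1)
    try:
        ox, oy = (float(v) for v in header["origin"].split())
        cell_size = float(header["cell_size"])
        nx, ny = int(header["nx"]), int(header["ny"])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed header value: {exc}") from None

    def read_block(tag: str, start: int) -> tuple[np.ndarray, int]:
        if start >= len(lines) or lines[start].strip() != tag:
            raise ParseError(f"{path}:{start + 1}: expected block marker {tag!r}")
        rows = []
        for r in range(ny):
            lineno = start + 2 + r
            if lineno - 1 >= len(lines):
                raise ParseError(f"{path}:{lineno}: unexpected end of file in {tag} block")
            cells = lines[lineno - 1].split()
            if len(cells) != nx:
                raise ParseError(
                    f"{path}:{lineno}: row {r} of {tag} has {len(cells)} cells, expected {nx}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric cell in {tag} block") from None
        return np.array(rows), start + 1 + ny

    lae, i = read_block("#LAE", i)
    lamax, i = read_block("#LAMAX", i)
    try:
        return FootprintGrid(key=key, origin=(ox, oy), cell_size=cell_size, lae=lae, lamax=lamax)
    except InvalidGridError as exc:
        raise ParseError(f"{path}: {exc}") from None


def read_grid_csv(path: str | Path, key: FootprintKey) -> FootprintGrid:
    """Read a grid from long-format CSV with columns ``x,y,lae,lamax``.

    The points must form a complete regular lattice; origin and cell size are
    inferred, and an irregular lattice raises :class:`ParseError`.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    required = {"x", "y", "lae", "lamax"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: CSV must have columns x,y,lae,lamax")
    xs = np.sort(df["x"].unique())
    ys = np.sort(df["y"].unique())
    if len(xs) < 2 or len(ys) < 2:
        raise ParseError(f"{path}: lattice must have at least 2 distinct x and y values")
    dxs, dys = np.diff(xs), np.diff(ys)
    if not (np.allclose(dxs, dxs[0]) and np.allclose(dys, dys[0]) and np.isclose(dxs[0], dys[0])):
        raise ParseError(f"{path}: points do not form a regular square lattice")
    cell = float(dxs[0])
    if len(df) != len(xs) * len(ys):
        raise ParseError(
            f"{path}: incomplete lattice ({len(df)} points, expected {len(xs) * len(ys)})"
        )
    nx, ny = len(xs), len(ys)
    lae = np.full((ny, nx), np.nan)
    lamax = np.full((ny, nx), np.nan)
    col = {x: j for j, x in enumerate(xs)}
    row = {y: ny - 1 - i for i, y in enumerate(ys)}  # row 0 = northernmost
    for x, y, a, m in df[["x", "y", "lae", "lamax"]].itertuples(index=False):
        lae[row[y], col[x]] = a
        lamax[row[y], col[x]] = m
    if np.isnan(lae).any() or np.isnan(lamax).any():
        raise ParseError(f"{path}: duplicate or missing lattice points")
    return FootprintGrid(
        key=key, origin=(float(xs[0]), float(ys[-1])), cell_size=cell, lae=lae, lamax=lamax
    )


def load_store(directory: str | Path, pattern: str = "*.grid") -> FootprintStore:
    """Load every grid file matching ``pattern`` under ``directory`` into a store."""
    directory = Path(directory)
    store = FootprintStore()
    for p in sorted(directory.glob(pattern)):
        store.add(read_grid(p))
    if len(store) == 0:
        raise MissingFootprintError(f"no grid files matching {pattern!r} in {directory}")
    return store
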