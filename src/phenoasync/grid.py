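"""Regular lat/lon grids and calendar-aware time-series cubes.

The analysis grid is a plate-carree raster addressed row-major, north to
south and west to east, with pixel *centers* at the stated coordinates.
Time series are carried as a pair of axes: linear time in days since the
series start (``t_days``) and the day of year (``doy``, 1-based, 365-day
calendar).  Synthetic timelines never contain leap days; real calendars are
folded onto the 365-day year by merging Feb 29 into day 59.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "TimeSeriesCube", "timeline_365", "timeline_from_dates"]


@dataclass(frozen=True)
class GridSpec:
    """A regular lat/lon grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape.
    cell_size
        Pixel edge length in degrees (> 0).
    origin
        ``(lat, lon)`` of the **center** of the north-west pixel.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must be non-empty")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        lats = self.lats
        if np.any(np.abs(lats) > 90.0):
            raise ValueError("grid extends beyond the poles")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lats(self) -> np.ndarray:
        """Latitudes of row centers, north to south."""
        return self.origin[0] - self.cell_size * np.arange(self.n_rows)

    @property
    def lons(self) -> np.ndarray:
        """Longitudes of column centers, west to east."""
        return self.origin[1] + self.cell_size * np.arange(self.n_cols)

    def pixel_latlon(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (row-major) latitude and longitude of every pixel center."""
        lat2, lon2 = np.meshgrid(self.lats, self.lons, indexing="ij")
        return lat2.ravel(), lon2.ravel()

    def rowcol(self, pixel: int) -> tuple[int, int]:
        return divmod(int(pixel), self.n_cols)

    def pixel_of(self, lat: float, lon: float) -> int | None:
        """Index of the pixel whose cell contains (lat, lon), or None."""
        half = self.cell_size / 2.0
        r = int(np.floor((self.origin[0] + half - lat) / self.cell_size))
        c = int(np.floor((lon - (self.origin[1] - half)) / self.cell_size))
        if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
            return r * self.n_cols + c
        return None


def timeline_365(n_years: int = 2, interval_days: int = 4, start_doy: int = 1):
    """Regular sampling on the 365-day calendar.

    Returns ``(t_days, doy)`` for observations every ``interval_days`` days
    over ``n_years`` years.  ``t_days`` counts from zero; ``doy`` wraps on
    the 365-day year.
    """
    if n_years < 1 or interval_days < 1:
        raise ValueError("need n_years >= 1 and interval_days >= 1")
    t = np.arange(0, n_years * 365, interval_days, dtype=float)
    doy = ((t.astype(int) + (start_doy - 1)) % 365) + 1
    return t, doy


def timeline_from_dates(dates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convert calendar dates to (t_days, doy) on the 365-day year.

    ``dates`` is an array of ``numpy.datetime64`` (any resolution).  Linear
    time is in days since the first date.  Leap days are merged: Feb 29 maps
    to day 59 (same as Feb 28) and all later days of a leap year are shifted
    down by one so that Dec 31 is always day 365.
    """
    d = np.asarray(dates, dtype="datetime64[D]")
    if d.size == 0:
        raise ValueError("empty timeline")
    if np.any(np.diff(d).astype(int) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    t_days = (d - d[0]).astype(float)
    years = d.astype("datetime64[Y]")
    raw_doy = (d - years).astype(int) + 1  # 1-based calendar doy
    y = years.astype(int) + 1970
    leap = ((y % 4 == 0) & (y % 100 != 0)) | (y % 400 == 0)
    doy = raw_doy.copy()
    doy[leap & (raw_doy >= 60)] -= 1  # Feb 29 (60) -> 59, Dec 31 -> 365
    return t_days, doy


@dataclass
class TimeSeriesCube:
    """Per-pixel index values over a shared timeline, with availability.

    ``values`` and ``available`` are ``(n_times, n_pixels)``; pixels are in
    the grid's row-major order.  Values must be finite wherever available.
    """

    grid: GridSpec
    t_days: np.ndarray
    doy: np.ndarray
    values: np.ndarray
    available: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t_days = np.asarray(self.t_days, dtype=float)
        self.doy = np.asarray(self.doy, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.available is None:
            self.available = np.ones(self.values.shape, dtype=bool)
        self.available = np.asarray(self.available, dtype=bool)
        n_t = self.t_days.shape[0]
        if self.doy.shape != (n_t,):
            raise ValueError("t_days and doy must have equal length")
        if np.any(np.diff(self.t_days) <= 0):
            raise ValueError("t_days must be strictly increasing")
        if np.any((self.doy < 1) | (self.doy > 365)):
            raise ValueError("doy must lie in [1, 365]")
        if self.values.shape != (n_t, self.grid.n_pixels):
            raise ValueError(
                f"values must be (n_times, n_pixels) = ({n_t}, {self.grid.n_pixels})"
            )
        if self.available.shape != self.values.shape:
            raise ValueError("available must match values in shape")
        if not np.all(np.isfinite(self.values[self.available])):
            raise ValueError("values must be finite wherever available")

    @property
    def n_times(self) -> int:
        return self.t_days.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.grid.n_pixels

    def copy(self) -> "TimeSeriesCube":
        return TimeSeriesCube(
            grid=self.grid,
            t_days=self.t_days.copy(),
            doy=self.doy.copy(),
            values=self.values.copy(),
            available=self.available.copy(),
        )
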