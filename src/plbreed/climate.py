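"""Agroclimatic covariates from daily weather over growth-phase windows.

Per growth phase (vegetative, reproductive, grain filling, full cycle)
the module computes temperature and rainfall indices in the climatrends
convention: "night temperature" statistics are taken over daily minimum
temperature, "day temperature" over daily maximum.  Windows are half-open
``[start, end)`` on calendar dates, so the flowering date itself belongs
to the reproductive phase only.

Units: temperatures degC, precipitation mm/day, GDD degC-days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "PhaseWindows",
    "CoverageError",
    "PHASES",
    "INDEX_NAMES",
    "compute_indices",
    "compute_covariate_table",
    "sowing_windows",
]

PHASES = ("veg", "rep", "fil", "full")

#: per-phase index names; NT = night (tmin) statistics, DT = day (tmax)
INDEX_NAMES = (
    "minNT", "maxNT", "meanNT",
    "minDT", "maxDT", "meanDT",
    "DTR",          # mean diurnal temperature range
    "GDD",          # growing degree days, sum of max(0, (tmax+tmin)/2 - base)
    "rain",         # total precipitation
    "rainyDays",    # days with >= 1 mm
    "maxDry",       # longest run of days < 1 mm
    "maxWet",       # longest run of days >= 1 mm
    "rain1d",       # largest 1-day total
    "rain5d",       # largest rolling 5-day total
)


class CoverageError(ValueError):
    """Weather series does not cover a requested phase window."""


@dataclass(frozen=True)
class DailyWeather:
    """Per-site daily series of (date, tmin, tmax, precip)."""

    site_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"date", "tmin", "tmax", "precip"}
        if not required.issubset(df.columns):
            raise ValueError(f"weather table must have columns {sorted(required)}")
        dates = pd.to_datetime(df["date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise ValueError(f"dates must be strictly increasing for site {self.site_id!r}")
        if (df["tmin"] > df["tmax"]).any():
            raise ValueError(f"tmin > tmax in weather for site {self.site_id!r}")
        object.__setattr__(self, "data", df.assign(date=dates).reset_index(drop=True))

    def window(self, start, end) -> pd.DataFrame:
        """Half-open slice [start, end); raises CoverageError naming the
        missing dates when the series does not cover every day."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        sel = self.data[(self.data["date"] >= start) & (self.data["date"] < end)]
        expected = pd.date_range(start, end - pd.Timedelta(days=1), freq="D")
        missing = expected.difference(sel["date"])
        if len(missing):
            raise CoverageError(
                f"site {self.site_id!r}: weather missing for "
                f"{missing[0].date()}..{missing[-1].date()} ({len(missing)} days)"
            )
        return sel


@dataclass(frozen=True)
class PhaseWindows:
    """Growth-phase boundary dates.

    Defines vegetative [planting, flowering), reproductive
    [flowering, maturity), grain filling [maturity, harvest) and the full
    cycle [planting, harvest).
    """

    planting_date: pd.Timestamp
    flowering_date: pd.Timestamp
    maturity_date: pd.Timestamp
    harvest_date: pd.Timestamp

    def __post_init__(self) -> None:
        dates = [
            pd.Timestamp(self.planting_date),
            pd.Timestamp(self.flowering_date),
            pd.Timestamp(self.maturity_date),
            pd.Timestamp(self.harvest_date),
        ]
        for name, d in zip(
            ("planting_date", "flowering_date", "maturity_date", "harvest_date"), dates
        ):
            object.__setattr__(self, name, d)
        if not (dates[0] < dates[1] < dates[2] < dates[3]):
            raise ValueError("phase dates must be strictly increasing")

    @classmethod
    def from_durations(cls, planting_date, durations: Sequence[int] = (60, 95, 120)) -> "PhaseWindows":
        """Windows from a sowing date and fixed (flowering, maturity,
        harvest) offsets in days."""
        p = pd.Timestamp(planting_date)
        f, m, h = (p + pd.Timedelta(days=int(d)) for d in durations)
        return cls(p, f, m, h)

    def windows(self) -> dict[str, tuple[pd.Timestamp, pd.Timestamp]]:
        return {
            "veg": (self.planting_date, self.flowering_date),
            "rep": (self.flowering_date, self.maturity_date),
            "fil": (self.maturity_date, self.harvest_date),
            "full": (self.planting_date, self.harvest_date),
        }


def _runs(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def compute_indices(
    w: DailyWeather,
    p: PhaseWindows,
    index_set: Iterable[str] | None = None,
    gdd_base: float = 0.0,
) -> pd.Series:
    """One CovariateTable row: ``{index}_{phase}`` for every requested
    index and phase, e.g. ``minNT_veg`` (minimum night temperature during
    vegetative growth) or ``maxNT_rep``."""
    wanted = tuple(index_set) if index_set is not None else INDEX_NAMES
    unknown = set(wanted) - set(INDEX_NAMES)
    if unknown:
        raise ValueError(f"unknown indices: {sorted(unknown)}")
    out: dict[str, float] = {}
    for phase, (start, end) in p.windows().items():
        sub = w.window(start, end)
        tmin = sub["tmin"].to_numpy(float)
        tmax = sub["tmax"].to_numpy(float)
        rain = sub["precip"].to_numpy(float)
        wet = rain >= 1.0
        vals = {
            "minNT": tmin.min(),
            "maxNT": tmin.max(),
            "meanNT": tmin.mean(),
            "minDT": tmax.min(),
            "maxDT": tmax.max(),
            "meanDT": tmax.mean(),
            "DTR": (tmax - tmin).mean(),
            "GDD": np.maximum(0.0, (tmax + tmin) / 2.0 - gdd_base).sum(),
            "rain": rain.sum(),
            "rainyDays": float(wet.sum()),
            "maxDry": float(_runs(~wet)),
            "maxWet": float(_runs(wet)),
            "rain1d": rain.max(),
            "rain5d": float(
                pd.Series(rain).rolling(min(5, rain.size), min_periods=1).sum().max()
            ),
        }
        for name in wanted:
            out[f"{name}_{phase}"] = float(vals[name])
    return pd.Series(out, name=w.site_id)


def compute_covariate_table(
    weather: Mapping[str, DailyWeather],
    phases: Mapping[str, PhaseWindows],
    index_set: Iterable[str] | None = None,
    gdd_base: float = 0.0,
) -> pd.DataFrame:
    """Stack per-site index rows into a covariate table (sites as rows)."""
    rows = {
        site: compute_indices(weather[site], phases[site], index_set, gdd_base)
        for site in weather
    }
    return pd.DataFrame(rows).T.rename_axis("site_id")


def sowing_windows(planting_dates: Sequence, k: int = 3) -> list[pd.Timestamp]:
    """k representative sowing dates: the midpoints of k equiprobable
    quantile intervals of the observed planting dates, i.e. empirical
    quantiles at probabilities (2j-1)/(2k), j=1..k, with linear
    interpolation between order statistics."""
    if k < 1:
        raise ValueError("k must be >= 1")
    dates = [pd.Timestamp(d) for d in planting_dates]
    if not dates:
        raise ValueError("need at least one planting date")
    ordinals = np.array([d.toordinal() for d in dates], dtype=float)
    probs = (2 * np.arange(1, k + 1) - 1) / (2 * k)
    qs = np.quantile(ordinals, probs, method="linear")
    return [pd.Timestamp.fromordinal(int(round(q))) for q in qs]
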