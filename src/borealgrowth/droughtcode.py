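"""Canadian Drought Code (DC) over the May–October fire season.

The DC is the deep-soil moisture component of the Canadian Forest Fire Weather
Index system: a cumulative daily rating of moisture depletion in deep, compact
organic layers.  0 means a fully recharged store; 200 indicates high and ≥ 300
extreme drought severity.  The code and its moisture equivalent Q (0–800
scale) are related by dc = 400·ln(800/Q).

The daily update is the standard one: rain above the 2.8 mm threshold is
converted to effective rain and recharges Q; potential evapotranspiration from
the day's maximum temperature (floored at −2.8 °C) plus a fixed monthly
day-length factor then deepens the code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RAIN_THRESHOLD = 2.8  # mm; smaller daily totals are intercepted, no recharge
TEMP_FLOOR = -2.8  # °C
Q_SCALE = 800.0
DC_SCALE = 400.0

#: Monthly day-length factors (Jan..Dec) for ~46° N, standard DC table.
DAY_LENGTH_FACTOR = [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]

SEASON_START = (5, 1)  # May 1
SEASON_END = (10, 31)  # Oct 31
SEASON_DAYS = 184
DEFAULT_SPRING_START = 15.0  # conventional spring start-up value after thaw


class DroughtCodeError(ValueError):
    pass


def moisture_equivalent(dc: float) -> float:
    """Q = 800·exp(−dc/400), the soil-moisture equivalent of a code value."""
    return Q_SCALE * np.exp(-np.asarray(dc, dtype=float) / DC_SCALE)


def dc_from_moisture(q) -> float:
    """dc = 400·ln(800/Q); inverse of :func:`moisture_equivalent`."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q > Q_SCALE):
        raise DroughtCodeError("moisture equivalent must lie in (0, 800]")
    return DC_SCALE * np.log(Q_SCALE / q)


@dataclass
class DroughtCodeState:
    """Drought code value with its internal moisture store."""

    dc: float

    @property
    def moisture_equivalent(self) -> float:
        return float(moisture_equivalent(self.dc))


def dc_daily_step(state: DroughtCodeState, tmax: float, precip: float, month: int) -> DroughtCodeState:
    """One daily Drought Code update (rain recharge, then evapotranspiration).

    Raises
    ------
    DroughtCodeError
        If ``month`` is outside the May–October season.
    """
    if not SEASON_START[0] <= month <= SEASON_END[0]:
        raise DroughtCodeError(f"month {month} outside the May–October drought-code season")
    dc = float(state.dc)
    if precip > RAIN_THRESHOLD:
        effective_rain = 0.83 * precip - 1.27
        q0 = Q_SCALE * np.exp(-dc / DC_SCALE)
        qr = q0 + 3.937 * effective_rain
        qr = min(qr, Q_SCALE)
        dc = max(0.0, DC_SCALE * np.log(Q_SCALE / qr))
    t = max(tmax, TEMP_FLOOR)
    pe = 0.36 * (t + 2.8) + DAY_LENGTH_FACTOR[month - 1]
    pe = max(pe, 0.0)
    dc = max(0.0, dc + 0.5 * pe)
    return DroughtCodeState(dc=dc)


@dataclass
class DroughtSeries:
    """Daily May 1 – Oct 31 drought code for one site-year."""

    site_id: str
    year: int
    dates: pd.DatetimeIndex
    daily_dc: np.ndarray

    @property
    def dc_max(self) -> float:
        return float(np.max(self.daily_dc))


def dc_season(daily: pd.DataFrame, start_value: float = DEFAULT_SPRING_START) -> DroughtSeries:
    """Iterate the daily update over one site-year's May 1 – Oct 31 record.

    ``daily`` must contain (at least) the full season for a single site-year,
    with ``date``, ``tmax`` and ``precip`` columns.  Each year restarts at
    ``start_value``; overwinter carry-over is deliberately not modeled.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    sites = df["site_id"].unique() if "site_id" in df.columns else ["?"]
    if len(sites) != 1:
        raise DroughtCodeError("dc_season expects a single site")
    years = df["date"].dt.year.unique()
    if len(years) != 1:
        raise DroughtCodeError("dc_season expects a single year")
    year = int(years[0])
    season = pd.date_range(f"{year}-05-01", f"{year}-10-31", freq="D")
    df = df.set_index("date").reindex(season)
    if df["tmax"].isna().any() or df["precip"].isna().any():
        n = int(df["tmax"].isna().sum() + df["precip"].isna().sum())
        raise DroughtCodeError(f"site {sites[0]} year {year}: missing season days ({n} missing values)")
    state = DroughtCodeState(dc=float(start_value))
    out = np.empty(len(season))
    for i, (ts, row) in enumerate(df.iterrows()):
        state = dc_daily_step(state, float(row["tmax"]), float(row["precip"]), ts.month)
        out[i] = state.dc
    return DroughtSeries(site_id=str(sites[0]), year=year, dates=season, daily_dc=out)


def dc_annual_max(series: DroughtSeries) -> float:
    """Annual maximum of the daily drought code (the panel's drought driver)."""
    if len(series.daily_dc) == 0:
        raise DroughtCodeError("empty drought series")
    return series.dc_max


def dc_table(daily: pd.DataFrame, start_value: float = DEFAULT_SPRING_START) -> pd.DataFrame:
    """Annual maximum drought code for every site-year in a daily climate table."""
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    rows = []
    for (site, year), grp in df.groupby([df["site_id"], df["date"].dt.year]):
        series = dc_season(grp, start_value=start_value)
        rows.append({"site_id": site, "year": int(year), "dc_max": series.dc_max})
    return pd.DataFrame(rows)
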