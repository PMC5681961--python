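"""Daily-climate derivatives: VPD, PAR from solar geometry, degree-day sums, annual summaries.

Daily climate is carried as a tidy :class:`pandas.DataFrame` with one row per
site-day and columns ``site_id, date, tmin, tmax, tmean, precip`` plus the
optional ``par`` (daytime-average photosynthetically active radiation,
μmol m⁻² s⁻¹) and per-site ``latitude`` (decimal degrees) / ``elevation`` (m).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLIMATE_COLUMNS = ["site_id", "date", "tmin", "tmax", "tmean", "precip"]

#: Tetens saturation-vapor-pressure constants (over water), e in kPa, T in °C.
TETENS_A = 0.61078
TETENS_B = 17.27
TETENS_C = 237.3

SOLAR_CONSTANT = 1367.0  # W m-2
PAR_ENERGY_FRACTION = 0.5  # fraction of shortwave energy in the PAR band
PAR_QUANTA_PER_JOULE = 4.57  # μmol photons per J of PAR energy
DEFAULT_TRANSMISSIVITY = 0.45

MAX_MISSING_DAYS = 10


class ClimateDataError(ValueError):
    """Raised for invalid or incomplete daily climate input."""


def saturation_vapor_pressure(t_celsius):
    """Saturation vapor pressure over water (kPa) by the Tetens formula.

    e_sat(T) = 0.6108 · exp(17.27 T / (T + 237.3)); e.g. e_sat(30 °C) ≈ 4.244 kPa,
    e_sat(15 °C) ≈ 1.705 kPa (stated to 4 significant figures).
    """
    t = np.asarray(t_celsius, dtype=float)
    return TETENS_A * np.exp(TETENS_B * t / (t + TETENS_C))


def vapor_pressure_deficit(tmax, tmin):
    """Daytime vapor pressure deficit (kPa) from the daily temperature extremes.

    Assumes the daily vapor pressure equals e_sat(tmin) (dewpoint ≈ tmin), the
    standard estimate when only temperatures are observed, so
    D = e_sat(tmax) − e_sat(tmin), floored at 0.

    Raises
    ------
    ClimateDataError
        If ``tmax < tmin`` anywhere.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ClimateDataError("tmax < tmin in VPD input")
    return np.maximum(0.0, saturation_vapor_pressure(tmax) - saturation_vapor_pressure(tmin))


def vapor_pressure_deficit_rh(tmax, rh=0.7):
    """Alternative VPD estimate assuming a fixed relative humidity fraction."""
    if not 0 < rh <= 1:
        raise ClimateDataError("relative humidity must be in (0, 1]")
    return (1.0 - rh) * saturation_vapor_pressure(np.asarray(tmax, dtype=float))


def degree_day_sum(tmean_series, base: float = 5.0) -> float:
    """Growing degree-days: Σ max(0, tmean − base) over one calendar year.

    ``tmean_series`` may be a plain sequence of daily means or a Series indexed
    by date (in which case the one-calendar-year precondition is enforced).
    """
    if isinstance(tmean_series, pd.Series) and isinstance(tmean_series.index, pd.DatetimeIndex):
        years = tmean_series.index.year.unique()
        if len(years) > 1:
            raise ClimateDataError(f"degree_day_sum spans multiple years: {list(years)}")
    t = np.asarray(tmean_series, dtype=float)
    return float(np.maximum(0.0, t - base).sum())


def _solar_declination(day_of_year):
    return math.radians(23.45) * np.sin(2.0 * np.pi * (284.0 + np.asarray(day_of_year)) / 365.0)


def par_from_geometry(latitude: float, day_of_year, transmissivity: float = DEFAULT_TRANSMISSIVITY,
                      par_fraction: float = PAR_ENERGY_FRACTION):
    """Daytime-average PAR (μmol m⁻² s⁻¹) from solar geometry.

    Daily extraterrestrial irradiance is integrated analytically from the
    sunset hour angle, scaled by atmospheric ``transmissivity`` and the PAR
    energy fraction, converted to quanta (4.57 μmol J⁻¹) and averaged over the
    day length.  Returns 0 during polar night.
    """
    if abs(latitude) > 90:
        raise ClimateDataError("latitude must be within ±90 degrees")
    doy = np.asarray(day_of_year, dtype=float)
    lat = math.radians(latitude)
    dec = _solar_declination(doy)
    cos_ws = -math.tan(lat) * np.tan(dec)
    # polar day/night clamp
    cos_ws = np.clip(cos_ws, -1.0, 1.0)
    ws = np.arccos(cos_ws)  # sunset hour angle, radians
    day_seconds = ws / np.pi * 86400.0
    # annual-mean sun-earth distance (no eccentricity correction): keeps the
    # annual integral hemisphere-symmetric, adequate for radiation plumbing
    h0 = (86400.0 / np.pi) * SOLAR_CONSTANT * (
        np.cos(lat) * np.cos(dec) * np.sin(ws) + ws * np.sin(lat) * np.sin(dec)
    )
    h0 = np.maximum(h0, 0.0)
    par_energy = h0 * transmissivity * par_fraction  # J m-2 day-1
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(day_seconds > 0, par_energy * PAR_QUANTA_PER_JOULE / np.where(day_seconds > 0, day_seconds, 1.0), 0.0)
    return q if q.ndim else float(q)


def validate_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily climate table; returns it sorted by (site_id, date).

    Enforces tmin ≤ tmean ≤ tmax, precip ≥ 0, par ≥ 0 when present, and
    strictly increasing unique dates per site.
    """
    missing = [c for c in CLIMATE_COLUMNS if c not in daily.columns]
    if missing:
        raise ClimateDataError(f"daily climate table missing columns: {missing}")
    out = daily.copy()
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values(["site_id", "date"]).reset_index(drop=True)
    if (out["tmin"] > out["tmean"] + 1e-9).any() or (out["tmean"] > out["tmax"] + 1e-9).any():
        raise ClimateDataError("temperature ordering violated (need tmin ≤ tmean ≤ tmax)")
    if (out["precip"] < 0).any():
        raise ClimateDataError("negative precipitation")
    if "par" in out.columns and (out["par"].dropna() < 0).any():
        raise ClimateDataError("negative PAR")
    dup = out.duplicated(subset=["site_id", "date"])
    if dup.any():
        raise ClimateDataError(f"duplicate site-days, first at row {int(np.argmax(dup.values))}")
    return out


def fill_missing_days(year_df: pd.DataFrame, site_id, year: int) -> pd.DataFrame:
    """Reindex one site-year to its full calendar; interpolate small gaps.

    ≤ ``MAX_MISSING_DAYS`` missing days are linearly interpolated (temperatures)
    or zero-filled (precipitation) with a logged warning; more raise.
    """
    full = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    df = year_df.set_index("date").reindex(full)
    n_missing = int(df["tmean"].isna().sum())
    if n_missing > MAX_MISSING_DAYS:
        raise ClimateDataError(f"site {site_id} year {year}: {n_missing} missing days (> {MAX_MISSING_DAYS})")
    if n_missing:
        logger.warning("site %s year %d: interpolating %d missing days", site_id, year, n_missing)
        for col in ("tmin", "tmax", "tmean"):
            df[col] = df[col].interpolate(limit_direction="both")
        df["precip"] = df["precip"].fillna(0.0)
        if "par" in df.columns:
            df["par"] = df["par"].interpolate(limit_direction="both")
    df["site_id"] = site_id
    return df.rename_axis("date").reset_index()


@dataclass
class AnnualClimateSummary:
    """One site-year of annual climate aggregates."""

    site_id: str
    year: int
    tsum: float  # growing degree-days, °Cd
    mat: float  # mean annual temperature, °C
    map: float  # total annual precipitation, mm
    dc_max: float | None = None  # annual maximum drought code
    gpp_annual: float | None = None  # mol m-2 year-1


def annual_summary(daily: pd.DataFrame, dc_max: pd.DataFrame | None = None,
                   gpp_annual: pd.DataFrame | None = None, base: float = 5.0) -> pd.DataFrame:
    """Aggregate a validated daily climate table to one row per site-year.

    MAT = mean(tmean); MAP = Σ precip; TSUM = Σ max(0, tmean − base).
    ``dc_max`` / ``gpp_annual`` are optional tables keyed on (site_id, year)
    whose values are attached by join.
    """
    daily = validate_daily(daily)
    daily = daily.assign(year=daily["date"].dt.year)
    rows = []
    for (site, year), grp in daily.groupby(["site_id", "year"], sort=True):
        grp = fill_missing_days(grp, site, int(year))
        rows.append(
            {
                "site_id": site,
                "year": int(year),
                "tsum": degree_day_sum(grp["tmean"].to_numpy(), base=base),
                "mat": float(grp["tmean"].mean()),
                "map": float(grp["precip"].sum()),
            }
        )
    out = pd.DataFrame(rows)
    for name, tab in (("dc_max", dc_max), ("gpp_annual", gpp_annual)):
        if tab is not None:
            out = out.merge(tab[["site_id", "year", name]], on=["site_id", "year"], how="left")
        else:
            out[name] = np.nan
    return out


def read_daily_climate(path) -> pd.DataFrame:
    """Read the delimited daily-climate format (CSV with ISO-8601 dates)."""
    df = pd.read_csv(path)
    return validate_daily(df)


def write_daily_climate(daily: pd.DataFrame, path) -> None:
    daily.to_csv(path, index=False, date_format="%Y-%m-%d")
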