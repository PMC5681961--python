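"""Daily canopy gross photosynthetic production with temperature acclimation.

Daily GPP per unit ground area, A(t) (mol m⁻² day⁻¹), is the harmonic
combination of a diffusion term (stomatal conductance g) and a biochemical
term (capacity α times light modifier γ), scaled by the ambient CO₂ mole
fraction C_a:

    A(t) = g·C_a·α·γ / (g + α·γ)

* γ(t) = Q/(Q + δ): saturating light response, half-saturation δ.
* α(t) = α_max / (1 + exp(−b·(S − T_s))): a sigmoid of the acclimated
  temperature state S(t), rising from a winter shutdown to warm saturation.
* dS/dt = (T_air − S)/τ: S is a low-pass filter of air temperature with time
  constant τ (days), integrated by daily Euler steps.
* g(t) = max(g_floor, α·γ·(√(C_a·10⁻⁶·λ/(1.6·D)) − 1)): the optimal-stomatal-
  control conductance, closing with vapor pressure deficit D (kPa); λ (kPa)
  sets the closure threshold D* = C_a·10⁻⁶·λ/1.6.

Unit convention: g and α are molar-flux capacities per unit CO₂ mole fraction
(mol m⁻² day⁻¹); multiplying the harmonic mean by C_a·10⁻⁶ yields A in
mol CO₂ m⁻² day⁻¹.  C_a is supplied in ppm and rises linearly between the
trajectory's anchor years (330→400 ppm over 1930–2010 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import climate as _climate


@dataclass
class GppParams:
    """Photosynthesis-model parameters.

    Defaults are order-of-magnitude values for boreal evergreen conifer
    canopies in this model family; site-calibrated values should be supplied
    through configuration for real analyses.
    """

    alpha_max: float = 60000.0  # mol m-2 day-1 per unit CO2 mole fraction (canopy scale)
    b: float = 0.5  # °C-1, sigmoid curvature (positive; α increases with S)
    t_s: float = 8.0  # °C, sigmoid inflection (α = α_max/2 at S = T_s)
    tau: float = 8.0  # days, acclimation time constant
    delta: float = 200.0  # μmol m-2 s-1, light half-saturation
    lambda_: float = 3000.0  # kPa, stomatal sensitivity to VPD
    g_floor: float = 1e-5  # mol m-2 day-1, conductance floor
    sqrt_conductance: bool = True  # optimal-control closed form; False = linear reading

    def __post_init__(self):
        if min(self.alpha_max, self.b, self.tau, self.delta, self.lambda_) <= 0:
            raise ValueError("GppParams must be strictly positive")


@dataclass
class Co2Trajectory:
    """Linear ambient CO₂ ramp (ppm) between two anchor years; flat outside."""

    year_start: int = 1930
    year_end: int = 2010
    ppm_start: float = 330.0
    ppm_end: float = 400.0

    def at(self, year) -> np.ndarray:
        year = np.asarray(year, dtype=float)
        frac = np.clip((year - self.year_start) / (self.year_end - self.year_start), 0.0, 1.0)
        return self.ppm_start + frac * (self.ppm_end - self.ppm_start)


def acclimation_update(s: float, tair: float, tau: float) -> float:
    """One daily Euler step of dS/dt = (T_air − S)/τ."""
    return s + (tair - s) / tau


def photosynthetic_capacity(s, params: GppParams):
    """α(S) = α_max / (1 + exp(−b·(S − T_s))), in (0, α_max)."""
    return params.alpha_max / (1.0 + np.exp(-params.b * (np.asarray(s, dtype=float) - params.t_s)))


def light_modifier(q, delta: float):
    """γ(Q) = Q/(Q + δ) — saturating light response in [0, 1)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("PAR must be non-negative")
    return q / (q + delta)


def stomatal_conductance(alpha, gamma, d, ca, params: GppParams):
    """Optimal stomatal conductance, floored at ``params.g_floor``.

    g̃ = α·γ·(√(C_a·10⁻⁶·λ/(1.6·D)) − 1); conductance falls to the floor once
    D exceeds the closure threshold C_a·10⁻⁶·λ/1.6.  The alternative linear
    reading (no square root) is selected by ``params.sqrt_conductance=False``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("vapor pressure deficit must be positive")
    ratio = np.asarray(ca, dtype=float) * 1e-6 * params.lambda_ / (1.6 * d)
    term = (np.sqrt(ratio) if params.sqrt_conductance else ratio) - 1.0
    return np.maximum(params.g_floor, np.asarray(alpha) * np.asarray(gamma) * term)


def daily_assimilation(g, ca, alpha, gamma):
    """A = g·C_a·α·γ / (g + α·γ), C_a in ppm converted to mole fraction."""
    g = np.asarray(g, dtype=float)
    bio = np.asarray(alpha, dtype=float) * np.asarray(gamma, dtype=float)
    ca_frac = np.asarray(ca, dtype=float) * 1e-6
    with np.errstate(invalid="ignore"):
        a = np.where(bio + g > 0, g * ca_frac * bio / (g + bio), 0.0)
    return np.maximum(a, 0.0)


@dataclass
class GppDailyOutput:
    """Daily model state and fluxes for one site."""

    dates: pd.DatetimeIndex
    s_state: np.ndarray  # acclimated temperature, °C
    alpha: np.ndarray
    gamma: np.ndarray
    g: np.ndarray
    a_daily: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "s_state": self.s_state,
                "alpha": self.alpha,
                "gamma": self.gamma,
                "g": self.g,
                "a_daily": self.a_daily,
            }
        )


@dataclass
class GppResult:
    daily: GppDailyOutput
    annual: pd.DataFrame = field(default_factory=pd.DataFrame)  # site_id, year, gpp_annual


def simulate_annual_gpp(daily: pd.DataFrame, params: GppParams,
                        co2: Co2Trajectory | None = None,
                        spinup_days: int = 0) -> GppResult:
    """Run the daily model over a contiguous site record; integrate per year.

    S₀ is the first day's air temperature; ``spinup_days`` optionally replays
    the first days to settle S before output.  PAR is taken from the ``par``
    column when present, else computed from solar geometry (the table must
    then carry ``latitude``).  Annual GPP is Σ A(t) over each calendar year,
    in mol m⁻² year⁻¹; winter days contribute ≈ 0 through the α shutdown.
    """
    co2 = co2 or Co2Trajectory()
    df = _climate.validate_daily(daily)
    sites = df["site_id"].unique()
    if len(sites) != 1:
        raise ValueError("simulate_annual_gpp expects a single site; loop over sites externally")
    dates = pd.DatetimeIndex(df["date"])
    if not (dates[1:] - dates[:-1] == pd.Timedelta(days=1)).all():
        raise _climate.ClimateDataError("daily record is not contiguous")

    tair = df["tmean"].to_numpy(float)
    if "par" in df.columns and not df["par"].isna().any():
        q = df["par"].to_numpy(float)
    else:
        if "latitude" not in df.columns:
            raise _climate.ClimateDataError("no PAR column and no latitude to derive it from")
        lat = float(df["latitude"].iloc[0])
        q = par_series(lat, dates)
    d = _climate.vapor_pressure_deficit(df["tmax"].to_numpy(float), df["tmin"].to_numpy(float))
    d = np.maximum(d, 1e-6)  # strictly positive for the conductance formula
    ca = co2.at(dates.year.to_numpy())

    s = float(tair[0])
    for i in range(min(spinup_days, len(tair))):
        s = acclimation_update(s, tair[i], params.tau)
    s_path = np.empty_like(tair)
    for i, t in enumerate(tair):
        s = acclimation_update(s, t, params.tau)
        s_path[i] = s

    alpha = photosynthetic_capacity(s_path, params)
    gamma = light_modifier(q, params.delta)
    g = stomatal_conductance(alpha, gamma, d, ca, params)
    a = daily_assimilation(g, ca, alpha, gamma)

    out = GppDailyOutput(dates=dates, s_state=s_path, alpha=alpha, gamma=gamma, g=g, a_daily=a)
    annual = (
        pd.DataFrame({"site_id": sites[0], "year": dates.year, "a": a})
        .groupby(["site_id", "year"], as_index=False)["a"]
        .sum()
        .rename(columns={"a": "gpp_annual"})
    )
    return GppResult(daily=out, annual=annual)


def par_series(latitude: float, dates: pd.DatetimeIndex,
               transmissivity: float = _climate.DEFAULT_TRANSMISSIVITY) -> np.ndarray:
    """Daytime-average PAR for a date range at one latitude."""
    doy = dates.dayofyear.to_numpy()
    return np.asarray(_climate.par_from_geometry(latitude, doy, transmissivity))


def gpp_table(daily: pd.DataFrame, params: GppParams, co2: Co2Trajectory | None = None) -> pd.DataFrame:
    """Annual GPP for every site in a multi-site daily climate table."""
    frames = []
    for site, grp in daily.groupby("site_id"):
        frames.append(simulate_annual_gpp(grp, params, co2).annual)
    return pd.concat(frames, ignore_index=True)
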