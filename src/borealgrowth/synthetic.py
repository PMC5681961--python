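"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of (config, seed).  Named random streams
are derived from the master seed by fixed documented offsets, so each stage
can be regenerated independently:

====================  ======
stream                offset
====================  ======
daily climate         1
stand / competition   2
panel regressors      3
ring panel            4
====================  ======

Default conditions emulate the study system: 44 sites of 14 subject trees
observed 1930–2010 (81 years); boreal seasonal climate whose site means span
roughly −2..3 °C MAT and ~260–630 mm MAP; annual maximum drought codes drawn
over the observed 221.4–672.3 band; annual photosynthetic production on a
scaled axis (mol m⁻² yr⁻¹ / 1000) over 0.04–0.12; and growth-model truth
equal to the reference mixed-model estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mixedmodel import MixedModelSpec

_STREAM_OFFSETS = {"climate": 1, "stand": 2, "regressors": 3, "panel": 4}


def stream(seed: int, name: str) -> np.random.Generator:
    """The named random stream for a master seed."""
    return np.random.default_rng([int(seed), _STREAM_OFFSETS[name]])


#: Reference truth for the growth model (fixed effects and variance
#: components of the two-level AR(1) mixed model; term order
#: intercept, gpp, drought).  The residual marginal SD is not part of the
#: reference estimates and defaults to 0.35 mm.
TABLE_TRUTH_FIXED = {"intercept": -0.316281, "gpp": 4.954676, "drought": -0.000153}
TABLE_TRUTH_SPEC = MixedModelSpec(
    sd_site=np.array([0.517795, 4.414104, 0.000260]),
    sd_tree=np.array([0.103754, 3.728128, 0.000002]),
    phi=0.826588,
    sigma=0.35,
)


@dataclass
class ClimateConfig:
    """Sinusoidal boreal seasonal cycle with AR(1) noise and Bernoulli-gamma rain."""

    mat_range: tuple[float, float] = (-2.0, 3.0)  # site MAT spread, °C
    seasonal_amplitude: float = 18.0  # °C, half peak-to-trough
    peak_doy: int = 200
    noise_sd: float = 3.0  # daily temperature noise SD, °C
    noise_ar: float = 0.7
    diurnal_range: float = 9.0  # mean tmax − tmin, °C
    precip_prob: float = 0.45
    precip_shape: float = 1.0
    precip_scale: float = 3.4  # mm; wet-day mean = shape·scale
    lat_range: tuple[float, float] = (52.0, 59.0)


@dataclass
class StandConfig:
    """Lognormal DBH, allometric heights, Poisson competitor plots."""

    dbh_log_mean: float = 4.7  # log mm (median ≈ 110 mm)
    dbh_log_sd: float = 0.5
    height_coef: float = 0.25
    height_exp: float = 0.8
    height_noise_sd: float = 0.10  # lognormal
    competitors_per_plot: float = 4.0  # Poisson mean
    species_probs: tuple[float, float, float] = (0.55, 0.05, 0.40)  # deciduous, pine, spruce


@dataclass
class SyntheticConfig:
    """Full study-conditions configuration for the generators."""

    n_sites: int = 44
    trees_per_site: int = 14
    year_start: int = 1930
    year_end: int = 2010
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    stand: StandConfig = field(default_factory=StandConfig)
    truth: MixedModelSpec = field(default_factory=lambda: replace(TABLE_TRUTH_SPEC))
    fixed_effects: dict = field(default_factory=lambda: dict(TABLE_TRUTH_FIXED))
    gpp_band: tuple[float, float] = (0.04, 0.12)  # scaled annual GPP covariate
    drought_band: tuple[float, float] = (221.4, 672.3)  # observed dc_max range
    ring_curve: tuple[float, float, float] = (2.5, 0.04, 0.3)  # a·exp(−c·age)+k, mm
    seed: int = 0

    @property
    def years(self) -> np.ndarray:
        if self.year_end < self.year_start + 1:
            raise ValueError("need a span of at least 2 years")
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def site_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_sites + 1)]


def gen_daily_climate(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Daily site climate: seasonal sinusoid + AR(1) noise, Bernoulli-gamma rain."""
    cc = config.climate
    rng = stream(config.seed if seed is None else seed, "climate")
    frames = []
    lats = np.linspace(cc.lat_range[0], cc.lat_range[1], config.n_sites)
    # site MAT decreases with latitude across the configured spread
    mats = np.linspace(cc.mat_range[1], cc.mat_range[0], config.n_sites)
    dates = pd.date_range(f"{config.year_start}-01-01", f"{config.year_end}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    season = np.cos(2.0 * np.pi * (doy - cc.peak_doy) / 365.25)
    for site, lat, mat in zip(config.site_ids, lats, mats):
        n = len(dates)
        eps = rng.normal(0.0, cc.noise_sd * np.sqrt(1 - cc.noise_ar**2), size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, cc.noise_sd)
        for t in range(1, n):
            noise[t] = cc.noise_ar * noise[t - 1] + eps[t]
        tmean = mat + cc.seasonal_amplitude * season + noise
        half = np.maximum(0.5, rng.normal(cc.diurnal_range / 2.0, 1.0, size=n))
        wet = rng.random(n) < cc.precip_prob
        precip = np.where(wet, rng.gamma(cc.precip_shape, cc.precip_scale, size=n), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site,
                    "date": dates,
                    "tmin": tmean - half,
                    "tmax": tmean + half,
                    "tmean": tmean,
                    "precip": precip,
                    "latitude": lat,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_stand(config: SyntheticConfig, seed: int | None = None):
    """Transect structure: subject-tree heights and competitor plots.

    Returns ``(heights, competitors)``: heights with columns
    transect_id/tree_id/height_m/dbh_mm; competitors in the long plot format
    read by the competition module.
    """
    sc = config.stand
    rng = stream(config.seed if seed is None else seed, "stand")
    species = np.array(["trembling aspen", "lodgepole pine", "white spruce"])
    h_rows, c_rows = [], []
    for transect in config.site_ids:
        for j in range(1, config.trees_per_site + 1):
            tree = f"{transect}T{j:02d}"
            dbh = float(rng.lognormal(sc.dbh_log_mean, sc.dbh_log_sd))
            height = (1.3 + sc.height_coef * dbh**sc.height_exp) * float(
                rng.lognormal(0.0, sc.height_noise_sd)
            )
            h_rows.append(
                {"transect_id": transect, "tree_id": tree, "height_m": height, "dbh_mm": dbh}
            )
            k = int(rng.poisson(sc.competitors_per_plot))
            if k == 0:
                c_rows.append(
                    {"transect_id": transect, "subject_tree_id": tree,
                     "competitor_dbh_mm": np.nan, "species": ""}
                )
                continue
            for dbh_c, sp in zip(
                rng.lognormal(sc.dbh_log_mean, sc.dbh_log_sd, size=k),
                rng.choice(species, size=k, p=sc.species_probs),
            ):
                c_rows.append(
                    {"transect_id": transect, "subject_tree_id": tree,
                     "competitor_dbh_mm": float(dbh_c), "species": sp}
                )
    return pd.DataFrame(h_rows), pd.DataFrame(c_rows)


def gen_regressors(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Per site-year covariates: scaled annual GPP and annual maximum drought code.

    Drawn uniform over the configured bands — the drought band spans the
    observed historical range, so the small drought coefficient is actually
    identifiable against realistic regressor magnitudes.
    """
    rng = stream(config.seed if seed is None else seed, "regressors")
    years = config.years
    rows = []
    for site in config.site_ids:
        gpp = rng.uniform(*config.gpp_band, size=len(years))
        dc = rng.uniform(*config.drought_band, size=len(years))
        rows.append(pd.DataFrame({"site_id": site, "year": years, "gpp": gpp, "drought": dc}))
    return pd.concat(rows, ignore_index=True)


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) path with marginal SD sigma."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    shocks = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + shocks[t]
    return e


def gen_ring_panel(config: SyntheticConfig, regressors: pd.DataFrame | None = None,
                   seed: int | None = None, with_widths: bool = False) -> pd.DataFrame:
    """Growth panel drawn from the two-level AR(1) mixed model.

    I_ijk = (b₁+β₁ᵢ+β₁ᵢⱼ) + (b₂+β₂ᵢ+β₂ᵢⱼ)·A_ik + (b₃+β₃ᵢ+β₃ᵢⱼ)·D_ik + AR(1)
    noise, with random effects drawn from the configured SDs.  With
    ``with_widths=True`` a negative-exponential age curve is added so the
    table also carries raw ``width_mm`` (floored at 0) and ``cambial_age``
    for exercising the detrending stage.
    """
    master = config.seed if seed is None else seed
    if regressors is None:
        regressors = gen_regressors(config, seed=master)
    rng = stream(master, "panel")
    truth = config.truth
    b = np.array([config.fixed_effects[t] for t in ("intercept", "gpp", "drought")])
    years = config.years
    n_years = len(years)
    a_curve, c_curve, k_curve = config.ring_curve
    reg = regressors.set_index(["site_id", "year"]).sort_index()
    frames = []
    for site in config.site_ids:
        beta_site = rng.normal(0.0, truth.sd_site)
        sub = reg.loc[site]
        missing = set(years) - set(sub.index)
        if missing:
            raise ValueError(f"regressors missing site-years for {site}: {sorted(missing)[:3]} ...")
        A = sub.loc[years, "gpp"].to_numpy(float)
        D = sub.loc[years, "drought"].to_numpy(float)
        for j in range(1, config.trees_per_site + 1):
            beta_tree = rng.normal(0.0, truth.sd_tree)
            coef = b + beta_site + beta_tree
            idx = coef[0] + coef[1] * A + coef[2] * D + _ar1_noise(rng, n_years, truth.phi, truth.sigma)
            frame = pd.DataFrame(
                {
                    "site_id": site,
                    "tree_id": f"{site}T{j:02d}",
                    "year": years,
                    "index": idx,
                    "gpp": A,
                    "drought": D,
                }
            )
            if with_widths:
                age = np.arange(1, n_years + 1)
                frame["cambial_age"] = age
                frame["width_mm"] = np.maximum(
                    0.0, a_curve * np.exp(-c_curve * age) + k_curve + idx
                )
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)
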