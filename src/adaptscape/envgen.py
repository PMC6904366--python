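"""Synthetic daily weather and soil/management settings for the TPE.

Four site archetypes describe contrasting wheat-belt growing areas (a
summer-dominant subtropical site, a winter-dominant Mediterranean site, a
second summer-dominant site with a deep soil, and an evenly distributed
temperate site). A Richardson-type stochastic weather generator produces
daily series: first-order Markov rain occurrence with month-varying
probabilities shaped by the rainfall pattern, gamma-distributed wet-day
amounts scaled to hit the annual/seasonal targets in expectation, and
seasonal sinusoids with AR(1) residuals for temperature and radiation. The
target population of environments (TPE) is the cross of site archetypes and
seasons, with soil reset at every sowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SiteArchetype",
    "WeatherSeries",
    "TrialEnvironment",
    "default_archetypes",
    "daylength",
    "simulate_weather",
    "build_tpe",
    "write_met",
    "read_weather_csv",
]

DAYS_PER_YEAR = 365
SOWING_DOY = 135  # 15 May in a 365-day year

# monthly rain-share shapes (Jan..Dec), normalized downstream
_RAIN_SHAPES = {
    "summer-dominant": np.array([1.8, 1.7, 1.4, 0.8, 0.6, 0.5, 0.4, 0.4, 0.5, 0.8, 1.2, 1.6]),
    "winter-dominant": np.array([0.5, 0.55, 0.6, 0.7, 1.6, 1.9, 2.0, 1.8, 1.2, 0.7, 0.15, 0.45]),
    "even": np.ones(12),
}

_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass(frozen=True)
class SiteArchetype:
    """Climate, soil and management targets for one trial location."""

    name: str
    latitude: float
    annual_rain: float  # mm
    seasonal_rain: float  # mm, May-November (sowing to maturity)
    rain_pattern: str  # summer-dominant | winter-dominant | even
    tmean: float  # daily mean temperature target, degC
    radiation: float  # daily mean radiation target, MJ m-2
    pawc: float  # plant-available water capacity, mm
    sowing_paw: float  # plant-available water at sowing, mm
    sowing_doy: int = SOWING_DOY
    soil_n: float = 30.0  # kg/ha at sowing
    applied_n: tuple[float, float, float] = (50.0, 0.0, 0.0)
    wet_day_prob: float | None = None  # override; None -> derived from targets

    def __post_init__(self):
        if self.pawc <= 0:
            raise ValueError("PAWC must be positive")
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude out of range")
        if self.rain_pattern not in _RAIN_SHAPES:
            raise ValueError(f"unknown rainfall pattern {self.rain_pattern!r}")
        if min(self.annual_rain, self.seasonal_rain, self.tmean, self.radiation) <= 0:
            raise ValueError("climate targets must be positive")


def default_archetypes() -> list[SiteArchetype]:
    """The four wheat-belt site archetypes of the default TPE."""
    return [
        SiteArchetype(
            name="Emerald", latitude=-23.53, annual_rain=585.0, seasonal_rain=89.0,
            rain_pattern="summer-dominant", tmean=17.5, radiation=16.7,
            pawc=133.5, sowing_paw=132.0, soil_n=30.0, applied_n=(50.0, 0.0, 0.0),
        ),
        SiteArchetype(
            name="Merredin", latitude=-31.50, annual_rain=313.0, seasonal_rain=181.0,
            rain_pattern="winter-dominant", tmean=12.9, radiation=14.4,
            pawc=101.1, sowing_paw=39.0, soil_n=30.0, applied_n=(20.0, 20.0, 30.0),
        ),
        SiteArchetype(
            name="Narrabri", latitude=-30.32, annual_rain=644.0, seasonal_rain=202.0,
            rain_pattern="summer-dominant", tmean=13.5, radiation=15.0,
            pawc=217.5, sowing_paw=175.0, soil_n=30.0, applied_n=(130.0, 0.0, 0.0),
        ),
        SiteArchetype(
            name="Yanco", latitude=-34.61, annual_rain=406.0, seasonal_rain=193.0,
            rain_pattern="even", tmean=11.9, radiation=13.6,
            pawc=190.8, sowing_paw=99.0, soil_n=50.0, applied_n=(40.0, 40.0, 40.0),
        ),
    ]


@dataclass
class WeatherSeries:
    """Daily weather for one site-year: tmin/tmax (degC), radn (MJ m-2), rain (mm)."""

    doy: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray
    radn: np.ndarray
    rain: np.ndarray
    latitude: float
    site: str = ""

    def __post_init__(self):
        if np.any(self.tmin > self.tmax):
            raise ValueError("tmin must be <= tmax")
        if np.any(self.rain < 0) or np.any(self.radn < 0):
            raise ValueError("rain and radiation must be non-negative")

    @property
    def n_days(self) -> int:
        return self.doy.size

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.tmin + self.tmax)

    @property
    def daylength(self) -> np.ndarray:
        return daylength(self.latitude, self.doy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"doy": self.doy, "tmin": self.tmin, "tmax": self.tmax,
             "radn": self.radn, "rain": self.rain}
        )


@dataclass
class TrialEnvironment:
    """One site × season trial: weather plus soil/management state."""

    site: SiteArchetype
    year_index: int
    weather: WeatherSeries
    pawc: float
    initial_paw: float
    et_label: str | None = None

    @property
    def name(self) -> str:
        return f"{self.site.name}_{self.year_index}"


def daylength(latitude: float, day_of_year) -> np.ndarray | float:
    """Astronomical daylength (hours) with a civil-twilight offset.

    Standard spherical-astronomy formula: solar declination from the
    day-of-year sinusoid, hour angle at a sun altitude of −0.83° (refraction
    plus solar radius, the conventional sunrise definition). Polar edge
    cases are clamped to (0, 24).
    """
    doy = np.asarray(day_of_year, float)
    lat = np.deg2rad(latitude)
    decl = np.deg2rad(23.44) * -np.cos(2 * np.pi * (doy + 10.0) / 365.0)
    alt = np.deg2rad(-0.83)
    cos_h = (np.sin(alt) - np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
    cos_h = np.clip(cos_h, -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(cos_h)
    hours = np.clip(hours, 1e-3, 24.0 - 1e-3)
    return float(hours) if np.isscalar(day_of_year) else hours


def _monthly_rain_stats(arch: SiteArchetype):
    """Per-month wet-day probability and mean wet-day amount hitting targets.

    The monthly rain totals follow the archetype's pattern shape, rescaled
    so the May–November window sums to the seasonal target and the year sums
    to the annual target (the two constraints are blended by scaling the
    in-season and off-season months separately).
    """
    shape = _RAIN_SHAPES[arch.rain_pattern].astype(float)
    totals = shape / shape.sum() * arch.annual_rain
    season = slice(4, 11)  # May..November (0-based months 4..10)
    in_season = totals[season].sum()
    off_season = arch.annual_rain - in_season
    target_off = arch.annual_rain - arch.seasonal_rain
    totals[season] *= arch.seasonal_rain / in_season
    if off_season > 0:
        off_mask = np.ones(12, bool)
        off_mask[season] = False
        totals[off_mask] *= target_off / off_season
    # wet-day probability scales with the month's share of rain
    base_p = arch.wet_day_prob
    if base_p is None:
        p_wet = np.clip(0.85 * totals / totals.max(), 0.05, 0.85)
    else:
        p_wet = np.full(12, base_p)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_amount = np.where(
            p_wet * _MONTH_LENGTHS > 0, totals / (p_wet * _MONTH_LENGTHS), 0.0
        )
    return p_wet, mean_amount


_DOY_MONTH = np.repeat(np.arange(12), _MONTH_LENGTHS)


def simulate_weather(arch: SiteArchetype, year_seed: int | None = None) -> WeatherSeries:
    """One synthetic calendar year of daily weather for a site archetype.

    Rain: first-order Markov occurrence (wet-after-wet odds mildly boosted)
    with month-varying probabilities; wet-day amounts are gamma (shape 3)
    with the month's mean, so annual/seasonal totals match the archetype
    targets in expectation. Temperature and radiation: seasonal
    sinusoids centered on the archetype means (southern-hemisphere phase)
    with AR(1) residuals; the diurnal range is 12 °C with seasonal
    modulation.
    """
    rng = np.random.default_rng(year_seed)
    doy = np.arange(1, DAYS_PER_YEAR + 1)
    month = _DOY_MONTH

    p_wet, mean_amount = _monthly_rain_stats(arch)
    # Markov occurrence: p(wet|dry)=p0, p(wet|wet)=min(2*p0, 0.85) with the
    # pair constrained to keep the stationary wet fraction at p_wet
    rain = np.zeros(DAYS_PER_YEAR)
    wet_prev = False
    u = rng.uniform(size=DAYS_PER_YEAR)
    for d in range(DAYS_PER_YEAR):
        p = p_wet[month[d]]
        if p <= 0:
            wet = False
        else:
            p11 = min(1.15 * p, 0.9)
            # solve p01 from stationarity: p = p*p11 + (1-p)*p01
            p01 = max(p * (1.0 - p11) / (1.0 - p), 1e-6) if p < 1 else 1.0
            wet = u[d] < (p11 if wet_prev else p01)
        if wet:
            rain[d] = rng.gamma(3.0, mean_amount[month[d]] / 3.0)
        wet_prev = wet

    # seasonal cycle: southern hemisphere -> warmest around mid January
    phase = np.cos(2 * np.pi * (doy - 15.0) / 365.0)
    t_amp = 6.0 + 0.12 * abs(arch.latitude)
    ar = 0.6
    eps_t = rng.normal(0, 1.6, DAYS_PER_YEAR)
    eps_r = rng.normal(0, 2.2, DAYS_PER_YEAR)
    for d in range(1, DAYS_PER_YEAR):
        eps_t[d] += ar * eps_t[d - 1]
        eps_r[d] += ar * eps_r[d - 1]
    tmean = arch.tmean + t_amp * phase + eps_t
    diurnal = 12.0 + 2.0 * phase  # slightly wider range in summer
    tmin = tmean - diurnal / 2.0
    tmax = tmean + diurnal / 2.0
    r_amp = 0.45 * arch.radiation
    radn = np.clip(arch.radiation + r_amp * phase + eps_r, 0.5, None)
    radn = np.where(rain > 0.2, radn * 0.75, radn)  # cloudy on wet days

    return WeatherSeries(
        doy=doy, tmin=tmin, tmax=tmax, radn=radn, rain=rain,
        latitude=arch.latitude, site=arch.name,
    )


def build_tpe(
    archetypes: list[SiteArchetype] | None = None,
    n_years: int = 31,
    master_seed: int | None = None,
) -> list[TrialEnvironment]:
    """Cross site archetypes with seasons into the TPE trial list.

    Each season is an independent environment sample: the soil is reset to
    the archetype's sowing plant-available water every year. The default
    four archetypes × 31 years give the 124-trial TPE.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if not archetypes:
        raise ValueError("at least one archetype required")
    if isinstance(master_seed, np.random.SeedSequence):
        ss = master_seed.spawn(len(archetypes) * n_years)
    else:
        ss = np.random.SeedSequence(master_seed).spawn(len(archetypes) * n_years)
    trials = []
    k = 0
    for arch in archetypes:
        for year in range(n_years):
            wx = simulate_weather(arch, year_seed=ss[k])
            trials.append(
                TrialEnvironment(
                    site=arch, year_index=year, weather=wx,
                    pawc=arch.pawc, initial_paw=min(arch.sowing_paw, arch.pawc),
                )
            )
            k += 1
    return trials


def write_met(series: WeatherSeries, path) -> None:
    """Write weather in a crop-model-compatible text (met) layout."""
    with open(path, "w") as fh:
        fh.write(f"[weather.met.weather]\n")
        fh.write(f"!site = {series.site}\n")
        fh.write(f"latitude = {series.latitude:.2f} (DECIMALDEGREES)\n")
        fh.write("day tmin tmax radn rain\n")
        fh.write("() (oC) (oC) (MJ/m2) (mm)\n")
        for d, tn, tx, rd, rn in zip(series.doy, series.tmin, series.tmax,
                                     series.radn, series.rain):
            fh.write(f"{d} {tn:.1f} {tx:.1f} {rd:.1f} {rn:.1f}\n")


def read_weather_csv(path, latitude: float, site: str = "") -> WeatherSeries:
    """Read a daily weather CSV (columns doy/date, tmin, tmax, radn, rain)."""
    df = pd.read_csv(path)
    if "doy" not in df.columns:
        df["doy"] = pd.to_datetime(df["date"]).dt.dayofyear
    return WeatherSeries(
        doy=df["doy"].to_numpy(), tmin=df["tmin"].to_numpy(float),
        tmax=df["tmax"].to_numpy(float), radn=df["radn"].to_numpy(float),
        rain=df["rain"].to_numpy(float), latitude=latitude, site=site,
    )
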