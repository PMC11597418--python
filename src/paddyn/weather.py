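"""Stochastic daily weather: a monthly two-state first-order Markov chain for
wet/dry occurrence with a two-parameter Gamma model for wet-day precipitation,
plus drought-index classification of years.

The occurrence chain has two states (wet, dry) and monthly transition
probabilities p_wd = P(wet | previous day dry) and p_ww = P(wet | previous day
wet).  Wet-day precipitation is ``wet_threshold`` plus a Gamma(shape, scale)
excess, with parameters per calendar month.  Temperatures are drawn from
monthly normals — minimal plumbing, used only to drive evapotranspiration.

Years are labelled wet / normal / dry from the drought index
``DI = (P − A) / σ`` where P is the rainfall of the classification window,
A and σ its multi-year mean and standard deviation: wet iff DI > 0.35,
dry iff DI < −0.35, normal on the closed band in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkovGammaParams",
    "TemperatureModel",
    "YearClass",
    "fit_markov_gamma",
    "generate_weather",
    "stationary_wet_probability",
    "drought_index",
    "season_rainfall",
    "WET_DI_THRESHOLD",
    "DRY_DI_THRESHOLD",
]

WET_DI_THRESHOLD = 0.35
DRY_DI_THRESHOLD = -0.35

_MONTHS = np.arange(1, 13)


class WeatherError(ValueError):
    """Invalid weather input or generator parameters."""


@dataclass(frozen=True)
class MarkovGammaParams:
    """Monthly Markov-chain / Gamma precipitation parameters.

    Arrays are indexed by calendar month − 1.  ``shape``/``scale`` describe
    the Gamma distribution of the wet-day excess over ``wet_threshold`` (mm),
    so the mean wet-day amount for month m is
    ``wet_threshold + shape[m-1] * scale[m-1]``.
    ``fallback_months`` flags months whose Gamma fit fell back to the pooled
    annual fit for lack of wet days.
    """

    p_wd: np.ndarray
    p_ww: np.ndarray
    shape: np.ndarray
    scale: np.ndarray
    wet_threshold: float = 0.1
    fallback_months: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("p_wd", "p_ww", "shape", "scale"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise WeatherError(f"{name} must have 12 monthly entries")
            object.__setattr__(self, name, arr)
        if self.wet_threshold < 0:
            raise WeatherError("wet_threshold must be >= 0")
        if ((self.p_wd < 0) | (self.p_wd > 1)).any() or ((self.p_ww < 0) | (self.p_ww > 1)).any():
            raise WeatherError("transition probabilities must lie in [0, 1]")
        if (self.shape <= 0).any() or (self.scale <= 0).any():
            raise WeatherError("Gamma shape and scale must be positive")

    def mean_wet_amount(self, month: int) -> float:
        """Mean wet-day precipitation (mm) for a calendar month."""
        return self.wet_threshold + self.shape[month - 1] * self.scale[month - 1]


@dataclass(frozen=True)
class TemperatureModel:
    """Monthly normal temperatures (°C) used to generate tmax/tmin.

    tmin is drawn from N(tmin_mean, sd); the diurnal range is drawn from
    N(tmax_mean − tmin_mean, sd/2) truncated at 0.5 °C so tmax ≥ tmin always.
    """

    tmax_mean: np.ndarray
    tmin_mean: np.ndarray
    sd: float = 2.5

    def __post_init__(self) -> None:
        for name in ("tmax_mean", "tmin_mean"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise WeatherError(f"{name} must have 12 monthly entries")
            object.__setattr__(self, name, arr)
        if (self.tmax_mean < self.tmin_mean).any():
            raise WeatherError("monthly tmax_mean must be >= tmin_mean")


# Yangtze middle/lower reaches humid-subtropical normals.
DEFAULT_TEMPERATURE = TemperatureModel(
    tmax_mean=np.array([7.0, 9.0, 14.0, 21.0, 26.0, 29.0, 32.0, 32.0, 28.0, 22.0, 16.0, 9.0]),
    tmin_mean=np.array([-1.0, 1.0, 5.0, 11.0, 17.0, 21.0, 25.0, 24.0, 19.0, 13.0, 7.0, 1.0]),
)


@dataclass(frozen=True)
class YearClass:
    """Drought-index classification of one year."""

    year: int
    P: float
    A: float
    sigma: float
    DI: float
    label: str


def _validate_weather_frame(weather: pd.DataFrame) -> pd.DataFrame:
    required = {"date", "prcp"}
    missing = required - set(weather.columns)
    if missing:
        raise WeatherError(f"weather table missing columns: {sorted(missing)}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    if not w["date"].is_monotonic_increasing or w["date"].duplicated().any():
        raise WeatherError("weather dates must be strictly increasing")
    if (w["prcp"] < 0).any():
        bad = w.index[w["prcp"] < 0][0]
        raise WeatherError(f"negative precipitation at row {bad}")
    return w


def fit_markov_gamma(
    weather: pd.DataFrame,
    wet_threshold: float = 0.1,
    method: str = "moments",
    min_wet_days: int = 5,
) -> MarkovGammaParams:
    """Fit monthly transition probabilities and Gamma wet-day parameters.

    Transition probabilities are the empirical conditional frequencies, with
    day pairs assigned to the month of the *current* day.  Gamma parameters
    are fitted to wet-day excess over ``wet_threshold`` by the method of
    moments (default) or maximum likelihood (``method="mle"``).  Months with
    fewer than ``min_wet_days`` wet days fall back to the pooled annual fit
    and are flagged in ``fallback_months``.
    """
    if wet_threshold < 0:
        raise WeatherError("wet_threshold must be >= 0")
    if method not in ("moments", "mle"):
        raise WeatherError("method must be 'moments' or 'mle'")
    w = _validate_weather_frame(weather)
    span_days = (w["date"].iloc[-1] - w["date"].iloc[0]).days + 1
    if span_days < 730:
        raise WeatherError("weather series must span at least 2 full years")

    prcp = w["prcp"].to_numpy(dtype=float)
    month = w["date"].dt.month.to_numpy()
    wet = prcp >= wet_threshold
    if not wet.any():
        raise WeatherError("record contains no wet days; all 12 months degenerate")

    prev_wet = wet[:-1]
    cur_wet = wet[1:]
    cur_month = month[1:]

    p_wd = np.zeros(12)
    p_ww = np.zeros(12)
    for m in _MONTHS:
        sel = cur_month == m
        dry_before = sel & ~prev_wet
        wet_before = sel & prev_wet
        p_wd[m - 1] = cur_wet[dry_before].mean() if dry_before.any() else 0.0
        p_ww[m - 1] = cur_wet[wet_before].mean() if wet_before.any() else 0.0

    excess_all = prcp[wet] - wet_threshold
    pooled = _fit_gamma(excess_all, method)
    shape = np.empty(12)
    scale = np.empty(12)
    fallback: list[int] = []
    for m in _MONTHS:
        excess_m = prcp[wet & (month == m)] - wet_threshold
        if excess_m.size < min_wet_days:
            shape[m - 1], scale[m - 1] = pooled
            fallback.append(int(m))
        else:
            shape[m - 1], scale[m - 1] = _fit_gamma(excess_m, method)
    return MarkovGammaParams(
        p_wd=p_wd,
        p_ww=p_ww,
        shape=shape,
        scale=scale,
        wet_threshold=wet_threshold,
        fallback_months=tuple(fallback),
    )


def _fit_gamma(excess: np.ndarray, method: str) -> tuple[float, float]:
    """Fit Gamma(shape, scale) to non-negative wet-day excess amounts."""
    excess = np.asarray(excess, dtype=float)
    mean = float(excess.mean())
    if mean <= 0:
        # all wet amounts exactly at threshold: near-degenerate spike at 0+
        return 1.0, 1e-6
    var = float(excess.var(ddof=1)) if excess.size > 1 else 0.0
    if var <= 0:
        # deterministic amounts: concentrate the Gamma near its mean
        return 1e6, mean / 1e6
    if method == "mle":
        a, _, sc = stats.gamma.fit(np.maximum(excess, 1e-9), floc=0.0)
        return float(a), float(sc)
    shape = mean**2 / var
    return shape, mean / shape


def stationary_wet_probability(params: MarkovGammaParams, month: int) -> float:
    """Long-run wet-day frequency p_wd / (1 + p_wd − p_ww) for the month."""
    pw, pd_ = params.p_ww[month - 1], params.p_wd[month - 1]
    denom = 1.0 + pd_ - pw
    return pd_ / denom if denom > 0 else 0.0


def generate_weather(
    params: MarkovGammaParams,
    n_years: int,
    seed: int | np.random.Generator,
    temperature_model: TemperatureModel = DEFAULT_TEMPERATURE,
    start_year: int = 2001,
) -> pd.DataFrame:
    """Generate a daily weather table for ``n_years`` calendar years.

    Reproducible given ``seed``; dry days have prcp = 0, wet days draw
    ``wet_threshold`` + Gamma excess.  Returns columns date, prcp, tmax, tmin.
    """
    if n_years < 1:
        raise WeatherError("n_years must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # second-resolution timestamps keep multi-century series representable
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31",
        freq="D", unit="s",
    )
    months = dates.month.to_numpy()
    n = len(dates)
    prcp = np.zeros(n)
    tmax = np.empty(n)
    tmin = np.empty(n)

    wet_prev = rng.random() < stationary_wet_probability(params, int(months[0]))
    for i in range(n):
        m = months[i] - 1
        p = params.p_ww[m] if wet_prev else params.p_wd[m]
        wet = rng.random() < p
        if wet:
            prcp[i] = params.wet_threshold + rng.gamma(params.shape[m], params.scale[m])
        wet_prev = wet
        lo = rng.normal(temperature_model.tmin_mean[m], temperature_model.sd)
        rng_range = max(
            0.5,
            rng.normal(
                temperature_model.tmax_mean[m] - temperature_model.tmin_mean[m],
                temperature_model.sd / 2.0,
            ),
        )
        tmin[i] = lo
        tmax[i] = lo + rng_range
    return pd.DataFrame({"date": dates, "prcp": prcp, "tmax": tmax, "tmin": tmin})


def season_rainfall(
    weather: pd.DataFrame,
    transplant: str = "06-10",
    harvest: str = "09-30",
) -> pd.Series:
    """Per-year rainfall total (mm) over the growing-season window.

    ``transplant``/``harvest`` are MM-DD strings applied to every year.
    """
    w = _validate_weather_frame(weather)
    years = w["date"].dt.year
    out = {}
    for y in sorted(years.unique()):
        t0 = pd.Timestamp(f"{y}-{transplant}")
        t1 = pd.Timestamp(f"{y}-{harvest}")
        sel = (w["date"] >= t0) & (w["date"] <= t1)
        out[int(y)] = float(w.loc[sel, "prcp"].sum())
    return pd.Series(out, name="season_prcp_mm")


def drought_index(yearly_P, years=None) -> list[YearClass]:
    """Classify years as wet / normal / dry from the standardized rainfall
    anomaly DI = (P − A)/σ with A, σ computed over the supplied years.

    Boundaries are inclusive for the normal class: DI = ±0.35 → normal.
    """
    P = np.asarray(list(yearly_P), dtype=float)
    if P.size < 3:
        raise WeatherError("drought index needs at least 3 years")
    if years is None:
        years = list(range(1, P.size + 1))
    A = float(P.mean())
    sigma = float(P.std(ddof=1))
    if sigma == 0:
        raise WeatherError("zero rainfall variance: classification undefined")
    out = []
    for yr, p in zip(years, P):
        di = (p - A) / sigma
        if di > WET_DI_THRESHOLD:
            label = "wet"
        elif di < DRY_DI_THRESHOLD:
            label = "dry"
        else:
            label = "normal"
        out.append(YearClass(year=int(yr), P=float(p), A=A, sigma=sigma, DI=di, label=label))
    return out
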