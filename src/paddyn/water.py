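"""Daily ponding-water balance for a bunded rice paddy.

End-of-day ponding depth follows
``Pd_n = Pd_{n-1} + Prem_n + Irri_n − ET_n − Inf_n − Rf_n`` (all mm), with
threshold runoff ``Rf = max(0, Pd − Pd_max)`` and managed drainage windows
(mid-season and pre-harvest dry-downs) during which the field is drained to
zero and irrigation is suppressed.  Within a day fluxes are applied in the
order precipitation → irrigation → evapotranspiration → infiltration →
runoff, so management reacts to same-day rain; ET and infiltration are capped
at the available water so the depth never goes negative.

Reference evapotranspiration is either taken verbatim from a supplied ``et0``
column or estimated by Hargreaves–Samani from tmax/tmin, latitude and day of
year; actual ET is kc × ET0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SoilHydroParams",
    "IrrigationPolicy",
    "PaddyDayRecord",
    "step_water_balance",
    "reference_et",
    "simulate_water_season",
]


class WaterError(ValueError):
    """Invalid hydrological parameter or input."""


@dataclass(frozen=True)
class SoilHydroParams:
    """Ponded-soil hydraulics: steady percolation rate (mm/day), maximum
    ponding depth before overflow (mm), and crop coefficient.

    ``kc`` may be a single float or a list of ``(start_day, end_day, kc)``
    tuples in days after transplanting.
    """

    perc_rate: float = 8.0
    pd_max: float = 250.0
    kc: float | tuple = 1.05

    def __post_init__(self) -> None:
        if self.perc_rate < 0:
            raise WaterError("perc_rate must be >= 0")
        if self.pd_max <= 0:
            raise WaterError("pd_max must be > 0")
        if isinstance(self.kc, (int, float)):
            if self.kc <= 0:
                raise WaterError("kc must be > 0")
        else:
            for _, _, k in self.kc:
                if k <= 0:
                    raise WaterError("kc must be > 0")

    def kc_at(self, day: int) -> float:
        if isinstance(self.kc, (int, float)):
            return float(self.kc)
        for start, end, k in self.kc:
            if start <= day <= end:
                return float(k)
        return 1.0


@dataclass(frozen=True)
class IrrigationPolicy:
    """Irrigate to ``pd_target`` when depth falls below ``pd_lower``;
    ``drainage_windows`` are inclusive (start, end) day ranges (days after
    transplanting) with forced drainage and no irrigation.

    ``pd_upper`` is the operational drainage control: when the end-of-day
    depth exceeds it (storm water), the field is actively drained back to
    ``pd_target``.  This managed-drainage volume is reported separately from
    bund overflow and summed into total runoff.  ``None`` disables active
    storm drainage, leaving only bund overflow at pd_max.
    """

    pd_lower: float = 20.0
    pd_target: float = 60.0
    pd_upper: float | None = 100.0
    drainage_windows: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.pd_lower < self.pd_target):
            raise WaterError("need 0 <= pd_lower < pd_target")
        if self.pd_upper is not None and self.pd_upper < self.pd_target:
            raise WaterError("pd_upper must be >= pd_target")
        object.__setattr__(
            self, "drainage_windows", tuple((int(a), int(b)) for a, b in self.drainage_windows)
        )

    def in_drainage(self, day: int) -> bool:
        return any(a <= day <= b for a, b in self.drainage_windows)


@dataclass(frozen=True)
class PaddyDayRecord:
    """One simulated day: end-of-day ponding depth and all water fluxes (mm).

    ``rf`` is total runoff = bund overflow (``rf_over``) + managed drainage
    (``rf_drain``, storm-control and dry-down releases)."""

    day: int
    pd: float
    prem: float
    irri: float
    et: float
    inf: float
    rf: float
    rf_over: float = 0.0
    rf_drain: float = 0.0


def step_water_balance(
    pd_prev: float,
    prem: float,
    et_demand: float,
    soil: SoilHydroParams,
    policy: IrrigationPolicy,
    day: int,
) -> PaddyDayRecord:
    """Advance the ponding depth one day.

    ``et_demand`` is the day's potential crop ET (kc × ET0, mm); actual ET and
    infiltration are capped at the available water.
    """
    if pd_prev < 0 or prem < 0 or et_demand < 0:
        raise WaterError("pd_prev, prem and et_demand must be >= 0")
    draining = policy.in_drainage(day)
    depth = pd_prev + prem
    irri = 0.0
    if not draining and depth < policy.pd_lower:
        irri = policy.pd_target - depth
        depth = policy.pd_target
    et = min(et_demand, depth)
    depth -= et
    inf = min(soil.perc_rate, depth)
    depth -= inf
    rf_over = max(0.0, depth - soil.pd_max)
    depth -= rf_over
    rf_drain = 0.0
    if draining:
        rf_drain = depth
        depth = 0.0
    elif policy.pd_upper is not None and depth > policy.pd_upper:
        rf_drain = depth - policy.pd_target
        depth = policy.pd_target
    return PaddyDayRecord(
        day=day, pd=depth, prem=prem, irri=irri, et=et, inf=inf,
        rf=rf_over + rf_drain, rf_over=rf_over, rf_drain=rf_drain,
    )


_GSC = 0.0820  # solar constant, MJ m-2 min-1


def reference_et(
    tmax: float,
    tmin: float,
    doy: int,
    latitude: float,
    et0: float | None = None,
) -> float:
    """Reference evapotranspiration ET0 (mm/day).

    Returns ``et0`` verbatim when supplied; otherwise the Hargreaves–Samani
    estimate 0.0023 · Ra · (Tmean + 17.8) · √(Tmax − Tmin), with
    extraterrestrial radiation Ra (converted to mm/day evaporation
    equivalent) from latitude and day of year.
    """
    if et0 is not None:
        if et0 < 0:
            raise WaterError("et0 must be >= 0")
        return float(et0)
    if tmax is None or tmin is None or np.isnan(tmax) or np.isnan(tmin):
        raise WaterError("missing temperatures and no et0 supplied")
    if tmax < tmin:
        raise WaterError("tmax must be >= tmin")
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra_mj = (
        24.0 * 60.0 / math.pi
        * _GSC
        * dr
        * (ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )
    ra_mm = 0.408 * ra_mj
    tmean = 0.5 * (tmax + tmin)
    return max(0.0, 0.0023 * ra_mm * (tmean + 17.8) * math.sqrt(tmax - tmin))


def simulate_water_season(
    weather: pd.DataFrame,
    soil: SoilHydroParams,
    policy: IrrigationPolicy,
    transplant,
    harvest,
    latitude: float = 30.0,
    initial_pd: float | None = None,
) -> pd.DataFrame:
    """Simulate the ponding-water balance from transplanting to harvest.

    ``weather`` must cover [transplant, harvest] with no gaps; returns one row
    per day with day index (days after transplanting), depth and fluxes.
    """
    transplant = pd.Timestamp(transplant)
    harvest = pd.Timestamp(harvest)
    if harvest <= transplant:
        raise WaterError("harvest must follow transplant")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    w = w.set_index("date")
    expected = pd.date_range(transplant, harvest, freq="D")
    missing = expected.difference(w.index)
    if len(missing):
        raise WaterError(f"weather gap: missing date {missing[0].date()}")
    season = w.loc[expected]

    depth = policy.pd_target if initial_pd is None else float(initial_pd)
    records = []
    for day, (date, row) in enumerate(season.iterrows(), start=1):
        et0 = row["et0"] if "et0" in season.columns and not pd.isna(row.get("et0")) else None
        e0 = reference_et(
            row.get("tmax"), row.get("tmin"), int(date.dayofyear), latitude, et0=et0
        )
        rec = step_water_balance(
            depth, float(row["prcp"]), soil.kc_at(day) * e0, soil, policy, day
        )
        depth = rec.pd
        records.append(rec)
    frame = pd.DataFrame([r.__dict__ for r in records])
    frame.insert(1, "date", expected)
    return frame
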