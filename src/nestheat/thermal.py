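"""Weather-station and black-bulb (operative temperature) processing.

Operative temperature (Te), logged by matte-black copper spheres placed in
nests, integrates air temperature, solar radiation and convection into a
single index of thermal load at the nest microsite. This module calibrates
the loggers, synchronizes them with the weather station on a 10-min grid,
summarizes weather into the daily covariates used downstream (daily maxima,
absolute humidity at the time of the daily maximum, antecedent rainfall,
incubation-period means) and counts exceedances of embryo-risk thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date, time as Time, timedelta

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    CoverageError,
    InsufficientCalibrationError,
    InvalidInputError,
)

log = logging.getLogger(__name__)

#: default daytime observation window (inclusive)
DAYTIME_START = Time(6, 0)
DAYTIME_END = Time(19, 0)
#: embryo-risk operative-temperature thresholds, degC
DEFAULT_EXCEEDANCE_THRESHOLDS = (41.0, 50.0)
#: antecedent-rain window: 61 calendar days ending the day before
RAIN_WINDOW_DAYS = 61

# Magnus saturation vapour pressure coefficients over water
_MAGNUS_A = 610.94  # Pa
_MAGNUS_B = 17.27
_MAGNUS_C = 237.7  # degC
_R_V = 461.5  # J kg^-1 K^-1, specific gas constant of water vapour


@dataclass(frozen=True)
class Calibration:
    """Linear map from logger reading to reference temperature."""

    slope: float
    intercept: float
    residual_sd: float
    n_pairs: int

    def apply(self, te_raw):
        return self.slope * np.asarray(te_raw, dtype=float) + self.intercept


def calibrate_logger(pairs, min_pairs: int = 3, min_span: float = 10.0) -> Calibration:
    """Least-squares line mapping logger degC to reference degC.

    ``pairs`` is an iterable of (logger, reference) water-bath readings;
    at least ``min_pairs`` points spanning ``min_span`` degC are required.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < min_pairs:
        raise InsufficientCalibrationError(
            f"need >= {min_pairs} (logger, reference) pairs"
        )
    logger_t, ref_t = arr[:, 0], arr[:, 1]
    if np.ptp(logger_t) < min_span:
        raise InsufficientCalibrationError(
            f"calibration span {np.ptp(logger_t):.1f} degC < {min_span} degC"
        )
    slope, intercept = np.polyfit(logger_t, ref_t, 1)
    resid = ref_t - (slope * logger_t + intercept)
    dof = max(len(resid) - 2, 1)
    return Calibration(
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n_pairs=len(resid),
    )


def saturation_vapour_pressure(t_air):
    """Magnus approximation of e_s over water, Pa."""
    t = np.asarray(t_air, dtype=float)
    return _MAGNUS_A * np.exp(_MAGNUS_B * t / (t + _MAGNUS_C))


def absolute_humidity(t_air, rh):
    """Absolute humidity (g m^-3) from air temperature (degC) and RH (%)."""
    t = np.asarray(t_air, dtype=float)
    r = np.asarray(rh, dtype=float)
    if np.any((t < -20) | (t > 60)):
        raise InvalidInputError("t_air outside [-20, 60] degC")
    if np.any((r < 0) | (r > 100)):
        raise InvalidInputError("rh outside [0, 100] %")
    e = saturation_vapour_pressure(t) * (r / 100.0)
    ah = e / (_R_V * (t + 273.15)) * 1000.0  # kg m^-3 -> g m^-3
    return float(ah) if np.isscalar(t_air) else ah


def daily_summaries(weather: pd.DataFrame) -> pd.DataFrame:
    """Daily covariates from a sub-hourly weather stream.

    Expects columns datetime, t_air, rh, solar, wind, rain_mm. Returns one
    row per day with t_max, sol_max, wind_max, abshum_tmax (absolute
    humidity at the first timestamp achieving t_max) and rain_prior_2mo
    (rain summed over the 61 days ending the day before). Days with no
    records are omitted with a logged warning.
    """
    w = weather.copy()
    w["datetime"] = pd.to_datetime(w["datetime"])
    w = w.sort_values("datetime", kind="stable").reset_index(drop=True)
    w["date"] = w["datetime"].dt.date
    if w.empty:
        raise InvalidInputError("empty weather stream")

    rows = []
    for day, grp in w.groupby("date", sort=True):
        if grp["t_air"].isna().all():
            log.warning("day %s has no usable records; omitted", day)
            continue
        imax = grp["t_air"].idxmax()  # first occurrence on ties
        rows.append(
            {
                "date": day,
                "t_max": float(grp.loc[imax, "t_air"]),
                "sol_max": float(grp["solar"].max()),
                "wind_max": float(grp["wind"].max()),
                "abshum_tmax": absolute_humidity(
                    float(grp.loc[imax, "t_air"]), float(grp.loc[imax, "rh"])
                ),
            }
        )
    daily = pd.DataFrame(rows)

    # antecedent rain on a continuous calendar so missing days count as 0
    rain_by_day = w.groupby("date")["rain_mm"].sum()
    idx = pd.date_range(rain_by_day.index.min(), rain_by_day.index.max(), freq="D")
    rain = rain_by_day.reindex(idx.date, fill_value=0.0)
    rain.index = idx
    prior = rain.rolling(RAIN_WINDOW_DAYS, min_periods=1).sum().shift(1)
    daily["rain_prior_2mo"] = [
        float(prior.get(pd.Timestamp(d), 0.0) if not pd.isna(prior.get(pd.Timestamp(d), np.nan)) else 0.0)
        for d in daily["date"]
    ]
    return daily


def incubation_period_means(
    daily: pd.DataFrame, start: Date, end: Date, nest_id: str | None = None
) -> dict:
    """Mean daily covariates over a closed incubation date range.

    Raises :class:`CoverageError` (listing the gaps) if any date in
    [start, end] is missing from ``daily``.
    """
    if start > end:
        raise InvalidInputError("start must be <= end")
    have = set(pd.to_datetime(daily["date"]).dt.date)
    wanted = [start + timedelta(days=i) for i in range((end - start).days + 1)]
    gaps = [d for d in wanted if d not in have]
    if gaps:
        raise CoverageError(f"{len(gaps)} uncovered dates in [{start}, {end}]", gaps)
    sel = daily[pd.to_datetime(daily["date"]).dt.date.isin(set(wanted)).values]
    return {
        "nest_id": nest_id,
        "mean_tmax_inc": float(sel["t_max"].mean()),
        "mean_solmax_inc": float(sel["sol_max"].mean()),
        "mean_windmax_inc": float(sel["wind_max"].mean()),
        "mean_abshum_tmax_inc": float(sel["abshum_tmax"].mean()),
        "n_days": len(sel),
    }


def daytime_mask(datetimes, start: Time = DAYTIME_START, end: Time = DAYTIME_END):
    """Boolean mask for timestamps inside the daytime window (inclusive)."""
    t = pd.to_datetime(pd.Series(datetimes)).dt.time
    return ((t >= start) & (t <= end)).to_numpy()


def align_te_weather(
    te: pd.DataFrame,
    weather: pd.DataFrame,
    daytime: tuple[Time, Time] = (DAYTIME_START, DAYTIME_END),
    tolerance: str = "5min",
) -> pd.DataFrame:
    """Pair daytime Te records with the nearest weather record in time.

    Each daytime Te record is matched to the weather record nearest in time
    within ``tolerance`` (half the nominal 10-min logging interval by
    default); unmatched records are dropped with a logged count.
    """
    te = te.copy()
    te["datetime"] = pd.to_datetime(te["datetime"])
    w = weather.copy()
    w["datetime"] = pd.to_datetime(w["datetime"])
    te = te[daytime_mask(te["datetime"], *daytime)]
    te = te.sort_values("datetime", kind="stable")
    w = w.sort_values("datetime", kind="stable")
    merged = pd.merge_asof(
        te,
        w[["datetime", "t_air"]].rename(columns={"datetime": "weather_datetime"}),
        left_on="datetime",
        right_on="weather_datetime",
        direction="nearest",
        tolerance=pd.Timedelta(tolerance),
    )
    n_dropped = int(merged["t_air"].isna().sum())
    if n_dropped:
        log.info("dropped %d Te records with no weather match", n_dropped)
    merged = merged.dropna(subset=["t_air"]).reset_index(drop=True)
    if merged.empty:
        raise AlignmentError("no Te/weather pairs within tolerance")
    return merged


def exceedance_stats(
    te: pd.DataFrame,
    thresholds=DEFAULT_EXCEEDANCE_THRESHOLDS,
    value_col: str = "te_cal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of Te records strictly above each embryo-risk threshold.

    Returns (per-nest table, fleet summary). The per-nest table has one row
    per (nest_id, threshold) with the count and the proportion of that
    nest's records; the summary aggregates counts across nests (total, mean,
    median, min, max, nests affected).
    """
    rows = []
    for nest, grp in te.groupby("nest_id", sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        for thr in thresholds:
            count = int(np.sum(vals > thr))
            rows.append(
                {
                    "nest_id": nest,
                    "threshold": float(thr),
                    "count": count,
                    "n_records": len(vals),
                    "proportion": count / len(vals) if len(vals) else float("nan"),
                }
            )
    per_nest = pd.DataFrame(rows)
    summaries = []
    for thr in thresholds:
        sub = per_nest[per_nest["threshold"] == thr]
        counts = sub["count"].to_numpy()
        summaries.append(
            {
                "threshold": float(thr),
                "total": int(counts.sum()),
                "n_nests_affected": int((counts > 0).sum()),
                "n_nests": len(counts),
                "mean_per_nest": float(counts.mean()) if len(counts) else float("nan"),
                "median_per_nest": float(np.median(counts)) if len(counts) else float("nan"),
                "min_per_nest": int(counts.min()) if len(counts) else 0,
                "max_per_nest": int(counts.max()) if len(counts) else 0,
                "proportion_of_records": float(
                    counts.sum() / sub["n_records"].sum()
                )
                if sub["n_records"].sum()
                else float("nan"),
            }
        )
    return per_nest, pd.DataFrame(summaries)
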