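"""Synthetic field-data generator with known ground truth.

Emulates every input stream of the pipeline for an arid-zone cooperatively
breeding passerine study: exponential isotope washout with measurement
noise, a diel air-temperature cycle with a seasonal trend, black-bulb nest
operative temperatures elevated above and linearly related to air
temperature, temperature-dependent nest attendance carved into incubation
bouts and recesses, logistic temperature-dependent hatching, and segmented
temperature-dependent overnight body-mass change. Every output is a pure
function of (config, seed), and the generating parameters are returned as
ground truth so each analysis stage can be scored for parameter recovery.

Defaults reflect the study conditions the generator emulates: daily maxima
around 34.1 +/- 4.5 degC (range 20.7-40.8), nest Te rising 1.207 degC per
degC of air temperature, a 50%-hatching threshold of 35.3 degC, and a
body-mass breakpoint at 36.1 degC with slope -1.016 g/degC above it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import date as Date, datetime, time as Time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import InvalidInputError
from .isotope import DEFAULT_BODY_WATER_FRACTION, MOLAR_MASS_WATER
from .thermal import DAYTIME_END, DAYTIME_START

# ---------------------------------------------------------------------------
# configuration


@dataclass
class WashoutConfig:
    """Isotope washout: single-pool exponential decay per isotope."""

    n_birds: int = 70
    kH_mean: float = 0.45  # deuterium turnover, per day
    kH_sd: float = 0.05
    k_diff_mean: float = 0.08  # kO - kH, per day
    k_diff_sd: float = 0.012
    mass_mean: float = 75.8  # grams
    mass_sd: float = 5.3  # CV ~ 0.07
    body_water_fraction: float = DEFAULT_BODY_WATER_FRACTION
    dose_excess_d2H: float = 1000.0  # per-mil above background at t = 0
    dose_excess_d18O: float = 1200.0
    background_d2H: float = 10.0
    background_d18O: float = 2.0
    noise_sd: float = 5.0  # per-mil measurement noise
    sample_times: tuple = (0.05, 0.2, 0.4, 0.6, 0.8, 1.0)  # days post-dose


@dataclass
class WeatherConfig:
    """Diel cycle + seasonal trend; daily maxima truncated to observed range."""

    n_days: int = 120
    start_date: str = "2017-10-01"
    tmax_mean: float = 34.1
    tmax_sd: float = 4.5
    tmax_min: float = 20.7
    tmax_max: float = 40.8
    seasonal_amplitude: float = 3.0  # degC swing of the daily-max mean
    diel_amplitude: float = 12.0  # dawn-to-peak swing within a day
    peak_hour: float = 15.0
    step_minutes: int = 10
    rh_base: float = 35.0
    rh_temp_coupling: float = 1.5  # % RH lost per degC above the mean
    rh_noise_sd: float = 5.0
    sol_max_mean: float = 999.0
    sol_max_sd: float = 150.0
    wind_max_mean: float = 4.2
    wind_max_sd: float = 1.4
    rain_prob: float = 0.08  # per-day probability of any rain
    rain_mean_mm: float = 8.0


@dataclass
class TeConfig:
    """Nest operative temperature: Te = a + b*Tair + nest offset + noise."""

    n_nests: int = 23
    days_per_nest: int = 12
    slope: float = 1.207
    intercept: float = 0.5
    noise_sd: float = 2.0
    nest_offset_sd: float = 4.0  # between-nest microsite spread
    cal_slope: float = 1.02  # factory miscalibration applied in reverse
    cal_intercept: float = 0.5


@dataclass
class BreedingConfig:
    """Hatching, attendance and body-mass models driven by daily Tmax."""

    n_nests: int = 99
    n_obs_days: int = 46
    n_mass_birds: int = 119
    incubation_days: tuple = (13, 15)
    group_size_range: tuple = (3, 6)
    # hatch: p = logistic(slope * (MeanTmaxInc - t50))
    hatch_t50: float = 35.3
    hatch_slope_per_degC: float = -0.45
    # attendance: logit(p) = a + b * (Tmax - ref) + noise
    attendance_intercept: float = 4.6
    attendance_slope: float = -0.35
    attendance_ref_temp: float = 34.1
    attendance_logit_sd: float = 0.6
    # overnight mass change: flat below breakpoint, linear decline above
    mass_breakpoint: float = 36.1
    mass_slope_above: float = -1.016
    mass_resid_sd: float = 2.0
    dawn_earliest: str = "05:00"
    dawn_latest: str = "06:48"
    obs_end: str = "19:00"
    # focals: ~4 x 20-min observations per 2-h session, 6 sessions/day
    focals_per_day: int = 23
    focal_duration_s: int = 1200


@dataclass
class SimulationConfig:
    """Everything needed to generate a full input bundle."""

    washout: WashoutConfig = field(default_factory=WashoutConfig)
    weather: WeatherConfig = field(default_factory=WeatherConfig)
    te: TeConfig = field(default_factory=TeConfig)
    breeding: BreedingConfig = field(default_factory=BreedingConfig)


@dataclass
class GroundTruth:
    """Generating parameters and per-entity true values for scoring recovery."""

    params: dict
    birds: pd.DataFrame | None = None
    nests: pd.DataFrame | None = None
    te_exceedance: pd.DataFrame | None = None
    attendance: pd.DataFrame | None = None
    focals: pd.DataFrame | None = None

    def to_json(self, path):
        payload = {"params": self.params}
        for name in ("birds", "nests", "te_exceedance", "attendance", "focals"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.to_dict(orient="records")
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


# ---------------------------------------------------------------------------
# isotope washout


def simulate_washout(
    config: WashoutConfig, seed, dose_datetimes=None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Isotope samples for ``n_birds`` bird-days plus per-bird ground truth.

    Per isotope, delta(t) = background + excess * exp(-k t) with additive
    Gaussian per-mil noise. Requires kO > kH > 0 (the oxygen pool turns over
    faster because CO2 production drains it on top of water efflux).
    """
    if config.kH_mean <= 0 or config.k_diff_mean <= 0:
        raise InvalidInputError("need kO > kH > 0")
    rng = np.random.default_rng(seed)
    n = config.n_birds
    kH = np.maximum(rng.normal(config.kH_mean, config.kH_sd, n), 1e-3)
    k_diff = np.maximum(rng.normal(config.k_diff_mean, config.k_diff_sd, n), 1e-4)
    kO = kH + k_diff
    mass = np.maximum(rng.normal(config.mass_mean, config.mass_sd, n), 40.0)
    W = config.body_water_fraction * mass
    N = W / MOLAR_MASS_WATER

    rows = []
    times = np.asarray(config.sample_times, dtype=float)
    for i in range(n):
        bird = f"dlw{i:03d}"
        dose_dt = None if dose_datetimes is None else dose_datetimes[i]

        def stamp(t_days):
            if dose_dt is None:
                return None
            return dose_dt + timedelta(days=float(t_days))

        rows.append(
            {
                "bird_id": bird,
                "t": -0.02,
                "datetime": stamp(-0.02),
                "d18O": config.background_d18O + rng.normal(0, config.noise_sd / 5),
                "d2H": config.background_d2H + rng.normal(0, config.noise_sd / 5),
                "is_background": True,
            }
        )
        for t in times:
            rows.append(
                {
                    "bird_id": bird,
                    "t": float(t),
                    "datetime": stamp(t),
                    "d18O": config.background_d18O
                    + config.dose_excess_d18O * np.exp(-kO[i] * t)
                    + rng.normal(0, config.noise_sd),
                    "d2H": config.background_d2H
                    + config.dose_excess_d2H * np.exp(-kH[i] * t)
                    + rng.normal(0, config.noise_sd),
                    "is_background": False,
                }
            )
    samples = pd.DataFrame(rows)

    rco2 = (N / 2.078) * k_diff - 0.0062 * kH * N
    dee_total = 27.42 * 22.4 * rco2
    truth_birds = pd.DataFrame(
        {
            "bird_id": [f"dlw{i:03d}" for i in range(n)],
            "kH": kH,
            "kO": kO,
            "k_diff": k_diff,
            "mass_g": mass,
            "N_mol": N,
            "dee_total": dee_total,
            "dee_per_g": dee_total / mass,
            "efflux": 1000.0 * kH * W / mass,  # constant-pool analytic value
        }
    )
    return samples, GroundTruth(params=asdict(config), birds=truth_birds)


# ---------------------------------------------------------------------------
# weather


def _truncnorm_location(target: float, sd: float, lo: float, hi: float) -> float:
    """Pre-truncation location whose truncated-normal mean equals ``target``."""
    target = min(max(target, lo + 0.25 * sd), hi - 0.25 * sd)

    def f(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return truncnorm.mean(a, b, loc=mu, scale=sd) - target

    return brentq(f, lo - 2 * sd, hi + 6 * sd, xtol=1e-6)


def simulate_weather(config: WeatherConfig, seed) -> pd.DataFrame:
    """Sub-hourly weather records over ``n_days``.

    Daily maxima are truncated-normal draws (location corrected so the
    realized mean matches ``tmax_mean`` despite the asymmetric truncation)
    around a sinusoidal seasonal trend; within each day the air temperature
    follows a cosine rising from dawn to ``peak_hour``. Relative humidity
    is inversely coupled to temperature; solar follows a clipped half-sine;
    rain falls in whole-day events.
    """
    rng = np.random.default_rng(seed)
    c = config
    start = pd.Timestamp(c.start_date)
    season_phase = rng.uniform(0, 2 * np.pi)
    day_idx = np.arange(c.n_days)
    seasonal = c.seasonal_amplitude * np.sin(
        2 * np.pi * day_idx / max(c.n_days, 1) + season_phase
    )

    loc_cache: dict[float, float] = {}
    tmax = np.empty(c.n_days)
    for i, s in enumerate(seasonal):
        key = round(c.tmax_mean + s, 2)
        if key not in loc_cache:
            loc_cache[key] = _truncnorm_location(key, c.tmax_sd, c.tmax_min, c.tmax_max)
        mu = loc_cache[key]
        a, b = (c.tmax_min - mu) / c.tmax_sd, (c.tmax_max - mu) / c.tmax_sd
        tmax[i] = truncnorm.rvs(a, b, loc=mu, scale=c.tmax_sd, random_state=rng)

    sol_max = np.clip(rng.normal(c.sol_max_mean, c.sol_max_sd, c.n_days), 186, 1383)
    wind_max = np.clip(rng.normal(c.wind_max_mean, c.wind_max_sd, c.n_days), 0.1, 8.9)
    rain_day = np.where(
        rng.random(c.n_days) < c.rain_prob,
        rng.exponential(c.rain_mean_mm, c.n_days),
        0.0,
    )

    steps = int(24 * 60 / c.step_minutes)
    hours = np.arange(steps) * c.step_minutes / 60.0
    diel = (1.0 - np.cos(2 * np.pi * (hours - c.peak_hour) / 24.0)) / 2.0  # 1 at peak
    solar_shape = np.clip(np.sin(np.pi * (hours - 6.0) / 13.0), 0.0, None) ** 1.5

    frames = []
    for i in range(c.n_days):
        t_air = tmax[i] - c.diel_amplitude * (1.0 - diel)
        rh = np.clip(
            c.rh_base
            - c.rh_temp_coupling * (t_air - c.tmax_mean)
            + rng.normal(0, c.rh_noise_sd, steps),
            2.0,
            100.0,
        )
        wind = wind_max[i] * np.clip(rng.uniform(0.2, 1.0, steps), 0, None)
        rain = np.zeros(steps)
        rain[0] = rain_day[i]
        frames.append(
            pd.DataFrame(
                {
                    "datetime": start + pd.Timedelta(days=i) + pd.to_timedelta(hours, "h"),
                    "t_air": t_air,
                    "rh": rh,
                    "solar": sol_max[i] * solar_shape,
                    "wind": wind,
                    "rain_mm": rain,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# nest operative temperature


def simulate_nest_te(
    weather: pd.DataFrame, config: TeConfig, seed
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Black-bulb records, calibration pairs, and true exceedance counts.

    True Te = intercept + slope*Tair + nest offset + noise, clipped so
    daytime Te >= Tair (a black sphere in a nest never reads below air
    temperature while the sun is up). Raw logger values are the true values
    passed backwards through the linear miscalibration, so a calibration
    against the emitted (noise-free) water-bath pairs recovers truth
    exactly. Exceedance truth counts daytime records above 41 and 50 degC.
    """
    rng = np.random.default_rng(seed)
    c = config
    w = weather.copy()
    w["datetime"] = pd.to_datetime(w["datetime"])
    days = sorted(w["datetime"].dt.date.unique())
    offsets = rng.normal(0.0, c.nest_offset_sd, c.n_nests)

    frames = []
    truth_rows = []
    for j in range(c.n_nests):
        nest = f"nest{j:02d}"
        if len(days) > c.days_per_nest:
            start = int(rng.integers(0, len(days) - c.days_per_nest))
        else:
            start = 0
        chosen = set(days[start : start + c.days_per_nest])
        sub = w[w["datetime"].dt.date.isin(chosen)].copy()
        te_true = (
            c.intercept
            + c.slope * sub["t_air"].to_numpy()
            + offsets[j]
            + rng.normal(0, c.noise_sd, len(sub))
        )
        tt = sub["datetime"].dt.time
        day_mask = ((tt >= DAYTIME_START) & (tt <= DAYTIME_END)).to_numpy()
        te_true = np.where(day_mask, np.maximum(te_true, sub["t_air"].to_numpy()), te_true)
        frames.append(
            pd.DataFrame(
                {
                    "nest_id": nest,
                    "datetime": sub["datetime"].to_numpy(),
                    "te_raw": (te_true - c.cal_intercept) / c.cal_slope,
                }
            )
        )
        day_vals = te_true[day_mask]
        truth_rows.append(
            {
                "nest_id": nest,
                "n_daytime_records": int(day_mask.sum()),
                "count_gt_41": int(np.sum(day_vals > 41.0)),
                "count_gt_50": int(np.sum(day_vals > 50.0)),
            }
        )
    te = pd.concat(frames, ignore_index=True)

    logger_vals = np.arange(5.0, 51.0, 5.0)
    calibration = pd.DataFrame(
        {
            "logger": logger_vals,
            "reference": c.cal_slope * logger_vals + c.cal_intercept,
        }
    )
    return te, calibration, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# breeding: nests, bouts, masses, focals


def _carve_day(rng, nest, day, dawn, end, p_incubated):
    """Split one observation window into contiguous bouts and recesses.

    The unattended total is exactly (1 - p) * window; it is split into a
    Poisson-drawn number of recesses interleaved with bouts at Dirichlet-
    random positions, so attendance metrics recover p to float precision.
    """
    total = (end - dawn).total_seconds()
    unatt = (1.0 - p_incubated) * total
    rows = []
    if unatt < 30.0:
        rows.append((nest, day, dawn, end, "incubation"))
        return rows, 0
    n_rec = 1 + int(rng.poisson(min(6.0, unatt / 600.0)))
    rec_parts = rng.dirichlet(np.ones(n_rec)) * unatt
    bout_parts = rng.dirichlet(np.ones(n_rec + 1)) * (total - unatt)
    cursor = dawn
    for i in range(n_rec):
        b_end = cursor + timedelta(seconds=float(bout_parts[i]))
        rows.append((nest, day, cursor, b_end, "incubation"))
        r_end = b_end + timedelta(seconds=float(rec_parts[i]))
        rows.append((nest, day, b_end, r_end, "recess"))
        cursor = r_end
    rows.append((nest, day, cursor, end, "incubation"))
    return rows, n_rec


def simulate_breeding(
    weather: pd.DataFrame, config: BreedingConfig, seed
) -> tuple[dict, GroundTruth]:
    """Nest outcomes, bout logs, dawn masses and focals from daily weather.

    Returns ``(tables, truth)`` where ``tables`` holds DataFrames ``nests``,
    ``bouts``, ``masses`` and ``focals``.
    """
    rng = np.random.default_rng(seed)
    c = config
    w = weather.copy()
    w["datetime"] = pd.to_datetime(w["datetime"])
    daily_tmax = w.groupby(w["datetime"].dt.date)["t_air"].max()
    days = list(daily_tmax.index)
    if len(days) < max(c.incubation_days) + 2:
        raise InvalidInputError("weather series too short for an incubation period")

    # --- nest outcomes -----------------------------------------------------
    nest_rows, truth_nest_rows = [], []
    max_start = len(days) - max(c.incubation_days) - 1
    for j in range(c.n_nests):
        nest = f"brood{j:03d}"
        s = int(rng.integers(0, max_start + 1))
        dur = int(rng.integers(c.incubation_days[0], c.incubation_days[1] + 1))
        period = days[s : s + dur + 1]
        mean_tmax = float(np.mean([daily_tmax[d] for d in period]))
        p_hatch = float(expit(c.hatch_slope_per_degC * (mean_tmax - c.hatch_t50)))
        hatched = bool(rng.random() < p_hatch)
        nest_rows.append(
            {
                "nest_id": nest,
                "group_size": int(rng.integers(c.group_size_range[0], c.group_size_range[1] + 1)),
                "incubation_start": period[0],
                "end_date": period[-1],
                "outcome": "hatched" if hatched else "failed",
            }
        )
        truth_nest_rows.append(
            {"nest_id": nest, "mean_tmax_inc": mean_tmax, "p_hatch": p_hatch}
        )

    # --- observation days: bouts + focals ---------------------------------
    dawn_lo = datetime.strptime(c.dawn_earliest, "%H:%M").time()
    dawn_hi = datetime.strptime(c.dawn_latest, "%H:%M").time()
    end_t = datetime.strptime(c.obs_end, "%H:%M").time()
    dawn_span_s = (
        datetime.combine(Date(2000, 1, 1), dawn_hi)
        - datetime.combine(Date(2000, 1, 1), dawn_lo)
    ).total_seconds()

    bout_rows, truth_att_rows = [], []
    focal_rows, truth_focal_rows = [], []
    seen_nest_days: set = set()
    k = 0
    attempts = 0
    while k < c.n_obs_days and attempts < 50 * c.n_obs_days:
        attempts += 1
        nr = nest_rows[int(rng.integers(0, len(nest_rows)))]
        start_d, end_d = nr["incubation_start"], nr["end_date"]
        span = (end_d - start_d).days
        day = start_d + timedelta(days=int(rng.integers(0, span + 1)))
        if (nr["nest_id"], day) in seen_nest_days:
            continue
        seen_nest_days.add((nr["nest_id"], day))
        tmax = float(daily_tmax.get(day, daily_tmax.iloc[0]))
        logit_p = (
            c.attendance_intercept
            + c.attendance_slope * (tmax - c.attendance_ref_temp)
            + rng.normal(0, c.attendance_logit_sd)
        )
        p = float(expit(logit_p))
        dawn = datetime.combine(day, dawn_lo) + timedelta(
            seconds=float(rng.uniform(0, dawn_span_s))
        )
        end = datetime.combine(day, end_t)
        rows, n_rec = _carve_day(rng, nr["nest_id"], day, dawn, end, p)
        total = (end - dawn).total_seconds()
        inc = sum((r[3] - r[2]).total_seconds() for r in rows if r[4] == "incubation")
        bout_rows.extend(rows)
        truth_att_rows.append(
            {
                "nest_id": nr["nest_id"],
                "date": day,
                "tmax": tmax,
                "p_model": p,
                "prop_incubated_true": inc / total,
                "n_recesses_true": n_rec,
            }
        )

        # focal time budget for one dosed bird on this day
        bird = f"dlw{k:03d}"
        frac = float(np.clip(p + rng.normal(0, 0.05), 0.02, 0.98))
        tot_target = 0.0
        tot_all = 0.0
        for fidx in range(c.focals_per_day):
            inc_s = max(1.0, round(frac * c.focal_duration_s))
            rest = c.focal_duration_s - inc_s
            forage = max(1.0, round(rest * 0.7))
            other = max(1.0, rest - forage)
            for label, dur in (("incubating", inc_s), ("foraging", forage), ("other", other)):
                focal_rows.append(
                    {
                        "bird_id": bird,
                        "date": day,
                        "behaviour_label": label,
                        "duration": float(dur),
                    }
                )
            tot_target += inc_s
            tot_all += inc_s + forage + other
        truth_focal_rows.append(
            {"bird_id": bird, "date": day, "fraction_incubating": tot_target / tot_all}
        )
        k += 1

    bouts = pd.DataFrame(
        bout_rows, columns=["nest_id", "date", "start", "end", "kind"]
    )

    # --- overnight body-mass change ----------------------------------------
    mass_rows = []
    mass_days = [days[int(i)] for i in rng.integers(0, len(days) - 1, c.n_mass_birds)]
    for i, day in enumerate(mass_days):
        tmax = float(daily_tmax[day])
        mu = (
            c.mass_slope_above * (tmax - c.mass_breakpoint)
            if tmax >= c.mass_breakpoint
            else 0.0
        )
        dm = mu + rng.normal(0, c.mass_resid_sd)
        m1 = float(rng.normal(75.8, 5.3))
        bird = f"mass{i:03d}"
        mass_rows.append({"bird_id": bird, "date": day, "mass_g": m1})
        mass_rows.append(
            {"bird_id": bird, "date": day + timedelta(days=1), "mass_g": m1 + dm}
        )
    masses = pd.DataFrame(mass_rows)

    tables = {
        "nests": pd.DataFrame(nest_rows),
        "bouts": bouts,
        "masses": masses,
        "focals": pd.DataFrame(focal_rows),
    }
    truth = GroundTruth(
        params=asdict(c),
        nests=pd.DataFrame(truth_nest_rows),
        attendance=pd.DataFrame(truth_att_rows),
        focals=pd.DataFrame(truth_focal_rows),
    )
    return tables, truth


# ---------------------------------------------------------------------------
# full bundle


def simulate_bundle(config: SimulationConfig, seed, outdir=None):
    """Generate every pipeline input (and ground truth) from one seed.

    Stage streams are spawned from a single :class:`numpy.random.SeedSequence`
    so each stage is reproducible independently of the others. If ``outdir``
    is given, CSVs (weather, te_loggers, calibration, isotopes, masses,
    bouts, focals, nests) and ``ground_truth.json`` are written there.
    """
    ss = np.random.SeedSequence(seed)
    s_weather, s_te, s_breeding, s_washout, s_dlw_mass = ss.spawn(5)

    weather = simulate_weather(config.weather, s_weather)
    te, calibration, te_truth = simulate_nest_te(weather, config.te, s_te)
    tables, breeding_truth = simulate_breeding(weather, config.breeding, s_breeding)

    # dose each DLW bird at 07:00 on a cycling observation day
    w_days = sorted(pd.to_datetime(weather["datetime"]).dt.date.unique())
    obs_days = sorted(set(tables["bouts"]["date"])) or w_days
    dose_dts = [
        datetime.combine(obs_days[i % len(obs_days)], Time(7, 0))
        for i in range(config.washout.n_birds)
    ]
    isotopes, washout_truth = simulate_washout(config.washout, s_washout, dose_dts)

    # dawn masses for the dosed birds; overnight change follows the same
    # segmented mass model (washout truth uses the day-1 mass for the pool)
    rng_m = np.random.default_rng(s_dlw_mass)
    daily_tmax = weather.groupby(pd.to_datetime(weather["datetime"]).dt.date)[
        "t_air"
    ].max()
    bc = config.breeding
    dlw_mass_rows = []
    for i, row in washout_truth.birds.iterrows():
        d0 = dose_dts[i].date()
        tmax0 = float(daily_tmax.get(d0, daily_tmax.iloc[0]))
        mu = (
            bc.mass_slope_above * (tmax0 - bc.mass_breakpoint)
            if tmax0 >= bc.mass_breakpoint
            else 0.0
        )
        dm = mu + rng_m.normal(0, bc.mass_resid_sd)
        dlw_mass_rows.append(
            {"bird_id": row["bird_id"], "date": d0, "mass_g": row["mass_g"]}
        )
        dlw_mass_rows.append(
            {
                "bird_id": row["bird_id"],
                "date": d0 + timedelta(days=1),
                "mass_g": row["mass_g"] + dm,
            }
        )
    masses = pd.concat(
        [tables["masses"], pd.DataFrame(dlw_mass_rows)], ignore_index=True
    )

    truth = GroundTruth(
        params={
            "seed": int(seed) if np.isscalar(seed) else None,
            "washout": asdict(config.washout),
            "weather": asdict(config.weather),
            "te": asdict(config.te),
            "breeding": asdict(config.breeding),
        },
        birds=washout_truth.birds,
        nests=breeding_truth.nests,
        te_exceedance=te_truth,
        attendance=breeding_truth.attendance,
        focals=breeding_truth.focals,
    )
    bundle = {
        "weather": weather,
        "te_loggers": te,
        "calibration": calibration,
        "isotopes": isotopes,
        "masses": masses,
        "bouts": tables["bouts"],
        "focals": tables["focals"],
        "nests": tables["nests"],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        truth.to_json(outdir / "ground_truth.json")
    return bundle, truth
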