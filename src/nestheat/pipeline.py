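"""End-to-end orchestration over a directory of CSV inputs.

Stage order mirrors the field workflow: thermal environment (weather and
nest loggers) -> incubation behaviour -> DLW energetics -> statistical
analysis (hatching threshold, attendance model, mass breakpoint, hot/cool
water-balance regressions, prey-water deficit). Each stage reads and writes
plain CSV; a manifest records the configuration hash, seed and row counts
so reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as bh
from . import isotope as iso
from . import stats as st
from . import thermal as th
from .errors import ConfigError, DataError, NestheatError

log = logging.getLogger(__name__)

#: Tmax at/above which a day counts as hot (critical threshold for this taxon)
HOT_DAY_THRESHOLD_C = 35.5
#: extreme-day windows used for the prey-water deficit
MWP_COOL_BELOW_C = 26.0
MWP_HOT_ABOVE_C = 39.0

ALL_STAGES = ("thermal", "behaviour", "dlw", "analyse")

_STAGE_INPUTS = {
    "thermal": ("weather.csv", "te_loggers.csv", "calibration.csv"),
    "behaviour": ("bouts.csv", "focals.csv"),
    "dlw": ("isotopes.csv", "masses.csv"),
    "analyse": ("nests.csv", "masses.csv", "weather.csv"),
}


@dataclass
class RunConfig:
    """Pipeline configuration: directories, stage toggles and parameters."""

    input_dir: str
    output_dir: str
    stages: tuple = ALL_STAGES
    seed: int = 0
    hot_day_threshold: float = HOT_DAY_THRESHOLD_C
    breakpoint_bootstrap_reps: int = 1000
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def validate(self):
        indir = Path(self.input_dir)
        if not indir.is_dir():
            raise ConfigError(f"input directory {indir} does not exist")
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ConfigError(f"unknown stage {stage!r}")
            for fname in _STAGE_INPUTS[stage]:
                if not (indir / fname).is_file():
                    raise ConfigError(f"stage {stage!r} requires missing {fname}")

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _read(indir: Path, name: str) -> pd.DataFrame:
    try:
        return pd.read_csv(indir / name)
    except Exception as exc:  # noqa: BLE001 - surfaced as a data error
        raise DataError(f"cannot read {name}: {exc}") from exc


def _write(df: pd.DataFrame, outdir: Path, name: str, counts: dict):
    path = outdir / name
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    counts[name] = len(df)


# ---------------------------------------------------------------------------
# stages


def thermal_stage(indir: Path, outdir: Path, counts: dict) -> dict:
    weather = _read(indir, "weather.csv")
    te = _read(indir, "te_loggers.csv")
    cal_pairs = _read(indir, "calibration.csv")
    cal = th.calibrate_logger(cal_pairs[["logger", "reference"]].to_numpy())
    te = te.copy()
    te["te_cal"] = np.round(cal.apply(te["te_raw"]), 10)

    daily = th.daily_summaries(weather)
    _write(daily.round(2), outdir, "daily_weather.csv", counts)

    pairs = th.align_te_weather(te, weather)
    _write(
        pairs[["nest_id", "datetime", "te_raw", "te_cal", "t_air"]].round(2),
        outdir,
        "te_pairs.csv",
        counts,
    )
    per_nest, summary = th.exceedance_stats(pairs)
    _write(per_nest, outdir, "te_exceedance.csv", counts)
    _write(summary, outdir, "te_exceedance_summary.csv", counts)
    return {"daily": daily, "pairs": pairs, "exceedance": per_nest, "calibration": cal}


def behaviour_stage(indir: Path, outdir: Path, counts: dict) -> dict:
    bouts = _read(indir, "bouts.csv")
    attendance = bh.attendance_table(bouts, coerce_gaps=True)
    _write(attendance, outdir, "attendance.csv", counts)
    focals = _read(indir, "focals.csv")
    budget = bh.focal_time_budget(focals)
    _write(budget, outdir, "time_budget.csv", counts)
    return {"attendance": attendance, "time_budget": budget}


def dlw_stage(indir: Path, outdir: Path, counts: dict) -> dict:
    isotopes = _read(indir, "isotopes.csv")
    masses = _read(indir, "masses.csv")
    results, excluded = dlw_results_table(isotopes, masses)
    _write(results, outdir, "dlw_results.csv", counts)
    for bird, reason in excluded:
        log.info("bird %s excluded from DLW results: %s", bird, reason)
    counts["dlw_excluded"] = len(excluded)
    return {"dlw": results}


def dlw_results_table(
    isotopes: pd.DataFrame, masses: pd.DataFrame
) -> tuple[pd.DataFrame, list]:
    """Run the DLW chain for every bird present in both tables.

    Sample times come from a ``t`` column (days since dose) if present,
    otherwise from ``datetime`` relative to the first post-dose sample.
    Returns (results, excluded) where ``excluded`` lists (bird_id, reason)
    for birds that could not be processed — no silent row loss.
    """
    results, excluded = [], []
    mass_by_bird = {
        bird: grp.sort_values("date") for bird, grp in masses.groupby("bird_id")
    }
    for bird, grp in isotopes.groupby("bird_id", sort=True):
        if bird not in mass_by_bird or len(mass_by_bird[bird]) < 2:
            excluded.append((bird, "missing dawn masses"))
            continue
        grp = grp.copy()
        if "t" not in grp.columns or grp["t"].isna().any():
            dt = pd.to_datetime(grp["datetime"])
            post = dt[~grp["is_background"].astype(bool)]
            t0 = post.min()
            grp["t"] = (dt - t0).dt.total_seconds() / 86400.0
        try:
            samples = [
                iso.EnrichmentSample(
                    bird_id=bird,
                    t=float(r.t),
                    d18O=float(r.d18O),
                    d2H=float(r.d2H),
                    is_background=bool(r.is_background),
                )
                for r in grp.itertuples()
            ]
            mrows = mass_by_bird[bird]
            body = iso.BodyRecord(
                bird_id=bird,
                M1=float(mrows["mass_g"].iloc[0]),
                M2=float(mrows["mass_g"].iloc[1]),
            )
            res = iso.analyse_bird_day(samples, body)
        except NestheatError as exc:
            excluded.append((bird, str(exc)))
            continue
        results.append(
            {
                "bird_id": bird,
                "date": mass_by_bird[bird]["date"].iloc[0],
                "N_mol": res.N,
                "rco2_mol": res.rco2_mol,
                "rco2_L": res.rco2_L,
                "dee_total": res.dee_total,
                "dee_per_g": res.dee_per_g,
                "efflux": res.efflux,
                "influx": res.influx,
                "water_balance": res.water_balance,
                "mwp": res.mwp,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(results), excluded


def analyse_stage(
    indir: Path,
    outdir: Path,
    counts: dict,
    seed: int = 0,
    hot_threshold: float = HOT_DAY_THRESHOLD_C,
    bootstrap_reps: int = 1000,
    staged: dict | None = None,
) -> dict:
    """Statistical layer: hatch threshold, attendance model, mass breakpoint,
    hot/cool water-balance regressions and the prey-water deficit."""
    staged = staged or {}
    daily = staged.get("daily")
    if daily is None:
        weather = _read(indir, "weather.csv")
        daily = th.daily_summaries(weather)
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    tmax_by_date = dict(zip(daily["date"], daily["t_max"]))
    thresholds = []

    # --- hatching vs incubation-period temperature -------------------------
    nests = _read(indir, "nests.csv")
    rows = []
    for r in nests.itertuples():
        start = pd.Timestamp(r.incubation_start).date()
        end = pd.Timestamp(r.end_date).date()
        try:
            means = th.incubation_period_means(daily, start, end, nest_id=r.nest_id)
        except NestheatError:
            continue
        rows.append(
            {
                "nest_id": r.nest_id,
                "hatched": 1.0 if r.outcome == "hatched" else 0.0,
                "mean_tmax_inc": means["mean_tmax_inc"],
                "group_size": float(r.group_size),
            }
        )
    hatch_df = pd.DataFrame(rows)
    hatch_t50 = float("nan")
    if len(hatch_df) >= 10:
        hatch_std, transform = st.standardize(hatch_df, ["mean_tmax_inc", "group_size"])
        candidates = [
            st.ModelSpec("hatched", "binomial", ["mean_tmax_inc"], hatch_std),
            st.ModelSpec("hatched", "binomial", ["group_size"], hatch_std),
            st.ModelSpec(
                "hatched", "binomial", ["mean_tmax_inc", "group_size"], hatch_std
            ),
        ]
        mset = st.model_selection(candidates)
        _write(mset.table().round(6), outdir, "model_tables/hatch.csv", counts)
        uni = next(
            f for f in mset.fits if list(f.spec.predictors) == ["mean_tmax_inc"]
        )
        hatch_t50 = st.threshold_from_logistic(uni, transform, "mean_tmax_inc")
        disp = st.dispersion_check(uni)
        thresholds.append(
            {
                "quantity": "hatch_t50_degC",
                "value": hatch_t50,
                "ci_lower": float("nan"),
                "ci_upper": float("nan"),
                "note": f"binomial-logit; dispersion={disp.ratio:.2f}",
            }
        )

    # --- attendance vs Tmax -------------------------------------------------
    att = staged.get("attendance")
    if att is None and (indir / "bouts.csv").is_file():
        att = bh.attendance_table(_read(indir, "bouts.csv"))
    if att is not None and len(att) >= 10:
        att = att.copy()
        att["date"] = pd.to_datetime(att["date"]).dt.date
        att["t_max"] = att["date"].map(tmax_by_date)
        att = att.dropna(subset=["t_max"])
        if len(att) >= 10:
            att["obs_minutes"] = (
                pd.to_datetime(att["obs_end"]) - pd.to_datetime(att["obs_start"])
            ).dt.total_seconds() / 60.0
            att_std, att_tr = st.standardize(att, ["t_max"])
            fit = st.fit_glm(
                st.ModelSpec(
                    "prop_incubated",
                    "binomial",
                    ["t_max"],
                    att_std,
                    weights="obs_minutes",
                )
            )
            _write(fit.coef_table().round(6), outdir, "model_tables/attendance.csv", counts)

    # --- body-mass breakpoint ----------------------------------------------
    masses = _read(indir, "masses.csv")
    masses = masses.copy()
    masses["date"] = pd.to_datetime(masses["date"]).dt.date
    dm_rows = []
    for bird, grp in masses.groupby("bird_id"):
        grp = grp.sort_values("date")
        if len(grp) < 2:
            continue
        d0 = grp["date"].iloc[0]
        if d0 not in tmax_by_date:
            continue
        dm_rows.append(
            {
                "bird_id": bird,
                "t_max": tmax_by_date[d0],
                "delta_mass": grp["mass_g"].iloc[1] - grp["mass_g"].iloc[0],
            }
        )
    dm = pd.DataFrame(dm_rows)
    bp = None
    if len(dm) >= 30:
        bp = st.fit_breakpoint(
            dm["t_max"],
            dm["delta_mass"],
            ci_bootstrap_reps=bootstrap_reps,
            seed=seed,
            xname="t_max",
            yname="delta_mass",
        )
        thresholds.append(
            {
                "quantity": "mass_breakpoint_degC",
                "value": bp.breakpoint,
                "ci_lower": bp.ci_lower,
                "ci_upper": bp.ci_upper,
                "note": f"above-slope={bp.above.params['t_max']:.3f}",
            }
        )
        seg = pd.concat(
            [
                bp.below.coef_table().assign(segment="below"),
                bp.above.coef_table().assign(segment="above"),
            ]
        )
        _write(seg.round(6), outdir, "model_tables/mass_segments.csv", counts)

    # --- DLW: water balance on hot vs cool days, prey-water deficit ---------
    dlw = staged.get("dlw")
    if dlw is None and (outdir / "dlw_results.csv").is_file():
        dlw = pd.read_csv(outdir / "dlw_results.csv")
    if dlw is not None and len(dlw) >= 10:
        dlw = dlw.copy()
        dlw["date"] = pd.to_datetime(dlw["date"]).dt.date
        dlw["t_max"] = dlw["date"].map(tmax_by_date)
        dlw = dlw.dropna(subset=["t_max"])

        budget = staged.get("time_budget")
        if budget is None and (outdir / "time_budget.csv").is_file():
            budget = pd.read_csv(outdir / "time_budget.csv")
        if budget is not None:
            budget = budget.copy()
            budget["date"] = pd.to_datetime(budget["date"]).dt.date
            joined = dlw.merge(
                budget[["bird_id", "date", "proportion"]], on=["bird_id", "date"]
            )
            wb_rows = []
            for label, sub in (
                ("overall", joined),
                ("cool", joined[joined["t_max"] < hot_threshold]),
                ("hot", joined[joined["t_max"] >= hot_threshold]),
            ):
                if len(sub) < 6:
                    continue
                fit = st.fit_glm(
                    st.ModelSpec(
                        "water_balance", "gaussian", ["proportion"], sub.reset_index()
                    )
                )
                wb_rows.append(
                    {
                        "response": "water_balance",
                        "subset": label,
                        "n": fit.n,
                        "estimate": fit.params["proportion"],
                        "se": fit.se["proportion"],
                        "ci_lower": fit.ci_lower["proportion"],
                        "ci_upper": fit.ci_upper["proportion"],
                    }
                )
            if wb_rows:
                _write(
                    pd.DataFrame(wb_rows).round(6),
                    outdir,
                    "model_tables/water_balance.csv",
                    counts,
                )

        cool = dlw[dlw["t_max"] < MWP_COOL_BELOW_C]["mwp"]
        hot = dlw[dlw["t_max"] > MWP_HOT_ABOVE_C]["mwp"]
        if len(cool) and len(hot):
            deficit_items = iso.prey_water_equivalents(cool.mean(), hot.mean())
            thresholds.append(
                {
                    "quantity": "prey_water_equivalents_items",
                    "value": float(deficit_items),
                    "ci_lower": float("nan"),
                    "ci_upper": float("nan"),
                    "note": f"mwp cool={cool.mean():.2f} hot={hot.mean():.2f} g/d",
                }
            )

    if thresholds:
        _write(pd.DataFrame(thresholds), outdir, "thresholds.csv", counts)
    return {"hatch_t50": hatch_t50, "breakpoint": bp, "thresholds": thresholds}


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    staged: dict = {}
    if "thermal" in config.stages:
        staged.update(thermal_stage(indir, outdir, counts))
    if "behaviour" in config.stages:
        staged.update(behaviour_stage(indir, outdir, counts))
    if "dlw" in config.stages:
        staged.update(dlw_stage(indir, outdir, counts))
    if "analyse" in config.stages:
        staged.update(
            analyse_stage(
                indir,
                outdir,
                counts,
                seed=config.seed,
                hot_threshold=config.hot_day_threshold,
                bootstrap_reps=config.breakpoint_bootstrap_reps,
                staged=staged,
            )
        )
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    staged["manifest"] = manifest
    return staged


def summarize_report(outdir) -> str:
    """One-page text summary of a report bundle; lists missing components."""
    outdir = Path(outdir)
    lines = ["nestheat pipeline summary", "=" * 25]
    missing = []

    def read(name):
        p = outdir / name
        if p.is_file():
            return pd.read_csv(p)
        missing.append(name)
        return None

    daily = read("daily_weather.csv")
    thr = read("thresholds.csv")
    dlw = read("dlw_results.csv")
    att = read("attendance.csv")
    exc = read("te_exceedance_summary.csv")

    if daily is not None:
        lines.append(
            f"weather: {len(daily)} days, Tmax mean {daily['t_max'].mean():.1f} degC"
            f" (range {daily['t_max'].min():.1f}-{daily['t_max'].max():.1f})"
        )
    if att is not None:
        lines.append(
            f"attendance: {len(att)} nest-days, median prop incubated"
            f" {att['prop_incubated'].median():.3f}"
        )
    if exc is not None:
        for r in exc.itertuples():
            lines.append(
                f"Te > {r.threshold:.0f} degC: {r.total} records"
                f" ({100 * r.proportion_of_records:.1f}% of records,"
                f" {r.n_nests_affected}/{r.n_nests} nests)"
            )
    if thr is not None:
        for r in thr.itertuples():
            lines.append(f"{r.quantity}: {r.value:.2f} [{r.note}]")
    if dlw is not None and daily is not None:
        dlw = dlw.copy()
        dlw["date"] = pd.to_datetime(dlw["date"]).dt.date
        tmax = dict(
            zip(pd.to_datetime(daily["date"]).dt.date, daily["t_max"])
        )
        dlw["t_max"] = dlw["date"].map(tmax)
        lines.append(
            f"DLW: {len(dlw)} bird-days, mean DEE {dlw['dee_per_g'].mean():.2f}"
            f" kJ/g/d, mean water balance {dlw['water_balance'].mean():.2f}"
        )
        for label, sub in (
            ("hot", dlw[dlw["t_max"] >= HOT_DAY_THRESHOLD_C]),
            ("cool", dlw[dlw["t_max"] < HOT_DAY_THRESHOLD_C]),
        ):
            if len(sub):
                frac = float((sub["water_balance"] < 1.0).mean())
                lines.append(
                    f"  {label} days (n={len(sub)}): {100 * frac:.0f}% below"
                    " neutral water balance"
                )
            else:
                lines.append(f"  {label} days: unavailable (no records)")
    if missing:
        lines.append("missing components: " + ", ".join(missing))
    return "\n".join(lines)
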