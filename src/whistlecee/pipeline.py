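"""End-to-end orchestration: geometry -> counting -> changepoints ->
ping-aligned response statistics -> models, with CSV/JSON reporting and a
run manifest recording every parameter and seed.

The module also ships the study's published per-experiment summary table
as a packaged fixture (``load_reference_table``) and two bundled
simulation scenarios: a null scenario (no acoustic response injected)
and a response scenario with a multiplicative whistle burst confined to
the ~5 s after each ping, which the analysis should detect at the 5-s
scale but not at the 10-min scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import changepoint as cpt
from . import counting, geometry, response
from .models import (
    ModelSpec,
    SelectionResult,
    backward_select,
    fit_model,
    pooled_t_test,
    welch_t_test,
)
from .synthetic import CEEMeta, SimConfig, SimulatedCEE, simulate_cee, write_cee_bundle

logger = logging.getLogger(__name__)


def load_reference_table() -> pd.DataFrame:
    """Published per-experiment summary table (transcribed): metadata,
    median/IQR whistle counts and changepoint counts by period."""
    with resources.files("whistlecee").joinpath("data/table1.csv").open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Study-level summaries

def summarize_study(meta: pd.DataFrame) -> dict:
    """Experiment-set summary: counts by type and subspecies, group sizes,
    received levels over sonar experiments, total baseline minutes
    (30 min per control)."""
    if len(meta) == 0:
        raise ValueError("no experiments to summarize")
    mfas = meta[meta["cee_type"] == "mfas"]
    control = meta[meta["cee_type"] == "control"]
    out = {
        "n_cee": int(len(meta)),
        "n_control": int(len(control)),
        "n_mfas": int(len(mfas)),
        "n_by_subspecies": meta.groupby("subspecies").size().to_dict(),
        "group_size_mean": float(meta["group_size"].mean()),
        "group_size_range": (int(meta["group_size"].min()), int(meta["group_size"].max())),
        "baseline_minutes_control": 30 * int(len(control)),
    }
    if len(mfas):
        out["mfas_group_size_mean"] = float(mfas["group_size"].mean())
        out["mfas_group_size_range"] = (int(mfas["group_size"].min()), int(mfas["group_size"].max()))
        if "rl_max_db" in mfas.columns and mfas["rl_max_db"].notna().any():
            out["mfas_rl_max_mean_db"] = float(mfas["rl_max_db"].mean())
            out["mfas_rl_max_range_db"] = (
                float(mfas["rl_max_db"].min()),
                float(mfas["rl_max_db"].max()),
            )
    return out


def changepoint_comparison(table: pd.DataFrame) -> dict:
    """Control-vs-sonar comparison of per-experiment |pre - exposure|
    changepoint counts (mean-type and variance-type), with pooled and
    Welch two-sample t-tests."""
    t = table.copy()
    t["delta_mean"] = (t["cpt_mean_pre"] - t["cpt_mean_exposure"]).abs()
    t["delta_var"] = (t["cpt_var_pre"] - t["cpt_var_exposure"]).abs()
    ctrl = t[t["cee_type"] == "control"]
    mfas = t[t["cee_type"] == "mfas"]
    out = {}
    for kind in ("mean", "var"):
        x = ctrl[f"delta_{kind}"].to_numpy(dtype=float)
        y = mfas[f"delta_{kind}"].to_numpy(dtype=float)
        out[kind] = {
            "control_mean": float(np.mean(x)),
            "control_sd": float(np.std(x, ddof=1)),
            "mfas_mean": float(np.mean(y)),
            "mfas_sd": float(np.std(y, ddof=1)),
            "pooled": pooled_t_test(x, y),
            "welch": welch_t_test(x, y),
        }
    return out


# ---------------------------------------------------------------------------
# Bundled simulation scenarios

def study_scenario(
    seed: int,
    n_control: int = 9,
    n_mfas: int = 9,
    response_fold: float = 1.0,
    suppress_during_ping: bool = False,
    duration_s: int = 1800,
) -> list[SimConfig]:
    """A set of experiment configurations mirroring the study layout:
    mixed subspecies, group sizes 10-350, per-experiment baseline
    intensities spanning the observed control range (0.3-4.6 whistles/s).
    ``response_fold=1`` with suppression off is the null scenario."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 97]))
    configs = []
    types = ["control"] * n_control + ["mfas"] * n_mfas
    for i, cee_type in enumerate(types):
        lo = float(rng.uniform(0.05, 0.8))
        hi = float(rng.uniform(1.5, 4.6))
        rl = float(rng.uniform(142.0, 159.0)) if cee_type == "mfas" else None
        configs.append(
            SimConfig(
                cee_id=f"sim_{i + 1:02d}",
                cee_type=cee_type,
                duration_s=duration_s,
                phase_bounds=(0, duration_s // 3, 2 * duration_s // 3, duration_s),
                state_intensities=(lo, hi),
                response_fold=response_fold if cee_type == "mfas" else 1.0,
                suppress_during_ping=suppress_during_ping and cee_type == "mfas",
                group_size=int(rng.integers(10, 351)),
                subspecies=str(rng.choice(["Db", "Dd"])),
                rl_max_db=rl,
                n_pings=min(24, max(1, int((duration_s // 3 - 2) // 25))),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return configs


def null_scenario(seed: int, **kw) -> list[SimConfig]:
    """No injected response: sonar and control experiments are
    statistically indistinguishable."""
    return study_scenario(seed, response_fold=1.0, suppress_during_ping=False, **kw)


def response_scenario(seed: int, fold: float = 4.0, **kw) -> list[SimConfig]:
    """A burst of ``fold`` times the baseline intensity in the ~5 s after
    each ping with suppression during the transmission — strong at the
    5-s scale, invisible at the 10-min scale."""
    return study_scenario(seed, response_fold=fold, suppress_during_ping=True, **kw)


# ---------------------------------------------------------------------------
# Per-experiment analysis

@dataclass
class AnalysisParams:
    """Every tunable of the analysis, recorded verbatim in the manifest."""

    threshold_m: float = 1600.0
    smooth_window_s: int = 5
    penalty: float | None = None          # None -> 3 log n
    max_cpts: int | None = None           # None -> n / 10
    window_long_s: float = 20.0
    window_short_s: float = 5.0
    align: str = "offset"


@dataclass
class CEEResult:
    """All per-experiment analysis products."""

    cee_id: str
    meta: dict
    selection: geometry.BuoySelection
    counts: counting.CountSeries
    summary: dict
    mean_cpts: cpt.ChangepointResult
    var_cpts: cpt.ChangepointResult
    cpt_summary: cpt.ChangepointSummary
    period_record: dict | None
    ping_long: pd.DataFrame
    ping_short: pd.DataFrame
    first_ping_fold: float | None
    first_ping_pronounced: bool | None


def analyze_cee(
    detections: pd.DataFrame,
    group_track: geometry.Track,
    buoy_tracks: list[geometry.Track],
    schedule: response.PingSchedule,
    meta: dict,
    duration_s: int,
    phase_bounds,
    params: AnalysisParams = AnalysisParams(),
    annotations: pd.DataFrame | None = None,
) -> CEEResult:
    """Run the full single-experiment chain on detection tables and tracks."""
    cee_id = str(meta.get("cee_id", ""))
    sel = geometry.select_closest_buoy(
        group_track, buoy_tracks, threshold_m=params.threshold_m,
        duration_s=duration_s, cee_id=cee_id,
    )
    det = detections
    if annotations is not None and len(annotations):
        det = counting.remove_annotated_detections(det, annotations)
    det = counting.stitch_closest_buoy(det, sel)
    cs = counting.bin_per_second(det, duration_s, sel, phase_bounds, cee_id=cee_id)
    summary = counting.summarize_cee(cs)

    smoothed = cpt.smooth(cs, params.smooth_window_s)
    mean_res = cpt.binseg(smoothed, "mean", penalty=params.penalty, max_cpts=params.max_cpts)
    var_res = cpt.binseg(smoothed, "variance", penalty=params.penalty, max_cpts=params.max_cpts)
    cpt_summary = cpt.count_by_period(mean_res, var_res, phase_bounds, cee_id=cee_id)

    covariates = {
        "ceeType": meta["cee_type"],
        "subSpecies": meta["subspecies"],
        "groupSize": float(meta["group_size"]),
        "buoyDist": sel.mean_distance_m,
        "medWhist": summary["med_whist"],
    }
    period_record = response.period_median_difference(cs, covariates)
    ping_long = response.ping_change_series(cs, schedule, params.window_long_s, params.align, covariates)
    ping_short = response.ping_change_series(cs, schedule, params.window_short_s, params.align, covariates)
    fold = response.first_ping_fold_change(cs, schedule, params.window_short_s)
    pronounced = (
        response.flag_pronounced_first_ping(ping_short) if len(ping_short) >= 4 else None
    )
    return CEEResult(
        cee_id=cee_id, meta=meta, selection=sel, counts=cs, summary=summary,
        mean_cpts=mean_res, var_cpts=var_res, cpt_summary=cpt_summary,
        period_record=period_record, ping_long=ping_long, ping_short=ping_short,
        first_ping_fold=fold, first_ping_pronounced=pronounced,
    )


def analyze_simulated_cee(cee: SimulatedCEE, params: AnalysisParams = AnalysisParams()) -> CEEResult:
    meta = {
        "cee_id": cee.meta.cee_id,
        "cee_type": cee.meta.cee_type,
        "subspecies": cee.meta.subspecies,
        "group_size": cee.meta.group_size,
        "rl_max_db": cee.meta.rl_max_db,
    }
    return analyze_cee(
        cee.detections, cee.group_track, cee.buoy_tracks, cee.schedule, meta,
        duration_s=cee.config.duration_s, phase_bounds=cee.config.phase_bounds, params=params,
    )


# ---------------------------------------------------------------------------
# Model specifications matching the three analysis scales

def period_model_spec(full: bool = True) -> ModelSpec:
    terms = ("ceeType", "subSpecies", "groupSize", "buoyDist") if full else ("ceeType",)
    return ModelSpec(
        response="periodDiff", fixed_terms=terms,
        random_intercept="ceeNum" if full else None, family="nbinom_log",
    )


def ping_model_spec(full: bool = True, ar1: bool = False) -> ModelSpec:
    terms = (
        ("ceeType", "subSpecies", "groupSize", "buoyDist", "medWhist")
        if full
        else ("ceeType", "medWhist")
    )
    return ModelSpec(
        response="pingChange", fixed_terms=terms, zi_terms=("medWhist",),
        correlation=("ar1", "times", "ceeNum") if ar1 else None, family="gaussian",
    )


# ---------------------------------------------------------------------------
# Full run

@dataclass
class RunConfig:
    """One full analysis run: simulation scenario (or pre-existing input
    files), analysis parameters, output directory and master seed."""

    seed: int = 0
    scenario: str = "null"                 # "null" | "response"
    response_fold: float = 4.0
    n_control: int = 9
    n_mfas: int = 9
    duration_s: int = 1800
    params: AnalysisParams = field(default_factory=AnalysisParams)
    select_models: bool = True
    outdir: str | None = None


@dataclass
class ReportBundle:
    results: list[CEEResult]
    study_summary: dict
    cpt_tests: dict
    baseline_switch_rates: dict
    period_fit: object
    ping_long_fit: object
    ping_short_fit: object
    tables: dict[str, pd.DataFrame]


def _records_table(results: list[CEEResult]) -> pd.DataFrame:
    rows = [r.period_record for r in results if r.period_record is not None]
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Simulate (or load), analyze every experiment, fit the three models
    and emit the report tables.  Deterministic for a fixed seed."""
    if config.scenario == "null":
        sims = null_scenario(config.seed, n_control=config.n_control,
                             n_mfas=config.n_mfas, duration_s=config.duration_s)
    elif config.scenario == "response":
        sims = response_scenario(config.seed, fold=config.response_fold,
                                 n_control=config.n_control, n_mfas=config.n_mfas,
                                 duration_s=config.duration_s)
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")

    results = []
    for sc in sims:
        cee = simulate_cee(sc)
        if config.outdir:
            write_cee_bundle(cee, Path(config.outdir) / "inputs")
        results.append(analyze_simulated_cee(cee, config.params))

    meta_df = pd.DataFrame([r.meta for r in results])
    study = summarize_study(meta_df)

    table1 = pd.DataFrame(
        {
            "cee_id": [r.cee_id for r in results],
            "subspecies": [r.meta["subspecies"] for r in results],
            "group_size": [r.meta["group_size"] for r in results],
            "cee_type": [r.meta["cee_type"] for r in results],
            "med_whist": [r.summary["med_whist"] for r in results],
            "iqr_whist": [r.summary["overall"]["iqr"] for r in results],
            "cpt_mean_pre": [r.cpt_summary.mean_pre for r in results],
            "cpt_mean_exposure": [r.cpt_summary.mean_exposure for r in results],
            "cpt_var_pre": [r.cpt_summary.var_pre for r in results],
            "cpt_var_exposure": [r.cpt_summary.var_exposure for r in results],
        }
    )
    cpt_tests = changepoint_comparison(table1)
    controls = [r for r in results if r.meta["cee_type"] == "control"]
    baseline = {
        "mean_per_min": cpt.switch_rate([r.mean_cpts for r in controls]) if controls else np.nan,
        "variance_per_min": cpt.switch_rate([r.var_cpts for r in controls]) if controls else np.nan,
    }

    period_data = _records_table(results)
    ping_long = pd.concat([r.ping_long for r in results], ignore_index=True)
    ping_short = pd.concat([r.ping_short for r in results], ignore_index=True)

    if config.select_models:
        period_fit = backward_select(period_data, period_model_spec(full=True))
        long_fit = backward_select(ping_long, ping_model_spec(full=True))
        short_fit = backward_select(ping_short, ping_model_spec(full=True, ar1=True))
    else:
        period_fit = fit_model(period_data, period_model_spec(full=False))
        long_fit = fit_model(ping_long, ping_model_spec(full=False))
        short_fit = fit_model(ping_short, ping_model_spec(full=False, ar1=True))

    tables = {
        "table1": table1,
        "period_records": period_data,
        "ping_change_long": ping_long,
        "ping_change_short": ping_short,
    }
    for name, fit in (("period", period_fit), ("ping_long", long_fit), ("ping_short", short_fit)):
        if isinstance(fit, SelectionResult):
            tables[f"model_table_{name}"] = fit.table

    bundle = ReportBundle(
        results=results, study_summary=study, cpt_tests=cpt_tests,
        baseline_switch_rates=baseline, period_fit=period_fit,
        ping_long_fit=long_fit, ping_short_fit=short_fit, tables=tables,
    )
    if config.outdir:
        _write_report(bundle, config)
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def _fit_report(fit) -> dict:
    if isinstance(fit, SelectionResult):
        best = fit.best_fit
        return {
            "selected": best.spec.formula(),
            "zi": best.spec.zi_formula(),
            "aic": best.aic,
            "loglik": best.loglik,
            "coefficients": best.params.to_dict(orient="records"),
            "lrt": fit.lrt.to_dict(orient="records"),
        }
    return {
        "selected": fit.spec.formula(),
        "zi": fit.spec.zi_formula(),
        "aic": fit.aic,
        "loglik": fit.loglik,
        "coefficients": fit.params.to_dict(orient="records"),
    }


def _write_report(bundle: ReportBundle, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in bundle.tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.9f")
    for r in bundle.results:
        counting.write_count_series_csv(r.counts, outdir / f"counts_{r.cee_id}.csv")
    report = {
        "study_summary": _jsonable(bundle.study_summary),
        "baseline_switch_rates": _jsonable(bundle.baseline_switch_rates),
        "changepoint_tests": _jsonable(bundle.cpt_tests),
        "models": {
            "period_10min": _fit_report(bundle.period_fit),
            "ping_20s": _fit_report(bundle.ping_long_fit),
            "ping_5s": _fit_report(bundle.ping_short_fit),
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    manifest = {
        "seed": config.seed,
        "scenario": config.scenario,
        "response_fold": config.response_fold,
        "n_control": config.n_control,
        "n_mfas": config.n_mfas,
        "duration_s": config.duration_s,
        "params": asdict(config.params),
        "select_models": config.select_models,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(manifest), fh, sort_keys=True)
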