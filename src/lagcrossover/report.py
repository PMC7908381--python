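"""Descriptive tables and the end-to-end pipeline orchestrator.

Produces the study's descriptive surface — event breakdowns, pooled
exposure summaries over all case and control days, paired case/control-day
t-tests — and runs the whole analysis (simulate → link → assemble → fit →
stratify → report) into a bundle of CSV tables plus a JSON run log.
"""

from __future__ import annotations

import dataclasses
import json
import math
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .config import SimulationConfig
from .crossover import (CaseCrossoverStratum, assemble_strata, filter_events,
                        strata_to_long)
from .model import bic_select, extrapolate_lag_or  # noqa: F401 (re-export)
from .modification import (fit_interaction, fit_stratified, lrt,
                           stratified_log_or_table)
from .simulate import (HospitalizationEvent, Subject, cohort_to_frame,
                       events_to_frame, simulate_study, write_study)

__all__ = ["ExposureSummary", "PairedComparison", "pooled_summary",
           "paired_t", "event_breakdown", "run_pipeline", "plot_lag_response"]

#: stratifiable binary risk factors plus area of residence
MODIFIERS = ("area", "age_ge85", "male", "ever_smoker",
             "occupational_exposure", "preexisting_cvd_resp")

ICD9_GROUPS = (
    ("Hypertensive disease", 401, 405),
    ("Ischemic heart disease", 410, 414),
    ("Diseases of pulmonary circulation", 415, 417),
    ("Other forms of heart disease", 420, 429),
    ("Cerebrovascular disease", 430, 438),
    ("Diseases of arteries, arterioles, and capillaries", 440, 449),
    ("Diseases of veins and lymphatics, and other diseases "
     "of circulatory system", 451, 459),
)


@dataclass
class ExposureSummary:
    """Pooled lag-0 exposure statistics over all study days."""

    pollutant: str
    resolution: str
    n_days: int
    mean: float
    sd: float
    median: float
    p25: float
    p75: float
    iqr: float


@dataclass
class PairedComparison:
    """Paired t-test of case-day vs control-day exposure."""

    pollutant: str
    comparison: str  # "delta(0,-7)" | "delta(0,+7)"
    n: int
    mean_case: float
    mean_control: float
    mean_diff: float
    sd_diff: float
    t_statistic: float
    p_value: float
    undefined: bool = False

    @property
    def significant(self) -> bool:
        return not self.undefined and self.p_value < 0.05

    @property
    def borderline(self) -> bool:
        return not self.undefined and 0.05 <= self.p_value < 0.1


def pooled_summary(strata: list[CaseCrossoverStratum]) -> ExposureSummary:
    """Mean, SD, median, quartiles and IQR of all pooled lag-0 exposures.

    Quartiles use linear interpolation between order statistics; the day
    count is the stratum bookkeeping total sum_i (1 + n_controls_i).
    """
    if not strata:
        raise ValueError("no strata to summarise")
    values = np.concatenate([s.lag_matrix[:, 0] for s in strata])
    p25, median, p75 = np.percentile(values, [25, 50, 75])
    return ExposureSummary(
        pollutant=strata[0].pollutant, resolution=strata[0].resolution,
        n_days=int(values.size), mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        median=float(median), p25=float(p25), p75=float(p75),
        iqr=float(p75 - p25))


def paired_t(strata: list[CaseCrossoverStratum],
             which_control: int) -> PairedComparison:
    """Classic paired t-test on (case − control) lag-0 exposures.

    ``which_control`` is −7 or +7: the control day at that offset from the
    case.  Only strata retaining that control contribute a pair.  A
    zero-variance set of differences yields an ``undefined`` flag, not a
    p-value of zero.
    """
    if which_control not in (-7, 7):
        raise ValueError("which_control must be -7 or +7")
    offset = pd.Timedelta(days=which_control)
    case_vals, control_vals = [], []
    for s in strata:
        target = s.case_date + offset
        for i, d in enumerate(s.control_dates):
            if d == target:
                case_vals.append(s.lag_matrix[0, 0])
                control_vals.append(s.lag_matrix[1 + i, 0])
                break
    n = len(case_vals)
    label = f"delta(0,{'+' if which_control > 0 else ''}{which_control})"
    if n < 2:
        raise ValueError(f"fewer than 2 strata have the {which_control:+d} "
                         "day control")
    case_arr = np.asarray(case_vals)
    control_arr = np.asarray(control_vals)
    diff = case_arr - control_arr
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return PairedComparison(
            pollutant=strata[0].pollutant, comparison=label, n=n,
            mean_case=float(case_arr.mean()),
            mean_control=float(control_arr.mean()),
            mean_diff=float(diff.mean()), sd_diff=0.0,
            t_statistic=math.nan, p_value=math.nan, undefined=True)
    t_stat = float(diff.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    return PairedComparison(
        pollutant=strata[0].pollutant, comparison=label, n=n,
        mean_case=float(case_arr.mean()),
        mean_control=float(control_arr.mean()),
        mean_diff=float(diff.mean()), sd_diff=sd,
        t_statistic=t_stat, p_value=p)


# ---------------------------------------------------------------------------
# event breakdown (Table-1-shaped)
# ---------------------------------------------------------------------------

def event_breakdown(events: list[HospitalizationEvent],
                    cohort: list[Subject]) -> pd.DataFrame:
    """Counts and integer percentages of qualifying admissions by block.

    Blocks: ICD-9 disease group, year, area of residence and the five
    binary risk factors.  Percentages are rounded to integers in the table;
    exact fractions live in the ``fraction`` column.
    """
    events = filter_events(events)
    subjects = {s.subject_id: s for s in cohort}
    n = len(events)
    rows = []

    def add(block, label, count):
        rows.append({"block": block, "category": label, "count": count,
                     "fraction": count / n if n else math.nan,
                     "percent": round(100 * count / n) if n else math.nan})

    for label, lo, hi in ICD9_GROUPS:
        count = sum(1 for e in events if lo <= int(str(e.icd9_code)[:3]) <= hi)
        add("disease_group", f"{label} ({lo}-{hi})", count)
    years = sorted({pd.Timestamp(e.admission_date).year for e in events})
    for year in years:
        add("year", str(year),
            sum(1 for e in events
                if pd.Timestamp(e.admission_date).year == year))
    for area in ("urban", "suburban"):
        add("area", area,
            sum(1 for e in events if subjects[e.subject_id].area == area))
    binary_blocks = {
        "age_class": ("age_ge85", {0: "<85 years", 1: ">=85 years"}),
        "gender": ("male", {0: "female", 1: "male"}),
        "smoking": ("ever_smoker", {0: "non-smoker", 1: "ever smoker"}),
        "occupational_exposure": ("occupational_exposure",
                                  {0: "not exposed", 1: "exposed"}),
        "preexisting_cvd_resp": ("preexisting_cvd_resp",
                                 {0: "no", 1: "yes"}),
    }
    for block, (attr, labels) in binary_blocks.items():
        for level in (0, 1):
            add(block, labels[level],
                sum(1 for e in events
                    if getattr(subjects[e.subject_id], attr) == level))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_lag_response(table: pd.DataFrame, path, title: str = "",
                      p_interaction: float | None = None) -> Path:
    """Log-OR vs lag per modifier level, with Wald bands.

    ``table`` is the long frame from ``stratified_log_or_table``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for level, sub in table.groupby("level"):
        ax.errorbar(sub["lag"], sub["log_or"],
                    yerr=[sub["log_or"] - sub["ci_low"],
                          sub["ci_high"] - sub["log_or"]],
                    marker="o", capsize=2, label=f"level {level:g}")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("lag (days)")
    ax.set_ylabel("log OR per 10 µg/m³")
    if p_interaction is not None:
        title = f"{title}  (p-interaction = {p_interaction:.3f})".strip()
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: SimulationConfig, outdir,
                 pollutants: tuple[str, ...] | None = None,
                 resolutions: tuple[str, ...] = ("coarse", "fine"),
                 adjust: bool = False,
                 write_inputs: bool = True,
                 make_plots: bool = False) -> dict:
    """Simulate one study and run the full analysis into ``outdir``.

    Writes per-pollutant/resolution OR tables under the symmetric design, a
    time-stratified sensitivity analysis for the causal pollutant, pooled
    exposure summaries, paired case/control-day comparisons, the event
    breakdown, per-modifier stratified results with interaction p-values,
    and a JSON run log (seed, versions, BIC comparison).  Returns a dict of
    in-memory results and written paths.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(config, resolutions=resolutions)
    if write_inputs:
        write_study(study, outdir / "inputs")
    cohort, events, calendar = (study["cohort"], study["events"],
                                study["calendar"])
    grids = study["grids"]
    if pollutants is None:
        pollutants = tuple(config.pollutants)
    period = config.period
    filtered = filter_events(events)

    or_rows, summary_rows, paired_rows = [], [], []
    bic_tables = []
    strata_by_key: dict[tuple[str, str], list] = {}
    fits: dict[tuple[str, str], object] = {}
    for pol in pollutants:
        for res in resolutions:
            grid = grids[(pol, res)]
            strata = assemble_strata(
                filtered, cohort, grid, period, design="symmetric",
                L=config.max_lag, calendar=calendar,
                with_covariates=adjust, pre_filtered=True)
            if not strata:
                continue
            strata_by_key[(pol, res)] = strata
            summary_rows.append(dataclasses.asdict(pooled_summary(strata)))
            for side in (-7, 7):
                comp = paired_t(strata, side)
                row = dataclasses.asdict(comp)
                row.update({"resolution": res,
                            "significant": comp.significant,
                            "borderline": comp.borderline})
                paired_rows.append(row)
            best, table = bic_select(
                strata, adjust_options=(False, True) if adjust else (False,),
                max_lag=config.max_lag)
            table.insert(0, "pollutant", pol)
            table.insert(1, "resolution", res)
            bic_tables.append(table)
            fits[(pol, res)] = best
            or_table = best.or_table(delta=10.0)
            or_table.insert(0, "pollutant", pol)
            or_table.insert(1, "resolution", res)
            or_table["design"] = "symmetric"
            or_rows.append(or_table)

    # sensitivity: time-stratified referents for the causal pollutant
    key = (config.causal_pollutant, config.causal_resolution)
    sensitivity = None
    if key in grids:
        ts_strata = assemble_strata(
            filtered, cohort, grids[key], period, design="time_stratified",
            L=config.max_lag, pre_filtered=True)
        if ts_strata:
            ts_best, _ = bic_select(ts_strata, max_lag=config.max_lag)
            ts_table = ts_best.or_table(delta=10.0)
            ts_table.insert(0, "pollutant", key[0])
            ts_table.insert(1, "resolution", key[1])
            ts_table["design"] = "time_stratified"
            or_rows.append(ts_table)
            sensitivity = ts_best

    # stratified analyses + interaction tests on the causal pollutant
    strat_tables, interaction_rows = [], []
    main_strata = strata_by_key.get(key)
    if main_strata:
        for modifier in MODIFIERS:
            per_level = fit_stratified(main_strata, cohort, modifier,
                                       max_lag=config.max_lag)
            table = stratified_log_or_table(per_level)
            p_int = math.nan
            try:
                inter = fit_interaction(main_strata, cohort, modifier,
                                        max_lag=config.max_lag)
                test = lrt(inter, inter.reduced)
                p_int = test.p_value
            except (RuntimeError, ValueError):
                pass
            if not table.empty:
                table.insert(0, "modifier", modifier)
                table["p_interaction"] = p_int
                strat_tables.append(table)
                if make_plots:
                    plot_lag_response(
                        table, outdir / f"lag_response_{modifier}.png",
                        title=f"{key[0]} ({key[1]}), by {modifier}",
                        p_interaction=p_int)
            interaction_rows.append(
                {"modifier": modifier, "p_interaction": p_int,
                 "significant": p_int < 0.05 if not math.isnan(p_int)
                 else False})

    # write the bundle
    paths: dict[str, Path] = {}

    def write_csv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path

    write_csv("event_breakdown", event_breakdown(events, cohort))
    if summary_rows:
        write_csv("exposure_summary", pd.DataFrame(summary_rows))
    if paired_rows:
        write_csv("paired_comparisons", pd.DataFrame(paired_rows))
    if or_rows:
        write_csv("or_tables", pd.concat(or_rows, ignore_index=True))
    if bic_tables:
        write_csv("bic_comparison", pd.concat(bic_tables, ignore_index=True))
    if strat_tables:
        write_csv("stratified_log_or",
                  pd.concat(strat_tables, ignore_index=True))
    if interaction_rows:
        write_csv("interaction_tests", pd.DataFrame(interaction_rows))
    if main_strata:
        long = strata_to_long(main_strata)
        write_csv("strata_long", long)

    log = {
        "seed": config.seed,
        "package_version": _pkg_version,
        "python": platform.python_version(),
        "n_subjects": len(cohort),
        "n_events_total": len(events),
        "n_events_qualifying": len(filtered),
        "n_strata": {f"{p}/{r}": len(s)
                     for (p, r), s in strata_by_key.items()},
        "config": config.to_dict(),
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=1, default=str))
    paths["run_log"] = log_path

    return {
        "study": study, "strata": strata_by_key, "fits": fits,
        "sensitivity_fit": sensitivity,
        "interaction_tests": pd.DataFrame(interaction_rows)
        if interaction_rows else None,
        "paths": paths,
    }
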