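"""Synthetic study generator: exposure grids, cohort, calendars, events.

Generates data with the statistical structure the downstream case-crossover
analysis assumes — seasonal, autocorrelated daily pollutant fields at two
grid resolutions, a two-area geocoded cohort with binary risk factors, a
time-varying confounder calendar, and sparse acute cardiovascular events
whose hazard carries a known log-linear distributed-lag exposure effect —
so every stage is testable against known truth without any external data.

All randomness flows from ``SimulationConfig.seed`` through named
``numpy`` seed sequences, so outputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .config import ConfounderEffects, LagEffect, SimulationConfig

__all__ = [
    "ExposureGrid", "Subject", "ConfounderCalendar", "HospitalizationEvent",
    "CalibrationError", "generate_exposure_grid", "generate_cohort",
    "generate_confounder_calendar", "simulate_events", "simulate_study",
    "simulate_matched_sets", "easter_sunday",
    "cohort_to_frame", "events_to_frame", "write_study",
]

RISK_FACTORS = ("age_ge85", "male", "ever_smoker", "occupational_exposure",
                "preexisting_cvd_resp")

#: ICD-9 band → (low, high, count among the 137 events) used to sample
#: plausible primary-diagnosis codes for simulated admissions
ICD9_BANDS = (
    (401, 405, 1),   # hypertensive disease
    (410, 414, 32),  # ischemic heart disease
    (415, 417, 9),   # diseases of pulmonary circulation
    (420, 429, 55),  # other forms of heart disease
    (430, 438, 27),  # cerebrovascular disease
    (440, 449, 8),   # diseases of arteries, arterioles, capillaries
    (451, 459, 5),   # veins, lymphatics, other circulatory
)


class CalibrationError(RuntimeError):
    """Hazard calibration produced capped probabilities too often."""


def _rng(seed: int, *tags: str) -> np.random.Generator:
    """Deterministic named stream: stable across platforms and runs."""
    keys = [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExposureGrid:
    """Daily concentration series on a rectangular grid, one pollutant.

    ``values[ix, iy, t]`` is the concentration (µg/m³) in the half-open cell
    ``[origin + i*cell_size, origin + (i+1)*cell_size)`` on ``dates[t]``.
    The date axis includes a warm-up of ``max_lag`` days before the study
    start so lag vectors are complete from day one.
    """

    pollutant: str
    resolution: str
    origin_x: float
    origin_y: float
    cell_size: float
    dates: pd.DatetimeIndex
    values: np.ndarray  # (n_cells_x, n_cells_y, n_days)

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != len(self.dates):
            raise ValueError("values must be (nx, ny, n_days)")
        if (self.values < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def n_cells(self) -> tuple[int, int]:
        return self.values.shape[0], self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float]:
        nx, ny = self.n_cells
        return nx * self.cell_size, ny * self.cell_size

    def date_index(self, date) -> int:
        """Position of ``date`` on the date axis, or -1 if uncovered."""
        loc = self.dates.get_indexer([pd.Timestamp(date)])[0]
        return int(loc)

    def series(self, ix: int, iy: int) -> pd.Series:
        return pd.Series(self.values[ix, iy, :], index=self.dates)

    def to_long_frame(self) -> pd.DataFrame:
        nx, ny = self.n_cells
        ix, iy, it = np.meshgrid(np.arange(nx), np.arange(ny),
                                 np.arange(len(self.dates)), indexing="ij")
        return pd.DataFrame({
            "cell_ix": ix.ravel(), "cell_iy": iy.ravel(),
            "date": self.dates[it.ravel()].strftime("%Y-%m-%d"),
            "value": self.values.ravel(),
        })

    def write(self, directory) -> tuple[Path, Path]:
        """Write long-format CSV plus a JSON metadata sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = f"grid_{self.pollutant}_{self.resolution}"
        csv_path = directory / f"{stem}.csv"
        meta_path = directory / f"{stem}.json"
        self.to_long_frame().to_csv(csv_path, index=False)
        nx, ny = self.n_cells
        meta = {
            "pollutant": self.pollutant, "resolution": self.resolution,
            "origin_x": self.origin_x, "origin_y": self.origin_y,
            "cell_size": self.cell_size, "n_cells_x": nx, "n_cells_y": ny,
            "date_start": str(self.dates[0].date()),
            "date_end": str(self.dates[-1].date()),
        }
        meta_path.write_text(json.dumps(meta, indent=1))
        return csv_path, meta_path

    @classmethod
    def read(cls, csv_path, meta_path=None) -> "ExposureGrid":
        csv_path = Path(csv_path)
        if meta_path is None:
            meta_path = csv_path.with_suffix(".json")
        meta = json.loads(Path(meta_path).read_text())
        long = pd.read_csv(csv_path, parse_dates=["date"])
        dates = pd.date_range(meta["date_start"], meta["date_end"], freq="D")
        nx, ny = meta["n_cells_x"], meta["n_cells_y"]
        values = np.full((nx, ny, len(dates)), np.nan)
        it = dates.get_indexer(long["date"])
        values[long["cell_ix"], long["cell_iy"], it] = long["value"]
        return cls(meta["pollutant"], meta["resolution"], meta["origin_x"],
                   meta["origin_y"], meta["cell_size"], dates, values)


@dataclass
class Subject:
    """Geocoded cohort member with binary risk-factor covariates."""

    subject_id: str
    x: float
    y: float
    area: str  # "urban" | "suburban"
    age_ge85: int
    male: int
    ever_smoker: int
    occupational_exposure: int
    preexisting_cvd_resp: int


@dataclass
class ConfounderCalendar:
    """Per-day confounders: three binary flags plus apparent temperature."""

    frame: pd.DataFrame  # index: dates; columns: summer_reduction, holiday,
    #                      influenza, apparent_temperature

    def __post_init__(self) -> None:
        required = {"summer_reduction", "holiday", "influenza",
                    "apparent_temperature"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"calendar missing columns {sorted(missing)}")
        for col in ("summer_reduction", "holiday", "influenza"):
            if not self.frame[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be binary")

    def lookup(self, date) -> pd.Series:
        return self.frame.loc[pd.Timestamp(date)]

    def write(self, path) -> Path:
        path = Path(path)
        out = self.frame.copy()
        out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
        out.to_csv(path, index=False)
        return path

    @classmethod
    def read(cls, path) -> "ConfounderCalendar":
        frame = pd.read_csv(path, parse_dates=["date"]).set_index("date")
        return cls(frame)


@dataclass
class HospitalizationEvent:
    """One dated hospital admission linked to a cohort subject."""

    subject_id: str
    admission_date: pd.Timestamp
    icd9_code: str
    admission_type: str  # "acute" | "scheduled"


# ---------------------------------------------------------------------------
# exposure grids
# ---------------------------------------------------------------------------

def _study_dates(config: SimulationConfig) -> pd.DatetimeIndex:
    """Study dates plus the max_lag warm-up preceding date_start."""
    return pd.date_range(config.start - pd.Timedelta(days=config.max_lag),
                         config.end, freq="D")


def _seasonal(dates: pd.DatetimeIndex, amplitude: float,
              peak_doy: int) -> np.ndarray:
    doy = dates.dayofyear.to_numpy()
    return amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _regional_ar1(config: SimulationConfig, pollutant: str,
                  n_days: int) -> np.ndarray:
    """Shared regional AR(1) series; identical for both resolutions."""
    spec = config.pollutants[pollutant]
    rng = _rng(config.seed, "regional", pollutant)
    phi = spec.ar1_coefficient
    innovations = rng.normal(0.0, spec.daily_noise_sd, size=n_days)
    if phi == 0.0:
        return innovations
    # stationary start: x_0 ~ N(0, sd²/(1-phi²)), then x_t = phi x_{t-1} + e_t
    x0 = rng.normal(0.0, spec.daily_noise_sd / np.sqrt(1.0 - phi**2))
    series, _ = signal.lfilter([1.0], [1.0, -phi], innovations,
                               zi=np.array([phi * x0]))
    return series


def generate_exposure_grid(config: SimulationConfig, pollutant: str,
                           resolution: str) -> ExposureGrid:
    """Simulate the daily concentration field for one pollutant/resolution.

    The field is ``max(0, mean + seasonal + regional AR(1) + cell offset +
    cell noise)``; the regional term is keyed only by pollutant, so coarse
    and fine grids of the same pollutant are strongly correlated, emulating
    one atmosphere sampled at two resolutions.
    """
    config.validate()
    spec = config.pollutants[pollutant]
    cell_size = config.cell_size(resolution)
    dates = _study_dates(config)
    if len(dates) == 0:
        raise ValueError("empty date range")
    nx = int(np.ceil(config.extent_x / cell_size))
    ny = int(np.ceil(config.extent_y / cell_size))
    base = (spec.annual_mean
            + _seasonal(dates, spec.seasonal_amplitude, spec.seasonal_peak_doy)
            + _regional_ar1(config, pollutant, len(dates)))
    rng = _rng(config.seed, "cells", pollutant, resolution)
    offsets = rng.normal(0.0, spec.cell_offset_sd, size=(nx, ny, 1))
    noise = rng.normal(0.0, spec.cell_noise_sd, size=(nx, ny, len(dates)))
    values = np.maximum(0.0, base[None, None, :] + offsets + noise)
    return ExposureGrid(pollutant, resolution, config.grid_origin_x,
                        config.grid_origin_y, cell_size, dates, values)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> list[Subject]:
    """Draw the geocoded cohort: two areas, binary risk factors.

    Urban subjects live in the western strip ``x < urban_fraction *
    extent_x``; suburban subjects in the remainder, so area is a
    deterministic function of the coordinates, as in a real geography.
    """
    config.validate()
    rng = _rng(config.seed, "cohort")
    n = config.n_subjects
    split_x = config.grid_origin_x + config.urban_fraction * config.extent_x
    urban = rng.random(n) < config.urban_fraction
    x = np.where(
        urban,
        config.grid_origin_x + rng.random(n) * (split_x - config.grid_origin_x),
        split_x + rng.random(n) * (config.grid_origin_x + config.extent_x
                                   - split_x),
    )
    # degenerate splits: all-urban (split at extent) or all-suburban
    x = np.clip(x, config.grid_origin_x,
                config.grid_origin_x + config.extent_x * (1 - 1e-9))
    y = config.grid_origin_y + rng.random(n) * config.extent_y
    factors = {name: (rng.random(n) < config.prevalences[name]).astype(int)
               for name in RISK_FACTORS}
    width = len(str(n))
    return [
        Subject(
            subject_id=f"S{i + 1:0{width}d}", x=float(x[i]), y=float(y[i]),
            area="urban" if urban[i] else "suburban",
            **{name: int(factors[name][i]) for name in RISK_FACTORS},
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: list[Subject]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in cohort])


# ---------------------------------------------------------------------------
# confounder calendar
# ---------------------------------------------------------------------------

def easter_sunday(year: int) -> pd.Timestamp:
    """Easter Sunday by the anonymous Gregorian computus."""
    a = year % 19
    b, c = divmod(year, 100)
    d, e = divmod(b, 4)
    g = (8 * b + 13) // 25
    h = (19 * a + b - d - g + 15) % 30
    i, k = divmod(c, 4)
    l = (32 + 2 * e + 2 * i - h - k) % 7
    m = (a + 11 * h + 22 * l) // 451
    month, day = divmod(h + l - 7 * m + 114, 31)
    return pd.Timestamp(year=year, month=month, day=day + 1)


def _holiday_dates(years) -> set[pd.Timestamp]:
    """Christmas/New Year block, Easter ± 1 day, isolated national holidays."""
    out: set[pd.Timestamp] = set()
    for year in years:
        for month, day in ((12, 24), (12, 25), (12, 26), (12, 31), (1, 1),
                           (4, 25), (5, 1), (8, 15), (11, 1)):
            out.add(pd.Timestamp(year=year, month=month, day=day))
        easter = easter_sunday(year)
        out.update({easter - pd.Timedelta(days=1), easter,
                    easter + pd.Timedelta(days=1)})
    return out


def generate_confounder_calendar(config: SimulationConfig) -> ConfounderCalendar:
    """Summer-reduction, holiday and influenza flags plus apparent temperature.

    Summer reduction is 1 from 15 July to 31 August; influenza windows are
    configurable and default to 1 January – 15 February; apparent temperature
    is an annual sinusoid (peak late July) plus Gaussian noise.
    """
    config.validate()
    dates = _study_dates(config)
    month, day = dates.month.to_numpy(), dates.day.to_numpy()
    summer = (((month == 7) & (day >= 15)) | (month == 8)).astype(int)
    holidays = _holiday_dates(range(dates[0].year, dates[-1].year + 1))
    holiday = dates.isin(sorted(holidays)).astype(int)

    (sm, sd), (em, ed) = config.influenza_start, config.influenza_end
    after_start = (month > sm) | ((month == sm) & (day >= sd))
    before_end = (month < em) | ((month == em) & (day <= ed))
    influenza = (after_start & before_end if (sm, sd) <= (em, ed)
                 else after_start | before_end).astype(int)

    rng = _rng(config.seed, "temperature")
    doy = dates.dayofyear.to_numpy()
    temp = (config.temperature_mean
            + config.temperature_amplitude
            * np.cos(2 * np.pi * (doy - 205) / 365.25)
            + rng.normal(0.0, config.temperature_noise_sd, len(dates)))
    frame = pd.DataFrame(
        {"summer_reduction": summer, "holiday": holiday,
         "influenza": influenza, "apparent_temperature": temp},
        index=dates)
    frame.index.name = "date"
    return ConfounderCalendar(frame)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def _sample_icd9(rng: np.random.Generator, n: int) -> list[str]:
    lows = np.array([b[0] for b in ICD9_BANDS])
    highs = np.array([b[1] for b in ICD9_BANDS])
    weights = np.array([b[2] for b in ICD9_BANDS], dtype=float)
    bands = rng.choice(len(ICD9_BANDS), size=n, p=weights / weights.sum())
    codes = rng.integers(lows[bands], highs[bands] + 1)
    return [str(c) for c in codes]


def _locate(grid: ExposureGrid, x: float, y: float) -> tuple[int, int]:
    # local copy of the half-open floor rule to avoid a circular import
    return (int(np.floor((x - grid.origin_x) / grid.cell_size)),
            int(np.floor((y - grid.origin_y) / grid.cell_size)))


def simulate_events(cohort: list[Subject],
                    grids: dict[tuple[str, str], ExposureGrid],
                    calendar: ConfounderCalendar,
                    config: SimulationConfig) -> list[HospitalizationEvent]:
    """Draw acute CVD admissions from the distributed-lag hazard.

    For each subject-day t after the warm-up, the event probability is
    ``min(1, baseline_hazard * exp(sum_l beta_l * x_{t-l} + confounders))``
    with ``beta_l = a + b*l`` (modifier-shifted where configured).  Aborts
    if more than 1% of subject-day probabilities hit the cap, which signals
    a miscalibrated hazard rather than a valid study.
    """
    config.validate()
    key = (config.causal_pollutant, config.causal_resolution)
    if key not in grids:
        raise KeyError(f"causal grid {key} not supplied")
    grid = grids[key]
    eff: LagEffect = config.true_lag_effect
    conf: ConfounderEffects = config.confounder_effects
    L = config.max_lag
    dates = grid.dates
    if dates[0] > config.start - pd.Timedelta(days=L):
        raise ValueError("grids must cover the max_lag warm-up")
    study = dates[dates >= config.start]
    n_days = len(study)

    cal = calendar.frame.reindex(dates)
    if cal.isna().any().any():
        raise ValueError("calendar must cover the grid dates")
    temp = cal["apparent_temperature"].to_numpy()
    temp01 = temp.copy()
    temp01[1:] = 0.5 * (temp[1:] + temp[:-1])
    conf_log_hazard = (
        conf.summer_reduction * cal["summer_reduction"].to_numpy()
        + conf.holiday * cal["holiday"].to_numpy()
        + conf.influenza * cal["influenza"].to_numpy()
        + conf.temperature_quadratic * ((temp01 - 20.0) / 10.0) ** 2
    )[len(dates) - n_days:]

    mod = config.modifier_effect
    rng = _rng(config.seed, "events")
    uniforms = rng.random((len(cohort), n_days))
    events: list[HospitalizationEvent] = []
    n_capped = 0
    cell_cache: dict[tuple[int, int], np.ndarray] = {}
    for row, subject in enumerate(cohort):
        cell = _locate(grid, subject.x, subject.y)
        eta_x = cell_cache.get(cell)
        if eta_x is None:
            x = grid.values[cell[0], cell[1], :]
            beta = np.array(eff.coefficients(L))
            # eta[t] = sum_l beta[l] * x[t - l]; valid from index L onwards
            eta_x = np.convolve(x, beta)[L:len(dates)]
            cell_cache[cell] = eta_x
        eta = eta_x
        if mod is not None and getattr(subject, mod.factor) == 1:
            x = grid.values[cell[0], cell[1], :]
            delta = np.array([mod.delta_intercept + mod.delta_slope * l
                              for l in range(L + 1)])
            eta = eta + np.convolve(x, delta)[L:len(dates)]
        p = config.baseline_hazard * np.exp(eta + conf_log_hazard)
        n_capped += int((p > 1.0).sum())
        p = np.minimum(p, 1.0)
        hits = np.flatnonzero(uniforms[row] < p)
        if not config.allow_repeat_events and hits.size > 1:
            hits = hits[:1]
        for t in hits:
            events.append(HospitalizationEvent(
                subject_id=subject.subject_id, admission_date=study[t],
                icd9_code="", admission_type="acute"))
    total = len(cohort) * n_days
    if n_capped > 0.01 * total:
        raise CalibrationError(
            f"hazard capped on {n_capped}/{total} subject-days (>1%); "
            "reduce baseline_hazard or the lag effect")
    events.sort(key=lambda e: (e.admission_date, e.subject_id))
    rng_codes = _rng(config.seed, "icd9")
    codes = _sample_icd9(rng_codes, len(events))
    for event, code in zip(events, codes):
        event.icd9_code = code

    # background admissions that the event filters must remove
    n_noise = int(round(config.noise_event_fraction * len(events)))
    if n_noise:
        rng_n = _rng(config.seed, "noise-events")
        subjects = rng_n.choice(len(cohort), size=n_noise)
        days = rng_n.choice(n_days, size=n_noise)
        scheduled = rng_n.random(n_noise) < 0.5
        for s, t, sched in zip(subjects, days, scheduled):
            if sched:  # scheduled CVD admission
                code = str(rng_n.integers(390, 460))
                atype = "scheduled"
            else:      # acute but non-cardiovascular
                code = str(rng_n.choice([250, 486, 574, 820]))
                atype = "acute"
            events.append(HospitalizationEvent(
                subject_id=cohort[s].subject_id, admission_date=study[t],
                icd9_code=code, admission_type=atype))
    events.sort(key=lambda e: (e.admission_date, e.subject_id, e.icd9_code))
    return events


def events_to_frame(events: list[HospitalizationEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": e.subject_id,
         "admission_date": pd.Timestamp(e.admission_date).strftime("%Y-%m-%d"),
         "icd9_code": e.icd9_code, "admission_type": e.admission_type}
        for e in events])


# ---------------------------------------------------------------------------
# whole-study convenience and writers
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig,
                   resolutions: tuple[str, ...] = ("coarse", "fine")) -> dict:
    """Generate every artefact of one synthetic study.

    Returns a dict with keys ``cohort``, ``grids`` (keyed by
    (pollutant, resolution)), ``calendar`` and ``events``.
    """
    config.validate()
    grids = {(pol, res): generate_exposure_grid(config, pol, res)
             for pol in config.pollutants for res in resolutions}
    cohort = generate_cohort(config)
    calendar = generate_confounder_calendar(config)
    events = simulate_events(cohort, grids, calendar, config)
    return {"config": config, "cohort": cohort, "grids": grids,
            "calendar": calendar, "events": events}


def write_study(study: dict, outdir) -> dict[str, Path]:
    """Write cohort/events/calendar CSVs and all grids under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cohort_path = outdir / "cohort.csv"
    cohort_to_frame(study["cohort"]).to_csv(cohort_path, index=False)
    paths["cohort"] = cohort_path
    events_path = outdir / "events.csv"
    events_to_frame(study["events"]).to_csv(events_path, index=False)
    paths["events"] = events_path
    paths["calendar"] = study["calendar"].write(outdir / "calendar.csv")
    for (pol, res), grid in study["grids"].items():
        csv_path, _ = grid.write(outdir / "grids")
        paths[f"grid_{pol}_{res}"] = csv_path
    return paths


# ---------------------------------------------------------------------------
# direct matched-set sampler (for calibration experiments)
# ---------------------------------------------------------------------------

def simulate_matched_sets(n_strata: int,
                          intercept: float,
                          slope: float,
                          rng: np.random.Generator,
                          max_lag: int = 6,
                          n_controls: int = 2,
                          modifier_prob: float = 0.0,
                          delta_intercept: float = 0.0,
                          delta_slope: float = 0.0,
                          spec=None,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                     np.ndarray]:
    """Sample 1-case : m-control day sets directly from the matched design.

    Candidate days 14 days apart are drawn from one seasonal AR(1)
    concentration series (so within-set lag vectors carry realistic
    autocorrelation), and the case day is drawn with probability
    proportional to ``exp(beta' x)`` — which is exactly the conditional
    likelihood the analysis fits, making this the correct direct simulator
    for parameter-recovery, coverage and test-calibration experiments.

    Returns ``(X, y, groups, modifier)`` where X is (n_days, max_lag+1),
    y marks case days, groups gives the stratum index of each row and
    modifier the stratum's binary effect-modifier level.
    """
    from .config import PollutantSpec
    if spec is None:
        spec = PollutantSpec()
    m = n_controls + 1
    # one long series, sets spaced so they never share days
    span = 14 * (m - 1) + max_lag + 1
    n_days_total = n_strata * span + 365
    innovations = rng.normal(0.0, spec.daily_noise_sd, n_days_total)
    phi = spec.ar1_coefficient
    regional = signal.lfilter([1.0], [1.0, -phi], innovations)
    doy = np.arange(n_days_total) % 365
    series = np.maximum(0.0, spec.annual_mean
                        + spec.seasonal_amplitude
                        * np.cos(2 * np.pi * (doy - 15) / 365.25)
                        + regional
                        + rng.normal(0.0, spec.cell_noise_sd, n_days_total))
    starts = rng.integers(max_lag, n_days_total - 14 * (m - 1),
                          size=n_strata)
    # lag matrix for every candidate day of every set
    day_idx = starts[:, None] + 14 * np.arange(m)[None, :]   # (n_strata, m)
    lag_idx = day_idx[:, :, None] - np.arange(max_lag + 1)[None, None, :]
    X = series[lag_idx]                                      # (n, m, L+1)

    modifier = (rng.random(n_strata) < modifier_prob).astype(float)
    a = intercept + delta_intercept * modifier
    b = slope + delta_slope * modifier
    lags = np.arange(max_lag + 1)
    beta = a[:, None] + b[:, None] * lags[None, :]           # (n, L+1)
    eta = np.einsum("nml,nl->nm", X, beta)
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n_strata)
    case = (u[:, None] > p.cumsum(axis=1)).sum(axis=1)

    y = np.zeros((n_strata, m))
    y[np.arange(n_strata), case] = 1.0
    groups = np.repeat(np.arange(n_strata), m)
    return (X.reshape(-1, max_lag + 1), y.ravel(), groups,
            np.repeat(modifier, m))
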