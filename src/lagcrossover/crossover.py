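"""Event filtering and matched case/control-day stratum construction.

Two referent-selection schemes are provided: symmetric bidirectional
(control days exactly 7 days before and after the admission) and
time-stratified (all days sharing the admission's weekday within the same
calendar month and year).  Both are self-matched: every day in a stratum
belongs to the same subject, so time-invariant covariates cancel from the
conditional likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage import build_lag_vector, locate_cell, OutOfDomainError
from .simulate import (ConfounderCalendar, ExposureGrid, HospitalizationEvent,
                       Subject)

__all__ = ["CaseCrossoverStratum", "filter_events", "symmetric_referents",
           "time_stratified_referents", "assemble_strata", "strata_to_long",
           "strata_to_arrays", "COVARIATE_COLUMNS"]

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("summer_reduction", "holiday", "influenza",
                     "apparent_temp_lag01", "apparent_temp_lag01_sq")


@dataclass
class CaseCrossoverStratum:
    """One case day plus its referent days for a single subject.

    ``lag_matrix`` holds one row per day (case first, then controls in
    ``control_dates`` order), columns = lags 0..L.  ``covariates`` (optional)
    is aligned the same way with columns ``COVARIATE_COLUMNS``.
    """

    stratum_id: int
    subject_id: str
    case_date: pd.Timestamp
    control_dates: list[pd.Timestamp]
    lag_matrix: np.ndarray
    pollutant: str
    resolution: str
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.case_date = pd.Timestamp(self.case_date)
        self.control_dates = [pd.Timestamp(d) for d in self.control_dates]
        if len(self.control_dates) < 1:
            raise ValueError("a stratum needs at least one control day")
        if self.case_date in self.control_dates:
            raise ValueError("case date duplicated among control dates")
        self.lag_matrix = np.asarray(self.lag_matrix, dtype=float)
        if self.lag_matrix.shape[0] != 1 + len(self.control_dates):
            raise ValueError("lag_matrix rows must be 1 + n_controls")
        if np.isnan(self.lag_matrix).any():
            raise ValueError("strata must only contain complete lag vectors")

    @property
    def n_days(self) -> int:
        return 1 + len(self.control_dates)

    @property
    def dates(self) -> list[pd.Timestamp]:
        return [self.case_date, *self.control_dates]


# ---------------------------------------------------------------------------
# event filtering
# ---------------------------------------------------------------------------

def filter_events(events: list[HospitalizationEvent],
                  icd9_low: int = 390, icd9_high: int = 459,
                  admission_type: str = "acute") -> list[HospitalizationEvent]:
    """Keep acute admissions whose primary ICD-9 code is cardiovascular.

    The range test uses the integer value of the first three characters of
    the code, so subcategory codes like "4101" qualify through their "410"
    prefix; V/E and otherwise unparseable codes are rejected with a warning.
    """
    kept = []
    for event in events:
        if event.admission_type != admission_type:
            continue
        prefix = str(event.icd9_code).strip()[:3]
        try:
            value = int(prefix)
        except ValueError:
            logger.warning("rejecting event with unparseable ICD-9 code %r "
                           "(subject %s)", event.icd9_code, event.subject_id)
            continue
        if icd9_low <= value <= icd9_high:
            kept.append(event)
    return kept


# ---------------------------------------------------------------------------
# referent selection
# ---------------------------------------------------------------------------

def _as_period(period) -> tuple[pd.Timestamp, pd.Timestamp]:
    start, end = period
    return pd.Timestamp(start), pd.Timestamp(end)


def symmetric_referents(case_date, period) -> list[pd.Timestamp]:
    """Bidirectional symmetric controls: the days exactly ±7 from the case.

    Near the study boundary one side may fall outside the period, leaving a
    singleton; if both do, the result is empty and the stratum is dropped
    by the caller.
    """
    case_date = pd.Timestamp(case_date)
    start, end = _as_period(period)
    if not start <= case_date <= end:
        raise ValueError(f"case date {case_date.date()} outside the period")
    week = pd.Timedelta(days=7)
    return [d for d in (case_date - week, case_date + week)
            if start <= d <= end]


def time_stratified_referents(case_date, period) -> list[pd.Timestamp]:
    """All same-weekday days in the case's calendar month and year."""
    case_date = pd.Timestamp(case_date)
    start, end = _as_period(period)
    if not start <= case_date <= end:
        raise ValueError(f"case date {case_date.date()} outside the period")
    month_days = pd.date_range(case_date.replace(day=1),
                               case_date.replace(day=case_date.days_in_month),
                               freq="D")
    return [d for d in month_days
            if d.dayofweek == case_date.dayofweek and d != case_date
            and start <= d <= end]


_DESIGNS = {"symmetric": symmetric_referents,
            "time_stratified": time_stratified_referents}


# ---------------------------------------------------------------------------
# stratum assembly
# ---------------------------------------------------------------------------

def _day_covariates(calendar: ConfounderCalendar,
                    dates: list[pd.Timestamp]) -> np.ndarray | None:
    """Per-day confounders incl. mean lag 0–1 apparent temperature ± square."""
    frame = calendar.frame
    rows = np.empty((len(dates), len(COVARIATE_COLUMNS)))
    for i, date in enumerate(dates):
        prev = date - pd.Timedelta(days=1)
        if date not in frame.index or prev not in frame.index:
            return None
        today = frame.loc[date]
        at01 = 0.5 * (today["apparent_temperature"]
                      + frame.loc[prev, "apparent_temperature"])
        rows[i] = (today["summer_reduction"], today["holiday"],
                   today["influenza"], at01, at01 ** 2)
    return rows


def assemble_strata(events: list[HospitalizationEvent],
                    cohort: list[Subject],
                    grid: ExposureGrid,
                    period,
                    design: str = "symmetric",
                    L: int = 6,
                    calendar: ConfounderCalendar | None = None,
                    with_covariates: bool = False,
                    pre_filtered: bool = False,
                    ) -> list[CaseCrossoverStratum]:
    """Build one matched stratum per qualifying admission.

    Applies the acute/ICD-9 filter (unless ``pre_filtered``), selects
    referents under ``design``, links each day to the subject's grid cell,
    and drops days with incomplete lag vectors and strata left without any
    control day.  When ``with_covariates`` is set, each retained day carries
    the three calendar indicators plus the mean lag 0–1 apparent temperature
    and its square.
    """
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; "
                         f"expected one of {sorted(_DESIGNS)}")
    if with_covariates and calendar is None:
        raise ValueError("with_covariates requires a calendar")
    referents = _DESIGNS[design]
    subjects = {s.subject_id: s for s in cohort}
    if not pre_filtered:
        events = filter_events(events)
    strata: list[CaseCrossoverStratum] = []
    for event in events:
        subject = subjects.get(event.subject_id)
        if subject is None:
            logger.warning("skipping event for unknown subject %s",
                           event.subject_id)
            continue
        try:
            cell = locate_cell(grid, subject.x, subject.y,
                               subject_id=subject.subject_id)
        except OutOfDomainError as err:
            logger.warning("skipping event: %s", err)
            continue
        case_date = pd.Timestamp(event.admission_date)
        controls = referents(case_date, period)
        if not controls:
            continue
        days = [case_date, *controls]
        vectors = [build_lag_vector(grid, cell, d, L=L) for d in days]
        keep = [i for i, v in enumerate(vectors) if v.complete]
        if 0 not in keep or len(keep) < 2:
            continue  # case day unusable, or no control survives
        kept_controls = [days[i] for i in keep if i > 0]
        lag_matrix = np.vstack([vectors[i].values for i in keep])
        covariates = None
        if with_covariates:
            covariates = _day_covariates(
                calendar, [case_date, *kept_controls])
            if covariates is None:
                continue  # calendar does not cover a retained day
        strata.append(CaseCrossoverStratum(
            stratum_id=len(strata), subject_id=subject.subject_id,
            case_date=case_date, control_dates=kept_controls,
            lag_matrix=lag_matrix, pollutant=grid.pollutant,
            resolution=grid.resolution, covariates=covariates))
    return strata


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def strata_to_long(strata: list[CaseCrossoverStratum]) -> pd.DataFrame:
    """Analysis-ready long table: one row per study day."""
    rows = []
    for s in strata:
        for i, date in enumerate(s.dates):
            row = {"stratum_id": s.stratum_id, "subject_id": s.subject_id,
                   "day_role": "case" if i == 0 else "control",
                   "date": date.strftime("%Y-%m-%d")}
            row.update({f"lag{l}": s.lag_matrix[i, l]
                        for l in range(s.lag_matrix.shape[1])})
            if s.covariates is not None:
                row.update(dict(zip(COVARIATE_COLUMNS, s.covariates[i])))
            rows.append(row)
    return pd.DataFrame(rows)


def strata_to_arrays(strata: list[CaseCrossoverStratum],
                     with_covariates: bool = False,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack strata into (X, y, groups) for the conditional-logistic fit.

    X holds the lag columns first, then (optionally) the covariate columns;
    y marks the case day of each stratum; groups is the stratum index of
    each row.
    """
    if not strata:
        raise ValueError("no strata to stack")
    blocks, ys, gs = [], [], []
    for g, s in enumerate(strata):
        block = s.lag_matrix
        if with_covariates:
            if s.covariates is None:
                raise ValueError(
                    f"stratum {s.stratum_id} has no covariates attached")
            block = np.hstack([block, s.covariates])
        blocks.append(block)
        y = np.zeros(s.n_days)
        y[0] = 1.0
        ys.append(y)
        gs.append(np.full(s.n_days, g))
    return np.vstack(blocks), np.concatenate(ys), np.concatenate(gs)
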