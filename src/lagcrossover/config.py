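"""Study configuration for the synthetic case-crossover pipeline.

The defaults emulate a small two-area cohort (one urban, one suburban)
followed for five years, with daily pollutant fields on a coarse (1 km-like)
and a fine (200 m-like) grid, and sparse acute cardiovascular events driven
by a log-linear distributed-lag exposure effect.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class PollutantSpec:
    """Stochastic structure of one pollutant's daily concentration field.

    The daily series in every grid cell is

        max(0, annual_mean + seasonal sinusoid + shared AR(1) regional term
               + fixed per-cell offset + per-cell daily noise)

    with the regional AR(1) term shared between the coarse and fine grids so
    the two resolutions stay correlated.  All concentration units are µg/m³.
    """

    annual_mean: float = 26.0
    seasonal_amplitude: float = 7.0
    #: day of year at which the seasonal sinusoid peaks (mid-January for
    #: combustion pollutants, mid-July for ozone)
    seasonal_peak_doy: int = 15
    ar1_coefficient: float = 0.75
    daily_noise_sd: float = 3.5
    cell_offset_sd: float = 2.0
    cell_noise_sd: float = 2.0

    def validate(self) -> None:
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ConfigError(
                f"ar1_coefficient must be in [0, 1), got {self.ar1_coefficient}"
            )
        for name in ("seasonal_amplitude", "daily_noise_sd", "cell_offset_sd",
                     "cell_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class LagEffect:
    """True distributed-lag effect on the log-odds/log-hazard scale.

    ``intercept`` is the log-OR per µg/m³ at lag 0 and ``slope`` the change
    per unit lag, so the per-lag coefficient is ``intercept + slope * l``.
    The defaults correspond to a lag-0 OR of about 1.27 per 10 µg/m³
    declining to below 1 by lag 5–6, the magnitude typical of particulate
    effects on acute cardiovascular admissions.
    """

    intercept: float = math.log(1.268) / 10.0
    slope: float = (math.log(1.190) - math.log(1.268)) / 10.0

    def coefficients(self, max_lag: int) -> list[float]:
        return [self.intercept + self.slope * l for l in range(max_lag + 1)]

    def lag0_or_per_10(self) -> float:
        return math.exp(10.0 * self.intercept)


@dataclass
class ModifierEffect:
    """Optional effect modification by one binary subject attribute.

    Subjects at level 1 of ``factor`` get ``intercept + delta_intercept``
    and ``slope + delta_slope`` instead of the base lag effect.
    """

    factor: str = "gender"
    delta_intercept: float = 0.0
    delta_slope: float = 0.0


@dataclass
class ConfounderEffects:
    """Log-hazard terms for the time-varying confounder calendar.

    ``temperature_quadratic`` multiplies ((T - 20 °C) / 10)², the U-shaped
    excess risk away from mild apparent temperature.
    """

    summer_reduction: float = -0.2
    holiday: float = -0.2
    influenza: float = 0.3
    temperature_quadratic: float = 0.05


DEFAULT_POLLUTANTS: dict[str, PollutantSpec] = {
    "pm10": PollutantSpec(annual_mean=26.0, seasonal_amplitude=7.0),
    "pm25": PollutantSpec(annual_mean=17.0, seasonal_amplitude=6.0),
    "no2": PollutantSpec(annual_mean=27.0, seasonal_amplitude=6.0),
    "o3": PollutantSpec(annual_mean=47.0, seasonal_amplitude=25.0,
                        seasonal_peak_doy=196, daily_noise_sd=7.0),
}

#: prevalence of the "exposed"/level-1 category of each binary risk factor
DEFAULT_PREVALENCES: dict[str, float] = {
    "age_ge85": 0.05,
    "male": 0.45,
    "ever_smoker": 0.50,
    "occupational_exposure": 0.45,
    "preexisting_cvd_resp": 0.25,
}


@dataclass
class SimulationConfig:
    """Everything needed to regenerate one synthetic study, given a seed."""

    date_start: str = "2011-01-01"
    date_end: str = "2015-12-31"
    n_subjects: int = 1585
    #: fraction of the cohort living in the urban area
    urban_fraction: float = 0.41
    grid_origin_x: float = 0.0
    grid_origin_y: float = 0.0
    #: map extent in metre-like map units; the urban area is the western
    #: strip [0, urban_fraction * extent_x), the suburban area the rest
    extent_x: float = 6000.0
    extent_y: float = 4000.0
    cell_size_coarse: float = 1000.0
    cell_size_fine: float = 200.0
    pollutants: dict[str, PollutantSpec] = field(
        default_factory=lambda: {k: dataclasses.replace(v)
                                 for k, v in DEFAULT_POLLUTANTS.items()})
    true_lag_effect: LagEffect = field(default_factory=LagEffect)
    modifier_effect: ModifierEffect | None = None
    max_lag: int = 6
    #: events per subject-day before exposure/confounder multipliers;
    #: calibrated so the default five-year study yields ≈137 qualifying
    #: events under the default lag effect (realised multiplier ≈2.55)
    baseline_hazard: float = 1.85e-5
    confounder_effects: ConfounderEffects = field(
        default_factory=ConfounderEffects)
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    causal_pollutant: str = "pm10"
    causal_resolution: str = "coarse"
    #: whether a subject may contribute more than one event
    allow_repeat_events: bool = True
    #: fraction of extra non-qualifying events (scheduled or non-CVD codes)
    #: added to exercise the event filters
    noise_event_fraction: float = 0.3
    #: mean and amplitude of the apparent-temperature sinusoid (°C)
    temperature_mean: float = 15.0
    temperature_amplitude: float = 10.0
    temperature_noise_sd: float = 2.0
    #: inclusive influenza-epidemic window, as (month, day) pairs
    influenza_start: tuple[int, int] = (1, 1)
    influenza_end: tuple[int, int] = (2, 15)
    seed: int = 0

    # -- derived helpers -------------------------------------------------
    @property
    def start(self) -> pd.Timestamp:
        return pd.Timestamp(self.date_start)

    @property
    def end(self) -> pd.Timestamp:
        return pd.Timestamp(self.date_end)

    @property
    def period(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (self.start, self.end)

    def cell_size(self, resolution: str) -> float:
        if resolution == "coarse":
            return self.cell_size_coarse
        if resolution == "fine":
            return self.cell_size_fine
        raise ConfigError(f"unknown resolution {resolution!r}")

    def validate(self) -> "SimulationConfig":
        if self.end <= self.start + pd.Timedelta(days=self.max_lag):
            raise ConfigError("date_end must exceed date_start + max_lag days")
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigError("urban_fraction must be in [0, 1]")
        if not 0.0 < self.baseline_hazard < 1.0:
            raise ConfigError("baseline_hazard must be in (0, 1)")
        if self.cell_size_coarse <= 0 or self.cell_size_fine <= 0:
            raise ConfigError("cell sizes must be positive")
        if self.extent_x <= 0 or self.extent_y <= 0:
            raise ConfigError("grid extent must be positive")
        if self.max_lag < 0:
            raise ConfigError("max_lag must be >= 0")
        for name, spec in self.pollutants.items():
            spec.validate()
        if self.causal_pollutant not in self.pollutants:
            raise ConfigError(
                f"causal pollutant {self.causal_pollutant!r} not configured")
        for name, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence {name} must be in [0, 1]")
        return self

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "pollutants" in data:
            data["pollutants"] = {
                name: spec if isinstance(spec, PollutantSpec)
                else PollutantSpec(**spec)
                for name, spec in data["pollutants"].items()
            }
        for key, typ in (("true_lag_effect", LagEffect),
                         ("confounder_effects", ConfounderEffects),
                         ("modifier_effect", ModifierEffect)):
            if isinstance(data.get(key), Mapping):
                data[key] = typ(**data[key])
        for key in ("influenza_start", "influenza_end"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
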