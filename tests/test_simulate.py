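"""Synthetic-data generator: determinism, calibration, degenerate cases."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from lagcrossover import (CalibrationError, ConfigError, LagEffect,
                          PollutantSpec, SimulationConfig,
                          generate_cohort, generate_confounder_calendar,
                          generate_exposure_grid, simulate_events,
                          simulate_matched_sets, simulate_study)
from lagcrossover.simulate import easter_sunday


def noise_free_config(**kw):
    spec = PollutantSpec(annual_mean=25.0, seasonal_amplitude=0.0,
                         ar1_coefficient=0.0, daily_noise_sd=0.0,
                         cell_offset_sd=0.0, cell_noise_sd=0.0)
    return SimulationConfig(
        date_start="2013-01-01", date_end="2013-03-31",
        pollutants={"pm10": spec}, causal_pollutant="pm10",
        n_subjects=20, extent_x=2000.0, extent_y=2000.0, seed=1, **kw)


def test_noise_free_grid_is_constant():
    grid = generate_exposure_grid(noise_free_config(), "pm10", "coarse")
    assert np.all(grid.values == 25.0)


def test_noise_free_seasonal_curve_is_deterministic():
    cfg = noise_free_config()
    cfg.pollutants["pm10"].seasonal_amplitude = 5.0
    grid = generate_exposure_grid(cfg, "pm10", "fine")
    doy = grid.dates.dayofyear.to_numpy()
    expected = 25.0 + 5.0 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    # every cell reproduces the seasonal curve exactly
    assert np.allclose(grid.values, expected[None, None, :], atol=1e-12)


def test_same_seed_gives_bit_identical_grids():
    cfg = SimulationConfig(seed=42, date_start="2013-01-01",
                           date_end="2013-06-30", n_subjects=10)
    g1 = generate_exposure_grid(cfg, "pm10", "coarse")
    g2 = generate_exposure_grid(cfg, "pm10", "coarse")
    assert np.array_equal(g1.values, g2.values)


def test_different_seed_changes_grids():
    base = dict(date_start="2013-01-01", date_end="2013-06-30",
                n_subjects=10)
    g1 = generate_exposure_grid(SimulationConfig(seed=1, **base),
                                "pm10", "coarse")
    g2 = generate_exposure_grid(SimulationConfig(seed=2, **base),
                                "pm10", "coarse")
    assert not np.array_equal(g1.values, g2.values)


def test_default_pooled_iqr_near_ten():
    """Default noise structure yields an IQR around 10 µg/m³ for PM."""
    cfg = SimulationConfig(seed=5)
    grid = generate_exposure_grid(cfg, "pm10", "coarse")
    q25, q75 = np.percentile(grid.values, [25, 75])
    assert 7.0 < q75 - q25 < 16.0


def test_coarse_and_fine_grids_share_regional_signal():
    cfg = SimulationConfig(seed=9, date_start="2013-01-01",
                           date_end="2015-12-31", n_subjects=10)
    coarse = generate_exposure_grid(cfg, "pm10", "coarse")
    fine = generate_exposure_grid(cfg, "pm10", "fine")
    r = np.corrcoef(coarse.values[0, 0, :], fine.values[0, 0, :])[0, 1]
    assert r > 0.5


def test_grid_errors():
    cfg = noise_free_config()
    cfg.cell_size_coarse = -5.0
    with pytest.raises(ConfigError):
        generate_exposure_grid(cfg, "pm10", "coarse")
    with pytest.raises(ConfigError):
        SimulationConfig(date_start="2013-01-10",
                         date_end="2013-01-12").validate()


# -- cohort ---------------------------------------------------------------

def test_cohort_area_split_matches_fraction():
    cfg = SimulationConfig(n_subjects=1585, urban_fraction=0.41, seed=3)
    cohort = generate_cohort(cfg)
    n_urban = sum(1 for s in cohort if s.area == "urban")
    # binomial 3-sigma band around 41%
    se = math.sqrt(0.41 * 0.59 / 1585)
    assert abs(n_urban / 1585 - 0.41) < 3 * se
    # coordinates respect the area boundary and the grid extent
    split = 0.41 * cfg.extent_x
    for s in cohort:
        assert (s.x < split) == (s.area == "urban")
        assert 0 <= s.x < cfg.extent_x and 0 <= s.y < cfg.extent_y


def test_cohort_degenerate_split_and_reproducibility():
    cfg = SimulationConfig(n_subjects=50, urban_fraction=1.0, seed=2)
    cohort = generate_cohort(cfg)
    assert all(s.area == "urban" for s in cohort)
    assert generate_cohort(cfg) == cohort
    with pytest.raises(ConfigError):
        SimulationConfig(n_subjects=0).validate()


# -- calendar -------------------------------------------------------------

def test_calendar_flags():
    cfg = SimulationConfig(date_start="2013-01-01", date_end="2013-12-31",
                           n_subjects=5, seed=1)
    cal = generate_confounder_calendar(cfg)
    assert cal.lookup("2013-08-01")["summer_reduction"] == 1
    assert cal.lookup("2013-12-25")["holiday"] == 1
    row = cal.lookup("2013-10-01")
    assert row["summer_reduction"] == 0 and row["holiday"] == 0
    assert cal.lookup("2013-01-20")["influenza"] == 1
    # Easter 2013 fell on 31 March; the day after is flagged too
    assert easter_sunday(2013) == pd.Timestamp("2013-03-31")
    assert cal.lookup("2013-04-01")["holiday"] == 1


@pytest.mark.parametrize("year,expected", [
    (2011, "2011-04-24"), (2014, "2014-04-20"), (2015, "2015-04-05"),
])
def test_easter_computus(year, expected):
    assert easter_sunday(year) == pd.Timestamp(expected)


# -- events ---------------------------------------------------------------

def null_config(baseline, n_subjects=300, seed=4):
    cfg = SimulationConfig(
        date_start="2013-01-01", date_end="2014-12-31",
        n_subjects=n_subjects, extent_x=2000.0, extent_y=2000.0,
        baseline_hazard=baseline, seed=seed,
        true_lag_effect=LagEffect(intercept=0.0, slope=0.0),
        noise_event_fraction=0.0)
    cfg.confounder_effects.summer_reduction = 0.0
    cfg.confounder_effects.holiday = 0.0
    cfg.confounder_effects.influenza = 0.0
    cfg.confounder_effects.temperature_quadratic = 0.0
    return cfg


def run_null(baseline, seed=4):
    cfg = null_config(baseline, seed=seed)
    study = simulate_study(cfg, resolutions=("coarse",))
    n_days = (cfg.end - cfg.start).days + 1
    return len(study["events"]), cfg.n_subjects * n_days


def test_null_event_rate_matches_baseline_hazard():
    count, exposure = run_null(5e-4)
    expected = 5e-4 * exposure
    assert abs(count - expected) < 3 * math.sqrt(expected)


def test_event_counts_scale_linearly_with_baseline():
    counts = []
    for i, baseline in enumerate((2e-4, 4e-4, 8e-4)):
        count, exposure = run_null(baseline, seed=10 + i)
        counts.append(count)
    for j, expected in enumerate((2e-4, 4e-4, 8e-4)):
        mu = expected * exposure
        assert abs(counts[j] - mu) < 3 * math.sqrt(mu)


def test_calibration_error_on_capped_hazard():
    cfg = null_config(0.9)
    cfg.true_lag_effect = LagEffect(intercept=0.05, slope=0.0)
    with pytest.raises(CalibrationError):
        simulate_study(cfg, resolutions=("coarse",))


def test_repeat_events_configurable(tiny_config):
    cfg = dataclasses.replace(tiny_config, allow_repeat_events=False,
                              noise_event_fraction=0.0,
                              baseline_hazard=2e-3)
    study = simulate_study(cfg, resolutions=("coarse",))
    ids = [e.subject_id for e in study["events"]]
    assert len(ids) == len(set(ids))


def test_study_is_reproducible(tiny_config):
    s1 = simulate_study(tiny_config, resolutions=("coarse",))
    s2 = simulate_study(tiny_config, resolutions=("coarse",))
    assert s1["cohort"] == s2["cohort"]
    assert s1["events"] == s2["events"]
    assert np.array_equal(s1["grids"][("pm10", "coarse")].values,
                          s2["grids"][("pm10", "coarse")].values)
    pd.testing.assert_frame_equal(s1["calendar"].frame, s2["calendar"].frame)


def test_brute_force_grid_search_recovers_lag_effect():
    """Coarse (a, b) likelihood grid peaks at the configured truth."""
    from lagcrossover.model import conditional_loglik, make_lag_basis
    rng = np.random.default_rng(21)
    a, b = 0.024, -0.006
    X, y, g, _ = simulate_matched_sets(4000, a, b, rng)
    basis = make_lag_basis("linear", 6)
    a_grid = np.linspace(0.0, 0.048, 25)
    b_grid = np.linspace(-0.012, 0.0, 25)
    ll = np.array([[conditional_loglik((ai, bi), X, y, g, basis)["value"]
                    for bi in b_grid] for ai in a_grid])
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    assert abs(a_grid[i] - a) <= 0.006
    assert abs(b_grid[j] - b) <= 0.0015
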