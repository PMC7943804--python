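"""Synthetic county-day hospitalization panels with known truth.

Generates Medicare-like daily hospitalization counts per county with the
statistical structure the downstream analysis assumes: winter-peaking
seasonality, day-of-week variation, a linear temperature effect, rare
May--October tropical-cyclone wind exposures with multiplicative lagged
effects, a log-population offset, and quasi-Poisson overdispersion
(variance proportional to the mean).  Every run is reproducible
bit-for-bit from the configuration's integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_panel",
    "write_panel",
    "write_truth",
]

#: calendar days in May..October (non-leap; leap years gain no in-window day)
_MAY_OCT_DAYS = 184


@dataclass(frozen=True)
class SimConfig:
    """Data-generating parameters for a county-day hospitalization panel.

    Defaults emulate the study design the analysis targets: 16 calendar
    years, exposures at ~0.18 county-days per year confined to the
    May--October storm season (≈2.9 expected exposure days per county
    over 16 years), ~5% of exposure days reaching hurricane force, and
    mild overdispersion.

    Parameters
    ----------
    baseline_rate
        Expected daily hospitalizations per 10,000 enrollees on the
        reference day (Sunday) at 0 °C, season-neutral.
    seasonal_amplitude
        Log-scale amplitude of the annual sinusoid in the count mean
        (peak mid-January, matching winter-dominant causes).
    dow_log_effects
        Log rate ratios for Monday..Saturday; Sunday is the reference.
    temp_log_effect
        Per-°C slope on the log count rate.
    true_beta_lags
        Log rate ratios for exposure lags 0..7 (the quantity the fitted
        model must recover).
    exposure_rate
        Expected exposure days per county per year; events are drawn
        independently per county-day within May--October.
    hurricane_fraction
        Share of exposure days drawn at hurricane force (>=64 kt).
    dispersion
        Quasi-Poisson dispersion phi >= 1; counts follow an NB1
        (gamma-mixed Poisson) law with Var = phi * mean.
    storm_run_mean
        Mean extra consecutive exposure days appended after each drawn
        event (geometric run length); 0 disables clustering.
    population_drift
        Per-year multiplicative drift in enrollee population (0 keeps
        each county's population constant across years).
    """

    n_counties: int = 100
    start_year: int = 1999
    end_year: int = 2014
    baseline_rate: float = 1.0
    seasonal_amplitude: float = 0.2
    dow_log_effects: tuple[float, ...] = (0.10, 0.09, 0.08, 0.08, 0.07, -0.02)
    temp_log_effect: float = 0.005
    true_beta_lags: tuple[float, ...] = (0.0,) * 8
    exposure_rate: float = 0.18
    hurricane_fraction: float = 0.05
    dispersion: float = 1.5
    population_range: tuple[int, int] = (5_000, 50_000)
    storm_run_mean: float = 0.0
    population_drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 1:
            raise ValueError("n_counties must be positive")
        if self.end_year < self.start_year:
            raise ValueError("end_year must be >= start_year")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1 (quasi-Poisson)")
        if self.exposure_rate < 0:
            raise ValueError("exposure_rate must be >= 0")
        if not (0.0 <= self.hurricane_fraction <= 1.0):
            raise ValueError("hurricane_fraction must lie in [0, 1]")
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ValueError("population_range must be positive and ordered")
        if len(self.dow_log_effects) != 6:
            raise ValueError("dow_log_effects must have 6 entries (Sunday is the reference)")
        if len(self.true_beta_lags) != 8:
            raise ValueError("true_beta_lags must have 8 entries (lags 0..7)")
        for name in ("baseline_rate", "seasonal_amplitude", "temp_log_effect"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not np.all(np.isfinite(self.dow_log_effects)) or not np.all(
            np.isfinite(self.true_beta_lags)
        ):
            raise ValueError("effect vectors must be finite")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated panel.

    ``exposure_calendar`` lists every planted exposure day with its wind
    category; ``true_beta`` is the lag-coefficient vector in design-column
    order; ``expected_count`` is the per-row conditional mean aligned with
    the panel rows.
    """

    config: SimConfig
    exposure_calendar: pd.DataFrame
    true_beta: pd.Series
    expected_count: np.ndarray


def simulate_counts(
    mean: float | np.ndarray, dispersion: float, rng: np.random.Generator
) -> int | np.ndarray:
    """Draw overdispersed counts with E = mean and Var = dispersion * mean.

    Uses the NB1 parameterization: a gamma-mixed Poisson with gamma shape
    ``mean / (phi - 1)`` and scale ``phi - 1``, which preserves the mean
    and inflates the variance to ``phi * mean``.  ``phi = 1`` is pure
    Poisson.
    """
    if dispersion < 1.0:
        raise ValueError("dispersion must be >= 1")
    mean_arr = np.asarray(mean, dtype=float)
    if np.any(mean_arr <= 0) or not np.all(np.isfinite(mean_arr)):
        raise ValueError("mean must be positive and finite")
    if dispersion == 1.0:
        out = rng.poisson(mean_arr)
    else:
        scale = dispersion - 1.0
        lam = rng.gamma(shape=mean_arr / scale, scale=scale)
        out = rng.poisson(lam)
    if np.isscalar(mean):
        return int(out)
    return out


def _county_ids(n: int) -> list[str]:
    # FIPS-style 5-char ids spread over 10 synthetic states (leading 2 chars)
    return [f"{(i % 10) + 1:02d}{i:03d}" for i in range(n)]


def _draw_exposure_days(
    in_season: np.ndarray, rate: float, run_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli exposure indicator on one county's daily grid.

    ``in_season`` marks May--October days.  The per-day probability is
    calibrated so the expected number of seed events per year equals
    ``rate``; optional geometric run lengths append consecutive days.
    """
    p = min(rate / _MAY_OCT_DAYS, 1.0)
    exposed = in_season & (rng.random(in_season.size) < p)
    if run_mean > 0:
        starts = np.flatnonzero(exposed)
        extra = rng.geometric(1.0 / (1.0 + run_mean), size=starts.size) - 1
        for t0, k in zip(starts, extra):
            hi = min(t0 + int(k) + 1, exposed.size)
            run = slice(t0, hi)
            exposed[run] = exposed[run] | in_season[run]
    return exposed


def simulate_panel(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a county-day panel and its ground truth.

    The per-row log mean is::

        log(population) + log(baseline_rate / 10_000)
        + seasonal sinusoid + DOW effect
        + temp_log_effect * temperature
        + sum_l true_beta_lags[l] * exposure(t - l)

    with exposure days drawn only in May--October and counts drawn by
    :func:`simulate_counts`.  Identical ``(config, seed)`` yields an
    identical panel.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_pop, rng_temp, rng_exp, rng_cat, rng_cnt, rng_wind = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    dates = pd.date_range(
        f"{config.start_year}-01-01", f"{config.end_year}-12-31", freq="D"
    )
    n_days = dates.size
    doy = dates.dayofyear.to_numpy()
    dow = dates.dayofweek.to_numpy()  # Mon=0 .. Sun=6
    year = dates.year.to_numpy()
    in_season = (dates.month >= 5) & (dates.month <= 10)
    in_season = np.asarray(in_season)

    # shared weather seasonality; per-county noise added below
    season_temp = 15.0 + 10.0 * np.cos(2 * np.pi * (doy - 196) / 365.25)
    season_count = config.seasonal_amplitude * np.cos(2 * np.pi * (doy - 15) / 365.25)
    dow_eff = np.append(np.asarray(config.dow_log_effects, dtype=float), 0.0)[dow]

    counties = _county_ids(config.n_counties)
    lo, hi = config.population_range
    base_pop = rng_pop.integers(lo, hi + 1, size=config.n_counties)

    beta = np.asarray(config.true_beta_lags, dtype=float)
    frames: list[pd.DataFrame] = []
    mu_all: list[np.ndarray] = []
    cal_rows: list[pd.DataFrame] = []

    for ci, county in enumerate(counties):
        pop = np.full(n_days, base_pop[ci], dtype=float)
        if config.population_drift != 0.0:
            pop = np.round(
                base_pop[ci]
                * (1.0 + config.population_drift) ** (year - config.start_year)
            )
        temp = season_temp + rng_temp.normal(0.0, 3.0, size=n_days)

        exposed = _draw_exposure_days(
            in_season, config.exposure_rate, config.storm_run_mean, rng_exp
        )
        is_hurricane = exposed & (rng_cat.random(n_days) < config.hurricane_fraction)
        wind = rng_wind.uniform(0.0, 20.0, size=n_days)
        gale = exposed & ~is_hurricane
        wind[gale] = rng_wind.uniform(34.0, 64.0, size=int(gale.sum()))
        wind[is_hurricane] = rng_wind.uniform(64.0, 120.0, size=int(is_hurricane.sum()))

        lag_term = np.zeros(n_days)
        exp_f = exposed.astype(float)
        for l in range(8):
            if beta[l] != 0.0:
                lag_term[l:] += beta[l] * exp_f[: n_days - l if l else n_days]

        log_mu = (
            np.log(pop)
            + np.log(config.baseline_rate / 10_000.0)
            + season_count
            + dow_eff
            + config.temp_log_effect * temp
            + lag_term
        )
        mu = np.exp(log_mu)
        counts = simulate_counts(mu, config.dispersion, rng_cnt)

        frames.append(
            pd.DataFrame(
                {
                    "county_id": county,
                    "date": dates,
                    "count": counts,
                    "population": pop.astype(int),
                    "temperature": temp,
                    "wind_knots": wind,
                }
            )
        )
        mu_all.append(mu)
        if exposed.any():
            cal_rows.append(
                pd.DataFrame(
                    {
                        "county_id": county,
                        "date": dates[exposed],
                        "category": np.where(
                            is_hurricane[exposed], "hurricane", "gale_to_violent_storm"
                        ),
                    }
                )
            )

    panel = pd.concat(frames, ignore_index=True)
    calendar = (
        pd.concat(cal_rows, ignore_index=True)
        if cal_rows
        else pd.DataFrame(columns=["county_id", "date", "category"])
    )
    truth = SimTruth(
        config=config,
        exposure_calendar=calendar,
        true_beta=pd.Series(beta, index=[f"exposure_lag{l}" for l in range(8)]),
        expected_count=np.concatenate(mu_all),
    )
    return panel, truth


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel as CSV with ISO-8601 dates."""
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.10g")


def read_panel(path) -> pd.DataFrame:
    """Read a panel written by :func:`write_panel`."""
    panel = pd.read_csv(path, dtype={"county_id": str})
    panel["date"] = pd.to_datetime(panel["date"])
    return panel


def write_truth(truth: SimTruth, path) -> None:
    """Write ground-truth parameters as a flat key=value sidecar."""
    lines = []
    for f in dataclasses.fields(truth.config):
        lines.append(f"{f.name} = {getattr(truth.config, f.name)}")
    for name, val in truth.true_beta.items():
        lines.append(f"true_{name} = {val!r}")
    lines.append(f"n_exposure_days = {len(truth.exposure_calendar)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
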