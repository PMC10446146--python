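"""Synthetic chamber series and filter samples with known ground truth.

Every pipeline stage can be exercised without instrument data: the chamber
generator emulates a sealed-chamber test (linear accumulation from a
constant source, additive instrument noise, and intermittent infiltration
spikes caused by brief external sampling draws), and the filter generator
emulates a gravimetric sampling campaign with a known true release factor
and an assay LOQ.

All generators are deterministic given their integer seed (one named
random stream per generator, no global state), and each returns a truth
record carrying the parameters that regenerate the dataset bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from .inference import (
    ConcentrationSeries,
    ExclusionIntervals,
    block_average,
    derivative_stats,
    emission_bound,
    mask_series,
)
from .release import FilterSample, SurfaceSpec, release_factors
from .units import tio2_to_ti

__all__ = [
    "ChamberSimConfig",
    "FilterSimConfig",
    "ChamberTruth",
    "FilterTruth",
    "RecoverySummary",
    "gen_chamber_series",
    "gen_filter_sample",
    "recovery_experiment",
]

_CM3_PER_M3 = 1e6
_S_PER_H = 3600.0
#: spikes are masked until decayed to 1% of their initial magnitude
_SPIKE_DECAY_FOLDS = math.log(100.0)


class ChamberSimConfig(BaseModel, frozen=True):
    """Sealed-chamber number-concentration simulation.

    Defaults emulate a three-day 220 L chamber test sampled at 1 Hz: a
    constant source of 4400 particles/s, a background of 8 1/cm3, additive
    Gaussian instrument noise of 0.5 1/cm3, and brief infiltration spikes
    (about three per day, a few 1/cm3, decaying within minutes) caused by
    external sampling draws pulling laboratory air into the chamber.
    """

    true_g_per_s: float = Field(default=4400.0, ge=0)
    volume_m3: float = Field(default=0.22, gt=0)
    c0_per_cm3: float = Field(default=8.0, ge=0)
    duration_s: float = Field(default=259200.0, gt=0)
    dt_s: float = Field(default=1.0, gt=0)
    noise_sd_per_cm3: float = Field(default=0.5, ge=0)
    spike_rate_per_h: float = Field(default=0.125, ge=0)
    spike_magnitude_per_cm3: float = Field(default=5.0, ge=0)
    spike_decay_per_h: float = Field(default=30.0, gt=0)
    seed: int = 0

    @property
    def slope_per_cm3_s(self) -> float:
        """True concentration slope G / V in 1/(cm3*s)."""
        return self.true_g_per_s / (self.volume_m3 * _CM3_PER_M3)


class FilterSimConfig(BaseModel, frozen=True):
    """Filter-sampling simulation with a known true TiO2 release factor.

    Defaults emulate a 96 h open-circuit campaign at the empirical mean
    flow of a 303.7 m3 sample, three 90 cm2 coated honeycombs, and a 1 ng
    Ti LOQ. Collected mass may carry multiplicative lognormal measurement
    noise (geometric sd exp(noise_sd_log); 0 disables it).
    """

    true_rf_ng_m2_m3: float = Field(default=0.185, ge=0)
    n_units: int = Field(default=3, ge=1)
    area_per_unit_m2: float = Field(default=0.009, gt=0)
    flow_m3_h: float = Field(default=303.7 / 96.0, gt=0)
    duration_h: float = Field(default=96.0, gt=0)
    loq_ng: float = Field(default=1.0, gt=0)
    noise_sd_log: float = Field(default=0.0, ge=0)
    seed: int = 0

    @property
    def surface(self) -> SurfaceSpec:
        return SurfaceSpec(n_units=self.n_units, area_per_unit_m2=self.area_per_unit_m2)


@dataclass(frozen=True)
class ChamberTruth:
    """Ground truth accompanying a generated chamber series."""

    config: ChamberSimConfig
    true_g_per_s: float
    slope_per_cm3_s: float
    spike_times_s: tuple[float, ...]
    exclusions: ExclusionIntervals


@dataclass(frozen=True)
class FilterTruth:
    """Ground truth accompanying a generated filter sample."""

    config: FilterSimConfig
    true_rf_ng_m2_m3: float
    tio2_mass_ng: float
    ti_mass_ng: float
    censored: bool


def gen_chamber_series(cfg: ChamberSimConfig) -> tuple[ConcentrationSeries, ChamberTruth]:
    """Simulate the chamber number-concentration series.

    signal = C0 + (G/V) t, plus independent Gaussian noise (truncated at 0)
    and Poisson-arriving exponentially decaying spikes. Spike windows are
    returned as exclusion-interval ground truth (each window extends until
    the spike has decayed to 1% of its magnitude).
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration_s, cfg.dt_s)
    signal = cfg.c0_per_cm3 + cfg.slope_per_cm3_s * t
    values = signal.copy()
    if cfg.noise_sd_per_cm3 > 0:
        values = values + rng.normal(0.0, cfg.noise_sd_per_cm3, size=t.size)

    duration_h = cfg.duration_s / _S_PER_H
    n_spikes = rng.poisson(cfg.spike_rate_per_h * duration_h) if cfg.spike_rate_per_h > 0 else 0
    spike_times = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_spikes))
    decay_per_s = cfg.spike_decay_per_h / _S_PER_H
    intervals = []
    for ts in spike_times:
        after = t >= ts
        values[after] += cfg.spike_magnitude_per_cm3 * np.exp(-decay_per_s * (t[after] - ts))
        intervals.append((float(ts), float(ts + _SPIKE_DECAY_FOLDS / decay_per_s)))

    series = ConcentrationSeries(
        timestamps_s=t,
        values=np.clip(values, 0.0, None),
        metric="number",
        instrument_label=f"synthetic-chamber(seed={cfg.seed})",
    )
    truth = ChamberTruth(
        config=cfg,
        true_g_per_s=cfg.true_g_per_s,
        slope_per_cm3_s=cfg.slope_per_cm3_s,
        spike_times_s=tuple(float(x) for x in spike_times),
        exclusions=ExclusionIntervals(tuple(intervals)),
    )
    return series, truth


def gen_filter_sample(cfg: FilterSimConfig) -> tuple[FilterSample, FilterTruth]:
    """Simulate one gravimetric filter sample.

    Collected TiO2 mass = rf * area * flow * duration; the assayed Ti mass
    is its Ti fraction, optionally perturbed by lognormal noise, and the
    sample is censored iff the Ti mass falls strictly below the LOQ (a mass
    exactly equal to the LOQ is reported as measured).
    """
    rng = np.random.default_rng(cfg.seed)
    volume = cfg.flow_m3_h * cfg.duration_h
    tio2_mass = cfg.true_rf_ng_m2_m3 * cfg.surface.total_area_m2 * volume
    ti_mass = tio2_to_ti(tio2_mass)
    if cfg.noise_sd_log > 0 and ti_mass > 0:
        ti_mass *= math.exp(rng.normal(0.0, cfg.noise_sd_log))
    censored = ti_mass < cfg.loq_ng
    sample = FilterSample(
        label=f"synthetic-filter(seed={cfg.seed})",
        ti_mass_ng=None if censored else ti_mass,
        loq_ng=cfg.loq_ng,
        sampled_volume_m3=volume,
        duration_h=cfg.duration_h,
    )
    truth = FilterTruth(
        config=cfg,
        true_rf_ng_m2_m3=cfg.true_rf_ng_m2_m3,
        tio2_mass_ng=tio2_mass,
        ti_mass_ng=ti_mass,
        censored=censored,
    )
    return sample, truth


@dataclass(frozen=True)
class RecoverySummary:
    """Replicate-level estimates and their summary statistics."""

    n_reps: int
    true_value: float
    estimates: np.ndarray
    upper_bounds: np.ndarray | None
    median_relative_bias: float
    median_abs_relative_bias: float
    upper_coverage: float | None

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "true_value": self.true_value,
            "median_relative_bias": self.median_relative_bias,
            "median_abs_relative_bias": self.median_abs_relative_bias,
            "upper_coverage": self.upper_coverage,
        }


def _summarize(
    true_value: float, estimates: np.ndarray, uppers: np.ndarray | None
) -> RecoverySummary:
    rel = (estimates - true_value) / true_value if true_value != 0 else estimates
    coverage = float(np.mean(uppers >= true_value)) if uppers is not None else None
    return RecoverySummary(
        n_reps=estimates.size,
        true_value=true_value,
        estimates=estimates,
        upper_bounds=uppers,
        median_relative_bias=float(np.median(rel)),
        median_abs_relative_bias=float(np.median(np.abs(rel))),
        upper_coverage=coverage,
    )


def recovery_experiment(
    n_reps: int,
    template: ChamberSimConfig | FilterSimConfig,
    seed: int,
    window_s: float = 900.0,
    k_sigma: float = 1.0,
) -> RecoverySummary:
    """Run the full estimation pipeline on n_reps seeded replicates.

    Chamber template: generate -> mask true spike windows -> block-average
    -> derivative statistics -> emission bound; summarises the recovery of
    the true source rate and the k-sigma upper bound's coverage of it.
    Filter template: generate -> release_factors; summarises recovery of
    the true release factor (the raw release factor of a censored sample
    is its LOQ-based upper bound).
    """
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    if isinstance(template, ChamberSimConfig):
        points = np.empty(n_reps)
        uppers = np.empty(n_reps)
        for i, s in enumerate(child_seeds):
            cfg = template.model_copy(update={"seed": int(s)})
            series, truth = gen_chamber_series(cfg)
            if truth.exclusions.intervals:
                series = mask_series(series, truth.exclusions)
            averaged = block_average(series, window_s)
            stats = derivative_stats(averaged)
            bound = emission_bound(stats, cfg.volume_m3, k_sigma=k_sigma)
            points[i] = bound.point
            uppers[i] = bound.upper
        return _summarize(template.true_g_per_s, points, uppers)
    if isinstance(template, FilterSimConfig):
        estimates = np.empty(n_reps)
        for i, s in enumerate(child_seeds):
            cfg = template.model_copy(update={"seed": int(s)})
            sample, _ = gen_filter_sample(cfg)
            estimates[i] = release_factors(sample, cfg.surface).rf_tio2_ng_m2_m3
        return _summarize(template.true_rf_ng_m2_m3, estimates, None)
    raise TypeError(f"unsupported template type: {type(template)!r}")
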