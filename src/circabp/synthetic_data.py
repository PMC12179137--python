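"""Synthetic cuffless-monitor datasets with known ground truth.

Emulates a small cohort wearing an automated wrist monitor: six subjects
over 14 days with on average 32 irregular resting measurements per day.
Each subject gets their own true curve parameters (drawn from truncated
normals inside the fitting bounds), the baseline and amplitude wander
from day to day within a subject, and observations are the model curve
plus Gaussian measurement noise.  Between-subject spread exceeds the
day-to-day spread by default, so the inter- vs intra-individual CV
pattern of real cohorts is reproducible.

Default systolic population means (base 104, incr 16, k 0.33 /h,
t1 4.8 h, t2 23.0 h) are calibrated to the overall medians observed in
young healthy adults with this device class; diastolic analogues are
scaled down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
from scipy.stats import truncnorm

from .fitting import BPMeasurement, default_bounds
from .model_core import ModelParams, predict

__all__ = ["SyntheticConfig", "TruthRecord", "draw_true_parameters", "sample_times", "generate_dataset"]

_PARAM_NAMES = ("base", "incr", "k", "t1", "t2")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; all pressures in mmHg, rates per hour, times
    in hours after midnight."""

    n_subjects: int = 6
    n_days: int = 14
    mean_obs_per_day: float = 32.0
    noise_sd_sys: float = 5.0
    noise_sd_dia: float = 4.0
    # population means per channel, order (base, incr, k, t1, t2)
    pop_mean_sys: tuple[float, ...] = (104.0, 16.0, 0.33, 4.8, 23.0)
    pop_mean_dia: tuple[float, ...] = (65.0, 12.0, 0.33, 4.8, 23.0)
    # between-subject sds of the subject-level parameters
    between_sd_sys: tuple[float, ...] = (8.0, 4.0, 0.15, 1.2, 1.0)
    between_sd_dia: tuple[float, ...] = (6.0, 3.0, 0.15, 1.2, 1.0)
    # day-to-day within-subject sds for base and incr (k, t1, t2 fixed per subject)
    within_sd_base_sys: float = 4.0
    within_sd_incr_sys: float = 5.0
    within_sd_base_dia: float = 3.0
    within_sd_incr_dia: float = 4.0
    # correlation of subject-level base and incr: high-baseline subjects
    # show smaller daytime rises, which keeps plateaus in a narrow band
    base_incr_corr: float = -0.5
    seed: int = 0
    start_date: datetime = field(default=datetime(2023, 5, 1))

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_days < 1:
            raise ValueError("counts must be >= 1")
        if self.mean_obs_per_day <= 0:
            raise ValueError("mean_obs_per_day must be positive")
        for sd in (
            self.noise_sd_sys, self.noise_sd_dia,
            *self.between_sd_sys, *self.between_sd_dia,
            self.within_sd_base_sys, self.within_sd_incr_sys,
            self.within_sd_base_dia, self.within_sd_incr_dia,
        ):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for channel, means in (("systolic", self.pop_mean_sys), ("diastolic", self.pop_mean_dia)):
            b = default_bounds(channel)
            if not all(lo <= m <= up for m, lo, up in zip(means, b.lower, b.upper)):
                raise ValueError(f"{channel} population means must lie inside the fitting bounds")

    def channel_settings(self, channel: str):
        if channel == "systolic":
            return (self.pop_mean_sys, self.between_sd_sys,
                    self.within_sd_base_sys, self.within_sd_incr_sys, self.noise_sd_sys)
        return (self.pop_mean_dia, self.between_sd_dia,
                self.within_sd_base_dia, self.within_sd_incr_dia, self.noise_sd_dia)


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth parameters for one subject-day-channel."""

    subject_id: str
    day_index: int
    channel: str
    params: ModelParams


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, up: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, up))
    a, b = (lo - mean) / sd, (up - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def subject_ids(config: SyntheticConfig) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_subjects)]


def draw_true_parameters(config: SyntheticConfig, rng: np.random.Generator) -> list[TruthRecord]:
    """Draw subject-level parameter means from truncated normals within
    the fitting bounds, then perturb base and incr day by day (normal,
    clipped back into bounds); k, t1, t2 are held at the subject level."""
    records: list[TruthRecord] = []
    for sid in subject_ids(config):
        for channel in ("systolic", "diastolic"):
            means, between_sd, wsd_base, wsd_incr, _ = config.channel_settings(channel)
            bounds = default_bounds(channel)
            # subject-level draws truncated at the fitting bounds and at
            # mean +/- 2 sd, keeping simulated cohorts inside the pressure
            # ranges such monitors report for healthy adults
            subj = [
                _truncated_normal(rng, m, sd, max(lo, m - 2 * sd), min(up, m + 2 * sd))
                for m, sd, lo, up in zip(means, between_sd, bounds.lower, bounds.upper)
            ]
            # incr is redrawn conditionally on base with the configured
            # negative correlation (bivariate-normal conditional)
            rho = config.base_incr_corr
            if between_sd[0] > 0 and between_sd[1] > 0 and rho != 0:
                cond_mean = means[1] + rho * between_sd[1] / between_sd[0] * (subj[0] - means[0])
                cond_sd = between_sd[1] * np.sqrt(1 - rho**2)
                subj[1] = _truncated_normal(
                    rng, cond_mean, cond_sd,
                    max(bounds.lower[1], means[1] - 2 * between_sd[1]),
                    min(bounds.upper[1], means[1] + 2 * between_sd[1]),
                )
            # keep the trough strictly positive and the rise fittable
            subj[2] = max(subj[2], bounds.lower[2])
            for day in range(config.n_days):
                day_vals = list(subj)
                day_vals[0] += rng.normal(0.0, wsd_base) if wsd_base else 0.0
                day_vals[1] += rng.normal(0.0, wsd_incr) if wsd_incr else 0.0
                day_vals = list(bounds.clip(np.array(day_vals)))
                records.append(
                    TruthRecord(sid, day, channel, ModelParams(*day_vals))
                )
    return records


def sample_times(config: SyntheticConfig, rng: np.random.Generator, day_index: int = 0) -> np.ndarray:
    """Measurement clock times for one day: a Poisson-distributed count
    (mean ``mean_obs_per_day``) of times uniform on [0, 24), sorted."""
    n = rng.poisson(config.mean_obs_per_day)
    return np.sort(rng.uniform(0.0, 24.0, size=n))


def generate_dataset(config: SyntheticConfig) -> tuple[list[BPMeasurement], list[TruthRecord]]:
    """Simulate the full cohort.

    Each observation is the basic-model curve at the day's true
    parameters plus Gaussian noise; a diastolic draw at or above its
    systolic partner is resampled.  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = draw_true_parameters(config, rng)
    by_key = {(r.subject_id, r.day_index, r.channel): r.params for r in truth}

    measurements: list[BPMeasurement] = []
    for sid in subject_ids(config):
        for day in range(config.n_days):
            times = sample_times(config, rng, day)
            if times.size == 0:
                continue
            p_sys = by_key[(sid, day, "systolic")]
            p_dia = by_key[(sid, day, "diastolic")]
            sbp = predict(times, *p_sys.as_array()) + rng.normal(0.0, config.noise_sd_sys, times.size)
            dbp = predict(times, *p_dia.as_array()) + rng.normal(0.0, config.noise_sd_dia, times.size)
            for _ in range(100):
                bad = (dbp >= sbp) | (dbp <= 0)
                if not bad.any():
                    break
                dbp[bad] = predict(times[bad], *p_dia.as_array()) + rng.normal(
                    0.0, config.noise_sd_dia, int(bad.sum())
                )
            ok = (sbp > dbp) & (dbp > 0)
            for t, s, d in zip(times[ok], sbp[ok], dbp[ok]):
                ts = config.start_date + timedelta(days=day, hours=float(t))
                measurements.append(
                    BPMeasurement(subject_id=sid, timestamp=ts, day_index=day,
                                  t=float(t), sbp=float(s), dbp=float(d))
                )
    return measurements, truth
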