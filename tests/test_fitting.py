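"""Bounded per-day least squares: default limits, starting values,
noise-free recovery, the skip rule, the extended carry chain, and the
determinism/independence contracts of the double loop."""

import numpy as np
import pytest

from circabp import (
    BPMeasurement,
    FitSettings,
    ModelParams,
    default_bounds,
    eval_basic,
    fit_day,
    fit_population,
    fit_subject,
    initial_params,
)
from circabp.synthetic_data import SyntheticConfig, generate_dataset


class TestDefaultBounds:
    @pytest.mark.parametrize(
        "channel, base_lo, base_up",
        [("systolic", 80.0, 200.0), ("diastolic", 20.0, 120.0)],
    )
    def test_base_limits_per_channel(self, channel, base_lo, base_up):
        b = default_bounds(channel)
        assert b.lower[0] == base_lo and b.upper[0] == base_up

    @pytest.mark.parametrize("channel", ["systolic", "diastolic"])
    def test_shared_limits(self, channel):
        b = default_bounds(channel)
        assert b.lower[1:] == (0.0, 0.01, 1.0, 18.0)
        assert b.upper[1:] == (60.0, 2.0, 11.0, 25.0)

    def test_unknown_channel(self):
        with pytest.raises(ValueError):
            default_bounds("mean_arterial")


class TestInitialParams:
    def test_min_and_spread_rule(self):
        obs = [(6, 95.0), (10, 110.0), (14, 130.0), (20, 102.0)]
        p = initial_params(obs, "systolic")
        assert (p.base, p.incr, p.k, p.t1, p.t2) == (95.0, 35.0, 0.3, 5.0, 22.0)

    def test_constant_day(self):
        p = initial_params([(6, 100.0), (12, 100.0)], "systolic")
        assert (p.base, p.incr) == (100.0, 0.0)

    def test_clipping_into_bounds(self):
        p = initial_params([(6, 70.0), (12, 150.0)], "systolic")
        assert p.base == 80.0  # systolic lower bound
        assert p.incr == 60.0  # spread 80 clipped to upper

    def test_empty_day_rejected(self):
        with pytest.raises(ValueError):
            initial_params([], "systolic")


class TestFitDay:
    def test_noise_free_recovery(self, dense_day):
        truth, obs = dense_day
        fit = fit_day(obs)
        assert fit.converged and not fit.skipped
        np.testing.assert_allclose(fit.params.as_array(), truth.as_array(), rtol=1e-3)
        assert fit.sse < 1e-8
        assert fit.n_obs == len(fit.residuals) == len(fit.weighted_residuals)

    def test_too_few_observations_skipped(self):
        fit = fit_day([(6, 100.0), (10, 110.0), (14, 120.0), (20, 105.0)])
        assert fit.skipped and fit.params is None and not fit.converged

    def test_constant_profile_degenerate(self):
        obs = [(t, 100.0) for t in np.linspace(0, 23, 24)]
        fit = fit_day(obs)
        assert fit.params.incr == pytest.approx(0.0, abs=1e-6)
        assert fit.params.base == pytest.approx(100.0, abs=1e-6)

    def test_non_finite_pressure_rejected(self):
        obs = [(t, 100.0) for t in range(8)]
        obs[3] = (3, float("nan"))
        with pytest.raises(ValueError):
            fit_day(obs)

    def test_bound_compliance_and_objective_non_inflation(self, dense_day):
        truth, obs = dense_day
        rng = np.random.default_rng(3)
        noisy = [(t, y + rng.normal(0, 5)) for t, y in obs]
        bounds = default_bounds("systolic")
        init = initial_params(noisy, "systolic")
        fit = fit_day(noisy)
        assert np.all(fit.params.as_array() >= np.array(bounds.lower) - 1e-12)
        assert np.all(fit.params.as_array() <= np.array(bounds.upper) + 1e-12)
        t = np.array([ti for ti, _ in noisy])
        y = np.array([yi for _, yi in noisy])
        sse_init = float(np.sum((y - [eval_basic(init, ti) for ti in t]) ** 2))
        assert fit.sse <= sse_init + 1e-9


def _measurement(sid, day, t, sbp, dbp=70.0):
    from datetime import datetime, timedelta
    ts = datetime(2023, 5, 1) + timedelta(days=day, hours=t)
    return BPMeasurement(subject_id=sid, timestamp=ts, day_index=day, t=t, sbp=sbp, dbp=dbp)


def _subject_obs(truth_by_day, n_per_day=24, sid="S01"):
    out = []
    for day, p in truth_by_day.items():
        for t in np.linspace(0.2, 23.8, n_per_day):
            out.append(_measurement(sid, day, float(t), eval_basic(p, float(t))))
    return out


class TestFitSubject:
    def test_one_fit_per_day(self):
        p = ModelParams(105, 18, 0.5, 6, 22)
        obs = _subject_obs({d: p for d in range(5)})
        fits = fit_subject(obs)
        assert [f.day_index for f in fits] == list(range(5))

    def test_identical_days_extended_equals_basic(self):
        p = ModelParams(105, 18, 0.5, 6, 22)
        obs = _subject_obs({d: p for d in range(3)})
        basic = fit_subject(obs, variant="basic")
        extended = fit_subject(obs, variant="extended")
        for fb, fe in zip(basic, extended):
            np.testing.assert_allclose(
                fe.params.as_array(), fb.params.as_array(), atol=1e-4
            )

    def test_carry_skips_unfitted_days(self):
        days = {d: ModelParams(100 + d, 18, 0.5, 6, 22) for d in range(5)}
        obs = _subject_obs(days)
        # leave day 3 with too few points to fit
        obs = [m for m in obs if m.day_index != 3]
        obs += [_measurement("S01", 3, t, 110.0) for t in (8.0, 12.0, 16.0)]
        fits = fit_subject(obs, variant="extended")
        assert fits[3].skipped
        day2 = fits[2]
        day4 = fits[4]
        assert day4.carry is not None
        assert day4.carry.base_prev == pytest.approx(day2.params.base)
        assert day4.carry.incr_prev == pytest.approx(day2.params.incr)

    def test_day0_extended_has_no_carry(self):
        p = ModelParams(105, 18, 0.5, 6, 22)
        fits = fit_subject(_subject_obs({0: p}), variant="extended")
        assert fits[0].carry is None

    def test_empty_subject(self):
        assert fit_subject([]) == []


class TestFitPopulation:
    def test_counts_and_composition(self, small_cohort):
        cfg, measurements, _ = small_cohort
        col = fit_population(measurements)
        assert len(col.fits) == cfg.n_subjects * cfg.n_days * 2
        one = [m for m in measurements if m.subject_id == "S01"]
        solo = fit_population(one, channels=("systolic",))
        paired = [f for f in col.fits if f.subject_id == "S01" and f.channel == "systolic"]
        for a, b in zip(solo.fits, paired):
            np.testing.assert_array_equal(a.params.as_array(), b.params.as_array())

    def test_deterministic_rerun(self, small_cohort):
        _, measurements, _ = small_cohort
        a = fit_population(measurements, channels=("systolic",))
        b = fit_population(measurements, channels=("systolic",))
        for fa, fb in zip(a.fits, b.fits):
            np.testing.assert_array_equal(fa.params.as_array(), fb.params.as_array())
            assert fa.sse == fb.sse

    def test_channel_independence(self, small_cohort):
        """Permuting the diastolic column never changes systolic fits."""
        _, measurements, _ = small_cohort
        rng = np.random.default_rng(0)
        dbps = np.array([m.dbp for m in measurements])
        lo = dbps.min()
        shuffled = rng.permutation(dbps - lo) + lo  # keep dbp < sbp plausible
        permuted = []
        for m, d in zip(measurements, shuffled):
            d = min(float(d), m.sbp - 1.0)
            permuted.append(
                BPMeasurement(m.subject_id, m.timestamp, m.day_index, m.t, m.sbp, d)
            )
        a = fit_population(measurements, channels=("systolic",))
        b = fit_population(permuted, channels=("systolic",))
        for fa, fb in zip(a.fits, b.fits):
            np.testing.assert_array_equal(fa.params.as_array(), fb.params.as_array())

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_population([])


class TestNoisyEstimates:
    def test_day_level_base_errors_centred(self):
        """With 5 mmHg noise and ~32 obs/day the day-level baseline
        estimates scatter around the simulated truth without systematic
        bias (the per-subject medians are exercised end to end in the
        acceptance suite)."""
        cfg = SyntheticConfig(n_subjects=3, n_days=14, seed=11)
        measurements, truth = generate_dataset(cfg)
        col = fit_population(measurements, channels=("systolic",))
        by = {(f.subject_id, f.day_index): f for f in col.select(channel="systolic")}
        errs = [
            by[(r.subject_id, r.day_index)].params.base - r.params.base
            for r in truth
            if r.channel == "systolic" and by[(r.subject_id, r.day_index)].fitted
        ]
        assert abs(np.mean(errs)) < 2.0
        assert np.std(errs) < 8.0
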