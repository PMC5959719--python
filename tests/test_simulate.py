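"""Generator correctness: constructions, distributions, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from svtrace import (
    RetrievalFractionDist,
    SimulationConfig,
    generate_experiment,
    generate_negative_control,
    generate_single_vesicle_trace,
    generate_train_trace,
)
from conftest import noiseless_config


def reconstruct_from_truth(config, truth):
    """Independent piecewise closed-form oracle for a noise-free trace."""
    t = np.arange(config.n_frames) / config.sampling_rate_hz
    out = config.background_level + config.bleach_amplitude * np.exp(-t / config.bleach_tau_s)
    for ev in truth:
        if not ev.fused:
            continue
        onset = t[np.searchsorted(t, ev.stimulus_time_s - 1e-12)]
        if ev.censored:
            out = np.where(t >= onset - 1e-12, out + ev.true_amplitude, out)
            continue
        decay_start = onset + ev.true_dwell_s
        endpoint = (1 - ev.true_retrieval_fraction) * ev.true_amplitude
        contrib = np.zeros_like(t)
        contrib[(t >= onset - 1e-12) & (t < decay_start)] = ev.true_amplitude
        mask = t >= decay_start
        contrib[mask] = endpoint + (ev.true_amplitude - endpoint) * np.exp(
            -(t[mask] - decay_start) / config.tau_reacidification_s
        )
        out = out + contrib
    return out


class TestSingleTrace:
    def test_noiseless_step_plateau_decay(self):
        cfg = noiseless_config(fixed_dwell_s=0.5, bleach_amplitude=20.0)
        trace, truth = generate_single_vesicle_trace(cfg)
        assert len(truth) == 1 and truth[0].fused
        np.testing.assert_allclose(
            trace.samples, reconstruct_from_truth(cfg, truth), rtol=0, atol=1e-9
        )

    def test_no_release_gives_flat_baseline(self):
        cfg = noiseless_config(p_release=0.0, bleach_amplitude=20.0)
        trace, truth = generate_single_vesicle_trace(cfg)
        t = trace.times()
        expected = cfg.background_level + cfg.bleach_amplitude * np.exp(-t / cfg.bleach_tau_s)
        np.testing.assert_allclose(trace.samples, expected, atol=1e-9)
        assert not any(ev.fused for ev in truth)

    def test_fused_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(p_release=0.15, seed=4)
        ds = generate_experiment(cfg, 500)
        n = len(ds.truth)
        p_hat = ds.truth.fused.mean()
        half = stats.norm.ppf(0.995) * np.sqrt(0.15 * 0.85 / n)
        assert abs(p_hat - 0.15) < half

    def test_censoring_iff_ultraslow(self, default_experiment):
        fused = default_experiment.truth[default_experiment.truth.fused]
        assert (fused.censored == (fused.true_mode == "ultraslow")).all()

    def test_dwell_draws_respect_mode_bands(self, default_experiment):
        fused = default_experiment.truth[default_experiment.truth.fused]
        uf = fused[fused.true_mode == "ultrafast"].true_dwell_s
        fa = fused[fused.true_mode == "fast"].true_dwell_s
        assert (uf <= 1.0).all() and (uf > 0).all()
        assert (fa > 1.0).all() and (fa <= 20.0).all()


class TestExperiment:
    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(seed=9)
        a = generate_experiment(cfg, 2)
        b = generate_experiment(cfg, 2)
        for ta, tb in zip(a.traces, b.traces):
            np.testing.assert_array_equal(ta.samples, tb.samples)
        assert a.truth.equals(b.truth)

    def test_different_seeds_differ(self):
        a = generate_experiment(SimulationConfig(seed=1), 1)
        b = generate_experiment(SimulationConfig(seed=2), 1)
        assert not np.array_equal(a.traces[0].samples, b.traces[0].samples)

    def test_mode_counts_within_multinomial_ci(self):
        cfg = SimulationConfig(seed=17, p_release=1.0, mode_weights=(0.2, 0.4, 0.4))
        ds = generate_experiment(cfg, 500)
        fused = ds.truth[ds.truth.fused]
        n = len(fused)
        for mode, w in zip(("ultrafast", "fast", "ultraslow"), (0.2, 0.4, 0.4)):
            frac = (fused.true_mode == mode).mean()
            half = stats.norm.ppf(0.995) * np.sqrt(w * (1 - w) / n)
            assert abs(frac - w) < half, mode

    def test_zero_boutons_rejected(self):
        with pytest.raises(ValueError):
            generate_experiment(SimulationConfig(), 0)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("p_release", 1.5),
            ("mode_weights", (0.5, 0.5, 0.5)),
            ("noise_sd", -1.0),
            ("tau_fast_s", 0.0),
            ("stimulus_times_s", [5.0, 3.0]),
        ],
    )
    def test_invalid_config_rejected(self, field, value):
        cfg = dataclasses.replace(SimulationConfig(), **{field: value})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_dwell_distribution_converges(self):
        # empirical uncensored dwell CDF vs the configured truncated mixture
        cfg = SimulationConfig(seed=3, p_release=1.0, duration_s=65.0,
                               stimulus_times_s=[20.0, 40.0])
        ds = generate_experiment(cfg, 5000)
        fused = ds.truth[ds.truth.fused & ~ds.truth.censored]
        dwells = fused.true_dwell_s.to_numpy()

        def trunc_cdf(x, tau, lo, hi):
            a, b = np.exp(-lo / tau), np.exp(-hi / tau)
            return np.clip((a - np.exp(-np.clip(x, lo, hi) / tau)) / (a - b), 0, 1)

        w_uf = 0.2 / 0.6  # ultrafast share among uncensored modes
        cdf = lambda x: w_uf * trunc_cdf(x, 0.2, 0.0, 1.0) + (1 - w_uf) * trunc_cdf(x, 8.0, 1.0, 20.0)
        stat = stats.kstest(dwells, cdf)
        assert stat.pvalue > 0.01


class TestNegativeControl:
    def test_no_fused_events_and_reproducible(self):
        cfg = SimulationConfig(seed=5)
        ds = generate_negative_control(cfg, 3)
        assert not ds.truth.fused.any()
        assert len(ds.truth) == 3 * len(cfg.stimulus_times_s)
        ds2 = generate_negative_control(cfg, 3)
        np.testing.assert_array_equal(ds.traces[0].samples, ds2.traces[0].samples)

    def test_raw_threshold_exceedance_matches_gaussian_tail(self):
        cfg = SimulationConfig(seed=6, bleach_amplitude=0.0)
        ds = generate_negative_control(cfg, 50)
        exceed = []
        for tr in ds.traces:
            x = tr.samples
            exceed.append(np.mean(x > x.mean() + 3 * x.std()))
        rate = np.mean(exceed)
        # one-sided 3-sigma Gaussian tail is 0.00135
        assert 0.0005 < rate < 0.0025


class TestTrain:
    def test_noiseless_decay_is_exact_exponential(self):
        cfg = noiseless_config(duration_s=120.0, stimulus_times_s=[])
        tr = generate_train_trace(cfg, endo_tau_s=10.0, train_start_s=10.0)
        t = tr.times()
        after = t >= 15.0
        peak = 40.0 * cfg.p_release * cfg.quantal_amplitude * 5.0
        expected = cfg.background_level + peak * np.exp(-(t[after] - 15.0) / 10.0)
        np.testing.assert_allclose(tr.samples[after], expected, rtol=1e-12)

    def test_zero_quantal_amplitude_flat(self):
        cfg = noiseless_config(duration_s=60.0, stimulus_times_s=[], quantal_amplitude=0.0)
        tr = generate_train_trace(cfg, endo_tau_s=5.0)
        assert np.ptp(tr.samples) < 1e-12

    def test_train_must_fit_in_trace(self):
        cfg = noiseless_config(duration_s=12.0, stimulus_times_s=[])
        with pytest.raises(ValueError):
            generate_train_trace(cfg, train_start_s=10.0, train_duration_s=5.0)


class TestRetrievalFractions:
    def test_short_dwells_mostly_quantal_and_dispersion_grows(self, rng):
        dist = RetrievalFractionDist()
        short, lab_s = dist.sample(rng, 3000, dwell_s=0.2)
        long, lab_l = dist.sample(rng, 3000, dwell_s=15.0)
        assert (lab_s == "quantal").mean() > 0.7
        assert (lab_l == "quantal").mean() < 0.4
        assert long.std() > short.std()

    def test_marginal_class_mix_matches_reported_breakdown(self):
        # over the default dwell composition the partial/quantal/excess mix
        # should approximate ~35/50/15
        ds = generate_experiment(SimulationConfig(seed=8, p_release=1.0), 300)
        fused = ds.truth[ds.truth.fused & ~ds.truth.censored]
        f = fused.true_retrieval_fraction
        partial = (f < 0.8).mean()
        quantal = ((f >= 0.8) & (f <= 1.2)).mean()
        excess = (f > 1.2).mean()
        assert abs(partial - 0.35) < 0.08
        assert abs(quantal - 0.50) < 0.08
        assert abs(excess - 0.15) < 0.08
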