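"""Dwell-distribution fitting, model selection, averaged events, trains."""

import dataclasses

import numpy as np
import pytest

from svtrace import (
    SimulationConfig,
    analyze_train_response,
    average_event_trace,
    compare_models,
    fit_dwell_distribution,
    fit_exponential_mixture_mle,
    fit_two_phase_decay,
    generate_train_trace,
    mode_proportions,
    retrieval_vs_dwell,
)
from svtrace.detect import FusionEvent
from conftest import noiseless_config


def two_component_dwells(rng, n=5000, w1=1 / 3, tau1=0.2, tau2=8.0):
    n1 = int(round(n * w1))
    return np.concatenate([rng.exponential(tau1, n1), rng.exponential(tau2, n - n1)])


class TestDwellFits:
    def test_double_fit_recovers_both_time_constants(self, rng):
        d = two_component_dwells(rng)
        fit = fit_dwell_distribution(d, "double")
        assert abs(fit.tau1_s - 0.2) / 0.2 < 0.15
        assert abs(fit.tau2_s - 8.0) / 8.0 < 0.15
        assert fit.tau1_s < fit.tau2_s and not fit.degenerate
        assert fit.r_square > 0.9

    def test_histogram_and_mle_routes_agree(self, rng):
        d = two_component_dwells(rng)
        fit = fit_dwell_distribution(d, "double")
        mle_tau1, mle_tau2 = fit.mle.taus_s
        assert abs(fit.tau1_s - mle_tau1) / mle_tau1 < 0.10
        assert abs(fit.tau2_s - mle_tau2) / mle_tau2 < 0.10

    def test_mle_oracle_on_pure_exponential(self, rng):
        d = rng.exponential(2.0, 4000)
        mle = fit_exponential_mixture_mle(d, 1)
        # the single-component MLE is the sample mean, by closed form
        assert mle.taus_s[0] == pytest.approx(d.mean())

    def test_single_exponential_data_degenerate_under_double_model(self, rng):
        d = rng.exponential(2.0, 4000)
        fit = fit_dwell_distribution(d, "double")
        amp = sorted([fit.amplitude1, fit.amplitude2])
        ratio = abs(fit.tau2_s - fit.tau1_s) / fit.tau2_s
        assert fit.degenerate or ratio < 0.3 or amp[0] < 0.05 * amp[1]

    def test_too_few_dwells_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_dwell_distribution(rng.exponential(1.0, 10), "double")


class TestModelComparison:
    def test_two_component_data_prefers_double(self, rng):
        d = two_component_dwells(rng)
        single = fit_dwell_distribution(d, "single")
        double = fit_dwell_distribution(d, "double")
        report = compare_models(single, double)
        assert report.preferred == "double" and report.p_value < 0.01
        assert report.r_square_double_adj > report.r_square_single_adj

    def test_one_component_data_prefers_single_across_seeds(self):
        prefer_single = 0
        for seed in range(10):
            d = np.random.default_rng(seed).exponential(2.0, 2000)
            s = fit_dwell_distribution(d, "single")
            dd = fit_dwell_distribution(d, "double")
            prefer_single += compare_models(s, dd).preferred == "single"
        assert prefer_single >= 9

    def test_equal_fits_give_zero_f(self, rng):
        d = two_component_dwells(rng)
        s = fit_dwell_distribution(d, "single")
        dd = dataclasses.replace(
            fit_dwell_distribution(d, "double"),
            residual_sum_squares=s.residual_sum_squares,
        )
        report = compare_models(s, dd)
        assert report.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert report.preferred == "single"

    def test_different_data_rejected(self, rng):
        s = fit_dwell_distribution(rng.exponential(1.0, 500), "single")
        d = fit_dwell_distribution(rng.exponential(1.0, 400), "double")
        with pytest.raises(ValueError):
            compare_models(s, d)


def make_event(mode, dwell=np.nan, fraction=np.nan):
    return FusionEvent("b", 0, 0.0, 0.0, 0.0, 5.0, 0.0, 1.0,
                       dwell_time_s=dwell, censored=mode == "ultraslow",
                       retrieval_fraction=fraction, mode=mode)


class TestModeProportions:
    def test_all_censored(self):
        events = [make_event("ultraslow") for _ in range(5)]
        assert mode_proportions(events) == (0.0, 0.0, 100.0)

    def test_single_ultrafast_event(self):
        assert mode_proportions([make_event("ultrafast", 0.5)]) == (100.0, 0.0, 0.0)

    def test_sums_to_100_and_order_invariant(self, rng):
        modes = ["ultrafast"] * 3 + ["fast"] * 5 + ["ultraslow"] * 2
        p = mode_proportions(modes)
        assert sum(p) == pytest.approx(100.0)
        perm = [modes[i] for i in rng.permutation(len(modes))]
        assert mode_proportions(perm) == p

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mode_proportions([])


class TestRetrievalVsDwell:
    def test_uniform_fractions(self):
        events = [make_event("fast", d, 1.0) for d in (0.05, 0.3, 2.0, 7.0)]
        table = retrieval_vs_dwell(events)
        assert (table.mean_fraction == 1.0).all()
        assert (table.sd_fraction == 0.0).all()

    def test_empty_bins_absent(self):
        events = [make_event("fast", 2.0, 1.0), make_event("fast", 3.0, 0.8)]
        table = retrieval_vs_dwell(events)
        assert len(table) == 1 and table.iloc[0].dwell_lo_s == 1.0

    def test_dispersion_grows_with_dwell(self, rng):
        events = []
        for _ in range(2000):
            d = rng.uniform(0.05, 19.5)
            frac = 1.0 + rng.normal(0, 0.05 + 0.04 * d)
            events.append(make_event("fast", d, frac))
        table = retrieval_vs_dwell(events)
        sds = table.sd_fraction.to_numpy()
        assert (np.diff(sds) > 0).all()


class TestAveragedEvents:
    def test_average_of_identical_events(self):
        cfg = noiseless_config(fixed_dwell_s=1.0)
        from svtrace import generate_single_vesicle_trace
        from svtrace.detect import detect_events, characterize_events
        traces, events = {}, []
        for i in range(25):
            tr, _ = generate_single_vesicle_trace(cfg, f"b{i}")
            res = detect_events(tr, [10.0])
            characterize_events(tr, res, [10.0])
            traces[f"b{i}"] = tr
            events.extend(res.events)
        t, mean, sd, n = average_event_trace(traces, events, pre_s=2.0, post_s=20.0)
        assert n == 25
        assert sd.max() < 1e-9
        assert mean[t < 0].max() < 1e-9 and mean[(t > 0.2) & (t < 0.9)].mean() == pytest.approx(5.0, rel=1e-6)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            average_event_trace({}, [])

    def test_two_phase_decay_recovery(self, rng):
        t = np.arange(0, 25, 0.1)
        y = 2.0 * np.exp(-t / 0.5) + 3.0 * np.exp(-t / 8.0) + 0.5
        y = y + rng.normal(0, 0.02, t.size)
        tau1, tau2, a1, a2, c, degenerate = fit_two_phase_decay(t, y)
        assert abs(tau1 - 0.5) / 0.5 < 0.25
        assert abs(tau2 - 8.0) / 8.0 < 0.25
        assert not degenerate

    def test_single_phase_data_degenerates(self, rng):
        t = np.arange(0, 25, 0.1)
        y = 5.0 * np.exp(-t / 4.0) + rng.normal(0, 0.02, t.size)
        tau1, tau2, a1, a2, c, degenerate = fit_two_phase_decay(t, y)
        small, big = sorted([a1, a2])
        assert degenerate or small < 0.1 * big or abs(tau2 - tau1) / tau2 < 0.3


class TestTrainResponse:
    def test_noiseless_exact_recovery(self):
        cfg = noiseless_config(duration_s=120.0, stimulus_times_s=[], p_release=0.15)
        tr = generate_train_trace(cfg, endo_tau_s=4.0, train_start_s=10.0)
        r = analyze_train_response(tr, 10.0, 5.0)
        assert r.amplitude == pytest.approx(150.0, rel=1e-6)
        assert r.rise_slope == pytest.approx(30.0, rel=1e-3)
        assert r.decay_tau_s == pytest.approx(4.0, rel=1e-3)

    def test_flat_trace_flagged(self):
        cfg = noiseless_config(duration_s=60.0, stimulus_times_s=[], quantal_amplitude=0.0)
        tr = generate_train_trace(cfg, endo_tau_s=4.0)
        r = analyze_train_response(tr, 10.0, 5.0)
        assert r.amplitude == pytest.approx(0.0, abs=1e-9)
        assert not r.converged

    def test_temperature_like_tau_ratio_recovered(self):
        base = SimulationConfig(duration_s=120.0, stimulus_times_s=[], noise_sd=1.0)
        r_warm = analyze_train_response(
            generate_train_trace(dataclasses.replace(base, seed=2), endo_tau_s=4.0), 10.0, 5.0
        )
        r_cold = analyze_train_response(
            generate_train_trace(dataclasses.replace(base, seed=3), endo_tau_s=10.0), 10.0, 5.0
        )
        assert abs(r_cold.decay_tau_s / r_warm.decay_tau_s - 2.5) / 2.5 < 0.10
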