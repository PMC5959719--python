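"""Photobleaching and background correction of raw traces.

Bleaching is modelled as an additive single-exponential trend fitted to
event-free samples and subtracted down to its asymptote, which preserves the
arbitrary-unit amplitude scale the quantal threshold operates on.  Background
is subtracted linearly (scalar or a cell-free region trace).

Two robustness measures deal with residual fusion events in the fitted
samples, which can only push fluorescence *up*: a soft-L1 loss with iterative
asymmetric trimming (samples more than two robust SDs above the current fit
are dropped), and an optional nonnegative linear drift term that absorbs the
slow staircase left by never-decaying (ultraslow) events.  The bleach time
constant can also be fixed from the experiment level (the same illumination
bleaches every bouton in a field of view), in which case only the amplitude,
drift and offset are refitted per ROI by robust linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .trace import FluorescenceTrace

__all__ = ["BleachFit", "default_event_free_mask", "correct_photobleaching", "subtract_background"]


@dataclass(frozen=True)
class BleachFit:
    amplitude: float
    tau_s: float
    asymptote: float
    drift_slope: float       # a.u./s, nonnegative staircase absorber
    method: str              # 'exponential', 'exponential_fixed_tau' or 'linear'
    converged: bool


def default_event_free_mask(
    trace: FluorescenceTrace,
    stimulus_times_s: np.ndarray | list[float],
    pre_s: float = 0.5,
    post_s: float = 20.0,
) -> np.ndarray:
    """Mask excluding [-pre_s, +post_s] around each stimulus.

    Prevents fusion-event plateaus from biasing the bleach fit.  When the
    stimuli are so dense that the exclusion would cover more than 90% of the
    trace (e.g. 0.05 Hz stimulation with a 20 s exclusion), the post-stimulus
    exclusion shrinks to 80% of the median inter-stimulus interval so the fit
    keeps the late, mostly decayed portion of each interval.
    """
    t = trace.times()
    stim = np.asarray(stimulus_times_s, dtype=float)

    def _build(post: float) -> np.ndarray:
        mask = np.ones(t.size, dtype=bool)
        for s in stim:
            mask &= ~((t >= s - pre_s) & (t <= s + post))
        return mask

    mask = _build(post_s)
    if stim.size > 1 and mask.mean() < 0.10:
        mask = _build(min(post_s, 0.8 * float(np.median(np.diff(stim)))))
    return mask


def _exp_lin(t, a, tau, b, c):
    return a * np.exp(-t / tau) + b * t + c


def _robust_step_fixed_tau(
    tm: np.ndarray,
    ym: np.ndarray,
    tau: float,
    step_times: np.ndarray | None,
) -> tuple[float, float]:
    """Robust fit of a*exp(-t/tau) + sum_j s_j*H(t - t_j) + c, a, s_j >= 0.

    Fusion events that never fully decay (ultraslow or partial retrieval)
    leave permanent upward steps at stimulus times; modelling those steps as
    nonnegative regressors keeps them out of the bleach amplitude, which is
    the only term that gets subtracted.  Solved by nonnegative least squares
    with the offset split into a +/- pair; iterative asymmetric trimming
    drops samples still elevated by transient decays.  Returns (a, c).
    """
    from scipy.optimize import nnls

    cols = [np.exp(-tm / tau)]
    if step_times is not None:
        for t_j in step_times:
            cols.append((tm > t_j).astype(float))
    cols.append(np.ones_like(tm))
    cols.append(-np.ones_like(tm))
    design = np.column_stack(cols)
    keep = np.ones(tm.size, dtype=bool)
    coef = np.zeros(design.shape[1])
    for _ in range(5):
        coef, _ = nnls(design[keep], ym[keep])
        resid = ym - design @ coef
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if sigma <= 0:
            break
        new_keep = resid < 2.0 * sigma
        if new_keep.sum() < max(20, 0.05 * tm.size) or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return float(coef[0]), float(coef[-2] - coef[-1])


def correct_photobleaching(
    trace: FluorescenceTrace,
    event_free_mask: np.ndarray | None = None,
    stimulus_times_s: np.ndarray | list[float] | None = None,
    tau_s: float | None = None,
) -> tuple[FluorescenceTrace, BleachFit]:
    """Fit and subtract a single-exponential bleaching trend.

    The model ``a * exp(-t/tau) + b*t + c`` (``a, b >= 0``) is fitted
    robustly to masked (event-free) samples; the fitted trend minus its final
    value is subtracted, flattening the baseline without shifting its level.
    With ``tau_s`` given (e.g. the experiment-level median), only the linear
    coefficients are refitted.  On non-convergence the correction falls back
    to a linear detrend and flags it.
    """
    if event_free_mask is None:
        if stimulus_times_s is not None:
            event_free_mask = default_event_free_mask(trace, stimulus_times_s)
        else:
            event_free_mask = np.ones(len(trace), dtype=bool)
    event_free_mask = np.asarray(event_free_mask, dtype=bool)
    if event_free_mask.size != len(trace):
        raise ValueError("mask length does not match the trace")
    if event_free_mask.mean() < 0.10:
        raise ValueError("event-free mask must cover at least 10% of samples")
    t = trace.times()
    tm, ym = t[event_free_mask], trace.samples[event_free_mask]
    span = max(t[-1] - t[0], 1e-9)
    head = ym[: max(ym.size // 10, 2)].mean()
    tail = ym[-max(ym.size // 10, 2):].mean()
    if tau_s is not None:
        steps = None if stimulus_times_s is None else np.asarray(stimulus_times_s, dtype=float)
        a, c = _robust_step_fixed_tau(tm, ym, tau_s, steps)
        fit = BleachFit(a, float(tau_s), c, 0.0, "exponential_fixed_tau", True)
        trend = a * np.exp(-t / tau_s)
    else:
        try:
            keep = np.ones(tm.size, dtype=bool)
            popt = [max(head - tail, 1e-6), span / 3.0, 0.0, tail]
            for _ in range(5):
                popt, _ = curve_fit(
                    _exp_lin,
                    tm[keep],
                    ym[keep],
                    p0=popt,
                    bounds=([0.0, span * 1e-3, 0.0, -np.inf], [np.inf, span, np.inf, np.inf]),
                    loss="soft_l1",
                    f_scale=2.0,
                    maxfev=20000,
                )
                resid = ym - _exp_lin(tm, *popt)
                sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
                if sigma <= 0:
                    break
                new_keep = resid < 2.0 * sigma
                if new_keep.sum() < max(20, 0.05 * tm.size) or np.array_equal(new_keep, keep):
                    break
                keep = new_keep
            a, tau, b, c = popt
            fit = BleachFit(float(a), float(tau), float(c), float(b), "exponential", True)
            trend = a * np.exp(-t / tau) + b * t
        except (RuntimeError, ValueError):
            slope, intercept = np.polyfit(tm, ym, 1)
            fit = BleachFit(
                float(slope * span), np.inf, float(intercept + slope * t[-1]), float(slope),
                "linear", False,
            )
            trend = slope * t
    corrected = trace.with_samples(
        trace.samples - (trend - trend[-1]),
        bleach_correction={
            "method": fit.method,
            "amplitude": fit.amplitude,
            "tau_s": fit.tau_s,
            "drift_slope": fit.drift_slope,
            "asymptote": fit.asymptote,
            "converged": fit.converged,
        },
    )
    return corrected, fit


def subtract_background(
    trace: FluorescenceTrace, background: float | np.ndarray | FluorescenceTrace
) -> FluorescenceTrace:
    """Linear (elementwise) background subtraction; scalar or same-length trace."""
    if isinstance(background, FluorescenceTrace):
        bg, source = background.samples, f"trace:{background.bouton_id}"
    elif np.isscalar(background):
        bg, source = float(background), "scalar"
    else:
        bg, source = np.asarray(background, dtype=float), "array"
    if not np.isscalar(bg) and np.size(bg) != len(trace):
        raise ValueError("background length does not match the trace")
    return trace.with_samples(trace.samples - bg, background_source=source)
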