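"""Time-domain nonlinear de-noising of fluorescence traces.

The workhorse is the Chung–Kennedy forward–backward filter, originally
developed for single-channel patch-clamp records: a bank of forward and
backward moving-average predictors of several window lengths is combined at
every sample with weights proportional to the inverse recent prediction error
of each predictor.  Because predictors that straddle a step accumulate large
errors, the weights switch sides at edges and the filter suppresses noise
while leaving step amplitudes and edge positions essentially intact — unlike
frequency-domain low-pass filtering, which smears fast steps and clips the
amplitude of short plateaus.  An FFT low-pass comparator and a residual
normality check are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trace import FluorescenceTrace

__all__ = [
    "DenoiseConfig",
    "chung_kennedy_filter",
    "chung_kennedy",
    "fft_lowpass",
    "NormalityReport",
    "noise_gaussianity",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters of the Chung–Kennedy predictor bank.

    ``predictor_windows`` are the moving-average lengths (samples) used both
    forwards and backwards; ``comparison_window_m`` is the number of recent
    one-sided residuals summed into each predictor's error; the error enters
    the weight as ``prior * (error + epsilon) ** -weighting_exponent_p``.
    Defaults resolve 100–250 ms plateaus at 10–40 Hz acquisition.
    """

    predictor_windows: tuple[int, ...] = (2, 4, 8, 16)
    comparison_window_m: int = 8
    weighting_exponent_p: float = 2.0
    regularizer_epsilon: float = 1e-12
    prior_weights: tuple[float, ...] | None = None

    def validate(self) -> None:
        w = np.asarray(self.predictor_windows, dtype=int)
        if w.size == 0 or np.any(w < 1) or np.any(np.diff(w) <= 0):
            raise ValueError("predictor windows must be strictly increasing positive integers")
        if self.comparison_window_m < 1:
            raise ValueError("comparison window M must be >= 1")
        if self.weighting_exponent_p <= 0 or self.regularizer_epsilon <= 0:
            raise ValueError("weighting exponent and epsilon must be positive")
        if self.prior_weights is not None:
            f = np.asarray(self.prior_weights, dtype=float)
            if f.size != w.size or np.any(f < 0):
                raise ValueError("prior_weights must match the number of windows and be >= 0")


def _one_sided_means(y: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Forward (preceding-w) and backward (following-w) running means.

    Windows are truncated at the trace boundaries; a zero count marks a
    position where that predictor has no data and must get zero weight.
    """
    n = y.size
    s = np.concatenate(([0.0], np.cumsum(y)))
    k = np.arange(n)
    lo = np.maximum(k - w, 0)
    cnt_f = (k - lo).astype(float)
    with np.errstate(invalid="ignore"):
        mean_f = (s[k] - s[lo]) / np.where(cnt_f > 0, cnt_f, 1.0)
    hi = np.minimum(k + 1 + w, n)
    cnt_b = (hi - (k + 1)).astype(float)
    mean_b = (s[hi] - s[k + 1]) / np.where(cnt_b > 0, cnt_b, 1.0)
    return mean_f, cnt_f > 0, mean_b, cnt_b > 0


def _trailing_sum(x: np.ndarray, m: int) -> np.ndarray:
    """sum of x[k-m+1 .. k], truncated at the left edge."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    k = np.arange(x.size)
    lo = np.maximum(k + 1 - m, 0)
    return c[k + 1] - c[lo]


def _leading_sum(x: np.ndarray, m: int) -> np.ndarray:
    """sum of x[k .. k+m-1], truncated at the right edge."""
    c = np.concatenate(([0.0], np.cumsum(x)))
    k = np.arange(x.size)
    hi = np.minimum(k + m, x.size)
    return c[hi] - c[k]


def chung_kennedy(y: np.ndarray, config: DenoiseConfig | None = None) -> np.ndarray:
    """Apply the Chung–Kennedy forward–backward filter to a 1-D array.

    For each sample the bank holds, per window length ``w``, a forward
    predictor (mean of the preceding ``w`` samples) and a backward predictor
    (mean of the following ``w``).  Each predictor's error is the sum of its
    own side's ``M`` most recent squared residuals (past residuals for forward
    predictors, future for backward); weights are
    ``prior * (error + eps)**(-p)`` normalised over the whole bank, and the
    output is the weighted sum of predictions.
    """
    config = config or DenoiseConfig()
    config.validate()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("input contains non-finite samples")
    if y.size <= max(config.predictor_windows) + config.comparison_window_m:
        raise ValueError("trace shorter than the largest window plus the comparison window")
    m = config.comparison_window_m
    p = config.weighting_exponent_p
    eps = config.regularizer_epsilon
    priors = (
        np.asarray(config.prior_weights, dtype=float)
        if config.prior_weights is not None
        else np.ones(len(config.predictor_windows))
    )
    num = np.zeros_like(y)
    den = np.zeros_like(y)
    for w, prior in zip(config.predictor_windows, priors):
        mean_f, ok_f, mean_b, ok_b = _one_sided_means(y, int(w))
        res_f = np.where(ok_f, (y - mean_f) ** 2, 0.0)
        res_b = np.where(ok_b, (y - mean_b) ** 2, 0.0)
        err_f = _trailing_sum(res_f, m)
        err_b = _leading_sum(res_b, m)
        wt_f = np.where(ok_f, prior * (err_f + eps) ** (-p), 0.0)
        wt_b = np.where(ok_b, prior * (err_b + eps) ** (-p), 0.0)
        num += wt_f * np.where(ok_f, mean_f, 0.0) + wt_b * np.where(ok_b, mean_b, 0.0)
        den += wt_f + wt_b
    return num / den


def chung_kennedy_filter(
    trace: FluorescenceTrace, config: DenoiseConfig | None = None
) -> FluorescenceTrace:
    """Trace-level wrapper around :func:`chung_kennedy`."""
    filtered = chung_kennedy(trace.samples, config)
    return trace.with_samples(filtered, denoised="chung_kennedy")


def fft_lowpass(trace: FluorescenceTrace, cutoff_hz: float = 2.0) -> FluorescenceTrace:
    """Hard FFT low-pass: frequency components above ``cutoff_hz`` are zeroed.

    Used only as a comparator; it attenuates the amplitude of plateaus shorter
    than roughly ``1 / (2 * cutoff)`` and is therefore unsuitable for
    quantal-amplitude analysis of ultrafast events.
    """
    nyquist = trace.sampling_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz")
    spectrum = np.fft.rfft(trace.samples)
    freqs = np.fft.rfftfreq(trace.samples.size, d=trace.dt_s)
    spectrum[freqs > cutoff_hz] = 0.0
    filtered = np.fft.irfft(spectrum, n=trace.samples.size)
    return trace.with_samples(filtered, denoised=f"fft_lowpass_{cutoff_hz}Hz")


@dataclass(frozen=True)
class NormalityReport:
    statistic: float
    p_value: float
    alpha: float
    gaussian: bool
    n: int


def noise_gaussianity(residuals: np.ndarray, alpha: float = 0.01) -> NormalityReport:
    """D'Agostino–Pearson normality test on baseline residuals.

    Residuals are raw minus de-noised values over event-free segments; the
    Chung–Kennedy weighting scheme assumes they are Gaussian.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 20:
        raise ValueError("need at least 20 residuals for a normality test")
    if np.ptp(r) == 0:
        raise ValueError("residuals are constant; normality is undefined")
    stat, p = stats.normaltest(r)
    return NormalityReport(float(stat), float(p), alpha, bool(p > alpha), int(r.size))
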