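"""Kinetic analysis: dwell-time distributions, averaged events, train responses.

Dwell-time histograms of uncensored events are fitted by one- or
two-component exponential decays without offset; a maximum-likelihood
exponential-mixture fit on the raw dwells serves as an internal cross-check of
the histogram least squares.  Model selection between single and double
exponentials uses the extra-sum-of-squares F test together with reduced-R2
comparison.  Averaged (non-de-noised) event traces are fitted with a
two-phase decay, and 40 Hz train responses yield amplitude, rise slope and a
single-exponential decay constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .detect import FusionEvent
from .trace import FluorescenceTrace

__all__ = [
    "KineticFit",
    "MixtureMLE",
    "ModelComparison",
    "TrainResponse",
    "dwell_histogram",
    "fit_exponential_mixture_mle",
    "fit_dwell_distribution",
    "compare_models",
    "mode_proportions",
    "retrieval_vs_dwell",
    "average_event_trace",
    "fit_two_phase_decay",
    "analyze_train_response",
]

DEFAULT_RETRIEVAL_BINS = (0.0, 0.1, 0.5, 1.0, 5.0, 10.0, 20.0)


@dataclass
class MixtureMLE:
    taus_s: tuple[float, ...]
    weights: tuple[float, ...]
    log_likelihood: float
    n: int
    converged: bool


@dataclass
class KineticFit:
    """Exponential fit of a dwell-time density histogram."""

    model: str                      # 'single' or 'double'
    tau1_s: float
    tau2_s: float | None
    amplitude1: float
    amplitude2: float | None
    r_square: float
    residual_sum_squares: float
    n_events: int
    n_censored: int
    bin_edges_s: np.ndarray
    degenerate: bool = False
    mle: MixtureMLE | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_s) - 1

    @property
    def n_parameters(self) -> int:
        return 2 if self.model == "single" else 4


@dataclass(frozen=True)
class ModelComparison:
    f_statistic: float
    p_value: float
    r_square_single_adj: float
    r_square_double_adj: float
    preferred: str


@dataclass
class TrainResponse:
    amplitude: float
    decay_tau_s: float
    rise_slope: float
    baseline: float
    decay_r_square: float
    rise_r_square: float
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def dwell_histogram(
    dwells: np.ndarray,
    fine_width_s: float = 0.1,
    coarse_width_s: float = 1.0,
    split_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Density-normalised histogram with fine bins below ``split_s``.

    Mixed widths (0.1 s below 1 s, 1 s above) resolve the ultrafast peak
    without starving the tail bins.  Returns (centers, density, edges).
    """
    dwells = np.asarray(dwells, dtype=float)
    top = max(np.ceil(dwells.max() / coarse_width_s) * coarse_width_s, split_s + coarse_width_s)
    edges = np.concatenate(
        [
            np.arange(0.0, split_s, fine_width_s),
            np.arange(split_s, top + coarse_width_s / 2, coarse_width_s),
        ]
    )
    counts, edges = np.histogram(dwells, bins=edges)
    widths = np.diff(edges)
    density = counts / (dwells.size * widths)
    centers = edges[:-1] + widths / 2
    return centers, density, edges


def _exp1(t, a, tau):
    return a * np.exp(-t / tau)


def _exp2(t, a1, tau1, a2, tau2):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def fit_exponential_mixture_mle(
    dwells: np.ndarray,
    n_components: int = 2,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> MixtureMLE:
    """EM fit of an exponential mixture to raw (uncensored) dwell times."""
    x = np.asarray(dwells, dtype=float)
    x = x[x > 0]
    qs = np.linspace(0.15, 0.85, n_components)
    taus = np.maximum(np.quantile(x, qs), 1e-6)
    if n_components == 1:
        tau = float(x.mean())
        ll = float(np.sum(-np.log(tau) - x / tau))
        return MixtureMLE((tau,), (1.0,), ll, x.size, True)
    w = np.full(n_components, 1.0 / n_components)
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = (w / taus) * np.exp(-x[:, None] / taus)   # (n, k)
        total = dens.sum(axis=1)
        ll = float(np.log(total).sum())
        resp = dens / total[:, None]
        nk = resp.sum(axis=0)
        w = nk / x.size
        taus = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        taus = np.maximum(taus, 1e-9)
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            converged = True
            break
        prev_ll = ll
    order = np.argsort(taus)
    return MixtureMLE(tuple(taus[order]), tuple(w[order]), ll, x.size, converged)


def fit_dwell_distribution(
    dwells: np.ndarray,
    model: str = "double",
    n_censored: int = 0,
    fine_width_s: float = 0.1,
    coarse_width_s: float = 1.0,
) -> KineticFit:
    """Least-squares exponential fit of the uncensored dwell-time density.

    ``A exp(-t/tau)`` or ``A1 exp(-t/tau1) + A2 exp(-t/tau2)`` (no offset) is
    fitted to the density histogram at bin centers; censored events are
    excluded and only counted.  For the double model a raw-data
    maximum-likelihood mixture fit is attached as an internal cross-check, and
    a collapse of the two components (tau1 ~ tau2 or a vanishing amplitude) is
    flagged as degenerate.
    """
    x = np.asarray(dwells, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 30:
        raise ValueError("need at least 30 uncensored dwell times")
    if model not in ("single", "double"):
        raise ValueError("model must be 'single' or 'double'")
    centers, density, edges = dwell_histogram(x, fine_width_s, coarse_width_s)
    tss = float(((density - density.mean()) ** 2).sum())
    mle = None
    if model == "single":
        p0 = [max(density.max(), 1e-6), max(x.mean(), 1e-3)]
        popt, _ = curve_fit(
            _exp1, centers, density, p0=p0, bounds=(0, np.inf), maxfev=20000
        )
        pred = _exp1(centers, *popt)
        a1, tau1 = popt
        a2 = tau2 = None
        degenerate = False
    else:
        mle = fit_exponential_mixture_mle(x, 2)
        t1, t2 = mle.taus_s
        w1, w2 = mle.weights
        p0 = [max(w1 / t1, 1e-6), t1, max(w2 / t2, 1e-6), t2]
        popt, _ = curve_fit(
            _exp2, centers, density, p0=p0, bounds=(0, np.inf), maxfev=20000
        )
        a1, tau1, a2, tau2 = popt
        if tau1 > tau2:  # report fast component first
            a1, tau1, a2, tau2 = a2, tau2, a1, tau1
        amp_total = a1 + a2
        degenerate = bool(
            abs(tau2 - tau1) / max(tau2, 1e-12) < 0.05
            or min(a1, a2) < 1e-3 * max(amp_total, 1e-12)
        )
        pred = _exp2(centers, a1, tau1, a2, tau2)
    rss = float(((density - pred) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return KineticFit(
        model=model,
        tau1_s=float(tau1),
        tau2_s=None if tau2 is None else float(tau2),
        amplitude1=float(a1),
        amplitude2=None if a2 is None else float(a2),
        r_square=float(r2),
        residual_sum_squares=rss,
        n_events=int(x.size),
        n_censored=int(n_censored),
        bin_edges_s=edges,
        degenerate=degenerate,
        mle=mle,
    )


def compare_models(single_fit: KineticFit, double_fit: KineticFit) -> ModelComparison:
    """Extra-sum-of-squares F test between nested exponential fits.

    Both fits must come from the same histogram (same events and binning).
    The verdict combines the F-test p-value (alpha = 0.05) with the reduced
    (adjusted) R2 comparison.
    """
    if single_fit.model != "single" or double_fit.model != "double":
        raise ValueError("pass the single fit first and the double fit second")
    if single_fit.n_events != double_fit.n_events or single_fit.n_bins != double_fit.n_bins:
        raise ValueError("fits were made on different data; the F test is not applicable")
    n = single_fit.n_bins
    df1 = double_fit.n_parameters - single_fit.n_parameters
    df2 = n - double_fit.n_parameters
    if df2 <= 0:
        raise ValueError("not enough histogram bins for the nested F test")
    rss_s, rss_d = single_fit.residual_sum_squares, double_fit.residual_sum_squares
    if rss_d <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = max((rss_s - rss_d) / df1 / (rss_d / df2), 0.0)
        p = float(stats.f.sf(f_stat, df1, df2))

    def _adj(fit: KineticFit) -> float:
        dof = n - fit.n_parameters
        return 1.0 - (1.0 - fit.r_square) * (n - 1) / dof if dof > 0 else np.nan

    r2s, r2d = _adj(single_fit), _adj(double_fit)
    preferred = "double" if (p < 0.05 and r2d >= r2s and not double_fit.degenerate) else "single"
    return ModelComparison(float(f_stat), float(p), float(r2s), float(r2d), preferred)


def _modes_of(events: Sequence[FusionEvent] | Sequence[str]) -> list[str]:
    return [ev.mode if isinstance(ev, FusionEvent) else str(ev) for ev in events]


def mode_proportions(events: Sequence[FusionEvent] | Sequence[str]) -> tuple[float, float, float]:
    """Percentage of ultrafast / fast / ultraslow events (sums to 100)."""
    modes = _modes_of(events)
    if not modes:
        raise ValueError("need at least one event")
    n = len(modes)
    return tuple(100.0 * modes.count(m) / n for m in ("ultrafast", "fast", "ultraslow"))


def retrieval_vs_dwell(
    events: Sequence[FusionEvent],
    dwell_bins_s: Sequence[float] = DEFAULT_RETRIEVAL_BINS,
) -> pd.DataFrame:
    """Mean +- SD retrieval fraction per dwell-time bin (empty bins omitted)."""
    rows = []
    dwells = np.array([ev.dwell_time_s for ev in events], dtype=float)
    fracs = np.array([ev.retrieval_fraction for ev in events], dtype=float)
    ok = np.isfinite(dwells) & np.isfinite(fracs)
    dwells, fracs = dwells[ok], fracs[ok]
    for lo, hi in zip(dwell_bins_s[:-1], dwell_bins_s[1:]):
        sel = (dwells >= lo) & (dwells < hi)
        if not sel.any():
            continue
        rows.append(
            {
                "dwell_lo_s": lo,
                "dwell_hi_s": hi,
                "n": int(sel.sum()),
                "mean_fraction": float(fracs[sel].mean()),
                "sd_fraction": float(fracs[sel].std(ddof=1)) if sel.sum() > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def average_event_trace(
    traces: dict[str, FluorescenceTrace],
    events: Sequence[FusionEvent],
    pre_s: float = 2.0,
    post_s: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Onset-aligned average of raw (non-de-noised) event segments.

    Segments are baseline-subtracted (each event's own baseline mean) before
    averaging.  Returns (time axis relative to onset, mean, SD, n).
    """
    if len(events) < 20:
        raise ValueError("need at least 20 events to average")
    rates = {tr.sampling_rate_hz for tr in traces.values()}
    if len(rates) != 1:
        raise ValueError("all traces must share one sampling rate")
    rate = rates.pop()
    n_pre, n_post = int(round(pre_s * rate)), int(round(post_s * rate))
    segs = []
    for ev in events:
        tr = traces[ev.bouton_id]
        onset = tr.frame_of(ev.onset_time_s)
        if onset - n_pre < 0 or onset + n_post > len(tr):
            continue
        segs.append(tr.samples[onset - n_pre : onset + n_post] - ev.baseline_mean)
    if len(segs) < 20:
        raise ValueError("fewer than 20 events fit entirely inside their traces")
    arr = np.vstack(segs)
    t = (np.arange(-n_pre, n_post)) / rate
    return t, arr.mean(axis=0), arr.std(axis=0, ddof=1), arr.shape[0]


def _exp2_offset(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def fit_two_phase_decay(
    t_s: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float, float, bool]:
    """Two-phase exponential decay fit of an averaged post-peak trace.

    A constant offset absorbs the floor contributed by censored (never
    decaying) events.  Returns (tau1, tau2, A1, A2, offset, degenerate); the
    fit is degenerate when the two time constants collapse or one amplitude
    vanishes.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(y, dtype=float)
    t = t - t[0]
    span = max(t[-1], 1e-6)
    scale = max(y.max() - y.min(), 1e-9)
    p0 = [scale / 2, span / 20, scale / 2, span / 2, y.min()]
    popt, _ = curve_fit(
        _exp2_offset,
        t,
        y,
        p0=p0,
        bounds=([0, 1e-4, 0, 1e-4, -np.inf], [np.inf, np.inf, np.inf, np.inf, np.inf]),
        maxfev=40000,
    )
    a1, tau1, a2, tau2, c = popt
    if tau1 > tau2:
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    degenerate = bool(
        abs(tau2 - tau1) / max(tau2, 1e-12) < 0.05 or min(a1, a2) < 0.01 * max(a1 + a2, 1e-12)
    )
    return float(tau1), float(tau2), float(a1), float(a2), float(c), degenerate


def analyze_train_response(
    trace: FluorescenceTrace,
    train_start_s: float,
    train_duration_s: float,
    baseline_s: float = 5.0,
) -> TrainResponse:
    """Amplitude, rise slope and decay constant of a stimulus-train response.

    Amplitude is the peak dF over the pre-train baseline; the rise slope is
    the linear regression of dF versus time during the train; the decay
    constant comes from a single-exponential fit (with free offset) of the
    post-train return.
    """
    rate = trace.sampling_rate_hz
    s0 = trace.frame_of(train_start_s)
    s1 = trace.frame_of(train_start_s + train_duration_s)
    b0 = max(s0 - int(round(baseline_s * rate)), 0)
    if s0 - b0 < 2 or s1 <= s0 + 2 or s1 >= len(trace) - 3:
        raise ValueError("train segment does not fit inside the trace")
    baseline = float(trace.samples[b0:s0].mean())
    df = trace.samples - baseline
    amplitude = float(df[s0 : s1 + 1].max())
    t = trace.times()
    rise = stats.linregress(t[s0:s1], df[s0:s1])
    diagnostics: dict = {}
    if amplitude <= 0:
        return TrainResponse(
            amplitude, np.nan, float(rise.slope), baseline, np.nan,
            float(rise.rvalue**2), False, {"reason": "no response above baseline"},
        )
    tail_t = t[s1:] - t[s1]
    tail_y = df[s1:]
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            tail_t,
            tail_y,
            p0=[max(tail_y[0], 1e-6), max(tail_t[-1] / 3, 1e-3), 0.0],
            bounds=([0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        a, tau, c = popt
        pred = a * np.exp(-tail_t / tau) + c
        tss = float(((tail_y - tail_y.mean()) ** 2).sum())
        r2 = 1.0 - float(((tail_y - pred) ** 2).sum()) / tss if tss > 0 else np.nan
        converged = True
    except (RuntimeError, ValueError) as exc:
        tau, r2, converged = np.nan, np.nan, False
        diagnostics["decay_fit_error"] = str(exc)
    return TrainResponse(
        amplitude=amplitude,
        decay_tau_s=float(tau),
        rise_slope=float(rise.slope),
        baseline=baseline,
        decay_r_square=float(r2),
        rise_r_square=float(rise.rvalue**2),
        converged=converged,
        diagnostics=diagnostics,
    )
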