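"""Stimulus-locked detection and characterisation of single-vesicle fusion events.

A successful fusion event is a fluorescence rise, coincident with a stimulus,
that exceeds three times the standard deviation of the local baseline (the
~2 s preceding the stimulus) on the de-noised trace, with a peak amplitude at
or below the quantal upper limit (multivesicular candidates are excluded and
logged).  The dwell time runs from the attainment of peak amplitude to the
onset of fluorescence decay — the first persistent switch of the discrete
first derivative to negative values; events with no decay onset inside the
censoring window (> 20 s) are censored and labelled ultraslow.  The fraction
of retrieval compares the decayed amplitude to the fusion step amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .trace import FluorescenceTrace

__all__ = [
    "DetectionConfig",
    "FusionEvent",
    "DetectionResult",
    "estimate_quantal_bounds",
    "detect_events",
    "measure_dwell_time",
    "fraction_of_retrieval",
    "classify_mode",
    "characterize_events",
    "release_probability",
    "ReleaseProbability",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Detection, censoring and classification thresholds.

    ``threshold_sd_multiple`` (3) and ``baseline_window_s`` (2 s) implement
    the 3x-baseline-SD success rule; ``mode_boundaries_s`` (1 s, 20 s)
    delimit ultrafast / fast / ultraslow retrieval; ``retrieval_class_bounds``
    (0.8, 1.2) delimit partial / quantal / excess retrieval.  The decay-onset
    search confirms that a candidate decay truly leaves the plateau
    (``departure_amp_fraction`` of the event amplitude, held for
    ``decay_onset_persistence_frames`` frames) before locating the onset as
    the last frame still at plateau level; see :func:`measure_dwell_time`.
    """

    baseline_window_s: float = 2.0
    threshold_sd_multiple: float = 3.0
    coincidence_window_frames: int = 3
    censor_limit_s: float = 20.0
    mode_boundaries_s: tuple[float, float] = (1.0, 20.0)
    retrieval_class_bounds: tuple[float, float] = (0.8, 1.2)
    decay_onset_persistence_frames: int = 2
    baseline_sd_source: str = "raw"   # 'raw' or 'denoised'
    baseline_sd_global_weight: float = 0.7
    departure_amp_fraction: float = 0.25
    plateau_window_s: float = 0.5
    plateau_tol_sd: float = 1.0
    plateau_tol_amp_fraction: float = 0.03
    confirm_extra_s: float = 10.0
    censor_at_next_stimulus: bool = False
    peak_search_limit_s: float = 1.0

    def validate(self) -> None:
        if min(self.baseline_window_s, self.threshold_sd_multiple, self.censor_limit_s) <= 0:
            raise ValueError("baseline window, threshold multiple and censor limit must be positive")
        if self.coincidence_window_frames < 1 or self.decay_onset_persistence_frames < 1:
            raise ValueError("frame windows must be >= 1")
        lo, hi = self.mode_boundaries_s
        if not (0 < lo < hi):
            raise ValueError("mode boundaries must be increasing and positive")
        a, b = self.retrieval_class_bounds
        if not (0 < a < 1 < b):
            raise ValueError("retrieval class bounds must straddle 1")
        if self.baseline_sd_source not in ("raw", "denoised"):
            raise ValueError("baseline_sd_source must be 'raw' or 'denoised'")


@dataclass
class FusionEvent:
    """A detected stimulus-locked single-vesicle fusion event."""

    bouton_id: str
    stimulus_index: int
    stimulus_time_s: float
    onset_time_s: float
    peak_time_s: float
    peak_amplitude: float
    baseline_mean: float
    baseline_sd: float                 # the SD the 3x threshold used
    baseline_sd_denoised: float = np.nan
    dwell_time_s: float = np.nan       # NaN when censored
    censored: bool = False
    censor_truncated: bool = False     # censoring forced by the trace edge
    decay_onset_time_s: float = np.nan
    retrieval_fraction: float = np.nan
    mode: str = ""
    retrieval_class: str = ""


@dataclass
class DetectionResult:
    """Per-trace detection outcome: events, exclusions, skipped stimuli."""

    events: list[FusionEvent] = field(default_factory=list)
    multivesicular: list[FusionEvent] = field(default_factory=list)
    skipped_stimuli: list[int] = field(default_factory=list)
    n_stimuli: int = 0


def estimate_quantal_bounds(amplitudes: np.ndarray, random_state: int = 0) -> tuple[float, float]:
    """Single-quantum mean and the multivesicular upper amplitude limit.

    The dominant peak of the amplitude distribution (kernel density estimate)
    is the single-vesicle mode ``q1``; the next density peak above it is the
    two-quantum mode ``q2``, and the upper limit is ``q1 + 0.5 * (q2 - q1)``
    — halfway between the one- and two-quantum peaks.  Each peak location is
    refined by a two-component location-mixture fit restricted to the
    amplitudes around the two peaks, which is robust to a sub-quantal
    false-positive tail.  If no second peak exists the distribution is
    treated as unimodal and the limit defaults to ``1.5 * q1`` with a
    warning.
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 50:
        raise ValueError("need at least 50 amplitudes to estimate quantal bounds")
    kde = stats.gaussian_kde(amps)
    grid = np.linspace(amps.min(), amps.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.nonzero(interior)[0] + 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    main = peaks[np.argmax(dens[peaks])]
    higher = peaks[(grid[peaks] > grid[main]) & (dens[peaks] > 0.05 * dens[main])]
    if higher.size == 0:
        warnings.warn(
            "amplitude distribution looks unimodal; upper limit set to 1.5 x single-quantum mean",
            stacklevel=2,
        )
        q1 = float(grid[main])
        return q1, 1.5 * q1
    second = higher[np.argmax(dens[higher])]
    q1_0, q2_0 = float(grid[main]), float(grid[second])
    # refine the two peak means with a local two-component mixture fit
    sel = amps[(amps > q1_0 - 0.5 * (q2_0 - q1_0)) & (amps < q2_0 + 0.5 * (q2_0 - q1_0))]
    if sel.size >= 50:
        gm = GaussianMixture(
            n_components=2,
            n_init=1,
            means_init=np.array([[q1_0], [q2_0]]),
            random_state=random_state,
        )
        gm.fit(sel.reshape(-1, 1))
        means = np.sort(gm.means_.ravel())
        if means[0] > 0 and (means[1] - means[0]) > 0.25 * (q2_0 - q1_0):
            q1_0, q2_0 = float(means[0]), float(means[1])
    return q1_0, float(q1_0 + 0.5 * (q2_0 - q1_0))


def _baseline_stats(x: np.ndarray, stim_frame: int, n_baseline: int) -> tuple[float, float]:
    """Baseline level at the stimulus and noise SD, detrended.

    A linear trend over the window absorbs the decay tail of a preceding
    event, so the level is extrapolated to the stimulus frame and the SD
    reflects noise rather than trend.  On a flat baseline this reduces to the
    plain mean and SD.
    """
    seg = x[stim_frame - n_baseline : stim_frame]
    k = np.arange(seg.size, dtype=float)
    slope, intercept = np.polyfit(k, seg, 1)
    resid = seg - (slope * k + intercept)
    level = float(slope * seg.size + intercept)
    sd = float(resid.std(ddof=2)) if seg.size > 2 else float(seg.std(ddof=1))
    return level, sd


def detect_events(
    trace_denoised: FluorescenceTrace,
    stimulus_times_s: Sequence[float],
    config: DetectionConfig | None = None,
    upper_limit: float | None = None,
    trace_raw: FluorescenceTrace | None = None,
) -> DetectionResult:
    """Call at most one fusion event per stimulus on a de-noised trace.

    An event is called iff the trace rises above
    ``baseline_mean + threshold_sd_multiple * baseline_sd`` within the
    coincidence window after the stimulus.  By default the baseline SD is
    taken from the raw (bleach-corrected, pre-filter) trace when supplied —
    the quantal threshold then sits at three raw noise SDs, which keeps
    sub-quantal filter-noise excursions from being called as events; set
    ``baseline_sd_source='denoised'`` (or omit ``trace_raw``) to threshold on
    the de-noised noise scale instead.  Candidates whose peak amplitude
    exceeds ``upper_limit`` are excluded as multivesicular and logged
    separately; stimuli too close to the trace start for a full baseline
    window are skipped and logged.
    """
    config = config or DetectionConfig()
    config.validate()
    x = trace_denoised.samples
    raw = trace_raw.samples if trace_raw is not None else None
    if raw is not None and raw.size != x.size:
        raise ValueError("raw and de-noised traces differ in length")
    rate = trace_denoised.sampling_rate_hz
    n_baseline = int(round(config.baseline_window_s * rate))
    result = DetectionResult(n_stimuli=len(stimulus_times_s))
    # camera noise is stationary: shrink each local baseline SD toward the
    # trace-level median to tame the variance of 20-sample SD estimates
    usable = [
        trace_denoised.frame_of(stim)
        for stim in stimulus_times_s
        if trace_denoised.frame_of(stim) - n_baseline >= 0
        and trace_denoised.frame_of(stim) < x.size
    ]
    global_sd_dn = float(np.median([_baseline_stats(x, s, n_baseline)[1] for s in usable])) if usable else np.nan
    global_sd_raw = (
        float(np.median([_baseline_stats(raw, s, n_baseline)[1] for s in usable]))
        if usable and raw is not None
        else np.nan
    )

    w = config.baseline_sd_global_weight

    def _shrink(local: float, global_: float) -> float:
        return (1 - w) * local + w * global_ if np.isfinite(global_) else local

    for idx, stim in enumerate(stimulus_times_s):
        s = trace_denoised.frame_of(stim)
        if s - n_baseline < 0 or s >= x.size:
            result.skipped_stimuli.append(idx)
            continue
        # de-noised stats stop 2 frames short of the stimulus: the filter's
        # backward predictors leak the upcoming step into those frames
        _, sd_dn = _baseline_stats(x, max(s - 2, n_baseline), n_baseline)
        sd_dn = _shrink(sd_dn, global_sd_dn)
        if raw is not None:
            mean, sd_raw = _baseline_stats(raw, s, n_baseline)
            sd_raw = _shrink(sd_raw, global_sd_raw)
            sd_thr = sd_raw if config.baseline_sd_source == "raw" else sd_dn
        else:
            mean, _ = _baseline_stats(x, max(s - 2, n_baseline), n_baseline)
            sd_thr = sd_dn
        # the absolute floor keeps sub-noise numerical drift (noise-free
        # traces, residual correction curvature) from registering as events
        threshold = mean + config.threshold_sd_multiple * sd_thr + 1e-3 * max(abs(mean), 1.0)
        window = x[s : min(s + config.coincidence_window_frames, x.size)]
        above = np.nonzero(window > threshold)[0]
        if above.size == 0:
            continue
        onset = s + int(above[0])
        # a fusion step must actually rise from the pre-stimulus level; a
        # decaying baseline whose convexity beats the linear extrapolation is
        # not an event (s-2 dodges the filter's pre-step leak at s-1)
        if s >= 2 and not (x[onset] > x[s - 2]):
            continue
        # peak attainment: climb while the de-noised trace still rises beyond
        # the baseline noise (tiny guard keeps noiseless plateaus in place)
        peak = onset
        limit = min(x.size - 1, onset + int(round(config.peak_search_limit_s * rate)))
        climb_tol = max(0.5 * sd_dn, 1e-9)
        while peak < limit and x[peak + 1] > x[peak] + climb_tol:
            peak += 1
        event = FusionEvent(
            bouton_id=trace_denoised.bouton_id,
            stimulus_index=idx,
            stimulus_time_s=float(stim),
            onset_time_s=float(onset / rate + trace_denoised.t0_s),
            peak_time_s=float(peak / rate + trace_denoised.t0_s),
            peak_amplitude=float(x[peak] - mean),
            baseline_mean=mean,
            baseline_sd=sd_thr,
            baseline_sd_denoised=sd_dn,
        )
        if upper_limit is not None and event.peak_amplitude > upper_limit:
            result.multivesicular.append(event)
        else:
            result.events.append(event)
    return result


def measure_dwell_time(
    trace_denoised: FluorescenceTrace,
    event: FusionEvent,
    config: DetectionConfig | None = None,
    next_stimulus_s: float | None = None,
) -> FusionEvent:
    """Measure the event's dwell time, censoring at the 20 s limit.

    The dwell runs from the attainment of peak amplitude to the onset of the
    fluorescence decay.  The decay onset is located in two steps tuned on
    simulated traces: (1) find the *departure* — the first run of
    ``decay_onset_persistence_frames`` frames that sit below
    ``peak - max(threshold_sd_multiple * baseline_sd,
    departure_amp_fraction * amplitude)``, i.e. the decay has demonstrably
    left the plateau; (2) walk back to the last frame whose trailing
    ``plateau_window_s`` mean is still at plateau level (within
    ``plateau_tol_sd`` baseline SDs, with a small amplitude-relative floor).
    On noiseless traces this coincides (to one frame) with the first switch
    of the discrete first derivative to negative values, which is how the
    onset is defined; the departure step merely makes the sign rule immune to
    noise on long plateaus.  Without a departure whose decay onset lies
    inside the censor window the event is censored; a window cut short by the
    trace edge (or the next stimulus, when ``censor_at_next_stimulus``) sets
    ``censor_truncated``.
    """
    config = config or DetectionConfig()
    x = trace_denoised.samples
    rate = trace_denoised.sampling_rate_hz
    peak_frame = trace_denoised.frame_of(event.peak_time_s)
    amp = event.peak_amplitude
    # median over three frames: the plateau reference must not ride a noise maximum
    peak_value = float(np.median(x[peak_frame : min(peak_frame + 3, x.size)]))
    # plateau/departure tolerances live on the de-noised noise scale
    sd = event.baseline_sd_denoised if np.isfinite(event.baseline_sd_denoised) else event.baseline_sd
    censor_end_s = event.onset_time_s + config.censor_limit_s
    confirm_end_s = censor_end_s + config.confirm_extra_s
    if config.censor_at_next_stimulus and next_stimulus_s is not None:
        censor_end_s = min(censor_end_s, next_stimulus_s)
    if next_stimulus_s is not None:
        confirm_end_s = min(confirm_end_s, next_stimulus_s)
    confirm_end = min(int(round(confirm_end_s * rate)), x.size - 1)
    censor_end = min(int(round(censor_end_s * rate)), x.size - 1)

    def _censor(truncated: bool) -> FusionEvent:
        event.dwell_time_s = np.nan
        event.censored = True
        event.censor_truncated = truncated
        event.decay_onset_time_s = np.nan
        return event

    window_truncated = (censor_end - peak_frame) / rate < config.censor_limit_s - 1.5 / rate
    departure = peak_value - max(config.threshold_sd_multiple * sd, config.departure_amp_fraction * amp)
    below = x[peak_frame : confirm_end + 1] < departure
    k = config.decay_onset_persistence_frames
    runs = np.convolve(below.astype(int), np.ones(k, dtype=int), mode="valid")
    hits = np.nonzero(runs == k)[0]
    if hits.size == 0:
        return _censor(window_truncated)
    t_departure = peak_frame + int(hits[0])
    # walk back: last frame whose trailing plateau-window mean is at plateau
    # level.  The amplitude-relative floor absorbs the slight plateau bow the
    # Chung-Kennedy filter leaves at plateau edges, so it only applies to
    # filtered traces; on unfiltered (e.g. noise-free synthetic) input the
    # tolerance collapses to the noise floor and the rule is exact.
    q = max(int(round(config.plateau_window_s * rate)), 2)
    bow_floor = (
        config.plateau_tol_amp_fraction * abs(amp)
        if trace_denoised.metadata.get("denoised")
        else 0.0
    )
    near = peak_value - max(config.plateau_tol_sd * sd, bow_floor, 1e-9)
    idx = np.arange(peak_frame, t_departure + 1)
    cum = np.cumsum(np.concatenate(([0.0], x)))
    lo = np.maximum(idx - q + 1, peak_frame)
    trailing_mean = (cum[idx + 1] - cum[lo]) / (idx + 1 - lo)
    good = np.nonzero(trailing_mean >= near)[0]
    decay_frame = peak_frame + (int(good[-1]) if good.size else 0)
    if decay_frame > censor_end:
        return _censor(window_truncated)
    event.dwell_time_s = float((decay_frame - peak_frame) / rate)
    event.decay_onset_time_s = float(decay_frame / rate + trace_denoised.t0_s)
    event.censored = False
    event.censor_truncated = False
    return event


def fraction_of_retrieval(
    trace_denoised: FluorescenceTrace,
    event: FusionEvent,
    config: DetectionConfig | None = None,
    next_stimulus_s: float | None = None,
) -> FusionEvent:
    """Retrieved fraction of the fused fluorescence, and its class.

    ``fraction = (peak - endpoint) / peak_amplitude`` with the endpoint taken
    as the mean over the final settled second before the next stimulus (or the
    trace end).  Defined only for events with an observed decay onset.
    """
    config = config or DetectionConfig()
    if event.censored:
        event.retrieval_fraction = np.nan
        event.retrieval_class = ""
        return event
    x = trace_denoised.samples
    rate = trace_denoised.sampling_rate_hz
    end_s = next_stimulus_s if next_stimulus_s is not None else trace_denoised.times()[-1]
    end_frame = min(trace_denoised.frame_of(end_s), x.size)
    start_frame = max(end_frame - int(round(rate)), trace_denoised.frame_of(event.decay_onset_time_s))
    endpoint = float(x[start_frame:end_frame].mean())
    peak_value = event.baseline_mean + event.peak_amplitude
    event.retrieval_fraction = float((peak_value - endpoint) / event.peak_amplitude)
    lo, hi = config.retrieval_class_bounds
    if event.retrieval_fraction < lo:
        event.retrieval_class = "partial"
    elif event.retrieval_fraction > hi:
        event.retrieval_class = "excess"
    else:
        event.retrieval_class = "quantal"
    return event


def classify_mode(event: FusionEvent, config: DetectionConfig | None = None) -> FusionEvent:
    """Assign the retrieval mode from the dwell band (0–1 s / 1–20 s / censored)."""
    config = config or DetectionConfig()
    lo, _ = config.mode_boundaries_s
    if event.censored:
        event.mode = "ultraslow"
    elif event.dwell_time_s <= lo:
        event.mode = "ultrafast"
    else:
        event.mode = "fast"
    return event


def characterize_events(
    trace_denoised: FluorescenceTrace,
    result: DetectionResult,
    stimulus_times_s: Sequence[float],
    config: DetectionConfig | None = None,
) -> DetectionResult:
    """Dwell, retrieval fraction and mode for every detected event in place."""
    config = config or DetectionConfig()
    stim = list(stimulus_times_s)
    for event in result.events:
        nxt = stim[event.stimulus_index + 1] if event.stimulus_index + 1 < len(stim) else None
        measure_dwell_time(trace_denoised, event, config, next_stimulus_s=nxt)
        fraction_of_retrieval(trace_denoised, event, config, next_stimulus_s=nxt)
        classify_mode(event, config)
    return result


@dataclass(frozen=True)
class ReleaseProbability:
    per_bouton: np.ndarray
    mean: float
    sem: float
    n_boutons: int


def release_probability(
    events_per_bouton: dict[str, int] | Sequence[int],
    n_stimuli_per_bouton: int,
) -> ReleaseProbability:
    """Failure-analysis release probability: successes / stimuli per bouton.

    Counts should include multivesicular candidates (they are fusion
    successes even though they are excluded from dwell analysis).
    """
    if n_stimuli_per_bouton < 1:
        raise ValueError("need at least one stimulus per bouton")
    counts = (
        np.asarray(list(events_per_bouton.values()), dtype=float)
        if isinstance(events_per_bouton, dict)
        else np.asarray(events_per_bouton, dtype=float)
    )
    p = counts / n_stimuli_per_bouton
    sem = float(p.std(ddof=1) / np.sqrt(p.size)) if p.size > 1 else 0.0
    return ReleaseProbability(p, float(p.mean()), sem, int(p.size))
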