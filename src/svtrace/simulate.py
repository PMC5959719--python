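"""Synthetic single-vesicle fluorescence trace generator.

Emulates pHluorin/pHTomato bouton recordings during sparse (0.05 Hz) field
stimulation: each stimulus independently triggers vesicle fusion with
probability ``p_release``; fusion produces a single-frame fluorescence step of
quantal amplitude (with occasional two-quantum multivesicular events), a
plateau whose duration (the dwell time) is drawn from one of three retrieval
modes — ultrafast, fast, or ultraslow/censored — followed by a
single-exponential re-acidification decay toward an endpoint set by the
fraction of retrieval.  An additive exponential photobleaching drift and
i.i.d. Gaussian noise complete the trace, matching the noise model the
nonlinear de-noising filter assumes.

Dwell times for the ultrafast and fast modes are drawn from exponential
distributions truncated to their kinetic bands (0–1 s and 1–20 s), so the
generative mode label coincides exactly with the dwell-band classification the
detector applies; ultraslow events never decay within the observation window
and are recorded as censored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trace import Condition, FluorescenceTrace

__all__ = [
    "RetrievalFractionDist",
    "SimulationConfig",
    "GroundTruthEvent",
    "ExperimentDataset",
    "generate_single_vesicle_trace",
    "generate_experiment",
    "generate_negative_control",
    "generate_train_trace",
    "generate_pool_trace",
    "truth_to_frame",
]

MODES = ("ultrafast", "fast", "ultraslow")


@dataclass(frozen=True)
class RetrievalFractionDist:
    """Mixture over retrieval-endpoint classes, conditioned on dwell time.

    Fractions of retrieval fall into three classes: partial (< 0.8 of the
    fused fluorescence retrieved), quantal (1.0 +- 0.2) and excess (> 1.2).
    Retrieval efficiency depends on retrieval speed: ultrafast events are
    almost all quantal, while the dispersion of retrieval grows with dwell
    time.  The generator therefore interpolates the class probabilities in
    log-dwell between ``anchor_short`` (dwell <= 0.5 s) and ``anchor_long``
    (dwell >= 20 s), and widens the quantal spread with dwell; the anchors
    are set so the marginal class mix over the default dwell composition is
    close to ``weights`` (~35% partial / 50% quantal / 15% excess).  Passing
    ``dwell_s=None`` (or ``dwell_dependent=False``) falls back to the
    unconditional ``weights``.
    """

    weights: tuple[float, float, float] = (0.35, 0.50, 0.15)  # partial, quantal, excess
    partial_range: tuple[float, float] = (0.3, 0.8)
    quantal_mean: float = 1.0
    quantal_sd: float = 0.06
    excess_range: tuple[float, float] = (1.2, 1.6)
    dwell_dependent: bool = True
    anchor_short: tuple[float, float, float] = (0.12, 0.82, 0.06)
    anchor_long: tuple[float, float, float] = (0.72, 0.00, 0.28)
    anchor_dwells_s: tuple[float, float] = (0.5, 20.0)
    quantal_sd_growth: float = 0.10   # added to quantal_sd at the long anchor

    def validate(self) -> None:
        for w in (self.weights, self.anchor_short, self.anchor_long):
            arr = np.asarray(w, dtype=float)
            if arr.size != 3 or np.any(arr < 0) or not np.isclose(arr.sum(), 1.0):
                raise ValueError("retrieval class weights must be nonnegative and sum to 1")

    def class_probabilities(self, dwell_s: float | None) -> np.ndarray:
        if dwell_s is None or not self.dwell_dependent or not np.isfinite(dwell_s):
            return np.asarray(self.weights, dtype=float)
        d_lo, d_hi = self.anchor_dwells_s
        beta = np.clip(np.log(max(dwell_s, 1e-6) / d_lo) / np.log(d_hi / d_lo), 0.0, 1.0)
        lo = np.asarray(self.anchor_short, dtype=float)
        hi = np.asarray(self.anchor_long, dtype=float)
        return (1 - beta) * lo + beta * hi

    def sample(
        self,
        rng: np.random.Generator,
        n: int,
        dwell_s: float | np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` retrieval fractions; returns (fractions, class labels)."""
        dwells = np.broadcast_to(
            np.asarray(np.nan if dwell_s is None else dwell_s, dtype=float), (n,)
        )
        d_lo, d_hi = self.anchor_dwells_s
        classes = np.array(["partial", "quantal", "excess"])
        out = np.empty(n)
        labels = np.empty(n, dtype=object)
        for i in range(n):
            d = (
                float(dwells[i])
                if self.dwell_dependent and np.isfinite(dwells[i])
                else None
            )
            lab = rng.choice(classes, p=self.class_probabilities(d))
            labels[i] = lab
            if lab == "partial":
                out[i] = rng.uniform(*self.partial_range)
            elif lab == "excess":
                out[i] = rng.uniform(*self.excess_range)
            else:
                beta = 0.0 if d is None else float(
                    np.clip(np.log(max(d, 1e-6) / d_lo) / np.log(d_hi / d_lo), 0.0, 1.0)
                )
                sd = self.quantal_sd + self.quantal_sd_growth * beta
                out[i] = np.clip(rng.normal(self.quantal_mean, sd), 0.8, 1.2)
        return out, labels.astype(str)


def _default_stimuli() -> list[float]:
    # 20 single APs at 0.05 Hz starting 20 s into the recording.
    return [20.0 + 20.0 * k for k in range(20)]


@dataclass
class SimulationConfig:
    """Generative parameters for a simulated single-vesicle experiment.

    Defaults correspond to the 2 mM Ca2+ / 24 degC condition: release
    probability 0.15 per stimulus, ~20/40/40% ultrafast/fast/ultraslow
    retrieval with time constants 0.2 s and 8 s, quantal signal-to-noise of 5,
    and a slow additive photobleaching drift.
    """

    sampling_rate_hz: float = 10.0
    duration_s: float = 425.0
    stimulus_times_s: list[float] = field(default_factory=_default_stimuli)
    p_release: float = 0.15
    quantal_amplitude: float = 5.0
    quantal_cv: float = 0.15
    multivesicular_prob: float = 0.10
    mode_weights: tuple[float, float, float] = (0.2, 0.4, 0.4)
    tau_ultrafast_s: float = 0.2
    tau_fast_s: float = 8.0
    mode_boundary_s: float = 1.0
    censor_limit_s: float = 20.0
    tau_reacidification_s: float = 4.0
    retrieval_fraction_dist: RetrievalFractionDist = field(default_factory=RetrievalFractionDist)
    bleach_tau_s: float = 100.0
    bleach_amplitude: float = 20.0
    background_level: float = 100.0
    noise_sd: float = 1.0
    fixed_dwell_s: float | None = None
    seed: int | None = None
    condition: Condition = field(default_factory=Condition)

    def validate(self) -> None:
        w = np.asarray(self.mode_weights, dtype=float)
        if w.size != 3 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("mode_weights must be three nonnegative values summing to 1")
        for name in ("tau_ultrafast_s", "tau_fast_s", "tau_reacidification_s", "bleach_tau_s"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not (0.0 <= self.p_release <= 1.0):
            raise ValueError("p_release must lie in [0, 1]")
        if not (0.0 <= self.multivesicular_prob <= 1.0):
            raise ValueError("multivesicular_prob must lie in [0, 1]")
        st = np.asarray(self.stimulus_times_s, dtype=float)
        if st.size and (np.any(np.diff(st) <= 0) or st[0] < 0 or st[-1] >= self.duration_s):
            raise ValueError("stimulus times must be strictly increasing and within the trace")
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        self.retrieval_fraction_dist.validate()

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass
class GroundTruthEvent:
    """Per-stimulus truth record (one row per stimulus, fused or not)."""

    bouton_id: str
    stimulus_index: int
    stimulus_time_s: float
    fused: bool
    n_quanta: int = 0
    true_amplitude: float = np.nan
    true_dwell_s: float = np.nan        # NaN when censored or not fused
    censored: bool = False
    true_mode: str = ""                 # '' when not fused
    true_retrieval_fraction: float = np.nan

    def __post_init__(self) -> None:
        if self.fused and self.n_quanta < 1:
            raise ValueError("fused events carry at least one quantum")
        if self.fused and (self.censored != (self.true_mode == "ultraslow")):
            raise ValueError("censoring and the ultraslow label must coincide")


@dataclass
class ExperimentDataset:
    """Bundle of simulated traces plus the ground-truth event table."""

    traces: list[FluorescenceTrace]
    truth: pd.DataFrame
    config: SimulationConfig


def _truncated_exponential(rng: np.random.Generator, tau: float, lo: float, hi: float) -> float:
    """Inverse-CDF draw from Exp(tau) conditioned on (lo, hi]."""
    a, b = np.exp(-lo / tau), np.exp(-hi / tau)
    u = rng.uniform(0.0, 1.0)
    return float(-tau * np.log(a - u * (a - b)))


def _baseline(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    return config.background_level + config.bleach_amplitude * np.exp(-t / config.bleach_tau_s)


def _sample_event(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, float, str, float, float]:
    """Draw (n_quanta, amplitude, mode, dwell, retrieval_fraction) for one fusion."""
    n_quanta = 2 if rng.uniform() < config.multivesicular_prob else 1
    sd = config.quantal_amplitude * config.quantal_cv
    amp = n_quanta * max(rng.normal(config.quantal_amplitude, sd), 0.05 * config.quantal_amplitude)
    mode = rng.choice(np.array(MODES), p=np.asarray(config.mode_weights, dtype=float))
    if mode == "ultraslow":
        dwell = np.nan
    elif config.fixed_dwell_s is not None:
        dwell = float(config.fixed_dwell_s)
    elif mode == "ultrafast":
        dwell = _truncated_exponential(rng, config.tau_ultrafast_s, 0.0, config.mode_boundary_s)
    else:
        dwell = _truncated_exponential(
            rng, config.tau_fast_s, config.mode_boundary_s, config.censor_limit_s
        )
    frac, _ = config.retrieval_fraction_dist.sample(rng, 1, dwell_s=dwell)
    return n_quanta, float(amp), str(mode), dwell, float(frac[0])


def event_waveform(
    t: np.ndarray,
    onset_s: float,
    amplitude: float,
    dwell_s: float,
    retrieval_fraction: float,
    tau_reacidification_s: float,
    censored: bool,
) -> np.ndarray:
    """Noise-free fluorescence contribution of a single fusion event.

    Step to ``amplitude`` at onset, plateau for ``dwell_s``, then exponential
    decay toward ``(1 - retrieval_fraction) * amplitude``.  Censored events
    plateau to the end of the trace.
    """
    out = np.zeros_like(t)
    on = t >= onset_s - 1e-12
    if censored:
        out[on] = amplitude
        return out
    decay_start = onset_s + dwell_s
    plateau = on & (t < decay_start)
    decay = t >= decay_start
    out[plateau] = amplitude
    endpoint = (1.0 - retrieval_fraction) * amplitude
    out[decay] = endpoint + (amplitude - endpoint) * np.exp(
        -(t[decay] - decay_start) / tau_reacidification_s
    )
    return out


def generate_single_vesicle_trace(
    config: SimulationConfig,
    bouton_id: str = "bouton0",
    rng: np.random.Generator | None = None,
) -> tuple[FluorescenceTrace, list[GroundTruthEvent]]:
    """Simulate one bouton under sparse stimulation with full ground truth.

    Returns the noisy trace and one :class:`GroundTruthEvent` per stimulus.
    Events whose plateau would extend beyond the end of the trace are recorded
    as censored (ultraslow) rather than drawn with an unobservable decay.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_frames) / config.sampling_rate_hz
    clean = _baseline(config, t)
    truth: list[GroundTruthEvent] = []
    for idx, stim in enumerate(config.stimulus_times_s):
        fused = rng.uniform() < config.p_release
        if not fused:
            truth.append(GroundTruthEvent(bouton_id, idx, float(stim), fused=False))
            continue
        n_q, amp, mode, dwell, frac = _sample_event(config, rng)
        onset = t[np.searchsorted(t, stim - 1e-12)]
        censored = mode == "ultraslow"
        if not censored and onset + dwell >= config.duration_s:
            mode, dwell, censored = "ultraslow", np.nan, True
        clean += event_waveform(
            t, onset, amp, dwell, frac, config.tau_reacidification_s, censored
        )
        truth.append(
            GroundTruthEvent(
                bouton_id,
                idx,
                float(stim),
                fused=True,
                n_quanta=n_q,
                true_amplitude=amp,
                true_dwell_s=dwell,
                censored=censored,
                true_mode=mode,
                true_retrieval_fraction=np.nan if censored else frac,
            )
        )
    samples = clean + rng.normal(0.0, config.noise_sd, size=clean.size) if config.noise_sd > 0 else clean
    trace = FluorescenceTrace(
        samples=samples,
        sampling_rate_hz=config.sampling_rate_hz,
        bouton_id=bouton_id,
        condition=config.condition,
        metadata={"seed": config.seed, "simulated": True},
    )
    return trace, truth


def truth_to_frame(truth: Sequence[GroundTruthEvent]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(ev) for ev in truth])


def generate_experiment(config: SimulationConfig, n_boutons: int) -> ExperimentDataset:
    """Simulate ``n_boutons`` independent boutons under one configuration.

    Reproducible for a fixed ``config.seed``: each bouton receives an
    independent child stream spawned from the master seed sequence.
    """
    if n_boutons < 1:
        raise ValueError("n_boutons must be at least 1")
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(n_boutons)
    traces, rows = [], []
    for b, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        trace, truth = generate_single_vesicle_trace(config, f"bouton{b:04d}", rng=rng)
        traces.append(trace)
        rows.extend(truth)
    return ExperimentDataset(traces=traces, truth=truth_to_frame(rows), config=config)


def generate_negative_control(config: SimulationConfig, n_boutons: int = 1) -> ExperimentDataset:
    """Experiment with fusion disabled (TTX-like control): p_release forced to 0.

    Stimulus timestamps are retained so detection can be scored per stimulus.
    """
    quiet = dataclasses.replace(config, p_release=0.0)
    return generate_experiment(quiet, n_boutons)


def generate_train_trace(
    config: SimulationConfig,
    train_rate_hz: float = 40.0,
    train_duration_s: float = 5.0,
    endo_tau_s: float = 10.0,
    train_start_s: float = 10.0,
    rng: np.random.Generator | None = None,
) -> FluorescenceTrace:
    """Simulate the bulk response to a 40 Hz, 5 s action-potential train.

    Fluorescence rises linearly during the train (slope = AP rate x release
    probability x quantal amplitude, i.e. the mean rate of quantal addition)
    and decays mono-exponentially with ``endo_tau_s`` after the train ends.
    Bleach drift and Gaussian noise are added as configured.
    """
    config.validate()
    if endo_tau_s <= 0:
        raise ValueError("endo_tau_s must be positive")
    if train_start_s + train_duration_s >= config.duration_s:
        raise ValueError("train must end before the trace does")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_frames) / config.sampling_rate_hz
    slope = train_rate_hz * config.p_release * config.quantal_amplitude
    signal = np.zeros_like(t)
    during = (t >= train_start_s) & (t < train_start_s + train_duration_s)
    after = t >= train_start_s + train_duration_s
    signal[during] = slope * (t[during] - train_start_s)
    peak = slope * train_duration_s
    signal[after] = peak * np.exp(-(t[after] - train_start_s - train_duration_s) / endo_tau_s)
    samples = _baseline(config, t) + signal
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, size=samples.size)
    return FluorescenceTrace(
        samples=samples,
        sampling_rate_hz=config.sampling_rate_hz,
        bouton_id="train",
        condition=config.condition,
        metadata={
            "seed": config.seed,
            "simulated": True,
            "train_rate_hz": train_rate_hz,
            "train_start_s": train_start_s,
            "train_duration_s": train_duration_s,
            "true_rise_slope": slope,
            "true_endo_tau_s": endo_tau_s,
        },
    )


def generate_pool_trace(
    surface_fraction: float,
    total_fluorescence: float = 200.0,
    epoch_duration_s: float = 20.0,
    sampling_rate_hz: float = 10.0,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> tuple[FluorescenceTrace, pd.DataFrame]:
    """Simulate an acid-quench / NH4Cl pool assay on one bouton.

    Three consecutive epochs — rest (Tyrode's), acid quench (surface probe
    dark) and NH4Cl (all probe bright) — with the resting level set so that
    ``surface_fraction`` of the total probe sits on the plasma membrane.
    Returns the trace and an epoch-annotation table (label, start_s, end_s).
    """
    if not (0.0 <= surface_fraction <= 1.0):
        raise ValueError("surface_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rate = sampling_rate_hz
    n_epoch = int(round(epoch_duration_s * rate))
    f_nh4 = total_fluorescence
    f_acid = 20.0  # residual background during the quench
    f_rest = f_acid + surface_fraction * (f_nh4 - f_acid)
    levels = np.repeat([f_rest, f_acid, f_nh4], n_epoch)
    samples = levels + rng.normal(0.0, noise_sd, size=levels.size)
    epochs = pd.DataFrame(
        {
            "label": ["rest", "acid", "nh4"],
            "start_s": [0.0, epoch_duration_s, 2 * epoch_duration_s],
            "end_s": [epoch_duration_s, 2 * epoch_duration_s, 3 * epoch_duration_s],
        }
    )
    trace = FluorescenceTrace(
        samples=samples, sampling_rate_hz=rate, bouton_id="pool", metadata={"seed": seed}
    )
    return trace, epochs
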