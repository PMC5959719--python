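# Methods

This note documents the models, estimators and numerical choices behind
`svtrace`, and what the synthetic-data generator does and does not emulate.

## Signal model

A bouton's fluorescence trace is modelled as

```
F(t) = B + A_b · exp(−t/τ_b)  +  Σ_events  s_i(t)  +  ε(t),   ε ~ N(0, σ²) i.i.d.
```

with background level `B`, additive photobleaching amplitude `A_b` and time
constant `τ_b`, and per-event waveforms `s_i`. Each stimulus independently
triggers fusion with probability `p`. A fused event steps within one frame to
a quantal amplitude `a ~ n_q · N(q, (q·cv)²)` (`n_q = 2` with the
multivesicular probability, 10% by default), holds a plateau for the dwell
time `d`, then decays as `a·[(1−f) + f·exp(−(t−t_d)/τ_reacid)]` toward an
endpoint set by the fraction of retrieval `f`. Censored (ultraslow) events
never decay within the observation window.

Defaults define the 2 mM Ca²⁺ / 24 °C-like condition: 10 Hz sampling,
20 single APs at 0.05 Hz, `p = 0.15`, `q = 5` a.u., `cv = 0.15`, `σ = 1`
(quantal signal-to-noise 5 — the acquisition settings the analysis was
designed for; not derivable from first principles, so exposed in
`SimulationConfig`), `B = 100`, `A_b = 20`, `τ_b = 100 s`, `τ_reacid = 4 s`
(chosen to be much slower than ultrafast dwells yet clearly visible at
10 Hz).

### Dwell-time mixture and mode labels

Retrieval modes are defined by dwell bands: ultrafast 0–1 s, fast 1–20 s,
ultraslow > 20 s (censored). The generator draws the mode from the
configured weights (default 20/40/40%) and then draws the dwell from an
exponential **truncated to the mode's band**: `Exp(τ_uf = 0.2 s)` on (0, 1],
`Exp(τ_fast = 8 s)` on (1, 20]. This makes the generative label and the
dwell-band classification coincide exactly, so parameter-recovery tests have
unambiguous truth; the truncation removes <1% of the ultrafast mass and ~8%
of an untruncated fast component. Events whose plateau would outlast the
trace are recorded as censored.

### Retrieval fractions

Fractions of retrieval fall into partial (<0.8), quantal (1.0 ± 0.2) and
excess (>1.2) classes. Retrieval efficiency depends on retrieval speed —
ultrafast events are almost always quantal and the dispersion of `f` grows
with dwell time — so the class probabilities are interpolated in log-dwell
between anchors at 0.5 s (12/82/6%) and 20 s (72/0/28%), and the quantal
spread widens from 0.06 to 0.16. The anchors are set so the marginal class
mix over the default composition is ≈35/50/15%. `dwell_dependent=False`
restores an unconditional mixture.

## De-noising

The Chung–Kennedy filter holds, per window length `w ∈ {2,4,8,16}` samples,
a forward predictor (mean of the preceding `w` samples) and a backward
predictor (mean of the following `w`). Each predictor's error is the sum of
its own side's `M = 8` most recent squared residuals; weights are
`prior · (error + ε)^(−p)` with `p = 2`, `ε = 10⁻¹²`, normalised over the
bank, and the output is the weighted sum of predictions. Boundary samples
use truncated windows (no reflection padding — segment edges are
stimulus-aligned and must not be mirrored); predictors with empty windows
get zero weight. The `ε` regulariser only matters when prediction errors
vanish (noise-free data) and cancels in the affine-equivariance property to
well below 10⁻⁹ relative.

Properties (all asserted by the suite): identity on constants; affine
equivariance; noise SD reduced below 0.5σ (≈0.27σ at the defaults);
sustained noisy step amplitudes preserved within 5%. Two residual artifacts
matter downstream and are compensated explicitly:

- the filter *leaks the upcoming step* into the last ~2 pre-stimulus frames
  (backward predictors see the event), so baseline statistics stop 2 frames
  short of the stimulus and the baseline level/SD for thresholding are taken
  from the raw (bleach-corrected) trace;
- plateaus shorter than ~1 s are *bowed down* by up to ~2% of the amplitude
  near their edges; the decay-onset search adds an amplitude-relative
  tolerance floor (3%) for filtered traces only.

Very short plateaus (≤0.25 s ≈ the comparison window) in noise are partly
attenuated by the filter — an inherent resolution limit at quantal
signal-to-noise 5 that shows up as a small loss of low-amplitude ultrafast
events, quantified in the composition-recovery test. The `fft_lowpass`
comparator (hard zeroing of bins above 2 Hz) attenuates the plateau level of
≤0.25 s events by >20% even without noise, which is why the nonlinear filter
is used for quantal analysis.

## Preprocessing

Photobleaching is corrected additively: `a·exp(−t/τ_b) + c` (`a ≥ 0`;
bleaching cannot brighten) is fitted to event-free samples and the trend
minus its final value subtracted, preserving the amplitude scale used by the
quantal threshold. The default event-free mask excludes [−0.5 s, +20 s]
around each stimulus and shrinks adaptively when stimuli are dense. Because
residual event contamination is strictly upward, the fit uses a soft-L1 loss
with iterative asymmetric trimming (drop residuals > 2 robust SDs above the
fit); an optional nonnegative linear term absorbs slow upward drift.

Events that never fully decay (ultraslow, partial retrieval) leave permanent
upward *steps* at stimulus times; no smooth trend fits such a staircase
without creating spurious local drift. The pipeline therefore (1) estimates
an experiment-level `τ_b` as the median of per-bouton fits — all boutons in
a field of view share the illumination — and (2) refits each bouton with
`τ_b` fixed under the model `a·exp(−t/τ_b) + Σ_j s_j·H(t−t_j) + c` with
nonnegative step coefficients `s_j` at the known stimulus times, solved by
NNLS with the same trimming. Only the exponential part is subtracted; the
steps are signal.

## Detection and dwell measurement

A success requires the de-noised trace to exceed
`baseline_level + 3·SD + 10⁻³·|level|` within 3 frames of the stimulus
(the absolute floor suppresses numerical drift on effectively noise-free
data) *and* to rise relative to the pre-stimulus level (a decaying baseline
whose convexity beats the linear baseline extrapolation is not an event).
Baseline level and SD come from a linear fit over the 2 s window before the
stimulus — detrending absorbs the decay tail of a preceding event — and the
SD is shrunk 70% toward the trace-level median (camera noise is stationary;
the local estimate guards residual nonstationarity). The threshold SD is
measured on the raw corrected trace by default (`baseline_sd_source`
switchable): at 3 raw SDs the threshold sits at ~0.6 quanta, whereas 3
de-noised SDs (~0.8 a.u.) would admit a few percent of sub-quantal
filter-noise excursions per stimulus. At most one event is called per
stimulus; candidates above the quantal upper limit are logged as
multivesicular and excluded from dwell analysis but counted as successes for
release probability (failure analysis counts fusions, whatever their size).

The quantal upper limit comes from the amplitude distribution: the dominant
density peak is the single-quantum mode `q̄₁`, the next peak above it the
two-quantum mode `q̄₂`, and the limit is `q̄₁ + ½(q̄₂ − q̄₁)`; peak means are
refined by a local two-component Gaussian mixture. Peak-finding (rather than
a global mixture fit) is robust to a sub-quantal false-positive tail.

Dwell time runs from peak attainment (climbing while the trace rises beyond
half a baseline SD per frame) to the decay onset — the first persistent
switch of the first derivative to negative values. A literal sign test has
no noise immunity (a 20 s plateau of filtered noise almost surely contains
2 consecutive negative derivatives), so the onset is located in two steps,
calibrated on simulated traces: (1) *departure*: the first run of
`decay_onset_persistence_frames = 2` frames below
`peak − max(3·SD_dn, 0.25·amplitude)`, i.e. the decay has demonstrably left
the plateau (searched up to 10 s beyond the censor window so decays that
straddle the 20 s limit are still confirmed); (2) walk back to the last
frame whose trailing 0.5 s mean is still at plateau level (within
1 SD_dn, with the 3% bow floor for filtered traces). On noise-free input the
rule reduces to the derivative definition and is exact to one frame at 10
and 40 Hz. Events without a decay onset inside 20 s are censored
(ultraslow); a window truncated by the trace edge is flagged. With noise,
the dominant residual error is occasional late onsets when a filtered-noise
excursion re-touches the plateau during the slow re-acidification decay,
moving ~1/4 of true ultrafast events just past the 1 s boundary; the
composition bias stays within ±3 percentage points at the default
conditions.

The fraction of retrieval is `(peak − endpoint)/amplitude` with the endpoint
averaged over the final second before the next stimulus (or trace end);
classes partial/quantal/excess at 0.8 and 1.2. With 0.05 Hz stimulation the
inter-stimulus interval equals the censor limit; `censor_at_next_stimulus`
switches the censor window to the next stimulus when they differ.

## Kinetics

Dwell histograms use 0.1 s bins below 1 s and 1 s bins above (resolving the
ultrafast peak at both acquisition rates), density-normalised; censored
events are excluded and counted, never modelled as an offset. Least-squares
fits (`A·e^{−t/τ}` or the two-component sum, no offset) are initialised from
an EM maximum-likelihood exponential-mixture fit on the raw dwells, which is
also reported as an internal cross-check; the two routes agree within 10% at
n = 5000. Model choice uses the extra-sum-of-squares F test on the shared
histogram plus reduced-R² comparison; τ-collapse or a vanishing amplitude
flags a degenerate double fit. Averaged event traces (raw, onset-aligned,
per-event baseline subtracted) are fitted post-peak by a two-phase
exponential **with** a constant offset — censored events put a floor under
the average. Train responses: amplitude = peak ΔF over the pre-train
baseline, rise slope by linear regression during the train, decay τ by a
single-exponential fit (free offset) of the post-train return.

## Statistics

Two groups: two-sample Kolmogorov–Smirnov. Three or more: Kruskal–Wallis,
then Dunn's rank post-test
`z = (R̄_i − R̄_j)/√((N(N+1)/12 − T)(1/n_i + 1/n_j))` with tie correction
`T = Σ(t³−t)/(12(N−1))` and Bonferroni family adjustment (the adjustment
method is this package's choice). Both tests hold their nominal 5% type-I
error within [0.03, 0.07] over 2000 null simulations.

## Pools

Surface = `F_rest − F_acid`, internal = `F_NH4 − F_rest`, fractions
normalised by their sum; the first 2 s after each solution switch are
excluded (perfusion mixing). Differencing makes the fractions invariant to
affine rescaling of the arbitrary units; negative pools are flagged and
fractions withheld.

## What the generator does not emulate

Single-frame rise (no finite fusion-pore kinetics), i.i.d. Gaussian noise
(no photon shot-noise scaling, no correlated camera artifacts), additive
bleaching of the baseline only (no differential bleaching of the event
fluorophores), no spontaneous (non-stimulus-locked) fusion, no movie-level
effects (drift, focus, ROI segmentation), and ultraslow retrieval modelled
as no decay for the whole trace rather than a slow tail. Passing tests
therefore validate the estimators against this statistical structure, not
against imaging artifacts outside it.

## Problem sizes

The verification suite uses 250–500 boutons × 20 stimuli for
detection-level checks (≥2000 events for composition recovery), 5000 dwell
samples for kinetic parameter recovery, and 2000 null replicates for test
calibration — sizes at which the binomial/multinomial confidence intervals
asserted by the tests are decisively narrower than the tolerances they
check.
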