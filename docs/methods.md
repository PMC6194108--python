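# Methods

This note documents the models, detection criteria, generator design, and
numerical choices behind `astrobarrage`, and states what the closed-loop
tests do and do not establish.

## The experiment being emulated

An NPY interneuron is driven with 1-s current steps at the start of 3-s
sweeps (~40 evoked spikes per step, up to 40 sweeps), while a nearby
astrocyte's membrane potential — and in imaging experiments, astrocytic
GCaMP fluorescence at 7 Hz — is recorded. After roughly six hundred evoked
spikes the interneuron abruptly begins *barrage firing*: sustained firing
above 4 Hz that starts after a step ends and persists for tens of seconds.
The astrocyte depolarizes abruptly tens of seconds before barrage onset,
and astrocytic calcium rises seconds before onset and outlasts the barrage.
Recordings start 30 s (voltage) or 120 s (calcium) before the first step so
that baseline statistics are available; stimulation stops at the end of the
step in which induction occurs.

## Latent integrator model

The hidden variable is

v(t) = c · [(1 − ρ) Σ_{t_i ≤ t} e^{−(t − t_i)/τ} + ρ · N(t)],

with per-spike increment c (default 1, arbitrary units), decay constant
τ = 7.7 s, slow fraction ρ, and N(t) the number of spikes delivered by t.
Evaluation is event-driven: the leaky sum obeys the recursion
S_i = S_{i−1} e^{−Δt/τ} + 1, so values are closed-form exact at spike times
and on the sampling grid between them; no ODE integration error exists
anywhere. Threshold crossings are evaluated at spike times (the variable
only increases at spikes) and ties count as crossings. τ = ∞ is supported
and reduces the model, with ρ = 0, to a pure spike counter.

**Why ρ exists and why it is 0.7.** A pure single-τ integrator driven by a
periodic protocol saturates: end-of-step peaks converge geometrically (with
ratio e^{−period/τ} ≈ 0.68) to an asymptote after ~4 sweeps (~160 spikes),
so no threshold can distinguish spike 200 from spike 600. Routing a
fraction ρ of each increment into a non-decaying accumulator makes the late
envelope grow by ρ·c·40 per sweep. The size of ρ matters: under
Poisson-jittered per-step counts, the leaky component fluctuates between
trials with SD ≈ 8·(1 − ρ) increment-units, while the slow component grows
ρ·40 per sweep. If the fluctuation dominates the growth (any ρ ≲ 0.2), the
first passage over a calibrated threshold happens hundreds of spikes early
and varies wildly. ρ = 0.7 puts the per-sweep growth (28 units) an order of
magnitude above the fluctuation SD (≈ 2.4 units); calibrated trials then
cross at 598.5 ± 4.0 spikes against a 604-spike target (measured over 200
jittered trials during design). The rest-period decay remains clearly
visible (30% of the increment mass is leaky). ρ = 0 stays available for
studying the pure leaky integrator.

**Calibration and its shadow zones.** `calibrate` simulates the nominal
(unjittered, evenly spaced) protocol and sets the threshold to the latent
value at the target spike. Because the trajectory dips during each rest,
spikes early in a step sit below the previous end-of-step peak; a threshold
placed at such a spike is first crossed a few spikes before the end of the
*previous* step. Exact crossing-at-target self-consistency therefore holds
only when the target spike is a running maximum of the nominal trajectory
(always true for the counter limit, and for targets late in a step); for
targets in a shadow zone the crossing lands within the preceding step,
never more than one sweep away.

**Decay-constant fitting.** `fit_decay_constant` removes the non-decaying
accumulator (constant during spike-free rests, and carried explicitly by
the trajectory) and pools a log-linear least-squares fit across rest
segments: one shared slope −1/τ, per-segment intercepts. Segments with
non-positive values are skipped; a non-decaying pooled slope is an error,
not a huge τ.

## Synthetic-data generator

The generator's defaults are the study's population values and are not
tuning knobs:

| quantity | mean ± SD | role |
| --- | --- | --- |
| evoked spikes per 1-s step | Poisson(40) | stimulation strength |
| spikes to induction | 604 ± 72 | when barrage starts |
| barrage duration | 33.2 ± 13.2 s | barrage length |
| astro depolarization peak | 10.3 ± 1.8 mV | event amplitude |
| 20–80% rise time | 1.3 ± 0.2 s | event abruptness |
| depolarization lead | 29.5 ± 5.8 s | A→B interval (Vm) |
| calcium lead | 10.75 ± 2.3 s | A→B interval (Ca) |
| peak ΔF/F | 1.7 ± 0.2 | calcium amplitude |
| astro event probability | 0.80 | paired-recording hit rate |
| astro outlasts barrage | 4/14 | mixture of decay modes |

Non-negative quantities are sampled as normal draws clipped at zero
("truncation, not resampling", so one draw is consumed per quantity and
runs are reproducible draw-for-draw). The sampled spikes-to-induction
target is realized at a completed step: induction is assigned to the step
whose cumulative evoked count is closest to the target, so realized counts
center on the population mean rather than overshooting by half a step.
Stimulation stops at that step's end, which is the true barrage onset; the
barrage itself is a homogeneous spike train at 20 Hz for a sampled
duration. 20 Hz (not a value closer to the 4-Hz criterion) is required for
the detector to be unbiased: at 10 Hz, 1-s windows with ≤ 4 spikes occur
often enough inside a genuine barrage that the contiguous-window rule
truncates the detected duration by tens of percent; at 20 Hz the
probability of such a dip is negligible and the detected duration is
unbiased to within +0.7 s of window-quantization.

Spikes are placed uniformly within their step (or barrage span) subject to
a 3-ms minimum inter-spike interval — an absolute refractory period —
implemented by count-exact hard-core sampling (sorted uniforms in the
gap-reduced interval, shifted apart). Without it, ~2-ms coincidences merge
under threshold-based spike detection and the recovered spike counts
undershoot ground truth by ~7%.

The astrocyte depolarization is a logistic rise cut on at 1% of peak (so
the event onset is an exact, well-defined time) with scale s = r/(2 ln 4),
making its 20–80% rise time exactly the sampled r; it is followed by an
exponential return, starting either before barrage onset (probability
10/14) or at barrage end (4/14, the outlasting mode). The calcium event
rises linearly from its onset to barrage onset, holds a plateau through the
barrage, and decays exponentially (τ = 10 s) afterwards — so calcium always
outlasts the barrage. Voltage noise is white Gaussian (SD 0.3 mV, a typical
whole-cell baseline); ΔF/F noise SD is 0.02 per ROI on the averaged-indicator
scale. The weak condition halves the evoked rate and produces no barrage and
no astrocyte or calcium events. Pharmacological/optogenetic manipulations
enter as named multiplicative `condition_modifiers` on the
spikes-to-induction mean (< 1 facilitation, > 1 inhibition, ∞ block); the
magnitudes are configuration, not claims.

Calcium image scenes paint 4 somata (40–60 μm²), 22 process blobs
(6–12 μm²), and 3 sub-threshold microdomains (3 μm²) into a 160 × 160 px
field at 1 μm/px, 7 Hz, with per-blob baseline intensity 1000 over a
background of 100 and Gaussian read noise (SD 20). Blob areas are realized
exactly (pixel count = area/pixel_size², nearest-to-center pixels painted),
so area filters can be tested against pixel-set equality.

**What the generator does not emulate:** biophysical membrane dynamics
(spikes are stereotyped waveforms), synaptic or network structure,
photon-shot/two-photon noise, bleaching, motion, spatially propagating
calcium waves, or any correlation between event amplitude and barrage
duration (they are sampled independently, emulating the reported
non-correlation). Passing recovery tests therefore demonstrates that the
detectors are unbiased and correctly calibrated under these statistical
conditions — not that they are robust to artifacts real recordings contain.

## Detection criteria and numerical choices

- **Barrage**: rate strictly > 4 Hz (a window of exactly 4.0 Hz never
  qualifies) in 1-s windows at 0.1-s stride, scanned only over post-step
  regions (rests and the post-protocol span), so evoked spikes cannot
  qualify; onset = start of the first window of the first qualifying run
  spanning ≥ 1 s; end = end of the last contiguous qualifying window.
  Window boundaries are closed; counts use binary search on the sorted
  spike times, so the detector is exactly invariant to the voltage
  sampling rate.
- **Onset**: baseline mean + 3 SD sustained ≥ 0.5 s. With a zero-variance
  baseline the rule degenerates gracefully: any sustained deviation is
  detected at its first sample. The ROC procedure establishes *whether* a
  change occurred; this explicit rule supplies the *when* needed for lead
  times. Onset detection on a finite-slope rise is systematically late by
  the time to climb 3 SD above baseline (≈ 0.3 s for calcium at the default
  slope, ≈ 1 s for the sigmoid depolarization) — a detection-side bias an
  order of magnitude smaller than the population SDs being recovered.
- **Event characterization**: peak amplitude and rise time are measured on
  a 50-ms moving-average copy of the trace; the raw maximum of ~10⁵ noisy
  samples would otherwise overestimate the peak by ~4 noise SDs (~1.2 mV).
  Level crossings (20%/80%) are linearly interpolated; the first upward
  crossings are used on non-monotone segments.
- **Spikes-to-induction** counts spikes inside step windows strictly before
  barrage onset; inter-step spikes are spontaneous, not evoked, and are
  excluded. Cells needing ≥ 2000 evoked spikes are QC-flagged, never
  silently dropped.
- **Detection probability**: the scalar sample value is the feature; the
  logistic link is monotone, so the ROC area equals the Mann–Whitney rank
  AUC (ties 0.5/pair; trapezoidal integration) — an identity the tests use
  as an independent oracle. The feature is standardized before fitting
  (affine, so the ROC is unchanged) and the ROC is oriented by the sign of
  the fitted slope, with sweep-above-baseline positive: a fitted
  classifier would otherwise fold every AUC to ≥ 0.5, biasing chance-level
  sweeps upward and breaking the label-swap complement. Fewer than two
  distinct pooled values pin the AUC at 0.5 with a flag. The per-recording
  summary defaults to the *mean* over pre-barrage sweeps; max and
  per-sweep-only are selectable, because the per-recording aggregation was
  not uniquely determined by the source analyses.
- **Segmentation**: deterministic replacement for a semi-manual workflow —
  intensity threshold (configuration; no principled default exists, the
  synthetic scenes use 500 between background ~100 and blobs ~1000) on a
  temporal-max projection, 8-connected components, soma pass before process
  pass with somata masked (so no process ROI overlaps a soma). Components
  in the ambiguous [4, 5] μm² band — between the "< 4 μm² excluded" and
  "> 5 μm² wave" filters — are retained as `unclassified` but excluded from
  default outputs, with a switch. The wave criterion is approximated by the
  component exceeding 5 μm² in the projection; spatiotemporal wave tracking
  is out of scope.

## Statistical reporting

`run_experiment` produces per-recording event tables and per-condition
mean ± SEM (SEM = SD/√n, n always reported) for spikes-to-induction,
duration, leads, rise, peak, and detection probability; reports conserve
recordings (n_input = n_analyzed + n_flagged) and reruns with the same
config and seed are byte-identical. `paired_comparison` is the two-tailed
paired t test (t = d̄/(s_d/√n)); zero-variance differences return the null
result (identical vectors) or a flagged degenerate result (constant shift)
instead of raising. `correlation_r2` is the squared Pearson correlation,
`None` for constant input. Heavier inferential machinery (repeated-measures
ANOVA and beyond) is deliberately outside the package surface; scipy and
statsmodels cover it directly.

## Problem sizes and reproducibility

Cohort-level tests and the acceptance script run recordings at 1 kHz
(resolving the 3-ms inter-spike interval and sub-second onset criteria) and
cohorts at the study's n (14 paired, 12 calcium, 18 duration, 12 scenes,
150 integrator trials); property tests use smaller deterministic fixtures.
All randomness flows through `numpy.random.SeedSequence` children of a
single seed; identical seeds give bit-identical traces, tables, and
reports.

## Known limitations

- Lead-time estimates inherit a small negative bias (~0.3–1.3 s) from
  threshold-crossing onset detection on finite-slope rises; it is visible
  in recovery comparisons but far inside 3 SEM at the study's cohort sizes.
- The detected barrage end is quantized upward by up to one window (~+0.7 s
  mean on the duration).
- The ρ device is a modeling commitment, not an observation: the source
  experiments constrain τ and the induction count, but not how the late
  envelope grows; any mechanism giving near-linear late growth would fit
  equally well.
- The latent variable integrates a single neuron's spikes; multi-neuron
  convergence onto one astrocyte network is not modeled.
- The generator's weak-condition evoked rate (half of strong) is a
  placeholder; the source material does not quantify it.
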