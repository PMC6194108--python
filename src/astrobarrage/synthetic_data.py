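"""Synthetic paired interneuron–astrocyte recordings with ground truth.

The generator emulates the paired-recording experiment in which barrage
firing is induced in an NPY interneuron by repeated 1-s current steps
(~40 evoked spikes per step, 2-s rests) while a nearby astrocyte's membrane
potential — and, optionally, astrocytic calcium (ΔF/F traces and image
stacks) — is monitored.  Under the strong condition, barrage firing begins
after a sampled number of evoked spikes (604 ± 72), lasts 33.2 ± 13.2 s, and
is preceded by an abrupt astrocyte depolarization (peak 10.3 ± 1.8 mV,
20–80% rise time 1.3 ± 0.2 s, lead 29.5 ± 5.8 s) and by a calcium increase
(lead 10.75 ± 2.3 s, peak ΔF/F 1.7 ± 0.2) that outlasts the barrage.  The
weak condition evokes fewer spikes and produces no barrage and no astrocyte
events.  Every sampled quantity is recorded as ground truth so downstream
detection can be validated by closed-loop parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "StimulationProtocol",
    "GeneratorSpec",
    "GroundTruth",
    "RecordingBundle",
    "BlobSpec",
    "SceneSpec",
    "CalciumScene",
    "make_protocol",
    "generate_recording",
    "generate_calcium_stack",
    "make_default_scene",
    "save_bundle",
    "load_trace_csv",
]

# Ratio between a logistic sigmoid's 20–80% rise time and its scale s:
# t(0.8) - t(0.2) = 2 s ln 4.
_LOGISTIC_2080 = 2.0 * math.log(4.0)
# The depolarization waveform is cut on at the 1%-of-peak point of the
# sigmoid, which defines the event's onset time exactly.
_ONSET_LEVEL = 0.01


@dataclass(frozen=True)
class StimulationProtocol:
    """Stepped current-injection schedule: 1-s steps at the start of 3-s sweeps."""

    step_duration: float = 1.0
    rest_duration: float = 2.0
    n_sweeps: int = 40
    target_spikes_per_step: int = 40
    sampling_rate: float = 10_000.0
    t0: float = 30.0

    def __post_init__(self) -> None:
        if not self.step_duration > 0:
            raise ValueError("step_duration must be > 0")
        if self.rest_duration < 0:
            raise ValueError("rest_duration must be >= 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.target_spikes_per_step < 1:
            raise ValueError("target_spikes_per_step must be >= 1")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    @property
    def period(self) -> float:
        return self.step_duration + self.rest_duration

    @property
    def end(self) -> float:
        """End of the last sweep (recording-relative seconds)."""
        return self.t0 + self.n_sweeps * self.period

    def sweep_start(self, k: int) -> float:
        return self.t0 + k * self.period

    def step_windows(self) -> np.ndarray:
        """(n_sweeps, 2) array of [step_start, step_end) windows."""
        starts = self.t0 + np.arange(self.n_sweeps) * self.period
        return np.column_stack([starts, starts + self.step_duration])

    def rest_windows(self) -> np.ndarray:
        """(n_sweeps, 2) array of [step_end, sweep_end) windows."""
        starts = self.t0 + np.arange(self.n_sweeps) * self.period
        return np.column_stack(
            [starts + self.step_duration, starts + self.period]
        )


def make_protocol(
    n_sweeps: int = 40,
    step_duration: float = 1.0,
    rest_duration: float = 2.0,
    target_spikes_per_step: int = 40,
    sampling_rate: float = 10_000.0,
    t0: float = 30.0,
) -> StimulationProtocol:
    """Build a stimulation protocol; sweeps tile [t0, t0 + n_sweeps * period)."""
    return StimulationProtocol(
        step_duration=step_duration,
        rest_duration=rest_duration,
        n_sweeps=n_sweeps,
        target_spikes_per_step=target_spikes_per_step,
        sampling_rate=sampling_rate,
        t0=t0,
    )


@dataclass(frozen=True)
class GeneratorSpec:
    """Generator condition and population parameters (means ± SD).

    Defaults are the study conditions: spikes-to-induction 604 ± 72, barrage
    duration 33.2 ± 13.2 s, depolarization peak 10.3 ± 1.8 mV with 20–80%
    rise 1.3 ± 0.2 s and lead 29.5 ± 5.8 s before barrage onset, calcium lead
    10.75 ± 2.3 s with peak ΔF/F 1.7 ± 0.2, and an 80% probability that the
    recorded astrocyte shows a depolarization event.  ``condition_modifiers``
    are named multiplicative factors applied to the spikes-to-induction mean
    (values < 1 emulate facilitation, > 1 inhibition, ``inf`` full block).
    """

    condition: str = "strong"
    astro_event_probability: float = 0.80
    astro_peak_mean: float = 10.3
    astro_peak_sd: float = 1.8
    rise_time_mean: float = 1.3
    rise_time_sd: float = 0.2
    depol_lead_mean: float = 29.5
    depol_lead_sd: float = 5.8
    calcium_lead_mean: float = 10.75
    calcium_lead_sd: float = 2.3
    barrage_duration_mean: float = 33.2
    barrage_duration_sd: float = 13.2
    spikes_to_induction_mean: float = 604.0
    spikes_to_induction_sd: float = 72.0
    dff_peak_mean: float = 1.7
    dff_peak_sd: float = 0.2
    barrage_rate_hz: float = 20.0
    weak_rate_factor: float = 0.5
    vm_noise_sd: float = 0.3
    dff_noise_sd: float = 0.02
    astro_resting_mv: float = -80.0
    neuron_resting_mv: float = -65.0
    astro_outlast_probability: float = 4.0 / 14.0
    astro_decay_tau: float = 5.0
    astro_plateau_s: float = 2.0
    astro_return_tau: float = 15.0
    calcium_decay_tau: float = 10.0
    include_calcium: bool = False
    n_calcium_rois: int = 4
    calcium_sampling_rate: float = 7.0
    tail_s: float = 30.0
    seed: int | None = None
    condition_modifiers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in ("strong", "weak"):
            raise ValueError(f"condition must be 'strong' or 'weak', got {self.condition!r}")
        if not 0.0 <= self.astro_event_probability <= 1.0:
            raise ValueError("astro_event_probability must be in [0, 1]")
        for name in (
            "astro_peak_sd", "rise_time_sd", "depol_lead_sd", "calcium_lead_sd",
            "barrage_duration_sd", "spikes_to_induction_sd", "dff_peak_sd",
            "vm_noise_sd", "dff_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.astro_outlast_probability <= 1.0:
            raise ValueError("astro_outlast_probability must be in [0, 1]")

    @property
    def effective_induction_mean(self) -> float:
        m = self.spikes_to_induction_mean
        for factor in self.condition_modifiers.values():
            m *= factor
        return m


@dataclass
class GroundTruth:
    """Sampled event parameters of one synthetic recording."""

    condition: str
    target_spikes_to_induction: float | None = None
    realized_spikes_to_induction: int | None = None
    barrage_onset: float | None = None
    barrage_end: float | None = None
    barrage_duration: float | None = None
    n_barrage_spikes: int | None = None
    astro_onset: float | None = None
    astro_peak_mv: float | None = None
    astro_rise_time: float | None = None
    astro_outlasts_barrage: bool | None = None
    calcium_onset: float | None = None
    calcium_end: float | None = None
    calcium_lead: float | None = None
    calcium_peaks: list[float] | None = None

    @property
    def depol_lead(self) -> float | None:
        if self.astro_onset is None or self.barrage_onset is None:
            return None
        return self.barrage_onset - self.astro_onset


@dataclass
class RecordingBundle:
    """One synthetic (or imported) paired recording.

    All series share the recording time origin t = 0; the first current step
    starts at ``protocol.t0``.  ``truth`` is present iff the bundle is
    synthetic.
    """

    protocol: StimulationProtocol
    neuron_trace: np.ndarray
    neuron_spikes: np.ndarray
    astro_trace: np.ndarray
    calcium_traces: np.ndarray | None = None
    calcium_sampling_rate: float | None = None
    calcium_stack: np.ndarray | None = None
    truth: GroundTruth | None = None

    @property
    def sampling_rate(self) -> float:
        return self.protocol.sampling_rate

    @property
    def duration(self) -> float:
        return self.neuron_trace.size / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.neuron_trace.size) / self.sampling_rate

    def calcium_times(self) -> np.ndarray:
        if self.calcium_traces is None:
            raise ValueError("bundle has no calcium traces")
        return np.arange(self.calcium_traces.shape[1]) / self.calcium_sampling_rate

    def calcium_average(self) -> np.ndarray:
        """Unweighted mean ΔF/F across ROIs."""
        if self.calcium_traces is None:
            raise ValueError("bundle has no calcium traces")
        return self.calcium_traces.mean(axis=0)


#: Absolute refractory period enforced between generated spikes, seconds.
_MIN_ISI = 0.003


def _constrained_uniform(
    rng: np.random.Generator, a: float, b: float, n: int, min_gap: float = _MIN_ISI
) -> np.ndarray:
    """n points uniform in [a, b] subject to a minimum spacing (count-exact).

    Sorted uniforms are drawn in the gap-reduced interval and shifted apart,
    emulating an absolute refractory period without changing the count.
    """
    if n <= 0:
        return np.empty(0)
    span = (b - a) - (n - 1) * min_gap
    if span <= 0:
        n = max(1, int((b - a) / min_gap))
        span = (b - a) - (n - 1) * min_gap
    u = np.sort(rng.uniform(0.0, span, n))
    return a + u + min_gap * np.arange(n)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, upper: float | None = None) -> float:
    """One normal draw truncated (clipped) at zero, optionally at an upper bound."""
    x = max(0.0, float(rng.normal(mean, sd)))
    if upper is not None:
        x = min(x, upper)
    return x


def _spike_template(fs: float) -> np.ndarray:
    """Brief triangular action-potential waveform (2 ms base, unit peak)."""
    half = max(1, int(round(0.001 * fs)))
    up = np.linspace(0.0, 1.0, half + 1)
    down = np.linspace(1.0, 0.0, half + 1)[1:]
    return np.concatenate([up, down])


def _insert_spikes(trace: np.ndarray, spikes: np.ndarray, fs: float, amplitude: float) -> None:
    template = _spike_template(fs) * amplitude
    n = trace.size
    for t in spikes:
        i0 = int(round(t * fs)) - (template.size // 2)
        a = max(i0, 0)
        b = min(i0 + template.size, n)
        if a < b:
            trace[a:b] += template[a - i0 : b - i0]


def _depolarization_waveform(
    t: np.ndarray,
    onset: float,
    peak: float,
    rise_2080: float,
    decay_start: float,
    decay_tau: float,
) -> np.ndarray:
    """Logistic rise (cut on at 1% of peak, so its onset is exact) followed by
    an exponential return toward baseline."""
    s = rise_2080 / _LOGISTIC_2080
    t_mid = onset + s * math.log((1.0 - _ONSET_LEVEL) / _ONSET_LEVEL)
    v = np.zeros_like(t)
    rising = (t >= onset) & (t <= decay_start)
    v[rising] = peak / (1.0 + np.exp(-(t[rising] - t_mid) / s))
    v_at_decay = peak / (1.0 + math.exp(-(decay_start - t_mid) / s))
    after = t > decay_start
    v[after] = v_at_decay * np.exp(-(t[after] - decay_start) / decay_tau)
    return v


def _calcium_shape(
    t: np.ndarray, onset: float, rise_end: float, plateau_end: float, decay_tau: float
) -> np.ndarray:
    """Linear rise from onset to rise_end, plateau at 1, exponential decay."""
    c = np.zeros_like(t)
    rising = (t >= onset) & (t < rise_end)
    if rise_end > onset:
        c[rising] = (t[rising] - onset) / (rise_end - onset)
    c[(t >= rise_end) & (t <= plateau_end)] = 1.0
    after = t > plateau_end
    c[after] = np.exp(-(t[after] - plateau_end) / decay_tau)
    return c


def generate_recording(
    spec: GeneratorSpec,
    protocol: StimulationProtocol | None = None,
    seed: int | None = None,
) -> RecordingBundle:
    """Generate one paired recording under the given condition.

    Strong condition: per-step evoked spike counts are Poisson around the
    protocol target with uniform placement within the step; the step during
    which the cumulative evoked count reaches the sampled spikes-to-induction
    target is the last one delivered (mirroring the experiment, where
    stimulation stops once barrage firing appears), and the barrage — a
    homogeneous Poisson train — starts at that step's end.  The astrocyte
    depolarization (probability ``astro_event_probability``) and the calcium
    increase are placed with sampled leads before barrage onset.  If the
    sampled induction target exceeds the evoked spikes available, the trial
    is marked "no barrage" rather than raising.
    """
    if protocol is None:
        t0 = 120.0 if spec.include_calcium else 30.0
        protocol = make_protocol(t0=t0)
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    fs = protocol.sampling_rate
    truth = GroundTruth(condition=spec.condition)

    # --- evoked spike trains -------------------------------------------------
    target = protocol.target_spikes_per_step
    if spec.condition == "weak":
        rate = max(1.0, target * spec.weak_rate_factor)
        counts = rng.poisson(rate, protocol.n_sweeps)
        delivered = protocol.n_sweeps
        induction_step = None
    else:
        counts = rng.poisson(target, protocol.n_sweeps)
        truth.target_spikes_to_induction = _truncnorm(
            rng, spec.effective_induction_mean, spec.spikes_to_induction_sd
        ) if math.isfinite(spec.effective_induction_mean) else math.inf
        cum = np.cumsum(counts)
        hit = np.nonzero(cum >= truth.target_spikes_to_induction)[0]
        if hit.size:
            # induction is declared at a completed step; take the step whose
            # cumulative evoked count is closest to the sampled target so the
            # realized counts are centered on the target population mean
            induction_step = int(hit[0])
            if induction_step > 0 and cum[induction_step - 1] > 0:
                over = cum[induction_step] - truth.target_spikes_to_induction
                under = truth.target_spikes_to_induction - cum[induction_step - 1]
                if under < over:
                    induction_step -= 1
            delivered = induction_step + 1
            truth.realized_spikes_to_induction = int(cum[induction_step])
        else:
            induction_step = None
            delivered = protocol.n_sweeps

    windows = protocol.step_windows()
    evoked = []
    for k in range(delivered):
        n_k = int(counts[k])
        if n_k:
            evoked.append(_constrained_uniform(rng, windows[k, 0], windows[k, 1], n_k))
    evoked = np.concatenate(evoked) if evoked else np.empty(0)

    delivered_protocol = replace(protocol, n_sweeps=delivered)

    # --- barrage -------------------------------------------------------------
    barrage_spikes = np.empty(0)
    if induction_step is not None:
        onset = float(windows[induction_step, 1])
        duration = _truncnorm(rng, spec.barrage_duration_mean, spec.barrage_duration_sd)
        n_b = rng.poisson(spec.barrage_rate_hz * duration)
        barrage_spikes = _constrained_uniform(rng, onset, onset + duration, n_b)
        truth.barrage_onset = onset
        truth.barrage_end = onset + duration
        truth.barrage_duration = duration
        truth.n_barrage_spikes = int(n_b)

    spikes = np.unique(np.concatenate([evoked, barrage_spikes]))

    # --- astrocyte membrane potential ---------------------------------------
    has_astro = (
        induction_step is not None
        and rng.random() < spec.astro_event_probability
    )
    # consume the sampled event parameters regardless of the Bernoulli draw
    # so that the evoked-spike realization does not depend on it
    lead = _truncnorm(rng, spec.depol_lead_mean, spec.depol_lead_sd)
    peak = _truncnorm(rng, spec.astro_peak_mean, spec.astro_peak_sd)
    rise = max(1e-3, _truncnorm(rng, spec.rise_time_mean, spec.rise_time_sd))
    outlasts = bool(rng.random() < spec.astro_outlast_probability)

    end_candidates = [protocol.t0 + delivered * protocol.period]
    if truth.barrage_end is not None:
        end_candidates.append(truth.barrage_end)

    ca_lead = _truncnorm(rng, spec.calcium_lead_mean, spec.calcium_lead_sd)
    if spec.include_calcium and induction_step is not None:
        truth.calcium_onset = truth.barrage_onset - ca_lead
        truth.calcium_lead = ca_lead
        # detectable end: decay to 1% of plateau after barrage end
        truth.calcium_end = truth.barrage_end + spec.calcium_decay_tau * math.log(100.0)
        end_candidates.append(truth.calcium_end)

    if has_astro:
        # keep the depolarization onset inside the stimulated span
        lead = max(min(lead, truth.barrage_onset - protocol.t0 - 2.0), 0.5)
        truth.astro_onset = truth.barrage_onset - lead
        truth.astro_peak_mv = peak
        truth.astro_rise_time = rise
        truth.astro_outlasts_barrage = outlasts
        if outlasts:
            decay_start = truth.barrage_end
            decay_tau = spec.astro_return_tau
        else:
            s = rise / _LOGISTIC_2080
            decay_start = truth.astro_onset + 2.0 * s * math.log(99.0) + spec.astro_plateau_s
            decay_tau = spec.astro_decay_tau
        end_candidates.append(decay_start + 5.0 * decay_tau)

    t_end = max(end_candidates) + spec.tail_s
    n_samples = int(round(t_end * fs))
    t = np.arange(n_samples) / fs

    astro = np.full(n_samples, spec.astro_resting_mv)
    if has_astro:
        astro += _depolarization_waveform(
            t, truth.astro_onset, peak, rise, decay_start, decay_tau
        )
    if spec.vm_noise_sd > 0:
        astro += rng.normal(0.0, spec.vm_noise_sd, n_samples)

    # --- neuron trace --------------------------------------------------------
    neuron = np.full(n_samples, spec.neuron_resting_mv)
    for k in range(delivered):
        a = int(round(windows[k, 0] * fs))
        b = int(round(windows[k, 1] * fs))
        neuron[a:b] += 15.0  # subthreshold step depolarization
    if spec.vm_noise_sd > 0:
        neuron += rng.normal(0.0, spec.vm_noise_sd, n_samples)
    _insert_spikes(neuron, spikes, fs, amplitude=95.0)

    # --- calcium ΔF/F traces -------------------------------------------------
    calcium = None
    if spec.include_calcium:
        ca_fs = spec.calcium_sampling_rate
        tc = np.arange(int(round(t_end * ca_fs))) / ca_fs
        calcium = np.zeros((spec.n_calcium_rois, tc.size))
        peaks = []
        for i in range(spec.n_calcium_rois):
            amp = _truncnorm(rng, spec.dff_peak_mean, spec.dff_peak_sd)
            peaks.append(amp)
            if induction_step is not None:
                calcium[i] = amp * _calcium_shape(
                    tc,
                    truth.calcium_onset,
                    truth.barrage_onset,
                    truth.barrage_end,
                    spec.calcium_decay_tau,
                )
            if spec.dff_noise_sd > 0:
                calcium[i] += rng.normal(0.0, spec.dff_noise_sd, tc.size)
        truth.calcium_peaks = peaks if induction_step is not None else None

    return RecordingBundle(
        protocol=delivered_protocol,
        neuron_trace=neuron,
        neuron_spikes=spikes,
        astro_trace=astro,
        calcium_traces=calcium,
        calcium_sampling_rate=spec.calcium_sampling_rate if calcium is not None else None,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Calcium imaging scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobSpec:
    """One fluorescent region painted into a scene.

    ``area_um2`` is realized exactly: the pixel count is
    ``round(area_um2 / pixel_size**2)`` and that many pixels closest to the
    center are painted.
    """

    center: tuple[float, float]
    area_um2: float
    baseline_intensity: float = 1000.0
    amplitude: float = 1.7
    kind: str = "soma"  # soma | process | microdomain


@dataclass(frozen=True)
class SceneSpec:
    """Synthetic calcium image-stack description."""

    shape: tuple[int, int] = (160, 160)
    pixel_size: float = 1.0
    frame_rate: float = 7.0
    duration_s: float = 170.0
    background: float = 100.0
    noise_sd: float = 20.0
    blobs: tuple[BlobSpec, ...] = ()
    event_onset: float = 110.0
    event_rise_s: float = 10.0
    event_plateau_s: float = 30.0
    event_decay_tau: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_rate <= 0 or self.duration_s <= 0:
            raise ValueError("frame_rate and duration_s must be > 0")
        for blob in self.blobs:
            r = math.sqrt(blob.area_um2 / self.pixel_size**2 / math.pi) + 1.5
            y, x = blob.center
            if (y - r < 0 or x - r < 0 or y + r >= self.shape[0]
                    or x + r >= self.shape[1]):
                raise ValueError(f"blob at {blob.center} does not fit inside the image")


@dataclass
class CalciumScene:
    """Generated stack plus ground truth."""

    spec: SceneSpec
    stack: np.ndarray  # (frames, H, W) uint16
    masks: list[np.ndarray]  # per-blob boolean masks
    labels: list[str]
    amplitudes: list[float]
    event_onset: float
    event_end: float

    def write_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.stack)


def _blob_mask(shape: tuple[int, int], center: tuple[float, float], n_pixels: int) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    order = np.argsort(d2.ravel(), kind="stable")[:n_pixels]
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[order] = True
    return mask


def generate_calcium_stack(scene: SceneSpec, seed: int | None = None) -> CalciumScene:
    """Render a TIFF-writable image stack with per-blob ground-truth masks.

    Each blob fluoresces at its baseline intensity scaled by
    ``1 + amplitude * shape(t)`` with a shared linear-rise / plateau /
    exponential-decay time course; Gaussian read noise is added last.
    """
    rng = np.random.default_rng(seed if seed is not None else scene.seed)
    n_frames = int(round(scene.duration_s * scene.frame_rate))
    t = np.arange(n_frames) / scene.frame_rate
    shape_t = _calcium_shape(
        t,
        scene.event_onset,
        scene.event_onset + scene.event_rise_s,
        scene.event_onset + scene.event_rise_s + scene.event_plateau_s,
        scene.event_decay_tau,
    )

    base = np.full(scene.shape, scene.background, dtype=np.float64)
    masks: list[np.ndarray] = []
    labels: list[str] = []
    amps: list[float] = []
    gain = np.zeros(scene.shape)  # per-pixel modulated intensity (baseline * amp)
    for blob in scene.blobs:
        n_px = max(1, int(round(blob.area_um2 / scene.pixel_size**2)))
        mask = _blob_mask(scene.shape, blob.center, n_px)
        if any((mask & m).any() for m in masks):
            raise ValueError("blobs overlap; adjust scene layout")
        base[mask] = blob.baseline_intensity
        gain[mask] = blob.baseline_intensity * blob.amplitude
        masks.append(mask)
        labels.append(blob.kind)
        amps.append(blob.amplitude)

    stack = base[None, :, :] + shape_t[:, None, None] * gain[None, :, :]
    if scene.noise_sd > 0:
        stack = stack + rng.normal(0.0, scene.noise_sd, stack.shape)
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)

    event_end = (
        scene.event_onset + scene.event_rise_s + scene.event_plateau_s
        + scene.event_decay_tau * math.log(100.0)
    )
    return CalciumScene(
        spec=scene,
        stack=stack,
        masks=masks,
        labels=labels,
        amplitudes=amps,
        event_onset=scene.event_onset,
        event_end=event_end,
    )


def make_default_scene(
    seed: int | None = None,
    n_somata: int = 4,
    n_processes: int = 22,
    n_microdomains: int = 3,
    dff_peak_mean: float = 1.7,
    dff_peak_sd: float = 0.2,
    shape: tuple[int, int] = (160, 160),
    **kwargs,
) -> SceneSpec:
    """Default field of view: 4 somata and 22 process ROIs per scene, plus a
    few sub-threshold microdomains, placed without overlap."""
    rng = np.random.default_rng(seed)
    blobs: list[BlobSpec] = []
    occupied: list[tuple[float, float, float]] = []  # (y, x, radius)

    def place(area_um2: float, kind: str) -> None:
        r = math.sqrt(area_um2 / math.pi) + 2.0
        for _ in range(10_000):
            y = rng.uniform(r + 2, shape[0] - r - 3)
            x = rng.uniform(r + 2, shape[1] - r - 3)
            if all((y - oy) ** 2 + (x - ox) ** 2 > (r + orr + 2) ** 2 for oy, ox, orr in occupied):
                occupied.append((y, x, r))
                amp = max(0.0, float(rng.normal(dff_peak_mean, dff_peak_sd)))
                blobs.append(BlobSpec(center=(y, x), area_um2=area_um2, amplitude=amp, kind=kind))
                return
        raise RuntimeError("could not place blob without overlap")

    for _ in range(n_somata):
        place(float(rng.uniform(40.0, 60.0)), "soma")
    for _ in range(n_processes):
        place(float(rng.uniform(6.0, 12.0)), "process")
    for _ in range(n_microdomains):
        place(3.0, "microdomain")
    return SceneSpec(shape=shape, blobs=tuple(blobs), seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_bundle(bundle: RecordingBundle, out_dir: str | Path, spec: GeneratorSpec | None = None) -> None:
    """Write a bundle as CSV trace tables, a CSV event table, and a YAML sidecar."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = bundle.times()
    pd.DataFrame({"time_s": t, "value": bundle.neuron_trace}).to_csv(
        out / "neuron_vm.csv", index=False
    )
    pd.DataFrame({"time_s": t, "value": bundle.astro_trace}).to_csv(
        out / "astrocyte_vm.csv", index=False
    )
    pd.DataFrame({"time_s": bundle.neuron_spikes}).to_csv(out / "spikes.csv", index=False)
    if bundle.calcium_traces is not None:
        tc = bundle.calcium_times()
        df = pd.DataFrame({"time_s": tc})
        for i, row in enumerate(bundle.calcium_traces):
            df[f"roi_{i}"] = row
        df.to_csv(out / "calcium_dff.csv", index=False)
    events = []
    if bundle.truth is not None:
        for name in ("astro_onset", "barrage_onset", "barrage_end", "calcium_onset", "calcium_end"):
            value = getattr(bundle.truth, name)
            if value is not None:
                events.append({"event": name, "time_s": value})
    pd.DataFrame(events, columns=["event", "time_s"]).to_csv(out / "events.csv", index=False)
    sidecar = {"protocol": asdict(bundle.protocol)}
    if spec is not None:
        d = asdict(spec)
        d["condition_modifiers"] = dict(d["condition_modifiers"])
        sidecar["generator"] = d
    (out / "bundle.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def load_trace_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a (time_s, value) CSV trace table."""
    import pandas as pd

    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df["value"].to_numpy()
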