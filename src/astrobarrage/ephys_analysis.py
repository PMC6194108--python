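"""Voltage-trace analysis: spikes, barrage firing, astrocyte events, timelines.

Conventions shared by all operations: traces are uniformly sampled arrays
starting at recording time t = 0; all reported times are recording-relative
seconds; level crossings are located by linear interpolation between
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic_data import StimulationProtocol

__all__ = [
    "BarrageEvent",
    "AstrocyteEvent",
    "EventTimeline",
    "detect_spikes",
    "detect_barrage",
    "count_spikes_to_induction",
    "detect_onset",
    "rise_time_20_80",
    "all_points_histogram",
    "build_timeline",
    "measure_astrocyte_event",
    "smooth_trace",
]


@dataclass(frozen=True)
class BarrageEvent:
    """A detected barrage-firing episode (>4 Hz sustained after a step ends)."""

    onset: float
    end: float
    spikes_to_induction: int | None = None
    n_barrage_spikes: int = 0

    def __post_init__(self) -> None:
        if self.end < self.onset:
            raise ValueError("barrage end must be >= onset")

    @property
    def duration(self) -> float:
        return self.end - self.onset


@dataclass(frozen=True)
class AstrocyteEvent:
    """A detected astrocyte depolarization (or calcium) event."""

    onset: float
    peak_amplitude: float
    rise_time_20_80: float | None = None
    return_time: float | None = None

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if self.return_time is not None and self.return_time < self.onset:
            raise ValueError("return_time must be >= onset")


@dataclass(frozen=True)
class EventTimeline:
    """Key event times of one recording.

    A = onset of the astrocyte signal (depolarization or calcium increase),
    B = barrage-firing start, C = barrage-firing end, D = end of the
    detectable astrocyte signal.  ``lead`` = B − A and ``overhang`` = D − C,
    defined only when both endpoints exist.
    """

    stim_start: float
    signal_onset: float | None = None
    barrage_start: float | None = None
    barrage_end: float | None = None
    signal_end: float | None = None

    @property
    def lead(self) -> float | None:
        if self.signal_onset is None or self.barrage_start is None:
            return None
        return self.barrage_start - self.signal_onset

    @property
    def overhang(self) -> float | None:
        if self.signal_end is None or self.barrage_end is None:
            return None
        return self.signal_end - self.barrage_end


def detect_spikes(
    trace: np.ndarray,
    sampling_rate: float,
    threshold_mv: float = -20.0,
    refractory_s: float = 0.002,
) -> np.ndarray:
    """Spike times from upward threshold crossings with a refractory period."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    above = trace >= threshold_mv
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if crossings.size == 0:
        return np.empty(0)
    times = crossings / sampling_rate
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def _scan_regions(protocol: StimulationProtocol, horizon: float) -> list[tuple[float, float]]:
    """Post-step regions: each inter-step rest plus the post-protocol span."""
    regions: list[tuple[float, float]] = []
    rests = protocol.rest_windows()
    for k in range(protocol.n_sweeps - 1):
        regions.append((float(rests[k, 0]), float(rests[k, 1])))
    final_start = float(rests[-1, 0])
    regions.append((final_start, max(horizon, final_start)))
    return regions


def detect_barrage(
    spikes: np.ndarray,
    protocol: StimulationProtocol,
    rate_criterion_hz: float = 4.0,
    min_duration_s: float = 1.0,
    window_s: float = 1.0,
    stride_s: float = 0.1,
    horizon: float | None = None,
) -> BarrageEvent | None:
    """Detect barrage firing: rate strictly > criterion sustained >= 1 s
    after a current step ends.

    A sliding 1-s window (0.1-s stride) scans every post-step region (rests
    between steps and the span after the final step); windows never overlap
    a step, so evoked spikes cannot qualify.  The onset is the start of the
    first window of the first qualifying run whose windows jointly span at
    least ``min_duration_s``; the end is the end of the last contiguous
    qualifying window of that run.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size and np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted")
    if horizon is None:
        horizon = (spikes[-1] + window_s) if spikes.size else protocol.end

    for region_start, region_end in _scan_regions(protocol, horizon):
        span = region_end - region_start
        if span < window_s:
            continue
        n_windows = int(math.floor((span - window_s) / stride_s)) + 1
        starts = region_start + stride_s * np.arange(n_windows)
        counts = np.searchsorted(spikes, starts + window_s, side="right") - np.searchsorted(
            spikes, starts, side="left"
        )
        qualifying = counts / window_s > rate_criterion_hz
        if not qualifying.any():
            continue
        # maximal runs of consecutive qualifying windows
        padded = np.concatenate([[False], qualifying, [False]])
        run_starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        run_ends = np.nonzero(~padded[1:] & padded[:-1])[0]  # exclusive
        for a, b in zip(run_starts, run_ends):
            sustained = (b - 1 - a) * stride_s + window_s
            if sustained >= min_duration_s:
                onset = float(starts[a])
                end = float(starts[b - 1] + window_s)
                n_in = int(
                    np.searchsorted(spikes, end, side="right")
                    - np.searchsorted(spikes, onset, side="left")
                )
                n_to_induction = count_spikes_to_induction(spikes, protocol, onset)
                return BarrageEvent(
                    onset=onset,
                    end=end,
                    spikes_to_induction=n_to_induction,
                    n_barrage_spikes=n_in,
                )
    return None


def count_spikes_to_induction(
    spikes: np.ndarray,
    protocol: StimulationProtocol,
    barrage_onset: float,
) -> int:
    """Evoked spikes before barrage onset: spikes inside step windows that
    fall strictly before the onset (inter-step spontaneous spikes excluded)."""
    spikes = np.asarray(spikes, dtype=float)
    total = 0
    for start, stop in protocol.step_windows():
        if start >= barrage_onset:
            break
        hi = min(stop, barrage_onset)
        total += int(
            np.searchsorted(spikes, hi, side="left") - np.searchsorted(spikes, start, side="left")
        )
    return total


def detect_onset(
    trace: np.ndarray,
    sampling_rate: float,
    baseline_window: tuple[float, float],
    k_sd: float = 3.0,
    sustain_s: float = 0.5,
    search_start: float | None = None,
) -> float | None:
    """First time the signal exceeds baseline mean + k·SD continuously for
    at least ``sustain_s`` seconds.

    With a zero-variance baseline the threshold degenerates to the baseline
    mean, so any sustained deviation is detected at its first sample.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    a = int(round(baseline_window[0] * sampling_rate))
    b = int(round(baseline_window[1] * sampling_rate))
    if not 0 <= a < b <= trace.size:
        raise ValueError("baseline window outside trace")
    baseline = trace[a:b]
    mu = float(baseline.mean())
    sd = float(baseline.std())
    threshold = mu + k_sd * sd

    start_idx = b if search_start is None else int(round(search_start * sampling_rate))
    above = trace[start_idx:] > threshold
    need = max(1, int(round(sustain_s * sampling_rate)))
    padded = np.concatenate([[False], above, [False]])
    run_starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    run_ends = np.nonzero(~padded[1:] & padded[:-1])[0]
    for s, e in zip(run_starts, run_ends):
        if e - s >= need:
            return float((start_idx + s) / sampling_rate)
    return None


def _first_upward_crossing(
    t: np.ndarray, v: np.ndarray, level: float
) -> float | None:
    """Time of the first upward crossing of ``level``, linearly interpolated."""
    above = v >= level
    if above[0]:
        return float(t[0])
    idx = np.nonzero(above[1:] & ~above[:-1])[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def rise_time_20_80(
    trace: np.ndarray,
    sampling_rate: float,
    onset: float,
    baseline_mean: float | None = None,
    peak_time: float | None = None,
) -> float:
    """20–80% rise time of the event starting at ``onset``.

    Amplitudes are measured relative to the baseline mean (the mean of the
    trace before onset if not given); the peak is the maximum after onset
    (or the value at ``peak_time``); crossing times use linear interpolation.
    """
    trace = np.asarray(trace, dtype=float)
    i_on = int(round(onset * sampling_rate))
    if baseline_mean is None:
        if i_on < 1:
            raise ValueError("cannot infer baseline mean: onset at trace start")
        baseline_mean = float(trace[:i_on].mean())
    if peak_time is None:
        i_peak = i_on + int(np.argmax(trace[i_on:]))
    else:
        i_peak = int(round(peak_time * sampling_rate))
    peak = float(trace[i_peak])
    amp = peak - baseline_mean
    if amp <= 0:
        raise ValueError("peak must exceed baseline")
    seg = trace[i_on : i_peak + 1]
    t = (i_on + np.arange(seg.size)) / sampling_rate
    t20 = _first_upward_crossing(t, seg, baseline_mean + 0.2 * amp)
    t80 = _first_upward_crossing(t, seg, baseline_mean + 0.8 * amp)
    if t20 is None or t80 is None:
        raise ValueError("trace does not cross the 20%/80% levels after onset")
    return t80 - t20


def all_points_histogram(
    trace: np.ndarray, bin_width_mv: float
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of every sample in the trace; counts sum to the sample count."""
    if bin_width_mv <= 0:
        raise ValueError("bin width must be > 0")
    trace = np.asarray(trace, dtype=float)
    lo = math.floor(trace.min() / bin_width_mv) * bin_width_mv
    n_bins = max(1, int(math.ceil((trace.max() - lo) / bin_width_mv)))
    edges = lo + bin_width_mv * np.arange(n_bins + 1)
    # make the last edge inclusive of the maximum
    if edges[-1] <= trace.max():
        edges = np.append(edges, edges[-1] + bin_width_mv)
    counts, edges = np.histogram(trace, bins=edges)
    return edges, counts


def smooth_trace(trace: np.ndarray, sampling_rate: float, width_s: float) -> np.ndarray:
    """Centered moving-average smoothing (reflected edges)."""
    n = max(1, int(round(width_s * sampling_rate)))
    if n == 1:
        return np.asarray(trace, dtype=float)
    kernel = np.full(n, 1.0 / n)
    padded = np.pad(np.asarray(trace, dtype=float), n, mode="reflect")
    return np.convolve(padded, kernel, mode="same")[n:-n]


def measure_astrocyte_event(
    trace: np.ndarray,
    sampling_rate: float,
    baseline_window: tuple[float, float],
    k_sd: float = 3.0,
    sustain_s: float = 0.5,
    smooth_s: float = 0.05,
) -> AstrocyteEvent | None:
    """Detect and characterize a depolarization/calcium event in one trace.

    Onset uses the baseline mean + k·SD sustained rule on the raw trace;
    peak amplitude and 20–80% rise time are measured on a lightly smoothed
    copy so the peak estimate is not inflated by the noise maximum.
    """
    onset = detect_onset(trace, sampling_rate, baseline_window, k_sd=k_sd, sustain_s=sustain_s)
    if onset is None:
        return None
    a = int(round(baseline_window[0] * sampling_rate))
    b = int(round(baseline_window[1] * sampling_rate))
    mu = float(np.asarray(trace[a:b], dtype=float).mean())
    sd = float(np.asarray(trace[a:b], dtype=float).std())
    smoothed = smooth_trace(trace, sampling_rate, smooth_s)
    i_on = int(round(onset * sampling_rate))
    i_peak = i_on + int(np.argmax(smoothed[i_on:]))
    peak_amplitude = float(smoothed[i_peak] - mu)
    rise = rise_time_20_80(
        smoothed, sampling_rate, onset, baseline_mean=mu, peak_time=i_peak / sampling_rate
    )
    # return time: first sustained drop back below threshold after the peak
    threshold = mu + k_sd * sd
    below = smoothed[i_peak:] <= threshold
    return_time = None
    idx = np.nonzero(below)[0]
    if idx.size:
        return_time = float((i_peak + idx[0]) / sampling_rate)
    return AstrocyteEvent(
        onset=onset,
        peak_amplitude=peak_amplitude,
        rise_time_20_80=rise,
        return_time=return_time,
    )


def build_timeline(
    stim_start: float,
    astro_event: AstrocyteEvent | None = None,
    barrage: BarrageEvent | None = None,
    signal_end: float | None = None,
) -> EventTimeline:
    """Assemble the A/B/C/D timeline; missing events leave intervals undefined."""
    if astro_event is None and barrage is None:
        raise ValueError("at least one event is required")
    return EventTimeline(
        stim_start=stim_start,
        signal_onset=astro_event.onset if astro_event is not None else None,
        barrage_start=barrage.onset if barrage is not None else None,
        barrage_end=barrage.end if barrage is not None else None,
        signal_end=signal_end
        if signal_end is not None
        else (astro_event.return_time if astro_event is not None else None),
    )
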