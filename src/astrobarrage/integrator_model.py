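"""Hidden-variable leaky-integrator model of barrage-firing induction.

Each evoked action potential increments a latent variable that decays as a
leaky integrator with time constant ``tau`` (~7.7 s).  When the latent
variable reaches a threshold, barrage firing is triggered after a fixed
delay.  Because a pure single-``tau`` integrator saturates within a few
seconds of stimulation, a fraction ``slow_fraction`` (rho) of each per-spike
increment is routed to a non-decaying accumulator, which lets the late
envelope grow with spike count so that threshold crossing after hundreds of
evoked spikes is well defined and robust to trial-to-trial jitter.

The simulation is event-driven: the latent value is exact at spike times and
evaluated in closed form between them, so no integration error is incurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .synthetic_data import StimulationProtocol

__all__ = [
    "IntegratorParams",
    "HiddenVariableTrajectory",
    "DecayFit",
    "simulate_hidden_variable",
    "predict_barrage_onset",
    "rest_segments",
    "fit_decay_constant",
    "calibrate",
    "nominal_spike_times",
]

#: Default decay time constant of the latent integrator, seconds.
DEFAULT_TAU = 7.7

#: Default fraction of each increment routed to the non-decaying accumulator.
#: Chosen so the per-sweep growth of the late envelope (rho * spikes/step)
#: dominates the trial-to-trial fluctuation of the leaky component (which has
#: SD ~ 8 * (1 - rho) increment-units under Poisson-jittered stimulation);
#: see docs/methods.md for the sizing argument.
DEFAULT_SLOW_FRACTION = 0.7


@dataclass(frozen=True)
class IntegratorParams:
    """Parameters of the latent integrator.

    tau
        Decay time constant of the leaky component, seconds.  ``math.inf``
        disables decay (pure spike counter when ``slow_fraction`` is 0).
    increment
        Latent-variable step per evoked spike, arbitrary units.
    slow_fraction
        Fraction rho of each increment routed to a non-decaying accumulator.
    threshold
        Latent value at which barrage firing is triggered; ``None`` until
        calibrated.
    delay
        Seconds between threshold crossing and barrage onset.
    """

    tau: float = DEFAULT_TAU
    increment: float = 1.0
    slow_fraction: float = DEFAULT_SLOW_FRACTION
    threshold: float | None = None
    delay: float = 0.0

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.increment > 0:
            raise ValueError(f"increment must be > 0, got {self.increment}")
        if not 0.0 <= self.slow_fraction < 1.0:
            raise ValueError(
                f"slow_fraction must be in [0, 1), got {self.slow_fraction}"
            )
        if self.threshold is not None and not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")


@dataclass(frozen=True)
class HiddenVariableTrajectory:
    """Latent-variable time course with threshold-crossing metadata.

    ``value`` is the full latent variable; ``slow`` is the non-decaying
    accumulator part (``increment * rho * #spikes``), so ``value - slow`` is
    the purely leaky component.  ``crossing_time`` is the first spike time at
    which ``value >= threshold`` (ties count as crossings), or ``None``.
    """

    time: np.ndarray
    value: np.ndarray
    slow: np.ndarray
    params: IntegratorParams
    crossing_time: float | None = None
    spikes_at_crossing: int | None = None

    @property
    def leaky(self) -> np.ndarray:
        return self.value - self.slow


class DecayFit(NamedTuple):
    tau: float
    residual: float


def _validate_spikes(spikes: np.ndarray, horizon: float | None = None) -> np.ndarray:
    spikes = np.asarray(spikes, dtype=float)
    if spikes.ndim != 1:
        raise ValueError("spike times must be a 1-D sequence")
    if spikes.size and np.any(np.diff(spikes) <= 0):
        raise ValueError("spike times must be strictly increasing")
    if spikes.size and horizon is not None:
        if spikes[0] < 0 or spikes[-1] > horizon:
            raise ValueError("spike times must lie within [0, horizon]")
    return spikes


def _leaky_sums_at_spikes(spikes: np.ndarray, tau: float) -> np.ndarray:
    """S_i = sum_{j<=i} exp(-(t_i - t_j)/tau), computed by recursion."""
    s = np.empty(spikes.size)
    acc = 0.0
    prev = 0.0
    for i, t in enumerate(spikes):
        if math.isinf(tau):
            acc = acc + 1.0
        else:
            acc = acc * math.exp(-(t - prev) / tau) + 1.0
        s[i] = acc
        prev = t
    return s


def _values_at_spikes(spikes: np.ndarray, params: IntegratorParams) -> np.ndarray:
    """Latent value immediately after each spike's increment."""
    s = _leaky_sums_at_spikes(spikes, params.tau)
    n = np.arange(1, spikes.size + 1)
    return params.increment * ((1.0 - params.slow_fraction) * s + params.slow_fraction * n)


def _first_crossing(
    spikes: np.ndarray, params: IntegratorParams
) -> tuple[float | None, int | None]:
    if params.threshold is None or spikes.size == 0:
        return None, None
    values = _values_at_spikes(spikes, params)
    idx = np.nonzero(values >= params.threshold)[0]
    if idx.size == 0:
        return None, None
    i = int(idx[0])
    return float(spikes[i]), i + 1


def simulate_hidden_variable(
    spikes: Sequence[float],
    params: IntegratorParams,
    horizon: float,
    dt: float = 0.01,
) -> HiddenVariableTrajectory:
    """Simulate the latent variable driven by a spike train.

    The returned trajectory is sampled on a uniform grid of spacing ``dt``
    merged with the exact spike times; values are closed-form exact
    everywhere (event-driven evaluation).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    spikes = _validate_spikes(spikes, horizon)
    grid = np.arange(0.0, horizon + 0.5 * dt, dt)
    t = np.union1d(grid, spikes)

    tau, inc, rho = params.tau, params.increment, params.slow_fraction
    if spikes.size == 0:
        zeros = np.zeros_like(t)
        return HiddenVariableTrajectory(t, zeros, zeros.copy(), params)

    s_at_spikes = _leaky_sums_at_spikes(spikes, tau)
    # index of last spike at or before each grid time (-1: none)
    last = np.searchsorted(spikes, t, side="right") - 1
    value = np.zeros_like(t)
    slow = np.zeros_like(t)
    has = last >= 0
    if math.isinf(tau):
        decay = np.ones(has.sum())
    else:
        decay = np.exp(-(t[has] - spikes[last[has]]) / tau)
    leaky = s_at_spikes[last[has]] * decay
    count = (last[has] + 1).astype(float)
    value[has] = inc * ((1.0 - rho) * leaky + rho * count)
    slow[has] = inc * rho * count

    crossing_time, spikes_at_crossing = _first_crossing(spikes, params)
    return HiddenVariableTrajectory(
        t, value, slow, params, crossing_time, spikes_at_crossing
    )


def predict_barrage_onset(
    spikes: Sequence[float], params: IntegratorParams
) -> float | None:
    """Predicted barrage onset: first threshold crossing plus the delay."""
    spikes = _validate_spikes(spikes)
    crossing_time, _ = _first_crossing(spikes, params)
    if crossing_time is None:
        return None
    return crossing_time + params.delay


def spikes_at_first_crossing(
    spikes: Sequence[float], params: IntegratorParams
) -> int | None:
    """Number of evoked spikes delivered when the threshold is first reached."""
    spikes = _validate_spikes(spikes)
    _, n = _first_crossing(spikes, params)
    return n


def rest_segments(
    trajectory: HiddenVariableTrajectory,
    protocol: StimulationProtocol,
    min_samples: int = 3,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Extract the spike-free rest-period segments of the leaky component.

    The non-decaying accumulator is constant during rests, so it is removed
    before fitting; what remains is a single exponential in ``tau``.
    """
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    leaky = trajectory.leaky
    for start, stop in protocol.rest_windows():
        mask = (trajectory.time > start) & (trajectory.time < stop)
        if mask.sum() >= min_samples:
            segments.append((trajectory.time[mask], leaky[mask]))
    return segments


def fit_decay_constant(
    segments: Sequence[tuple[np.ndarray, np.ndarray]],
) -> DecayFit:
    """Pooled log-linear least-squares fit of a single-exponential decay.

    Each segment contributes its own intercept (initial value) but all share
    one slope ``-1/tau``.  Segments containing non-positive values are
    skipped; if all are skipped a ``ValueError`` is raised.
    """
    sxx = 0.0
    sxy = 0.0
    rows: list[tuple[np.ndarray, np.ndarray]] = []
    for t, v in segments:
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if t.size < 3 or np.any(v <= 0):
            continue
        y = np.log(v)
        tc = t - t.mean()
        yc = y - y.mean()
        sxx += float(tc @ tc)
        sxy += float(tc @ yc)
        rows.append((tc, yc))
    if not rows or sxx == 0.0:
        raise ValueError("no usable rest segments for decay fit")
    slope = sxy / sxx
    if slope >= 0:
        raise ValueError("segments do not decay; cannot fit a time constant")
    residual = sum(float(np.sum((yc - slope * tc) ** 2)) for tc, yc in rows)
    return DecayFit(tau=-1.0 / slope, residual=residual)


def nominal_spike_times(protocol: StimulationProtocol) -> np.ndarray:
    """Evenly spaced evoked spikes of the nominal (unjittered) protocol.

    Each 1-s step carries ``target_spikes_per_step`` spikes at spacing
    ``step_duration / n``, the last one landing exactly on the step end.
    """
    n = protocol.target_spikes_per_step
    offsets = (np.arange(1, n + 1) / n) * protocol.step_duration
    starts = protocol.t0 + np.arange(protocol.n_sweeps) * protocol.period
    return (starts[:, None] + offsets[None, :]).ravel()


def calibrate(
    params: IntegratorParams,
    protocol: StimulationProtocol,
    target_spikes: int,
) -> IntegratorParams:
    """Set the threshold so the nominal protocol crosses at a target spike.

    Deterministic: the latent variable is evaluated on the nominal evenly
    spaced spike train and the threshold is fixed to its value at the
    ``target_spikes``-th spike (1-indexed).
    """
    if target_spikes < 1:
        raise ValueError("target_spikes must be >= 1")
    spikes = nominal_spike_times(protocol)
    if target_spikes > spikes.size:
        raise ValueError(
            f"target {target_spikes} exceeds protocol capacity {spikes.size}"
        )
    values = _values_at_spikes(spikes, params)
    return replace(params, threshold=float(values[target_spikes - 1]))
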