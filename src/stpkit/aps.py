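"""Action-potential detection, waveform features and excitability metrics.

Spikes are detected as upward dV/dt crossings of a slope threshold
(20 mV/ms by default; the value is configurable and recorded in output)
followed by a voltage peak within 2 ms.  Waveform features follow the
usual current-clamp conventions: threshold is the membrane potential at
the last 20 mV/ms upward crossing before the peak, amplitude is peak
minus threshold, half-width is measured at threshold + amplitude/2 with
linear interpolation, maximal rates of depolarization/repolarization are
the dV/dt extrema between threshold and the AHP trough (both reported as
positive magnitudes), and the AHP is measured from threshold to the
voltage minimum within 10 ms after the peak.  Derivatives use central
differences at the native sampling rate, without smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundsError, MeasurementError, ParameterError
from .signal_core import StimulusProtocol, Trace

__all__ = [
    "APFeatures",
    "detect_spikes",
    "ap_features",
    "evoked_firing_metrics",
    "spontaneous_rate",
    "input_resistance",
]


@dataclass
class APFeatures:
    threshold: float   # mV
    amplitude: float   # mV, peak - threshold
    half_width: float  # ms
    max_rise: float    # mV/ms
    max_fall: float    # mV/ms, magnitude
    ahp: float         # mV below threshold
    peak_time: float   # s
    latency: float | None = None  # ms, first evoked spike only


def _dvdt(trace: Trace) -> np.ndarray:
    """Central-difference dV/dt in mV/ms."""
    return np.gradient(trace.samples, 1e3 / trace.sampling_rate)


def detect_spikes(
    trace: Trace,
    dvdt_threshold: float = 20.0,
    min_peak: float = -20.0,
    refractory_ms: float = 1.0,
    peak_window_ms: float = 2.0,
) -> np.ndarray:
    """Spike peak times (s).

    A spike is an upward dV/dt crossing of ``dvdt_threshold`` whose
    voltage reaches at least ``min_peak`` within ``peak_window_ms``; the
    reported time is the voltage maximum in that window.  Crossings
    within ``refractory_ms`` of an accepted spike are ignored.
    """
    if trace.kind != "voltage":
        raise ParameterError("spike detection operates on voltage traces")
    v = trace.samples
    dv = _dvdt(trace)
    above = dv >= dvdt_threshold
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1
    w = max(int(round(peak_window_ms * 1e-3 * trace.sampling_rate)), 1)
    refr = refractory_ms * 1e-3
    peaks: list[float] = []
    last = -np.inf
    for i in crossings:
        t_cross = trace.start_time + i / trace.sampling_rate
        if t_cross - last < refr:
            continue
        seg = v[i : i + w + 1]
        if seg.size == 0 or seg.max() < min_peak:
            continue
        j = i + int(np.argmax(seg))
        t_peak = trace.start_time + j / trace.sampling_rate
        peaks.append(t_peak)
        last = t_peak
    return np.asarray(peaks)


def ap_features(
    trace: Trace,
    spike_time: float,
    dvdt_threshold: float = 20.0,
    ahp_window_ms: float = 10.0,
    search_back_ms: float = 10.0,
) -> APFeatures:
    """Waveform features of the spike whose peak lies at ``spike_time``."""
    if trace.kind != "voltage":
        raise ParameterError("AP features operate on voltage traces")
    v = trace.samples
    rate = trace.sampling_rate
    dt_ms = 1e3 / rate
    i_near = trace.index_of(spike_time)
    lo = max(i_near - int(round(0.5e-3 * rate)), 0)
    hi = min(i_near + int(round(0.5e-3 * rate)) + 1, v.size)
    peak_idx = lo + int(np.argmax(v[lo:hi]))

    back = min(int(round(search_back_ms * 1e-3 * rate)), peak_idx - 1)
    ahp_n = int(round(ahp_window_ms * 1e-3 * rate))
    if back < 1 or peak_idx + ahp_n >= v.size:
        raise BoundsError("spike too close to the trace edge for feature windows")

    dv = _dvdt(trace)
    # threshold: last upward crossing of the slope criterion before the peak
    thr_idx = None
    for i in range(peak_idx, peak_idx - back, -1):
        if dv[i] >= dvdt_threshold and dv[i - 1] < dvdt_threshold:
            thr_idx = i
            break
    if thr_idx is None:
        raise MeasurementError("no dV/dt threshold crossing before the peak")
    threshold = float(v[thr_idx])
    amplitude = float(v[peak_idx] - threshold)
    if amplitude <= 0:
        raise MeasurementError("peak does not rise above threshold")

    trough_rel = int(np.argmin(v[peak_idx : peak_idx + ahp_n + 1]))
    trough_idx = peak_idx + trough_rel
    ahp = float(threshold - v[trough_idx])

    half = threshold + amplitude / 2.0

    def _interp_cross(i0: int, i1: int, rising: bool) -> float:
        """Time (sample units) of the half-level crossing in [i0, i1]."""
        rng_ = range(i1, i0, -1) if rising else range(i0 + 1, i1 + 1)
        for i in rng_:
            a, b = v[i - 1], v[i]
            if (a < half <= b) if rising else (a >= half > b):
                return (i - 1) + (half - a) / (b - a)
        raise MeasurementError("no half-amplitude crossing found")

    up = _interp_cross(thr_idx - 1, peak_idx, rising=True)
    down = _interp_cross(peak_idx, trough_idx, rising=False)
    half_width = float((down - up) * dt_ms)

    window = dv[thr_idx : trough_idx + 1]
    max_rise = float(window.max())
    max_fall = float(-window.min())
    return APFeatures(
        threshold=threshold,
        amplitude=amplitude,
        half_width=half_width,
        max_rise=max_rise,
        max_fall=max_fall,
        ahp=ahp,
        peak_time=trace.start_time + peak_idx / rate,
    )


def evoked_firing_metrics(
    trace: Trace, protocol: StimulusProtocol, **detect_kwargs
) -> tuple[float, float, int]:
    """(firing rate Hz, first-spike latency ms, spike count) for one step.

    Counts spikes whose peaks fall within the current step; latency is
    the first spike peak minus step onset.  Sweeps without spikes return
    (0.0, nan, 0).
    """
    if protocol.step_onset is None or protocol.step_duration is None:
        raise ParameterError("protocol lacks a current-step definition")
    spikes = detect_spikes(trace, **detect_kwargs)
    t0, t1 = protocol.step_onset, protocol.step_onset + protocol.step_duration
    in_step = spikes[(spikes >= t0) & (spikes < t1)]
    count = int(in_step.size)
    rate = count / protocol.step_duration
    latency = float((in_step[0] - t0) * 1e3) if count else float("nan")
    return rate, latency, count


def spontaneous_rate(trace_or_events, duration: float | None = None) -> float:
    """Spike count divided by duration (Hz).

    Accepts a voltage Trace (spikes are detected) or an array of spike
    times with an explicit ``duration``.
    """
    if isinstance(trace_or_events, Trace):
        events = detect_spikes(trace_or_events)
        if duration is None:
            duration = trace_or_events.duration
    else:
        events = np.asarray(trace_or_events, dtype=float)
        if duration is None:
            raise ParameterError("duration required when passing spike times")
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    return events.size / duration


def input_resistance(steps) -> float:
    """Input resistance (MOhm) from (delta-I pA, steady-state delta-V mV) steps.

    Ordinary least squares on the step points plus the origin (zero
    current gives zero deflection by definition).
    """
    steps = np.asarray(steps, dtype=float).reshape(-1, 2)
    if steps.shape[0] < 1 or np.all(steps[:, 0] == 0):
        raise ParameterError("need at least one step with nonzero current")
    di = np.concatenate([[0.0], steps[:, 0]])
    dv = np.concatenate([[0.0], steps[:, 1]])
    xm, ym = di.mean(), dv.mean()
    slope = np.sum((di - xm) * (dv - ym)) / np.sum((di - xm) ** 2)
    return float(slope * 1e3)  # mV/pA -> MOhm
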