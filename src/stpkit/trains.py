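"""Evoked IPSC train analysis: amplitudes, PPR, depression and the two
cumulative-amplitude estimators of release probability and pool size.

Train method: cumulative normalized IPSC amplitude is plotted against
stimulus number and the late, linear portion (stimuli 33-40 of a 40 x
100 Hz train by default) is fit by ordinary least squares.  The y-intercept
is the readily releasable pool relative to the first response (since the
first normalized IPSC is 1, release probability is its reciprocal) and the
slope is proportional to the vesicle replenishment rate.

EQ (Elmqvist-Quastel) method: each normalized IPSC is plotted against the
cumulative amplitude of the *preceding* IPSCs and the first 5 points are
fit; the x-intercept is the relative pool and the reciprocal of the
x-intercept is the release probability.  For a purely geometric
(depleting, non-replenishing) train this plot is exactly linear, so the
estimator is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundsError, ParameterError, ShapeError
from .signal_core import StimulusProtocol, Trace

__all__ = [
    "TrainEstimates",
    "measure_train_amplitudes",
    "normalize_amplitudes",
    "paired_pulse_ratio",
    "steady_state_depression",
    "train_method",
    "eq_method",
]


@dataclass
class TrainEstimates:
    """Result of one cumulative-IPSC fit."""

    method: str                 # 'train' or 'eq'
    rrp_rel: float              # pool size relative to the first IPSC
    p_r_est: float              # estimated release probability
    repl_slope_rel: float | None  # per-stimulus replenishment (train method)
    fit_intercept: float
    fit_slope: float
    fit_r2: float
    fit_range: tuple[int, int]  # 1-based stimulus indices used, inclusive
    valid: bool = True


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares line; returns (slope, intercept, r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = np.sum((y - slope * x - intercept) ** 2)
    ss_tot = np.sum((y - ym) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def measure_train_amplitudes(
    trace: Trace,
    protocol: StimulusProtocol,
    window: tuple[float, float] = (0.5e-3, 8e-3),
    baseline_window: float | None = None,
    baseline_mode: str = "extrapolate",
    peak_average_halfwidth: float = 0.0,
) -> np.ndarray:
    """Per-stimulus IPSC amplitudes (pA magnitudes) from an averaged trace.

    The response latency is located once, on the first (largest) response,
    as the extremal deviation from a linear pre-stimulus baseline within
    ``window`` (s, relative to the stimulus).  Each amplitude is then the
    deviation at that fixed latency (optionally averaged over +/-
    ``peak_average_halfwidth`` seconds) from the local baseline.

    With ``baseline_mode='extrapolate'`` (default) the baseline is a
    quadratic fit over ``baseline_window`` seconds immediately
    pre-stimulus extrapolated under the response, which removes the
    curved, decaying tails of earlier responses during 100 Hz trains;
    ``'constant'`` subtracts the pre-stimulus mean only.  The default
    baseline window is 5 ms (clamped below the inter-stimulus interval),
    or 1 ms in constant mode.
    """
    if protocol.n_stimuli < 1:
        raise ParameterError("protocol must contain at least one stimulus")
    if baseline_mode not in ("constant", "extrapolate"):
        raise ParameterError(f"unknown baseline_mode {baseline_mode!r}")
    if baseline_window is None:
        baseline_window = 5e-3 if baseline_mode == "extrapolate" else 1e-3
    times = protocol.stimulus_times
    if times.size > 1:
        baseline_window = min(baseline_window, 0.8 * float(np.min(np.diff(times))))
    y = trace.samples
    rate = trace.sampling_rate

    # latency of the response extremum, from the first stimulus
    t0 = times[0]
    i0, i1 = trace.index_of(t0 + window[0]), trace.index_of(t0 + window[1])
    b0, b1 = trace.index_of(t0 - min(baseline_window, 1e-3)), trace.index_of(t0)
    if b0 < 0 or i1 > trace.n_samples or i0 >= i1:
        raise BoundsError("measurement window for stimulus 1 exceeds trace")
    bx = np.arange(b0, b1, dtype=float)
    slope, intercept, _ = _ols(bx, y[b0:b1])
    dev0 = y[i0:i1] - (intercept + slope * np.arange(i0, i1, dtype=float))
    latency = i0 + int(np.argmax(np.abs(dev0))) - trace.index_of(t0)
    half = max(int(round(peak_average_halfwidth * rate)), 0)

    amps = np.empty(times.size)
    for k, t in enumerate(times):
        s = trace.index_of(t)
        b0, b1 = trace.index_of(t - baseline_window), s
        lo, hi = s + latency - half, s + latency + half + 1
        if b0 < 0 or hi > trace.n_samples:
            raise BoundsError(f"measurement window for stimulus {k + 1} exceeds trace")
        if baseline_mode == "constant" or b1 - b0 < 4:
            pred = np.full(hi - lo, y[b0:b1].mean())
        else:
            coef = np.polyfit(np.arange(b0, b1, dtype=float), y[b0:b1], 2)
            pred = np.polyval(coef, np.arange(lo, hi, dtype=float))
        amps[k] = abs(float(np.mean(y[lo:hi] - pred)))
    return amps


def normalize_amplitudes(amps: np.ndarray) -> np.ndarray:
    """Divide by the first amplitude; the first element becomes 1."""
    amps = np.asarray(amps, dtype=float)
    if amps.size < 1:
        raise ShapeError("need at least one amplitude")
    if amps[0] <= 0:
        raise ParameterError("first amplitude must be > 0 to normalize")
    return amps / amps[0]


def paired_pulse_ratio(amps: np.ndarray) -> float:
    """Second amplitude over first (50 ms ISI pairs by convention)."""
    amps = np.asarray(amps, dtype=float)
    if amps.size < 2:
        raise ShapeError("paired-pulse ratio needs at least two amplitudes")
    if amps[0] <= 0:
        raise ParameterError("first amplitude must be > 0")
    return float(amps[1] / amps[0])


def steady_state_depression(norm: np.ndarray, n_last: int = 5) -> float:
    """Mean of the last ``n_last`` normalized amplitudes."""
    norm = np.asarray(norm, dtype=float)
    if norm.size < n_last:
        raise ShapeError(f"need at least {n_last} amplitudes, got {norm.size}")
    return float(norm[-n_last:].mean())


def train_method(
    norm: np.ndarray, fit_range: tuple[int, int] = (33, 40)
) -> TrainEstimates:
    """Cumulative-amplitude ('Train') estimator.

    ``fit_range`` gives the first and last stimulus (1-based, inclusive)
    of the late linear fit.  A non-positive y-intercept (a non-depressing
    input) yields ``valid=False`` rather than an exception.
    """
    norm = np.asarray(norm, dtype=float)
    lo, hi = fit_range
    if not 1 <= lo < hi:
        raise ParameterError(f"bad fit_range {fit_range}")
    if norm.size < hi:
        raise ShapeError(f"need {hi} amplitudes for fit_range {fit_range}")
    cum = np.cumsum(norm)
    x = np.arange(lo, hi + 1, dtype=float)
    y = cum[lo - 1 : hi]
    slope, intercept, r2 = _ols(x, y)
    valid = intercept > 0
    return TrainEstimates(
        method="train",
        rrp_rel=intercept,
        p_r_est=1.0 / intercept if valid else float("nan"),
        repl_slope_rel=slope,
        fit_intercept=intercept,
        fit_slope=slope,
        fit_r2=r2,
        fit_range=(lo, hi),
        valid=valid,
    )


def eq_method(norm: np.ndarray, n_points: int = 5) -> TrainEstimates:
    """Elmqvist-Quastel estimator.

    Plots IPSC_k against the cumulative amplitude of the preceding IPSCs
    (exclusive convention; the x-intercept is identical under the
    inclusive one) and fits the first ``n_points`` points.  A
    non-negative fitted slope (no depression) yields ``valid=False``.
    """
    norm = np.asarray(norm, dtype=float)
    if norm.size < n_points + 1:
        raise ShapeError(f"need at least {n_points + 1} amplitudes")
    cum_prev = np.concatenate([[0.0], np.cumsum(norm)[:-1]])
    x = cum_prev[:n_points]
    y = norm[:n_points]
    slope, intercept, r2 = _ols(x, y)
    valid = slope < 0
    x_int = -intercept / slope if valid else float("nan")
    valid = valid and x_int > 0
    return TrainEstimates(
        method="eq",
        rrp_rel=x_int,
        p_r_est=norm[0] / x_int if valid else float("nan"),
        repl_slope_rel=None,
        fit_intercept=intercept,
        fit_slope=slope,
        fit_r2=r2,
        fit_range=(1, n_points),
        valid=valid,
    )
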