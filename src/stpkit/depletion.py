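"""Vesicle depletion-and-replenishment model of short-term depression.

Each stimulus releases a fraction ``p_r`` of the readily releasable pool
``N`` and the postsynaptic response is ``N * p_r * Q``.  Between stimuli
the pool is refilled at a constant rate (vesicles/s).  The deterministic
mode propagates expected values; the stochastic mode draws binomial
release counts per stimulus (replenishment stays deterministic).

The uncapped deterministic train has the closed form

    n_k / n0 = r/p + (1 - r/p) * (1 - p)^(k-1),   r = repl_rate * ISI / n0

which serves as the analytic oracle for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .signal_core import StimulusProtocol

__all__ = [
    "DepletionParams",
    "AmplitudeSeries",
    "simulate_train",
    "simulate_recovery",
    "closed_form_train",
]


@dataclass(frozen=True)
class DepletionParams:
    """Model parameters.

    n0 : initial releasable vesicles (> 0)
    p_r : release probability per stimulus, in [0, 1]
    q : quantal postsynaptic amplitude, pA per vesicle (> 0)
    repl_rate : replenishment, vesicles/s (>= 0), constant during a train
    mode : 'deterministic' (expected value) or 'stochastic' (binomial)
    pool_cap : clamp pool at n0; ``None`` means off for trains and on for
        recovery simulations (ratios must saturate at 1)
    """

    n0: float = 100.0
    p_r: float = 0.2
    q: float = 1.0
    repl_rate: float = 0.0
    mode: str = "deterministic"
    pool_cap: bool | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_r <= 1.0:
            raise ParameterError(f"p_r must lie in [0, 1], got {self.p_r}")
        if not self.n0 > 0:
            raise ParameterError(f"n0 must be > 0, got {self.n0}")
        if not self.q > 0:
            raise ParameterError(f"q must be > 0, got {self.q}")
        if self.repl_rate < 0:
            raise ParameterError(f"repl_rate must be >= 0, got {self.repl_rate}")
        if self.mode not in ("deterministic", "stochastic"):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass
class AmplitudeSeries:
    """Per-stimulus bookkeeping of one simulated train."""

    pool_before: np.ndarray   # vesicles available just before each release
    released: np.ndarray      # vesicles released per stimulus
    amplitude: np.ndarray     # pA, released * q

    def __post_init__(self):
        self.pool_before = np.asarray(self.pool_before, dtype=float)
        self.released = np.asarray(self.released, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)

    @property
    def normalized(self) -> np.ndarray:
        """Amplitudes divided by the first amplitude (first element = 1)."""
        if self.amplitude[0] <= 0:
            raise ParameterError("first amplitude must be > 0 to normalize")
        return self.amplitude / self.amplitude[0]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus": np.arange(1, len(self.amplitude) + 1),
                "pool_before": self.pool_before,
                "released": self.released,
                "amplitude_pA": self.amplitude,
                "normalized": self.amplitude / self.amplitude[0]
                if self.amplitude[0] > 0
                else np.nan,
            }
        )


def _release(n: float, p: float, rng: np.random.Generator | None, stochastic: bool) -> float:
    if stochastic:
        drawn = float(rng.binomial(int(round(n)), p))
        return min(drawn, n)  # never release more than the (fractional) pool
    return p * n


def simulate_train(
    params: DepletionParams,
    protocol: StimulusProtocol,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AmplitudeSeries:
    """Simulate one stimulus train.

    Release happens at each stimulus time; replenishment accrues over
    each inter-stimulus interval (increment = repl_rate * dt) after
    release.  With ``pool_cap`` the pool is clamped at ``n0``.
    """
    times = protocol.stimulus_times
    if times.size < 1:
        raise ParameterError("protocol must contain at least one stimulus")
    stochastic = params.mode == "stochastic"
    if stochastic and rng is None:
        if seed is None:
            raise ConfigurationError("stochastic mode requires a seed (or rng)")
        rng = np.random.default_rng(seed)
    cap = bool(params.pool_cap) if params.pool_cap is not None else False

    n = params.n0
    pool_before = np.empty(times.size)
    released = np.empty(times.size)
    for k in range(times.size):
        pool_before[k] = n
        rel = _release(n, params.p_r, rng, stochastic)
        released[k] = rel
        n = n - rel
        assert n >= -1e-9, "pool went negative"
        if k + 1 < times.size:
            n += params.repl_rate * (times[k + 1] - times[k])
            if cap:
                n = min(n, params.n0)
    return AmplitudeSeries(pool_before, released, released * params.q)


def simulate_recovery(
    params: DepletionParams,
    protocol: StimulusProtocol,
    intervals: Sequence[float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Depleting train followed by a single test stimulus per interval.

    Replenishment continues through the recovery interval; by default the
    pool is capped at ``n0`` during recovery so ratios saturate at 1.
    Returns a table of (interval_s, recovery_ratio).
    """
    intervals = np.asarray(list(intervals), dtype=float)
    if intervals.size == 0:
        raise ParameterError("need at least one recovery interval")
    if np.any(intervals <= 0):
        raise ParameterError("recovery intervals must be > 0")
    cap = True if params.pool_cap is None else bool(params.pool_cap)
    stochastic = params.mode == "stochastic"
    if stochastic and seed is None:
        raise ConfigurationError("stochastic mode requires a seed")

    ratios = np.empty(intervals.size)
    for i, interval in enumerate(intervals):
        rng = np.random.default_rng(seed + i) if stochastic else None
        train = simulate_train(replace(params, pool_cap=cap), protocol, rng=rng)
        # pool left after the last release, then refill over the interval
        n_end = train.pool_before[-1] - train.released[-1]
        n_rec = n_end + params.repl_rate * interval
        if cap:
            n_rec = min(n_rec, params.n0)
        rel = _release(n_rec, params.p_r, rng, stochastic)
        ratios[i] = (rel * params.q) / train.amplitude[0]
    return pd.DataFrame({"interval_s": intervals, "recovery_ratio": ratios})


def closed_form_train(
    params: DepletionParams, n_stimuli: int, isi: float = 0.010
) -> np.ndarray:
    """Analytic normalized amplitudes for the uncapped deterministic train.

    Valid for regular inter-stimulus interval ``isi`` and pool cap off.
    """
    if params.mode != "deterministic":
        raise ParameterError("closed form applies to deterministic mode only")
    if params.pool_cap:
        raise ParameterError("closed form applies with pool cap off")
    p = params.p_r
    if p == 0:
        raise ParameterError("closed form undefined for p_r = 0")
    r = params.repl_rate * isi / params.n0
    k = np.arange(1, n_stimuli + 1)
    return (r / p) + (1.0 - r / p) * (1.0 - p) ** (k - 1)
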