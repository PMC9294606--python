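"""Recovery from short-term depression.

After a depleting 100 Hz train, a single test stimulus probes the pool at
intervals of 50-4,000 ms; recovery is the test IPSC amplitude over the
first IPSC of the train.  An optional single-exponential fit
R(t) = plateau - (plateau - floor) * exp(-t/tau) summarizes the curve
(the underlying capped-linear refill of the depletion model is not
exponential, so residuals are reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ParameterError, ShapeError

__all__ = ["RecoveryCurve", "RecoveryFit", "recovery_ratios", "fit_recovery",
           "DEFAULT_INTERVALS"]

# the experimental interval grid, 50 ms to 4 s
DEFAULT_INTERVALS = np.array([0.05, 0.1, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0])


@dataclass
class RecoveryFit:
    tau_recovery: float  # s
    floor: float
    plateau: float
    rss: float           # residual sum of squares
    degenerate: bool = False


@dataclass
class RecoveryCurve:
    intervals: np.ndarray          # s, ascending
    ratios: np.ndarray
    n: np.ndarray | None = None    # observations per point
    fit: RecoveryFit | None = None

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.intervals.size != self.ratios.size:
            raise ShapeError("intervals and ratios must have equal length")
        if self.intervals.size > 1 and not np.all(np.diff(self.intervals) > 0):
            raise ParameterError("intervals must be strictly ascending")
        if not np.all(np.isfinite(self.ratios)):
            raise ParameterError("ratios must be finite")

    def as_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"interval_s": self.intervals, "recovery_ratio": self.ratios})
        if self.n is not None:
            out["n"] = self.n
        return out


def recovery_ratios(train_amps: np.ndarray, tests: pd.DataFrame) -> RecoveryCurve:
    """Ratio of each test amplitude to the first amplitude of the train.

    ``tests`` must carry columns ``interval_s`` and ``amplitude`` (pA).
    """
    train_amps = np.asarray(train_amps, dtype=float)
    if train_amps.size < 1 or train_amps[0] <= 0:
        raise ParameterError("first train amplitude must be > 0")
    for col in ("interval_s", "amplitude"):
        if col not in tests.columns:
            raise ShapeError(f"tests table lacks column {col!r}")
    order = np.argsort(tests["interval_s"].to_numpy())
    intervals = tests["interval_s"].to_numpy()[order]
    ratios = tests["amplitude"].to_numpy()[order] / train_amps[0]
    return RecoveryCurve(intervals, ratios)


def fit_recovery(curve: RecoveryCurve, plateau_max: float = 1.2) -> RecoveryFit:
    """Least-squares single-exponential fit of the recovery curve.

    Initialization: plateau 1, floor = first ratio, tau = median interval.
    A flat curve (negligible variance) returns a degenerate flag instead
    of fit parameters.
    """
    if curve.intervals.size < 4:
        raise ShapeError("recovery fit needs at least 4 distinct intervals")
    t, r = curve.intervals, curve.ratios
    if np.var(r) < 1e-12:
        fit = RecoveryFit(float("nan"), float(r.mean()), float(r.mean()),
                          0.0, degenerate=True)
        curve.fit = fit
        return fit

    def model(tt, tau, floor, plateau):
        return plateau - (plateau - floor) * np.exp(-tt / tau)

    p0 = (float(np.median(t)), float(r[0]), 1.0)
    bounds = ([1e-6, -np.inf, -np.inf], [np.inf, np.inf, plateau_max])
    popt, _ = curve_fit(model, t, r, p0=p0, bounds=bounds, maxfev=20000)
    rss = float(np.sum((model(t, *popt) - r) ** 2))
    fit = RecoveryFit(float(popt[0]), float(popt[1]), float(popt[2]), rss)
    curve.fit = fit
    return fit
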