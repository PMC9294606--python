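"""Two-group comparison mirroring a classic ephys analysis workflow:
unpaired two-tailed Student's t-test (pooled variance), with Welch's
variant available by flag.  No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

__all__ = ["GroupComparison", "group_compare"]


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p: float
    variant: str


def group_compare(
    a,
    b,
    variant: str = "student",
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of per-cell values.

    The Student variant pools variances (df = n_a + n_b - 2); the Welch
    variant uses the Welch-Satterthwaite df.  Two identical groups with
    zero pooled variance return t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ParameterError(f"unknown variant {variant!r}")
    import warnings

    with warnings.catch_warnings():
        # identical groups trigger a harmless precision warning; the t=0,
        # p=1 convention is applied below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if not np.isfinite(t):  # zero variance in both groups
        t = 0.0
        p = 1.0
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        t=t,
        df=df,
        p=p,
        variant=variant,
    )
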