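"""Cross-test agreement and power-law structure of digit-partitioned data.

Kendall rank correlation measures how far independent conformity
statistics order a set of datasets the same way. Log-log ordinary least
squares fits power laws ``y = a * x^b``: the Benford probabilities
themselves are closely power-law in the digit index, and Taylor's
power law ``V = a * M^b`` relates the variance to the mean of
measurements grouped by first-digit category, with an exponent near 2
indicating an aggregated spatial pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .core import PreprocessPolicy, significant_digits, tally_digits

__all__ = [
    "kendall_tau",
    "PowerFit",
    "loglog_power_fit",
    "DigitPartitionStats",
    "digit_partition_stats",
]


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b rank correlation (reduces to tau-a when tie-free)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError(f"Kendall tau needs at least 2 pairs, got {x.size}")
    return float(_sps.kendalltau(x, y).statistic)


@dataclass(frozen=True)
class PowerFit:
    """OLS fit of log10(y) = log10(a) + b*log10(x), i.e. y = a * x^b."""

    coefficient: float  # a
    exponent: float  # b
    r_loglog: float
    n_points: int

    @property
    def r_squared_loglog(self) -> float:
        return self.r_loglog**2

    def predict(self, x):
        return self.coefficient * np.asarray(x, dtype=float) ** self.exponent


def loglog_power_fit(x: Sequence[float], y: Sequence[float]) -> PowerFit:
    """Fit a power law by ordinary least squares in log10-log10 space."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"power-law fit needs at least 3 points, got {x.size}")
    for name, v in (("x", x), ("y", y)):
        if (v <= 0).any():
            bad = v[v <= 0][0]
            raise ValueError(f"power-law fit requires positive {name}; offending value {bad!r}")
    res = _sps.linregress(np.log10(x), np.log10(y))
    return PowerFit(
        coefficient=float(10**res.intercept),
        exponent=float(res.slope),
        r_loglog=float(res.rvalue),
        n_points=int(x.size),
    )


@dataclass(frozen=True)
class DigitPartitionStats:
    """Measurements partitioned by first digit, with per-class moments.

    ``variances[d]`` is the sample variance (n-1 denominator); classes
    with fewer than two members have variance NaN and are excluded by
    :meth:`taylor_xy` from downstream mean-variance fits.
    """

    members: Mapping[int, tuple[float, ...]]
    means: Mapping[int, float]
    variances: Mapping[int, float]

    def taylor_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """(mean, variance) pairs over digit classes with defined variance."""
        ds = [d for d in sorted(self.means) if np.isfinite(self.variances[d])]
        return (
            np.array([self.means[d] for d in ds]),
            np.array([self.variances[d] for d in ds]),
        )


def digit_partition_stats(
    values: Iterable[float], policy: PreprocessPolicy = PreprocessPolicy()
) -> DigitPartitionStats:
    """Group measurements by first significant digit; mean/variance per class."""
    arr = np.asarray(list(values), dtype=float)
    tally_digits(arr, policy)  # validates and enforces the preprocessing contract
    arr = arr[arr != 0]
    arr = np.abs(arr) if policy.negatives == "abs" else arr[arr > 0]
    digits = significant_digits(arr)
    members: dict[int, tuple[float, ...]] = {}
    means: dict[int, float] = {}
    variances: dict[int, float] = {}
    for d in range(1, 10):
        vals = arr[digits == d]
        if vals.size == 0:
            continue
        members[d] = tuple(float(v) for v in vals)
        means[d] = float(vals.mean())
        variances[d] = float(vals.var(ddof=1)) if vals.size >= 2 else float("nan")
    return DigitPartitionStats(members, means, variances)
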