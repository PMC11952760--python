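"""Conformity statistics between observed and Benford digit distributions.

Five complementary measures of distance between an observed first-digit
distribution OBS and the Benford reference EXP:

* Morrow's sample-size-scaled Euclidean distance
  ``d*_n = sqrt(n) * ||OBS - EXP||_2`` — supports inference against
  simulated critical values (1.22 / 1.33 / 1.57 at alpha 0.10/0.05/0.01).
* Kossovsky's sum of squared deviations
  ``SSD = sum((OBS - EXP)^2) * 1e4`` — descriptive, n-free.
* Cohen's W effect size ``sqrt(sum((OBS - EXP)^2 / EXP))`` — n-free,
  with conventional 0.1 / 0.3 / 0.5 weak/moderate/strong anchors.
* Signed Pearson residuals per digit,
  ``(count_d - n*EXP_d) / sqrt(n*EXP_d)`` — microscopic, |PR| >= 1.96
  flags an individual digit at the 5% level.
* Kullback-Leibler divergence ``sum(OBS * log10(OBS/EXP))`` in Hartley
  units (log base 10) — information loss relative to the reference.

The two scale families obey the exact identity
``d*_n^2 = n * SSD * 1e-4``, used as an internal consistency check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BENFORD_PROBS, DigitTally, as_distribution

__all__ = [
    "morrow_distance",
    "kossovsky_ssd",
    "cohen_w",
    "pearson_residuals",
    "kl_divergence",
    "simpson_index",
    "percentage_difference",
    "ConformityReport",
    "conformity_report",
]


def _ref(ref: Sequence[float] | None) -> np.ndarray:
    return BENFORD_PROBS if ref is None else as_distribution(ref)


def morrow_distance(tally: DigitTally, ref: Sequence[float] | None = None) -> float:
    """Sample-size-scaled Euclidean distance d*_n = sqrt(n)*||OBS - EXP||."""
    if tally.n == 0:
        raise ValueError("Morrow distance requires a non-empty tally (n > 0)")
    diff = tally.proportions() - _ref(ref)
    return float(np.sqrt(tally.n) * np.sqrt(np.sum(diff**2)))


def kossovsky_ssd(obs: Sequence[float], ref: Sequence[float] | None = None) -> float:
    """Sum of squared probability deviations scaled by 10^4."""
    diff = as_distribution(obs) - _ref(ref)
    return float(np.sum(diff**2) * 1e4)


def cohen_w(obs: Sequence[float], ref: Sequence[float] | None = None) -> float:
    """Cohen's W effect size sqrt(sum((OBS - EXP)^2 / EXP))."""
    e = _ref(ref)
    diff = as_distribution(obs) - e
    return float(np.sqrt(np.sum(diff**2 / e)))


def pearson_residuals(tally: DigitTally, ref: Sequence[float] | None = None) -> np.ndarray:
    """Signed per-digit residuals (count_d - n*EXP_d) / sqrt(n*EXP_d)."""
    if tally.n == 0:
        raise ValueError("Pearson residuals require a non-empty tally (n > 0)")
    expected = tally.n * _ref(ref)
    return (tally.as_array() - expected) / np.sqrt(expected)


def kl_divergence(
    obs: Sequence[float], ref: Sequence[float] | None = None, *, base: float = 10.0
) -> float:
    """Kullback-Leibler divergence of OBS from EXP.

    Base 10 by default, so the result is in Hartley units. Empty
    observed cells contribute 0 (the x*log x -> 0 limit); the Benford
    reference has no zero cells, so no smoothing is needed.
    """
    p = as_distribution(obs)
    q = _ref(ref)
    mask = p > 0
    terms = p[mask] * (np.log(p[mask] / q[mask]) / np.log(base))
    return float(np.sum(terms))


def simpson_index(obs: Sequence[float]) -> float:
    """Simpson concentration over the nine digit-probability categories.

    ``D = sum(p_d^2)``: 1/9 for uniform digit use, 1 when a single digit
    carries all mass; 0.165 for the Benford reference itself.
    """
    p = as_distribution(obs)
    return float(np.sum(p**2))


def percentage_difference(a: float, b: float) -> float:
    """Symmetric percentage difference |a-b| / mean(a,b) * 100."""
    if a < 0 or b < 0:
        raise ValueError(f"percentage difference expects non-negative inputs, got {a!r}, {b!r}")
    if a + b == 0:
        raise ValueError("percentage difference undefined when both values are zero")
    return float(abs(a - b) / ((a + b) / 2.0) * 100.0)


@dataclass(frozen=True)
class ConformityReport:
    """Full-precision bundle of every conformity statistic for one tally."""

    n: int
    morrow_d: float
    ssd: float
    cohen_w: float
    pearson_residuals: tuple[float, ...]
    kl_d: float
    simpson_d: float

    @property
    def max_abs_residual(self) -> float:
        return max(abs(r) for r in self.pearson_residuals)

    def display(self) -> dict:
        """Rounded values at the precision used in published summaries."""
        return {
            "n": self.n,
            "d*_n": round(self.morrow_d, 3),
            "SSD": round(self.ssd, 1) if self.ssd >= 10 else round(self.ssd, 2),
            "Cohen-W": round(self.cohen_w, 3),
            "max |PR|": round(self.max_abs_residual, 2),
            "KL_D (Hartley)": round(self.kl_d, 4),
            "Simpson D": round(self.simpson_d, 3),
        }

    def to_json(self) -> str:
        payload = {
            "n": self.n,
            "morrow_d": self.morrow_d,
            "ssd": self.ssd,
            "cohen_w": self.cohen_w,
            "pearson_residuals": list(self.pearson_residuals),
            "kl_d": self.kl_d,
            "simpson_d": self.simpson_d,
            "display": self.display(),
        }
        return json.dumps(payload, indent=2)


def conformity_report(tally: DigitTally, ref: Sequence[float] | None = None) -> ConformityReport:
    """Compute all conformity statistics for one digit tally."""
    obs = tally.proportions()
    return ConformityReport(
        n=tally.n,
        morrow_d=morrow_distance(tally, ref),
        ssd=kossovsky_ssd(obs, ref),
        cohen_w=cohen_w(obs, ref),
        pearson_residuals=tuple(float(r) for r in pearson_residuals(tally, ref)),
        kl_d=kl_divergence(obs, ref),
        simpson_d=simpson_index(obs),
    )
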