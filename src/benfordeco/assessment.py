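"""Threshold-based state classification and bootstrap confidence intervals.

Each conformity statistic maps to one of three states via fixed
cut-points: ``conform``, ``transition_signal`` (the open window between
the conformity and non-conformity bounds, read as an impending state
transition either toward or away from the Benford steady state), or
``nonconform``. The overall verdict is the worst individual state —
a weight-of-evidence summary in which any flagged method dominates —
with the per-method verdicts always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as _t_dist

from .core import BENFORD_PROBS, DigitTally
from .stats import ConformityReport, cohen_w, kossovsky_ssd

__all__ = [
    "State",
    "ThresholdConfig",
    "MethodVerdict",
    "Assessment",
    "classify",
    "BootstrapCI",
    "bootstrap_ci",
    "summarize_cases",
]


class State(str, Enum):
    CONFORM = "conform"
    TRANSITION_SIGNAL = "transition_signal"
    NONCONFORM = "nonconform"


_SEVERITY = {State.CONFORM: 0, State.TRANSITION_SIGNAL: 1, State.NONCONFORM: 2}


@dataclass(frozen=True)
class ThresholdConfig:
    """Cut-points for the four threshold-based methods.

    Non-conformity bounds are closed (statistic >= bound rejects);
    transition-signal windows are open intervals just below them.
    Defaults follow the published protocol: Euclidean-distance critical
    values 1.22/1.33/1.57 (alpha 0.10/0.05/0.01, rejection at the 0.05
    value), SSD <= 25 moderate-to-strong conformity with 75-100 signal
    window, Cohen-W 0.1/0.3/0.5 anchors with 0.3-0.5 signal window, and
    a z-based residual rule: two or more |PR| >= 1.96 is non-conformity,
    exactly one a signal.
    """

    morrow_alpha10: float = 1.22
    morrow_alpha05: float = 1.33
    morrow_alpha01: float = 1.57
    ssd_conform: float = 25.0
    ssd_signal_low: float = 75.0
    ssd_nonconform: float = 100.0
    w_weak: float = 0.1
    w_signal_low: float = 0.3
    w_nonconform: float = 0.5
    pr_z: float = 1.96
    pr_nonconform_count: int = 2
    pr_signal_count: int = 1
    pd_nominal: float = 10.0

    def __post_init__(self) -> None:
        if not (self.morrow_alpha10 < self.morrow_alpha05 < self.morrow_alpha01):
            raise ValueError("Morrow critical values must increase with confidence level")
        if not (self.ssd_signal_low < self.ssd_nonconform):
            raise ValueError("SSD signal window must lie below the non-conformity bound")
        if not (self.w_signal_low < self.w_nonconform):
            raise ValueError("Cohen-W signal window must lie below the non-conformity bound")


@dataclass(frozen=True)
class MethodVerdict:
    method: str  # "morrow" | "ssd" | "cohen_w" | "pearson"
    state: State
    statistic: float
    note: str = ""


@dataclass(frozen=True)
class Assessment:
    verdicts: tuple[MethodVerdict, ...]
    overall: State

    def by_method(self) -> Mapping[str, MethodVerdict]:
        return {v.method: v for v in self.verdicts}


def _window_state(x: float, signal_low: float, nonconform: float) -> State:
    if x >= nonconform:
        return State.NONCONFORM
    if signal_low < x < nonconform:
        return State.TRANSITION_SIGNAL
    return State.CONFORM


def classify(report: ConformityReport, config: ThresholdConfig = ThresholdConfig()) -> Assessment:
    """Map a conformity report to per-method and overall verdicts.

    The Pearson rule counts digits with |PR| at or above the z cut —
    absolute values, since a large deficit in a digit class is as strong
    a departure as a large excess.
    """
    verdicts = []

    verdicts.append(
        MethodVerdict(
            "morrow",
            _window_state(report.morrow_d, config.morrow_alpha10, config.morrow_alpha05),
            report.morrow_d,
        )
    )

    ssd_state = _window_state(report.ssd, config.ssd_signal_low, config.ssd_nonconform)
    note = "moderate to strong conformity" if report.ssd <= config.ssd_conform else ""
    verdicts.append(MethodVerdict("ssd", ssd_state, report.ssd, note))

    verdicts.append(
        MethodVerdict(
            "cohen_w",
            _window_state(report.cohen_w, config.w_signal_low, config.w_nonconform),
            report.cohen_w,
        )
    )

    n_flagged = sum(1 for r in report.pearson_residuals if abs(r) >= config.pr_z)
    if n_flagged >= config.pr_nonconform_count:
        pr_state = State.NONCONFORM
    elif n_flagged >= config.pr_signal_count:
        pr_state = State.TRANSITION_SIGNAL
    else:
        pr_state = State.CONFORM
    verdicts.append(
        MethodVerdict("pearson", pr_state, report.max_abs_residual, f"{n_flagged} digit(s) flagged")
    )

    overall = max((v.state for v in verdicts), key=_SEVERITY.__getitem__)
    return Assessment(tuple(verdicts), overall)


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    sd_boot: float
    B: int
    seed: int
    statistic: str
    mode: str = "t9"


_STATISTICS: dict[str, Callable[[np.ndarray], float]] = {
    "ssd": lambda p: kossovsky_ssd(p),
    "cohen_w": lambda p: cohen_w(p),
}


def bootstrap_ci(
    tally: DigitTally,
    statistic: str = "ssd",
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    mode: str = "t9",
) -> BootstrapCI:
    """Bootstrap CI for an n-free conformity statistic of a digit tally.

    The n individual digit observations are resampled with replacement
    B times (equivalently, multinomial resampling of the observed digit
    proportions) and the statistic recomputed on each replicate;
    ``sd_boot`` is the sample standard deviation of the replicates.

    Two interval modes:

    * ``"t9"`` (default): half-width ``t(1-alpha/2, df=8) * sd_boot / 3``,
      i.e. a t interval treating the nine digit categories as the
      degrees-of-freedom base. This mirrors the published protocol's
      spreadsheet construction and is what its reported intervals use.
    * ``"percentile"``: the conventional (alpha/2, 1-alpha/2) percentile
      interval of the replicate distribution.
    """
    if tally.n == 0:
        raise ValueError("bootstrap requires a non-empty tally")
    if B < 2:
        raise ValueError(f"need at least 2 bootstrap replicates, got B={B}")
    try:
        stat = _STATISTICS[statistic]
    except KeyError:
        raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}, got {statistic!r}")

    rng = np.random.default_rng(seed)
    obs = tally.proportions()
    point = stat(obs)
    # resampling n digits with replacement == multinomial(n, obs)
    reps = rng.multinomial(tally.n, obs, size=B) / tally.n
    values = np.array([stat(p) for p in reps])
    sd = float(values.std(ddof=1))
    if mode == "t9":
        half = float(_t_dist.ppf(1 - alpha / 2, df=8)) * sd / 3.0
        lower, upper = point - half, point + half
    elif mode == "percentile":
        lower, upper = (float(q) for q in np.quantile(values, [alpha / 2, 1 - alpha / 2]))
    else:
        raise ValueError(f"mode must be 't9' or 'percentile', got {mode!r}")
    return BootstrapCI(point, lower, upper, sd, B, seed, statistic, mode)


def summarize_cases(
    reports: Mapping[str, ConformityReport],
    diagnostics: Mapping[str, int] | None = None,
    cis: Mapping[str, Mapping[str, BootstrapCI]] | None = None,
    config: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """One-row-per-case summary table of all conformity statistics.

    ``diagnostics`` optionally maps case name to orders of magnitude;
    ``cis`` optionally maps case name to per-statistic bootstrap CIs.
    Missing CI entries leave the column blank.
    """
    if not reports:
        raise ValueError("summarize_cases needs at least one report")
    rows = []
    for name, rep in reports.items():
        assessment = classify(rep, config)
        flagged = [v.method for v in assessment.verdicts if v.state is not State.CONFORM]
        case_cis = (cis or {}).get(name, {})

        def _ci_str(stat: str) -> str:
            ci = case_cis.get(stat)
            return f"[{ci.lower:.3g}, {ci.upper:.3g}]" if ci is not None else ""

        rows.append(
            {
                "case": name,
                "n": rep.n,
                "OM": (diagnostics or {}).get(name, pd.NA),
                "max_PR": round(rep.max_abs_residual, 2),
                "d*_n": round(rep.morrow_d, 3),
                "Cohen_W": round(rep.cohen_w, 3),
                "Cohen_W_CI": _ci_str("cohen_w"),
                "SSD": round(rep.ssd, 1) if rep.ssd >= 10 else round(rep.ssd, 2),
                "SSD_CI": _ci_str("ssd"),
                "KL_D": round(rep.kl_d, 4),
                "overall": assessment.overall.value,
                "flags": ",".join(flagged),
            }
        )
    return pd.DataFrame(rows).set_index("case")
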