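"""Synthetic generators with the digit-level structure the analysis assumes.

Four generators cover the study conditions end to end:

* :func:`gen_loguniform` — the canonical Benford-exact process: values
  ``10**U`` with ``U`` uniform over ``decades`` orders of magnitude.
  For integer ``decades`` the first-digit law is exactly Benford in
  expectation.
* :func:`gen_hill_mixture` — Hill-style aggregation: many lognormal
  components with randomly drawn location and scale. Individual
  components need not be close to Benford; their pooled sample is, on
  average, closer (lower SSD) than the typical component.
* :func:`gen_digit_tally` — a multinomial null sampler over the nine
  digit categories, for threshold calibration (e.g. type-I error of the
  Euclidean-distance test under the Benford null).
* :func:`perturb_large_digits` — thins values with leading digit 6-9,
  emulating the loss of large-leading-digit measurements seen in
  declining populations.

All generators take an explicit ``seed`` (or a ``numpy.random.Generator``)
and are bit-reproducible; there is no global RNG state.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import DigitTally, as_distribution, significant_digits

__all__ = [
    "gen_loguniform",
    "gen_hill_mixture",
    "gen_digit_tally",
    "perturb_large_digits",
]

#: Default log10-space ranges for Hill-mixture lognormal components:
#: location uniform over [-2, 4] decades, scale uniform over [0.3, 1.5].
HILL_LOC_RANGE = (-2.0, 4.0)
HILL_SCALE_RANGE = (0.3, 1.5)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_loguniform(n: int, decades: float, seed: int | np.random.Generator) -> np.ndarray:
    """Sample ``n`` values 10**U, U ~ Uniform(0, decades).

    For integer ``decades`` the induced first-digit distribution is
    exactly Benford in expectation; fractional spans under-weight the
    digits whose decade segment is truncated.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 samples, got {n}")
    if decades <= 0:
        raise ValueError(f"decades must be positive, got {decades}")
    rng = _rng(seed)
    return 10.0 ** rng.uniform(0.0, decades, size=n)


def gen_hill_mixture(
    n_dists: int,
    n_per: int,
    seed: int | np.random.Generator,
    loc_range: tuple[float, float] = HILL_LOC_RANGE,
    scale_range: tuple[float, float] = HILL_SCALE_RANGE,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pooled sample from ``n_dists`` randomly-parameterised lognormals.

    Components are lognormal in base 10: ``10**Normal(loc, scale)`` with
    ``loc ~ U(loc_range)`` and ``scale ~ U(scale_range)``, ``n_per``
    draws each. Returns ``(combined, components)`` so callers can
    compare pooled against per-component conformity.
    """
    if n_dists < 1 or n_per < 1:
        raise ValueError(f"need n_dists >= 1 and n_per >= 1, got {n_dists}, {n_per}")
    rng = _rng(seed)
    components = []
    for _ in range(n_dists):
        loc = rng.uniform(*loc_range)
        scale = rng.uniform(*scale_range)
        components.append(10.0 ** rng.normal(loc, scale, size=n_per))
    return np.concatenate(components), components


def gen_digit_tally(
    n: int, probs: Sequence[float], seed: int | np.random.Generator
) -> DigitTally:
    """Multinomial(n, probs) tally over the nine digit categories."""
    p = as_distribution(probs)
    if n < 0:
        raise ValueError(f"sample size must be non-negative, got {n}")
    rng = _rng(seed)
    return DigitTally(tuple(int(c) for c in rng.multinomial(n, p)))


def perturb_large_digits(
    values: Sequence[float], fraction: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Independently drop values with first digit in {6,7,8,9}.

    Each large-digit value is removed with probability ``fraction``,
    depleting the upper digit categories the way a decline of
    large-measurement individuals depletes them in field data.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"thinning fraction must be in [0, 1), got {fraction}")
    arr = np.asarray(values, dtype=float)
    if fraction == 0.0 or arr.size == 0:
        return arr.copy()
    rng = _rng(seed)
    large = significant_digits(np.abs(arr[arr != 0])) >= 6
    # align mask with the original array (zeros are never 'large')
    mask = np.zeros(arr.size, dtype=bool)
    mask[arr != 0] = large
    drop = mask & (rng.random(arr.size) < fraction)
    return arr[~drop]
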