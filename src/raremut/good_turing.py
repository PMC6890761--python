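"""Good-Turing probability estimation on variant frequency vectors.

For a variant observed in ``r`` of ``m`` tumors, the Good-Turing estimate of
the probability that it occurs in one additional, randomly drawn tumor is

    q_GT(r) = (r + 1) / (m + 1) * S(N_{r+1}) / S(N_r)

where ``N_r`` is the number of distinct variants observed in exactly ``r``
tumors and ``S`` is a smoothing function of the frequency-of-frequencies
vector.  The probability that a new tumor carries at least one *hitherto
unseen* variant does not require the unknown ``N_0``; it is approximated by

    p_unseen = 1 - exp(-N_1 / (m + 1)),

driven entirely by the singleton count.  Smoothing follows Simple
Good-Turing (Gale & Sampson 1995): a log-log linear fit to rank-averaged
``N_r`` supplies smoothed class sizes where the raw counts become unreliable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from raremut.catalog_io import FrequencyVector

logger = logging.getLogger(__name__)


class UnsmoothableGapError(ValueError):
    """q_GT requested at a frequency class whose successor class is empty
    and no smoothing is in effect."""


@dataclass(frozen=True)
class SmoothingSpec:
    """How to smooth N_r before forming Good-Turing ratios.

    method:
        ``"none"`` uses raw counts (S(N_r) = N_r exactly); ``"simple_good_turing"``
        fits log Z_r = a + b log r by least squares to the rank-averaged
        counts Z_r and switches from raw to fitted values at the first r
        where the raw estimate is within ``switch_z`` standard deviations of
        the fitted one (the standard Gale-Sampson switch rule).
    """

    method: str = "simple_good_turing"
    switch_z: float = 1.96

    def __post_init__(self) -> None:
        if self.method not in ("none", "simple_good_turing"):
            raise ValueError(f"unknown smoothing method {self.method!r}")


@dataclass(frozen=True)
class VariantProbability:
    scope: str
    r: int
    q: float
    smoothed: bool


def _sgt_fit(rs: np.ndarray, ns: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of log Z_r = a + b log r.

    Z_r averages N_r over the gap to the neighboring non-empty classes:
    Z_r = N_r / (0.5 * (t - q)) with q, t the previous and next non-empty
    r (q=0 at the low end; t = 2r - q at the high end).
    """
    q = np.concatenate(([0], rs[:-1]))
    t = np.concatenate((rs[1:], [2 * rs[-1] - rs[-2] if len(rs) > 1 else 2 * rs[-1]]))
    z = ns / (0.5 * (t - q))
    x = np.log(rs.astype(float))
    y = np.log(z)
    if len(x) == 1:
        return float(y[0]), 0.0
    xm, ym = x.mean(), y.mean()
    b = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    return float(ym - b * xm), b


def smooth(freq: FrequencyVector, spec: SmoothingSpec | None = None) -> Callable[[int], float]:
    """Build the smoothing function S: r -> S(N_r).

    Returns a callable defined for every r in 1..max_r+1.  With
    ``method="none"`` it returns raw counts and raises
    :class:`UnsmoothableGapError` when asked for an empty interior class
    (a gap makes the raw Good-Turing ratio zero/undefined).  With Simple
    Good-Turing, raw counts are used for small r and the log-log fit for
    large r, switching permanently once the raw and fitted values are
    statistically indistinguishable or a gap is hit.
    """
    spec = spec or SmoothingSpec()
    if not freq.counts:
        raise ValueError("cannot smooth an empty frequency vector")
    max_r = freq.max_r
    raw = {r: float(n) for r, n in freq.counts.items()}

    if spec.method == "none":

        def s_none(r: int) -> float:
            if r < 1:
                raise ValueError(f"S defined for r >= 1, got {r}")
            n = raw.get(r, 0.0)
            if n == 0.0 and r <= max_r:
                raise UnsmoothableGapError(
                    f"N_{r} = 0 in scope {freq.scope!r}: unsmoothable gap with method='none'"
                )
            return n

        return s_none

    rs = np.array(sorted(raw), dtype=int)
    ns = np.array([raw[r] for r in rs], dtype=float)
    a, b = _sgt_fit(rs, ns)

    def fitted(r: int) -> float:
        return math.exp(a + b * math.log(r))

    # Gale-Sampson switch: use raw N_r until |raw - fitted next-class ratio
    # estimate| is within switch_z SDs of the raw estimate, or a gap occurs;
    # from then on use the fitted power law for all larger r.
    switch_at = max_r + 2  # default: never (all raw)
    for r in range(1, max_r + 1):
        n_r = raw.get(r, 0.0)
        n_r1 = raw.get(r + 1, 0.0)
        if n_r == 0.0 or n_r1 == 0.0:
            switch_at = r
            break
        # SD of the raw (r+1) N_{r+1}/N_r turn estimate (Gale & Sampson)
        sd = (r + 1) / n_r * math.sqrt(n_r1 * (1.0 + n_r1 / n_r))
        raw_turn = (r + 1) * n_r1 / n_r
        sgt_turn = (r + 1) * fitted(r + 1) / fitted(r)
        if abs(raw_turn - sgt_turn) <= spec.switch_z * sd:
            switch_at = r
            break

    def s_sgt(r: int) -> float:
        if r < 1:
            raise ValueError(f"S defined for r >= 1, got {r}")
        if r < switch_at:
            return raw[r]
        return fitted(r)

    return s_sgt


def gt_probability(
    freq: FrequencyVector,
    r: int,
    s: Callable[[int], float] | None = None,
    spec: SmoothingSpec | None = None,
) -> VariantProbability:
    """Good-Turing probability that a variant seen r times recurs in a new tumor.

    Evaluates q = (r+1)/(m+1) * S(N_{r+1})/S(N_r), clamped to [0, 1] with a
    logged warning if the raw ratio exceeds 1 (possible in tiny scopes).
    Unseen variants (r = 0) are out of scope here: use
    :func:`unseen_event_probability`, which avoids the unknown N_0.
    """
    if r < 1:
        raise ValueError("r must be >= 1; unseen variants are handled separately")
    if freq.counts.get(r, 0) <= 0:
        raise ValueError(f"no variant observed exactly r={r} times in scope {freq.scope!r}")
    used_spec = spec or SmoothingSpec()
    if s is None:
        s = smooth(freq, used_spec)
        smoothed = used_spec.method != "none"
    else:
        smoothed = spec.method != "none" if spec is not None else True
    s_r = s(r)
    if s_r <= 0:
        raise ValueError(f"S(N_{r}) = {s_r} <= 0")
    try:
        s_r1 = s(r + 1)
    except UnsmoothableGapError:
        if r + 1 > freq.max_r:
            s_r1 = 0.0  # no class beyond the largest observed r
        else:
            raise
    q = (r + 1) / (freq.m + 1) * s_r1 / s_r
    if q > 1.0:
        logger.warning(
            "q_GT = %.4g > 1 clamped to 1 (scope %s, r=%d, m=%d)", q, freq.scope, r, freq.m
        )
        q = 1.0
    return VariantProbability(scope=freq.scope, r=r, q=q, smoothed=smoothed)


def expected_new_variants_per_tumor(n1: int, m: int) -> float:
    """Poisson rate of hitherto-unseen variants in one additional tumor: N_1/(m+1)."""
    if n1 < 0 or m < 1:
        raise ValueError("need N1 >= 0 and m >= 1")
    return n1 / (m + 1)


def unseen_event_probability(n1: int, m: int) -> float:
    """Probability a new tumor carries at least one hitherto-unseen variant.

    1 - exp(-N_1/(m+1)): the Good-Turing missing-mass approximation, which
    requires only the singleton count N_1 and never the unknown number of
    unobserved variants.  Monotone increasing in N_1, decreasing in m.
    """
    return 1.0 - math.exp(-expected_new_variants_per_tumor(n1, m))
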