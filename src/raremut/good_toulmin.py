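"""Good-Toulmin extrapolation of unseen-variant counts.

Given the frequency-of-frequencies vector of m sequenced tumors, Δ(t) is
the expected number of *new* distinct variants that would be discovered if
t·m additional tumors were sequenced.  The plain Good-Toulmin estimator is
the alternating series

    Δ(t) = Σ_{r>=1} (-1)^(r+1) t^r N_r ,

unbiased in the Poisson regime but exploding for t > 1, where the terms
grow geometrically.  For t > 1 we use the Euler/binomial-tail smoothed
variant (Orlitsky, Suresh & Wu 2016): each term is damped by the binomial
tail weight P(L >= r) with L ~ Binomial(k, 2/(t+2)) and
k = ceil(0.5 * log2(m t^2 / (t-1))), which trades a small bias for bounded
variance.  Standard errors come from a tumor-level bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from raremut.catalog_io import Cohort, FrequencyVector, build_frequency_vector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RichnessEstimate:
    scope: str
    t: float
    delta: float
    se: float | None = None
    method: str = "plain"
    bootstrap_b: int | None = None
    seed: int | None = None


def euler_k(m: int, t: float) -> int:
    """Euler-smoothing truncation parameter k = ceil(0.5 log2(m t^2/(t-1)))."""
    if t <= 1:
        raise ValueError("Euler smoothing applies only for t > 1")
    return int(np.ceil(0.5 * np.log2(m * t * t / (t - 1.0))))


def good_toulmin(freq: FrequencyVector, t: float) -> RichnessEstimate:
    """Estimate Δ(t), the expected number of new variants in t·m more tumors.

    Uses the plain alternating series for t <= 1 and the Euler/binomial-tail
    smoothed series for t > 1.  The series runs over every observed
    frequency class (no truncation of the sum itself).  A negative estimate
    — possible with heavy high-r classes — is truncated to zero with a
    warning, since a count cannot be negative.
    """
    if t <= 0:
        raise ValueError("extrapolation factor t must be > 0")
    if not freq.counts:
        return RichnessEstimate(scope=freq.scope, t=t, delta=0.0, method="plain")
    rs = np.array(sorted(freq.counts), dtype=int)
    ns = np.array([freq.counts[r] for r in rs], dtype=float)
    signs = np.where(rs % 2 == 1, 1.0, -1.0)
    if t <= 1.0:
        method = "plain"
        delta = float(np.sum(signs * np.power(t, rs.astype(float)) * ns))
    else:
        method = "euler_smoothed"
        k = euler_k(freq.m, t)
        weights = stats.binom.sf(rs - 1, k, 2.0 / (t + 2.0))  # P(L >= r)
        delta = float(np.sum(signs * np.power(t, rs.astype(float)) * ns * weights))
    if delta < 0.0:
        logger.warning(
            "Δ(t=%.4g) = %.4g < 0 truncated to 0 (scope %s)", t, delta, freq.scope
        )
        delta = 0.0
    return RichnessEstimate(scope=freq.scope, t=t, delta=delta, method=method)


def expected_new_variants_in_one_tumor(freq: FrequencyVector) -> RichnessEstimate:
    """Δ evaluated at t = 1/m: the expected number of new variants in a
    single additional tumor (plain series; converges since t <= 1)."""
    if freq.m < 1:
        raise ValueError("cohort size m must be >= 1")
    return good_toulmin(freq, 1.0 / freq.m)


def bootstrap_se(
    cohort: Cohort,
    scope: str,
    t: float,
    b: int = 200,
    seed: int | None = None,
) -> float:
    """Bootstrap standard error of Δ(t) by resampling tumors with replacement.

    Each of the ``b`` resamples draws m tumors with replacement, rebuilds
    the frequency vector (a tumor drawn twice contributes twice to every
    variant it carries) and re-evaluates Δ(t); the SE is the standard
    deviation across resamples.
    """
    if b < 2:
        raise ValueError("bootstrap needs b >= 2 resamples")
    if b < 50:
        logger.warning("bootstrap with b=%d < 50 resamples is noisy", b)
    rng = np.random.default_rng(seed)
    rec = cohort.records
    if scope != "global":
        rec = rec[rec["gene"] == scope]
    sample_ids = cohort.samples["sample_id"].to_numpy()
    m = len(sample_ids)
    id_index = {s: i for i, s in enumerate(sample_ids)}
    # incidence lists: variant -> array of tumor indices carrying it
    var_codes, var_uniques = rec["variant_key"].factorize()
    tumor_idx = rec["sample_id"].map(id_index).to_numpy()
    deltas = np.empty(b)
    for i in range(b):
        mult = np.bincount(rng.integers(0, m, size=m), minlength=m)
        if len(var_uniques):
            r_per_variant = np.bincount(var_codes, weights=mult[tumor_idx]).astype(int)
            r_per_variant = r_per_variant[r_per_variant > 0]
            counts: dict[int, int] = {}
            for r, n in zip(*np.unique(r_per_variant, return_counts=True)):
                counts[int(r)] = int(n)
        else:
            counts = {}
        fv = FrequencyVector(scope=scope, m=m, counts=counts)
        deltas[i] = good_toulmin(fv, t).delta
    return float(np.std(deltas, ddof=1))


def richness_with_se(
    cohort: Cohort,
    scope: str,
    t: float,
    b: int = 200,
    seed: int | None = None,
) -> RichnessEstimate:
    """Point estimate of Δ(t) for a scope plus its bootstrap SE."""
    freq = build_frequency_vector(cohort, scope)
    est = good_toulmin(freq, t)
    se = bootstrap_se(cohort, scope, t, b=b, seed=seed)
    return RichnessEstimate(
        scope=scope, t=t, delta=est.delta, se=se, method=est.method, bootstrap_b=b, seed=seed
    )
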