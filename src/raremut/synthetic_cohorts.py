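"""Synthetic somatic-mutation cohorts with known ground truth.

The generator embodies the occurrence model the estimators assume: every
variant v carries a per-tumor probability p_v and occurs independently
across tumors and across variants (a product-binomial incidence model).
Per-gene variant pools follow long-tailed laws — log-series, Zipf, or a
hotspot mixture (a few high-probability variants over a long tail, the
pattern of oncogenes like KRAS) — so that most observed variants are
singletons, as in real tumor catalogs.  Tissue dependence enters as
per-tissue rate multipliers, hypermutation as a per-tumor multiplier on
every probability.  Because the truth (every p_v) is retained, exact
oracles for the unseen-variant probability and the expected number of new
variants are available for calibration testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from raremut.catalog_io import Cohort

logger = logging.getLogger(__name__)

LAWS = ("log_series", "zipf", "hotspot_mixture")


@dataclass(frozen=True)
class GeneModel:
    """Per-gene variant-pool model.

    ``rate`` is the expected number of incidences per (baseline-tissue,
    non-hypermutated) tumor in the gene; the law distributes it over a pool
    of ``pool_size`` variants.  ``hotspot_probs`` are absolute per-tumor
    probabilities prepended to the tail pool (hotspot_mixture only).
    ``tissue_multipliers`` scale every variant's probability in the named
    tissues (unnamed tissues use 1.0).
    """

    gene: str
    law: str = "hotspot_mixture"
    pool_size: int = 200
    rate: float = 0.05
    alpha: float = 0.999  # log-series parameter in (0, 1)
    s: float = 1.2  # zipf exponent
    hotspot_probs: tuple[float, ...] = ()
    tissue_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValueError(f"unknown variant law {self.law!r}; choose from {LAWS}")
        if self.pool_size < 1 or self.rate <= 0:
            raise ValueError("pool_size >= 1 and rate > 0 required")
        if any(m <= 0 for m in self.tissue_multipliers.values()):
            raise ValueError("tissue multipliers must be positive")
        if any(not 0 <= p <= 1 for p in self.hotspot_probs):
            raise ValueError("hotspot probabilities must lie in [0, 1]")

    def variant_probs(self) -> np.ndarray:
        """Baseline per-tumor occurrence probability of each pool variant."""
        k = np.arange(1, self.pool_size + 1, dtype=float)
        if self.law == "log_series":
            w = self.alpha**k / k
        elif self.law == "zipf":
            w = k**-self.s
        else:  # hotspot_mixture: zipf tail under the explicit hotspots
            w = k**-self.s
        tail = self.rate * w / w.sum()
        if self.law == "hotspot_mixture" and self.hotspot_probs:
            return np.concatenate([np.asarray(self.hotspot_probs, dtype=float), tail])
        return tail

    def variant_keys(self) -> list[str]:
        n = self.pool_size + (len(self.hotspot_probs) if self.law == "hotspot_mixture" else 0)
        return [f"{self.gene}:p{i + 1}" for i in range(n)]


@dataclass(frozen=True)
class CohortTruth:
    """Everything the generator knew: the oracle side of a simulation."""

    gene_probs: dict[str, np.ndarray]  # baseline per-variant probabilities
    gene_keys: dict[str, list[str]]
    tissue_multipliers: dict[str, Mapping[str, float]]  # gene -> tissue -> mult
    tissue_names: tuple[str, ...]
    tissue_mix: tuple[float, ...]
    m: int
    hypermutation_fraction: float
    hypermutation_multiplier: float


@dataclass(frozen=True)
class SimulatedCohort:
    cohort: Cohort
    truth: CohortTruth
    seed: int


def _effective_probs(truth: CohortTruth, gene: str, tissue: str) -> np.ndarray:
    mult = truth.tissue_multipliers.get(gene, {}).get(tissue, 1.0)
    return np.minimum(truth.gene_probs[gene] * mult, 1.0)


def simulate(
    genes: Sequence[GeneModel],
    m: int,
    tissue_mix: Mapping[str, float] | None = None,
    hypermutation_fraction: float = 0.0,
    hypermutation_multiplier: float = 1.0,
    hypermutated_label: str = "MMR",
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate an m-tumor cohort under the product-binomial model.

    Each tumor first draws a tissue from ``tissue_mix`` (default: one
    tissue "PAN") and a hypermutation flag; each variant then occurs
    independently with its tissue- and multiplier-adjusted probability,
    capped at 1.  Emits a full :class:`~raremut.catalog_io.Cohort` (MAF-like
    records plus annotation roster with burdens and signature labels) and
    the generating truth.  Identical seeds reproduce the cohort exactly.
    A warning is logged if the probability cap fires for more than 1% of
    variant-tumor pairs (the model is then misspecified).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= hypermutation_fraction <= 1.0:
        raise ValueError("hypermutation_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if tissue_mix is None:
        tissue_mix = {"PAN": 1.0}
    tissue_names = tuple(sorted(tissue_mix))
    mix = np.array([tissue_mix[c] for c in tissue_names], dtype=float)
    if not np.isclose(mix.sum(), 1.0):
        raise ValueError(f"tissue mix sums to {mix.sum():.6g}, expected 1")

    # tumor-level draws first so tissue-stratified sample counts are exact
    tissue_idx = rng.choice(len(tissue_names), size=m, p=mix)
    hyper = rng.random(m) < hypermutation_fraction
    sample_ids = np.array([f"S{i:06d}" for i in range(m)])

    gene_probs: dict[str, np.ndarray] = {}
    gene_keys: dict[str, list[str]] = {}
    tissue_mults: dict[str, Mapping[str, float]] = {}
    rec_samples: list[np.ndarray] = []
    rec_genes: list[str] = []
    rec_keys: list[str] = []
    n_capped = 0
    n_pairs = 0

    strata = [
        (ci, h, np.where((tissue_idx == ci) & (hyper == h))[0])
        for ci in range(len(tissue_names))
        for h in (False, True)
    ]
    for model in genes:
        base = model.variant_probs()
        keys = model.variant_keys()
        gene_probs[model.gene] = base
        gene_keys[model.gene] = keys
        tissue_mults[model.gene] = dict(model.tissue_multipliers)
        for ci, h, idx in strata:
            if len(idx) == 0:
                continue
            mult = model.tissue_multipliers.get(tissue_names[ci], 1.0)
            if h:
                mult *= hypermutation_multiplier
            p = base * mult
            n_capped += int(np.sum(p > 1.0)) * len(idx)
            n_pairs += len(p) * len(idx)
            p = np.minimum(p, 1.0)
            counts = rng.binomial(len(idx), p)
            for v in np.nonzero(counts)[0]:
                carriers = rng.choice(idx, size=counts[v], replace=False)
                rec_samples.append(np.sort(carriers))
                rec_genes.extend([model.gene] * counts[v])
                rec_keys.extend([keys[v]] * counts[v])

    if n_pairs and n_capped / n_pairs > 0.01:
        logger.warning(
            "probability cap fired for %.2f%% of variant-tumor pairs; model misspecified",
            100 * n_capped / n_pairs,
        )

    sample_rows = np.concatenate(rec_samples) if rec_samples else np.array([], dtype=int)
    records = pd.DataFrame(
        {
            "sample_id": sample_ids[sample_rows],
            "tumor_type": np.asarray(tissue_names)[tissue_idx[sample_rows]]
            if len(sample_rows)
            else [],
            "gene": rec_genes,
            "variant_key": rec_keys,
            "variant_class": "Missense_Mutation",
            "variant_type": "SNP",
        }
    )
    records["protein_change"] = records["variant_key"].str.split(":").str[-1]
    records = records.sort_values(["sample_id", "gene", "variant_key"]).reset_index(drop=True)
    burden = records.groupby("sample_id").size()
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tumor_type": np.asarray(tissue_names)[tissue_idx],
            "mutation_burden": pd.Series(sample_ids).map(burden).fillna(0).astype(int),
            "signature_label": np.where(hyper, hypermutated_label, "none"),
        }
    )
    truth = CohortTruth(
        gene_probs=gene_probs,
        gene_keys=gene_keys,
        tissue_multipliers=tissue_mults,
        tissue_names=tissue_names,
        tissue_mix=tuple(mix),
        m=m,
        hypermutation_fraction=hypermutation_fraction,
        hypermutation_multiplier=hypermutation_multiplier,
    )
    return SimulatedCohort(cohort=Cohort(records=records, samples=samples), truth=truth, seed=seed)


def sample_variant_counts(probs: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Per-variant tumor counts r_v ~ Binomial(m, p_v) for one stratum.

    Marginally equivalent to simulating the full incidence matrix when all
    tumors share the same effective probabilities; the fast path for
    calibration harnesses that only need frequency vectors.
    """
    return rng.binomial(m, np.minimum(probs, 1.0))


def true_unseen_probability(
    truth: CohortTruth,
    seen_keys: set[str],
    gene: str,
    tissue: str | None = None,
) -> float:
    """Exact probability a new tumor carries >= 1 training-unseen variant of ``gene``.

    1 - prod over unseen pool variants of (1 - p_v) for one new
    (non-hypermutated) tumor of the given tissue; with ``tissue=None`` the
    probability is marginalized over the generating tissue mix.
    """
    keys = truth.gene_keys[gene]
    unseen = np.array([k not in seen_keys for k in keys])
    if not unseen.any():
        return 0.0
    if tissue is not None:
        p = _effective_probs(truth, gene, tissue)[unseen]
        return float(1.0 - np.prod(1.0 - p))
    acc = 0.0
    for w, t in zip(truth.tissue_mix, truth.tissue_names):
        p = _effective_probs(truth, gene, t)[unseen]
        acc += w * (1.0 - np.prod(1.0 - p))
    return float(acc)


def true_new_variant_count(
    truth: CohortTruth, seen_keys: set[str], t: float, gene: str | None = None
) -> float:
    """Exact expected number of training-unseen variants found in t·m new tumors.

    For each unseen variant, the chance of remaining unseen in one future
    tumor is q_v = sum_c w_c (1 - p_v,c) over the tissue mix; the expected
    discovery count is sum_v (1 - q_v^(t·m)).  Restricted to one gene when
    given, otherwise summed over all genes.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    n_future = t * truth.m
    genes = [gene] if gene is not None else sorted(truth.gene_keys)
    total = 0.0
    for g in genes:
        keys = truth.gene_keys[g]
        unseen = np.array([k not in seen_keys for k in keys])
        if not unseen.any():
            continue
        q = np.zeros(int(unseen.sum()))
        for w, tis in zip(truth.tissue_mix, truth.tissue_names):
            q += w * (1.0 - _effective_probs(truth, g, tis)[unseen])
        total += float(np.sum(1.0 - q**n_future))
    return total
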