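"""Tissue specificity of variant occurrence via normalized mutual information.

A variant (or a gene's hitherto-unseen-variant event) with per-tissue
occurrence probabilities p_c and tissue prevalences w_c defines a joint
distribution over (tissue T, binary event E): P(T=c, E=1) = w_c * p_c.
The specificity score is the mutual information I(T; E) normalized (by
default) by the tissue-label entropy H(T), so that a lineage-independent
event scores 0 and a tissue-deterministic one scores 1.  Observed scores
are referenced against a permutation null in which tissue labels are
randomly reallocated across tumors, preserving each tissue's sample count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from raremut.catalog_io import Cohort

NORMALIZERS = ("tissue_entropy", "event_entropy", "min", "sqrt_product")


@dataclass(frozen=True)
class TissueSpecificityScore:
    scope: str
    nmi: float
    null_percentile_95: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    normalizer: str = "tissue_entropy"


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def nmi(
    event_probabilities_by_tissue: Mapping[str, float],
    tissue_weights: Mapping[str, float],
    normalizer: str = "tissue_entropy",
) -> float:
    """NMI between tissue label and a binary mutation event.

    ``event_probabilities_by_tissue`` maps tissue -> P(event | tissue);
    ``tissue_weights`` maps tissue -> cohort proportion (must sum to 1).
    Zero when all per-tissue probabilities are equal (lineage independence);
    defined as 0 for a single tissue.  The normalizer is reported alongside
    the score and is one of H(T) (default), H(E), min(H(T),H(E)) or
    sqrt(H(T)H(E)).
    """
    if not event_probabilities_by_tissue:
        raise ValueError("empty probability map")
    if normalizer not in NORMALIZERS:
        raise ValueError(f"unknown normalizer {normalizer!r}; choose from {NORMALIZERS}")
    tissues = sorted(event_probabilities_by_tissue)
    if len(tissues) == 1:
        return 0.0
    w = np.array([tissue_weights[c] for c in tissues], dtype=float)
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError(f"tissue weights sum to {w.sum():.6g}, expected 1")
    p = np.array([event_probabilities_by_tissue[c] for c in tissues], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("event probabilities must lie in [0, 1]")
    joint = np.column_stack([w * p, w * (1.0 - p)])  # (tissue, E=1/E=0)
    p_e = joint.sum(axis=0)
    h_t = _entropy(w)
    h_e = _entropy(p_e)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (w[:, None] * p_e[None, :])
        terms = np.where(joint > 0, joint * np.log(np.where(joint > 0, ratio, 1.0)), 0.0)
    mi = float(terms.sum())
    denom = {
        "tissue_entropy": h_t,
        "event_entropy": h_e,
        "min": min(h_t, h_e),
        "sqrt_product": float(np.sqrt(h_t * h_e)),
    }[normalizer]
    if denom <= 0:
        return 0.0
    return max(0.0, mi / denom)


def index_tissue_nmi(
    event_probabilities_by_tissue: Mapping[str, float],
    tissue_weights: Mapping[str, float],
    index_tissue: str,
    normalizer: str = "tissue_entropy",
) -> float:
    """NMI of the event against the binarized label index-tissue vs rest.

    Measures how much an event (e.g. a gene-pair co-mutation) is elevated in
    one index cancer type relative to the pooled average of all others.
    With only two tissues this reduces to :func:`nmi` on the same data.
    """
    if index_tissue not in event_probabilities_by_tissue:
        raise ValueError(f"index tissue {index_tissue!r} not present")
    w_idx = tissue_weights[index_tissue]
    w_rest = sum(v for c, v in tissue_weights.items() if c != index_tissue)
    if w_rest <= 0:
        return 0.0
    p_rest = (
        sum(
            tissue_weights[c] * event_probabilities_by_tissue[c]
            for c in event_probabilities_by_tissue
            if c != index_tissue
        )
        / w_rest
    )
    return nmi(
        {index_tissue: event_probabilities_by_tissue[index_tissue], "__rest__": p_rest},
        {index_tissue: w_idx, "__rest__": w_rest},
        normalizer=normalizer,
    )


def _gene_incidence(cohort: Cohort, gene: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tissue codes per tumor, tissue names, tumor x variant incidence matrix)."""
    samples = cohort.samples.reset_index(drop=True)
    tissue_codes, tissue_names = pd.factorize(samples["tumor_type"], sort=True)
    id_index = {s: i for i, s in enumerate(samples["sample_id"])}
    rec = cohort.records[cohort.records["gene"] == gene]
    var_codes, var_names = rec["variant_key"].factorize(sort=True)
    x = np.zeros((len(samples), len(var_names)), dtype=np.int8)
    if len(rec):
        rows = rec["sample_id"].map(id_index).to_numpy()
        x[rows, var_codes] = 1
    return tissue_codes.astype(np.int64), np.asarray(tissue_names), x


def _unseen_probs_from_incidence(
    x: np.ndarray, tissue_codes: np.ndarray, n_tissues: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tissue (p_unseen, m_c) from a tumor x variant 0/1 matrix."""
    m_c = np.bincount(tissue_codes, minlength=n_tissues)
    onehot = np.zeros((len(tissue_codes), n_tissues), dtype=np.float32)
    onehot[np.arange(len(tissue_codes)), tissue_codes] = 1.0
    counts = onehot.T @ x.astype(np.float32)
    n1_c = np.count_nonzero(np.abs(counts - 1.0) < 0.5, axis=1)
    with np.errstate(divide="ignore"):
        p = np.where(m_c > 0, 1.0 - np.exp(-n1_c / (m_c + 1.0)), 0.0)
    return p, m_c


def tissue_unseen_probabilities(cohort: Cohort, gene: str) -> dict[str, float]:
    """Per-tissue probability of seeing a hitherto-unseen variant of ``gene``.

    Each tissue contributes its own stratified frequency vector (own m_c and
    singleton count N_1), so the unseen-variant probability is estimated
    within-tissue: p_c = 1 - exp(-N_1c/(m_c + 1)).
    """
    tissue_codes, tissue_names, x = _gene_incidence(cohort, gene)
    p, _ = _unseen_probs_from_incidence(x, tissue_codes, len(tissue_names))
    return dict(zip(tissue_names, p))


def gene_unseen_nmi(
    cohort: Cohort, gene: str, normalizer: str = "tissue_entropy"
) -> float:
    """Observed NMI of a gene's unseen-variant event across tissues."""
    samples = cohort.samples
    weights = samples["tumor_type"].value_counts(normalize=True).to_dict()
    probs = tissue_unseen_probabilities(cohort, gene)
    return nmi(probs, weights, normalizer=normalizer)


def null_nmi_distribution(
    cohort: Cohort,
    gene: str,
    n_permutations: int = 1000,
    seed: int | None = None,
    normalizer: str = "tissue_entropy",
) -> tuple[np.ndarray, float]:
    """Permutation null for a gene's unseen-variant NMI.

    Each permutation reallocates tissue labels uniformly at random across
    tumors while fixing every tissue's sample count m_c, recomputes the
    tissue-stratified unseen-variant probabilities, and records the NMI.
    Returns the full null sample and its 95th percentile.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations for a stable 95th percentile")
    tissue_codes, tissue_names, x = _gene_incidence(cohort, gene)
    n_tissues = len(tissue_names)
    if n_tissues < 2:
        raise ValueError("permutation null needs at least two tissues")
    rng = np.random.default_rng(seed)
    m = len(tissue_codes)
    weights = {c: n / m for c, n in zip(tissue_names, np.bincount(tissue_codes))}
    null = np.empty(n_permutations)
    xf = x.astype(np.float32)
    for i in range(n_permutations):
        perm_codes = tissue_codes[rng.permutation(m)]
        p, _ = _unseen_probs_from_incidence(xf, perm_codes, n_tissues)
        null[i] = nmi(dict(zip(tissue_names, p)), weights, normalizer=normalizer)
    return null, float(np.percentile(null, 95))


def score_gene(
    cohort: Cohort,
    gene: str,
    n_permutations: int = 1000,
    seed: int | None = None,
    normalizer: str = "tissue_entropy",
) -> TissueSpecificityScore:
    """Observed unseen-variant NMI for a gene with its permutation-null cutoff."""
    observed = gene_unseen_nmi(cohort, gene, normalizer=normalizer)
    _, null95 = null_nmi_distribution(
        cohort, gene, n_permutations=n_permutations, seed=seed, normalizer=normalizer
    )
    return TissueSpecificityScore(
        scope=f"gene-unseen:{gene}",
        nmi=observed,
        null_percentile_95=null95,
        n_permutations=n_permutations,
        seed=seed,
        normalizer=normalizer,
    )
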