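"""Gene-pair co-mutation and mutual-exclusivity analysis.

Pair analysis is gene-level, not variant-level: a gene counts as mutated in
a tumor when the tumor carries any non-synonymous SNV in it.  For an
unordered pair (A, B), a tumor shows a *co-mutation* event when both genes
are mutated and a *mutual-exclusivity* event when exactly one is.  The two
events are disjoint, and with "neither" they exhaust the tumor.  Pair event
counts over a gene-panel universe form a frequency-of-frequencies vector
(N_r = number of pairs whose event occurs in exactly r tumors) to which the
Good-Turing estimator applies unchanged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from raremut.catalog_io import Cohort, FrequencyVector
from raremut.good_turing import SmoothingSpec, VariantProbability, gt_probability

logger = logging.getLogger(__name__)

EVENT_TYPES = ("co_mutation", "mutual_exclusive")


class UnseenPairError(ValueError):
    """The pair's event was never observed; no Good-Turing probability for it."""


@dataclass(frozen=True)
class PairEventCount:
    gene_a: str
    gene_b: str
    event_type: str
    count: int
    per_tissue: dict[str, int]


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    if gene_a == gene_b:
        raise ValueError(f"gene pair must be two distinct genes, got {gene_a!r} twice")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def gene_mutation_matrix(cohort: Cohort, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Tumor x gene 0/1 mutation-status matrix (any non-synonymous SNV).

    Rows cover every profiled sample (zero rows for unmutated tumors);
    columns are the requested genes, or every mutated gene when ``genes``
    is None.
    """
    rec = cohort.records
    if genes is not None:
        rec = rec[rec["gene"].isin(set(genes))]
    status = (
        rec.drop_duplicates(["sample_id", "gene"])
        .assign(one=1)
        .pivot_table(index="sample_id", columns="gene", values="one", fill_value=0)
    )
    status = status.reindex(cohort.samples["sample_id"], fill_value=0)
    if genes is not None:
        status = status.reindex(columns=list(genes), fill_value=0)
    return status.astype(np.int8)


def pair_event_counts(
    cohort: Cohort, gene_a: str, gene_b: str, event_type: str
) -> PairEventCount:
    """Count tumors showing the pair event, overall and per tissue.

    ``event_type`` is ``"co_mutation"`` (both genes mutated) or
    ``"mutual_exclusive"`` (exactly one mutated).  Counts tumors, never
    records, and is symmetric in the two genes.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}; choose from {EVENT_TYPES}")
    a, b = canonical_pair(gene_a, gene_b)
    status = gene_mutation_matrix(cohort, [a, b])
    sa = status[a].to_numpy()
    sb = status[b].to_numpy()
    ind = (sa & sb) if event_type == "co_mutation" else (sa ^ sb)
    tissues = cohort.samples["tumor_type"].to_numpy()
    per_tissue = (
        pd.Series(ind, index=tissues).groupby(level=0).sum().astype(int).to_dict()
    )
    return PairEventCount(
        gene_a=a, gene_b=b, event_type=event_type, count=int(ind.sum()), per_tissue=per_tissue
    )


def pair_frequency_vector(
    cohort: Cohort, genes: Sequence[str], event_type: str, warn_above: int = 200
) -> tuple[FrequencyVector, dict[tuple[str, str], int]]:
    """Frequency vector over the gene-pair universe, plus per-pair counts.

    The universe is all unordered pairs within ``genes`` (a user-supplied
    panel keeps the N_r classes populated; genome-wide universes are legal
    but sparse).  N_r is the number of pairs whose event occurs in exactly
    r tumors; pairs with zero events are the unseen pairs and do not enter
    the vector.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event_type!r}; choose from {EVENT_TYPES}")
    genes = sorted(set(genes))
    if len(genes) > warn_above:
        logger.warning(
            "pair universe over %d genes (%d pairs) will be sparse",
            len(genes),
            len(genes) * (len(genes) - 1) // 2,
        )
    status = gene_mutation_matrix(cohort, genes).to_numpy()
    pair_counts: dict[tuple[str, str], int] = {}
    for i, j in itertools.combinations(range(len(genes)), 2):
        sa, sb = status[:, i], status[:, j]
        ind = (sa & sb) if event_type == "co_mutation" else (sa ^ sb)
        c = int(ind.sum())
        if c > 0:
            pair_counts[(genes[i], genes[j])] = c
    freq_counts: dict[int, int] = {}
    for c in pair_counts.values():
        freq_counts[c] = freq_counts.get(c, 0) + 1
    scope = f"pairs:{event_type}"
    return FrequencyVector(scope=scope, m=cohort.m, counts=freq_counts), pair_counts


def pair_gt_probability(
    freq: FrequencyVector,
    pair_counts: dict[tuple[str, str], int],
    gene_a: str,
    gene_b: str,
    spec: SmoothingSpec | None = None,
) -> VariantProbability:
    """Good-Turing probability that a pair's event recurs in a new tumor.

    Applies the ordinary Good-Turing estimator with the pair's observed
    event count r against the pair-universe frequency vector.  A pair whose
    event was never observed is refused (report it as unseen, not as a
    probability — the singleton-based missing-mass formula covers the
    aggregate, not one specific pair).
    """
    pair = canonical_pair(gene_a, gene_b)
    r = pair_counts.get(pair, 0)
    if r == 0:
        raise UnseenPairError(f"pair {pair} never shows the event in this cohort")
    return gt_probability(freq, r, spec=spec)
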