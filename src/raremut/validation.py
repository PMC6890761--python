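"""Cross-cohort validation of unseen-variant predictions.

Train on one cohort, validate on another: for each gene, the training
cohort yields (a) the probability that a new tumor carries at least one
variant never seen in training and (b) the Good-Toulmin predicted number of
new variants in a cohort of the validation's size (t = m_valid / m_train).
The validation cohort supplies the observed counterparts — the fraction of
its tumors carrying a training-unseen variant in the gene, and the count of
its distinct variants absent from training.  Agreement across genes is
scored with Lin's concordance correlation coefficient (CCC), which, unlike
Pearson's r, penalizes departures from the identity line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from raremut.catalog_io import Cohort, build_frequency_vector
from raremut.good_toulmin import good_toulmin
from raremut.good_turing import unseen_event_probability

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePrediction:
    gene: str
    predicted_p_unseen: float
    observed_fraction: float
    predicted_new_count: float
    observed_new_count: int


def observed_new_variants(
    train: Cohort, valid: Cohort, gene: str, _train_keys: set[str] | None = None
) -> tuple[int, float]:
    """Count validation variants of ``gene`` absent from training.

    A validation variant is *new* iff its variant_key never occurs anywhere
    in the training cohort.  Returns (number of distinct new variant keys,
    fraction of validation tumors carrying at least one new variant in the
    gene over all validation tumors).  Both cohorts must use the same
    variant-key scheme.
    """
    train_keys = _train_keys if _train_keys is not None else set(train.records["variant_key"])
    vrec = valid.records[valid.records["gene"] == gene]
    new = vrec[~vrec["variant_key"].isin(train_keys)]
    n_new = int(new["variant_key"].nunique())
    n_tumors_with_new = int(new["sample_id"].nunique())
    return n_new, n_tumors_with_new / valid.m


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), using
    population (n-denominator) moments.  Equals 1 only when y = x exactly;
    bounded by |Pearson r| in magnitude.  Two constant equal vectors are
    perfectly concordant (1); constant unequal vectors give 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("lin_ccc needs two equal-length 1-D vectors of length >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("lin_ccc inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population variance
    cov = float(np.mean((x - mx) * (y - my)))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # both constant with equal means
    return float(2.0 * cov / denom)


def gene_predictions(
    train: Cohort, valid: Cohort, genes: list[str] | None = None
) -> pd.DataFrame:
    """Per-gene predicted vs observed unseen-variant quantities.

    Restricted to genes present in both cohorts (or the supplied list);
    genes absent from either side are dropped with a log entry.  The
    predicted count uses Δ(t) at t = m_valid / m_train.
    """
    train_genes = set(train.records["gene"])
    valid_genes = set(valid.records["gene"])
    if genes is None:
        genes = sorted(train_genes & valid_genes)
        dropped = sorted((train_genes | valid_genes) - set(genes))
    else:
        requested = list(genes)
        genes = sorted(g for g in requested if g in train_genes and g in valid_genes)
        dropped = sorted(set(requested) - set(genes))
    if dropped:
        logger.info("gene_predictions: dropped %d genes absent from a cohort", len(dropped))
    t = valid.m / train.m
    train_keys = set(train.records["variant_key"])
    rows = []
    for gene in genes:
        freq = build_frequency_vector(train, gene)
        p_unseen = unseen_event_probability(freq.n1, freq.m)
        pred_count = good_toulmin(freq, t).delta
        n_new, frac = observed_new_variants(train, valid, gene, _train_keys=train_keys)
        rows.append(
            GenePrediction(
                gene=gene,
                predicted_p_unseen=p_unseen,
                observed_fraction=frac,
                predicted_new_count=pred_count,
                observed_new_count=n_new,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def validate_cohorts(
    train: Cohort,
    valid: Cohort,
    genes: list[str] | None = None,
    subgroups: pd.DataFrame | None = None,
) -> dict:
    """Concordance summary of train-based predictions against validation.

    Returns ``{"per_gene": DataFrame, "ccc_probability": ..., "ccc_counts":
    ...}``; when per-sample subgroup assignments are supplied (for both
    cohorts, concatenated), the same comparison is repeated within each
    subgroup under ``"per_subgroup"``.
    """
    table = gene_predictions(train, valid, genes)
    out: dict = {"per_gene": table}
    if len(table) >= 2:
        out["ccc_probability"] = lin_ccc(
            table["predicted_p_unseen"].to_numpy(), table["observed_fraction"].to_numpy()
        )
        out["ccc_counts"] = lin_ccc(
            table["predicted_new_count"].to_numpy(),
            table["observed_new_count"].to_numpy(dtype=float),
        )
    if subgroups is not None:
        per_subgroup = {}
        lookup = subgroups.set_index("sample_id")["subgroup"]
        for name in sorted(lookup.unique()):
            ids = set(lookup[lookup == name].index)
            tr = train.subset_samples(ids)
            va = valid.subset_samples(ids)
            if tr.m == 0 or va.m == 0:
                continue
            sub_table = gene_predictions(tr, va, genes)
            entry: dict = {"n_genes": len(sub_table), "m_train": tr.m, "m_valid": va.m}
            if len(sub_table) >= 2:
                entry["ccc_probability"] = lin_ccc(
                    sub_table["predicted_p_unseen"].to_numpy(),
                    sub_table["observed_fraction"].to_numpy(),
                )
                entry["ccc_counts"] = lin_ccc(
                    sub_table["predicted_new_count"].to_numpy(),
                    sub_table["observed_new_count"].to_numpy(dtype=float),
                )
            per_subgroup[name] = entry
        out["per_subgroup"] = per_subgroup
    return out
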