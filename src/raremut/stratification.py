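"""Mutational-signature cohort stratification.

Tumors are partitioned into six categories — non-hypermutated plus five
dominant single-base-substitution (SBS) signature groups (APOBEC, Smoking,
MMR, UV, POLE) — using a per-tumor signature label and a mutation-burden
threshold.  Tumors above the burden threshold that carry none of the five
signature labels are excluded from analysis.  When two cohorts are sequenced
over very different target sizes (whole exome vs a gene panel), the burden
threshold is rescaled by the ratio of the cohorts' median burdens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SIGNATURE_GROUPS = ("APOBEC", "Smoking", "MMR", "UV", "POLE")
NON_HYPERMUTATED = "non_hypermutated"
EXCLUDED = "excluded"

#: Dominant-signature group -> COSMIC SBS numbers (configurable; the
#: APOBEC convention is SBS2/13).
DEFAULT_SBS_GROUP_MAP: dict[str, tuple[int, ...]] = {
    "APOBEC": (2, 13),
    "Smoking": (4,),
    "MMR": (6, 14, 15, 20, 21, 26, 44),
    "UV": (7,),
    "POLE": (10,),
}


class SignatureLabelError(ValueError):
    """Unrecognized dominant-signature label."""


@dataclass(frozen=True)
class SubgroupAssignment:
    sample_id: str
    subgroup: str
    burden: int
    threshold_used: int


def scaled_hypermutation_threshold(
    base_threshold: int, median_burden_target: float, median_burden_reference: float
) -> int:
    """Rescale a hypermutation burden threshold across cohorts.

    Multiplies ``base_threshold`` by the ratio of the target cohort's median
    total mutation burden to the reference cohort's and rounds up, so that
    a threshold calibrated on one sequencing footprint transfers to another
    (e.g. a 500-mutation whole-exome threshold with median burdens 4 vs 54
    gives ceil(500*4/54) = 38 for a targeted panel).
    """
    if base_threshold <= 0 or median_burden_target <= 0 or median_burden_reference <= 0:
        raise ValueError("all threshold-scaling arguments must be positive")
    return math.ceil(base_threshold * median_burden_target / median_burden_reference)


def assign_subgroups(
    samples: pd.DataFrame,
    threshold: int,
    signature_groups: Sequence[str] = SIGNATURE_GROUPS,
) -> pd.DataFrame:
    """Assign each tumor to one of six categories or exclusion.

    Rule order: a dominant-signature label in ``signature_groups`` wins
    regardless of burden; otherwise burden < ``threshold`` (strict) is
    non-hypermutated, and burden >= threshold with no signature label is
    excluded.

    ``samples`` needs columns ``sample_id``, ``mutation_burden`` and
    optionally ``signature_label`` (missing/NaN treated as ``none``).
    Returns a DataFrame of :class:`SubgroupAssignment` fields.
    """
    if "mutation_burden" not in samples.columns:
        raise ValueError("samples table needs a 'mutation_burden' column")
    labels = (
        samples["signature_label"].fillna("none").astype(str)
        if "signature_label" in samples.columns
        else pd.Series("none", index=samples.index)
    )
    legal = set(signature_groups) | {"none"}
    bad = sorted(set(labels) - legal)
    if bad:
        raise SignatureLabelError(
            f"unrecognized signature label(s) {bad}; legal labels: {sorted(legal)}"
        )
    burden = samples["mutation_burden"].astype(int)
    subgroup = labels.where(labels != "none", "")
    hyper = burden >= threshold
    subgroup = subgroup.mask(
        subgroup == "", np.where(hyper, EXCLUDED, NON_HYPERMUTATED)
    )
    return pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "subgroup": subgroup,
            "burden": burden,
            "threshold_used": threshold,
        }
    ).reset_index(drop=True)


def dominant_signature_label(
    exposures: Mapping[int, float],
    sbs_group_map: Mapping[str, Sequence[int]] = DEFAULT_SBS_GROUP_MAP,
) -> str:
    """Map an SBS exposure vector to its argmax group label.

    Helper for when upstream annotation provides exposures rather than a
    dominant label: group exposures are summed over each group's SBS numbers
    and the largest group wins; ``none`` if all grouped exposure is zero.
    The SBS-to-group mapping is a convention, not a fit, and is configurable.
    """
    totals = {
        group: sum(exposures.get(s, 0.0) for s in sbs_numbers)
        for group, sbs_numbers in sbs_group_map.items()
    }
    best = max(totals, key=lambda g: totals[g])
    return best if totals[best] > 0 else "none"
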