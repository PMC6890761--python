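"""Shared fixtures: toy MAF text, hotspot-gene frequency vectors, small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from raremut.catalog_io import Cohort, FrequencyVector
from raremut.synthetic_cohorts import GeneModel, simulate

MAF_HEADER = "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\tVariant_Type\tHGVSp_Short\tTumor_Type"


def maf_text(rows: list[tuple[str, str, str, str, str, str]]) -> str:
    body = "\n".join("\t".join(r) for r in rows)
    return f"{MAF_HEADER}\n{body}\n"


@pytest.fixture
def toy_maf(tmp_path):
    """5 rows, 2 samples, one duplicated (sample, variant) row -> 4 incidences."""
    rows = [
        ("KRAS", "S1", "Missense_Mutation", "SNP", "p.G12D", "PAAD"),
        ("KRAS", "S1", "Missense_Mutation", "SNP", "p.G12D", "PAAD"),  # duplicate
        ("TP53", "S1", "Nonsense_Mutation", "SNP", "p.R175H", "PAAD"),
        ("KRAS", "S2", "Missense_Mutation", "SNP", "p.G12V", "LUAD"),
        ("TP53", "S2", "Missense_Mutation", "SNP", "p.R273C", "LUAD"),
    ]
    path = tmp_path / "toy.maf"
    path.write_text(maf_text(rows))
    return path


@pytest.fixture
def kras_like_freq():
    """Hotspot-gene frequency vector: 24 singletons, 3 doubletons, and
    hotspots at r = 142, 120, 44 over a cohort of 6696 tumors."""
    return FrequencyVector(
        scope="KRAS", m=6696, counts={1: 24, 2: 3, 142: 1, 120: 1, 44: 1}
    )


def cohort_from_records(rows, sample_ids=None, tumor_types=None) -> Cohort:
    """Build a Cohort directly from (sample_id, tumor_type, gene, variant_key) tuples."""
    records = pd.DataFrame(
        rows, columns=["sample_id", "tumor_type", "gene", "variant_key"]
    )
    records["variant_class"] = "Missense_Mutation"
    records["variant_type"] = "SNP"
    if sample_ids is None:
        sample_ids = sorted(records["sample_id"].unique())
        tt = records.set_index("sample_id")["tumor_type"].to_dict()
        tumor_types = [tt[s] for s in sample_ids]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tumor_type": tumor_types,
            "mutation_burden": [
                int((records["sample_id"] == s).sum()) for s in sample_ids
            ],
            "signature_label": "none",
        }
    )
    return Cohort(records=records, samples=samples)


@pytest.fixture(scope="session")
def small_sim():
    """One long-tailed gene plus one hotspot gene, 300 tumors, 2 tissues."""
    genes = [
        GeneModel(gene="TAILY", law="zipf", pool_size=400, s=1.1, rate=0.15),
        GeneModel(
            gene="HOTTY",
            law="hotspot_mixture",
            pool_size=100,
            rate=0.02,
            hotspot_probs=(0.05, 0.02),
        ),
    ]
    return simulate(
        genes, m=300, tissue_mix={"PAAD": 0.5, "LUAD": 0.5}, seed=20240917
    )


def brute_force_freq(cohort: Cohort, gene: str | None = None) -> dict[int, int]:
    """Independent (r, N_r) tally straight off the incidence records."""
    rec = cohort.records
    if gene is not None:
        rec = rec[rec["gene"] == gene]
    per_variant: dict[str, set] = {}
    for sid, key in zip(rec["sample_id"], rec["variant_key"]):
        per_variant.setdefault(key, set()).add(sid)
    out: dict[int, int] = {}
    for tumors in per_variant.values():
        out[len(tumors)] = out.get(len(tumors), 0) + 1
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(11)
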