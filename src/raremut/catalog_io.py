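"""Reading MAF-style somatic mutation tables and building frequency vectors.

A cohort is reduced to *incidences*: one (tumor, variant) pair per variant
observed in a tumor, regardless of how many MAF rows report it.  All
downstream estimators consume the *frequency of frequencies* vector: the
pairs ``(r, N_r)`` where ``N_r`` is the number of distinct variants observed
in exactly ``r`` tumors of the cohort of size ``m``.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default MAF column names -> internal field names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "variant_class": "Variant_Classification",
    "variant_type": "Variant_Type",
    "protein_change": "HGVSp_Short",
    "tumor_type": "Tumor_Type",
    "chromosome": "Chromosome",
    "position": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
}

#: Variant_Classification values counted as non-synonymous (SNV context).
DEFAULT_NONSYNONYMOUS_CLASSES: frozenset[str] = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "Splice_Site",
    }
)

MANDATORY_FIELDS = ("sample_id", "gene", "variant_class", "variant_type", "protein_change")


class MafConfigError(ValueError):
    """A required column is missing or the configuration is inconsistent."""


@dataclass(frozen=True)
class VariantRecord:
    """One sample-variant incidence."""

    sample_id: str
    tumor_type: str
    gene: str
    variant_key: str
    variant_class: str
    variant_type: str
    chromosome: str | None = None
    position: int | None = None
    ref: str | None = None
    alt: str | None = None


@dataclass
class Cohort:
    """A set of variant incidences plus the sample roster.

    ``m`` counts every profiled sample, including samples with zero
    surviving variants after filtering; that convention matters because
    filtering must not shrink the denominator of per-tumor probabilities.
    ``records`` is a DataFrame with one row per (sample, variant) incidence
    and columns ``sample_id, tumor_type, gene, variant_key, variant_class,
    variant_type`` (plus optional coordinate columns).  ``samples`` has one
    row per profiled sample: ``sample_id, tumor_type, mutation_burden,
    signature_label``.
    """

    records: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.records):
            known = set(self.samples["sample_id"])
            stray = set(self.records["sample_id"]) - known
            if stray:
                raise ValueError(
                    f"{len(stray)} record sample_ids missing from roster, e.g. {sorted(stray)[:3]}"
                )

    @property
    def m(self) -> int:
        """Cohort size: number of distinct profiled samples."""
        return int(self.samples["sample_id"].nunique())

    @property
    def n_incidences(self) -> int:
        return int(len(self.records))

    def subset_samples(self, sample_ids: Iterable[str]) -> "Cohort":
        """Restrict the cohort to the given samples (roster and records)."""
        keep = set(sample_ids)
        return Cohort(
            records=self.records[self.records["sample_id"].isin(keep)].reset_index(drop=True),
            samples=self.samples[self.samples["sample_id"].isin(keep)].reset_index(drop=True),
        )


@dataclass(frozen=True)
class FrequencyVector:
    """The pairs (r, N_r) over a scope, plus the cohort size m.

    ``counts[r]`` is the number of distinct variants (or gene-pair events)
    observed in exactly ``r`` tumors.  ``sum(counts.values())`` is the
    number of distinct observed variants; ``sum(r * N_r)`` the total
    incidence count.
    """

    scope: str
    m: int
    counts: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r, n in self.counts.items():
            if r < 1:
                raise ValueError(f"frequency class r={r} < 1")
            if n < 0:
                raise ValueError(f"N_{r}={n} < 0")
            if r > self.m:
                raise ValueError(f"frequency class r={r} exceeds cohort size m={self.m}")

    @property
    def n_distinct(self) -> int:
        return sum(self.counts.values())

    @property
    def n_incidences(self) -> int:
        return sum(r * n for r, n in self.counts.items())

    @property
    def n1(self) -> int:
        """Number of singletons (variants observed in exactly one tumor)."""
        return int(self.counts.get(1, 0))

    @property
    def max_r(self) -> int:
        return max(self.counts) if self.counts else 0

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        return pd.DataFrame(
            {
                "scope": self.scope,
                "r": [r for r, _ in rows],
                "N_r": [n for _, n in rows],
                "m": self.m,
            }
        )


def _resolve_columns(header: Sequence[str], column_map: Mapping[str, str]) -> dict[str, str]:
    resolved = {}
    for fld in MANDATORY_FIELDS:
        col = column_map[fld]
        if col not in header:
            raise MafConfigError(
                f"MAF is missing mandatory column '{col}' (for field '{fld}'); "
                f"available columns: {list(header)}"
            )
        resolved[fld] = col
    for fld in ("tumor_type", "chromosome", "position", "ref", "alt"):
        col = column_map.get(fld)
        if col is not None and col in header:
            resolved[fld] = col
    return resolved


def make_variant_key(gene: str, protein_change: str) -> str:
    """Default protein-level variant identity, e.g. ``KRAS:G12D``."""
    pc = (protein_change or "").removeprefix("p.")
    return f"{gene}:{pc}"


def read_maf(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    key_scheme: str = "protein",
    annotations: pd.DataFrame | None = None,
) -> Cohort:
    """Read a tab-separated MAF into a :class:`Cohort`.

    Parameters
    ----------
    path:
        TSV file with a header row; ``#``-prefixed lines are skipped.
    column_map:
        Overrides for :data:`DEFAULT_COLUMN_MAP` (internal field -> column).
    key_scheme:
        ``"protein"`` keys variants by (gene, protein change);
        ``"genomic"`` by (chrom, pos, ref, alt).
    annotations:
        Optional per-sample table (``sample_id, tumor_type, mutation_burden,
        signature_label``).  Samples listed there but absent from the MAF
        stay in the roster (zero surviving variants still count in ``m``).

    Rows with a missing gene or sample are dropped (logged); duplicate
    (sample, variant_key) rows collapse to one incidence.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read MAF file {path}: {exc}") from exc
    resolved = _resolve_columns(df.columns, cmap)

    out = pd.DataFrame(
        {fld: df[col].astype(str).str.strip() for fld, col in resolved.items()}
    )
    n_raw = len(out)
    out = out[(out["sample_id"] != "") & (out["gene"] != "")]
    n_dropped = n_raw - len(out)
    if n_dropped:
        logger.info("read_maf: dropped %d rows with missing sample or gene", n_dropped)

    if key_scheme == "protein":
        out["variant_key"] = [
            make_variant_key(g, p) for g, p in zip(out["gene"], out["protein_change"])
        ]
    elif key_scheme == "genomic":
        for fld in ("chromosome", "position", "ref", "alt"):
            if fld not in out.columns:
                raise MafConfigError(
                    f"key_scheme='genomic' requires column '{cmap[fld]}' (field '{fld}')"
                )
        out["variant_key"] = (
            out["chromosome"] + ":" + out["position"] + ":" + out["ref"] + ">" + out["alt"]
        )
    else:
        raise MafConfigError(f"unknown key_scheme {key_scheme!r}; use 'protein' or 'genomic'")

    if "position" in out.columns:
        out["position"] = pd.to_numeric(out["position"], errors="coerce").astype("Int64")

    n_before = len(out)
    out = out.drop_duplicates(subset=["sample_id", "variant_key"]).reset_index(drop=True)
    if n_before - len(out):
        logger.info("read_maf: collapsed %d duplicate (sample, variant) rows", n_before - len(out))

    if annotations is not None:
        samples = annotations.copy()
        extra = sorted(set(out["sample_id"]) - set(samples["sample_id"]))
        if extra:
            raise MafConfigError(
                f"{len(extra)} MAF samples absent from annotations, e.g. {extra[:3]}"
            )
        out = out.drop(columns=["tumor_type"], errors="ignore").merge(
            samples[["sample_id", "tumor_type"]], on="sample_id", how="left"
        )
    else:
        if "tumor_type" not in out.columns:
            out["tumor_type"] = "UNKNOWN"
        samples = (
            out.groupby("sample_id", as_index=False)
            .agg(tumor_type=("tumor_type", "first"), mutation_burden=("variant_key", "size"))
        )
        samples["signature_label"] = "none"
    return Cohort(records=out, samples=samples.reset_index(drop=True))


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-sample annotation TSV.

    Requires ``sample_id`` and ``tumor_type``; ``mutation_burden`` and
    ``signature_label`` are optional (label defaults to ``none``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "tumor_type"):
        if col not in df.columns:
            raise MafConfigError(f"annotation table is missing mandatory column '{col}'")
    if "signature_label" not in df.columns:
        df["signature_label"] = "none"
    df["signature_label"] = df["signature_label"].fillna("none")
    return df


def write_maf(cohort: Cohort, path: str | Path, column_map: Mapping[str, str] | None = None) -> None:
    """Write a cohort's incidences back to a standard-column MAF TSV."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rec = cohort.records
    out = pd.DataFrame(
        {
            cmap["sample_id"]: rec["sample_id"],
            cmap["gene"]: rec["gene"],
            cmap["variant_class"]: rec["variant_class"],
            cmap["variant_type"]: rec["variant_type"],
            cmap["protein_change"]: rec["protein_change"]
            if "protein_change" in rec.columns
            else rec["variant_key"].str.split(":").str[-1],
            cmap["tumor_type"]: rec["tumor_type"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def filter_nonsynonymous_snv(
    cohort: Cohort, classes: Iterable[str] = DEFAULT_NONSYNONYMOUS_CLASSES
) -> Cohort:
    """Retain non-synonymous single-nucleotide variants only.

    Keeps records with ``variant_type == "SNP"`` and a variant class in
    ``classes``.  The sample roster — and hence ``m`` — is unchanged:
    a tumor whose variants are all silent remains a profiled tumor.
    """
    classes = set(classes)
    rec = cohort.records
    keep = (rec["variant_type"] == "SNP") & rec["variant_class"].isin(classes)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_nonsynonymous_snv: removed %d records", n_removed)
    return Cohort(records=rec[keep].reset_index(drop=True), samples=cohort.samples)


def build_frequency_vector(cohort: Cohort, scope: str = "global") -> FrequencyVector:
    """Tally the (r, N_r) pairs for a gene scope or genome-wide.

    ``r`` counts *tumors* harboring the variant, never records: a variant
    present in k tumors contributes one to ``N_k``.  ``scope`` is a HUGO
    gene symbol or ``"global"``.  A gene absent from the data yields an
    empty counts map with ``m`` still set.
    """
    rec = cohort.records
    if scope != "global":
        rec = rec[rec["gene"] == scope]
    # per-variant tumor counts (records are already unique per (sample, key))
    r_per_variant = rec.groupby("variant_key")["sample_id"].nunique()
    counts = Counter(int(r) for r in r_per_variant)
    return FrequencyVector(scope=scope, m=cohort.m, counts=dict(counts))


def frequency_vectors_by_gene(cohort: Cohort) -> dict[str, FrequencyVector]:
    """Frequency vectors for every gene with at least one incidence."""
    m = cohort.m
    out: dict[str, FrequencyVector] = {}
    per_gene = cohort.records.groupby("gene")["variant_key"]
    for gene, keys in per_gene:
        counts = Counter(Counter(keys).values())
        out[gene] = FrequencyVector(scope=gene, m=m, counts=dict(counts))
    return out


def write_frequency_vector(freq: FrequencyVector, path: str | Path, fmt: str = "tsv") -> None:
    """Serialize a frequency vector as TSV (scope, r, N_r, m) or JSON."""
    if fmt == "tsv":
        freq.to_frame().to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = {
            "scope": freq.scope,
            "m": freq.m,
            "counts": {str(r): n for r, n in sorted(freq.counts.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def replace_counts(freq: FrequencyVector, counts: Mapping[int, int]) -> FrequencyVector:
    return replace(freq, counts=dict(counts))
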