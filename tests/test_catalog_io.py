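"""MAF parsing, non-synonymous SNV filtering and frequency-vector construction."""

import pandas as pd
import pytest

from raremut.catalog_io import (
    FrequencyVector,
    MafConfigError,
    build_frequency_vector,
    filter_nonsynonymous_snv,
    frequency_vectors_by_gene,
    read_maf,
    write_maf,
)

from .conftest import brute_force_freq, cohort_from_records, maf_text


class TestReadMaf:
    def test_duplicate_rows_collapse_to_one_incidence(self, toy_maf):
        cohort = read_maf(toy_maf)
        assert cohort.m == 2
        assert cohort.n_incidences == 4

    def test_variant_key_is_protein_level(self, toy_maf):
        cohort = read_maf(toy_maf)
        assert "KRAS:G12D" in set(cohort.records["variant_key"])

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("Hugo_Symbol\tTumor_Sample_Barcode\nKRAS\tS1\n")
        with pytest.raises(MafConfigError, match="Variant_Classification"):
            read_maf(path)

    def test_silent_only_sample_still_counted_in_m(self, tmp_path):
        rows = [
            ("KRAS", "S1", "Missense_Mutation", "SNP", "p.G12D", "PAAD"),
            ("TP53", "S2", "Silent", "SNP", "p.P36P", "LUAD"),
        ]
        path = tmp_path / "silent.maf"
        path.write_text(maf_text(rows))
        cohort = filter_nonsynonymous_snv(read_maf(path))
        assert cohort.m == 2
        assert cohort.n_incidences == 1

    def test_simulated_maf_round_trips_m_and_incidences(self, small_sim, tmp_path):
        path = tmp_path / "sim.maf"
        write_maf(small_sim.cohort, path)
        reread = read_maf(path, annotations=small_sim.cohort.samples)
        assert reread.m == small_sim.cohort.m
        assert reread.n_incidences == small_sim.cohort.n_incidences


class TestFilterNonsynonymousSnv:
    def test_silent_snvs_all_removed_m_unchanged(self):
        cohort = cohort_from_records(
            [("S1", "PAAD", "KRAS", "KRAS:G12G"), ("S2", "PAAD", "TP53", "TP53:P36P")]
        )
        cohort.records["variant_class"] = "Silent"
        out = filter_nonsynonymous_snv(cohort)
        assert len(out.records) == 0
        assert out.m == 2

    def test_indels_excluded_by_variant_type(self):
        cohort = cohort_from_records(
            [("S1", "PAAD", "KRAS", "KRAS:G12D"), ("S1", "PAAD", "APC", "APC:T1556fs")]
        )
        cohort.records.loc[1, "variant_class"] = "Frame_Shift_Del"
        cohort.records.loc[1, "variant_type"] = "DEL"
        out = filter_nonsynonymous_snv(cohort)
        assert list(out.records["gene"]) == ["KRAS"]

    def test_mixed_cohort_default_class_set(self):
        # 10 records; by hand, 6 fall in the default non-synonymous SNV set
        spec = [
            ("Missense_Mutation", "SNP", True),
            ("Nonsense_Mutation", "SNP", True),
            ("Nonstop_Mutation", "SNP", True),
            ("Translation_Start_Site", "SNP", True),
            ("Splice_Site", "SNP", True),
            ("Missense_Mutation", "SNP", True),
            ("Silent", "SNP", False),
            ("3'UTR", "SNP", False),
            ("Splice_Site", "DEL", False),
            ("Frame_Shift_Ins", "INS", False),
        ]
        rows = [("S1", "PAAD", f"G{i}", f"G{i}:v") for i in range(len(spec))]
        cohort = cohort_from_records(rows)
        for i, (vc, vt, _) in enumerate(spec):
            cohort.records.loc[i, ["variant_class", "variant_type"]] = [vc, vt]
        out = filter_nonsynonymous_snv(cohort)
        assert len(out.records) == sum(keep for _, _, keep in spec) == 6


class TestFrequencyVector:
    def test_tumor_counts_not_record_counts(self):
        # variants seen in {1,1,1,2} tumors -> N1=3, N2=1
        cohort = cohort_from_records(
            [
                ("S1", "PAAD", "G", "G:a"),
                ("S1", "PAAD", "G", "G:d"),
                ("S2", "PAAD", "G", "G:b"),
                ("S2", "PAAD", "G", "G:d"),
                ("S3", "PAAD", "G", "G:c"),
            ]
        )
        fv = build_frequency_vector(cohort, "G")
        assert fv.counts == {1: 3, 2: 1}
        assert fv.m == 3

    def test_hotspot_gene_fixture(self, kras_like_freq):
        fv = kras_like_freq
        assert fv.counts[1] == 24 and fv.counts[2] == 3
        assert fv.counts[142] == fv.counts[120] == fv.counts[44] == 1
        assert fv.n_distinct == 30
        assert fv.n_incidences == 24 + 6 + 142 + 120 + 44

    def test_absent_gene_gives_empty_counts_with_m(self, small_sim):
        fv = build_frequency_vector(small_sim.cohort, "NOSUCHGENE")
        assert fv.counts == {}
        assert fv.m == small_sim.cohort.m

    def test_matches_brute_force_tally_on_simulation(self, small_sim):
        for scope in ("TAILY", "HOTTY", "global"):
            fv = build_frequency_vector(
                small_sim.cohort, scope if scope != "global" else "global"
            )
            oracle = brute_force_freq(
                small_sim.cohort, None if scope == "global" else scope
            )
            assert dict(fv.counts) == oracle

    def test_gene_scopes_sum_to_global(self, small_sim):
        by_gene = frequency_vectors_by_gene(small_sim.cohort)
        global_fv = build_frequency_vector(small_sim.cohort, "global")
        assert sum(fv.n_distinct for fv in by_gene.values()) == global_fv.n_distinct
        assert sum(fv.n_incidences for fv in by_gene.values()) == global_fv.n_incidences

    def test_invalid_vectors_rejected(self):
        with pytest.raises(ValueError):
            FrequencyVector(scope="g", m=5, counts={0: 3})
        with pytest.raises(ValueError):
            FrequencyVector(scope="g", m=5, counts={6: 1})
        with pytest.raises(ValueError):
            FrequencyVector(scope="g", m=5, counts={1: -1})

    def test_maf_round_trip_preserves_frequency_vectors(self, small_sim, tmp_path):
        path = tmp_path / "rt.maf"
        write_maf(small_sim.cohort, path)
        reread = read_maf(path, annotations=small_sim.cohort.samples)
        for gene in ("TAILY", "HOTTY"):
            assert dict(build_frequency_vector(reread, gene).counts) == dict(
                build_frequency_vector(small_sim.cohort, gene).counts
            )

    def test_duplicated_records_leave_n_r_unchanged(self, small_sim):
        cohort = small_sim.cohort
        doubled = type(cohort)(
            records=pd.concat([cohort.records, cohort.records], ignore_index=True)
            .drop_duplicates(["sample_id", "variant_key"])
            .reset_index(drop=True),
            samples=cohort.samples,
        )
        assert dict(build_frequency_vector(doubled, "global").counts) == dict(
            build_frequency_vector(cohort, "global").counts
        )
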