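"""Filter cascade, MAF emission and mutation co-occurrence."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ayamel.synthetic import generate_variant_records
from ayamel.variants import (
    FilterThresholds,
    VariantRecord,
    apply_filter_cascade,
    mutation_cooccurrence,
    read_maf,
    read_variants_tsv,
    read_variants_vcf,
    write_maf,
    write_variants_tsv,
)


def passing_record(**overrides) -> VariantRecord:
    rec = VariantRecord(
        chrom="7", pos=100, ref="A", alt="T", gene="BRAF", caller="merged",
        udp=50, uao=12, dao=3, af=0.3, homopolymer_count=2,
        gnomad_ad=0.0, global_af=0.0, seq_dir_bias_prob=0.5,
        sample_strand_bias_prob=0.5, sample_strand_bias_ratio=0.5,
        mdaf95=0.1, impact="MODERATE", consequence="missense_variant",
        sample="S1",
    )
    return dataclasses.replace(rec, **overrides)


# hand-trace of the 20-record seeded fixture against rules 1-8, frozen:
# index -> first failing rule (None = kept)
FIXTURE_TRACE = {
    0: None, 1: 1, 2: 1, 3: 2, 4: 3, 5: 4, 6: 5, 7: 6, 8: 6, 9: 7,
    10: 7, 11: 8, 12: 8, 13: None, 14: None, 15: None, 16: 1, 17: None,
    18: 3, 19: 4,
}


class TestFilterCascade:
    def test_low_unique_depth_attributed_to_rule_one(self):
        report = apply_filter_cascade([passing_record(udp=5)])
        assert not report.kept
        assert report.dropped_by_rule == {1: 1}

    def test_tert_promoter_waivers(self):
        rec = passing_record(
            gene="TERT", is_tert_promoter=True, uao=2, dao=0,
            seq_dir_bias_prob=0.05, impact="MODIFIER",
            consequence="upstream_gene_variant",
        )
        report = apply_filter_cascade([rec])
        assert report.kept == [rec]

    def test_tert_promoter_udp_not_waived(self):
        rec = passing_record(
            gene="TERT", is_tert_promoter=True, udp=5,
            consequence="upstream_gene_variant", impact="MODIFIER",
        )
        assert apply_filter_cascade([rec]).dropped_by_rule == {1: 1}

    def test_fixture_matches_hand_trace(self):
        records = generate_variant_records(20, seed=3)
        report = apply_filter_cascade(records)
        kept_idx = [i for i, r in enumerate(records) if r in report.kept]
        assert kept_idx == [i for i, rule in FIXTURE_TRACE.items() if rule is None]
        for rec, rule in report.dropped:
            assert FIXTURE_TRACE[records.index(rec)] == rule
        expected_counts: dict[int, int] = {}
        for rule in FIXTURE_TRACE.values():
            if rule is not None:
                expected_counts[rule] = expected_counts.get(rule, 0) + 1
        assert report.dropped_by_rule == expected_counts

    def test_report_counts_partition_input(self):
        records = generate_variant_records(40, seed=9)
        report = apply_filter_cascade(records)
        assert report.input_count == len(records) == len(report.kept) + sum(
            report.dropped_by_rule.values()
        )

    def test_keep_set_independent_of_rule_order(self):
        records = generate_variant_records(40, seed=5)
        baseline = apply_filter_cascade(records)
        rng = np.random.default_rng(0)
        for _ in range(5):
            order = list(rng.permutation(range(1, 9)))
            permuted = apply_filter_cascade(records, rule_order=order)
            assert permuted.kept == baseline.kept

    def test_idempotent_on_kept_set(self):
        records = generate_variant_records(40, seed=6)
        kept = apply_filter_cascade(records).kept
        again = apply_filter_cascade(kept)
        assert again.kept == kept
        assert not again.dropped_by_rule

    @given(st.integers(0, 2**31 - 1))
    def test_tightening_thresholds_never_keeps_more(self, seed):
        rng = np.random.default_rng(seed)
        records = generate_variant_records(30, seed=int(rng.integers(0, 1000)))
        base = FilterThresholds()
        tighter = FilterThresholds(
            r1_min_udp=base.r1_min_udp + int(rng.integers(0, 20)),
            r1_min_uao=base.r1_min_uao + int(rng.integers(0, 10)),
            r2_max_homopolymer=base.r2_max_homopolymer - int(rng.integers(0, 3)),
            r3_max_gnomad_ad=base.r3_max_gnomad_ad * float(rng.uniform(0.1, 1)),
            r5_min_seq_dir_bias_prob=base.r5_min_seq_dir_bias_prob
            + float(rng.uniform(0, 0.5)),
            r6_max_mdaf95=base.r6_max_mdaf95 * float(rng.uniform(0.1, 1)),
        )
        n_base = len(apply_filter_cascade(records, base).kept)
        n_tight = len(apply_filter_cascade(records, tighter).kept)
        assert n_tight <= n_base

    def test_malformed_record_reports_index(self):
        records = [passing_record(), passing_record(af=1.5)]
        with pytest.raises(ValueError, match="record 1"):
            apply_filter_cascade(records)

    def test_invalid_rule_order_rejected(self):
        with pytest.raises(ValueError):
            apply_filter_cascade([], rule_order=[1, 2, 3])


class TestMaf:
    def test_empty_report_header_only(self, tmp_path):
        report = apply_filter_cascade([])
        path = tmp_path / "empty.maf"
        maf = write_maf(report, path=path)
        assert maf.empty
        assert path.read_text().splitlines()[0].startswith("Hugo_Symbol\t")

    def test_single_snv_row(self):
        rec = passing_record()
        maf = write_maf(apply_filter_cascade([rec]), sample_id="AYA09")
        assert len(maf) == 1
        row = maf.iloc[0]
        assert row.Hugo_Symbol == "BRAF"
        assert row.Start_Position == row.End_Position == 100
        assert row.Variant_Type == "SNP"
        assert row.Tumor_Sample_Barcode == "AYA09"

    def test_missing_gene_becomes_unknown(self):
        maf = write_maf(apply_filter_cascade([passing_record(gene="")]))
        assert maf.iloc[0].Hugo_Symbol == "Unknown"

    def test_round_trip_core_fields(self, tmp_path):
        records = generate_variant_records(20, seed=3)
        report = apply_filter_cascade(records)
        path = tmp_path / "out.maf"
        write_maf(report, path=path)
        back = read_maf(path)
        assert len(back) == len(report.kept)
        for row, rec in zip(back.itertuples(index=False), report.kept):
            assert (row.Hugo_Symbol, row.Chromosome, row.Start_Position,
                    row.Reference_Allele, row.Tumor_Seq_Allele2) == (
                rec.gene, rec.chrom, rec.pos, rec.ref, rec.alt)


class TestCooccurrence:
    @staticmethod
    def maf_for(samples_a, samples_b):
        rows = [passing_record(gene="BRAF", sample=s) for s in samples_a]
        rows += [passing_record(gene="TERT", chrom="5", pos=1295228, sample=s,
                                is_tert_promoter=True, impact="MODIFIER",
                                consequence="upstream_gene_variant")
                 for s in samples_b]
        return write_maf(apply_filter_cascade(rows))

    def test_balanced_table_p_one(self):
        # table [[1,1],[1,1]]: BRAF+TERT in s1, BRAF in s2, TERT in s3, neither s4
        maf = self.maf_for(["s1", "s2"], ["s1", "s3"])
        odds, p = mutation_cooccurrence(maf, "BRAF", "TERT", ["s1", "s2", "s3", "s4"])
        assert p == 1.0

    def test_perfect_cooccurrence(self):
        maf = self.maf_for(["s1", "s2", "s3", "s4", "s5"], ["s1", "s2", "s3", "s4", "s5"])
        cohort = [f"s{i}" for i in range(1, 11)]
        odds, p = mutation_cooccurrence(maf, "BRAF", "TERT", cohort)
        assert odds > 1
        assert p == pytest.approx(2 / 252)  # [[5,0],[0,5]] by enumeration

    def test_absent_gene_gives_zero_row(self):
        maf = self.maf_for(["s1"], [])
        odds, p = mutation_cooccurrence(maf, "BRAF", "NRAS", ["s1", "s2"])
        assert p == 1.0

    def test_empty_cohort_rejected(self):
        maf = self.maf_for(["s1"], [])
        with pytest.raises(ValueError):
            mutation_cooccurrence(maf, "BRAF", "TERT", [])


class TestVariantIO:
    def test_tsv_round_trip(self, tmp_path):
        records = generate_variant_records(25, seed=4)
        path = tmp_path / "variants.tsv"
        write_variants_tsv(records, path)
        assert read_variants_tsv(path) == records

    def test_minimal_vcf_reader_with_interval_flag(self, tmp_path):
        vcf = tmp_path / "calls.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "7\t140453136\t.\tA\tT\t.\tPASS\t"
            "GENE=BRAF;CALLER=FreeBayes;UDP=60;UAO=15;DAO=2;AF=0.31;"
            "SSBP=0.3;SSBR=0.5;MDAF95=0.05;IMPACT=MODERATE;CSQ=missense_variant\n"
            "5\t1295228\t.\tG\tA\t.\tPASS\t"
            "GENE=TERT;CALLER=merged;UDP=40;UAO=2;DAO=0;AF=0.2;"
            "IMPACT=MODIFIER;CSQ=upstream_gene_variant\n"
        )
        records = read_variants_vcf(vcf, tert_promoter_interval=("5", 1295000, 1295600))
        assert records[0].gene == "BRAF" and records[0].caller == "FreeBayes"
        assert not records[0].is_tert_promoter
        assert records[1].is_tert_promoter
        report = apply_filter_cascade(records)
        assert len(report.kept) == 2
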