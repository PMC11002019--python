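"""Somatic variant post-calling filter cascade and MAF emission.

Variants arrive already called (FreeBayes / LoFreq, possibly merged) and
annotated with caller metrics, population frequencies and Ensembl-style
impact/consequence.  The cascade applies eight rules in a fixed printed
order; a record is kept iff it satisfies every applicable rule, and a
dropped record is attributed to the FIRST failing rule:

1. UDP > 10, and unless the variant lies in the TERT promoter, UAO > 6 and
   DAO > 1 (the promoter sits in a GC-rich low-efficiency region, hence
   the waiver).
2. Homopolymer count < 6.
3. gnomAD AD < 0.01 and global AF < 0.01 (germline/population filter).
4. No positive call for sequence-direction bias or sample strand bias
   (both boolean flags false).
5. Sequence-direction strand-bias probability > 0.1 (waived for the TERT
   promoter).
6. FreeBayes calls only: (sample strand-bias probability > 0.05 or sample
   strand-bias ratio > 0.4) and 95MDAF < 0.2.
7. LoFreq calls only: 0.1 < AF <= 0.2 (implemented as printed; the upper
   bound can be disabled in the thresholds).
8. Coding variants kept only with HIGH or MODERATE impact; non-coding
   variants only with a 5_prime_UTR_variant or upstream_gene_variant
   consequence.

Rules 6 and 7 do not apply to records merged from both callers.  All
thresholds live in :class:`FilterThresholds`, numbered like the rules.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "FilterThresholds",
    "FilterReport",
    "apply_filter_cascade",
    "write_maf",
    "read_maf",
    "mutation_cooccurrence",
    "read_variants_tsv",
    "write_variants_tsv",
]

#: sequence-ontology terms treated as non-coding for rule 8
NONCODING_CONSEQUENCES = frozenset(
    {
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intron_variant",
        "intergenic_variant",
        "non_coding_transcript_exon_variant",
        "regulatory_region_variant",
        "TF_binding_site_variant",
    }
)

CALLERS = ("FreeBayes", "LoFreq", "merged")


@dataclass
class VariantRecord:
    """One called variant with the metrics the cascade inspects."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    caller: str  # FreeBayes | LoFreq | merged
    udp: int  # unique depth
    uao: int  # unique alt observations
    dao: int  # duplex alt observations
    af: float  # allele fraction
    homopolymer_count: int = 0
    gnomad_ad: float = 0.0
    global_af: float = 0.0
    seq_dir_bias_flag: bool = False
    sample_strand_bias_flag: bool = False
    seq_dir_bias_prob: float = 1.0
    sample_strand_bias_prob: float = 1.0
    sample_strand_bias_ratio: float = 1.0
    mdaf95: float = 0.0  # 95th-percentile minimum detectable allele fraction
    impact: str = "MODERATE"  # HIGH | MODERATE | LOW | MODIFIER
    consequence: str = "missense_variant"
    is_tert_promoter: bool = False
    sample: str = ""

    def validate(self, index: int | None = None) -> None:
        where = f" (record {index})" if index is not None else ""
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1{where}")
        for name in ("udp", "uao", "dao", "homopolymer_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0{where}")
        for name in (
            "af", "gnomad_ad", "global_af", "seq_dir_bias_prob",
            "sample_strand_bias_prob", "sample_strand_bias_ratio", "mdaf95",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]{where}")
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}{where}")
        if self.impact not in {"HIGH", "MODERATE", "LOW", "MODIFIER"}:
            raise ValueError(f"unknown impact {self.impact!r}{where}")

    @property
    def is_coding(self) -> bool:
        return self.consequence not in NONCODING_CONSEQUENCES


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds; field names mirror the rule numbering."""

    r1_min_udp: int = 10          # UDP strictly greater than this
    r1_min_uao: int = 6           # waived for TERT promoter
    r1_min_dao: int = 1           # waived for TERT promoter
    r2_max_homopolymer: int = 6   # strictly less than this
    r3_max_gnomad_ad: float = 0.01
    r3_max_global_af: float = 0.01
    r5_min_seq_dir_bias_prob: float = 0.1  # waived for TERT promoter
    r6_min_ssb_prob: float = 0.05
    r6_min_ssb_ratio: float = 0.4
    r6_max_mdaf95: float = 0.2
    r7_min_af: float = 0.1
    r7_max_af: float = 0.2
    r7_upper_bound: bool = True   # the printed "AF <= 0.2" bound, toggleable
    r8_keep_impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    r8_keep_noncoding: frozenset[str] = frozenset(
        {"5_prime_UTR_variant", "upstream_gene_variant"}
    )


def _rule_passes(record: VariantRecord, rule: int, t: FilterThresholds) -> bool:
    if rule == 1:
        if record.udp <= t.r1_min_udp:
            return False
        if not record.is_tert_promoter:
            if record.uao <= t.r1_min_uao or record.dao <= t.r1_min_dao:
                return False
        return True
    if rule == 2:
        return record.homopolymer_count < t.r2_max_homopolymer
    if rule == 3:
        return record.gnomad_ad < t.r3_max_gnomad_ad and record.global_af < t.r3_max_global_af
    if rule == 4:
        return not record.seq_dir_bias_flag and not record.sample_strand_bias_flag
    if rule == 5:
        if record.is_tert_promoter:
            return True
        return record.seq_dir_bias_prob > t.r5_min_seq_dir_bias_prob
    if rule == 6:
        if record.caller != "FreeBayes":
            return True
        bias_ok = (
            record.sample_strand_bias_prob > t.r6_min_ssb_prob
            or record.sample_strand_bias_ratio > t.r6_min_ssb_ratio
        )
        return bias_ok and record.mdaf95 < t.r6_max_mdaf95
    if rule == 7:
        if record.caller != "LoFreq":
            return True
        if record.af <= t.r7_min_af:
            return False
        return (record.af <= t.r7_max_af) if t.r7_upper_bound else True
    if rule == 8:
        if record.is_coding:
            return record.impact in t.r8_keep_impacts
        return record.consequence in t.r8_keep_noncoding
    raise ValueError(f"unknown rule {rule}")


RULE_ORDER = (1, 2, 3, 4, 5, 6, 7, 8)


@dataclass
class FilterReport:
    kept: list[VariantRecord]
    dropped_by_rule: dict[int, int]
    input_count: int
    dropped: list[tuple[VariantRecord, int]] = field(default_factory=list)

    def first_failing_rule(self, record: VariantRecord) -> int | None:
        for rec, rule in self.dropped:
            if rec is record:
                return rule
        return None


def apply_filter_cascade(
    records: Sequence[VariantRecord],
    thresholds: FilterThresholds | None = None,
    rule_order: Sequence[int] = RULE_ORDER,
) -> FilterReport:
    """Run the eight-rule cascade over ``records``.

    Keep/drop is conjunctive over all applicable rules, so the decision is
    independent of ``rule_order``; only the per-rule attribution of drops
    follows the order (first failing rule wins).
    """
    t = thresholds or FilterThresholds()
    if sorted(rule_order) != list(RULE_ORDER):
        raise ValueError("rule_order must be a permutation of rules 1-8")
    kept: list[VariantRecord] = []
    dropped: list[tuple[VariantRecord, int]] = []
    counts = {r: 0 for r in RULE_ORDER}
    for i, rec in enumerate(records):
        try:
            rec.validate(index=i)
        except ValueError as exc:
            raise ValueError(f"malformed variant record: {exc}") from exc
        for rule in rule_order:
            if not _rule_passes(rec, rule, t):
                counts[rule] += 1
                dropped.append((rec, rule))
                break
        else:
            kept.append(rec)
    report = FilterReport(
        kept=kept,
        dropped_by_rule={r: c for r, c in counts.items() if c},
        input_count=len(records),
        dropped=dropped,
    )
    logger.info(
        "filter cascade: %d in, %d kept, drops by rule %s",
        report.input_count, len(kept), report.dropped_by_rule,
    )
    return report


# ---------------------------------------------------------------------------
# MAF emission
# ---------------------------------------------------------------------------

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
]

_CLASSIFICATION = {
    "missense_variant": "Missense_Mutation",
    "stop_gained": "Nonsense_Mutation",
    "stop_lost": "Nonstop_Mutation",
    "synonymous_variant": "Silent",
    "frameshift_variant": "Frame_Shift_Del",
    "inframe_deletion": "In_Frame_Del",
    "inframe_insertion": "In_Frame_Ins",
    "splice_acceptor_variant": "Splice_Site",
    "splice_donor_variant": "Splice_Site",
    "start_lost": "Translation_Start_Site",
    "5_prime_UTR_variant": "5'UTR",
    "3_prime_UTR_variant": "3'UTR",
    "upstream_gene_variant": "5'Flank",
    "downstream_gene_variant": "3'Flank",
    "intron_variant": "Intron",
    "intergenic_variant": "IGR",
}


def _variant_type(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(ref) > len(alt):
        return "DEL"
    if len(ref) < len(alt):
        return "INS"
    return "ONP"


def write_maf(
    report: FilterReport, sample_id: str = "", path: str | Path | None = None
) -> pd.DataFrame:
    """One MAF row per kept record (1-based inclusive coordinates).

    ``sample_id`` overrides the per-record sample barcode when given.
    Records without a gene symbol are emitted as ``Unknown`` with a
    warning.  Returns the MAF as a DataFrame and optionally writes a TSV.
    """
    rows = []
    for rec in report.kept:
        gene = rec.gene
        if not gene:
            logger.warning(
                "kept variant %s:%d %s>%s has no gene symbol; writing 'Unknown'",
                rec.chrom, rec.pos, rec.ref, rec.alt,
            )
            gene = "Unknown"
        end = rec.pos + max(len(rec.ref) - 1, 0)
        rows.append(
            {
                "Hugo_Symbol": gene,
                "Chromosome": rec.chrom,
                "Start_Position": rec.pos,
                "End_Position": end,
                "Reference_Allele": rec.ref,
                "Tumor_Seq_Allele2": rec.alt,
                "Variant_Classification": _CLASSIFICATION.get(rec.consequence, "Targeted_Region"),
                "Variant_Type": _variant_type(rec.ref, rec.alt),
                "Tumor_Sample_Barcode": sample_id or rec.sample or "Unknown",
            }
        )
    maf = pd.DataFrame(rows, columns=MAF_COLUMNS)
    if path is not None:
        maf.to_csv(path, sep="\t", index=False)
    return maf


def read_maf(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"Chromosome": str, "Tumor_Sample_Barcode": str}
    )


def mutation_cooccurrence(
    maf: pd.DataFrame, gene_a: str, gene_b: str, cohort: Sequence[str]
) -> tuple[float, float]:
    """Sample-level co-occurrence of mutations in two genes.

    Builds the 2x2 presence/absence table over ``cohort`` samples and
    returns (odds ratio, two-sided Fisher P).  The odds ratio uses the
    Haldane +0.5 correction when any cell is zero.  A gene absent from the
    MAF simply contributes a zero row.
    """
    if not len(cohort):
        raise ValueError("cohort must contain at least one sample")
    mutated = {
        g: set(maf.loc[maf["Hugo_Symbol"] == g, "Tumor_Sample_Barcode"])
        for g in (gene_a, gene_b)
    }
    both = a_only = b_only = neither = 0
    for s in cohort:
        in_a, in_b = s in mutated[gene_a], s in mutated[gene_b]
        if in_a and in_b:
            both += 1
        elif in_a:
            a_only += 1
        elif in_b:
            b_only += 1
        else:
            neither += 1
    table = [[both, a_only], [b_only, neither]]
    p = _stats.fisher_exact(table)
    cells = [both, a_only, b_only, neither]
    if 0 in cells:
        both, a_only, b_only, neither = (c + 0.5 for c in cells)
    odds_ratio = (both * neither) / (a_only * b_only)
    return float(odds_ratio), float(p)


# ---------------------------------------------------------------------------
# flat-file IO: TSV projection of annotated VCF INFO fields
# ---------------------------------------------------------------------------

_BOOL_FIELDS = {"seq_dir_bias_flag", "sample_strand_bias_flag", "is_tert_promoter"}
_INT_FIELDS = {"pos", "udp", "uao", "dao", "homopolymer_count"}
_FLOAT_FIELDS = {
    "af", "gnomad_ad", "global_af", "seq_dir_bias_prob",
    "sample_strand_bias_prob", "sample_strand_bias_ratio", "mdaf95",
}


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    names = [f.name for f in dc_fields(VariantRecord)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(names)
        for rec in records:
            w.writerow([getattr(rec, n) for n in names])


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            kwargs: dict = {}
            for name, raw in row.items():
                if name in _BOOL_FIELDS:
                    kwargs[name] = raw.strip().lower() in {"1", "true", "yes"}
                elif name in _INT_FIELDS:
                    kwargs[name] = int(raw)
                elif name in _FLOAT_FIELDS:
                    kwargs[name] = float(raw)
                else:
                    kwargs[name] = raw
            rec = VariantRecord(**kwargs)
            rec.validate(index=i)
            records.append(rec)
    return records


#: default mapping from VCF INFO keys to VariantRecord fields; callers with
#: a different annotation schema pass their own map.
DEFAULT_INFO_MAP = {
    "GENE": "gene",
    "CALLER": "caller",
    "UDP": "udp",
    "UAO": "uao",
    "DAO": "dao",
    "AF": "af",
    "HPC": "homopolymer_count",
    "GNOMAD_AD": "gnomad_ad",
    "GAF": "global_af",
    "SDBF": "seq_dir_bias_flag",
    "SSBF": "sample_strand_bias_flag",
    "SDBP": "seq_dir_bias_prob",
    "SSBP": "sample_strand_bias_prob",
    "SSBR": "sample_strand_bias_ratio",
    "MDAF95": "mdaf95",
    "IMPACT": "impact",
    "CSQ": "consequence",
    "TERTP": "is_tert_promoter",
    "SAMPLE": "sample",
}


def read_variants_vcf(
    path: str | Path,
    info_map: dict[str, str] | None = None,
    tert_promoter_interval: tuple[str, int, int] | None = None,
) -> list[VariantRecord]:
    """Minimal VCF reader (CHROM, POS, REF, ALT, INFO key=value pairs).

    ``info_map`` maps INFO keys to VariantRecord field names (default
    :data:`DEFAULT_INFO_MAP`).  TERT promoter membership comes either from
    a mapped flag or from an explicit (chrom, start, end) interval
    (1-based inclusive; assembly-dependent, so never hard-coded).
    """
    info_map = dict(info_map or DEFAULT_INFO_MAP)
    records = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 8:
            raise ValueError(f"malformed VCF line: {line!r}")
        chrom, pos, _id, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
        info = parts[7]
        kwargs: dict = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                        "gene": "", "caller": "merged", "udp": 0, "uao": 0,
                        "dao": 0, "af": 0.0}
        for item in info.split(";"):
            if "=" not in item:
                continue
            key, raw = item.split("=", 1)
            name = info_map.get(key)
            if name is None:
                continue
            if name in _BOOL_FIELDS:
                kwargs[name] = raw.strip().lower() in {"1", "true", "yes"}
            elif name in _INT_FIELDS:
                kwargs[name] = int(raw)
            elif name in _FLOAT_FIELDS:
                kwargs[name] = float(raw)
            else:
                kwargs[name] = raw
        rec = VariantRecord(**kwargs)
        if tert_promoter_interval is not None:
            c, start, end = tert_promoter_interval
            if rec.chrom == c and start <= rec.pos <= end:
                rec.is_tert_promoter = True
        rec.validate(index=len(records))
        records.append(rec)
    return records
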