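"""Synthetic cohort generator.

Emulates the statistical structure of a baseline melanoma ICI cohort so
every analysis stage is testable without patient data:

* bulk RNA-seq counts: negative-binomial (mean/dispersion, variance
  mu + a*mu^2, dispersion shared across genes) with per-sample library
  factors and a planted resistance expression program.  Three outcome
  classes are generated: ``resistant`` (PD-like, full planted effect),
  ``CR`` (complete responders, no effect) and ``PR`` (partial responders,
  half the effect on the log2 scale — they are excluded from signature
  training downstream, and the half effect exercises that rule);
* multiplex-IF cell tables: homogeneous Poisson counts per (phenotype,
  region) with intensity x area expected cells, uniform coordinates inside
  two disjoint rectangles (intratumor and peritumor), areas in mm^2 and
  coordinates in micrometers;
* annotated variant records stratified so every filter rule's pass and
  fail branch is covered, including TERT-promoter records and both caller
  labels;
* outcome tables with exponential survival (class-dependent hazard, in
  events per month) and independent exponential censoring.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .spatial import MARKERS, CellTable
from .variants import VariantRecord

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "ConfigurationError",
    "generate_expression_cohort",
    "generate_cell_table",
    "generate_variant_records",
    "generate_outcomes",
    "DEFAULT_PHENOTYPE_MARKERS",
]

CLASSES = ("resistant", "CR", "PR")

#: marker flag patterns for generated phenotypes (SOX10 marks tumor cells)
DEFAULT_PHENOTYPE_MARKERS: dict[str, dict[str, int]] = {
    "tumor": {"SOX10": 1},
    "t_cell": {"CD3": 1},
    "cytotoxic_t": {"CD3": 1, "CD8": 1, "GZMB": 1},
    "treg": {"CD3": 1, "FOXP3": 1},
    "treg_activated": {"CD3": 1, "FOXP3": 1, "ICOS": 1},
    "exhausted_t": {"CD3": 1, "CD8": 1, "PD1": 1},
}

# Default spatial intensities (cells per mm^2), informed by reported
# peritumoral vs intratumoral regulatory and cytotoxic T-cell densities in
# ICI-treated melanoma (Tregs concentrate peritumorally, ~100 vs ~17).
_DEFAULT_INTENSITIES: dict[tuple[str, str], float] = {
    ("tumor", "intratumor"): 1500.0,
    ("tumor", "peritumor"): 100.0,
    ("t_cell", "intratumor"): 150.0,
    ("t_cell", "peritumor"): 400.0,
    ("cytotoxic_t", "intratumor"): 250.0,
    ("cytotoxic_t", "peritumor"): 600.0,
    ("treg", "intratumor"): 17.0,
    ("treg", "peritumor"): 100.0,
    ("treg_activated", "intratumor"): 10.0,
    ("treg_activated", "peritumor"): 60.0,
    ("exhausted_t", "intratumor"): 80.0,
    ("exhausted_t", "peritumor"): 500.0,
}

LN2 = math.log(2.0)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition knobs for all generators.

    Defaults reflect the cohort scale the analysis is designed around:
    two trainable outcome classes of 24 samples each, 2,000 genes of which
    100 carry a planted |log2 fold change| of 1.5, moderately overdispersed
    counts, and PD-like monthly hazards several times those of complete
    responders (median PFS of a few months vs years).
    """

    n_per_group: int = 24
    n_genes: int = 2000
    n_signature_genes: int = 100
    log2_effect: float = 1.5
    nb_dispersion: float = 0.15
    baseline_mean: float = 100.0
    seed: int = 0
    cell_intensities: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_INTENSITIES)
    )
    region_areas: Mapping[str, float] = field(
        default_factory=lambda: {"intratumor": 2.0, "peritumor": 1.0}
    )
    hazard_by_group: Mapping[str, float] = field(
        default_factory=lambda: {
            "resistant": LN2 / 3.4,  # median PFS ~3.4 months
            "PR": LN2 / 10.0,
            "CR": LN2 / 40.0,
        }
    )
    censoring_rate: float = 0.01  # events per month; 0 disables censoring

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not (0 <= self.n_signature_genes <= self.n_genes):
            raise ConfigurationError("n_signature_genes must be in [0, n_genes]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be > 0")
        for region, area in self.region_areas.items():
            if area <= 0:
                raise ConfigurationError(f"region_areas[{region}] must be > 0")
        for (ph, region), rate in self.cell_intensities.items():
            if rate < 0:
                raise ConfigurationError(f"cell_intensities[{ph}, {region}] must be >= 0")
            if region not in self.region_areas:
                raise ConfigurationError(f"unknown region name {region!r} in cell_intensities")
        for group, h in self.hazard_by_group.items():
            if h <= 0:
                raise ConfigurationError(f"hazard_by_group[{group}] must be > 0")
        if self.censoring_rate < 0:
            raise ConfigurationError("censoring_rate must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of the planted resistance program, for recovery tests."""

    up_genes: list[str]
    down_genes: list[str]
    class_labels: dict[str, str]  # sample -> resistant | CR | PR

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up_genes and down_genes must be disjoint")

    def samples_of(self, label: str) -> list[str]:
        return [s for s, c in self.class_labels.items() if c == label]


# A handful of immune marker genes placed at the head of the gene list (and
# never planted), so immunophenogram and drug-matching stages see real
# symbols in synthetic cohorts.
_MARKER_GENES = [
    "CD8A", "CD8B", "GZMA", "GZMB", "PRF1", "IFNG", "TBX21",
    "FOXP3", "IL10", "TGFB1", "ENTPD1", "CCL22", "IDO1",
    "PDCD1", "CTLA4", "LAG3", "TIGIT", "HAVCR2", "CD274", "BTLA",
    "HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2", "HLA-DRA",
    "IL2RG", "TNFRSF9", "CD3D", "ICOS",
]


def sample_nb(rng: np.random.Generator, mu, dispersion: float) -> np.ndarray:
    """NB draws in the mean/dispersion parameterization (var = mu + a*mu^2).

    numpy's negative_binomial takes (shape n, success prob p) with
    n = 1/dispersion and p = n / (n + mu).
    """
    mu = np.asarray(mu, dtype=float)
    n_param = 1.0 / dispersion
    return rng.negative_binomial(n_param, n_param / (n_param + mu))


def _gene_names(n_genes: int) -> list[str]:
    names = _MARKER_GENES[:n_genes]
    names += [f"G{i:05d}" for i in range(n_genes - len(names))]
    return names


def generate_expression_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """NB counts with a planted resistance program.

    Per-gene baseline means are log-normal around ``baseline_mean``
    (median), library factors log-normal with sigma 0.25.  Planted genes
    have their mean multiplied by 2**(+-log2_effect) in the resistant
    class (half the exponent in PR); the first half of the planted genes
    go up in resistance, the second half up in CR.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    samples = []
    labels: dict[str, str] = {}
    for cls, prefix in zip(CLASSES, ("PD", "CR", "PR")):
        for i in range(config.n_per_group):
            s = f"{prefix}{i + 1:02d}"
            samples.append(s)
            labels[s] = cls

    base = config.baseline_mean * np.exp(rng.normal(0.0, 1.0, size=config.n_genes))
    lib = np.exp(rng.normal(0.0, 0.25, size=len(samples)))

    # plant the program outside the named marker genes
    candidates = np.arange(len(_MARKER_GENES[: config.n_genes]), config.n_genes)
    if config.n_signature_genes > len(candidates):
        raise ConfigurationError(
            "n_signature_genes exceeds the number of plantable genes"
        )
    planted = rng.choice(candidates, size=config.n_signature_genes, replace=False)
    n_up = config.n_signature_genes - config.n_signature_genes // 2
    up_idx = planted[:n_up]
    down_idx = planted[n_up:]

    effect_by_class = {"resistant": config.log2_effect, "PR": config.log2_effect / 2.0, "CR": 0.0}
    log2shift = np.zeros((config.n_genes, len(samples)))
    for j, s in enumerate(samples):
        e = effect_by_class[labels[s]]
        log2shift[up_idx, j] += e
        log2shift[down_idx, j] -= e

    mu = base[:, None] * lib[None, :] * np.exp2(log2shift)
    counts = sample_nb(rng, mu, config.nb_dispersion)

    matrix = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    truth = PlantedTruth(
        up_genes=[genes[i] for i in up_idx],
        down_genes=[genes[i] for i in down_idx],
        class_labels=labels,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# spatial cell tables
# ---------------------------------------------------------------------------

_REGION_HEIGHT_UM = 1000.0
_REGION_GAP_UM = 100.0


def _region_rectangles(region_areas: Mapping[str, float]) -> dict[str, tuple[float, float, float, float]]:
    """Disjoint side-by-side rectangles (x0, x1, y0, y1) in micrometers."""
    rects = {}
    x0 = 0.0
    for region, area_mm2 in region_areas.items():
        width = area_mm2 * 1e6 / _REGION_HEIGHT_UM
        rects[region] = (x0, x0 + width, 0.0, _REGION_HEIGHT_UM)
        x0 += width + _REGION_GAP_UM
    return rects


def generate_cell_table(config: SimulationConfig) -> CellTable:
    """Homogeneous Poisson point pattern per (phenotype, region)."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rects = _region_rectangles(config.region_areas)
    rows = []
    for (phenotype, region), rate in sorted(config.cell_intensities.items()):
        if phenotype not in DEFAULT_PHENOTYPE_MARKERS:
            raise ConfigurationError(f"unknown phenotype {phenotype!r}")
        area = config.region_areas[region]
        n = int(rng.poisson(rate * area))
        x0, x1, y0, y1 = rects[region]
        xs = rng.uniform(x0, x1, size=n)
        ys = rng.uniform(y0, y1, size=n)
        flags = {m: DEFAULT_PHENOTYPE_MARKERS[phenotype].get(m, 0) for m in MARKERS}
        for k in range(n):
            rows.append({"x_um": xs[k], "y_um": ys[k], "region": region, **flags})
    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "region", *MARKERS])
    return CellTable(cells=cells, region_areas=dict(config.region_areas))


# ---------------------------------------------------------------------------
# variant fixtures
# ---------------------------------------------------------------------------

def _base_variant(**overrides) -> VariantRecord:
    rec = VariantRecord(
        chrom="7", pos=140_453_136, ref="A", alt="T", gene="BRAF",
        caller="merged", udp=50, uao=12, dao=3, af=0.30,
        homopolymer_count=2, gnomad_ad=0.0, global_af=0.0,
        seq_dir_bias_flag=False, sample_strand_bias_flag=False,
        seq_dir_bias_prob=0.5, sample_strand_bias_prob=0.5,
        sample_strand_bias_ratio=0.5, mdaf95=0.1,
        impact="MODERATE", consequence="missense_variant",
        is_tert_promoter=False, sample="AYA01",
    )
    return dataclasses.replace(rec, **overrides)


def _stratified_variants() -> list[VariantRecord]:
    """20 deterministic records covering every rule's pass and fail branch."""
    v = _base_variant
    return [
        v(sample="AYA01"),                                           # 0 kept
        v(udp=5, gene="NRAS", chrom="1", pos=115_256_529, sample="AYA02"),      # 1 rule 1 (UDP)
        v(uao=3, gene="PTEN", chrom="10", pos=89_692_905, sample="AYA03"),      # 2 rule 1 (UAO)
        v(homopolymer_count=8, gene="TP53", chrom="17", pos=7_577_120,
          sample="AYA04"),                                           # 3 rule 2
        v(gnomad_ad=0.05, gene="KIT", chrom="4", pos=55_593_464, sample="AYA05"),  # 4 rule 3
        v(seq_dir_bias_flag=True, gene="CDKN2A", chrom="9", pos=21_971_120,
          sample="AYA06"),                                           # 5 rule 4
        v(seq_dir_bias_prob=0.05, gene="NF1", chrom="17", pos=29_553_485,
          sample="AYA07"),                                           # 6 rule 5
        v(caller="FreeBayes", sample_strand_bias_prob=0.01,
          sample_strand_bias_ratio=0.2, gene="KRAS", chrom="12", pos=25_398_284,
          sample="AYA08"),                                           # 7 rule 6 (bias)
        v(caller="FreeBayes", mdaf95=0.3, gene="PIK3CA", chrom="3",
          pos=178_936_091, sample="AYA09"),                          # 8 rule 6 (MDAF)
        v(caller="LoFreq", af=0.5, gene="PTEN", chrom="10", pos=89_717_672,
          sample="AYA10"),                                           # 9 rule 7 (high AF)
        v(caller="LoFreq", af=0.05, gene="NRAS", chrom="1", pos=115_258_747,
          sample="AYA11"),                                           # 10 rule 7 (low AF)
        v(impact="LOW", consequence="synonymous_variant", gene="TP53",
          chrom="17", pos=7_578_210, sample="AYA12"),                # 11 rule 8 (coding)
        v(consequence="intron_variant", impact="MODIFIER", gene="CDKN2A",
          chrom="9", pos=21_970_900, sample="AYA13"),                # 12 rule 8 (non-coding)
        v(gene="TERT", chrom="5", pos=1_295_228, ref="G", alt="A",
          is_tert_promoter=True, uao=2, dao=0, seq_dir_bias_prob=0.05,
          impact="MODIFIER", consequence="upstream_gene_variant",
          sample="AYA01"),                                           # 13 kept (waivers)
        v(caller="FreeBayes", sample_strand_bias_prob=0.2, mdaf95=0.1,
          gene="BRAF", chrom="7", pos=140_453_137, sample="AYA02"),  # 14 kept
        v(caller="LoFreq", af=0.15, gene="NRAS", chrom="1", pos=115_252_203,
          sample="AYA03"),                                           # 15 kept
        v(gene="TERT", chrom="5", pos=1_295_250, ref="G", alt="A",
          is_tert_promoter=True, udp=5, impact="MODIFIER",
          consequence="upstream_gene_variant", sample="AYA04"),      # 16 rule 1 (UDP not waived)
        v(gene="PTEN", chrom="10", pos=89_720_852, impact="HIGH",
          consequence="stop_gained", sample="AYA05"),                # 17 kept
        v(global_af=0.05, gene="KIT", chrom="4", pos=55_599_321,
          sample="AYA06"),                                           # 18 rule 3 (global AF)
        v(sample_strand_bias_flag=True, gene="KRAS", chrom="12",
          pos=25_380_275, sample="AYA07"),                           # 19 rule 4
    ]


def generate_variant_records(n: int, seed: int) -> list[VariantRecord]:
    """Variant fixture factory.

    For n >= 20 the first 20 records are a deterministic stratified set
    covering every filter rule's pass and fail branch (including TERT-
    promoter waivers and both caller labels); extra records are random.
    For n < 20 the stratified set is truncated.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    base = _stratified_variants()[:n]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    genes = ["BRAF", "NRAS", "PTEN", "TP53", "CDKN2A", "KIT", "KRAS", "NF1"]
    extra = []
    for i in range(max(0, n - len(base))):
        extra.append(
            _base_variant(
                gene=str(rng.choice(genes)),
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(1, 2_000_000)),
                caller=str(rng.choice(CALLER_CHOICES)),
                udp=int(rng.integers(5, 100)),
                uao=int(rng.integers(0, 30)),
                dao=int(rng.integers(0, 6)),
                af=float(rng.uniform(0.01, 0.6)),
                homopolymer_count=int(rng.integers(0, 10)),
                gnomad_ad=float(rng.uniform(0, 0.03)),
                global_af=float(rng.uniform(0, 0.03)),
                seq_dir_bias_flag=bool(rng.random() < 0.1),
                sample_strand_bias_flag=bool(rng.random() < 0.1),
                seq_dir_bias_prob=float(rng.uniform(0, 1)),
                sample_strand_bias_prob=float(rng.uniform(0, 1)),
                sample_strand_bias_ratio=float(rng.uniform(0, 1)),
                mdaf95=float(rng.uniform(0, 0.4)),
                impact=str(rng.choice(["HIGH", "MODERATE", "LOW", "MODIFIER"])),
                consequence=str(
                    rng.choice(
                        ["missense_variant", "synonymous_variant",
                         "5_prime_UTR_variant", "intron_variant"]
                    )
                ),
                sample=f"AYA{int(rng.integers(1, 29)):02d}",
            )
        )
    return base + extra


CALLER_CHOICES = ("FreeBayes", "LoFreq", "merged")


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

_RESPONSE_OF_CLASS = {"resistant": "PD", "CR": "CR", "PR": "PR"}
# combination ICI is over-represented among responders, mirroring observed
# treatment-response association
_COMBO_PROB = {"CR": 0.8, "PR": 0.6, "resistant": 0.35}


def generate_outcomes(truth: PlantedTruth, config: SimulationConfig) -> pd.DataFrame:
    """Exponential PFS/OS with class-dependent hazards.

    PFS time ~ Exp(hazard_by_group[class]); OS hazard is one third of the
    PFS hazard.  An independent Exp(censoring_rate) censoring time right-
    censors both endpoints (censoring_rate=0 disables censoring).
    Columns: sample, response, treatment, pfs_months, pfs_event,
    os_months, os_event.
    """
    config.validate()
    if not truth.class_labels:
        raise ValueError("truth has no class labels")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    rows = []
    for s, cls in truth.class_labels.items():
        h = config.hazard_by_group[cls]
        pfs = rng.exponential(1.0 / h)
        os_time = pfs + rng.exponential(3.0 / h)
        if config.censoring_rate > 0:
            censor = rng.exponential(1.0 / config.censoring_rate)
        else:
            censor = math.inf
        treatment = "combination" if rng.random() < _COMBO_PROB[cls] else (
            "anti-PD-1" if rng.random() < 0.8 else "anti-CTLA-4"
        )
        rows.append(
            {
                "sample": s,
                "response": _RESPONSE_OF_CLASS[cls],
                "treatment": treatment,
                "pfs_months": min(pfs, censor),
                "pfs_event": int(pfs <= censor),
                "os_months": min(os_time, censor),
                "os_event": int(os_time <= censor),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sidecar IO
# ---------------------------------------------------------------------------

def write_truth_json(truth: PlantedTruth, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "up_genes": truth.up_genes,
                "down_genes": truth.down_genes,
                "class_labels": truth.class_labels,
            },
            indent=2,
        )
    )


def read_truth_json(path: str | Path) -> PlantedTruth:
    data = json.loads(Path(path).read_text())
    return PlantedTruth(
        up_genes=data["up_genes"],
        down_genes=data["down_genes"],
        class_labels=data["class_labels"],
    )


def write_outcomes_csv(outcomes: pd.DataFrame, path: str | Path) -> None:
    outcomes.to_csv(path, index=False)


def read_outcomes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
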