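"""Druggable-target matching against a drug-gene interaction table.

Per-patient expressed and mutated gene sets are cross-matched with a
DGIdb-style interaction table (gene, drug, interaction type, category
tags).  An interaction matches when its gene is expressed or mutated in
the patient AND its tags contain every required tag for that basis.  The
required tags are configurable per basis because immunotherapy-style
targets are typically matched on expression while small-molecule targets
are matched on mutations; the default requires
{approved, antineoplastic, immunotherapy} for expression-based matches and
{approved, antineoplastic} for mutation-based ones.

A small synthetic interaction snapshot ships with the package for demos
and tests (``data/drug_gene_interactions_synthetic.tsv``); real analyses
should load an actual DGIdb export with :func:`load_interactions`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DrugGeneInteraction",
    "PatientTargetProfile",
    "load_interactions",
    "load_synthetic_interactions",
    "expressed_genes_from_matrix",
    "match_druggable_targets",
]

DEFAULT_EXPRESSION_TAGS = frozenset({"approved", "antineoplastic", "immunotherapy"})
DEFAULT_MUTATION_TAGS = frozenset({"approved", "antineoplastic"})


@dataclass(frozen=True)
class DrugGeneInteraction:
    gene: str
    drug: str
    interaction_type: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene or not self.drug:
            raise ValueError("gene and drug must be nonempty")
        object.__setattr__(self, "categories", frozenset(self.categories))


@dataclass
class PatientTargetProfile:
    patient: str
    expressed_genes: set[str]
    mutated_genes: set[str]
    matched: list[tuple[str, str, str]] = field(default_factory=list)  # (gene, drug, basis)


def load_interactions(path: str | Path) -> list[DrugGeneInteraction]:
    """Read a TSV with columns gene, drug, interaction_type, categories
    (semicolon-separated tags)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "drug", "interaction_type", "categories"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        tags = frozenset(t.strip() for t in str(row.categories).split(";") if t.strip())
        out.append(
            DrugGeneInteraction(
                gene=str(row.gene), drug=str(row.drug),
                interaction_type=str(row.interaction_type), categories=tags,
            )
        )
    return out


def load_synthetic_interactions() -> list[DrugGeneInteraction]:
    """The packaged synthetic DGIdb-style snapshot."""
    ref = resources.files("ayamel").joinpath("data/drug_gene_interactions_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_interactions(path)


def expressed_genes_from_matrix(
    matrix: ExpressionMatrix, sample: str, quantile: float = 0.75
) -> set[str]:
    """Genes whose normalized expression in ``sample`` exceeds the cohort
    per-gene quantile (default: upper quartile)."""
    values = matrix.normalized()
    threshold = values.quantile(quantile, axis=1)
    return set(values.index[values[sample] > threshold])


def match_druggable_targets(
    patient: str,
    expressed_genes: Iterable[str],
    mutated_genes: Iterable[str],
    interactions: Sequence[DrugGeneInteraction],
    required_tags_expression: frozenset[str] = DEFAULT_EXPRESSION_TAGS,
    required_tags_mutation: frozenset[str] = DEFAULT_MUTATION_TAGS,
) -> PatientTargetProfile:
    """Cross-match one patient's expressed/mutated genes with the table.

    Output matches are sorted by gene then drug; a gene both expressed and
    mutated can match on both bases.  An empty interaction table yields an
    empty match list with a warning.
    """
    expressed = set(expressed_genes)
    mutated = set(mutated_genes)
    if not interactions:
        warnings.warn("empty drug-gene interaction table; no matches possible")
    matched: list[tuple[str, str, str]] = []
    for it in interactions:
        if it.gene in expressed and required_tags_expression <= it.categories:
            matched.append((it.gene, it.drug, "expression"))
        if it.gene in mutated and required_tags_mutation <= it.categories:
            matched.append((it.gene, it.drug, "mutation"))
    matched = sorted(set(matched))
    return PatientTargetProfile(
        patient=patient, expressed_genes=expressed, mutated_genes=mutated, matched=matched
    )


def matches_to_frame(profiles: Sequence[PatientTargetProfile]) -> pd.DataFrame:
    rows = [
        {"patient": p.patient, "gene": g, "drug": d, "basis": b}
        for p in profiles
        for (g, d, b) in p.matched
    ]
    return pd.DataFrame(rows, columns=["patient", "gene", "drug", "basis"])
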