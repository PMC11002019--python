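"""Directed rank-based single-sample gene-signature scoring.

The central statistic: for a signed ("directed") gene set, every gene of a
sample's transcriptome is ranked once by abundance (average ranks on ties);
expected-up genes (+1) contribute their increasing-abundance rank, expected-
down genes (-1) their decreasing-abundance rank (G + 1 - rank), and the
score is the mean of these directed ranks over the set genes observed in
the data.  Set genes absent from the data are excluded from both numerator
and denominator.

A resistance signature (e.g. a YIM-style score) is constructed from a
differential-expression table by weighting genes up in resistant (PD)
patients +1 and genes up in complete responders -1.  Comparator signatures
are supported: equal-weight (+1) sets such as IPRES, and composite immune
scores merging positively weighted effector components with negatively
weighted suppressive components (IMMU-style).

Also here: immunophenogram category profiles (mean cross-sample expression
z-scores of marker genes per immune category) and signature overlap
measures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedGeneSet",
    "ScoreResult",
    "ImmunophenogramProfile",
    "UndefinedScoreError",
    "EmptySignatureError",
    "build_directed_signature",
    "directed_rank_score",
    "score_cohort",
    "build_composite_signature",
    "immunophenogram_scores",
    "signature_overlap",
    "read_gmt",
    "write_gmt",
    "DEFAULT_IMMUNOPHENOGRAM_CATEGORIES",
]


class UndefinedScoreError(RuntimeError):
    """Raised when a sample shares no genes with the scored set."""


class EmptySignatureError(RuntimeError):
    """Raised when no gene passes the signature-construction thresholds."""


@dataclass(frozen=True)
class DirectedGeneSet:
    """A gene set whose members carry an expected direction (+1 or -1)."""

    name: str
    weights: Mapping[str, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("a directed gene set needs at least one gene")
        bad = {g: w for g, w in self.weights.items() if w not in (+1, -1)}
        if bad:
            raise ValueError(f"weights must be +1 or -1, got {bad}")
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def genes(self) -> set[str]:
        return set(self.weights)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class ScoreResult:
    sample: str
    score: float
    n_used: int
    ranks_used: Mapping[str, float]


@dataclass(frozen=True)
class ImmunophenogramProfile:
    sample: str
    category_scores: Mapping[str, float]  # NaN flags a category with no gene present


# Marker panel for the four immunophenogram categories.  These lists are an
# editable reconstruction of commonly used marker genes per category; any
# user-supplied category -> gene-list mapping (e.g. from a GMT file) can be
# passed instead.
DEFAULT_IMMUNOPHENOGRAM_CATEGORIES: dict[str, list[str]] = {
    "effector cells": ["CD8A", "CD8B", "GZMA", "GZMB", "PRF1", "IFNG", "TBX21"],
    "suppressor cells": ["FOXP3", "IL10", "TGFB1", "ENTPD1", "CCL22", "IDO1"],
    "checkpoints": ["PDCD1", "CTLA4", "LAG3", "TIGIT", "HAVCR2", "CD274", "BTLA"],
    "MHC": ["HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2", "HLA-DRA"],
}


def build_directed_signature(
    de: pd.DataFrame, alpha: float = 0.05, name: str = "signature"
) -> DirectedGeneSet:
    """Signed signature from a DE table (group_a = resistant, group_b = CR).

    Genes with adjusted P < ``alpha`` are weighted by the sign of their
    log2 fold change: +1 when up in the resistant group, -1 when up in the
    complete responders.  PR samples must have been excluded upstream of
    the DE comparison.
    """
    sig = de[(de["padj"] < alpha) & (de["log2fc"] != 0)]
    if sig.empty:
        raise EmptySignatureError(
            f"no gene passes padj < {alpha}; cannot build a directed signature"
        )
    weights = {g: (1 if fc > 0 else -1) for g, fc in sig["log2fc"].items()}
    return DirectedGeneSet(name=name, weights=weights, provenance=f"DE, padj<{alpha}")


def directed_rank_score(
    sample_expression: Mapping[str, float] | pd.Series,
    gene_set: DirectedGeneSet,
    *,
    normalized: bool = False,
    two_block: bool = False,
    sample: str = "",
) -> ScoreResult:
    """Score one sample's transcriptome against a directed gene set.

    All G genes of the sample are ranked once by abundance with average
    (fractional) ranks on ties.  The raw score is the mean directed rank
    over the observed set genes and lies in [1, G]; ``normalized=True``
    rescales it to [0, 1] via (score - 1) / (G - 1), a monotone transform.
    ``two_block=True`` computes the mean up-block rank and the mean
    (direction-reversed) down-block rank separately and sums them, a
    sensitivity-analysis variant of the default single pooled mean.
    """
    if isinstance(sample_expression, pd.Series):
        series = sample_expression.astype(float)
    else:
        series = pd.Series(sample_expression, dtype=float)
    label = sample or (series.name if series.name is not None else "")
    g_total = len(series)
    observed = [g for g in gene_set.weights if g in series.index]
    if not observed:
        raise UndefinedScoreError(
            f"sample {label!r} shares no genes with set {gene_set.name!r}"
        )

    ranks_inc = pd.Series(rankdata(series.values), index=series.index)
    directed: dict[str, float] = {}
    for g in observed:
        r = float(ranks_inc[g])
        directed[g] = r if gene_set.weights[g] == +1 else g_total + 1 - r

    if two_block:
        up = [directed[g] for g in observed if gene_set.weights[g] == +1]
        down = [directed[g] for g in observed if gene_set.weights[g] == -1]
        score = sum(float(np.mean(b)) for b in (up, down) if b)
    else:
        score = float(np.mean(list(directed.values())))
    if normalized:
        score = (score - 1.0) / (g_total - 1.0) if g_total > 1 else 0.0
    return ScoreResult(sample=str(label), score=score, n_used=len(observed), ranks_used=directed)


def score_cohort(
    matrix: ExpressionMatrix,
    gene_set: DirectedGeneSet,
    *,
    normalized: bool = False,
    two_block: bool = False,
) -> list[ScoreResult]:
    """Score every sample of a cohort; one ScoreResult per scorable sample.

    Samples with no overlap with the set are skipped with a warning rather
    than aborting the cohort.  Scoring uses the normalized view when size
    factors are present (ranks are unchanged by the per-sample scaling, so
    this matters only if the caller passes transformed data).
    """
    if matrix.counts.empty:
        raise ValueError("expression matrix is empty")
    values = matrix.normalized()
    results: list[ScoreResult] = []
    for s in values.columns:
        try:
            results.append(
                directed_rank_score(
                    values[s], gene_set, normalized=normalized, two_block=two_block
                )
            )
        except UndefinedScoreError as exc:
            logger.warning("skipping sample: %s", exc)
    return results


def scores_to_frame(results: Sequence[ScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample": [r.sample for r in results],
         "score": [r.score for r in results],
         "n_used": [r.n_used for r in results]}
    )


def build_composite_signature(
    positive_components: Mapping[str, Iterable[str]],
    negative_components: Mapping[str, Iterable[str]],
    name: str = "composite",
) -> DirectedGeneSet:
    """Merge component gene lists into one signed set.

    Genes of positively weighted components (e.g. chemokine, interferon-
    gamma, T-effector, T-cell-inflamed) get +1; genes of negatively
    weighted components (e.g. B-catenin, TGF-beta, immunosuppression) get
    -1.  A gene claimed by both sides is dropped with a warning since a
    directed set cannot carry both signs.
    """
    pos = {g for genes in positive_components.values() for g in genes}
    neg = {g for genes in negative_components.values() for g in genes}
    conflict = pos & neg
    if conflict:
        warnings.warn(
            f"{len(conflict)} gene(s) in both effector and suppressive components "
            f"dropped from {name!r}: {sorted(conflict)}"
        )
    weights = {g: +1 for g in pos - conflict}
    weights.update({g: -1 for g in neg - conflict})
    if not weights:
        raise EmptySignatureError("composite signature has no unambiguous genes")
    return DirectedGeneSet(name=name, weights=weights, provenance="composite")


def immunophenogram_scores(
    matrix: ExpressionMatrix,
    categories: Mapping[str, Sequence[str]] | None = None,
) -> list[ImmunophenogramProfile]:
    """Mean marker-gene z-scores per immune category, per sample.

    Per gene, z = (value - cross-sample mean) / cross-sample SD (ddof=1);
    zero-variance genes get z = 0 everywhere.  A category's score is the
    mean z over its marker genes present in the matrix; a category with no
    gene present scores NaN (flagged, not an exception).  Needs >= 2
    samples for the cross-sample variance.
    """
    if len(matrix.samples) < 2:
        raise ValueError("immunophenogram z-scores need at least 2 samples")
    categories = dict(categories or DEFAULT_IMMUNOPHENOGRAM_CATEGORIES)
    values = matrix.normalized()
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    z = values.sub(mu, axis=0).div(sd.replace(0.0, np.inf), axis=0)

    profiles = []
    for s in values.columns:
        cat_scores: dict[str, float] = {}
        for cat, genes in categories.items():
            present = [g for g in genes if g in values.index]
            if not present:
                logger.warning("category %r has no marker gene in the matrix", cat)
                cat_scores[cat] = float("nan")
            else:
                cat_scores[cat] = float(z.loc[present, s].mean())
        profiles.append(ImmunophenogramProfile(sample=str(s), category_scores=cat_scores))
    return profiles


def stratify_by_immunogenicity(
    profiles: Sequence[ImmunophenogramProfile], threshold: float = 0.0
) -> dict[str, str]:
    """Qualitative high/low immunogenicity split on the mean category score.

    A reconstruction of the high vs low stratification: samples whose mean
    category z-score exceeds ``threshold`` are labelled ``"high"`` (an
    inflamed, SIL-high-like profile), the rest ``"low"``.
    """
    out = {}
    for p in profiles:
        vals = [v for v in p.category_scores.values() if np.isfinite(v)]
        out[p.sample] = "high" if vals and float(np.mean(vals)) > threshold else "low"
    return out


class OverlapResult(NamedTuple):
    fraction: float  # |A ∩ B| / |A|
    jaccard: float   # |A ∩ B| / |A ∪ B|


def signature_overlap(set_a: DirectedGeneSet, set_b: DirectedGeneSet) -> OverlapResult:
    """Gene overlap of two signatures, ignoring direction."""
    a, b = set_a.genes, set_b.genes
    if not a or not b:
        raise ValueError("both gene sets must be nonempty")
    inter = len(a & b)
    return OverlapResult(fraction=inter / len(a), jaccard=inter / len(a | b))


# ---------------------------------------------------------------------------
# signed-GMT IO: set name, description, then gene:+1 / gene:-1 tokens
# (plain GMT rows, without the :sign suffix, load with all weights +1)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[DirectedGeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, desc, *tokens = fields
        weights: dict[str, int] = {}
        for tok in tokens:
            if not tok:
                continue
            if tok.endswith(":+1") or tok.endswith(":-1"):
                gene, sign = tok.rsplit(":", 1)
                weights[gene] = int(sign)
            else:
                weights[tok] = +1
        sets.append(DirectedGeneSet(name=name, weights=weights, provenance=desc))
    return sets


def write_gmt(sets: Sequence[DirectedGeneSet], path: str | Path) -> None:
    lines = []
    for s in sets:
        tokens = [f"{g}:{w:+d}" for g, w in sorted(s.weights.items())]
        lines.append("\t".join([s.name, s.provenance or "-"] + tokens))
    Path(path).write_text("\n".join(lines) + "\n")
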