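"""Bulk RNA-seq count processing and differential expression.

Implements the expression side of the pipeline: low-count gene filtering,
median-of-ratios library-size normalization, a negative-binomial Wald test
for differential expression between two response groups, and BH / BKY
multiple-testing adjustment.

The DE test is deliberately lightweight: per-gene dispersion is estimated
by the method of moments (floored at 1e-8) with no shrinkage across genes,
and the Wald statistic for the log2 fold change of normalized group means
(pseudo-count 0.5) is compared against a standard normal.  Downstream use
relies on recovery of planted effects, not on matching any particular DE
package's P-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "NormalizationError",
    "filter_low_counts",
    "median_of_ratios_normalize",
    "differential_expression",
    "adjust_pvalues",
    "read_counts_tsv",
    "write_counts_tsv",
]

DISPERSION_FLOOR = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5


class NormalizationError(RuntimeError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene-by-sample integer count matrix with optional size factors.

    ``counts`` is a pandas DataFrame indexed by gene identifier with one
    column per sample.  ``size_factors`` (per sample, > 0) are set by
    :func:`median_of_ratios_normalize`; the normalized view is
    count / size_factor.
    """

    counts: pd.DataFrame
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None:
            sf = self.size_factors.reindex(self.counts.columns)
            if sf.isna().any() or (sf <= 0).any():
                raise ValueError("size factors must be positive and cover all samples")
            self.size_factors = sf

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def normalized(self) -> pd.DataFrame:
        """Counts divided by per-sample size factors (1.0 if never normalized)."""
        if self.size_factors is None:
            return self.counts.astype(float)
        return self.counts / self.size_factors

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[list(genes)], self.size_factors)


def read_counts_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene-by-sample TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_counts_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene")


def filter_low_counts(
    matrix: ExpressionMatrix, min_count: int = 20, min_samples: int = 5
) -> ExpressionMatrix:
    """Drop low-information genes.

    A gene is kept iff its count exceeds ``min_count`` in strictly more
    than ``min_samples`` samples.  With the defaults this removes genes
    with <= 20 counts in all but at most 5 samples.  The sample set is
    unchanged; an empty matrix passes through untouched.
    """
    if min_count < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    if matrix.counts.empty:
        return matrix
    keep = (matrix.counts > min_count).sum(axis=1) > min_samples
    logger.info("low-count filter kept %d / %d genes", int(keep.sum()), len(keep))
    return ExpressionMatrix(matrix.counts.loc[keep], matrix.size_factors)


def median_of_ratios_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios size factors.

    For each sample the size factor is the median, over reference genes
    (genes with nonzero counts in every sample), of
    count / geometric-mean-across-samples.
    """
    counts = matrix.counts.astype(float)
    reference = (counts > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; consider a pseudo-reference "
            "(e.g. add a pseudo-count) before normalizing"
        )
    ref = counts.loc[reference]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geo_mean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    return ExpressionMatrix(matrix.counts, pd.Series(size_factors, index=counts.columns))


def adjust_pvalues(p: Sequence[float], method: str = "BH", alpha: float = 0.05) -> np.ndarray:
    """Multiple-testing adjustment.

    ``BH`` is the standard Benjamini-Hochberg step-up; ``BKY`` the
    Benjamini-Krieger-Yekutieli two-stage step-up (stage-1 BH at
    alpha/(1+alpha), then BH with the re-estimated number of true nulls),
    reported at the given ``alpha`` (default 0.05).  Output order matches
    input order.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    key = {"BH": "fdr_bh", "BKY": "fdr_tsbky"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    adjusted = multipletests(p, alpha=alpha, method=key)[1]
    return np.minimum(adjusted, 1.0)


def _moment_dispersion(norm: np.ndarray, sf: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion by the method of moments on normalized counts.

    With counts K ~ NB(mean s*q, dispersion a), the normalized values
    y = K/s satisfy E Var(y) ~= q * mean(1/s) + a * q^2, so
    a ~= (var(y) - q * mean(1/s)) / q^2, floored at DISPERSION_FLOOR.
    """
    q = norm.mean(axis=1)
    v = norm.var(axis=1, ddof=1)
    inv_s = float(np.mean(1.0 / sf))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - q * inv_s) / np.square(q)
    alpha[~np.isfinite(alpha)] = DISPERSION_FLOOR
    return np.maximum(alpha, DISPERSION_FLOOR)


def _pooled_within_group_dispersion(
    ya: np.ndarray, yb: np.ndarray, sfa: np.ndarray, sfb: np.ndarray
) -> np.ndarray:
    """Within-group moment dispersions combined by degrees of freedom."""
    na, nb = ya.shape[1], yb.shape[1]
    aa = _moment_dispersion(ya, sfa)
    ab = _moment_dispersion(yb, sfb)
    return ((na - 1) * aa + (nb - 1) * ab) / (na + nb - 2)


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """NB Wald test per gene, group_a vs group_b.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (positive
    means higher in ``group_a``), ``pvalue``, ``padj`` (BH), ``mean_a``
    and ``mean_b`` (normalized means).

    The matrix must already carry size factors (see
    :func:`median_of_ratios_normalize`); otherwise all size factors are
    taken as 1.
    """
    ga, gb = list(group_a), list(group_b)
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = (set(ga) | set(gb)) - set(matrix.samples)
    if missing:
        raise ValueError(f"samples not in matrix: {sorted(missing)}")

    norm = matrix.normalized()
    sf = (
        matrix.size_factors
        if matrix.size_factors is not None
        else pd.Series(1.0, index=matrix.samples)
    )
    ya = norm[ga].values
    yb = norm[gb].values
    sfa = sf[ga].values
    sfb = sf[gb].values
    na, nb = len(ga), len(gb)

    mean_a = ya.mean(axis=1)
    mean_b = yb.mean(axis=1)
    qa = mean_a + LOG2FC_PSEUDOCOUNT
    qb = mean_b + LOG2FC_PSEUDOCOUNT
    log2fc = np.log2(qa) - np.log2(qb)

    alpha = _pooled_within_group_dispersion(ya, yb, sfa, sfb)

    # delta-method variance of log2 of the normalized group mean
    ln2_sq = np.log(2.0) ** 2
    var_qa = (qa * np.mean(1.0 / sfa) + alpha * qa**2) / na
    var_qb = (qb * np.mean(1.0 / sfb) + alpha * qb**2) / nb
    var_l2 = var_qa / (qa**2 * ln2_sq) + var_qb / (qb**2 * ln2_sq)
    se = np.sqrt(var_l2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * (1.0 - ndtr(np.abs(z)))
    pvalue = np.clip(pvalue, 0.0, 1.0)
    padj = adjust_pvalues(pvalue, method="BH")

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "mean_a": mean_a,
            "mean_b": mean_b,
        },
        index=matrix.genes,
    )


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")
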