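# ayamel

Immunogenomic analysis of immune-checkpoint-inhibitor (ICI) resistance in
adolescent and young adult (AYA) melanoma.

Response to anti-PD-1 / anti-CTLA-4 therapy in young melanoma patients is
poorer than in older adults and correlates with an immunosuppressed tumor
microenvironment: regulatory T cells (T_reg, CD3⁺FOXP3⁺) concentrated in
the peritumoral stroma, dysfunctional effector T cells, and in a second
resistant subtype a general lack of immune activation.  `ayamel` packages
the computational machinery needed to study this at cohort scale:

* **directed rank-based signature scoring** — the score of sample *i*
  against a signed ("directed") gene set is

  S₍dir,i₎ = ( Σ₉ R₉₍dir,i₎ ) / N₍dir,i₎

  where every gene of the sample's transcriptome is ranked once by
  abundance (average ranks on ties), expected-up genes (weight +1)
  contribute their increasing-abundance rank R, expected-down genes
  (weight −1) the reversed rank G + 1 − R, and N is the number of set
  genes observed in the data (absent genes are excluded from numerator and
  denominator).  A resistance score is trained by weighting genes up in
  progressing (PD) patients +1 and genes up in complete responders −1;
  equal-weight comparator sets (IPRES-style) and signed composites of
  effector/suppressive components (IMMU-style) are supported;
* **differential expression** — low-count filtering, median-of-ratios
  normalization, and a per-gene negative-binomial Wald test with
  method-of-moments dispersion, BH-adjusted;
* **immunophenogram profiles** — mean cross-sample expression z-scores of
  marker genes per immune category (effector cells, suppressor cells,
  checkpoints, MHC);
* **somatic variant filtering** — the eight-rule post-calling cascade
  (unique depth/observations, homopolymers, population frequency, strand
  bias, caller-specific rules, impact/consequence) with TERT-promoter
  waivers, first-failing-rule accounting, and MAF emission;
* **spatial quantification** — phenotype densities (cells/mm²) per tissue
  region (intratumor vs peritumor) and derived ratios from segmented
  multiplex-IF cell tables;
* **outcome statistics** — exact Fisher 2×2 and Freeman–Halton r×c tests,
  chi-square, Mann–Whitney U (exact for small samples), Kruskal–Wallis,
  Spearman correlation, Kaplan–Meier / Mantel–Cox log-rank, ROC AUC, and
  BH / Benjamini–Krieger–Yekutieli two-stage multiple-testing adjustment;
* **druggable-target matching** — cross-matching expressed/mutated genes
  against a DGIdb-style interaction table with category-tag filters;
* **a synthetic cohort generator** — negative-binomial counts with a
  planted resistance program, Poisson cell point patterns with
  region-dependent intensities, stratified variant fixtures and
  exponential survival — so the full pipeline runs, and is tested,
  without patient data.

## Worked example

Train a resistance signature on a synthetic cohort with a planted
expression program and evaluate its discrimination:

```python
import numpy as np
from ayamel import (
    SimulationConfig, generate_expression_cohort,
    filter_low_counts, median_of_ratios_normalize, differential_expression,
    build_directed_signature, score_cohort, roc_auc,
)

config = SimulationConfig(seed=7)   # 24 PD + 24 CR (+24 PR), 2,000 genes,
                                    # 100 planted genes at |log2FC| = 1.5
matrix, truth = generate_expression_cohort(config)
normed = median_of_ratios_normalize(filter_low_counts(matrix))
de = differential_expression(normed, truth.samples_of("resistant"),
                             truth.samples_of("CR"))
signature = build_directed_signature(de, alpha=0.05, name="YIM")
scores = {r.sample: r.score for r in score_cohort(normed, signature)}
```

Summarizing the signature and the per-class score means prints:

```
signature size: 104 genes (52 up, 52 down)
mean score, resistant (PD): 1465.9
mean score, complete responders: 1008.1
ROC AUC (PD vs CR): 1.000
```

The signature recovers 97 of the 100 planted genes plus a handful of false
positives; resistant samples rank near the top of the score range
(the theoretical midpoint for ~1,974 retained genes is ≈ 987.5), and the
score separates the two outcome classes perfectly on this synthetic
cohort.  The same steps are exposed on the command line:

```sh
ayamel simulate --seed 7 --out demo/
ayamel de --counts demo/counts.tsv --group-a PD01,...,PD24 --group-b CR01,...,CR24 --out demo/de.tsv
ayamel run --config examples/demo_config.yaml --out demo_run/
```

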