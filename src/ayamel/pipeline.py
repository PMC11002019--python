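"""Configuration-driven orchestration of the full analysis.

Stages run in the order the analysis needs them: synthetic cohort
generation (or loading of user inputs) -> count filtering and
normalization -> differential expression (resistant vs CR, PR excluded)
-> signature construction and cohort scoring -> immunophenogram profiling
-> variant filter cascade and MAF emission -> spatial density
quantification -> outcome statistics -> druggable-target matching.

Every stage writes its outputs under the configured output directory and
nothing mutates another stage's inputs.  A run manifest (seed, package
version, per-stage output files with SHA-256 hashes) is written at the
end; rerunning the same configuration reproduces byte-identical numeric
outputs because the single global seed is expanded into per-stage
substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import drugs as _drugs
from . import expression as _expr
from . import scoring as _scoring
from . import spatial as _spatial
from . import stats as _stats
from . import synthetic as _syn
from . import variants as _var

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "ayamel_out"
    synthetic: dict[str, Any] | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    n_variants: int = 30
    de_alpha: float = 0.05
    min_count: int = 20
    min_samples: int = 5
    score_normalized: bool = False
    score_two_block: bool = False
    expression_quantile: float = 0.75
    filter_thresholds: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.synthetic is not None:
            # fail before any output is written
            _syn.SimulationConfig(seed=self.seed, **self.synthetic).validate()
        if self.synthetic is None:
            required = {"counts", "truth", "cells", "outcomes", "variants"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(
                    f"no synthetic block and missing input paths: {sorted(missing)}"
                )
            for key, path in self.inputs.items():
                if not Path(path).exists():
                    raise ValueError(f"input path for {key!r} does not exist: {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "status": "running",
    }
    manifest_path = outdir / "manifest.json"

    def record(stage: str, files: dict[str, Path], **extra: Any) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
            **extra,
        }

    def fail(stage: str, exc: Exception) -> None:
        manifest["status"] = f"failed at {stage}"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 1: inputs -------------------------------------------------
    stage = "simulate" if config.synthetic is not None else "load"
    try:
        if config.synthetic is not None:
            sim = _syn.SimulationConfig(seed=config.seed, **config.synthetic)
            matrix, truth = _syn.generate_expression_cohort(sim)
            cells = _syn.generate_cell_table(sim)
            outcomes = _syn.generate_outcomes(truth, sim)
            records = _syn.generate_variant_records(config.n_variants, seed=config.seed)
            files = {
                "counts": outdir / "counts.tsv",
                "truth": outdir / "truth.json",
                "cells": outdir / "cells.csv",
                "outcomes": outdir / "outcomes.csv",
                "variants": outdir / "variants.tsv",
                "areas": outdir / "region_areas.json",
            }
            _expr.write_counts_tsv(matrix, files["counts"])
            _syn.write_truth_json(truth, files["truth"])
            _spatial.write_cell_table(cells, files["cells"])
            _syn.write_outcomes_csv(outcomes, files["outcomes"])
            _var.write_variants_tsv(records, files["variants"])
            files["areas"].write_text(json.dumps(cells.region_areas, indent=2))
            record(stage, files)
        else:
            matrix = _expr.read_counts_tsv(config.inputs["counts"])
            truth = _syn.read_truth_json(config.inputs["truth"])
            areas = json.loads(Path(config.inputs["areas"]).read_text())
            cells = _spatial.read_cell_table(config.inputs["cells"], areas)
            outcomes = _syn.read_outcomes_csv(config.inputs["outcomes"])
            records = _var.read_variants_tsv(config.inputs["variants"])
            record(stage, {}, inputs=dict(config.inputs))
    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        fail(stage, exc)

    # --- stage 2: expression processing ----------------------------------
    try:
        filtered = _expr.filter_low_counts(matrix, config.min_count, config.min_samples)
        normed = _expr.median_of_ratios_normalize(filtered)
        resistant = truth.samples_of("resistant")
        cr = truth.samples_of("CR")  # PR excluded from signature training
        de = _expr.differential_expression(normed, resistant, cr)
        de_path = outdir / "differential_expression.tsv"
        _expr.write_de_table(de, de_path)
        record("expression", {"de": de_path},
               n_genes_in=len(matrix.genes), n_genes_kept=len(filtered.genes))
    except Exception as exc:
        fail("expression", exc)

    # --- stage 3: signature scoring + immunophenogram ---------------------
    try:
        signature = _scoring.build_directed_signature(de, alpha=config.de_alpha, name="YIM")
        results = _scoring.score_cohort(
            normed, signature,
            normalized=config.score_normalized, two_block=config.score_two_block,
        )
        scores = _scoring.scores_to_frame(results)
        scores_path = outdir / "signature_scores.tsv"
        scores.to_csv(scores_path, sep="\t", index=False)
        sig_path = outdir / "signature.gmt"
        _scoring.write_gmt([signature], sig_path)

        profiles = _scoring.immunophenogram_scores(normed)
        ipg = pd.DataFrame(
            [{"sample": p.sample, **p.category_scores} for p in profiles]
        )
        ipg_path = outdir / "immunophenogram.tsv"
        ipg.to_csv(ipg_path, sep="\t", index=False)
        record("signature", {"scores": scores_path, "gmt": sig_path, "immunophenogram": ipg_path},
               signature_size=len(signature))
    except Exception as exc:
        fail("signature", exc)

    # --- stage 4: variant filtering ---------------------------------------
    try:
        thresholds = _var.FilterThresholds(**config.filter_thresholds)
        report = _var.apply_filter_cascade(records, thresholds)
        maf_path = outdir / "variants.maf"
        _var.write_maf(report, path=maf_path)
        report_path = outdir / "filter_report.json"
        report_path.write_text(
            json.dumps(
                {
                    "input_count": report.input_count,
                    "kept": len(report.kept),
                    "dropped_by_rule": {str(k): v for k, v in report.dropped_by_rule.items()},
                },
                indent=2,
            )
        )
        record("variants", {"maf": maf_path, "report": report_path},
               records_in=report.input_count, records_kept=len(report.kept))
    except Exception as exc:
        fail("variants", exc)

    # --- stage 5: spatial quantification ----------------------------------
    try:
        queries = {
            "t_cell": _spatial.PhenotypeQuery.parse("CD3+SOX10-"),
            "cytotoxic_t": _spatial.PhenotypeQuery.parse("CD3+CD8+"),
            "treg": _spatial.PhenotypeQuery.parse("CD3+FOXP3+"),
            "treg_activated": _spatial.PhenotypeQuery.parse("CD3+CD8-FOXP3+ICOS+"),
            "foxp3": _spatial.PhenotypeQuery.parse("FOXP3+"),
        }
        densities = _spatial.density_table(cells, queries)
        dens_path = outdir / "densities.tsv"
        _spatial.write_density_table(densities, dens_path)
        record("spatial", {"densities": dens_path}, n_cells=len(cells.cells))
    except Exception as exc:
        fail("spatial", exc)

    # --- stage 6: outcome statistics ---------------------------------------
    try:
        merged = outcomes.merge(scores, on="sample")
        rows = []

        labels = (merged["response"] == "PD").astype(int)
        if labels.nunique() == 2:
            auc = _stats.roc_auc(merged["score"], labels)
            rows.append({"test": "roc_auc_score_pd_vs_rest", "statistic": auc, "p": ""})
            pd_scores = merged.loc[merged["response"] == "PD", "score"]
            cr_scores = merged.loc[merged["response"] == "CR", "score"]
            if len(pd_scores) and len(cr_scores):
                u, p = _stats.mann_whitney_u(pd_scores, cr_scores)
                rows.append({"test": "mann_whitney_score_pd_vs_cr", "statistic": u, "p": p})

        combo = merged["treatment"] == "combination"
        resistant_mask = merged["response"] == "PD"
        table = [
            [int((combo & ~resistant_mask).sum()), int((combo & resistant_mask).sum())],
            [int((~combo & ~resistant_mask).sum()), int((~combo & resistant_mask).sum())],
        ]
        if all(sum(r) for r in table):
            p = _stats.fisher_exact(table)
            rows.append({"test": "fisher_combo_vs_mono_response", "statistic": "", "p": p})

        if resistant_mask.any() and (merged["response"] == "CR").any():
            comp = _stats.survival_compare(
                merged["pfs_months"], merged["pfs_event"],
                merged["response"], "PD", "CR",
            )
            rows.append({"test": "logrank_pfs_pd_vs_cr", "statistic": comp.chi2, "p": comp.p_value})

        stats_path = outdir / "statistics.tsv"
        pd.DataFrame(rows, columns=["test", "statistic", "p"]).to_csv(
            stats_path, sep="\t", index=False
        )
        record("stats", {"statistics": stats_path})
    except Exception as exc:
        fail("stats", exc)

    # --- stage 7: drug matching --------------------------------------------
    try:
        interactions = _drugs.load_synthetic_interactions()
        maf = _var.read_maf(maf_path)
        profiles = []
        for s in truth.samples_of("resistant"):
            if s not in normed.samples:
                continue
            expressed = _drugs.expressed_genes_from_matrix(
                normed, s, quantile=config.expression_quantile
            )
            mutated = set(maf.loc[maf["Tumor_Sample_Barcode"] == s, "Hugo_Symbol"])
            profiles.append(
                _drugs.match_druggable_targets(s, expressed, mutated, interactions)
            )
        matches = _drugs.matches_to_frame(profiles)
        matches_path = outdir / "drug_matches.tsv"
        matches.to_csv(matches_path, sep="\t", index=False)
        record("drugmatch", {"matches": matches_path}, n_matches=len(matches))
    except Exception as exc:
        fail("drugmatch", exc)

    manifest["status"] = "complete"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
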