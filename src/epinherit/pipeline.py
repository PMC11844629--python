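"""End-to-end orchestration: simulate (or load), call DMRs per generation,
classify inheritance, integrate expression, run enrichment, emit a report.

The report is a plain dict (JSON-serializable) whose every number is
recomputable from the stage outputs it cites; provenance records the config
hash, seed and package version so identical config+seed reruns produce
identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .diffmeth import call_dmrs, direction_balance, results_to_frame
from .enrichment import (enrichment_to_frame, gsea, ora_analysis,
                         rank_by_signed_significance)
from .expression import (canonical_extract, derive_dmegs, expression_to_frame,
                         nb_wald_test)
from .inheritance import (biotype_tally, classify_common_loci, pattern_census,
                          transmission_stats)
from .methylation import (LocationClassifier, aggregate_regions,
                          filter_coverage, promoter_windows, tile_genome)
from .simulate import (GENERATION_ORDER, SimulationConfig, TruthTable,
                       simulate_annotation, simulate_expression,
                       simulate_gene_sets, simulate_methylomes)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and stage switches for a full run."""

    seed: int | None = None
    outdir: str | None = None
    min_cov: int = 3
    window: int = 100
    step: int = 100
    promoter_up: int = 3000
    promoter_down: int = 300
    meth_fdr: float = 0.1
    expr_fdr: float = 0.05
    test: str = "auto"
    overdispersion: str = "pooled"
    generation_order: tuple[str, ...] = tuple(GENERATION_ORDER)
    n_perm: int = 1000
    gsea_weight: float = 1.0
    with_expression: bool = True
    with_enrichment: bool = True
    with_tiles: bool = True
    simulation: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "generation_order" in data:
            data["generation_order"] = tuple(data["generation_order"])
        return cls(**data)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Run simulate -> diffmeth -> inheritance -> expression -> enrichment.

    Returns the report dict; stage tables are written under ``outdir`` when
    given.  Stages downstream of a disabled one are skipped and the report
    is flagged as partial.
    """
    outdir = Path(outdir) if outdir is not None else (
        Path(config.outdir) if config.outdir else None)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    sim = SimulationConfig(**config.simulation)
    seed = config.seed
    logger.info("stage simulate: %d genes, %d roles", sim.n_genes,
                len(sim.roles))
    genes = simulate_annotation(sim, seed=seed)
    samples, groups, truth = simulate_methylomes(sim, genes, seed=seed)

    promoters = promoter_windows(genes, config.promoter_up,
                                 config.promoter_down)
    classifier = LocationClassifier(genes, promoters)

    report: dict[str, Any] = {
        "provenance": {
            "package_version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config),
        },
        "comparisons": {},
        "partial": False,
    }

    # --- per-role differential methylation on promoters (and tiles) -------
    direction_by_role: dict[str, dict[str, str]] = {}
    for role in sim.roles:
        role_samples = {name: recs for name, recs in samples.items()
                        if name.startswith(role + "_")}
        filtered = {name: filter_coverage(recs, config.min_cov)
                    for name, recs in role_samples.items()}
        role_groups = {name: groups[name] for name in role_samples}
        regions = aggregate_regions(filtered, promoters, groups=role_groups)
        results = call_dmrs(regions, fdr=config.meth_fdr, test=config.test,
                            overdispersion=config.overdispersion)
        logger.info("stage diffmeth[%s]: %d promoters tested, %d significant",
                    role, len(results),
                    sum(r.direction != "none" for r in results))
        direction_by_role[role] = {r.region_id: r.direction for r in results
                                   if r.direction != "none"}
        n_hyper, n_hypo, frac = direction_balance(results)
        comp: dict[str, Any] = {
            "n_promoters_tested": len(results),
            "n_dmp": n_hyper + n_hypo,
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "hyper_fraction": frac,
        }
        if config.with_tiles:
            tiles = tile_genome(filtered, window=config.window,
                                step=config.step, groups=role_groups)
            tile_results = call_dmrs(tiles, fdr=config.meth_fdr,
                                     test=config.test,
                                     overdispersion=config.overdispersion)
            location = {"promoter": 0, "exon": 0, "intron": 0,
                        "intergenic": 0}
            for r in tile_results:
                if r.direction != "none" and r.region is not None:
                    location[classifier.classify(r.region)] += 1
            comp["n_tiles_tested"] = len(tile_results)
            comp["n_tile_dmr"] = sum(
                r.direction != "none" for r in tile_results)
            comp["dmr_location"] = location
        report["comparisons"][role] = comp
        if outdir is not None:
            results_to_frame(results).to_csv(
                outdir / f"dmp_{role}.tsv", sep="\t", index=False)

    # --- inheritance across the generation order --------------------------
    order = list(config.generation_order)
    per_generation = [direction_by_role[r] for r in order]
    records = classify_common_loci(per_generation)
    census = pattern_census(records, n_generations=len(order))
    stats = transmission_stats(*(set(direction_by_role[r]) for r in order[:3]))
    common_genes = [rec.locus_id for rec in records]
    report["inheritance"] = {
        "generation_order": order,
        "n_common_all": len(records),
        "pattern_census": census,
        "transmission": {
            "n_f0": stats.n_f0, "n_f1": stats.n_f1, "n_f2": stats.n_f2,
            "n_common_all": stats.n_common_all,
            "n_skipped": stats.n_skipped, "n_novel_f1": stats.n_novel_f1,
            "percentages": stats.percentages,
        },
        "biotypes": biotype_tally(common_genes, genes),
    }
    logger.info("stage inheritance: %d common loci across %s",
                len(records), "/".join(order))
    if outdir is not None:
        pd.DataFrame(
            [{"locus_id": r.locus_id, "pattern": r.pattern} for r in records]
        ).to_csv(outdir / "inheritance.tsv", sep="\t", index=False)
        (outdir / "transmission.json").write_text(
            json.dumps(report["inheritance"]["transmission"], indent=1))

    # --- expression integration -------------------------------------------
    if not config.with_expression:
        report["partial"] = True
        logger.info("expression stage disabled; stopping after inheritance")
        return report

    counts, sheet = simulate_expression(sim, truth, genes, seed=seed)
    expr_groups = dict(zip(sheet["sample"], sheet["group"]))
    de_results = nb_wald_test(counts, expr_groups, qthresh=config.expr_fdr)
    dmegs = derive_dmegs(records, de_results)
    ppp_n, nnn_p = canonical_extract(dmegs)
    n_sig_de = sum(r.direction != "none" for r in de_results)
    report["expression"] = {
        "n_genes_tested": len(de_results),
        "n_significant_degs": n_sig_de,
        "n_dmegs": len(dmegs),
        "n_canonical_hyper_down": len(ppp_n),
        "n_canonical_hypo_up": len(nnn_p),
    }
    logger.info("stage expression: %d DEGs, %d DMEGs (%d PPPn, %d NNNp)",
                n_sig_de, len(dmegs), len(ppp_n), len(nnn_p))
    if outdir is not None:
        expression_to_frame(de_results).to_csv(
            outdir / "expression.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene_id": d.gene_id, "pattern": d.pattern,
              "expression_direction": d.expression_direction,
              "canonical_class": d.canonical_class} for d in dmegs]
        ).to_csv(outdir / "dmegs.tsv", sep="\t", index=False)

    # --- enrichment ---------------------------------------------------------
    if not config.with_enrichment:
        report["partial"] = True
        return report

    gene_sets = simulate_gene_sets(sim, truth, genes, seed=seed)
    ranked = rank_by_signed_significance(de_results)
    gsea_results = gsea(ranked, gene_sets, n_perm=config.n_perm,
                        seed=seed if seed is not None else 0,
                        weight_exponent=config.gsea_weight)
    universe = [g.gene_id for g in genes]
    ora_results = ora_analysis(sorted(ppp_n), gene_sets, universe)
    report["enrichment"] = {
        "gsea": [
            {"set": r.name, "size": r.size, "es": r.es, "nes": r.nes,
             "pvalue": r.pvalue, "fdr_q": r.fdr_q} for r in gsea_results],
        "ora_canonical_hyper_down": [
            {"set": r.name, "overlap": r.overlap, "expected": r.expected,
             "pvalue": r.pvalue, "fdr_q": r.fdr_q} for r in ora_results],
    }
    logger.info("stage enrichment: %d sets (GSEA), %d sets (ORA)",
                len(gsea_results), len(ora_results))
    if outdir is not None:
        enrichment_to_frame(gsea_results).to_csv(
            outdir / "gsea.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True))
    return report


def score_against_truth(
    report_records, truth: TruthTable,
) -> dict[str, float | int]:
    """Compare classified inheritance records with the generator's truth.

    Returns planted-locus recovery (exact pattern match) and the empirical
    false-discovery rate among called common loci.
    """
    called = {r.locus_id: r.pattern for r in report_records}
    planted = truth.patterns
    n_planted = len(planted)
    n_exact = sum(1 for gid, pat in planted.items()
                  if called.get(gid) == pat)
    n_called = len(called)
    n_false = sum(1 for gid in called if gid not in planted)
    return {
        "n_planted": n_planted,
        "n_called": n_called,
        "n_recovered_exact": n_exact,
        "recovery_rate": n_exact / n_planted if n_planted else float("nan"),
        "false_discovery_rate": n_false / n_called if n_called else 0.0,
    }
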