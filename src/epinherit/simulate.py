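"""Synthetic multi-generation methylome and transcriptome generator.

The generator emulates the structure of a two-lineage (control vs exposed)
transgenerational design: four sample roles (F0 sperm, F1 sperm, F2 liver
female, F2 liver male) with three biological replicates per lineage, plus a
matched F2 liver expression experiment.  Heritable promoter epimutations are
planted according to a pattern plan (e.g. 27 loci hypermethylated in all
three generations), and each planted gene's expression is coupled inversely
to its F2 promoter state: promoter hypermethylation in F2 drives expression
down, hypomethylation drives it up.  A truth table records every planted
locus so downstream recovery can be scored exactly.

Counts are beta-binomial at the CpG level: each CpG in each sample draws its
methylation probability from Beta(mu*s, (1-mu)*s) around the group-level
mean mu with precision s, then binomial reads at Poisson coverage.  This
replicate-level overdispersion is what makes the replicate-aware logistic
test (rather than pooled Fisher) the appropriate default downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (CpGRecord, GeneModel, GeneSetCollection,
                         write_bismark_coverage, write_gmt, write_gtf)
from .methylation import RegionMethylation, GenomicInterval

ROLES = ("F0_sperm", "F1_sperm", "F2_liver_F", "F2_liver_M")
#: roles entering the headline three-generation comparison, in order
GENERATION_ORDER = ("F0_sperm", "F1_sperm", "F2_liver_F")

DEFAULT_PATTERN_TABLE = {
    "PPP": 27, "NNN": 1,
    "PNP": 8, "NPP": 8, "NNP": 8, "PNN": 8, "NPN": 8, "PPN": 8,
}

DEFAULT_BIOTYPE_FREQS = {
    "protein_coding": 0.85, "miRNA": 0.05, "snoRNA": 0.04,
    "pseudogene": 0.03, "rRNA": 0.03,
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the modelled study's stated design: three biological
    replicates per lineage, minimum-coverage-3-friendly mean coverage of 30x,
    100 bp-scale promoter CpG density, a planted-pattern plan dominated by
    27 consistently hypermethylated loci plus one consistently hypomethylated
    locus, and a 40-percentage-point planted methylation shift.
    """

    n_genes: int = 300
    n_chromosomes: int = 4
    gene_spacing: int = 12_000
    gene_body: int = 2_000
    cpgs_per_promoter: int = 12
    background_cpgs_per_gene: int = 4
    coverage_mean: float = 30.0
    replicates_per_group: int = 3
    roles: Sequence[str] = ROLES
    generation_order: Sequence[str] = GENERATION_ORDER
    baseline_beta: tuple[float, float] = (2.0, 2.0)
    planted_baseline_range: tuple[float, float] = (0.2, 0.8)
    precision: float = 100.0  # beta-binomial within-group precision s
    effect_pp: float = 40.0  # planted methylation shift, percentage points
    pattern_table: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_TABLE))
    biotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_FREQS))
    # expression block
    expression_role: str = "F2_liver_F"
    expr_base_mean_log: float = float(np.log(200.0))
    expr_base_sigma: float = 1.0
    expr_dispersion: float = 0.1
    coupled_log2fc: float = 3.0
    coupled_min_mean: float = 100.0
    library_size_range: tuple[float, float] = (0.7, 1.3)
    couple_expression: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_pp <= 100.0:
            raise ValueError("effect_pp must be in [0, 100]")
        if any(v < 0 for v in self.pattern_table.values()):
            raise ValueError("pattern counts must be >= 0")
        if min(self.baseline_beta) <= 0 or self.precision <= 0:
            raise ValueError("beta parameters must be positive")
        n_planted = sum(self.pattern_table.values())
        if n_planted > self.n_genes:
            raise ValueError(
                f"pattern table plants {n_planted} loci but only "
                f"{self.n_genes} genes are simulated")
        k = len(self.generation_order)
        for pat in self.pattern_table:
            if len(pat) != k or any(c not in "PN" for c in pat):
                raise ValueError(f"bad pattern {pat!r} for {k} generations")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class TruthTable:
    """Planted ground truth: per-locus pattern, per-role exposed-group
    methylation means, and the coupled expression effect."""

    patterns: dict[str, str]
    baseline: dict[str, float]
    role_means: dict[str, dict[str, float]]  # gene -> role -> exposed mean
    log2fc: dict[str, float]
    expression_direction: dict[str, str]  # gene -> {"p","n"} for coupled genes

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


def _seed_for(seed: int | None, stage: str) -> np.random.Generator:
    """Independent, deterministic RNG per stage derived from one seed."""
    import zlib

    ss = np.random.SeedSequence([seed if seed is not None else 0,
                                 zlib.crc32(stage.encode())])
    return np.random.default_rng(ss)


def simulate_annotation(
    config: SimulationConfig, seed: int | None = None,
) -> list[GeneModel]:
    """Place non-overlapping two-exon genes on alternating strands.

    Genes are laid out on ``n_chromosomes`` chromosomes with a fixed spacing
    that leaves room for the -3000/+300 promoter window on either strand;
    biotypes are sampled from ``config.biotype_freqs``.
    """
    rng = _seed_for(seed, "annotation")
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    chrom_len = (per_chrom + 1) * config.gene_spacing
    if config.gene_spacing < config.gene_body + 4000:
        raise ValueError("gene_spacing too small for promoter windows")
    biotypes = list(config.biotype_freqs)
    probs = np.array(list(config.biotype_freqs.values()), dtype=float)
    probs = probs / probs.sum()
    sampled = rng.choice(len(biotypes), size=config.n_genes, p=probs)
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        slot = i // config.n_chromosomes
        body_start = slot * config.gene_spacing + 4000
        body_end = body_start + config.gene_body
        strand = "+" if i % 2 == 0 else "-"
        third = config.gene_body // 3
        exons = [(body_start, body_start + third),
                 (body_end - third, body_end)]
        if body_end > chrom_len:
            raise ValueError("genome capacity overflow")
        genes.append(GeneModel.from_exons(
            gene_id=f"gene{i + 1:04d}", chrom=chrom, strand=strand,
            exons=exons, biotype=biotypes[sampled[i]],
        ))
    return genes


def _plan_patterns(
    config: SimulationConfig, genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> dict[str, str]:
    gene_ids = [g.gene_id for g in genes]
    n_planted = sum(config.pattern_table.values())
    chosen = rng.choice(len(gene_ids), size=n_planted, replace=False)
    patterns: dict[str, str] = {}
    cursor = 0
    for pattern, count in config.pattern_table.items():
        for j in range(count):
            patterns[gene_ids[chosen[cursor + j]]] = pattern
        cursor += count
    return patterns


def _promoter_interval(gene: GeneModel, upstream: int = 3000,
                       downstream: int = 300) -> tuple[int, int]:
    if gene.strand == "+":
        return max(gene.tss - upstream, 0), gene.tss + downstream
    return max(gene.tss - downstream, 0), gene.tss + upstream


def simulate_methylomes(
    config: SimulationConfig, genes: Sequence[GeneModel],
    seed: int | None = None, outdir: str | Path | None = None,
) -> tuple[dict[str, list[CpGRecord]], dict[str, str], TruthTable]:
    """Draw per-sample CpG counts for every role and lineage.

    Returns ``(samples, groups, truth)`` where samples maps sample name to
    CpG records, groups maps sample name to "control"/"exposed", and the
    truth table records the planted loci.  Bismark-dialect coverage files
    are written when ``outdir`` is given.
    """
    rng = _seed_for(seed, "methylome")
    patterns = _plan_patterns(config, genes, rng)
    # roles in the generation order use their own pattern character; any
    # extra role (the other-sex F2 liver) shares the final (F2) character
    gen_index = {role: i for i, role in enumerate(config.generation_order)}
    char_of_role = {role: gen_index.get(role, len(config.generation_order) - 1)
                    for role in config.roles}

    a, b = config.baseline_beta
    # planted (epimutable) promoters start at intermediate methylation so
    # the configured shift is expressible; background promoters draw from
    # the full baseline distribution
    lo_p, hi_p = config.planted_baseline_range
    baseline = {}
    for g in genes:
        if g.gene_id in patterns:
            baseline[g.gene_id] = float(rng.uniform(lo_p, hi_p))
        else:
            baseline[g.gene_id] = float(np.clip(rng.beta(a, b), 0.05, 0.95))

    # per-gene CpG coordinates: evenly spread promoter CpGs + background
    promoter_cpgs: dict[str, np.ndarray] = {}
    background: list[tuple[str, int, float]] = []  # (chrom, pos, mean)
    for g in genes:
        p_start, p_end = _promoter_interval(g)
        pos = np.linspace(p_start + 10, p_end - 10,
                          config.cpgs_per_promoter).astype(int)
        promoter_cpgs[g.gene_id] = np.unique(pos)
        body_pos = np.linspace(g.start + 5, g.end - 5,
                               config.background_cpgs_per_gene).astype(int)
        body_mu = float(np.clip(rng.beta(a, b), 0.05, 0.95))
        background.extend((g.chrom, int(p), body_mu) for p in body_pos)

    shift = config.effect_pp / 100.0
    role_means: dict[str, dict[str, float]] = {gid: {} for gid in patterns}
    n_clipped = 0
    for gid, pattern in patterns.items():
        m0 = baseline[gid]
        for role in config.roles:
            char = pattern[char_of_role[role]]
            mu = m0 + shift if char == "P" else m0 - shift
            clipped = float(np.clip(mu, 0.02, 0.98))
            if clipped != mu:
                n_clipped += 1
            role_means[gid][role] = clipped
    if n_clipped:
        warnings.warn(
            f"{n_clipped} planted role-level methylation mean(s) clipped "
            "into [0.02, 0.98]", stacklevel=2)

    s = config.precision
    samples: dict[str, list[CpGRecord]] = {}
    groups: dict[str, str] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for role in config.roles:
        for group in ("control", "exposed"):
            for rep in range(1, config.replicates_per_group + 1):
                name = f"{role}_{group}_rep{rep}"
                groups[name] = group
                records: list[CpGRecord] = []
                for g in genes:
                    if group == "exposed" and g.gene_id in role_means:
                        mu = role_means[g.gene_id][role]
                    else:
                        mu = baseline[g.gene_id]
                    pos_arr = promoter_cpgs[g.gene_id]
                    cov = rng.poisson(config.coverage_mean, size=pos_arr.size)
                    p_site = rng.beta(mu * s, (1.0 - mu) * s,
                                      size=pos_arr.size)
                    meth = rng.binomial(cov, p_site)
                    for p, c, m in zip(pos_arr, cov, meth):
                        if c > 0:
                            records.append(CpGRecord(
                                g.chrom, int(p), int(m), int(c - m)))
                for chrom, p, mu in background:
                    c = int(rng.poisson(config.coverage_mean))
                    if c == 0:
                        continue
                    m = int(rng.binomial(c, rng.beta(mu * s, (1 - mu) * s)))
                    records.append(CpGRecord(chrom, p, m, c - m))
                records.sort(key=lambda r: (r.chrom, r.pos))
                samples[name] = records

    # expression coupling plan: F2 promoter state P -> expression down (n)
    log2fc: dict[str, float] = {}
    expr_dir: dict[str, str] = {}
    if config.couple_expression:
        for gid, pattern in patterns.items():
            if pattern[-1] == "P":
                log2fc[gid] = -config.coupled_log2fc
                expr_dir[gid] = "n"
            else:
                log2fc[gid] = config.coupled_log2fc
                expr_dir[gid] = "p"

    truth = TruthTable(patterns=patterns, baseline=baseline,
                       role_means=role_means, log2fc=log2fc,
                       expression_direction=expr_dir)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, records in samples.items():
            write_bismark_coverage(records, outdir / f"{name}.cov")
        truth.to_json(outdir / "truth.json")
    return samples, groups, truth


def simulate_expression(
    config: SimulationConfig, truth: TruthTable,
    genes: Sequence[GeneModel], seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix for the expression role.

    Coupled genes (planted promoters) have their exposed-lineage mean scaled
    by 2**log2fc with the sign dictated by the F2 promoter state; all other
    genes are null.  Returns (counts genes x samples, sample sheet).
    """
    rng = _seed_for(seed, "expression")
    gene_ids = [g.gene_id for g in genes]
    base = rng.lognormal(config.expr_base_mean_log, config.expr_base_sigma,
                         size=len(gene_ids))
    for i, gid in enumerate(gene_ids):
        if gid in truth.log2fc:
            base[i] = max(base[i], config.coupled_min_mean)
    fold = np.array([2.0 ** truth.log2fc.get(gid, 0.0) for gid in gene_ids])

    sample_names: list[str] = []
    rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}
    alpha = config.expr_dispersion
    lo, hi = config.library_size_range
    for group in ("control", "exposed"):
        for rep in range(1, config.replicates_per_group + 1):
            name = f"{config.expression_role}_{group}_rna_rep{rep}"
            lib = rng.uniform(lo, hi)
            mu = base * (fold if group == "exposed" else 1.0) * lib
            r = 1.0 / alpha
            p = r / (r + mu)
            columns[name] = rng.negative_binomial(r, p)
            sample_names.append(name)
            rows.append({"sample": name, "group": group,
                         "generation": "F2", "tissue": "liver",
                         "sex": "F" if config.expression_role.endswith("F")
                                else "M"})
    counts = pd.DataFrame(columns, index=gene_ids)
    sheet = pd.DataFrame(rows)
    return counts, sheet


def simulate_gene_sets(
    config: SimulationConfig, truth: TruthTable,
    genes: Sequence[GeneModel], seed: int | None = None,
    n_random_sets: int = 5, random_set_size: int = 30,
) -> GeneSetCollection:
    """A disease-like gene set (the down-coupled planted genes plus random
    padding, mimicking a curated disease list) and random control sets."""
    rng = _seed_for(seed, "genesets")
    gene_ids = [g.gene_id for g in genes]
    down = [gid for gid, d in truth.expression_direction.items() if d == "n"]
    padding = [gid for gid in gene_ids if gid not in truth.patterns]
    pad = list(rng.choice(padding, size=min(len(down), len(padding)),
                          replace=False))
    sets: dict[str, tuple[str, ...]] = {
        "DISEASE_SYNTHETIC": tuple(dict.fromkeys(down + pad)),
    }
    for j in range(n_random_sets):
        members = rng.choice(gene_ids, size=random_set_size, replace=False)
        sets[f"RANDOM_{j + 1}"] = tuple(members)
    return GeneSetCollection(name="synthetic", sets=sets)


def simulate_null_regions(
    n_regions: int, coverage_mean: float = 30.0, n_cpgs: int = 12,
    replicates_per_group: int = 3, precision: float = 100.0,
    baseline_beta: tuple[float, float] = (2.0, 2.0),
    seed: int | None = None,
) -> list[RegionMethylation]:
    """Null promoter-like regions: both groups drawn from identical
    beta-binomial parameters (for type-I-error checks)."""
    rng = _seed_for(seed, "null-regions")
    a, b = baseline_beta
    regions: list[RegionMethylation] = []
    groups = {}
    names = []
    for group in ("control", "exposed"):
        for rep in range(1, replicates_per_group + 1):
            name = f"{group}_rep{rep}"
            names.append(name)
            groups[name] = group
    for i in range(n_regions):
        mu = float(np.clip(rng.beta(a, b), 0.05, 0.95))
        counts = {}
        for name in names:
            cov = rng.poisson(coverage_mean, size=n_cpgs)
            p_site = rng.beta(mu * precision, (1 - mu) * precision,
                              size=n_cpgs)
            meth = rng.binomial(cov, p_site)
            counts[name] = (int(meth.sum()), int((cov - meth).sum()))
        regions.append(RegionMethylation(
            region=GenomicInterval("chrN", i * 100, i * 100 + 100),
            region_id=f"null{i}", counts=counts, groups=dict(groups)))
    return regions


def simulate_null_expression(
    n_genes: int, n_per_group: int = 3, mean_log: float = float(np.log(200.0)),
    sigma: float = 1.0, dispersion: float = 0.1, seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Null NB count matrix with no group effect (type-I-error checks)."""
    rng = _seed_for(seed, "null-expression")
    base = rng.lognormal(mean_log, sigma, size=n_genes)
    columns = {}
    groups = {}
    r = 1.0 / dispersion
    for group in ("control", "exposed"):
        for rep in range(1, n_per_group + 1):
            name = f"{group}_rep{rep}"
            groups[name] = group
            p = r / (r + base)
            columns[name] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(columns,
                          index=[f"gene{i + 1:04d}" for i in range(n_genes)])
    return counts, groups


def write_dataset(
    config: SimulationConfig, outdir: str | Path, seed: int | None = None,
) -> dict[str, Path]:
    """Simulate and write a complete dataset (GTF, coverage files, counts,
    sample sheet, gene sets, truth table).  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = simulate_annotation(config, seed=seed)
    samples, groups, truth = simulate_methylomes(
        config, genes, seed=seed, outdir=outdir / "coverage")
    counts, sheet = simulate_expression(config, truth, genes, seed=seed)
    sets = simulate_gene_sets(config, truth, genes, seed=seed)

    paths = {
        "annotation": outdir / "genes.gtf",
        "counts": outdir / "counts.tsv",
        "sample_sheet": outdir / "samples.tsv",
        "gene_sets": outdir / "genesets.gmt",
        "truth": outdir / "coverage" / "truth.json",
        "coverage_dir": outdir / "coverage",
        "methylome_groups": outdir / "methylome_samples.tsv",
    }
    write_gtf(genes, paths["annotation"])
    counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    write_gmt(sets, paths["gene_sets"])
    meth_sheet = pd.DataFrame(
        [{"sample": name, "group": grp,
          "file": str(Path("coverage") / f"{name}.cov")}
         for name, grp in groups.items()])
    meth_sheet.to_csv(paths["methylome_groups"], sep="\t", index=False)
    return paths
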