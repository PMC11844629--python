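"""Differential expression and methylation-expression integration (DMEGs).

The built-in differential-expression stage is a deliberately small
approximation of the DESeq2 workflow: median-of-ratios size factors,
gene-wise negative-binomial dispersion by the method of moments (floored at
the across-genes median so near-zero moment estimates at n=3/group do not
produce spuriously tiny p-values), and a Wald test on the group coefficient
of an NB log-linear model.  Externally computed DE tables (e.g. DESeq2
output) are accepted as a drop-in replacement via :func:`ingest_de_table`.

A DMEG (differentially methylated and expressed gene) is a gene whose
promoter epimutation is inherited across all compared generations and whose
F2 expression is significantly changed.  The canonical classes couple the
two directions: PPPn (always hypermethylated, expression down) and NNNp
(always hypomethylated, expression up).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffmeth import bh_adjust
from .inheritance import InheritanceRecord

logger = logging.getLogger(__name__)

_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class ExpressionResult:
    """Per-gene log2 fold change (treatment over control), p, q, and
    direction p (up) / n (down) / none."""

    gene_id: str
    log2fc: float
    pvalue: float
    qvalue: float
    direction: str
    base_mean: float = float("nan")


@dataclass(frozen=True)
class DmegRecord:
    """A gene with an inherited P/N pattern and an expression direction."""

    gene_id: str
    pattern: str
    expression_direction: str  # {"p", "n"}
    canonical_class: str  # e.g. "PPPn", "NNNp", or "other"


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios size factors (genes x samples input).

    The reference is the per-gene geometric mean over samples; each sample's
    factor is the median ratio to that reference across genes expressed in
    every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_positive = np.all(mat > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no gene has positive counts in every sample; supply a "
            "pseudo-reference or filter samples"
        )
    sub = mat[all_positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _moment_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Method-of-moments NB dispersion from within-group normalized counts."""
    mu = norm.mean()
    if mu <= 0:
        return 0.0
    variances = [norm[idx].var(ddof=1) for idx in group_idx if idx.size >= 2]
    if not variances:
        return 0.0
    var_w = float(np.mean(variances))
    return max((var_w - mu) / (mu * mu), 0.0)


def nb_wald_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[str],
    qthresh: float = 0.05,
    treatment: str = "exposed",
    control: str = "control",
) -> list[ExpressionResult]:
    """Per-gene negative-binomial Wald test of treatment vs control.

    ``counts`` is genes x samples; ``groups`` maps sample names to group
    labels (or gives labels in column order).  All-zero genes are excluded
    (logged).  The log2 fold change is treatment over control.
    """
    if not isinstance(groups, Mapping):
        groups = dict(zip(counts.columns, groups))
    labels = np.array([groups[s] for s in counts.columns])
    t_idx = np.flatnonzero(labels == treatment)
    c_idx = np.flatnonzero(labels == control)
    if t_idx.size < 2 or c_idx.size < 2:
        raise ValueError("need >= 2 samples per group")

    sf = size_factors(counts).to_numpy()
    mat = counts.to_numpy(dtype=float)
    norm = mat / sf

    nonzero = mat.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("nb_wald_test: %d all-zero gene(s) excluded", n_dropped)

    genes = counts.index.to_numpy()
    group_idx = [t_idx, c_idx]
    alphas = np.array([
        _moment_dispersion(norm[i], group_idx) if nonzero[i] else np.nan
        for i in range(mat.shape[0])
    ])
    # moderate gene-wise dispersions: log-scale shrinkage toward the
    # across-genes median (gene-wise moment estimates at n=3/group are far
    # too noisy to use raw; cf. the dispersion shrinkage of DESeq2/edgeR)
    positive = alphas[nonzero & (alphas > 0)]
    alpha_prior = float(np.median(positive)) if positive.size else 0.01
    prior_weight = 0.7
    with np.errstate(divide="ignore"):
        log_gene = np.log(np.maximum(np.nan_to_num(alphas), 1e-4))
    alpha_used = np.exp((1.0 - prior_weight) * log_gene
                        + prior_weight * np.log(max(alpha_prior, 1e-4)))

    results: list[ExpressionResult] = []
    kept: list[int] = []
    pvals: list[float] = []
    stats_rows: list[tuple[str, float, float]] = []
    for i in range(mat.shape[0]):
        if not nonzero[i]:
            continue
        alpha = alpha_used[i]
        mu_t = norm[i, t_idx].mean()
        mu_c = norm[i, c_idx].mean()
        eps = 0.5 * min(1.0 / sf[t_idx].mean(), 1.0 / sf[c_idx].mean())
        beta = np.log((mu_t + (eps if mu_t == 0 else 0))
                      / (mu_c + (eps if mu_c == 0 else 0)))
        # Wald SE of the log group-mean ratio under NB sampling:
        # Var(log mean_g) ~ (1/n_g) * (1/mu_g + alpha)
        se = np.sqrt(
            (1.0 / t_idx.size) * (1.0 / max(mu_t, eps) + alpha)
            + (1.0 / c_idx.size) * (1.0 / max(mu_c, eps) + alpha)
        )
        z = beta / se if se > 0 else 0.0
        from scipy.stats import norm as norm_dist

        p = float(2.0 * norm_dist.sf(abs(z)))
        kept.append(i)
        pvals.append(p)
        stats_rows.append((str(genes[i]), beta / _LN2, float(norm[i].mean())))

    qvals = bh_adjust(pvals)
    for (gene_id, log2fc, base_mean), p, q in zip(stats_rows, pvals, qvals):
        if q < qthresh and log2fc > 0:
            direction = "p"
        elif q < qthresh and log2fc < 0:
            direction = "n"
        else:
            direction = "none"
        results.append(ExpressionResult(
            gene_id=gene_id, log2fc=float(log2fc), pvalue=float(p),
            qvalue=float(q), direction=direction, base_mean=base_mean,
        ))
    return results


def ingest_de_table(path, qthresh: float = 0.05) -> list[ExpressionResult]:
    """Load an external DE table (TSV with gene_id, log2fc, pvalue, qvalue).

    Direction labels are recomputed from qvalue and log2fc at ``qthresh``,
    so DESeq2 output can be dropped in regardless of its own threshold.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "pvalue", "qvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing column(s): {sorted(missing)}")
    results = []
    for row in df.itertuples(index=False):
        if row.qvalue < qthresh and row.log2fc > 0:
            direction = "p"
        elif row.qvalue < qthresh and row.log2fc < 0:
            direction = "n"
        else:
            direction = "none"
        results.append(ExpressionResult(
            gene_id=str(row.gene_id), log2fc=float(row.log2fc),
            pvalue=float(row.pvalue), qvalue=float(row.qvalue),
            direction=direction,
        ))
    return results


def _canonical_class(pattern: str, direction: str) -> str:
    if set(pattern) == {"P"} and direction == "n":
        return pattern + "n"
    if set(pattern) == {"N"} and direction == "p":
        return pattern + "p"
    return "other"


def derive_dmegs(
    inherited: Iterable[InheritanceRecord],
    expression: Iterable[ExpressionResult],
) -> list[DmegRecord]:
    """Intersect inherited promoter epimutations with significant DEGs.

    Genes with expression direction "none" never enter the DMEG set even if
    their promoters carry inherited DMPs.
    """
    de_dir = {r.gene_id: r.direction for r in expression
              if r.direction in ("p", "n")}
    dmegs: list[DmegRecord] = []
    for rec in inherited:
        direction = de_dir.get(rec.locus_id)
        if direction is None:
            continue
        dmegs.append(DmegRecord(
            gene_id=rec.locus_id, pattern=rec.pattern,
            expression_direction=direction,
            canonical_class=_canonical_class(rec.pattern, direction),
        ))
    return dmegs


def canonical_extract(
    dmegs: Iterable[DmegRecord],
) -> tuple[set[str], set[str]]:
    """Partition canonical DMEGs: (all-P with expression down,
    all-N with expression up)."""
    ppp_n: set[str] = set()
    nnn_p: set[str] = set()
    for d in dmegs:
        if d.canonical_class == "other":
            continue
        if d.canonical_class.endswith("n"):
            ppp_n.add(d.gene_id)
        else:
            nnn_p.add(d.gene_id)
    return ppp_n, nnn_p


def expression_to_frame(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "log2fc": r.log2fc, "pvalue": r.pvalue,
          "qvalue": r.qvalue, "direction": r.direction,
          "base_mean": r.base_mean} for r in results],
        columns=["gene_id", "log2fc", "pvalue", "qvalue", "direction",
                 "base_mean"])
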