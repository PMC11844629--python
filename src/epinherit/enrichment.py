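"""Gene-set enrichment: weighted-KS GSEA with a permutation null, and
hypergeometric over-representation analysis (ORA).

The enrichment score walks the ranked list accumulating |score|^p (normalized
over the set's hits) at each hit and subtracting 1/(N - Nh) at each miss; the
score is the maximum-deviation extremum of that running sum.  The null is a
gene-label permutation (the entry point is a ranked list, not sample-level
expression), NES divides the observed score by the mean null |score| of
matching sign, and the FDR pools positive- and negative-score nulls
separately in the style of the original GSEA method.  Permutation p-values
use the (b + 1)/(m + 1) convention, so an observed score never exceeded by
the null reports p = 1/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffmeth import bh_adjust
from .io_formats import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's enrichment against a ranked list or query set."""

    name: str
    size: int
    es: float
    nes: float
    pvalue: float
    fdr_q: float
    leading_edge: tuple[str, ...] = ()
    defined: bool = True


@dataclass(frozen=True)
class OraResult:
    """Hypergeometric over-representation of a gene set in a query."""

    name: str
    size: int
    overlap: int
    expected: float
    pvalue: float
    fdr_q: float = float("nan")
    overlap_genes: tuple[str, ...] = ()


def _as_ranked(ranked) -> tuple[np.ndarray, np.ndarray]:
    """Validate and sort a ranked list into (genes, scores) descending."""
    if isinstance(ranked, pd.Series):
        genes = np.asarray(ranked.index, dtype=object)
        scores = ranked.to_numpy(dtype=float)
    else:
        items = list(ranked)
        genes = np.array([g for g, _ in items], dtype=object)
        scores = np.array([s for _, s in items], dtype=float)
    if len(genes) != len(set(genes)):
        raise ValueError("ranked list contains duplicate genes")
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    order = np.argsort(-scores, kind="stable")
    return genes[order], scores[order]


def _running_extremum(weights: np.ndarray, hits: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Weighted-KS running sum; returns (es, extremum index, running)."""
    n = hits.size
    n_hit = int(hits.sum())
    denom_hit = float(weights[hits].sum())
    if denom_hit <= 0:
        # all hit scores are zero: fall back to equal hit weights
        step_hit = np.where(hits, 1.0 / n_hit, 0.0)
    else:
        step_hit = np.where(hits, weights / denom_hit, 0.0)
    miss = 1.0 / (n - n_hit) if n > n_hit else 0.0
    steps = np.where(hits, step_hit, -miss)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx, running


def enrichment_score(
    ranked,
    geneset: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Enrichment score of ``geneset`` against a ranked list.

    ``ranked`` is a pandas Series (gene -> score) or an iterable of
    (gene, score) pairs; it is sorted descending internally.  Returns
    ``(es, running profile, leading edge genes)``.  A set disjoint from the
    ranked list yields ``(nan, empty, ())``.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    genes, scores = _as_ranked(ranked)
    members = set(geneset)
    hits = np.array([g in members for g in genes])
    if not hits.any():
        warnings.warn("gene set disjoint from ranked list; ES undefined",
                      stacklevel=2)
        return float("nan"), np.empty(0), ()
    weights = np.abs(scores) ** weight_exponent
    es, idx, running = _running_extremum(weights, hits)
    if es >= 0:
        leading = tuple(genes[: idx + 1][hits[: idx + 1]])
    else:
        leading = tuple(genes[idx:][hits[idx:]])
    return es, running, leading


def gsea(
    ranked,
    sets: GeneSetCollection | Mapping[str, Iterable[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 2000,
) -> list[EnrichmentResult]:
    """GSEA over a collection of gene sets with a gene-label permutation null.

    Sets outside the [min_size, max_size] filter (after restriction to the
    ranked universe) are excluded.  Results are reproducible under a fixed
    seed: the same seed yields bit-identical NES, p and FDR values.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    genes, scores = _as_ranked(ranked)
    n = genes.size
    weights = np.abs(scores) ** weight_exponent
    set_items = sets.sets.items() if isinstance(sets, GeneSetCollection) else sets.items()

    universe = {g: i for i, g in enumerate(genes)}
    kept: list[tuple[str, np.ndarray]] = []
    for name, members in set_items:
        idx = np.array(sorted({universe[m] for m in members if m in universe}),
                       dtype=int)
        if min_size <= idx.size <= max_size:
            kept.append((name, idx))

    rng = np.random.default_rng(seed)
    observed: list[tuple[str, int, float, tuple[str, ...]]] = []
    null_es: list[np.ndarray] = []
    for name, idx in kept:
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        es, ext_idx, _running = _running_extremum(weights, hits)
        if es >= 0:
            leading = tuple(genes[: ext_idx + 1][hits[: ext_idx + 1]])
        else:
            leading = tuple(genes[ext_idx:][hits[ext_idx:]])
        observed.append((name, idx.size, es, leading))
        nulls = np.empty(n_perm)
        size = idx.size
        for b in range(n_perm):
            perm_hits = np.zeros(n, dtype=bool)
            perm_hits[rng.choice(n, size=size, replace=False)] = True
            nulls[b], _, _ = _running_extremum(weights, perm_hits)
        null_es.append(nulls)

    # normalize observed and null scores by the mean |null| of matching sign
    obs_nes = np.full(len(kept), np.nan)
    null_nes_all: list[np.ndarray] = []
    pvalues = np.ones(len(kept))
    for i, ((_name, _size, es, _le), nulls) in enumerate(zip(observed, null_es)):
        pos = nulls[nulls > 0]
        neg = nulls[nulls < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        norm_null = np.where(nulls > 0, nulls / mean_pos,
                             np.where(nulls < 0, nulls / mean_neg, 0.0))
        null_nes_all.append(norm_null[np.isfinite(norm_null)])
        if es >= 0:
            obs_nes[i] = es / mean_pos if np.isfinite(mean_pos) else np.nan
            b = int((nulls >= es).sum())
        else:
            obs_nes[i] = es / mean_neg if np.isfinite(mean_neg) else np.nan
            b = int((nulls <= es).sum())
        # exceedances in the observed direction over ALL permutations,
        # with the +1 guard so a never-exceeded score reports 1/(n_perm+1)
        pvalues[i] = (b + 1) / (n_perm + 1)

    pooled_null = (np.concatenate(null_nes_all) if null_nes_all
                   else np.empty(0))
    pos_null = pooled_null[pooled_null > 0]
    neg_null = pooled_null[pooled_null < 0]
    finite_obs = obs_nes[np.isfinite(obs_nes)]
    pos_obs = finite_obs[finite_obs > 0]
    neg_obs = finite_obs[finite_obs < 0]

    results: list[EnrichmentResult] = []
    for (name, size, es, leading), nes, p in zip(observed, obs_nes, pvalues):
        if not np.isfinite(nes):
            results.append(EnrichmentResult(
                name=name, size=size, es=es, nes=float("nan"), pvalue=p,
                fdr_q=1.0, leading_edge=leading, defined=False))
            continue
        if nes >= 0:
            num = ((pos_null >= nes).sum() / pos_null.size
                   if pos_null.size else 0.0)
            den = ((pos_obs >= nes).sum() / pos_obs.size
                   if pos_obs.size else 1.0)
        else:
            num = ((neg_null <= nes).sum() / neg_null.size
                   if neg_null.size else 0.0)
            den = ((neg_obs <= nes).sum() / neg_obs.size
                   if neg_obs.size else 1.0)
        fdr_q = float(min(1.0, num / den)) if den > 0 else 1.0
        results.append(EnrichmentResult(
            name=name, size=size, es=float(es), nes=float(nes),
            pvalue=float(p), fdr_q=fdr_q, leading_edge=leading))
    return results


def ora_test(
    query: Iterable[str],
    geneset: Iterable[str],
    universe: Iterable[str],
    name: str = "",
) -> OraResult:
    """Hypergeometric upper-tail test of overlap between query and gene set.

    p = P(overlap >= k) with the universe as the sampling frame.  Query or
    set members outside the universe are trimmed with a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    s = set(geneset)
    if q - uni:
        warnings.warn(f"{len(q - uni)} query gene(s) outside universe trimmed",
                      stacklevel=2)
        q &= uni
    if s - uni:
        warnings.warn(f"{len(s - uni)} set gene(s) outside universe trimmed",
                      stacklevel=2)
        s &= uni
    big_n, big_k, n = len(uni), len(s), len(q)
    overlap = q & s
    k = len(overlap)
    pvalue = float(hypergeom.sf(k - 1, big_n, big_k, n))
    expected = n * big_k / big_n
    return OraResult(name=name, size=big_k, overlap=k, expected=expected,
                     pvalue=pvalue, overlap_genes=tuple(sorted(overlap)))


def ora_analysis(
    query: Iterable[str],
    sets: GeneSetCollection | Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[OraResult]:
    """ORA over a collection of sets with BH adjustment across all sets."""
    set_items = sets.sets.items() if isinstance(sets, GeneSetCollection) else sets.items()
    raw = [ora_test(query, members, universe, name=name)
           for name, members in set_items]
    if not raw:
        return []
    qvals = bh_adjust([r.pvalue for r in raw])
    return [OraResult(name=r.name, size=r.size, overlap=r.overlap,
                      expected=r.expected, pvalue=r.pvalue, fdr_q=float(q),
                      overlap_genes=r.overlap_genes)
            for r, q in zip(raw, qvals)]


def compare_enrichment(results_a, results_b) -> pd.DataFrame:
    """Join two enrichment result collections on set name.

    Reports -log10 q side by side and which side is more enriched
    ("A", "B", or "tie").
    """
    def to_map(results):
        out = {}
        for r in results:
            q = r.fdr_q
            out[r.name] = q
        return out

    qa = to_map(results_a)
    qb = to_map(results_b)
    rows = []
    floor = 1e-300
    for name in sorted(set(qa) & set(qb)):
        la = -np.log10(max(qa[name], floor))
        lb = -np.log10(max(qb[name], floor))
        more = "A" if la > lb else ("B" if lb > la else "tie")
        rows.append({"set": name, "neglog10_q_a": la, "neglog10_q_b": lb,
                     "more_enriched": more})
    return pd.DataFrame(rows, columns=["set", "neglog10_q_a", "neglog10_q_b",
                                       "more_enriched"])


def rank_by_signed_significance(results) -> pd.Series:
    """Default GSEA ranking metric for DE results:
    sign(log2fc) * -log10(pvalue)."""
    genes, scores = [], []
    for r in results:
        p = max(r.pvalue, 1e-300)
        genes.append(r.gene_id)
        scores.append(float(np.sign(r.log2fc) * -np.log10(p)))
    return pd.Series(scores, index=genes).sort_values(ascending=False)


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"set": r.name, "size": r.size, "es": r.es, "nes": r.nes,
          "pvalue": r.pvalue, "fdr_q": r.fdr_q,
          "leading_edge": ";".join(r.leading_edge)} for r in results],
        columns=["set", "size", "es", "nes", "pvalue", "fdr_q",
                 "leading_edge"])
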