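"""Per-region differential-methylation testing with FDR control and P/N labels.

Two test paths are provided, mirroring the methylKit conventions for
replicated bisulfite designs:

* ``fisher_region_test`` — two-sided Fisher exact test on the 2x2 table of
  pooled within-group counts, computed by exact integer hypergeometric
  enumeration (tables with point probability <= the observed one are summed).
* ``logistic_region_test`` — binomial logistic regression of the methylated
  proportion on the group indicator across replicates.  With a single binary
  covariate the MLE is available in closed form (group-pooled proportions),
  so the likelihood-ratio statistic is computed directly and referred to
  chi-square(1).

``call_dmrs`` routes each region (logistic when both groups have >= 2
replicates, Fisher otherwise or on separation), optionally rescales the
logistic LRT by a pooled quasi-binomial dispersion factor (median residual
deviance/df across regions) to absorb replicate overdispersion, applies
Benjamini-Hochberg across all tested regions, and labels directions:
``P`` (hypermethylated in the treatment group) or ``N`` (hypomethylated)
for significant regions, ``none`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .methylation import ConfigurationError, GenomicInterval, RegionMethylation


@dataclass(frozen=True)
class DiffMethResult:
    """Per-region methylation difference (treatment - control, percentage
    points from pooled within-group counts), p-value, BH q-value, direction."""

    region_id: str
    meth_diff: float
    pvalue: float
    qvalue: float
    direction: str  # {"P", "N", "none"}
    method: str = "logistic"  # {"logistic", "fisher"}
    region: GenomicInterval | None = None


def fisher_region_test(meth_t: int, unmeth_t: int,
                       meth_c: int, unmeth_c: int) -> float:
    """Two-sided Fisher exact p-value for the pooled 2x2 count table.

    Exact integer arithmetic: with fixed margins every table's hypergeometric
    probability shares the denominator C(n, c1), so tables are included when
    their integer numerator C(r1, k)*C(r2, c1-k) is <= the observed one.
    Degenerate tables (a zero margin) return p = 1.0.
    """
    counts = (meth_t, unmeth_t, meth_c, unmeth_c)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative counts {counts}")
    r1 = meth_t + unmeth_t
    r2 = meth_c + unmeth_c
    c1 = meth_t + meth_c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate: a zero margin carries no information
    num_obs = math.comb(r1, meth_t) * math.comb(r2, meth_c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num_k <= num_obs:
            total += num_k
    return float(total / math.comb(n, c1))


@dataclass(frozen=True)
class RegionTestResult:
    pvalue: float
    meth_diff: float
    method: str
    lrt: float = float("nan")
    deviance: float = float("nan")
    df_resid: int = 0
    separated: bool = False


def _binom_loglik(meth: np.ndarray, unmeth: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(meth * np.log(p) + unmeth * np.log1p(-p)))


def logistic_region_test(
    meth_t: Sequence[float], unmeth_t: Sequence[float],
    meth_c: Sequence[float], unmeth_c: Sequence[float],
) -> RegionTestResult:
    """Binomial logistic regression LRT of methylation on group membership.

    Falls back to :func:`fisher_region_test` on pooled counts when either
    group has fewer than two replicates or is completely separated
    (pooled proportion exactly 0 or 1); the result is flagged accordingly.
    ``meth_diff`` is always the pooled-count percentage difference
    (treatment - control).
    """
    mt = np.asarray(meth_t, dtype=float)
    ut = np.asarray(unmeth_t, dtype=float)
    mc = np.asarray(meth_c, dtype=float)
    uc = np.asarray(unmeth_c, dtype=float)
    Mt, Ut, Mc, Uc = mt.sum(), ut.sum(), mc.sum(), uc.sum()
    if Mt + Ut == 0 or Mc + Uc == 0:
        return RegionTestResult(1.0, 0.0, "fisher", separated=True)
    pt = Mt / (Mt + Ut)
    pc = Mc / (Mc + Uc)
    meth_diff = 100.0 * (pt - pc)

    few_reps = len(mt) < 2 or len(mc) < 2
    separated = pt in (0.0, 1.0) or pc in (0.0, 1.0)
    if few_reps or separated:
        p = fisher_region_test(int(Mt), int(Ut), int(Mc), int(Uc))
        return RegionTestResult(p, meth_diff, "fisher", separated=separated)

    ll_full = (_binom_loglik(mt, ut, np.full(len(mt), pt))
               + _binom_loglik(mc, uc, np.full(len(mc), pc)))
    p0 = (Mt + Mc) / (Mt + Ut + Mc + Uc)
    ll_null = (_binom_loglik(mt, ut, np.full(len(mt), p0))
               + _binom_loglik(mc, uc, np.full(len(mc), p0)))
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    pvalue = float(stats.chi2.sf(lrt, df=1))

    # saturated model for the residual (within-group) deviance
    with np.errstate(divide="ignore", invalid="ignore"):
        covered_t = (mt + ut) > 0
        covered_c = (mc + uc) > 0
        phat_t = np.where(covered_t, mt / np.maximum(mt + ut, 1), 0.0)
        phat_c = np.where(covered_c, mc / np.maximum(mc + uc, 1), 0.0)
    ll_sat = (_binom_loglik(mt[covered_t], ut[covered_t], phat_t[covered_t])
              + _binom_loglik(mc[covered_c], uc[covered_c], phat_c[covered_c]))
    deviance = max(0.0, 2.0 * (ll_sat - ll_full))
    df_resid = int(covered_t.sum() + covered_c.sum() - 2)
    return RegionTestResult(pvalue, meth_diff, "logistic", lrt=lrt,
                            deviance=deviance, df_resid=df_resid)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, aligned to the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def call_dmrs(
    regions: Iterable[RegionMethylation],
    fdr: float = 0.1,
    treatment: str = "exposed",
    control: str = "control",
    test: str = "auto",
    min_diff: float = 0.0,
    overdispersion: str = "pooled",
) -> list[DiffMethResult]:
    """Call differentially methylated regions between two lineage groups.

    ``test`` is "auto" (logistic with >=2 replicates per group, else Fisher),
    "logistic", or "fisher" (always on pooled counts).  ``overdispersion``
    "pooled" rescales logistic LRTs by the across-region median residual
    deviance/df (floored at 1) before recomputing p-values; "none" disables
    the rescaling.  BH adjustment runs over all tested regions; significant
    regions with |meth_diff| > ``min_diff`` get direction P (positive
    difference) or N (negative).
    """
    if not 0.0 < fdr < 1.0:
        raise ConfigurationError(f"fdr must be in (0, 1), got {fdr}")
    if test not in ("auto", "logistic", "fisher"):
        raise ConfigurationError(f"unknown test {test!r}")

    regions = list(regions)
    raw: list[RegionTestResult] = []
    for reg in regions:
        mt, ut = reg.replicate_counts(treatment)
        mc, uc = reg.replicate_counts(control)
        if test == "fisher":
            Mt, Ut, Mc, Uc = int(mt.sum()), int(ut.sum()), int(mc.sum()), int(uc.sum())
            pt = Mt / max(Mt + Ut, 1)
            pc = Mc / max(Mc + Uc, 1)
            raw.append(RegionTestResult(
                fisher_region_test(Mt, Ut, Mc, Uc), 100.0 * (pt - pc), "fisher"))
        else:
            raw.append(logistic_region_test(mt, ut, mc, uc))

    pvalues = np.array([r.pvalue for r in raw])
    if overdispersion == "pooled":
        ratios = [r.deviance / r.df_resid for r in raw
                  if r.method == "logistic" and r.df_resid > 0]
        if ratios:
            phi = max(1.0, float(np.median(ratios)))
            for i, r in enumerate(raw):
                if r.method == "logistic":
                    pvalues[i] = stats.chi2.sf(r.lrt / phi, df=1)
    elif overdispersion != "none":
        raise ConfigurationError(f"unknown overdispersion mode {overdispersion!r}")

    qvalues = bh_adjust(pvalues)
    out: list[DiffMethResult] = []
    for reg, r, p, q in zip(regions, raw, pvalues, qvalues):
        if q < fdr and r.meth_diff > min_diff:
            direction = "P"
        elif q < fdr and r.meth_diff < -min_diff:
            direction = "N"
        else:
            direction = "none"
        out.append(DiffMethResult(
            region_id=reg.region_id, meth_diff=float(r.meth_diff),
            pvalue=float(p), qvalue=float(q), direction=direction,
            method=r.method, region=reg.region,
        ))
    return out


def direction_balance(results: Iterable[DiffMethResult]) -> tuple[int, int, float | None]:
    """Counts of hyper (P) and hypo (N) calls and the hyper fraction.

    The fraction is ``None`` when there are no significant calls.
    """
    n_hyper = sum(1 for r in results if r.direction == "P")
    n_hypo = sum(1 for r in results if r.direction == "N")
    total = n_hyper + n_hypo
    frac = n_hyper / total if total else None
    return n_hyper, n_hypo, frac


def results_to_frame(results: Sequence[DiffMethResult]):
    """Tabulate results (region_id, chrom, start, end, meth_diff, pvalue,
    qvalue, direction, method) for TSV export."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "region_id": r.region_id,
            "chrom": r.region.chrom if r.region else "",
            "start": r.region.start if r.region else -1,
            "end": r.region.end if r.region else -1,
            "meth_diff": r.meth_diff,
            "pvalue": r.pvalue,
            "qvalue": r.qvalue,
            "direction": r.direction,
            "method": r.method,
        })
    return pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "meth_diff",
                       "pvalue", "qvalue", "direction", "method"])
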