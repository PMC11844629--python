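"""Coverage filtering, genome tiling, promoter windows, and count aggregation.

The whole-genome bisulfite workflow modelled here mirrors the standard
methylKit-style analysis: CpG sites are kept when their read coverage meets a
minimum (default 3), the genome is cut into fixed tiles (default 100 bp window
and step), and promoters are TSS-anchored windows (default -3000/+300,
strand-aware).  Per-region counts are the sums of the member CpG counts for
each sample; a region is retained only when every sample contributes at least
one covered CpG (the unite-across-all rule differential tests need), which is
configurable via ``require_all_samples``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import CpGRecord, GeneModel


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class RegionMethylation:
    """A tile or promoter with per-sample aggregated (meth, unmeth) counts."""

    region: GenomicInterval
    region_id: str
    counts: dict[str, tuple[int, int]]
    groups: dict[str, str] = field(default_factory=dict)

    def group_counts(self, group: str) -> tuple[int, int]:
        """Pooled (meth, unmeth) over the samples belonging to ``group``."""
        m = u = 0
        for sample, (mi, ui) in self.counts.items():
            if self.groups.get(sample) == group:
                m += mi
                u += ui
        return m, u

    def replicate_counts(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        samples = [s for s in self.counts if self.groups.get(s) == group]
        meth = np.array([self.counts[s][0] for s in samples], dtype=float)
        unmeth = np.array([self.counts[s][1] for s in samples], dtype=float)
        return meth, unmeth


def filter_coverage(sites: Iterable[CpGRecord], min_cov: int = 3) -> list[CpGRecord]:
    """Keep sites with coverage >= ``min_cov`` (order preserved)."""
    if min_cov < 1:
        raise ConfigurationError("min_cov must be >= 1")
    return [s for s in sites if s.coverage >= min_cov]


def _tile_anchors(pos: int, window: int, step: int) -> range:
    """Anchors (multiples of ``step``) of every tile containing ``pos``."""
    lo = math.floor((pos - window) / step) + 1
    hi = pos // step
    return range(max(lo, 0), hi + 1)


def tile_genome(
    samples: Mapping[str, Sequence[CpGRecord]],
    window: int = 100,
    step: int = 100,
    groups: Mapping[str, str] | None = None,
    require_all_samples: bool = True,
) -> list[RegionMethylation]:
    """Aggregate per-sample CpG counts into fixed genome tiles.

    Tiles are anchored at coordinates that are multiples of ``step`` from 0,
    so with ``step == window`` every CpG belongs to exactly one tile.  Only
    tiles with at least one covered CpG in every sample (or in any sample,
    with ``require_all_samples=False``) are emitted.
    """
    if window < 1 or step < 1:
        raise ConfigurationError("window and step must be >= 1")
    if step > window:
        raise ConfigurationError(
            "step > window leaves gaps that would drop CpGs silently"
        )
    per_sample: dict[str, dict[tuple[str, int], list[int]]] = {}
    for sample, sites in samples.items():
        acc: dict[tuple[str, int], list[int]] = {}
        for site in sites:
            for anchor in _tile_anchors(site.pos, window, step):
                key = (site.chrom, anchor * step)
                cell = acc.setdefault(key, [0, 0])
                cell[0] += site.meth_count
                cell[1] += site.unmeth_count
        per_sample[sample] = acc

    all_keys: set[tuple[str, int]] = set()
    for acc in per_sample.values():
        all_keys.update(acc)
    regions: list[RegionMethylation] = []
    for chrom, start in sorted(all_keys):
        key = (chrom, start)
        present = [s for s, acc in per_sample.items() if key in acc]
        if require_all_samples and len(present) < len(per_sample):
            continue
        counts = {s: tuple(per_sample[s][key]) for s in present}
        regions.append(RegionMethylation(
            region=GenomicInterval(chrom, start, start + window),
            region_id=f"{chrom}:{start}",
            counts=counts,
            groups=dict(groups or {}),
        ))
    return regions


def promoter_windows(
    genes: Iterable[GeneModel],
    upstream: int = 3000,
    downstream: int = 300,
) -> list[tuple[str, GenomicInterval]]:
    """TSS-anchored promoter windows, strand-aware and clamped at 0.

    Plus strand: ``[tss - upstream, tss + downstream)``; minus strand the
    mirror image ``[tss - downstream, tss + upstream)``.
    """
    if upstream < 0 or downstream < 0:
        raise ConfigurationError("upstream/downstream must be >= 0")
    out: list[tuple[str, GenomicInterval]] = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        else:
            start, end = g.tss - downstream, g.tss + upstream
        start = max(start, 0)
        if end <= start:
            continue
        out.append((g.gene_id, GenomicInterval(g.chrom, start, end, g.strand)))
    return out


def aggregate_regions(
    samples: Mapping[str, Sequence[CpGRecord]],
    regions: Sequence[tuple[str, GenomicInterval]],
    groups: Mapping[str, str] | None = None,
    require_all_samples: bool = True,
) -> list[RegionMethylation]:
    """Sum per-sample CpG counts over arbitrary (possibly overlapping) regions.

    Used for promoter windows keyed by gene_id.  Counts are conserved: each
    region's per-sample counts are exactly the sums over its member sites.
    """
    # sort each sample's sites per chromosome once, then range-query
    indexed: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for sample, sites in samples.items():
        by_chrom: dict[str, list[CpGRecord]] = {}
        for site in sites:
            by_chrom.setdefault(site.chrom, []).append(site)
        chrom_arrays = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: r.pos)
            pos = np.array([r.pos for r in recs], dtype=np.int64)
            meth = np.array([r.meth_count for r in recs], dtype=np.int64)
            unmeth = np.array([r.unmeth_count for r in recs], dtype=np.int64)
            chrom_arrays[chrom] = (pos, meth, unmeth)
        indexed[sample] = chrom_arrays

    out: list[RegionMethylation] = []
    for region_id, iv in regions:
        counts: dict[str, tuple[int, int]] = {}
        for sample, chrom_arrays in indexed.items():
            arrays = chrom_arrays.get(iv.chrom)
            if arrays is None:
                continue
            pos, meth, unmeth = arrays
            lo = np.searchsorted(pos, iv.start, side="left")
            hi = np.searchsorted(pos, iv.end, side="left")
            if hi > lo:
                counts[sample] = (int(meth[lo:hi].sum()), int(unmeth[lo:hi].sum()))
        if require_all_samples and len(counts) < len(indexed):
            continue
        if not counts:
            continue
        out.append(RegionMethylation(
            region=iv, region_id=region_id, counts=counts,
            groups=dict(groups or {}),
        ))
    return out


# ---------------------------------------------------------------------------
# Genomic-location classification
# ---------------------------------------------------------------------------


class LocationClassifier:
    """Label regions as promoter/exon/intron/intergenic by overlap.

    Overlap means at least one shared base.  When a region overlaps several
    feature classes the label follows a precedence order (default promoter >
    exon > intron > intergenic), which is configurable.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        promoters: Sequence[tuple[str, GenomicInterval]],
        precedence: Sequence[str] = ("promoter", "exon", "intron", "intergenic"),
    ) -> None:
        from intervaltree import IntervalTree

        self.precedence = tuple(precedence)
        self._trees: dict[str, dict[str, "IntervalTree"]] = {
            "promoter": {}, "exon": {}, "gene": {},
        }

        def add(kind: str, chrom: str, start: int, end: int) -> None:
            tree = self._trees[kind].setdefault(chrom, IntervalTree())
            tree.addi(start, end)

        for _gid, iv in promoters:
            add("promoter", iv.chrom, iv.start, iv.end)
        for g in genes:
            add("gene", g.chrom, g.start, g.end)
            for start, end in g.exons:
                add("exon", g.chrom, start, end)

    def _hits(self, kind: str, region: GenomicInterval) -> bool:
        tree = self._trees[kind].get(region.chrom)
        return bool(tree and tree.overlap(region.start, region.end))

    def classify(self, region: GenomicInterval) -> str:
        flags = {
            "promoter": self._hits("promoter", region),
            "exon": self._hits("exon", region),
        }
        # intron: inside a gene body but not only because of its exons
        flags["intron"] = self._hits("gene", region)
        flags["intergenic"] = True
        for label in self.precedence:
            if flags.get(label, False):
                return label
        return "intergenic"


def classify_region_location(
    region: GenomicInterval,
    genes: Iterable[GeneModel],
    promoters: Sequence[tuple[str, GenomicInterval]],
    precedence: Sequence[str] = ("promoter", "exon", "intron", "intergenic"),
) -> str:
    """One-shot convenience wrapper around :class:`LocationClassifier`."""
    return LocationClassifier(genes, promoters, precedence).classify(region)


# ---------------------------------------------------------------------------
# Global methylation comparison
# ---------------------------------------------------------------------------


def global_methylation_compare(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
) -> tuple[float, float, str]:
    """One-sided Wilcoxon rank-sum comparison of per-window methylation levels.

    Returns ``(U statistic of A vs B, one-sided p-value, direction)`` where
    direction is ``"a"`` or ``"b"`` for whichever sample has the greater
    location, or ``"none"`` for a tie.  scipy's Mann-Whitney U is used with
    its automatic method choice: exact for small untied samples, otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 0.5, "none"
    greater = stats.mannwhitneyu(a, b, alternative="greater")
    less = stats.mannwhitneyu(a, b, alternative="less")
    if greater.pvalue < less.pvalue:
        return float(greater.statistic), float(greater.pvalue), "a"
    if less.pvalue < greater.pvalue:
        return float(greater.statistic), float(less.pvalue), "b"
    return float(greater.statistic), 0.5, "none"
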