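"""Cross-generation tracking of differentially methylated promoters (DMPs).

A locus (gene-keyed promoter, or ``chrom:start`` tile) that is significant in
every compared generation receives a pattern string over {P, N}, one
character per generation in fixed order — e.g. "NPN" means hypomethylated in
F0 sperm, hypermethylated in F1 sperm, hypomethylated again in F2 liver.
Transmission statistics summarise the set algebra of the per-generation DMP
sets: loci common to all three generations (consistent inheritance), present
in F0 and F2 but not F1 (skipped inheritance), and novel in F1 yet inherited
by F2.  Percentages are expressed against explicitly named reference sets
with half-up rounding to one decimal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneModel


@dataclass(frozen=True)
class InheritanceRecord:
    """A locus with its per-generation direction string and optional
    expression suffix (p = upregulated, n = downregulated in F2)."""

    locus_id: str
    pattern: str
    expression_suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.pattern or any(c not in "PN" for c in self.pattern):
            raise ValueError(
                f"{self.locus_id}: pattern must be non-empty over {{P,N}}, "
                f"got {self.pattern!r}"
            )
        if self.expression_suffix not in (None, "p", "n"):
            raise ValueError(
                f"{self.locus_id}: expression suffix must be p/n/None"
            )


def intersect_dmps(
    sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], list[str]]:
    """All pairwise and higher-order intersections of named DMP sets.

    Returns a mapping from name tuples (in input order) to sorted member
    lists.  Duplicate loci within a set are deduplicated with a warning.
    """
    cleaned: dict[str, set[str]] = {}
    for name, loci in sets.items():
        loci = list(loci)
        uniq = set(loci)
        if len(uniq) < len(loci):
            warnings.warn(
                f"DMP set {name!r}: {len(loci) - len(uniq)} duplicate "
                "locus id(s) removed", stacklevel=2)
        cleaned[name] = uniq
    names = list(cleaned)
    out: dict[tuple[str, ...], list[str]] = {}
    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            inter = set.intersection(*(cleaned[n] for n in combo))
            out[combo] = sorted(inter)
    return out


def classify_pattern(
    locus_id: str,
    directions: Sequence[str],
    expression_suffix: str | None = None,
) -> InheritanceRecord:
    """Concatenate per-generation directions into a pattern string.

    Any direction outside {P, N} (e.g. "none") rejects the locus.
    """
    for d in directions:
        if d not in ("P", "N"):
            raise ValueError(
                f"{locus_id}: direction {d!r} is not P/N; locus rejected"
            )
    return InheritanceRecord(locus_id=locus_id, pattern="".join(directions),
                             expression_suffix=expression_suffix)


def classify_common_loci(
    per_generation: Sequence[Mapping[str, str]],
) -> list[InheritanceRecord]:
    """Classify every locus with a P/N call in all generations.

    ``per_generation`` is a sequence of {locus_id: direction} mappings in
    fixed generation order; loci missing from any generation, or carrying a
    non-P/N direction anywhere, are dropped.
    """
    if not per_generation:
        return []
    common = set(per_generation[0])
    for gen in per_generation[1:]:
        common &= set(gen)
    records: list[InheritanceRecord] = []
    for locus in sorted(common):
        dirs = [gen[locus] for gen in per_generation]
        if all(d in ("P", "N") for d in dirs):
            records.append(classify_pattern(locus, dirs))
    return records


def pattern_census(
    records: Iterable[InheritanceRecord],
    n_generations: int | None = None,
) -> dict[str, int]:
    """Counts over all 2^k possible P/N patterns (absent patterns are 0)."""
    records = list(records)
    if n_generations is None:
        n_generations = len(records[0].pattern) if records else 3
    census = {"".join(p): 0 for p in product("PN", repeat=n_generations)}
    for rec in records:
        if len(rec.pattern) != n_generations:
            raise ValueError(
                f"{rec.locus_id}: pattern length {len(rec.pattern)} != "
                f"{n_generations}"
            )
        census[rec.pattern] += 1
    return census


def biotype_tally(
    locus_ids: Iterable[str],
    genes: Iterable[GeneModel],
) -> dict[str, int]:
    """Count loci per gene biotype; unresolvable ids go to "unknown"."""
    biotypes = {g.gene_id: g.biotype for g in genes}
    tally: Counter[str] = Counter()
    for locus in locus_ids:
        tally[biotypes.get(locus, "unknown")] += 1
    return dict(tally)


def _pct(count: int, reference: int) -> float | None:
    """100*count/reference with half-up rounding to 1 decimal; None if the
    reference set is empty."""
    if reference == 0:
        return None
    frac = Decimal(100 * count) / Decimal(reference)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TransmissionStats:
    """Set sizes, intersections, and percentages of DMP transmission."""

    n_f0: int
    n_f1: int
    n_f2: int
    n_common_all: int
    n_skipped: int
    n_novel_f1: int
    percentages: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_common_all > min(self.n_f0, self.n_f1, self.n_f2):
            raise ValueError("common set larger than a parent set")
        if (self.n_skipped + self.n_common_all > self.n_f0
                or self.n_skipped + self.n_common_all > self.n_f2):
            raise ValueError("skipped + common exceeds |F0| or |F2|")


def transmission_stats_from_counts(
    n_f0: int, n_f1: int, n_f2: int,
    n_common_all: int, n_skipped: int, n_novel_f1: int = 0,
) -> TransmissionStats:
    """Transmission statistics from already-tabulated set sizes.

    Each intersection is expressed against each of its named parent sets:
    the common-to-all count against F0, F1 and F2; the skipped count
    (F0 and F2, absent from F1) against F0 and F2; the novel-in-F1 count
    against F1 and F2.
    """
    percentages = {
        "common_vs_f0": _pct(n_common_all, n_f0),
        "common_vs_f1": _pct(n_common_all, n_f1),
        "common_vs_f2": _pct(n_common_all, n_f2),
        "skipped_vs_f0": _pct(n_skipped, n_f0),
        "skipped_vs_f2": _pct(n_skipped, n_f2),
        "novel_f1_vs_f1": _pct(n_novel_f1, n_f1),
        "novel_f1_vs_f2": _pct(n_novel_f1, n_f2),
    }
    return TransmissionStats(
        n_f0=n_f0, n_f1=n_f1, n_f2=n_f2, n_common_all=n_common_all,
        n_skipped=n_skipped, n_novel_f1=n_novel_f1, percentages=percentages,
    )


def transmission_stats(
    f0: Iterable[str], f1: Iterable[str], f2: Iterable[str],
) -> TransmissionStats:
    """Transmission statistics from the per-generation significant-locus sets.

    Consistent inheritance: F0 ∩ F1 ∩ F2.  Skipped: (F0 ∩ F2) \\ F1.
    Novel in F1: (F1 ∩ F2) \\ F0.
    """
    s0, s1, s2 = set(f0), set(f1), set(f2)
    common = s0 & s1 & s2
    skipped = (s0 & s2) - s1
    novel = (s1 & s2) - s0
    return transmission_stats_from_counts(
        n_f0=len(s0), n_f1=len(s1), n_f2=len(s2),
        n_common_all=len(common), n_skipped=len(skipped),
        n_novel_f1=len(novel),
    )
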