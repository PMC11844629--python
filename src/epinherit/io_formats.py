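"""Readers and writers for the plain-text formats the pipeline touches.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based, half-open ``[start, end)``.  Each
reader documents and applies its own shift:

* Bismark CpG coverage files carry 1-based inclusive positions; the reader
  subtracts one.
* GTF/GFF features are 1-based inclusive; starts are shifted by one.
* BED-like gene tables are already 0-based half-open and pass through.

Methylation percentages in coverage files are advisory only: the counts are
the statistical primitives, so ``meth_pct`` is always recomputed and a single
consistency warning is raised if the file's column disagrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


class ValidationError(ValueError):
    """Input violated a documented invariant (negative counts, bad strand...)."""


# ---------------------------------------------------------------------------
# CpG coverage records (Bismark dialect)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CpGRecord:
    """A covered cytosine with methylated/unmethylated read counts.

    ``pos`` is 0-based.  ``meth_pct`` is derived from the counts and is
    ``None`` when total coverage is zero (degenerate but retained).
    """

    chrom: str
    pos: int
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValidationError(
                f"negative counts at {self.chrom}:{self.pos}: "
                f"({self.meth_count}, {self.unmeth_count})"
            )

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def meth_pct(self) -> float | None:
        """Percentage methylated in [0, 100]; None if coverage is zero."""
        cov = self.coverage
        if cov == 0:
            return None
        return 100.0 * self.meth_count / cov


def read_bismark_coverage(path: str | Path) -> list[CpGRecord]:
    """Read a Bismark CpG coverage file (6-column TSV).

    Columns: chrom, start (1-based), end, methylation %, count methylated,
    count unmethylated.  Positions are converted to 0-based; the percentage
    column is ignored beyond a consistency check.
    """
    records: list[CpGRecord] = []
    n_pct_mismatch = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=6 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                file_pct = float(fields[3])
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative counts ({meth}, {unmeth})"
                )
            rec = CpGRecord(chrom=chrom, pos=start - 1, meth_count=meth,
                            unmeth_count=unmeth)
            if rec.coverage > 0 and abs((rec.meth_pct or 0.0) - file_pct) > 1e-3:
                n_pct_mismatch += 1
            records.append(rec)
    if n_pct_mismatch:
        warnings.warn(
            f"{path}: methylation % column disagrees with counts on "
            f"{n_pct_mismatch} line(s); percentages recomputed from counts",
            stacklevel=2,
        )
    return records


def write_bismark_coverage(records: Iterable[CpGRecord], path: str | Path) -> None:
    """Write records in the Bismark coverage dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for rec in records:
            pct = rec.meth_pct
            pct_str = f"{pct:g}" if pct is not None else "0"
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.pos + 1}\t{pct_str}\t"
                f"{rec.meth_count}\t{rec.unmeth_count}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GTF / BED dialects)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, biotype, TSS, and 0-based half-open exons.

    The TSS is the 5'-most exon boundary respecting strand: the smallest
    exon start on ``+``, the largest exon end on ``-`` (a half-open boundary
    coordinate, so promoter windows tile naturally on either strand).
    """

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"gene {self.gene_id}: empty exon ({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = end

    @classmethod
    def from_exons(cls, gene_id: str, chrom: str, strand: str,
                   exons: Sequence[tuple[int, int]],
                   biotype: str = "protein_coding") -> "GeneModel":
        """Build a model with the TSS derived strand-aware from the exons."""
        if strand == ".":
            warnings.warn(
                f"gene {gene_id}: strand '.' treated as '+'", stacklevel=2
            )
            strand = "+"
        exons_t = tuple(sorted((int(a), int(b)) for a, b in exons))
        tss = exons_t[0][0] if strand == "+" else max(e[1] for e in exons_t)
        return cls(gene_id=gene_id, biotype=biotype, chrom=chrom,
                   strand=strand, tss=tss, exons=exons_t)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return max(e[1] for e in self.exons)


def _read_gtf_genes(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        exons_by_gene.setdefault(gid, []).append((exon.start - 1, exon.end))
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        exons = exons_by_gene.get(gid)
        if not exons:
            warnings.warn(f"gene {gid}: no exon features, skipped", stacklevel=3)
            continue
        biotype = (feat.attributes.get("gene_biotype")
                   or feat.attributes.get("biotype")
                   or ["protein_coding"])[0]
        genes.append(GeneModel.from_exons(
            gene_id=gid, chrom=feat.seqid, strand=feat.strand,
            exons=exons, biotype=biotype,
        ))
    return genes


def _read_bed_genes(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: BED gene table needs >=6 columns"
                )
            chrom, start, end, gene_id, _score, strand = fields[:6]
            biotype = fields[6] if len(fields) > 6 else "protein_coding"
            if strand not in ("+", "-", "."):
                raise ValidationError(
                    f"{path}: line {lineno}: unknown strand {strand!r}"
                )
            genes.append(GeneModel.from_exons(
                gene_id=gene_id, chrom=chrom, strand=strand,
                exons=[(int(start), int(end))], biotype=biotype,
            ))
    return genes


def read_gene_annotation(path: str | Path, dialect: str = "gtf") -> list[GeneModel]:
    """Read gene models from a GTF/GFF (``dialect="gtf"``) or BED6-like table.

    The BED dialect carries one interval per gene with columns
    chrom, start, end, gene_id, score, strand[, biotype].
    """
    if dialect == "gtf":
        return _read_gtf_genes(path)
    if dialect == "bed":
        return _read_bed_genes(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gtf(genes: Iterable[GeneModel], path: str | Path,
              source: str = "epinherit") -> None:
    """Write gene models as GTF2.2 (gene + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for start, end in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Gene sets (GMT dialect)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets; member order is preserved, duplicates dropped."""

    name: str = ""
    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_name: str) -> frozenset[str]:
        return frozenset(self.sets[set_name])


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: set name, description, then members, tab-separated."""
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >=3 fields "
                    "(name, description, members...)"
                )
            set_name = fields[0]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ParseError(
                    f"{path}: line {lineno}: gene set {set_name!r} is empty"
                )
            sets[set_name] = members
    return GeneSetCollection(name=name or str(path), sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_name, members in collection.sets.items():
            fh.write("\t".join([set_name, description, *members]) + "\n")
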