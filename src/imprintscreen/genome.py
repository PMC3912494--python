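"""Genomic annotations, coordinate conventions, and promoter derivation.

All coordinates are internally 0-based half-open ([start, end)), the BED
convention. GTF input (1-based closed) is converted on read. A gene's
transcription start site (TSS) is the strand-aware 5' end: ``interval.start``
on the + strand, ``interval.end - 1`` on the - strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with its genomic extent, strand-aware TSS, and expression flag.

    Expression state is an input annotation (e.g. from prior RNA-seq calls),
    not computed here.
    """

    gene_id: str
    interval: GenomicInterval
    expressed: bool = False

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class PromoterConfig:
    """Putative-promoter window: bases upstream/downstream of the TSS."""

    upstream: int = 5000
    downstream: int = 500

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream and downstream must be >= 0")
        if self.upstream == 0 and self.downstream == 0:
            raise ValueError("promoter window cannot be empty")


@dataclass
class Annotation:
    """Gene models plus CpG islands, chromosome sizes, and haploid chromosomes.

    ``haploid_chroms`` marks chromosomes present in a single copy (e.g. the X
    in a male sample); candidates found there indicate false positives, since
    a one-allele locus cannot show a pooled-allele bivalent signature.
    """

    genes: list[GeneModel] = field(default_factory=list)
    cpg_islands: list[GenomicInterval] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    haploid_chroms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.chrom_lengths:
            for g in self.genes:
                L = self.chrom_lengths.get(g.chrom)
                if L is None:
                    raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
                if g.interval.end > L:
                    raise ValueError(
                        f"gene {g.gene_id} extends past end of {g.chrom} ({L})"
                    )
            for iv in self.cpg_islands:
                L = self.chrom_lengths.get(iv.chrom)
                if L is None:
                    raise ValueError(f"CpG island on unknown chromosome {iv.chrom}")
                if iv.end > L:
                    raise ValueError(f"CpG island {iv} extends past end of {iv.chrom}")
            extra = self.haploid_chroms - set(self.chrom_lengths)
            if extra:
                raise ValueError(f"haploid chromosomes not in genome: {sorted(extra)}")


def derive_promoter(
    gene: GeneModel, cfg: PromoterConfig, chrom_len: int
) -> GenomicInterval:
    """Putative promoter window around the TSS, clipped to the chromosome.

    On the + strand the window is [tss - upstream, tss + downstream); on the
    - strand it is the mirror image [tss - downstream + 1, tss + upstream + 1).
    """
    tss = gene.tss
    if not (0 <= tss < chrom_len):
        raise ValueError(f"gene {gene.gene_id}: TSS {tss} outside chromosome")
    if gene.interval.strand == "-":
        start = tss - cfg.downstream + 1
        end = tss + cfg.upstream + 1
    else:
        start = tss - cfg.upstream
        end = tss + cfg.downstream
    start = max(0, start)
    end = min(chrom_len, end)
    if start >= end:
        raise ValueError(f"gene {gene.gene_id}: promoter window empty after clipping")
    return GenomicInterval(gene.chrom, start, end, gene.interval.strand)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(path: str | Path, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF gene rows or a minimal TSV.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    The TSV format has columns: gene_id, chrom, strand, tss[, expressed]
    (header optional; tss is 0-based). Output is sorted by (chrom, start)
    and gene_id for determinism.
    """
    path = Path(path)
    if format == "gtf":
        genes = _read_gtf(path)
    elif format == "tsv":
        genes = _read_gene_tsv(path)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    seen: dict[str, int] = {}
    for g in genes:
        seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
    dups = [k for k, v in seen.items() if v > 1]
    if dups:
        raise ValueError(f"duplicate gene_id(s): {sorted(dups)[:5]}")
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def _read_gtf(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start_i < 1 or end_i < start_i:
                raise ValueError(f"{path}:{lineno}: invalid GTF coordinates")
            m = _GTF_GENE_ID.search(attrs)
            if not m:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            expressed = 'expressed "1"' in attrs or 'expressed "true"' in attrs
            genes.append(
                GeneModel(
                    gene_id=m.group(1),
                    interval=GenomicInterval(chrom, start_i - 1, end_i, strand),
                    expressed=expressed,
                )
            )
    return genes


def _read_gene_tsv(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "gene_id":
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 TSV columns")
            gene_id, chrom, strand, tss = fields[:4]
            try:
                tss_i = int(tss)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer tss") from None
            expressed = len(fields) > 4 and fields[4] in ("1", "true", "True")
            # a TSV model carries only the TSS; represent the gene as a
            # 1-base interval anchored there (tss == start == end-1 both strands)
            iv = GenomicInterval(chrom, tss_i, tss_i + 1, strand)
            genes.append(GeneModel(gene_id=gene_id, interval=iv, expressed=expressed))
    return genes


def read_intervals(
    path: str | Path,
    format: str = "bed",
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval] | tuple[list[GenomicInterval], list[float]]:
    """Read BED3/BED6 intervals or a bedGraph (intervals + values).

    Returns intervals sorted by (chrom, start, end); logs a warning if the
    file was out of order. bedGraph returns ``(intervals, values)``.
    """
    path = Path(path)
    records: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            minimum = 4 if format == "bedgraph" else 3
            if len(fields) < minimum:
                raise ValueError(f"{path}:{lineno}: expected >={minimum} columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
                if end > chrom_lengths[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: interval past chromosome end"
                    )
            strand = "."
            if format == "bed" and len(fields) >= 6 and fields[5] in STRANDS:
                strand = fields[5]
            value = 0.0
            if format == "bedgraph":
                try:
                    value = float(fields[3])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric value") from None
            records.append((GenomicInterval(chrom, start, end, strand), value))
    keys = [(iv.chrom, iv.start, iv.end) for iv, _ in records]
    if keys != sorted(keys):
        logger.warning("%s: intervals out of order; returning sorted", path)
        records.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    if format == "bedgraph":
        return [r[0] for r in records], [r[1] for r in records]
    return [r[0] for r in records]


def write_intervals(
    path: str | Path,
    intervals: Sequence[GenomicInterval],
    values: Sequence[float] | None = None,
) -> None:
    """Write sorted canonical BED3 (or bedGraph when values are given)."""
    recs = sorted(
        zip(intervals, values if values is not None else [None] * len(intervals)),
        key=lambda r: (r[0].chrom, r[0].start, r[0].end),
    )
    with open(path, "w") as fh:
        for iv, v in recs:
            if v is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v:g}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes
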