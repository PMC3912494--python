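"""Promoter mark profiles and the candidate-imprinted-gene screen.

A candidate imprinted gene is one whose putative promoter is concurrently
marked by significant H3K4me3, H3K9Ac, and H3K9me3 peaks and contains an
annotated CpG island. Because ChIP pools both parental alleles, an imprinted
promoter carries marks of activation (from the expressed allele) and
H3K9me3 (from the silenced allele) at once. A male sample's single X serves
as an internal control: no haploid-chromosome gene can genuinely show the
pooled-allele signature, so candidates there flag false positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genome import Annotation, GeneModel, GenomicInterval, PromoterConfig, derive_promoter
from .intervals import FeatureSet, cooccurs_at, full_overlap_tier

logger = logging.getLogger(__name__)

MARK_K4ME3 = "H3K4me3"
MARK_K9AC = "H3K9Ac"
MARK_K9ME3 = "H3K9me3"
REQUIRED_MARKS = (MARK_K4ME3, MARK_K9AC, MARK_K9ME3)


@dataclass(frozen=True)
class PromoterProfile:
    """Per-gene promoter booleans: the candidate-selection record."""

    gene_id: str
    promoter: GenomicInterval
    has_k4me3: bool
    has_k9ac: bool
    has_k9me3: bool
    has_cpg: bool
    full_overlap: bool
    chrom_class: str  # "autosome" | "haploid"

    def __post_init__(self) -> None:
        if self.full_overlap and not (
            self.has_k4me3 and self.has_k9ac and self.has_k9me3
        ):
            raise ValueError("full_overlap requires all three marks present")

    @property
    def is_candidate(self) -> bool:
        return self.has_k4me3 and self.has_k9ac and self.has_k9me3 and self.has_cpg


@dataclass
class ScreenSummary:
    """Nested filter-layer totals; each layer <= the previous."""

    n_promoters: int
    n_k4me3: int
    n_k4me3_cpg: int
    n_all_marks: int
    n_candidates: int  # all three marks AND CpG island
    n_full_overlap: int
    per_chrom_candidates: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (
            self.n_promoters >= self.n_k4me3 >= self.n_all_marks >= self.n_candidates
            >= self.n_full_overlap
        ) or self.n_k4me3 < self.n_k4me3_cpg:
            raise ValueError("screen layers must be nested and non-increasing")

    def to_json_dict(self) -> dict:
        return {
            "promoters": self.n_promoters,
            "k4me3_marked": self.n_k4me3,
            "k4me3_and_cpg": self.n_k4me3_cpg,
            "all_three_marks": self.n_all_marks,
            "candidates": self.n_candidates,
            "full_overlap_candidates": self.n_full_overlap,
            "per_chrom_candidates": self.per_chrom_candidates,
        }


def profile_promoters(
    ann: Annotation,
    peaksets: Mapping[str, FeatureSet],
    cfg: PromoterConfig | None = None,
) -> list[PromoterProfile]:
    """Build one PromoterProfile per gene from the three mark peak sets."""
    cfg = cfg or PromoterConfig()
    missing = [m for m in REQUIRED_MARKS if m not in peaksets]
    if missing:
        raise ValueError(f"missing required mark(s): {missing}")
    marks = [peaksets[m] for m in REQUIRED_MARKS]
    cpg = FeatureSet("CpG", list(ann.cpg_islands))
    profiles = []
    for gene in ann.genes:
        chrom_len = ann.chrom_lengths.get(gene.chrom)
        if chrom_len is None:
            raise ValueError(f"no chromosome length for {gene.chrom}")
        promoter = derive_promoter(gene, cfg, chrom_len)
        occ = cooccurs_at(promoter, marks)
        all_marks = all(occ.values())
        profiles.append(
            PromoterProfile(
                gene_id=gene.gene_id,
                promoter=promoter,
                has_k4me3=occ[MARK_K4ME3],
                has_k9ac=occ[MARK_K9AC],
                has_k9me3=occ[MARK_K9ME3],
                has_cpg=cpg.overlaps_region(promoter),
                full_overlap=full_overlap_tier(promoter, marks) if all_marks else False,
                chrom_class="haploid" if gene.chrom in ann.haploid_chroms else "autosome",
            )
        )
    return profiles


def select_candidates(
    profiles: Sequence[PromoterProfile],
    force_include: Sequence[str] = (),
) -> list[str]:
    """Genes whose promoters carry all three marks plus a CpG island.

    ``force_include`` adds known-imprinted genes that lack the signature
    (so they still enter downstream SNP screening); they are appended after
    the screened candidates, preserving stable order.
    """
    selected = [p.gene_id for p in profiles if p.is_candidate]
    seen = set(selected)
    known = {p.gene_id for p in profiles}
    for gid in force_include:
        if gid in known and gid not in seen:
            selected.append(gid)
            seen.add(gid)
    return selected


def haploid_control_check(
    candidates: Sequence[str], ann: Annotation, profiles: Sequence[PromoterProfile]
) -> list[str]:
    """Candidates on haploid chromosomes — should be empty in a clean run."""
    if not ann.haploid_chroms:
        logger.warning("no haploid chromosomes declared; control check vacuous")
        return []
    haploid_genes = {p.gene_id for p in profiles if p.chrom_class == "haploid"}
    return [g for g in candidates if g in haploid_genes]


def summarize_screen(
    profiles: Sequence[PromoterProfile],
) -> ScreenSummary:
    per_chrom: dict[str, int] = {}
    for p in profiles:
        if p.is_candidate:
            per_chrom[p.promoter.chrom] = per_chrom.get(p.promoter.chrom, 0) + 1
    return ScreenSummary(
        n_promoters=len(profiles),
        n_k4me3=sum(p.has_k4me3 for p in profiles),
        n_k4me3_cpg=sum(p.has_k4me3 and p.has_cpg for p in profiles),
        n_all_marks=sum(p.has_k4me3 and p.has_k9ac and p.has_k9me3 for p in profiles),
        n_candidates=sum(p.is_candidate for p in profiles),
        n_full_overlap=sum(p.full_overlap and p.has_cpg for p in profiles),
        per_chrom_candidates=per_chrom,
    )


def mark_distribution(
    peaks: FeatureSet, ann: Annotation, cfg: PromoterConfig | None = None
) -> dict[str, float]:
    """Fraction of peaks in promoter / genic / intergenic territory.

    Each peak is assigned to the first matching category in priority order
    promoter > genic > intergenic. Used e.g. to diagnose diffusely
    distributed marks that concentrate in intergenic space.
    """
    if len(peaks) == 0:
        raise ValueError("mark_distribution: empty peak set")
    cfg = cfg or PromoterConfig()
    promoters = FeatureSet(
        "promoters",
        [
            derive_promoter(g, cfg, ann.chrom_lengths[g.chrom])
            for g in ann.genes
        ],
    )
    genic = FeatureSet("genic", [g.interval for g in ann.genes])
    counts = {"promoter": 0, "genic": 0, "intergenic": 0}
    for pk in peaks.intervals:
        if promoters.overlaps_region(pk):
            counts["promoter"] += 1
        elif genic.overlaps_region(pk):
            counts["genic"] += 1
        else:
            counts["intergenic"] += 1
    n = len(peaks)
    return {k: v / n for k, v in counts.items()}
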