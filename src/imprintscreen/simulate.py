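"""Seed-reproducible synthetic genome and pipeline inputs with planted truth.

The generator emulates the study design the screen targets: a small male
genome (several autosomes plus one haploid X), genes of five classes
(expressed biallelic, repressed, imprinted maternal/paternal, allele-biased),
ChIP coverage whose promoter enrichment reflects class — marks of activation
at expressed promoters, H3K9me3 at repressed promoters, and all three marks
concurrently (at half the homozygous dose each) at imprinted and
allele-biased promoters because ChIP pools the two parental alleles —
heterozygous 3'-UTR SNPs segregating in reciprocal crosses between two
stocks, allele-count noise, and bisulfite clones with configurable per-CpG
methylation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .allelic import CrossFamily, SNPSite
from .genome import Annotation, GeneModel, GenomicInterval, PromoterConfig, derive_promoter
from .methylation import BisulfiteAmplicon
from .peaks import CoverageTrack

CLASSES = (
    "expressed_biallelic",
    "repressed",
    "imprinted_maternal",
    "imprinted_paternal",
    "allele_biased",
)
EXPRESSED_CLASSES = {
    "expressed_biallelic",
    "imprinted_maternal",
    "imprinted_paternal",
    "allele_biased",
}


@dataclass
class TruthConfig:
    """Study-design parameters for the synthetic genome.

    Defaults give ~500 genes across 4 autosomes and one haploid X, with
    10 imprinted (5 maternal- + 5 paternal-expressed) and 10 allele-biased
    genes, a planted expressed-allele fraction of 0.9, and ChIP enrichment
    folds strong enough to mimic well-behaved marks.
    """

    n_autosomes: int = 4
    genes_per_chrom: int = 100
    gene_length: int = 2000
    gene_spacing: int = 20000
    haploid_chrom: str = "chrX"
    class_proportions: dict = field(
        default_factory=lambda: {
            "expressed_biallelic": 0.66,
            "repressed": 0.30,
            "imprinted_maternal": 0.01,
            "imprinted_paternal": 0.01,
            "allele_biased": 0.02,
        }
    )
    expressed_fraction: float = 0.9  # planted expressed-allele fraction
    chip_background: float = 10.0  # Poisson rate per bin
    chip_fold: float = 10.0  # homozygous enrichment fold over background
    bin_width: int = 50
    gdna_depth: int = 500
    cdna_depth: int = 500
    rho: float = 0.01  # beta-binomial overdispersion of allele counts
    pyro_replicates: int = 2
    pyro_sd: float = 1.0  # percent; keeps |r1 - r2| <= 3 in >= 95% of draws
    offspring_per_family: int = 2
    uninformative_rate: float = 0.0  # per-gene chance a cross is uninformative
    clones_per_amplicon: int = 16
    cpgs_per_amplicon: int = 16
    conversion_rate: float = 0.995
    methylation_probs: tuple[float, float] = (0.05, 0.05)  # per-allele
    cpg_island_prob: dict = field(
        default_factory=lambda: {
            "expressed_biallelic": 0.5,
            "repressed": 0.3,
            "imprinted_maternal": 1.0,
            "imprinted_paternal": 1.0,
            "allele_biased": 1.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.chip_fold < 1:
            raise ValueError("enrichment fold must be >= 1")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_autosomes)] + [self.haploid_chrom]

    @property
    def chrom_length(self) -> int:
        return self.genes_per_chrom * self.gene_spacing + 2 * self.gene_spacing


@dataclass
class TruthSet:
    """The planted ground truth all pipeline inputs derive from."""

    annotation: Annotation
    gene_class: dict  # gene_id -> class label
    snp_alleles: dict  # gene_id -> (stock_A_base, stock_B_base)
    snp_positions: dict  # gene_id -> (chrom, pos)
    families: list  # two CrossFamily, one per reciprocal direction
    parent_genotypes: dict  # (sample, gene_id) -> tuple of 2 bases
    uninformative: dict  # gene_id -> set of family_ids with uninformative SNP
    config: TruthConfig = None

    def serialize(self) -> str:
        """Deterministic JSON serialization (reproducibility checks)."""
        payload = {
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": g.interval.start,
                    "end": g.interval.end,
                    "strand": g.interval.strand,
                    "expressed": g.expressed,
                    "class": self.gene_class[g.gene_id],
                }
                for g in self.annotation.genes
            ],
            "cpg_islands": [
                [iv.chrom, iv.start, iv.end] for iv in self.annotation.cpg_islands
            ],
            "chrom_lengths": dict(sorted(self.annotation.chrom_lengths.items())),
            "haploid": sorted(self.annotation.haploid_chroms),
            "snps": {
                g: {
                    "alleles": list(self.snp_alleles[g]),
                    "pos": list(self.snp_positions[g]),
                }
                for g in sorted(self.snp_alleles)
            },
            "parent_genotypes": {
                f"{s}|{g}": list(gt)
                for (s, g), gt in sorted(self.parent_genotypes.items())
            },
            "uninformative": {g: sorted(v) for g, v in sorted(self.uninformative.items())},
        }
        return json.dumps(payload, sort_keys=True)


def _allocate_classes(cfg: TruthConfig, n_genes: int) -> list[str]:
    """Class labels with counts within +/-1 of proportions x gene count."""
    exact = {c: cfg.class_proportions.get(c, 0.0) * n_genes for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in exact.items()}
    remainder = n_genes - sum(counts.values())
    # largest-remainder apportionment
    order = sorted(CLASSES, key=lambda c: exact[c] - counts[c], reverse=True)
    for c in order[:remainder]:
        counts[c] += 1
    labels = []
    for c in CLASSES:
        labels.extend([c] * counts[c])
    return labels


def build_truth(cfg: TruthConfig | None = None) -> TruthSet:
    """Lay out the genome, assign classes, plant SNPs and pedigree.

    Deterministic for a fixed seed. Imprinted and allele-biased genes are
    never placed on the haploid chromosome. Every imprinted/allele-biased
    gene carries a 3'-UTR SNP informative in both cross directions, except
    for a configurable fraction made uninformative in one direction (to
    emulate genes whose transmission cannot be tracked).
    """
    cfg = cfg or TruthConfig()
    rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chrom_names
    chrom_lengths = {c: cfg.chrom_length for c in chroms}
    n_genes = len(chroms) * cfg.genes_per_chrom
    if cfg.gene_spacing < cfg.gene_length + 6000:
        raise ValueError("genes do not fit: spacing too small for promoters")

    labels = _allocate_classes(cfg, n_genes)
    # indices of gene slots; haploid slots are the last genes_per_chrom
    n_autosomal = cfg.n_autosomes * cfg.genes_per_chrom
    special = [i for i, lab in enumerate(labels) if lab in (
        "imprinted_maternal", "imprinted_paternal", "allele_biased")]
    # shuffle labels, then swap any special class off the haploid chromosome
    perm = rng.permutation(n_genes)
    assigned = [labels[perm[i]] for i in range(n_genes)]
    autosomal_plain = [
        i for i in range(n_autosomal)
        if assigned[i] in ("expressed_biallelic", "repressed")
    ]
    rng.shuffle(autosomal_plain)
    swap_iter = iter(autosomal_plain)
    for i in range(n_autosomal, n_genes):
        if assigned[i] in ("imprinted_maternal", "imprinted_paternal", "allele_biased"):
            j = next(swap_iter)
            assigned[i], assigned[j] = assigned[j], assigned[i]

    genes: list[GeneModel] = []
    islands: list[GenomicInterval] = []
    gene_class: dict[str, str] = {}
    snp_alleles: dict[str, tuple[str, str]] = {}
    snp_positions: dict[str, tuple[str, int]] = {}
    strands = ["+", "-"]
    base_pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    idx = 0
    for chrom in chroms:
        for k in range(cfg.genes_per_chrom):
            gid = f"gene_{chrom}_{k:04d}"
            cls = assigned[idx]
            strand = strands[k % 2]
            tss = cfg.gene_spacing + k * cfg.gene_spacing
            if strand == "+":
                iv = GenomicInterval(chrom, tss, tss + cfg.gene_length, "+")
            else:
                iv = GenomicInterval(chrom, tss - cfg.gene_length + 1, tss + 1, "-")
            genes.append(
                GeneModel(gene_id=gid, interval=iv, expressed=cls in EXPRESSED_CLASSES)
            )
            gene_class[gid] = cls
            if rng.random() < cfg.cpg_island_prob.get(cls, 0.0):
                islands.append(GenomicInterval(chrom, max(0, tss - 500), tss + 500))
            # 3'-UTR SNP near the gene's 3' end
            utr = iv.end - 100 if strand == "+" else iv.start + 100
            snp_positions[gid] = (chrom, utr)
            snp_alleles[gid] = base_pairs[int(rng.integers(len(base_pairs)))]
            idx += 1

    annotation = Annotation(
        genes=genes,
        cpg_islands=sorted(islands, key=lambda iv: (iv.chrom, iv.start)),
        chrom_lengths=chrom_lengths,
        haploid_chroms={cfg.haploid_chrom},
    )

    families = [
        CrossFamily("fam1", "AxB", mother="A_dam1", father="B_sire1",
                    offspring=tuple(f"F1_AxB_{i + 1}" for i in range(cfg.offspring_per_family))),
        CrossFamily("fam2", "BxA", mother="B_dam2", father="A_sire2",
                    offspring=tuple(f"F1_BxA_{i + 1}" for i in range(cfg.offspring_per_family))),
    ]
    parent_genotypes: dict[tuple[str, str], tuple[str, str]] = {}
    uninformative: dict[str, set] = {}
    for gid in gene_class:
        a, b = snp_alleles[gid]
        # stock-A animals homozygous for allele a, stock-B for allele b
        stock_of = {"A_dam1": a, "B_sire1": b, "B_dam2": b, "A_sire2": a}
        drop: set[str] = set()
        for fam in families:
            if rng.random() < cfg.uninformative_rate:
                drop.add(fam.family_id)
        for fam in families:
            for parent in (fam.mother, fam.father):
                if fam.family_id in drop:
                    # both parents het: the F1's alleles cannot be assigned
                    parent_genotypes[(parent, gid)] = (a, b)
                else:
                    base = stock_of[parent]
                    parent_genotypes[(parent, gid)] = (base, base)
        uninformative[gid] = drop

    return TruthSet(
        annotation=annotation,
        gene_class=gene_class,
        snp_alleles=snp_alleles,
        snp_positions=snp_positions,
        families=families,
        parent_genotypes=parent_genotypes,
        uninformative=uninformative,
        config=cfg,
    )


# marks enriched per class: (mark -> dose), dose 1 = both alleles, 0.5 = one
_CLASS_MARKS = {
    "expressed_biallelic": {"H3K4me3": 1.0, "H3K9Ac": 1.0},
    "repressed": {"H3K9me3": 1.0},
    "imprinted_maternal": {"H3K4me3": 0.5, "H3K9Ac": 0.5, "H3K9me3": 0.5},
    "imprinted_paternal": {"H3K4me3": 0.5, "H3K9Ac": 0.5, "H3K9me3": 0.5},
    "allele_biased": {"H3K4me3": 0.5, "H3K9Ac": 0.5, "H3K9me3": 0.5},
}


def simulate_chip(
    truth: TruthSet, cfg: TruthConfig | None = None
) -> tuple[dict[str, CoverageTrack], CoverageTrack]:
    """Per-mark treatment tracks plus one input track.

    Poisson background everywhere; over each promoter window the treatment
    rate is background * (1 + dose * fold), where dose is 1 for a mark
    carried by both alleles and 0.5 for the one-allele contribution at
    imprinted/allele-biased promoters (and everywhere on the haploid
    chromosome, which has a single allele genome-wide).
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    ann = truth.annotation
    bw = cfg.bin_width
    n_bins = {c: int(np.ceil(L / bw)) for c, L in ann.chrom_lengths.items()}
    pcfg = PromoterConfig()

    rate = {
        mark: {c: np.full(n, cfg.chip_background, dtype=np.float64)
               for c, n in n_bins.items()}
        for mark in ("H3K4me3", "H3K9Ac", "H3K9me3")
    }
    for gene in ann.genes:
        cls = truth.gene_class[gene.gene_id]
        doses = _CLASS_MARKS[cls]
        haploid = gene.chrom in ann.haploid_chroms
        promoter = derive_promoter(gene, pcfg, ann.chrom_lengths[gene.chrom])
        b0, b1 = promoter.start // bw, (promoter.end - 1) // bw + 1
        for mark, dose in doses.items():
            d = dose * 0.5 if haploid else dose
            rate[mark][gene.chrom][b0:b1] += cfg.chip_background * cfg.chip_fold * d

    treatments = {
        mark: CoverageTrack(
            counts={c: rng.poisson(r) for c, r in sorted(chrom_rates.items())},
            bin_width=bw,
        )
        for mark, chrom_rates in rate.items()
    }
    control = CoverageTrack(
        counts={
            c: rng.poisson(cfg.chip_background, size=n)
            for c, n in sorted(n_bins.items())
        },
        bin_width=bw,
    )
    return treatments, control


@dataclass
class AllelicData:
    """Simulated gDNA/cDNA pileups and pyrosequencing replicates."""

    sites: dict  # gene_id -> SNPSite with per-sample gDNA counts
    cdna_counts: dict  # gene_id -> {animal: (count_allele1, count_allele2)}
    pyro: dict  # gene_id -> {animal: tuple of replicate maternal %}
    maternal_stock: dict  # (gene_id, animal) -> "A" | "B"


def _beta_binomial(rng, n: int, mu: float, rho: float) -> tuple[int, float]:
    """Draw (count, underlying p) from a beta-binomial with mean mu."""
    if rho <= 0:
        return int(rng.binomial(n, mu)), mu
    conc = (1 - rho) / rho
    p = float(rng.beta(mu * conc, (1 - mu) * conc))
    return int(rng.binomial(n, p)), p


def simulate_allelic_reads(
    truth: TruthSet, cfg: TruthConfig | None = None
) -> AllelicData:
    """Simulate gDNA and cDNA allele counts and pyrosequencing replicates.

    gDNA at het sites is Binomial(depth, 0.5). cDNA maternal-allele counts
    are beta-binomial with mean equal to the planted expressed-allele
    fraction for imprinted genes (in the planted direction), the stock-A
    tracking fraction for allele-biased genes, and 0.5 for biallelic genes.
    Each animal also gets pyrosequencing replicates whose mean matches its
    underlying allele fraction.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 2)
    sites: dict[str, SNPSite] = {}
    cdna: dict[str, dict[str, tuple[int, int]]] = {}
    pyro: dict[str, dict[str, tuple[float, ...]]] = {}
    maternal_stock: dict[tuple[str, str], str] = {}

    for gene in truth.annotation.genes:
        gid = gene.gene_id
        cls = truth.gene_class[gid]
        chrom, pos = truth.snp_positions[gid]
        a1, a2 = truth.snp_alleles[gid]  # a1 = stock-A allele
        counts: dict[str, tuple[int, int]] = {}
        for fam in truth.families:
            for parent in (fam.mother, fam.father):
                gt = truth.parent_genotypes[(parent, gid)]
                n1 = sum(1 for x in gt if x == a1)
                c1 = int(rng.binomial(cfg.gdna_depth, n1 / 2)) if 0 < n1 < 2 else (
                    cfg.gdna_depth if n1 == 2 else 0
                )
                counts[parent] = (c1, cfg.gdna_depth - c1)
        cdna[gid] = {}
        pyro[gid] = {}
        for fam in truth.families:
            informative = fam.family_id not in truth.uninformative[gid]
            # F1s are het a1/a2 (parents are opposite-stock homozygotes when
            # informative; uninformative families still produce het F1s)
            mat_allele_is_a = (fam.cross_type == "AxB")
            for animal in fam.offspring:
                c1 = int(rng.binomial(cfg.gdna_depth, 0.5))
                counts[animal] = (c1, cfg.gdna_depth - c1)
                maternal_stock[(gid, animal)] = "A" if mat_allele_is_a else "B"
                if not gene.expressed:
                    continue
                if cls == "imprinted_maternal":
                    mu_mat = cfg.expressed_fraction
                elif cls == "imprinted_paternal":
                    mu_mat = 1 - cfg.expressed_fraction
                elif cls == "allele_biased":
                    # stock-A allele favoured regardless of parent
                    mu_mat = cfg.expressed_fraction if mat_allele_is_a else 1 - cfg.expressed_fraction
                else:
                    mu_mat = 0.5
                mat_count, p_mat = _beta_binomial(rng, cfg.cdna_depth, mu_mat, cfg.rho)
                # counts stored in (allele1, allele2) = (stock A, stock B) order
                if mat_allele_is_a:
                    cdna[gid][animal] = (mat_count, cfg.cdna_depth - mat_count)
                else:
                    cdna[gid][animal] = (cfg.cdna_depth - mat_count, mat_count)
                reps = tuple(
                    float(np.clip(100 * p_mat + rng.normal(0, cfg.pyro_sd), 0, 100))
                    for _ in range(cfg.pyro_replicates)
                )
                pyro[gid][animal] = reps
        sites[gid] = SNPSite(chrom=chrom, pos=pos, alleles=(a1, a2), counts=counts)
    return AllelicData(
        sites=sites, cdna_counts=cdna, pyro=pyro, maternal_stock=maternal_stock
    )


def overlap_fixture(
    n_query: int, n_overlapping: int, chrom: str = "chr1", spacing: int = 100
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Two interval lists where exactly ``n_overlapping`` of the ``n_query``
    query intervals overlap a subject interval (for overlap-rate checks).

    Query intervals tile the chromosome at ``spacing``; the first
    ``n_overlapping`` get a half-offset subject partner, the rest none.
    """
    if not (0 <= n_overlapping <= n_query):
        raise ValueError("need 0 <= n_overlapping <= n_query")
    width = spacing // 2
    queries = [
        GenomicInterval(chrom, i * spacing, i * spacing + width)
        for i in range(n_query)
    ]
    subjects = [
        GenomicInterval(chrom, i * spacing + width // 2, i * spacing + width // 2 + width)
        for i in range(n_overlapping)
    ]
    return queries, subjects


def _amplicon_reference(rng, n_cpgs: int) -> tuple[str, tuple[int, ...], int]:
    """A reference with evenly spaced CpGs, scattered non-CpG Cs, and a SNP slot."""
    length = 20 + 10 * n_cpgs
    bases = []
    for i in range(length):
        bases.append(str(rng.choice(["A", "T", "G", "C"], p=[0.3, 0.3, 0.2, 0.2])))
    # remove accidental CpGs
    for i in range(length - 1):
        if bases[i] == "C" and bases[i + 1] == "G":
            bases[i + 1] = "A"
    snp_offset = 5
    bases[snp_offset] = "A"  # alleles (A, G): never a cytosine, no conversion clash
    if snp_offset > 0 and bases[snp_offset - 1] == "C":
        bases[snp_offset - 1] = "T"
    cpg_offsets = tuple(15 + 10 * j for j in range(n_cpgs))
    for off in cpg_offsets:
        bases[off], bases[off + 1] = "C", "G"
        if bases[off - 1] == "C":
            bases[off - 1] = "T"
    # fix any CpG re-introduced after a G substitution
    for i in range(length - 1):
        if bases[i] == "C" and bases[i + 1] == "G" and i not in cpg_offsets:
            bases[i] = "T"
    return "".join(bases), cpg_offsets, snp_offset


def simulate_bisulfite(
    truth: TruthSet,
    cfg: TruthConfig | None = None,
    gene_ids: list[str] | None = None,
    methylation_probs: tuple[float, float] | None = None,
) -> dict[str, tuple[BisulfiteAmplicon, list[str], list[str]]]:
    """Bisulfite clone sequences per amplicon.

    Each amplicon gets ``clones_per_amplicon`` clones, split evenly between
    the two SNP alleles; each CpG is methylated with the planted per-allele
    probability, and non-CpG Cs convert at ``conversion_rate``.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 3)
    probs = methylation_probs or cfg.methylation_probs
    if gene_ids is None:
        gene_ids = [
            g for g, c in sorted(truth.gene_class.items())
            if c in ("imprinted_maternal", "imprinted_paternal", "allele_biased")
        ]
    out = {}
    for gid in gene_ids:
        ref, cpg_offsets, snp_offset = _amplicon_reference(rng, cfg.cpgs_per_amplicon)
        chrom, pos = truth.snp_positions[gid]
        amplicon = BisulfiteAmplicon(
            region=GenomicInterval(chrom, pos, pos + len(ref)),
            reference=ref,
            cpg_offsets=cpg_offsets,
            snp_offset=snp_offset,
            snp_alleles=("A", "G"),
        )
        non_cpg = amplicon.non_cpg_c_offsets
        seqs, names = [], []
        for ci in range(cfg.clones_per_amplicon):
            allele_idx = ci % 2
            allele = ("A", "G")[allele_idx]
            chars = list(ref)
            chars[snp_offset] = allele
            for off in cpg_offsets:
                methylated = rng.random() < probs[allele_idx]
                chars[off] = "C" if methylated else "T"
            for off in non_cpg:
                if rng.random() < cfg.conversion_rate:
                    chars[off] = "T"
            seqs.append("".join(chars))
            names.append(f"{gid}_clone{ci + 1}_{allele}")
        out[gid] = (amplicon, seqs, names)
    return out
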