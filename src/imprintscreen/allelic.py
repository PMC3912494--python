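"""Allele-specific expression analysis from reciprocal crosses.

Reciprocal crosses (stock A dam x stock B sire, and the reverse) separate
parent-of-origin effects from allele-identity effects: an imprinted gene
tracks the parent (always the maternal — or always the paternal — allele is
expressed, in both cross directions), whereas allele-biased expression tracks
the physical allele (the stock-A allele is favoured no matter which parent
transmitted it). A gene informative in only one cross direction cannot
distinguish the two and is called undetermined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from scipy import stats


class Genotype(Enum):
    HOM1 = "hom1"
    HOM2 = "hom2"
    HET = "het"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class SNPConfig:
    """Thresholds for calling genotypes from allele counts."""

    min_coverage: int = 20
    min_minor_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not (0 < self.min_minor_fraction <= 0.5):
            raise ValueError("min_minor_fraction must be in (0, 0.5]")


@dataclass
class SNPSite:
    """A biallelic site with per-sample allele counts."""

    chrom: str
    pos: int  # 0-based
    alleles: tuple[str, str]
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or self.alleles[0] == self.alleles[1]:
            raise ValueError("exactly two distinct alleles required")
        for sample, (c1, c2) in self.counts.items():
            if c1 < 0 or c2 < 0:
                raise ValueError(f"negative allele count for {sample}")


@dataclass(frozen=True)
class CrossFamily:
    """One family of a reciprocal-cross pair."""

    family_id: str
    cross_type: str  # "AxB" (stock-A dam) or "BxA"
    mother: str
    father: str
    offspring: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.cross_type not in ("AxB", "BxA"):
            raise ValueError("cross_type must be 'AxB' or 'BxA'")


def call_het_snps(
    counts: tuple[int, int], cfg: SNPConfig | None = None
) -> Genotype:
    """Genotype from a (allele1, allele2) count pair.

    Sites below the coverage floor are not called; a heterozygote requires
    both allele fractions at or above the minor-fraction threshold.
    """
    cfg = cfg or SNPConfig()
    c1, c2 = counts
    total = c1 + c2
    if total < cfg.min_coverage:
        return Genotype.NO_CALL
    f1, f2 = c1 / total, c2 / total
    if f1 >= cfg.min_minor_fraction and f2 >= cfg.min_minor_fraction:
        return Genotype.HET
    return Genotype.HOM1 if c1 >= c2 else Genotype.HOM2


class TrackableResult(Enum):
    UNINFORMATIVE = "uninformative"
    INCONSISTENT = "inconsistent"


def trackable(
    f1: tuple[str, str], mother: tuple[str, str], father: tuple[str, str]
) -> dict[str, str] | TrackableResult:
    """Assign a het F1's alleles to parents, if unambiguous.

    Returns ``{"maternal": base, "paternal": base}`` when the assignment is
    forced by the parental genotypes, ``UNINFORMATIVE`` when either parental
    origin is ambiguous (e.g. both parents het for the same alleles), and
    ``INCONSISTENT`` when the F1 genotype is Mendelian-impossible.
    """
    a, b = f1
    if a == b:
        return TrackableResult.UNINFORMATIVE  # F1 must be heterozygous
    m, f = set(mother), set(father)
    if (a not in m and a not in f) or (b not in m and b not in f):
        return TrackableResult.INCONSISTENT
    # enumerate consistent (maternal, paternal) transmissions
    assignments = [
        (x, y)
        for x, y in ((a, b), (b, a))
        if x in m and y in f
    ]
    if not assignments:
        return TrackableResult.INCONSISTENT
    if len(assignments) > 1:
        return TrackableResult.UNINFORMATIVE
    mat, pat = assignments[0]
    return {"maternal": mat, "paternal": pat}


@dataclass
class AlleleMeasurement:
    """Replicate-averaged maternal-allele expression for one animal.

    ``maternal_fraction`` is the percent of transcripts from the maternal
    allele (mean of replicates); ``maternal_stock`` records which stock the
    maternal allele came from, letting the classifier separate
    parent-tracking from allele-tracking bias.
    """

    gene_id: str
    animal: str
    cross_type: str
    maternal_fraction: float
    replicates: tuple[float, ...]
    discordance_flag: bool = False
    maternal_stock: str = "A"

    def __post_init__(self) -> None:
        if not (0 <= self.maternal_fraction <= 100):
            raise ValueError("maternal_fraction must be a percentage in [0, 100]")


def allele_fraction(
    replicates: Sequence[float],
    tolerance: float = 3.0,
    gene_id: str = "",
    animal: str = "",
    cross_type: str = "AxB",
    maternal_stock: str = "A",
) -> AlleleMeasurement:
    """Average replicate allele percentages into one measurement.

    The discordance flag is raised when the replicate spread (max - min)
    exceeds the tolerance (percent).
    """
    if len(replicates) == 0:
        raise ValueError("at least one replicate required")
    reps = tuple(float(r) for r in replicates)
    mean = sum(reps) / len(reps)
    return AlleleMeasurement(
        gene_id=gene_id,
        animal=animal,
        cross_type=cross_type,
        maternal_fraction=mean,
        replicates=reps,
        discordance_flag=(max(reps) - min(reps)) > tolerance,
        maternal_stock=maternal_stock,
    )


class Call(Enum):
    IMPRINTED_MATERNAL = "imprinted_maternal_expressed"
    IMPRINTED_PATERNAL = "imprinted_paternal_expressed"
    ALLELE_BIASED = "allele_biased"
    BIALLELIC = "biallelic"
    UNDETERMINED = "undetermined"


@dataclass
class ImprintCall:
    gene_id: str
    call: Call
    n_informative: dict[str, int] = field(default_factory=dict)  # per cross_type
    leakage: float | None = None  # mean repressed-allele %, imprinted genes only
    reason: str = ""


def binomial_bias_p(maternal_count: int, total: int) -> float:
    """Two-sided exact binomial p for deviation from a 50/50 allele ratio."""
    return float(stats.binomtest(maternal_count, total, 0.5).pvalue)


def classify_gene(
    gene_id: str,
    measurements: Sequence[AlleleMeasurement],
    bias_threshold: float = 70.0,
) -> ImprintCall:
    """Classify a gene as imprinted / allele-biased / biallelic / undetermined.

    Per animal: maternal-biased if maternal_fraction >= bias_threshold,
    paternal-biased if <= 100 - bias_threshold, else unbiased. The gene is
    imprinted (maternal- or paternal-expressed) when every informative animal
    is biased toward the same parent and both reciprocal cross directions are
    informative; allele-biased when the bias instead consistently tracks one
    stock's allele across both directions; biallelic when all animals are
    unbiased; undetermined when only one direction is informative or the
    patterns conflict. Leakage is the mean repressed-allele percentage over
    informative animals of an imprinted gene.
    """
    if not measurements:
        return ImprintCall(gene_id, Call.UNDETERMINED, reason="no informative measurements")
    per_cross: dict[str, int] = {}
    for m in measurements:
        per_cross[m.cross_type] = per_cross.get(m.cross_type, 0) + 1
    both_crosses = len(per_cross) >= 2

    lo = 100.0 - bias_threshold
    maternal_biased = [m.maternal_fraction >= bias_threshold for m in measurements]
    paternal_biased = [m.maternal_fraction <= lo for m in measurements]
    unbiased = [not a and not b for a, b in zip(maternal_biased, paternal_biased)]

    def stock_a_fraction(m: AlleleMeasurement) -> float:
        return m.maternal_fraction if m.maternal_stock == "A" else 100 - m.maternal_fraction

    stock_a_biased = [stock_a_fraction(m) >= bias_threshold for m in measurements]
    stock_b_biased = [stock_a_fraction(m) <= lo for m in measurements]

    if all(unbiased):
        return ImprintCall(gene_id, Call.BIALLELIC, n_informative=per_cross)
    if not both_crosses:
        return ImprintCall(
            gene_id,
            Call.UNDETERMINED,
            n_informative=per_cross,
            reason="informative in a single cross direction only",
        )
    if all(maternal_biased):
        leak = sum(100 - m.maternal_fraction for m in measurements) / len(measurements)
        return ImprintCall(
            gene_id, Call.IMPRINTED_MATERNAL, n_informative=per_cross, leakage=leak
        )
    if all(paternal_biased):
        leak = sum(m.maternal_fraction for m in measurements) / len(measurements)
        return ImprintCall(
            gene_id, Call.IMPRINTED_PATERNAL, n_informative=per_cross, leakage=leak
        )
    if all(stock_a_biased) or all(stock_b_biased):
        return ImprintCall(gene_id, Call.ALLELE_BIASED, n_informative=per_cross)
    return ImprintCall(
        gene_id,
        Call.UNDETERMINED,
        n_informative=per_cross,
        reason="conflicting bias patterns across animals",
    )
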