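"""Bisulfite clone sequencing: methylation matrices, summaries, DMR tests.

Bisulfite treatment deaminates unmethylated cytosines to uracil (sequenced
as T) while methylated CpG cytosines stay C. A clone sequence aligned to the
untreated reference therefore reads out per-CpG methylation, and the non-CpG
cytosines double as a conversion-efficiency control: a clone retaining too
many non-CpG Cs underwent incomplete conversion and is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import GenomicInterval

METHYLATED = 1
UNMETHYLATED = 0
MISSING = -1


@dataclass
class BisulfiteAmplicon:
    """A bisulfite PCR amplicon: reference sequence, CpG sites, optional SNP.

    ``cpg_offsets`` are 0-based offsets (within the reference) of the C of
    each CpG dinucleotide. ``snp_offset``/``snp_alleles``, when present,
    phase clones to alleles.
    """

    region: GenomicInterval
    reference: str
    cpg_offsets: tuple[int, ...]
    snp_offset: int | None = None
    snp_alleles: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        for off in self.cpg_offsets:
            if not (0 <= off < len(self.reference) - 1):
                raise ValueError(f"CpG offset {off} outside reference")
            if self.reference[off : off + 2] != "CG":
                raise ValueError(f"offset {off} is not a CpG in the reference")

    @property
    def non_cpg_c_offsets(self) -> list[int]:
        cpg = set(self.cpg_offsets)
        return [
            i for i, base in enumerate(self.reference) if base == "C" and i not in cpg
        ]


@dataclass
class MethylationMatrix:
    """Clones x CpG-site calls, plus per-clone QC and allele labels."""

    calls: np.ndarray  # (n_clones, n_cpgs), values in {1, 0, -1}
    conversion: np.ndarray  # per-clone non-CpG C->T fraction
    clone_names: list[str]
    allele_labels: list[str | None]
    excluded: np.ndarray  # per-clone bool, failed conversion QC
    cpg_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.calls.shape[1] != len(self.cpg_offsets):
            raise ValueError("matrix columns must equal number of CpG sites")
        if ((self.conversion < 0) | (self.conversion > 1)).any():
            raise ValueError("conversion rates must lie in [0, 1]")

    @property
    def passing(self) -> np.ndarray:
        return ~self.excluded


def tabulate_clones(
    amplicon: BisulfiteAmplicon,
    clone_seqs: Sequence[str],
    clone_names: Sequence[str] | None = None,
    min_conversion: float = 0.98,
) -> MethylationMatrix:
    """Call per-CpG methylation for each aligned clone sequence.

    At each CpG cytosine: C = methylated, T = unmethylated, anything else
    missing. Per-clone conversion efficiency is the fraction of non-CpG
    reference Cs read as T; clones below ``min_conversion`` are flagged
    excluded (they still appear in the matrix). Allele labels come from the
    phasing SNP base when the amplicon defines one.
    """
    if not amplicon.cpg_offsets:
        raise ValueError("amplicon has no CpG sites")
    names = (
        list(clone_names)
        if clone_names is not None
        else [f"clone_{i + 1}" for i in range(len(clone_seqs))]
    )
    n = len(clone_seqs)
    calls = np.full((n, len(amplicon.cpg_offsets)), MISSING, dtype=np.int8)
    conversion = np.zeros(n)
    alleles: list[str | None] = [None] * n
    non_cpg = amplicon.non_cpg_c_offsets
    for ci, seq in enumerate(clone_seqs):
        seq = seq.upper()
        if len(seq) != len(amplicon.reference):
            raise ValueError(
                f"clone {names[ci]}: length {len(seq)} != reference "
                f"{len(amplicon.reference)}"
            )
        for j, off in enumerate(amplicon.cpg_offsets):
            base = seq[off]
            if base == "C":
                calls[ci, j] = METHYLATED
            elif base == "T":
                calls[ci, j] = UNMETHYLATED
        if non_cpg:
            converted = sum(1 for off in non_cpg if seq[off] == "T")
            conversion[ci] = converted / len(non_cpg)
        else:
            conversion[ci] = 1.0
        if amplicon.snp_offset is not None and amplicon.snp_alleles is not None:
            base = seq[amplicon.snp_offset]
            if base in amplicon.snp_alleles:
                alleles[ci] = base
    return MethylationMatrix(
        calls=calls,
        conversion=conversion,
        clone_names=names,
        allele_labels=alleles,
        excluded=conversion < min_conversion,
        cpg_offsets=tuple(amplicon.cpg_offsets),
    )


def per_cpg_fraction(matrix: MethylationMatrix) -> np.ndarray:
    """Methylated fraction per CpG over passing clones (NaN if no calls)."""
    calls = matrix.calls[matrix.passing]
    with np.errstate(invalid="ignore"):
        meth = (calls == METHYLATED).sum(axis=0).astype(float)
        known = (calls != MISSING).sum(axis=0)
        return np.where(known > 0, meth / np.maximum(known, 1), np.nan)


def summarize_region(
    matrix: MethylationMatrix, hypo: float = 0.2, hyper: float = 0.8
) -> dict:
    """Per-CpG methylated fractions and an overall region status.

    Status is hypomethylated when the mean per-CpG fraction is below ``hypo``,
    hypermethylated above ``hyper``, intermediate otherwise.
    """
    if not matrix.passing.any():
        raise ValueError("all clones excluded by conversion QC")
    fractions = per_cpg_fraction(matrix)
    mean = float(np.nanmean(fractions))
    if mean < hypo:
        status = "hypomethylated"
    elif mean > hyper:
        status = "hypermethylated"
    else:
        status = "intermediate"
    return {
        "per_cpg_fraction": fractions,
        "mean_fraction": mean,
        "status": status,
        "n_clones": int(matrix.passing.sum()),
    }


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def allele_dmr_test(
    matrix: MethylationMatrix,
    alpha: float = 0.01,
    min_diff: float = 0.5,
    min_clones_per_allele: int = 5,
) -> dict:
    """Test allele-partitioned differential methylation across CpGs.

    Each CpG gets a one-sided hypergeometric (exact 2x2) p-value in the
    direction of the observed between-allele difference, BH-adjusted across
    CpGs. The region is a DMR when more than half the CpGs pass the adjusted
    alpha AND the mean methylated-fraction difference between alleles is at
    least ``min_diff``. Verdict is ``not_assessable`` without a phasing SNP
    or with too few clones per allele.
    """
    labels = [
        lab if ok else None
        for lab, ok in zip(matrix.allele_labels, matrix.passing)
    ]
    groups = sorted({lab for lab in labels if lab is not None})
    if len(groups) != 2:
        return {"verdict": "not_assessable", "reason": "no phasing SNP or single allele"}
    g1 = np.array([lab == groups[0] for lab in labels])
    g2 = np.array([lab == groups[1] for lab in labels])
    if g1.sum() < min_clones_per_allele or g2.sum() < min_clones_per_allele:
        return {
            "verdict": "not_assessable",
            "reason": f"fewer than {min_clones_per_allele} clones for an allele",
        }
    n_cpg = matrix.calls.shape[1]
    pvals = np.ones(n_cpg)
    diffs = np.zeros(n_cpg)
    for j in range(n_cpg):
        col = matrix.calls[:, j]
        m1 = int(((col == METHYLATED) & g1).sum())
        u1 = int(((col == UNMETHYLATED) & g1).sum())
        m2 = int(((col == METHYLATED) & g2).sum())
        u2 = int(((col == UNMETHYLATED) & g2).sum())
        n1, n2 = m1 + u1, m2 + u2
        if n1 == 0 or n2 == 0:
            pvals[j] = 1.0
            continue
        f1, f2 = m1 / n1, m2 / n2
        diffs[j] = f1 - f2
        M, K, N = n1 + n2, m1 + m2, n1
        # one-sided tail toward the observed direction of difference
        if f1 >= f2:
            pvals[j] = float(stats.hypergeom.sf(m1 - 1, M, K, N))
        else:
            pvals[j] = float(stats.hypergeom.cdf(m1, M, K, N))
    adjusted = _bh_adjust(pvals)
    frac_significant = float((adjusted <= alpha).mean())
    mean_diff = float(np.abs(diffs).mean())
    verdict = (
        "dmr_positive"
        if frac_significant > 0.5 and mean_diff >= min_diff
        else "dmr_negative"
    )
    return {
        "verdict": verdict,
        "alleles": groups,
        "p_values": pvals,
        "p_adjusted": adjusted,
        "fraction_difference": diffs,
        "mean_abs_difference": mean_diff,
        "fraction_significant_cpgs": frac_significant,
    }


def read_clones_fasta(path) -> tuple[list[str], list[str]]:
    """Clone sequences from FASTA; returns (names, sequences)."""
    from Bio import SeqIO

    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    return names, seqs


def write_clones_fasta(path, names: Sequence[str], seqs: Sequence[str]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(s), id=n, description="") for n, s in zip(names, seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def plot_lollipop(matrix: MethylationMatrix, path) -> None:
    """Lollipop plot: one row per passing clone, one circle per CpG;
    filled = methylated, open = unmethylated, absent = missing."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = np.flatnonzero(matrix.passing)
    fig, ax = plt.subplots(
        figsize=(max(3, 0.3 * matrix.calls.shape[1]), max(2, 0.3 * len(rows)))
    )
    for y, ci in enumerate(rows):
        for x in range(matrix.calls.shape[1]):
            call = matrix.calls[ci, x]
            if call == MISSING:
                continue
            filled = call == METHYLATED
            ax.scatter(
                x, y, s=60,
                facecolors="black" if filled else "white",
                edgecolors="black", zorder=3,
            )
        ax.plot(
            [-0.5, matrix.calls.shape[1] - 0.5], [y, y],
            color="grey", lw=0.8, zorder=1,
        )
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([matrix.clone_names[ci] for ci in rows], fontsize=6)
    ax.set_xticks(range(matrix.calls.shape[1]))
    ax.set_xlabel("CpG site")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def matrix_to_sequences(
    amplicon: BisulfiteAmplicon, matrix: MethylationMatrix
) -> list[str]:
    """Regenerate bisulfite-converted clone sequences from matrix calls.

    Assumes full conversion at non-CpG Cs; only defined for clones without
    missing CpG calls (used for round-trip checks).
    """
    seqs = []
    non_cpg = set(amplicon.non_cpg_c_offsets)
    for ci in range(matrix.calls.shape[0]):
        chars = list(amplicon.reference)
        for off in non_cpg:
            chars[off] = "T"
        for j, off in enumerate(matrix.cpg_offsets):
            call = matrix.calls[ci, j]
            if call == MISSING:
                raise ValueError("cannot regenerate a clone with missing calls")
            chars[off] = "C" if call == METHYLATED else "T"
        if (
            amplicon.snp_offset is not None
            and matrix.allele_labels[ci] is not None
        ):
            chars[amplicon.snp_offset] = matrix.allele_labels[ci]
        seqs.append("".join(chars))
    return seqs
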