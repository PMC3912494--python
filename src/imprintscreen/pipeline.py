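"""End-to-end orchestration: simulate -> call peaks -> screen -> classify.

Library functions behind the command-line entry points. Every stage's
thresholds live in :class:`RunConfig`; outputs are deterministic for a fixed
seed (sorted tables, no timestamps in data files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .allelic import (
    AlleleMeasurement,
    Call,
    Genotype,
    ImprintCall,
    SNPConfig,
    TrackableResult,
    allele_fraction,
    call_het_snps,
    classify_gene,
    trackable,
)
from .genome import Annotation, PromoterConfig
from .intervals import FeatureSet, venn_counts
from .peaks import CoverageTrack, Peak, PeakCallerConfig, call_peaks
from .screen import (
    REQUIRED_MARKS,
    PromoterProfile,
    haploid_control_check,
    profile_promoters,
    select_candidates,
    summarize_screen,
)
from .simulate import AllelicData, TruthConfig, TruthSet, build_truth, simulate_allelic_reads, simulate_chip

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and inputs for a pipeline run.

    Defaults are the screen's canonical values: peak significance p <= 1e-5,
    20x SNP coverage, promoter window 5000/500, replicate tolerance 3%.
    """

    promoter: PromoterConfig = field(default_factory=PromoterConfig)
    peaks: PeakCallerConfig = field(default_factory=PeakCallerConfig)
    snp: SNPConfig = field(default_factory=SNPConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    bias_threshold: float = 70.0
    replicate_tolerance: float = 3.0
    force_include: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.truth, dict):
            self.truth = TruthConfig(**self.truth)
        if self.seed != self.truth.seed:
            self.truth.seed = self.seed


@dataclass
class ScreenResult:
    profiles: list[PromoterProfile]
    candidates: list[str]
    summary: object
    venn: object
    haploid_violations: list[str]
    peaksets: dict


def run_screen(
    cfg: RunConfig,
    ann: Annotation,
    treatments: dict[str, CoverageTrack] | None = None,
    control: CoverageTrack | None = None,
    peaksets: dict[str, FeatureSet] | None = None,
) -> ScreenResult:
    """Call peaks (when coverage is supplied), profile promoters, select
    candidates, and run the haploid-chromosome internal control."""
    if peaksets is None:
        if treatments is None or control is None:
            raise ValueError("need either peak sets or coverage tracks")
        missing = [m for m in REQUIRED_MARKS if m not in treatments]
        if missing:
            raise ValueError(f"missing coverage for mark(s): {missing}")
        peaksets = {
            mark: FeatureSet(
                mark, [p.interval for p in call_peaks(treatments[mark], control, cfg.peaks)]
            )
            for mark in REQUIRED_MARKS
        }
    profiles = profile_promoters(ann, peaksets, cfg.promoter)
    candidates = select_candidates(profiles, force_include=cfg.force_include)
    violations = haploid_control_check(candidates, ann, profiles)
    return ScreenResult(
        profiles=profiles,
        candidates=candidates,
        summary=summarize_screen(profiles),
        venn=venn_counts([peaksets[m] for m in REQUIRED_MARKS]),
        haploid_violations=violations,
        peaksets=peaksets,
    )


def _genotype_bases(gt: Genotype, alleles: tuple[str, str]) -> tuple[str, str] | None:
    if gt == Genotype.HET:
        return alleles
    if gt == Genotype.HOM1:
        return (alleles[0], alleles[0])
    if gt == Genotype.HOM2:
        return (alleles[1], alleles[1])
    return None


def classify_candidates(
    cfg: RunConfig,
    candidates: list[str],
    data: AllelicData,
    families: list,
) -> dict[str, ImprintCall]:
    """Classify each candidate from SNP pileups, pedigree, and replicates.

    For every F1 animal with a trackable het SNP, the maternal-allele
    percentage comes from replicate-averaged pyrosequencing values when
    available, otherwise from the cDNA allele counts. Genes without any
    trackable SNP are undetermined ("no trackable SNP"); Mendelian
    inconsistencies abort that gene's classification with an error entry.
    """
    calls: dict[str, ImprintCall] = {}
    for gid in candidates:
        site = data.sites.get(gid)
        if site is None:
            calls[gid] = ImprintCall(gid, Call.UNDETERMINED, reason="no SNP assayed")
            continue
        measurements: list[AlleleMeasurement] = []
        inconsistent = False
        for fam in families:
            mother_gt = _genotype_bases(
                call_het_snps(site.counts.get(fam.mother, (0, 0)), cfg.snp), site.alleles
            )
            father_gt = _genotype_bases(
                call_het_snps(site.counts.get(fam.father, (0, 0)), cfg.snp), site.alleles
            )
            if mother_gt is None or father_gt is None:
                continue
            for animal in fam.offspring:
                f1_gt = _genotype_bases(
                    call_het_snps(site.counts.get(animal, (0, 0)), cfg.snp), site.alleles
                )
                if f1_gt is None or f1_gt[0] == f1_gt[1]:
                    continue
                assignment = trackable(f1_gt, mother_gt, father_gt)
                if assignment is TrackableResult.INCONSISTENT:
                    inconsistent = True
                    break
                if assignment is TrackableResult.UNINFORMATIVE:
                    continue
                maternal = assignment["maternal"]
                maternal_stock = "A" if maternal == site.alleles[0] else "B"
                reps = data.pyro.get(gid, {}).get(animal)
                if reps is None:
                    counts = data.cdna_counts.get(gid, {}).get(animal)
                    if counts is None:
                        continue
                    mat_count = counts[0] if maternal == site.alleles[0] else counts[1]
                    total = counts[0] + counts[1]
                    if total == 0:
                        continue
                    reps = (100.0 * mat_count / total,)
                measurements.append(
                    allele_fraction(
                        reps,
                        tolerance=cfg.replicate_tolerance,
                        gene_id=gid,
                        animal=animal,
                        cross_type=fam.cross_type,
                        maternal_stock=maternal_stock,
                    )
                )
            if inconsistent:
                break
        if inconsistent:
            calls[gid] = ImprintCall(
                gid, Call.UNDETERMINED, reason="Mendelian inconsistency at assayed SNP"
            )
            continue
        if not measurements:
            calls[gid] = ImprintCall(gid, Call.UNDETERMINED, reason="no trackable SNP")
            continue
        calls[gid] = classify_gene(gid, measurements, bias_threshold=cfg.bias_threshold)
    return calls


@dataclass
class PipelineResult:
    truth: TruthSet
    screen: ScreenResult
    calls: dict
    methylation: dict = field(default_factory=dict)


def summarize_candidate_methylation(cfg: RunConfig, truth: TruthSet,
                                    candidates: list[str]) -> dict:
    """Bisulfite summaries for candidate-gene promoter amplicons."""
    from .methylation import allele_dmr_test, summarize_region, tabulate_clones
    from .simulate import simulate_bisulfite

    have_amplicons = [g for g in candidates if g in truth.gene_class]
    sims = simulate_bisulfite(truth, cfg.truth, gene_ids=have_amplicons)
    out = {}
    for gid, (amp, seqs, names) in sims.items():
        matrix = tabulate_clones(amp, seqs, names)
        summary = summarize_region(matrix)
        dmr = allele_dmr_test(matrix)
        out[gid] = {
            "status": summary["status"],
            "mean_fraction": round(summary["mean_fraction"], 4),
            "n_clones": summary["n_clones"],
            "dmr_verdict": dmr["verdict"],
        }
    return out


def run_all(cfg: RunConfig) -> PipelineResult:
    """Simulate a truth set and run the full screen + classification."""
    truth = build_truth(cfg.truth)
    treatments, control = simulate_chip(truth, cfg.truth)
    screen = run_screen(cfg, truth.annotation, treatments, control)
    data = simulate_allelic_reads(truth, cfg.truth)
    calls = classify_candidates(cfg, screen.candidates, data, truth.families)
    methylation = summarize_candidate_methylation(cfg, truth, screen.candidates)
    return PipelineResult(truth=truth, screen=screen, calls=calls,
                          methylation=methylation)


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------


def write_candidates_tsv(path, profiles: list[PromoterProfile], candidates: list[str]):
    chosen = set(candidates)
    rows = [
        {
            "gene_id": p.gene_id,
            "chrom": p.promoter.chrom,
            "promoter_start": p.promoter.start,
            "promoter_end": p.promoter.end,
            "H3K4me3": int(p.has_k4me3),
            "H3K9Ac": int(p.has_k9ac),
            "H3K9me3": int(p.has_k9me3),
            "CpG_island": int(p.has_cpg),
            "full_overlap": int(p.full_overlap),
        }
        for p in profiles
        if p.gene_id in chosen
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_imprint_calls_tsv(path, calls: dict[str, ImprintCall]):
    rows = [
        {
            "gene_id": gid,
            "call": c.call.value,
            "leakage_pct": "" if c.leakage is None else f"{c.leakage:.2f}",
            "informative_AxB": c.n_informative.get("AxB", 0),
            "informative_BxA": c.n_informative.get("BxA", 0),
            "reason": c.reason,
        }
        for gid, c in sorted(calls.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_reports(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_candidates_tsv(outdir / "candidates.tsv", result.screen.profiles, result.screen.candidates)
    write_imprint_calls_tsv(outdir / "imprint_calls.tsv", result.calls)
    with open(outdir / "screen_summary.json", "w") as fh:
        json.dump(result.screen.summary.to_json_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "venn.json", "w") as fh:
        json.dump(result.screen.venn.to_json_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "methylation_summary.json", "w") as fh:
        json.dump(result.methylation, fh, indent=2, sort_keys=True)
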