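# Methods

## Coordinate conventions and promoters

All coordinates are 0-based half-open internally; GTF (1-based closed) is
converted on read, BED/bedGraph pass through natively. Two features overlap
iff they share at least one base (`max(starts) < min(ends)`), strand always
ignored — histone peaks are unstranded. Overlap counts are per source
interval, never per merged region, so a peak overlapping two promoters
counts once on the peak side and twice on the promoter side.

A gene's putative promoter spans `upstream` (default 5,000) bases 5′ and
`downstream` (default 500) bases 3′ of the annotated TSS, strand-aware and
clipped to the chromosome. One promoter per gene, anchored at the gene's
annotated 5′ end; per-transcript promoters are out of scope, but the window
is configurable. Expression state is an input boolean per gene, not
computed.

### The "full overlap" tier

Peak callers never produce identical boundaries across marks, so "100%
overlap" is defined as the strictest criterion that does not require it:
per mark, select the peak with the longest intersection with the promoter;
the tier passes iff the shortest selected peak is fully contained in every
other selected peak (equivalently, the common intersection length equals the
shortest peak's length). This is invariant to mark ordering.

## Peak caller

A Poisson local-background scan stands in for a full ChIP-seq caller, which
would model fragment shift and duplicates upstream of the binned inputs this
pipeline consumes. Per bin (default 50 b): the expected count is
`λ = max(genome-wide rate, 5 kb rate, 10 kb rate)` from the input control,
scaled by the treatment/control depth ratio and floored at `min_lambda`
(default 0.1/bin) so empty control regions cannot produce p = 0 artifacts.
Significance is the Poisson upper tail `P(X ≥ k)` via the regularised
incomplete gamma function (stable to ~1e-300; deeper tails underflow to 0,
far below any usable threshold). Bins at p ≤ 10⁻⁵ are merged across gaps
≤ 100 b; merged peaks shorter than 200 b are dropped. The per-bin test is
discrete and therefore conservative: under the null the significant-window
rate is below the nominal threshold (tested against a 10× bound over 10⁶
windows).

## Imprinting classification

- **Genotypes from counts.** A site needs ≥ 20 reads to be called;
  heterozygous requires both allele fractions ≥ 0.2, otherwise homozygous
  for the majority allele. This simple fraction rule replaces
  genotype-likelihood machinery because only the coverage floor and a
  het/hom decision matter here.
- **Trackability.** A het F1's alleles are assigned to parents by
  enumerating consistent transmissions; the assignment must be unique
  (requires at least one informative homozygous parent). F1 alleles absent
  from both parents are a Mendelian inconsistency, which aborts that gene's
  classification rather than being silently dropped.
- **Replicate averaging.** Assay replicates are averaged arithmetically; a
  spread (max − min) above 3 percentage points raises a discordance flag.
- **Calls.** Per animal, maternal-biased means maternal fraction ≥ 70%,
  paternal-biased ≤ 30%. The 70% default sits well below the weakest bias a
  genuinely imprinted gene tends to show (high 70s) and well above binomial
  noise around 50% at the depths used; it is configurable, and when raw
  read counts rather than assay percentages are the input an exact binomial
  test against 0.5 (`binomial_bias_p`) is available as an additional guard.
  A gene is imprinted only when *every* informative animal is biased toward
  the same parent **and** both reciprocal directions are informative;
  allele-biased when the bias instead consistently tracks one stock's
  allele; biallelic when no animal is biased; undetermined otherwise
  (single-direction informativeness, conflicting patterns, or no trackable
  SNP). Leakage is the mean repressed-allele percentage over informative
  animals. The classifier is invariant to relabelling the cross directions
  together with the stock annotations.

## Methylation

Clone sequences are assumed gaplessly aligned to the amplicon reference. At
each CpG cytosine, C reads as methylated and T as unmethylated; anything
else is missing. Conversion efficiency is the fraction of non-CpG reference
cytosines read as T; clones below 0.98 are flagged and excluded from
summaries (a standard QC convention, exposed in config). Region status uses
the mean per-CpG methylated fraction: < 0.2 hypomethylated, > 0.8
hypermethylated, else intermediate.

The allele DMR test requires a phasing SNP and ≥ 5 passing clones per
allele (otherwise `not_assessable`, the honest outcome when phasing is
impossible). Each CpG gets a one-sided hypergeometric tail probability in
the direction of the observed between-allele difference — for a fully split
8 vs 8 table this is `1/C(16,8) ≈ 7.8e-5` — BH-corrected across CpGs. The
region is a DMR when more than half the CpGs pass adjusted α = 0.01 *and*
the mean fraction difference is ≥ 0.5. The thresholds make an otherwise
qualitative judgment reproducible; all are config fields.

## Synthetic data: what it emulates, and what it does not

`build_truth` lays out 4 autosomes plus one haploid X (100 genes each,
20 kb TSS spacing, 2 kb genes, alternating strands) and assigns classes by
largest-remainder apportionment of the configured proportions (defaults:
66% expressed biallelic, 30% repressed, 1% + 1% imprinted maternal/paternal,
2% allele-biased → 10 imprinted and 10 allele-biased among 500 genes).
Special classes never land on the X: class labels drawn there are swapped
with randomly chosen plain autosomal slots. CpG islands (±500 b of the TSS)
appear with per-class probability (1.0 for imprinted/allele-biased, 0.5
expressed, 0.3 repressed).

- **ChIP coverage** is Poisson per 50 b bin: background rate 10/bin
  everywhere; over promoter windows the treatment rate is
  `background · (1 + dose · fold)` with fold 10 and dose 1 for marks carried
  by both alleles, 0.5 for the one-allele contribution at
  imprinted/allele-biased promoters — the quantitative signature the screen
  exploits. Haploid-chromosome promoters get dose 0.5 for their single
  allele and are always MOA-only or MOR-only, which makes the X control
  check meaningful. The input track is pure background.
- **Crosses.** Two families, one per reciprocal direction, two offspring
  each. Parents are opposite-stock homozygotes at each gene's 3′-UTR SNP, so
  every F1 is het and trackable; a configurable `uninformative_rate` makes a
  family's parents both het instead, reproducing genes whose transmission
  cannot be tracked (default 0).
- **Allele counts.** gDNA at het sites is Binomial(500, 0.5). cDNA maternal
  counts are beta-binomial (ρ = 0.01 overdispersion, modelling biological +
  technical variation) with mean 0.9 for imprinted genes in the planted
  direction, 0.9 toward the stock-A allele for allele-biased genes, and 0.5
  for biallelic genes. Pyrosequencing replicates (2/animal, sd 1%) are
  centred on the animal's underlying fraction, keeping replicate spread
  ≤ 3% in ≥ 95% of draws. Exact-binomial tail bounds (e.g. 0.5 ± 0.07 at
  depth 500) hold with ρ = 0, which the config supports.
- **Bisulfite clones.** 16 clones per amplicon split between alleles via an
  A/G phasing SNP, 16 CpGs methylated Bernoulli per planted per-allele
  probability (default 0.05/0.05 — hypomethylated, no DMR), non-CpG
  conversion rate 0.995.

Everything is driven by `numpy.random.default_rng(seed)` with fixed
sub-stream offsets per stage; identical config + seed reproduces every
output byte-identically.

What the generator does *not* emulate: read-level artefacts (mapping bias,
duplicates, GC), realistic peak-width and fragment-size distributions,
annotation error (mis-placed TSSs), imprinted-gene clustering under shared
control regions, and tissue-specific or partial imprinting. Passing tests
therefore demonstrate that the decision rules are implemented correctly and
recover truth under idealized-but-noisy conditions, not that the screen's
sensitivity on real genomes matches these rates.

## Problem sizes

The default synthetic genome (~10 Mb, 500 genes, ~41 k bins × 4 tracks per
chromosome set) runs the full pipeline in under a second; the acceptance
script's largest computations are the 52,511-interval overlap fixture and
200 seeded DMR replicates, a few seconds in total. These sizes were chosen
so the screen's behaviour (recall, false-positive structure, calibration
bands) is measurable with comfortable statistical margins while the suite
stays quick to iterate on.

## Known limitations

- The peak caller's per-bin test ignores correlation between adjacent bins;
  merged-peak `min_p` is a summary, not a region-level p-value, and no
  FDR/q-value is computed (the screen uses a fixed p threshold by design).
- `allele_biased` vs `imprinted` separation needs both cross directions; at
  one informative animal per direction, a single aberrant animal flips the
  gene to `undetermined` rather than being outvoted.
- The DMR test treats clones as independent; PCR duplicates among clones
  would inflate significance.
- TSV gene models carry only the TSS, so `mark_distribution`'s genic
  category degenerates to the TSS base for such inputs; use GTF when gene
  bodies matter.
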