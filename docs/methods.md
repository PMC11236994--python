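# Methods

This note documents the models, parameter choices and numerical
conventions behind `egranule`, and what the synthetic-data conditions do
and do not establish about real libraries.

## The generative model for 22G libraries

A toy genome is a single random chromosome with non-overlapping,
single-exon genes placed sequentially in a seeded random order with
≥ 50 nt intergenic gaps (so every antisense read assigns to exactly one
annotated locus). Germline coding genes carry a hidden truth class —
E (E-granule-dependent siRNAs), M (Mutator-dependent), UP (siRNAs
amplified upon E-granule loss) or NEUTRAL — partitioned by exact largest
remainder from configurable fractions (default 30:30:15:45 of 120 genes),
and a baseline synthesis rate drawn from Gamma(2, 1) + 0.2. UP-class
genes have their wild-type rate scaled by 0.1: the up-regulated set in
this biology has near-zero wild-type signal (*sid-1*/*rde-11*-like), and
keeping its library share small also prevents its mutant amplification
from distorting the compositional (per-million) normalization of every
other gene.

Reads are drawn antisense to coding transcripts from a per-gene,
per-region rate model. Each gene's emission mass splits 80/20 between a
5′ region and a 3′-terminal region (the 20% tail is the proxy for "the
last exon"; the paper-level boundary is gene-specific and unknowable
here). Genotypes act as multipliers on that mass:

| genotype      | E 5′ (δ₅) | E 3′ (δ₃) | M (δ_M) | UP (δ_up) |
|---------------|-----------|-----------|---------|-----------|
| WT            | 1         | 1         | 1       | 1         |
| egc1 / elli1  | 0.1       | 1         | 1       | 8         |
| ego1          | 0.1       | 0.1       | 1       | 1         |
| mut16         | 1         | 1         | 0.05    | 0.05      |
| doubles       | product of the two parents (multiplicative composition) |

δ₅ = 0.1 is the positional-depletion condition the acceptance checks
prescribe; δ_M = 0.05 encodes essentially complete M-class ablation;
δ_up = 8 is a conservative class-wide amplification (individual genes in
the source biology rise > 10×); mut-16 suppresses the UP class because
those siRNAs are Mutator-derived, which is also what makes the
amplification vanish in the doubles (8 × 0.05 = 0.4 < 2).

Within a gene, the 5′/3′ split is applied to the **read-start space**
(first 80% of valid start positions vs the rest), not to raw transcript
coordinates. With region mass spread over transcript length instead, the
length-truncated 3′ start range would concentrate its 20% mass on fewer
start positions and produce a ~2× 3′-coverage excess in wild type; the
start-space convention makes wild-type per-base coverage uniform (up to
an unavoidable ~21 nt span ramp at both gene ends) while leaving per-gene
and per-region expected masses exactly as tabulated above.

Read lengths follow a configurable distribution over 18–26 nt peaked at
22 (P(22) = 0.6). A 5′ G is imposed with probability 0.9 by
*conditioning the template start on a C at the pairing position* rather
than by mutating the read — every simulated read therefore remains an
exact antisense substring of its template and maps perfectly. 5% of each
library is sense rRNA fragments, present specifically to exercise the
rRNA-subtraction normalization. The 3′ adapter (the DNA sequence of the
ligated adaptor, TCGTATGCCGTCTTCTGCTTG) is appended on FASTQ export and
removed again by the cleaning stage.

Deliberately unmodeled (and therefore untested by these conditions):
sequencing errors and quality values, splicing, multi-isoform loci, SNPs,
UMI structure, ligation biases, and any capture bias among 5′-phosphate
species. Passing tests show the analysis logic is correct under
error-free, single-isoform, compositionally simple libraries — not that
the thresholds are optimal for real data.

## Quantification

Cleaning locates the longest prefix of the 3′ adapter (≥ 8 nt) in each
read and truncates there; reads without a hit are dropped when
`discard_untrimmed` (a trailing 5′-primer remnant, if configured, is also
removed). Survivors are length-filtered: 17–30 nt for quantification,
18–26 nt for metagene work.

Mapping is full-length exact matching against both strands of every
annotated transcript via a 12-mer seed-and-verify index — a deliberate,
reproducible stand-in for a short-read aligner that is feasible because
simulated reads are error-free; mismatch tolerance is out of scope. A
read hitting *n* loci contributes weight 1/*n* at each (deterministic,
unlike single-best random reporting; a brute-force substring scan is kept
as the test oracle). The transcript offset of a hit follows the
5′-most-base convention; for an antisense read that is the *rightmost*
base of the aligned span.

Two denominators are tallied: total mapped reads minus sense-rRNA reads
(quantification RPM — degradation fragments of abundant structural RNAs
must not inflate the denominator), and 18–26 nt reads with no hit on a
structural biotype (rRNA/tRNA/snRNA/snoRNA/ncRNA) for the metagene
scale. Counting sums **antisense** weights per gene; sense hits never
count. The default restricts counting to relaxed 22G reads (21–23 nt,
5′ G); whether non-G or all 17–30 nt reads should count is genuinely
ambiguous, so both modes are exposed (`only_22g`) and the relaxed default
is documented here rather than asserted as the only reading. miRNA/21U
loci are flagged excluded and soma genes soma-specific; class calls never
include them. Per-base antisense coverage (full aligned span, weighted,
18–26 nt reads) is accumulated in transcript coordinates, so minus-strand
genes are automatically reported 5′→3′; a 5′-end-only coverage mode is
not provided because window fold changes are span-scale invariant.

## Class definitions

A gene is *depleted* in a mutant when wild-type RPM ≥ 10, the gene is
eligible (not excluded/soma), and (mutant + ε)/(WT + ε) ≤ 0.5 with
ε = 0.1 RPM. The pseudocount is negligible for any gene passing the
10 RPM floor but keeps fold changes defined at zero; ε = 0 is available
for exactness tests. *Up* contrasts use the same machinery with the
abundance floor applied to the mutant table instead — the up-set's
wild-type signal is near zero, so a wild-type floor would empty it; this
floor choice is interpretive and flagged as such. EGC-1/ELLI-1 targets
are the intersection over two independently simulated alleles; E class =
union of the two target sets, M class = mut-16 targets, UP class = union
of the up contrasts.

Recovery metrics compare called sets against the **generative
expectation**: the genes whose expected compositional fold change
(ratio of rate shares between genotypes) crosses the twofold cutoff.
This matters because libraries are per-million: the M class is expected
to contain the UP genes (their siRNAs are Mutator-derived), and neutral
genes sit slightly above 1 in mutants that lose total siRNA mass.

The mRNA DE filter is a plain 2-fold criterion on library-size-normalized
replicate means with a minimum-abundance floor (5 normalized counts) and
pseudocount 0.5 — intentionally not a dispersion-model DE method, since
the procedure being reproduced is a fold-change filter. ΔΔCt averages
technical replicates per biological replicate, references each sample's
ΔCt to the control sample's mean ΔCt, and reports 2^−ΔΔCt per biological
replicate with mean ± SD.

## Metagene profiles and positional bias

Gene bodies are rescaled to 100 bins (contiguous near-equal base
intervals, remainder bases assigned to the leading bins — deterministic
and well-defined for any length ≥ 100 nt); the bin value is mean
per-base coverage, and the metaprofile is the unweighted mean across
genes (a per-gene-normalized mode is available when expression weighting
is unwanted; the upstream binning/weighting recipe is not fully
specified anywhere, so both are kept and the raw mean is the default).

Positional bias contrasts window sums over the first 80% of bins (5′)
and the last 20% (3′): fc₅ ≤ 0.5 with fc₃ ≥ 0.75 is
`five_prime_depleted`; both ≤ 0.5 `uniform_depleted`; both ≥ 0.75
`unchanged`; anything else `other`. The 0.5 echoes the study's twofold
criterion; 0.75 is this package's retention threshold and is
configurable. A gene is only *callable* when each wild-type window holds
≥ 25 read-equivalents (window coverage / 22): below that, a twofold
window call is Poisson-dominated and any label would be noise;
uncallable genes are reported as such and excluded from labeled
fractions.

## Imaging

Pearson colocalization is the plain correlation over ROI pixels with no
intensity thresholding (the simplest reading of an ROI-based Coloc
workflow; Costes-style thresholding is out of scope), and raises rather
than returning a value when a channel has zero variance in the ROI.
Focus detection is fixed-value or Otsu thresholding plus 4-connected
components with a minimum area (default 4 px). Contact between two foci
is minimum pixel-to-pixel distance ≤ 1 px — the closest discrete reading
of "no empty space observable between two foci"; both the connectivity
and the tolerance are configurable, and the foci simulator computes its
ground-truth contact graph with the *same* boundary-distance contract
from centers and radii.

The arrangement taxonomy anchors each granule at its largest P focus:
one E in contact with P and no E–Z contact → `EP_only`; that E also
touching a Z → `EPZ`; ≥ 2 E on one P → `multiE_P` (the Z condition seen
in real multi-E granules is a property of the generator layouts, not a
classifier requirement); otherwise `other`. Z foci touching nothing are
ignored — the taxonomy is defined relative to the P anchor.

Synthetic foci render as flat-topped radial profiles
I·exp(−(d/r)⁴), so thresholding at 0.35·I recovers a disc of
≈ 1.01 r and segmented contact agrees with analytic truth. Cohorts
allocate category counts by largest remainder (67/101/42 for weights
0.32/0.48/0.20 at n = 210) in a seeded random order with random granule
orientations: a fixed-size observed cohort has a fixed composition, and
the recovery checks then measure re-classification fidelity rather than
multinomial resampling noise.

## Pipeline, determinism and problem sizes

One user-facing seed is fanned out to per-stage streams by hashing stage
labels (CRC32) into child seeds (< 2³¹), so any stage can be reproduced
in isolation. The demo panel — 120 germline genes, 7 genotypes, two
alleles each for *egc-1*/*elli-1* (9 libraries), 2×10⁵ reads per
library — was sized so that a median gene's 3′ window holds enough
wild-type reads (~300) for stable twofold window calls while a full run
stays under a minute on one CPU; the persisted `report.json` excludes
wall-clock time so reruns are byte-identical. The report audits itself:
E class must equal the recomputed target-set union and all overlap
statistics must satisfy inclusion–exclusion exactly, else the run fails.

## Known limitations

Exact matching cannot model mismatch-tolerant alignment or sequencing
error; the 80/20 region split is a fixed-fraction proxy for a
gene-specific exon boundary; the mRNA module has no dispersion-model DE;
imaging is strictly 2-D single-plane with no deconvolution, sub-pixel
localization or cross-talk correction; and the toy genome's gene count
and compositional simplicity mean that absolute thresholds (10 RPM
floor, 25-read callability) should be re-derived before use on real
libraries.
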