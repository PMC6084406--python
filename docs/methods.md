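# Methods

This note documents the models and procedures implemented in `chipstarr`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); 1-based
inclusive dialects (e.g. the UCSC RepeatMasker table with a
`one_based=True` flag) are converted at the I/O boundary. Book-ended
intervals (end == start) do not overlap but are merged by the merge
operations, matching common merge-tool defaults.

## Region scaffold

Peaks are fixed to an assay-specific width around the summit — 500 bp for
transcription-factor ChIP, 1000 bp for histone marks — because TF binding
is point-like while histone domains are broad. A summit offset of −1
(MACS2's "no point source") maps to the interval midpoint. At the left
chromosome edge the fixed window is shifted right to preserve its width;
at a known right edge it is truncated (chromosome sizes are an optional
input). Peaks overlapping a blacklist by ≥ 1 bp are removed entirely, not
trimmed.

The pooled fixed-width peaks are merged and each merged block wider than
1000 bp is halved recursively. Halving is applied at uniform depth: the
smallest k with ceil(w/2^k) ≤ 1000 determines 2^k pieces, the left part of
each split receiving floor(w/2). This makes piece widths within a block
differ by at most 1 bp and makes the operation idempotent. Whether widths
are fixed before or after merging is exposed (`fix_widths`); fixing first
is the default, matching the order of the processing steps.

## RPP quantification

The plasmid universe of a library is defined by its DNA sample: every
distinct (chrom, start, end) with at least one DNA read. RNA fragments
contribute only to the plasmid with *identical* coordinates; near-misses
are tallied as orphans and reported, never assigned. This exact-matching
rule is the core of the assay's per-plasmid resolution.

Each library's DNA sample and all RNA samples derived from it are
normalized jointly by median-of-ratios size factors:
s_j = median_i( c_ij / g_i ) over plasmids i positive in every sample,
where g_i is the row geometric mean. Factors are rescaled to product 1 so a
single-sample normalization is exactly the identity. If no plasmid is
positive everywhere (very sparse data) the geometric mean falls back to the
positive entries of each row and the median runs over positive ratios only.
Different libraries are never normalized together; cross-library
comparability comes only through the RPP ratio itself.

RPP per replicate is rna_norm / dna_norm with no pseudocount — the
denominator is positive by construction because plasmids are DNA-defined.
The plasmid-level activity is the mean over all RNA replicates of the
library (an RNA count of zero in a transfected replicate is a measurement
of zero, not missing data); replicate RPPs of the same plasmid position
from different libraries are pooled before averaging. Region-level activity
is the maximum plasmid-level mean RPP over the plasmids overlapping the
region by ≥ 1 bp; the maximizing plasmid is recorded for provenance, with
coordinate order breaking ties.

## Activity threshold

Regions are ranked by log2(RPP+1) and the threshold θ is derived from a
changepoint in that curve, back-transformed to RPP scale; classification is
inclusive (RPP ≥ θ is active).

Segmentation minimizes twice the Gaussian negative log-likelihood with
segment-specific mean and variance plus a penalty β per changepoint
(default "MBIC-like" 3·log n; "bic" and numeric values accepted). Four
solvers share the cost function: `exact_dp` (exact O(n²) dynamic program,
the oracle), `pelt` (exact with pruning), `binseg` (greedy), and `amoc`
(best single split). Minimum segment length is 2. Segment variances are
floored at 1% of the overall curve variance: without a floor the
mean+variance likelihood diverges on near-duplicate point pairs and every
solver overfits them.

**Why AMOC is the pipeline default.** A ranked curve of continuous values
is a vector of order statistics. Sorting makes any segment's variance drop
roughly four-fold when it is halved, so a multi-changepoint fit keeps
subdividing until segments reach about penalty size — the right-most
changepoint then tracks the top of the curve rather than the boundary
between the inactive mass and the active tail, and a threshold taken at
the highest-valued changepoint ends up calling only a handful of top
regions active. The single best mean+variance split (at most one
changepoint — also the default mode of standard changepoint software) is
scale-robust and lands at the inactive/active boundary whenever the curve
has one. With a single changepoint, "highest-valued changepoint" and
"largest cost reduction" coincide. The multi-changepoint solvers remain
available for general segmentation and for oracle cross-checks.

For curves beyond `max_points` (default 50,000) an even rank-subsample is
segmented instead; θ is a value, not an index, so subsampling changes the
threshold only within the low-density gap between modes. A constant curve
yields no changepoints and the threshold step reports the absence instead
of inventing a cutoff; the pipeline then leaves regions classified only as
measured/unmeasured.

## Core/extended modules and gene assignment

Active regions overlapping the merged predicted-enhancer set by ≥ 1 bp are
"core", active regions without overlap "extended", everything else "none" —
so core + extended always equals the active count. Gene assignment uses
the geometric basal-plus-extension rule: a basal domain of 5 kb upstream
and 1 kb downstream of the TSS (strand-aware), extended outward to the
nearer of the neighbouring gene's basal boundary or 100 kb; a region is
assigned to every gene whose domain it overlaps. Distances are signed
boundary-to-TSS distances, negative upstream on the gene's strand.
Curated regulatory domains (a database internal to web-based tools) are
out of scope. The TSS-proximal split of a module uses the shortest
unsigned boundary distance with a 2 kb window.

## Transposable-element enrichment

For each repeat name, overlaps with the measured-region universe give
f_all = n_overlaps / n_regions, and O/E = (n_overlap_test / n_test) / f_all
for a test group (by default the active regions, or nested groups
rpp_max ≥ b for rising cutoffs b). The overlap unit is the (region, copy)
pair — one region hitting k copies counts k — with `unit="regions"` as the
alternative. O/E > 2 is enriched, < 0.5 depleted; families with ≤ 15
universe overlaps are excluded from interpretation as too sparse. When the
test group equals the universe O/E is exactly 1 for every family.

## Super-enhancers

H3K27ac peaks fully contained in ±2.5 kb of a TSS are removed; the rest
are stitched transitively at gaps ≤ 12.5 kb (d = 0 reduces to an overlap
merge, the alternate run). Signal per stitched enhancer is the sum of
(chip − input) coverage over the constituent peak bases, floored at 0; a
`ratio` mode (Σchip/Σinput) is provided since coverage-track conventions
vary. After ranking, both axes are scaled to [0, 1] and the super-enhancer
cutoff is the point where a slope-1 tangent touches the curve — computed
discretely as the rank maximizing x − y, ties broken toward the higher
rank (fewer SEs). Enhancers strictly above the cutoff signal are super;
flat curves or fewer than 3 enhancers yield none, with a warning.

Dissection: per stitched enhancer, overlapping plasmids are counted,
plasmids with mean RPP ≥ θ are active, and the *active subspace* is the
union of active-plasmid footprints clipped to the enhancer, reported in
bases and as a fraction of the enhancer width.

## Sequence features and classifier

GC content excludes N from the denominator. Dinucleotide features take,
per dinucleotide, the maximum of its frequency on the forward strand and
on the reverse complement. Conservation is the maximum track value
overlapping the region (0 where the track is silent). Motif hits are
binary: at least one window on either strand scoring at or above the exact
p < 0.05 threshold. The threshold comes from the full null distribution of
the integer-quantized log2-odds score (quantization step 1/1000,
probabilities floored at 1e-4 to keep scores finite) computed by
position-wise convolution under the background model; it is the smallest
score with null exceedance below α. The background defaults to uniform and
is an explicit parameter — reproducible, unlike an implicit genome-derived
background. Motif quality grades are carried as metadata, not enforced.

The classifier is a random forest with the stated protocol: 500 trees, 50
features per split (clipped with a warning when fewer exist), depth 10,
10-fold stratified cross-validation, the majority class downsampled within
each training fold. Reported AUC and balanced accuracy pool the
out-of-fold predictions; importances come from a final fit on the full
balanced data.

## Synthetic data

The generator emulates the measurement process the pipeline inverts, at
roughly a thousandth of real-library scale so a full run takes seconds:

- **Loci.** 300 enhancer loci of 1 kb on a 900-kb toy chromosome, each with
  a latent activity multiplier: 20% active, multiplier LogNormal(ln 150, 1)
  — activities spanning more than an order of magnitude, as reporter data
  show — and inactive LogNormal(0, 0.4), a mild baseline jitter. Each locus
  emits a TF and a histone peak, so the scaffold reconstructs the loci
  exactly.
- **Plasmids.** 50,000 plasmids drawn with locus weights ~ Gamma(2)
  (ChIP-enrichment proxy), fragment centres Normal(locus centre, 300 bp),
  insert sizes truncated Normal(221, 60) on [100, 450] bp — the 221 bp mean
  matches the assay's typical insert. DNA counts are multinomial over
  Gamma(1.5) plasmid abundances at 6 reads/plasmid mean; plasmids with no
  DNA read do not exist downstream.
- **RNA.** Per replicate, counts are negative-binomial with mean
  dna_count × activity × 0.5 × depth-distortion and dispersion 1.0
  (Var = μ + μ²). The dispersion default was calibrated once so that the
  replicate log-count correlation at count ≥ 5 is ≈ 0.81, inside the
  0.6–0.85 band typical of such replicate measurements. A configurable 2%
  of RNA counts are written at coordinates absent from the library to
  exercise the orphan tally.
- **Repeats.** Families are planted with a target O/E by placing each copy
  in an active locus with probability O/E × f_active, otherwise in an
  inactive locus; a 10-copy family exercises the sparsity exclusion.
- **Super-enhancers.** A separate chromosome carries 5 SE domains of 40 kb
  (6 constituent H3K27ac peaks each, within stitching range) plus 60
  isolated "normal" peaks, with chip/input coverage tracks encoding their
  signal. 600 plasmids tile each SE; those fully inside a planted
  sub-interval of 3% of the SE width carry activity 300, the rest 1. The
  sub-interval is planted inside the constituent-peak span so truth and the
  stitched domain refer to the same interval. One TSS with a fully
  contained sacrificial peak inside the first SE exercises the exclusion
  rule without breaking stitching.
- **Annotation.** 40 genes (30 near loci for the proximal split), a
  blacklist region with decoy peaks, a predicted-enhancer set covering 40%
  of loci, a conservation track elevated in active loci (Beta(8,3) vs
  Beta(2,6)) so the sequence classifier has recoverable signal, and three
  random demo motifs.

What the generator does **not** emulate: alignment error and multi-mapping,
sequence-driven (motif-dependent) activity, GC or fragmentation bias,
UMI-less PCR duplicates beyond plain count multiplicity, and transfection
batch effects. Passing recovery tests therefore demonstrates that the
pipeline inverts its own generative model faithfully at desk scale — not
that real libraries are free of these artefacts.

Determinism: one `numpy` generator seeded from the config drives every
draw, and all files are written in sorted order, so equal seeds give
byte-identical datasets.

## Problem sizes in the test suite

The default simulated experiment (50,000 plasmids, 300 loci, 2 replicates)
runs the full pipeline in a few seconds; recovery checks (activity rank
correlation ≥ 0.8, balanced accuracy ≥ 0.85, planted O/E within ×/÷1.5,
SE active fraction within ±0.01) run on that one dataset. Oracle checks
use exhaustive enumeration at small n: all segmentations for n ≤ 16, all
4^L sequences for motif length ≤ 8, quadratic overlap scans at 500×500.
The classifier protocol runs at 1000 samples × 60 features under the full
hyperparameters.

## Known limitations

- PELT/exact-DP are pure-Python O(n²)-ish; ranked curves beyond ~50,000
  points should use the rank subsample (the default) or `amoc`.
- The orchestration cache keys on file checksums and parameters; it does
  not track code versions, so editing the package between resumed runs
  warrants a fresh output directory.
- BAM fragment input requires name-grouped or coordinate-sorted files small
  enough to hold mate pairs in memory per query name.
- The slope-1 SE cutoff assumes a convex scaled rank curve, as rank-signal
  curves of real H3K27ac data are; strongly non-convex synthetic curves can
  place the tangent at a local feature.
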