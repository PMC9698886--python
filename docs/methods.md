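# Methods

`atacdiff` implements a differential chromatin-accessibility analysis of the
kind used to compare resting, cytokine-primed (CytP) and antigen-stimulated
(AgS) CD8+ T cells by ATAC-seq: a cross-condition peak atlas, a
regularized-log (rlog) fold-change classification of opening and closing
peaks, cross-condition overlap quantification, nearest-TSS annotation, motif
and gene-set enrichment, and library QC. Because the pipeline's statistical
behaviour can only be validated against known truth, the package ships a
first-class synthetic data generator that emulates the three-condition
design end to end.

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based, closed) is converted on read; the conversion is self-inverse.
Fragment files are 3-column BED, one fragment span per line — the analysis
needs only spans, not read pairs.

## Synthetic data model

The generator places `n_regions` accessible regions (default 500, widths
~N(400, 60²) bp, floored at 50 bp) on `n_chroms` uniform-composition random
chromosomes (default 2 × 1 Mb), non-overlapping with ≥ 500 bp gaps and a
2 kb margin at chromosome ends. Gene TSSs are placed inside or within
200 bp of a random subset of regions (default 300 genes), making TSS
enrichment testable.

**Count model.** Each region has a baseline strength `a_rN ~
Gamma(1/α, α)` with mean 1 (α = `nb_dispersion`, default 0.2); condition
effects multiply the shared strength, `a_rc = a_rN·2^log2FC_rc`. Given the
strengths, per-library counts are Poisson with mean `depth·a_rc / Σ_r a_rc`
(default depth 100,000 fragments per condition, i.e. a mean of ~200
fragments per region). Marginally every count is negative-binomial with
dispersion α; placing the overdispersion at the region level and sharing it
across libraries reflects the biology (strong enhancers are strong in every
condition) and leaves only Poisson noise on the cross-condition contrast.
With one library per condition — the non-replicated design this pipeline
targets — independent per-library NB noise at α = 0.2 would put ~0.9 log2
units of noise on every contrast, more than the detection threshold itself,
and no fold-change classifier could distinguish a planted 4-fold effect
from background; the shared-strength model is the construction under which
a threshold classifier is a sensible instrument, which is exactly how the
original non-replicated analyses implicitly operate.

**Differential structure.** `frac_diff_per_condition` defaults to 0.40 for
AgS and 0.04 for CytP — the 10:1 asymmetry of the motivating design — with
planted |log2FC| = 2. Opening fractions default to 0.63 (AgS) and 0.30
(CytP), and the shared fractions of CytP-differential regions that are also
AgS-differential (same direction) default to 0.33 for opening and 0.63 for
closing, mirroring the published overlap structure. Differential
assignments are drawn largest condition first; shared members are sampled
from the larger condition's set, the remainder from regions differential
nowhere.

**Fragments.** Midpoints are uniform within the region; lengths come from
a three-component Gaussian mixture (weights 0.5/0.35/0.15, means
75/200/400 bp, sds 15/30/40 bp — nucleosome-free, mono- and di-nucleosome)
truncated to [20, 800] bp by resampling. Background fragments are placed
uniformly at 10⁻⁴ fragments/bp. The generator does not model Tn5 insertion
bias, sequencing error, duplicates or GC bias, so passing tests demonstrate
the pipeline's statistical correctness, not robustness to those artefacts.

**Peak calls.** Every region with accessibility ≥ 0.05 is emitted per
condition, boundaries jittered by N(0, 10²) bp; jitter is resampled until
each call keeps ≥ 90 % reciprocal overlap with its region, which guarantees
(and is asserted at generation) that same-region calls across conditions
stay above the 75 % merge threshold.

**Motifs.** Each stimulated condition's opening regions carry that
condition's built-in motif consensus (STAT-family-like for CytP,
bZIP-family-like for AgS; 0.97 probability on the consensus base), written
once at the region center on a random strand; regions opening in several
conditions carry all of their motifs side by side.

All randomness derives from a single seed through independent per-stage
streams; outputs are byte-identical across reruns of the same seed.

## Peak atlas

Two peaks merge when they share the chromosome and their overlap covers at
least `min_frac` (default 0.75) of **both** lengths, boundary inclusive.
The reciprocal rule keeps the predicate symmetric and stops a long interval
from absorbing short neighbours; one-sided and strict-boundary variants are
available as options. Merged peaks take the union span (evidence must not
be clipped). Merging iterates to a fixpoint over a start-sorted scan in
which the working interval is compared against every following interval it
overlaps — a mergeable pair must overlap, but a non-mergeable call can sit
between two mergeable ones, so an adjacent-only scan can stall short of the
fixpoint. The result is deterministic and provably non-mergeable pairwise;
on small instances it is verified to be a member of the set of fixpoints
reachable by merging any mergeable pair in any order.

Counting assigns a fragment to every atlas peak it overlaps by
≥ `min_overlap_bp` (default 1 bp, the coverage-tool convention on fragment
input); fragments overlapping no peak are tallied per sample as
unassigned.

## Differential accessibility

Size factors are median-of-ratios over peaks with positive counts in all
samples, rescaled to geometric mean 1. Per-peak dispersions are method of
moments, `α_i = max(0, (v_i − m_i)/m_i²)` on normalized counts, with a
least-squares trend `α(μ) = a0 + a1/μ` (a0 floored at 0.01, the trended
value floored at 10⁻⁸). The rlog is a closed-form empirical-Bayes
shrinkage:

    β_ij = log2(n_ij + 0.5) − μ_i
    w_ij = (1/ln 2)²·(1/(n_ij + 0.5) + α̂_i)
    σ²   = (q95(|β|)/1.645)²          (floored at 10⁻⁶)
    c_ij = σ²/(σ² + w_ij)
    rlog_ij = μ_i + c_ij·β_ij

The prior variance is matched so that the 95th percentile of observed
|β| sits at 1.645 prior standard deviations — i.e. the prior is calibrated
to the bulk of the observed fold-change spread. The 0.5 pseudocount keeps
zeros finite and symmetric. This transform is deliberately an explicit,
reproducible, monotone formulation of the shrunken-log idea; bit-level
agreement with any external rlog implementation is a non-goal. A peak is
opening for the ordered pair (A, B) when `rlog_B − rlog_A ≥ log2(1.5)`
(≈ 0.585), closing when ≤ −log2(1.5); ties at the threshold count as
differential so the rule is deterministic. The naive condition is the
reference (first element) of every default contrast.

PCA selects the `top_n` (default 500) peaks by rlog row variance, centers
rows, and takes the SVD of the samples × peaks matrix. The random split of
peak IDs into two subgroups is an independent fair coin per peak under a
stated seed. Overlap percentages are rounded half away from zero to the
nearest integer, the precision at which such percentages are convention-
ally reported.

## Annotation and enrichment

A peak's position is its integer center. The nearest gene minimizes
|center − TSS| on the same chromosome; ties break to the lexicographically
smaller gene id; peaks on gene-less chromosomes get the sentinel `none`.
The signed distance is negative when the center lies 5′ (upstream) of the
TSS in the gene's orientation: `center − tss` on +, `tss − center` on −
strand genes.

Gene-set overrepresentation and motif enrichment both use the upper-tail
hypergeometric probability — for gene sets, population = universe (an
explicit required input), successes = term members in the universe, draws =
query; for motifs, ZOOPS counting over peaks with population = foreground +
background peaks — followed by Benjamini–Hochberg correction, with results
sorted by (FDR, p, name) for determinism. Both tails are verified against
an exact rational sum-of-pmf oracle to 10⁻¹².

Motif scanning scores log2 odds against a background base model (uniform
by default, overridable by observed composition) on both strands, skipping
windows containing N; the default detection threshold is 0.8 × the
consensus score, or the per-motif threshold carried by HOMER-style files
when requested. Optional GC matching downsamples the background to the
foreground's GC-decile profile. PFM counts are pseudocounted 0.001 per
cell before column renormalization.

## QC

The fragment-length histogram uses 1-bp bins on [20, 800] with an overflow
tally, an 11-bin centered moving average, and reports at most one mode per
band (nucleosome-free < 120 bp, mono-nucleosome 120–250 bp, di-nucleosome
250–500 bp) among smoothed local maxima exceeding 10 % of the global
maximum; plateau maxima report their center. The TSS profile aggregates
both fragment endpoints (cut sites) over ±1 kb around each TSS with full
flanks, strand-oriented; the enrichment score divides the smoothed maximum
within ±50 bp by the mean signal over the outermost 100 bp of each flank
(an ENCODE-style flank normalization; a zero flank yields an `inf`
sentinel with a warning). No Tn5 +4/−5 correction is applied since inputs
are abstract spans.

## Simple peak caller

For real fragment input the pipeline includes a deliberately simple
caller: 200-bp windows stepped by 50 bp, midpoint counts tested against
the genome-wide uniform Poisson rate (upper tail), BH across windows at
q = 0.01, significant overlapping windows merged. It is a plumbing
component for end-to-end runs, not a replacement for a production caller;
the synthetic workflow uses the generator's emitted calls.

## Validation scale and limitations

The test and acceptance workloads run the default conditions — ~500
regions, three conditions at 100k in-region fragments each, planted
|log2FC| = 2 — which a single CPU completes in seconds. Known limitations:
no replication (dispersion across conditions is confounded with signal, so
the trend intercept absorbs planted effects; shrinkage remains monotone
and the classification is threshold-based, not inferential), no p-values
for differential calls by design, no GC or insertion-bias modelling in the
generator, and GTF support restricted to gene features.
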