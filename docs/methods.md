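# Methods

`captes` analyses locus-specific transcription of transposable elements
(TEs) — chiefly Alu and LINE-1 — from long cDNA reads produced by
Cas9-targeted nanopore enrichment. This note documents the models and
procedures the package implements, the parameters that matter, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was open.

## Read-level TE detection

Reads are scanned against subfamily consensus sequences with an
affine-gap Smith–Waterman aligner under a simple DNA scheme: match +5,
mismatch −5, gap open −10, gap extend −5 (the open score is charged for
the first gapped base, so a gap of length L costs 10 + 5(L−1); `N`
never matches). A segment is reported as a TE hit when its score
exceeds 225 *and* its divergence (mismatches over aligned columns) is
below 18% — both strict inequalities. Multiple hits per read are found
by masking each accepted or rejected segment with `N` and re-aligning;
hits therefore never overlap on the read.

The in-package scanner is a deliberate simplification of a full repeat
annotator: it uses one flat scoring scheme rather than neutral
substitution matrices, and consensus libraries rather than full repeat
databases. For real data the RepeatMasker `.out` parser is the intended
path; the scanner exists so that the entire pipeline is testable on
synthetic data with known truth.

Numerics: the dynamic-programming fill is numba-compiled; traceback
runs in Python over the stored score matrices. Co-optimal alignments
are resolved to the smallest `(query_start, target_start, query_end,
target_end)`, making results deterministic across platforms. An empty
query or target yields score 0 and an empty alignment.

## Enrichment QC

* **On-target rate** — a read is on-target when an Alu/L1 hit *starts*
  within its first 50 nt (start-based rule; a hit that begins earlier
  and merely extends into the window does not count). The window is
  configurable.
* **Strand-side assignment** — the first 30 (Alu) or 80 (L1) bases of
  each read are aligned to the consensus and its reverse complement; a
  PAM/PAM-distal call requires the best score to reach 80 (Alu) or 100
  (L1) *and* the alignment to start at read base 0, the signature of a
  Cas9-released 5′ end. Orientation maps to side through the gRNA's PAM
  orientation (configurable; default forward → PAM-distal).
* **Side-reaction rate** — fraction of hybrid reads (spike-in plus
  host cDNA chimeras) among all reads containing a spike-in segment.
  Host content is decided by a pluggable detector; the synthetic
  pipeline uses an exact 25-mer index over the transcriptome
  (≥ 2 host k-mers outside spike-in segments), which at a 2%
  substitution rate detects any ≥ 50 nt host fragment with high
  probability while random carrier sequence yields none.
* **Data yield** — reads per available pore per minute over the first
  30 minutes; available pores are the distinct channels observed in
  the window. Relative yield normalises to a control run.

## Read filtering

Reads with mean quality ≥ 7 and length ≥ 300 are kept (both
inclusive). Mean quality is the arithmetic mean of per-base Phred
scores by default; an error-probability mean (which penalises
low-quality stretches more strongly, as the common nanopore filtering
tools do) is available via `mean_read_quality(..., method="error_rate")`.

## Repeat aging

milliDiv (mismatches per kb against the subfamily consensus) is
converted to a Jukes–Cantor distance d = −(3/4)·ln(1 − 4p/3) with
p = milliDiv/1000, and to an age d/μ with μ = 2.2×10⁻⁹ substitutions
per site per year by default. The copy is treated as a single lineage
diverging from its (ancestral) consensus, so the distance is not
halved; both μ and the convention matter only as a scale factor and μ
is exposed as a parameter. A locus is *young* when its age is strictly
below 2 Myr, which at the default μ corresponds to milliDiv < 4.387.
p ≥ 0.75 is a saturation error, not NaN.

## Transcript classification

Assembled transcripts are compared with the reference annotation and
given exactly one class code, with precedence:

1. **full match** — identical splice-junction chain on the same strand,
   both ends within 100 nt (nanopore transcript ends are ragged; the
   tolerance is configurable);
2. **intron retention** — an exon fully covers a reference intron of an
   overlapping same-strand transcript;
3. **novel junction** — same-strand gene overlap with at least one
   junction absent from the reference;
4. **intronic** — fully inside one reference intron;
5. **intergenic** — no gene-span overlap;
6. **other genic overlap**.

Genomic context is assigned independently: intergenic (no gene-span
overlap), intronic (fully inside an intron), spanning (overlaps both
genic and intergenic space), else genic. Gene spans are the union of
each gene's transcript isoforms.

TE–transcript overlap uses the transcript's **full genomic span**
(≥ 1 bp suffices) and ignores TE strand; exon-only intersection is
available behind a flag. A TE containing the strand-aware first/last
transcribed base has role `tss`/`tes` (both when it contains both
ends, e.g. a short transcript entirely inside a TE), otherwise
`internal`.

Patterns collapse code + roles: intron retention and noncanonical
splicing follow the code directly; alternative TSS/TES require an
intronic or intergenic transcript starting/ending inside a TE and may
co-occur. Containment of the start/end base is required — a gap
between the transcript end and the TE edge does not count.

## Transcription modes and autonomy

Each transcript containing a TE locus receives one mode at that locus,
with precedence autonomous > intron retention > passive:

* **autonomous** — the transcript is fully intronic/intergenic and its
  first transcribed base lies inside the TE (the TE's own promoter);
* **intron retention** — the transcript retains an intron and the TE
  lies strictly 3′ (strand-aware) of its start;
* **passive** — everything else.

The autonomy ratio of a locus is autonomous abundance over the summed
abundance of all transcripts containing the locus (0 = purely passive,
1 = fully autonomous). A transcript containing several TE loci is
credited in full to each locus — abundance is not split, because the
ratio is defined per locus against the same denominator. Mode
contributions divide per-mode abundance by the host gene's total
expression.

## Quantification and differential expression

Fractional counting follows the multimapper-aware rule: a read with x
genomic alignments, each overlapping y features by at least 20 aligned
bases, adds 1/(x·y) to each such feature; alignments touching no
feature contribute nothing; counting is unstranded. Overlap is summed
over an alignment's blocks, so spliced alignments count exonic overlap
only.

Features are pre-filtered (count ≥ 3 in ≥ 3 samples), normalised by
median-of-ratios size factors (computed over everywhere-nonzero
features; library-size fallback otherwise), and tested with a
**moderated t-test** on log2(normalised + 0.5): per-feature pooled
variances are shrunk toward their across-feature mean with 4 prior
degrees of freedom, which the t distribution gains. This is the
standard small-sample stabilisation and is the package's own choice of
default engine — a plain Welch test is provided and any per-feature
test can be plugged in. The engine is a documented, simplified stand-in
for a negative-binomial GLM; it preserves the published thresholds
exactly (|log2FC| > 1, BH-adjusted p < 0.05) but does not model
count-level dispersion, so borderline, low-count calls should not be
over-interpreted. Measured behaviour at the defaults: null type-I
≈ 2–3% at nominal 5% (slightly conservative), ≥ 45/50 recovery of
8-fold changes at n = 3 vs 3 against a majority-null background.
Benjamini–Hochberg adjustment is implemented directly (step-up, clipped
at 1) and cross-checked against statsmodels in the tests.

Contribution statistics: per gene, the noncanonical (resp. canonical)
share of an expression change is its case-minus-control difference
divided by the summed differences of both types; the two shares sum to
1 and can leave [0, 1] when the differences have opposite signs (they
are reported as-is).

## Insertion post-processing

Raw insertion calls are merged per chromosome and family by
single-linkage within 200 bp — closely spaced calls chain
transitively. Merged support is the members' sum; the merged position
is their support-weighted median (robust to one noisy member). The
supporting-read threshold is either a family default (Alu 6, L1 5) or
estimated from the data as the knee of N(s) = #calls with support ≥ s:
the s maximising perpendicular distance to the chord from (1, N(1)) to
(s_max, N(s_max)), ties to the smaller s; fewer than three distinct
support values fall back to threshold 1. Thresholding is applied after
merging.

Annotation is positional: a call is genic when its point position lies
inside a gene's half-open union span; all overlapped genes are
recorded. Oncogene enrichment compares the oncogene fraction of
insertions against the oncogene fraction of expressed TEs: fold =
(a/n₁)/(b/n₂), chi-squared on the 2×2 table without continuity
correction, BH-adjusted across the families tested together.
Gene-body profiles are strand-aware 120-vectors: 10 upstream windows
over 1 kb, 100 equal body windows, 10 downstream windows.

## Saturation analysis

TE-containing reads are subsampled without replacement at proportions
0.05–1.00 (step 0.05), 50 replicates each; identifications are the
distinct transcripts among sampled reads. The mean curve is fitted with
a saturating hyperbola y = a·x/(b + x) (a = asymptote, b =
half-saturation); the data requirement for a target t < a inverts the
fit, x = b·t/(a − t), converted to Gb by a per-read yield factor.
Fitting runs in the curve's native x-units (proportions or reads) and
converts afterward. The functional form is a package choice — the
hyperbola matches rarefaction behaviour at moderate depth; the exact
expectation E[S_k] = Σ_t [1 − C(N−n_t, k)/C(N, k)] is implemented for
validation and the Monte-Carlo means agree with it within 3 standard
errors in the tests.

## The synthetic-data generator

All pipeline inputs are generated from one seed with integer RNG
streams, so outputs are byte-identical across platforms. The defaults
emulate a small targeted-enrichment run: a 2 Mb genome with 40
multi-exon genes and 300 TE loci (70% Alu / 30% L1) planted in exons,
introns, and intergenic space; 2000 reads of which 70% begin inside a
TE segment (the enrichment signature, matching the ~69% on-target rate
such libraries reach); 2% substitution errors; spike-in reads with a
2.2% hybrid (side-reaction) fraction.

Constructions worth knowing about:

* TE copies realise their drawn milliDiv **exactly** (a fixed mismatch
  count rather than a binomial draw), and the non-young milliDiv draw
  is capped at 120 so every planted locus sits well inside the < 18%
  reporting rule even after read errors. Ten percent of loci are drawn
  young (milliDiv < 5).
* Noncanonical transcripts are built to be unambiguous: intron
  retention merges the exons flanking a TE-bearing intron; noncanonical
  splicing shifts a donor site 30 nt; alternative TSS/TES transcripts
  are monoexonic, start (resp. end) inside an intronic or intergenic
  TE, and keep their other end ≥ 50 nt clear of any TE. Intergenic TEs
  get wide placement clearance for the same reason.
* Off-target reads start ≥ 200 nt before any TE segment (50 nt window
  plus a buffer, because a co-optimal local alignment can extend a
  hit's start somewhat leftward through zero-cost prefixes).
* Reads are transcript suffixes (the length distribution of
  Cas9-released fragments is not modelled); errors are substitutions
  only, so every read's genomic origin — and hence its alignment
  record — is exact without an external aligner.
* Insertion-call simulation jitters each planted insertion into 1–3
  member calls within ±80 bp plus low-support noise; the planted-knee
  support generator mixes a geometric noise regime with a uniform
  signal plateau and declares its knee analytically (where the
  expected noise tail crosses the signal count).

What passing on this generator does **not** show: robustness to real
nanopore error profiles (indels, homopolymer bias, quality-correlated
errors), to ambiguous TE fragments and nested repeats, to
multimapping-driven misassignment (simulated reads have x = 1 unless
constructed otherwise), or to assembler artefacts — the generator's
noncanonical transcripts are clean by design, which is exactly what
makes zero-confusion label recovery a meaningful correctness check
rather than a performance claim.

## Problem sizes

The test suite and the acceptance script run the scanner on 120–150
reads (scanning costs ~70 ms per read against the two-consensus
library), use the default 2 Mb / 2000-read dataset for truth-recovery
checks, 200 replicates for knee recovery, 1000 vectors for the BH
cross-check, and 500 features for the null-calibration check. The suite
completes in under a minute on one CPU.

## Known limitations

* The scanner is not a RepeatMasker replacement; scores are not
  comparable to RepeatMasker output even though the acceptance
  thresholds (225 / 18%) are the same.
* The DE engine ignores count dispersion structure; use a dedicated
  negative-binomial framework for production differential calls.
* BAM input is supported through the documented tabular alignment
  dialect; binary BAM parsing is not wired into the CLI.
* Saturation extrapolation inherits the hyperbola's bias when the true
  accumulation curve is heavier-tailed; treat multi-fold extrapolations
  as order-of-magnitude estimates.
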