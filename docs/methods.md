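# Methods

## The mixture model

An aCGH probe reports the log2 ratio of sample to reference DNA after
normalization. For a tumor sample containing a fraction ρ ∈ (0, 1] of tumor
cells whose genome has integer copy number c at the probe and average ploidy
ψ, with the remaining cells normal diploid, the expected normalized ratio is

    E(c; ρ, ψ) = log2( (ρ·c + 2(1−ρ)) / (ρ·ψ + 2(1−ρ)) ).

The denominator is the mixture's average copy number: the model assumes
array normalization centers each profile on its own mean, which is exactly
why polyploid or contaminated samples cannot be compared on raw ratios.
E is strictly increasing in c for ρ > 0, and E(ψ) = 0 for every ρ. The
c = 0, ρ = 1 case would be log2(0); it is clipped at a floor (default −8),
as saturated array spots are in practice. The same formula is the forward
model of the simulator and the inverse model of the estimator, with one
deliberate asymmetry: the simulator adds i.i.d. Gaussian probe noise
(default sd 0.15, a configuration choice) after clipping.

## Segmentation

Circular binary segmentation on each chromosome independently. For a piece
of n probes the candidate split is the arc [i, j) maximizing

    T(i,j) = |mean(arc) − mean(complement)| / (s·√(1/n_arc + 1/n_comp)),

with s the pooled standard deviation over both groups (n − 2 degrees of
freedom). s = 0 with unequal means scores +inf; s = 0 with equal means
scores 0. Significance is a permutation test: the maximal statistic is
recomputed on shuffles of the piece and p is the fraction reaching the
observed maximum; the split is accepted when p ≤ α. Defaults α = 0.0001
with 10,000 permutations; permuting aborts early once the exceedance count
already forces p > α, which makes null pieces cheap. An arc touching the
piece boundary degenerates to a single breakpoint (plain binary split).
Accepted splits recurse into each resulting piece, left to right.

Numerical and procedural choices:

- `min_width` (default 2) forbids splits creating a segment of fewer probes,
  applied identically to observed and permuted scans.
- An arc and its complement have identical statistics in exact arithmetic
  but can differ by an ulp in the vectorized scan; maxima within 1e-9
  (relative) are treated as ties and resolved to the smallest (i, j). This
  makes tie-breaking deterministic and independent of summation order.
- No post-hoc "undo splits" pass and no tail-approximation p-values: the
  procedure is the plain recursive test at the stated α.
- Randomness: one integer seed; each chromosome gets an independent child
  generator, so results for one chromosome do not depend on how many
  permutations another consumed.

## Purity/ploidy estimation and integer copy numbers

Given segment means m_s with probe counts n_s, the estimator scans the full
grid ρ ∈ {0.05, 0.06, …, 1.00}, ψ ∈ {1.00, 1.05, …, 6.00}. For each
candidate, every segment is assigned the nearest integer copy number
ĉ_s = argmin_c |m_s − E(c; ρ, ψ)| with c ≤ c_max (default 12; equidistant
means resolve to the smaller c), and the objective is

    Σ_s n_s · (m_s − E(ĉ_s))²  +  λ·ψ,      λ = 1e-3 · Σ_s n_s.

Ties break toward smaller ψ, then larger ρ. Grid search rather than
continuous optimization keeps the fit reproducible and exposes the
ambiguity surface; at this grid size a fit costs well under a second.

**Identifiability.** The mixture has two exact reparameterization families:

1. *Doubling*: at ρ = 1, (ψ, {c}) and (2ψ, {2c}) produce identical
   expectations. The λ·ψ penalty resolves this toward the smaller genome.
2. *Unit shift*: (ρ, ψ, {c}) and (ρ′, ψ−1, {c−1}) with ρ′ = 2ρ/(2+ρ)
   produce identical expectations for every segment with c ≥ 1. Only a
   segment at c = 0 breaks this family, because c = −1 does not exist: a
   homozygous deletion anchors the absolute copy-number scale. Profiles
   with no homozygous deletion (and no odd/even structure to veto doubling)
   are genuinely ambiguous, and the penalty then selects the smallest-ψ
   member of the family. An all-neutral profile (every mean 0) is the
   extreme case: the fit returns ρ = 1.00, ψ = 1.0 by the same parsimony
   rule, and the downstream track log2(ĉ/ψ̂) is identically zero either
   way, so no aberration is ever fabricated. Parameter-recovery claims in
   the test suite therefore use cohorts containing homozygous deletions,
   which is also what the renal-carcinoma cohorts that motivated the
   package look like.

The reported per-probe track is log2(ĉ/ψ̂) — independent of ρ, so profiles
of different purity are directly comparable. ĉ = 0 carries the floor value
and an explicit HD flag; downstream code never parses sentinels.

## Aberration calling and cohort maps

Classes on the log2(ĉ/ψ̂) track: homozygous deletion wherever ĉ = 0, else
amplification above +0.811, gain above +0.377, loss below −0.377, else
neutral. The thresholds are the empirical cut points derived from the
recalculated-ratio distribution of the motivating 15-sample renal-carcinoma
cohort; both are configurable. Precedence HD > amplification > gain > loss
makes the classes disjoint, so cohort frequencies of the four non-neutral
classes plus neutral partition to 1 at every probe. For display,
amplifications are graded into four bins of the track value
((0.811, 1.2], (1.2, 1.6], (1.6, 2.0], > 2.0); the bin edges are package
defaults, not measured quantities.

The *most overlapping section* of a chromosome is the interval over which
the largest number of samples is aberrant for a class. Because an interval's
support is the number of samples aberrant over **all** of it, a run of
probes at peak per-probe support can only be extended while the same sample
set stays aberrant; the implementation enforces set identity between
adjacent probes and the tests check it against exhaustive interval
enumeration. Ties resolve to the longest interval in base pairs, then the
leftmost.

Gene summaries follow the wording asymmetry of the motivating analysis: a
gene counts as *completely deleted* in a sample only if every probe
overlapping it is HD, while a single amplified probe suffices for
*amplified*. Genes with no overlapping probes are skipped with a warning.

## Cross-species projection and similarity

Synteny blocks pair a source interval with a target interval and an
orientation. A target position maps to the source by proportional (affine)
interpolation of its fractional offset — blocks rarely match in length —
and reverse blocks reflect the offset: forward src = start + ⌊f·L⌋, reverse
src = end − 1 − ⌊f·L⌋. Blocks overlapping on the target are resolved by
keeping the longer one (logged); positions outside any block are missing,
not errors. The projected value at a mapped position is the log2(ĉ/ψ̂) of
the covering source *segment* — the denoised signal — rather than a nearest
probe.

Two projected profiles are compared by Pearson correlation r over the
positions both cover (at least `min_overlap`, default 10 for toy grids;
use ≥ 1000 at genome scale), reported as the similarity index
s = sign(r)·√|r|·1000. The square root stretches weak correlations;
s is bounded in [−1000, 1000], equals 1000 for self-comparison and −1000
against a negated copy. Pairwise matrices fix the diagonal at 1000;
undefined pairs (insufficient overlap, zero variance) become missing with a
warning and are excluded from group means, which average all cross-group
pairs and exclude self-pairs within a group.

## Cohort statistics

Whole-genome tracks are clustered agglomeratively with average linkage on
correlation distance d = 1 − r (d ∈ [0, 2]); the motivating analysis named
only "hierarchical clustering", and correlation distance matches its use of
correlation everywhere else. HD floor values participate in the correlation
as-is — they carry real signal — and this is configurable by masking before
calling. Merge order ties follow input order; dendrograms export to Newick
with branch lengths equal to merge heights. Trait associations use Pearson
r with the two-sided p from the t distribution on n − 2 degrees of freedom.
Windowed means tile non-overlapping windows (default 2 Mb) from position 0;
empty windows are missing, not zero.

## The simulator: what it does and does not emulate

`make_genome` lays out a desk-scale surrogate of a CGH array (default 20
chromosomes × 500 jittered probes ≈ 10,000 loci, standing in for the
~180,000 of the real platform). `simulate_truth` plants non-overlapping
gains (+1), losses (−1), homozygous deletions (0), focal amplicons (above
the amplification threshold) and optional whole-chromosome losses on a
baseline of round(ψ), then reports the realized ploidy as the exact
length-weighted mean copy number of the emitted segments — the invariant
the tests assert. `render_ratios` applies the mixture formula and Gaussian
noise.

Deliberately not modeled: GC waves and other spatial autocorrelation, dye
bias, replicate/saturating probes, allele-specific signal, and subclonal
(non-integer) copy number. Passing tests on this generator demonstrate the
pipeline's arithmetic and inference under the stated model; they do not
certify performance against wave artifacts or heterogeneous tumors.

## Problem sizes and determinism

Test and demo cohorts use 3–10 chromosomes of 60–100 probes with 2–4
samples, chosen so the full suite and the demo pipeline run in minutes on
one core while every stage still crosses segment, chromosome and sample
boundaries; the statistical tests (null false-split rate at 200 replicates,
parameter recovery over 50 cohorts) use the sizes their claims state. All
randomness flows through explicit integer seeds via independent per-unit
child generators, pipeline reruns are byte-identical, and the run manifest
(config echo, seed, artifact checksums) suffices to reproduce any run.
Readers parse floats in round-trip mode so TSV round-trips are exact.

## Known limitations

- The purity/ploidy estimator is a surrogate with the stated inputs,
  outputs and purpose; no claim of numerical equivalence with any
  particular published per-sample estimate is made.
- Significance of recurrence is not assessed (support counts only); there
  is no GISTIC-style scoring.
- Synteny blocks are consumed, not computed; block quality bounds
  projection quality.
- With α = 0.0001 and 10,000 permutations the attainable p resolution is
  exactly one exceedance; raising `n_permutations` sharpens the test at
  linear cost.
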