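# Methods

## The analysis model

Bisulfite treatment converts unmethylated cytosine to uracil (sequenced as
T) while 5-methylcytosine is protected (sequenced as C). In a directional
single-end library every read reports the strand it was drawn from: a
forward-strand read is informative at reference C positions (C = retained,
T = converted) and a reverse-strand read at reference G positions (G
retained, A converted, once the read is oriented to forward coordinates).
The methylation level of a cytosine is estimated as
retained / (retained + converted) over the reads covering it.

Plant methylation is analysed per sequence context, read 5′→3′ on the
cytosine's own strand: CG (next base G), CHG (H then G, H = A/C/T), CHH
(two H bases). Subcontexts refine the picture: the NCG classes record the
5′ neighbour of a CG (with DCG = NCG minus CCG, D = A/G/T), CHG splits into
CWG (CAG/CTG, W = A/T) versus CCG, and CHH sites with a middle W are CWH
(additionally CWA when the third base is A). A cytosine whose
context-defining neighbours fall outside the chromosome or contain N is
"undefined" and excluded from every table. Context symmetry means CG and
CHG sites pair across strands while CHH is asymmetric; the caller treats
each strand's cytosines independently and never mixes strands at a
position.

### Alignment

Alignment happens in three-letter space. The reference is stored twice:
with C→T applied (forward space) and with G→A applied (reverse space). A
read with C→T applied is matched directly against the forward copy; its
reverse complement — which is exactly the G→A reduction of the
reverse-complemented read — is matched against the reverse copy, so a hit
in either space fixes both locus and origin strand. The internal aligner
seeds with the first k bases of the converted read (exact k-mer lookup,
default k = 20) and extends without gaps, counting mismatches in converted
space. A read is kept only if its best hit is unique and within
`max_mismatches` (default 2); reads whose best score ties at several loci
are discarded as multi-mapped rather than assigned at random, which
prevents methylation bleeding between repeat copies. Reads shorter than
the seed are counted unaligned. `exhaustive_align` implements the same
contract by scanning every start position of both spaces and exists purely
as a seed-free reference: the seeded path can miss a locus only when the
seed itself is corrupted, which cannot happen for conversion-only reads.
Duplicates are not collapsed and there is no gapped or quality-aware mode.

### Windows, the percent-change statistic, and DMRs

Counts are pooled in non-overlapping 50-bp tiles per context; a window's
fraction is pooled retained/(retained+converted) (count-weighted, unlike
the per-cytosine averages, which are unweighted means of levels), and its
"informative sequenced cytosines" is the pooled read total. Two samples
are compared per window with

    +(wt − mut)/wt × 100  if wt > mut,
    −(mut − wt)/mut × 100 if wt < mut,  0 at equality,

i.e. the difference normalised by the *higher* of the two levels, signed so
that loss in the mutant is positive. The statistic is antisymmetric and
bounded in ±100; both-zero falls into the equality branch. A DMR is a
window with fraction ≥ 0.1 in either sample, ≥ 10 informative cytosines in
both samples, and a two-sided Fisher's exact p < 0.05 on the 2×2 pooled
count table. The box-plot style stratification analyses share the
≥ 0.1-in-either rule but demand ≥ 20 informative cytosines. No
multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists); DMRs are reported at window granularity without merging.

Choices worth flagging: the informative-cytosine floor is required in
*both* samples (requiring it in only one lets a zero-coverage sample pass);
the Fisher test is two-sided because DMRs are reported in both directions;
windows are fixed tiles rather than a sliding window, which keeps adjacent
tests disjoint.

### Clone assay and paired t-test

For amplicon bisulfite-PCR data each Sanger-sequenced clone is scored
against the reference forward strand: C → methylated, T → unmethylated,
anything else unreadable; a clone with > 10% unreadable C sites is
rejected. Genotypes are compared with a classical paired t-test on
per-site fractions (pairing by cytosine position, optionally restricted to
one context). Degenerate inputs are handled explicitly: identical vectors
give (t = 0, p = 1); differences constant and nonzero give (±inf, p → 0);
fewer than two complete pairs is an error.

### Meta-analyses

TE metaplots align elements at their 5′ ends (strand-aware) and report the
unweighted mean of per-cytosine levels per 100-bp offset bin, together with
contributing element counts — long elements dominate deep offsets, so the
composition per bin matters and is exposed. The TE–TSS histogram converts
the TE annotation to edge entries and, per gene, tests for the closest
*facing* edge (TE end for + genes, TE start for − genes) in 25-bp windows
up to 500 bp upstream of the TSS; each gene counts at most once. Centile
stratification assigns windows to ascending empirical quantile groups (5
for GC and TE size, 10 for siRNA counts, 4 for histone log-ratios); histone
features are log2((mark+ε)/(H3+ε)) with ε = 1.0, and windows with no
signal in H3K9me2, H3K4me3 or H3 form the extra "ND" group; ties resolve to
the lower centile and a constant feature collapses into one group without
error. Correlation matrices are Pearson with pairwise-complete deletion
(≥ 3 windows per pair; zero-variance features yield NaN). Chromosome
profiles average levels in 100-kb bins and smooth with LOWESS (default span
0.1 of the bins, floored at 2/n). The siRNA/methylation/TE overlap counts
take both the "methylated TE" level threshold and the "siRNA-positive"
count threshold as mandatory explicit parameters, since no canonical
values exist.

## The simulator

The generator is the package's test bed: it emulates a compact genome in
which every downstream claim is checkable against known truth.

- **Genome & annotations.** n chromosomes (default 2 × 100 kb) of i.i.d.
  bases at a target GC (default 0.34), with non-overlapping TEs (default
  40, log-uniform 100–3000 bp) and genes (default 30, 0.5–2 kb) placed
  longest-first into free gaps with a 50-bp margin; packing beyond 80% of
  the genome is rejected. Each TE's neighbourhood (±200 bp) is re-drawn at
  a GC that rises with the TE's length rank, so long TEs sit in GC-richer
  chromatin-like surroundings.
- **Chromatin tracks** (per 50-bp window): H3K9me2 rises and H3K4me3 falls
  linearly with TE length rank over a noisy background; H3 is a flat
  control; siRNA counts are Poisson with rates concentrated quadratically
  on long TEs plus a small tunable euchromatic fraction; a sparse
  TE-expression track prefers short/euchromatic elements; ~1% of windows
  carry no histone signal at all, exercising the ND class.
- **Methylome.** Under the default TE-restricted landscape p_true is zero
  outside TEs; inside TEs it is a logistic function of the window's
  H3K9me2 and GC z-scores, rescaled (with clipping and an iterative
  correction) so the per-context mean over TE cytosines equals the target
  base levels — defaults CG 0.8, CHG 0.7, CHH 0.2, high symmetric and low
  asymmetric methylation as in a moss-like TE methylome. A "uniform"
  landscape methylates the whole genome at the same calibrated levels and
  is the right null for calibration studies. Genotype effects multiply
  p_true by per-context retention factors (e.g. a CG-maintenance knockout
  at r_CG = 0.07 for a 93% truth-space loss), optionally override specific
  subcontexts, and can redistribute CHH methylation along chromatin: p is
  scaled by 1 − d·z where z is the H3K9me2 z-score over *methylated* CHH
  sites (computing z over all sites would let the unmethylated background
  drag the mean down and mark every TE heterochromatic), clipped to keep
  p in [0, 1]. The identity effect is an exact no-op.
- **Reads.** Single-end, error-free apart from chemistry: read count is
  depth × genome / read_length (default depth 30, 75 bp), starts uniform,
  strands equiprobable. Each covered strand-space cytosine is methylated
  Bernoulli(p_true); an unmethylated C reads T with probability
  `conversion_rate` (default 0.995) and a methylated C reads T with
  probability `methylation_failure_rate` (default 0.005). Depth and
  conversion efficiency are simulator choices — no published values exist
  for them — and were fixed before any evaluation.

Everything is driven by one integer seed through independent deterministic
streams; identical configurations reproduce all outputs bit for bit.

What the simulator does *not* emulate: real genome composition or repeat
families (TEs are unique sequences, so multi-mapping is rare), coverage
bias, PCR duplicates, adapters, sequencing errors (an optional substitution
model was considered and dropped to keep the statistical behaviour of the
pipeline isolated), paired-end reads, and organelle genomes. Passing tests
therefore demonstrate correctness of the statistics and geometry, not
robustness to real-library artefacts.

### The non-conversion floor and "percent loss"

With p_true = 0 the expected measured level is 1 − conversion_rate, not
zero. Consequently a genome-wide average is the true signal plus a
background of ≈ 0.005, and the measured percent loss between WT and a
knockout is deterministically *smaller* than the truth-space loss, the more
so the weaker the context's signal: with retention factors 0.07/0.03/0.05
the truth-space losses are exactly 93/97/95%, while the measured
genome-wide losses at the default chemistry land a few points lower (CHH,
the weakest signal, is hit hardest). The recovery tests therefore compare
the pipeline's measurement against the construction's *measured-space*
expectation, E[level] = p(1 − failure) + (1 − p)(1 − conversion) averaged
over cytosines, which the acceptance report prints alongside the
truth-space losses. Real WGBS studies face the same floor and typically
correct with an unmethylated control (e.g. chloroplast DNA); such a
correction is out of scope here.

## Numerical and interface choices

- Internal coordinates 0-based half-open everywhere; single-c output is
  1-based, GFF3 1-based inclusive, BED/bedGraph half-open.
- Genome averages are unweighted per-cytosine means with no coverage floor
  by default (`min_coverage` is exposed); window thresholds handle noise.
- Window fractions are count-weighted by construction.
- Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  cross-checks them against an exact integer hypergeometric enumeration.
- LOWESS span floors at 2/n so short chromosomes degrade gracefully; a
  single-bin chromosome returns its unsmoothed mean.
- The paired t-test treats differences constant to within 1e-12 as
  degenerate to avoid astronomically large t values from float rounding.
- Problem sizes in the tests and the acceptance script (genomes of
  10–200 kb, depths 7.5–50, 10⁴-read oracle comparisons) are chosen as the
  smallest scales at which every property is statistically identifiable;
  all of them are plain parameters and scale up unchanged.

## Known limitations

- The seeded aligner requires an exact first-k-mer match; with sequencing
  errors enabled it would lose reads whose seed is corrupted (the
  exhaustive aligner does not, and quantifies the gap).
- No per-cytosine statistical test against the conversion background; the
  pipeline reports raw ratios.
- DMR windows are not merged into regions, and adjacent-window dependence
  is avoided rather than modelled.
- Fisher's exact test is conservative at low counts; null rejection rates
  approach the nominal level only once windows carry tens of informative
  cytosines, which the default depth provides.
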