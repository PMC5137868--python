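# Methods

This note records the models implemented in `ampliscan`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
construction existed.

## Coordinates

All internal coordinates are 0-based half-open; every reported coordinate
(segments, junction calls, BED names aside) is 1-based inclusive, matching
the convention of genome browsers and published breakpoint positions. An
amplicon reported as `bp5..bp3` has length `bp3 - bp5 + 1`.

## Synthetic data generator

The generator emulates a resequencing study of strains carrying tandem
amplifications, plus the three phenotype assays.

**Reference and haplotypes.** References are uniform i.i.d. ACGT; repeats
are not simulated (the repeat content flanking real amplicons matters for
the *origin* of duplications, not for the detection signal). An
`AmpliconArchitecture` (unit `[bp5, bp3)`, copy count, optional per-copy
deletions) is realized as a haplotype by laying copies strictly head-to-tail;
the haplotype carries an explicit coordinate map to the reference. Adjacent
colinear blocks are merged in the map, so the only map discontinuities are
true junctions (copy-to-copy, and deletion edges). Haplotype length is
`ref + (copies - 1) * unit - total deleted`, and the map round-trips the
sequence byte-for-byte; both are property-tested.

**Read pairs.** Paired 100 bp reads (125 bp supported by parameter) with
Gaussian fragment ("insert") lengths, default mean 250 and sd 25 (sd 10% of
the mean; the studies that motivated the design quote only the mean).
`insert` is the full outer template length, so the insert-size histogram of
a concordant library modes at `insert_mean`. `coverage` is the total
diploid fold-depth over the reference: each haplotype is sampled at
`coverage/2`, giving `coverage * L / (2 * read_length)` pairs per
single-copy genome and a mean of `coverage` read starts per 100 bp window at
100 bp reads. Fragment starts are uniform with 3'-overhanging fragments
shifted inward (no wrap-around). Substitution errors are drawn once per
library as a sparse set keyed by (pair, mate, offset), which keeps output
byte-identical for a seed regardless of how sequences are extracted.
Qualities are constant; indel and quality-model realism, PCR duplicates and
GC bias are deliberately out of scope — conclusions from passing tests
therefore cover CNV/junction signal geometry and estimator calibration, not
robustness to platform-specific artefacts of real libraries.

**Oracle projection instead of mapping.** Reads are projected analytically
through the coordinate map. A read inside one colinear block gets an
all-match CIGAR at its projected position; a read spanning a junction is
anchored on the longer portion (5' portion on ties) with the remainder
soft-clipped and the clip sequence preserved; a read with no colinear
portion of at least `min_anchor = 20` bases is emitted unmapped. This
reproduces exactly the signatures a local aligner leaves at a tandem
junction — soft-clips pinned to the breakpoints, and pairs straddling the
junction mapping with apparent spans near `unit - insert + 2 * read_length`
— while keeping the pipeline deterministic and free of external binaries.
Records use SAM semantics (flags 0x1/0x2/0x10/0x20/0x40/0x80, MAPQ 60,
CIGAR ops M and S only, signed TLEN); `ampliscan.sam` round-trips them
through pysam, and FASTA/FASTQ through Biopython.

**Assay simulators.** qPCR wells follow
`Cq = baseline - log_E(copies/2) + eps`, so a two-copy diploid sits at the
baseline and reads ratio 1; each locus gets a 10-fold dilution series with
steps of `log_E(10)` cycles. Bioassay death counts are
`Binomial(n, c + (1-c) * Phi(slope * (log10 d - log10 LC50)))` with dose-0
controls. Enzyme activities are Gaussian around strictly additive per-copy
means (`A_R ~ N(n_R a_R, sd)`, truncated at 0), with the per-copy resistant
activity defaulting to roughly one quarter of the susceptible one in the
examples, reflecting the activity cost of the resistance substitution.

## Depth-of-coverage CNV calling

Reads are counted once each, in the window containing the leftmost aligned
base (the membership rule is otherwise arbitrary; this one conserves
counts). Windows default to 100 bp. The test/control ratio divides each
track by its own mean count over the normalization region; windows with a
zero control count are flagged undefined and excluded from statistics, never
imputed. Normalization is two-pass: pass 1 uses the whole chromosome to
locate candidate amplifications, pass 2 excludes them so the single-copy
background sits at ratio 1 (the exclusion cannot be specified a priori
without already knowing the duplication).

Segmentation thresholds a running median (21 windows) and keeps runs of at
least `min_run = 20` windows (2 kb); runs separated by gaps shorter than
`min_run` are merged, because at 30x a chance hot- or cold-spot in either
library can dip the smoothed ratio below threshold for a couple of windows
inside a genuine amplification. Defaults `threshold = 1.5` (midway between
single-copy and one extra copy) and `deletion step = 0.25` detect
single-extra-copy events at >= 20x while rejecting Poisson noise; all are
configurable. Copies per chromosome = round(segment mean ratio x control
copies per chromosome). Deletion calls recompute the amplified baseline
from amplicon windows *outside* the deletion runs, so a wide deletion does
not dilute its own reference level; the deleted-copy estimate is
round(baseline - run mean) and the fractional drop (baseline - run)/baseline
(one third for one copy lost out of three).

Window-mean ratios carry a small convexity bias (`E[t/c] ~ k(1 + 1/c̄)`,
about +3% at 30 reads per control window); it is left uncorrected because
the spec-level tolerances absorb it and integer rounding is unaffected.
HMM/CBS segmentation, GC and mappability correction are out of scope.

## Junction resolution

Soft-clips of at least `min_clip = 10` bases are collected from both read
ends; clip boundaries are clustered with a +/-2 bp tolerance and clusters
need `min_support = 3` clips. Within a cluster only clips at the modal
boundary vote. The 3'-side (right-clip) consensus is matched against the
reference at each candidate 5'-side boundary and vice versa (mismatch rate
<= 10%, accommodating sequencing errors); a mutually consistent pair makes a
junction call — tandem when the 5' boundary lies upstream, internal deletion
when downstream. Multiple junctions (tandem + deletion) are resolved
independently from their clusters. The junction consensus is built by
positional voting anchored on the clip boundary rather than by multiple
sequence alignment: for breakpoint-anchored short reads the two are
equivalent, and voting is deterministic and dependency-free. Ties vote N.
Ambiguous pairings (one clipped consensus matching two reference positions)
raise an explicit error rather than guessing; insufficient support raises a
no-call carrying the evidence counts. With substitution errors at 0.5% and
30x, recovery stays exact in >= 95% of replicates and failures are no-calls,
never calls displaced beyond the cluster tolerance.

Discordant pairs (outer span > mean + 4 sd, or orientation other than
inward forward-reverse) corroborate each call; each pair is attributed to
the junction whose implied span it best matches. The relative 5'-3' order
of non-identical copies within the array is not determined — that requires
phased variants, outside automated scope.

In-silico PCR is exact substring matching of both primers on both strands;
the product includes both primers (length = reverse 3' end - forward 5'
start, 1-based). Primer thermodynamics are not modelled.

## qPCR quantification

The vendor's proprietary "advanced relative quantification" is implemented
as the standard efficiency-corrected ratio of a target and a single-copy
reference locus between sample and calibrator. Standard curves are
least-squares fits of Cq on log10 quantity; `E = 10^(-1/slope)`, with an
explicit error for inverted series. Replicate wells (4 by default) are
averaged after dropping wells more than 1 Cq from the replicate median; the
standard error propagates the four replicate-mean variances through the log
ratio. Copies per individual = 2 x ratio (diploid, calibrator single-copy);
per-chromosome counts come from homozygote halving or a known haplotype
remainder, and are otherwise reported as unresolvable — a total alone cannot
distinguish, say, 2+2 from 1+3. Flanking loci pass the single-copy check
within +/-30% of ratio 1 (about two single-plate standard deviations at
typical assay noise).

## Dose-mortality analysis

Abbott's correction `m' = (m - c)/(1 - c)` uses the pooled per-strain
control mortality and refuses strains with c >= 50%. The probit model is a
maximum-likelihood binomial GLM (statsmodels) of corrected mortality on
log10 dose; control rows are excluded after correction.
`LC_p = 10^((z_p - a)/b)`. Confidence intervals use Fieller's theorem on
`(z_p - a)/b`; when the slope is weakly determined (|t| < 4 or g >= 1) the
delta method is used with a logged caveat. The heterogeneity chi-square
sums `(obs - exp)^2 / (n p (1-p))` over dose-replicate cells, df = cells-2.
Calibration: at the standard design (25 larvae x 4 replicates x 6 doses
bracketing the LC50), nominal 95% intervals cover the generating LC50 in
93-97% of replicates (verified at 200 replicates in the test suite).

Strain comparison reports `RR_p` ratios with CIs from summed delta-method
variances of the log10 LCs, pairwise likelihood-ratio tests of a common
LC50 (slopes free; constrained fit by Nelder-Mead on the joint likelihood),
and a compact letter display built greedily over LC50-ordered strains:
maximal runs of mutually non-significant strains share a letter. Hormesis,
mixture models and time-to-death analyses are out of scope.

## Activity statistics

`A_S = A_TOT - A_R`, floored at zero with a warning beyond tolerance (the
inhibited well never reads exactly zero because the chromogenic substrate
degrades spontaneously; an optional per-plate blank can be subtracted before
decomposition). Per-copy activities divide homozygote means by their total
copy number (e.g. total activity / 6 for a three-copies-per-chromosome
homozygote); predictions are linear and homogeneous in copy counts, so the
predicted ratio between genotypes is the ratio of copy-weighted sums —
10/6 = 1.7 (one decimal) for five- versus three-copy homozygotes. The
activity index `(A_x - A_R3)/(A_R5 - A_R3)` is affine-invariant, not clipped
to [0, 1], and undefined when the control means coincide; controls are
plate-matched. The dosage regression is ordinary least squares of A_R on
copy number with a two-sided t test on the slope; sexes should be analysed
separately when recorded, since absolute activities differ between them.

## Pipeline and reproducibility

`run_genomic` chains simulate (optional) -> windowed depth -> two-pass
ratio -> segmentation -> deletion calls -> junction resolution, writing
window and ratio TSVs, a segment BED, a junction JSON and a consolidated
report. Every output embeds the tool version, seed and a SHA-256 hash of
the resolved configuration; identical configuration and seed reproduce
byte-identical outputs. Stage failures abort with the stage name and no
partial report. The `tally` helper cross-tabulates resistance phenotype
against the junction diagnostic and flags resistant individuals lacking a
junction product, which under the single-shared-amplicon model should not
occur.

## Problem sizes

Test and acceptance runs use desk-scale problems chosen to keep the full
suite in the low minutes while preserving the signal regimes of interest:
200 kb-1 Mb references with 12-200 kb amplicons at 30x for CNV and junction
recovery, one 3.7 Mb chromosome for junction recovery at the reported
breakpoint coordinates, 50 random architectures for the breakpoint oracle
suite, and 100-200 replicates for the probit and qPCR calibration checks.

## Known limitations

- Reads are projected, not mapped: mapping ambiguity from genomic repeats,
  mismapping and MAPQ filtering are not exercised.
- Single-chromosome analyses; no joint multi-sample segmentation.
- The DOC ratio assumes the control is single-copy and free of CNVs in the
  normalization region.
- Junction calls assume breakpoint-pinned clips; junctions inside long exact
  repeats would shear into multiple clusters and raise ambiguity errors
  rather than resolve.
- The in-silico PCR requires exact primer matches; near-matches and primer
  thermodynamics are not modelled.
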