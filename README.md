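# ampliscan

Characterization of tandem gene amplifications from short-read data, with the
downstream assays that connect copy number to phenotype. The package was
built around a concrete case: amplification of the *ace-1* locus (the target
of organophosphate and carbamate insecticides) in *Anopheles gambiae*, where
a ~203 kb unit containing *ace-1* and eleven neighbouring genes is repeated
head-to-tail — either as a heterogeneous duplication pairing one susceptible
(S) and one resistant (R) copy, or as homogeneous arrays of 2–5 identical R
copies — and where resistance and enzyme activity scale with the number of
copies. Everything is general to any tandem amplification analysed against a
single-copy reference genome.

It is aimed at researchers analysing copy-number-mediated adaptation who need
a reproducible, fully testable desk-scale pipeline: every input the analysis
consumes can also be simulated with known truth.

## What it computes

**CNV detection from depth of coverage (DOC).** Mapped reads are counted in
adjacent 100 bp windows; the test/control ratio, after scaling each track by
its own chromosome mean outside the candidate region (found in two passes),
is segmented into amplified regions. For an amplification of `k` copies per
chromosome in a homozygote against a single-copy control, the expected ratio
is `k`, so copies/chromosome = round(mean ratio x control copies). Runs
depressed below the amplified baseline inside a segment are called as
intra-amplicon deletions; a deletion in one of three copies drops the ratio
by one third.

**Base-resolution breakpoints and junction.** A read crossing the junction
between adjacent copies aligns to the reference only partially: its clip
boundary pins a breakpoint. Read pairs straddling the junction map with an
apparent span near the amplicon length. `ampliscan` clusters clip
boundaries, votes a per-column consensus over clipped and anchored bases, and
pairs 3'-side with 5'-side clusters by matching the clipped consensus back to
the reference; a 5' boundary upstream of the 3' boundary is a head-to-tail
tandem junction, downstream is an internal deletion. An exact-match
in-silico PCR (primers on either side of the junction, product only on
duplicated templates) reproduces the logic of the junction diagnostic test.

**qPCR copy-number quantification.** Efficiency-corrected relative
quantification against a single-copy reference locus,
`ratio = E_t^(Cq_t,cal - Cq_t,s) / E_r^(Cq_r,cal - Cq_r,s)`, with
efficiencies `E = 10^(-1/slope)` fitted from 10-fold standard-dilution
curves, calibrated so a single-copy diploid reads 1. Flanking loci act as
single-copy controls delimiting the amplicon; zygosity arithmetic converts
totals to copies per chromosome.

**Phenotype statistics.** AChE1 activity decomposition
`A_S = A_TOT - A_R`; per-copy activities and strictly additive predictions
(`n_R a_R + n_S a_S`, e.g. a 10/6 = 1.7 predicted ratio between five- and
three-copy homozygotes); the activity index
`A_I = (A_x - A_R3)/(A_R5 - A_R3)`; OLS regression of insensitive activity on
copy number; Abbott correction `m' = (m - c)/(1 - c)`; maximum-likelihood
probit regression of mortality on log10 dose with Fieller confidence
intervals for LC50/LC95; resistance ratios `RR50 = LC50(strain)/LC50(ref)`
with pairwise likelihood-ratio tests and a compact letter display.

**Synthetic data with oracle alignments.** The simulator realizes any
architecture (copies, per-copy deletions) as a haplotype with an explicit
coordinate map and *projects* reads analytically instead of mapping them, so
soft-clip and discordant-pair signatures are produced exactly and every
emitted base is checkable against the reference.

## Worked example

Simulate a homozygote carrying three tandem copies of a 100 kb unit with a
48 kb deletion in the middle copy, call CNVs against a single-copy library,
and resolve the junctions:

```python
from ampliscan import (
    AmpliconArchitecture, ReadProfile, build_reference, collect_evidence,
    homozygote, project_alignments, resolve_junctions, simulate_read_pairs,
    two_pass_ratio, window_counts, call_internal_deletions,
)

ref = build_reference(1, {"2R": 500_000})
r3 = AmpliconArchitecture("2R", 200_000, 300_000, 3,
                          deletions=((1, 230_000, 278_000),), label="R3")
ss = AmpliconArchitecture("2R", 200_000, 300_000, 1, label="S")

def library(arch, seed):
    sim = simulate_read_pairs(homozygote(ref, arch), ReadProfile(coverage=30.0, seed=seed))
    return list(project_alignments(sim))

test, control = library(r3, 11), library(ss, 12)
t = window_counts(test, ref.lengths)["2R"]
c = window_counts(control, ref.lengths)["2R"]
track, segments = two_pass_ratio(t, c)
seg = segments[0]
print(f"amplified segment {seg.start:,}-{seg.end:,}  mean ratio {seg.mean_ratio:.2f}  "
      f"copies/chromosome {seg.copies}")
for d in call_internal_deletions(track, seg):
    print(f"internal deletion {d.start:,}-{d.end:,}  drop {d.fractional_drop:.2f}  "
          f"deleted copies {d.copies}")
evidence = collect_evidence(test, insert_mean=250, insert_sd=25.0)
for call in resolve_junctions(evidence, ref):
    print(f"{call.kind} junction: bp5={call.bp5:,} bp3={call.bp3:,}  "
          f"clips={call.clip_support} discordant={call.discordant_support}")
```

prints

```
amplified segment 200,001-300,000  mean ratio 2.51  copies/chromosome 3
internal deletion 230,201-278,100  drop 0.33  deleted copies 1
tandem junction: bp5=200,001 bp3=300,000  clips=45 discordant=46
deletion junction: bp5=278,001 bp3=230,000  clips=19 discordant=19
```

The segment mean of 2.51 reflects three copies over just over half the unit
and two over the deleted stretch; the deletion depresses the ratio by one
third of the amplified baseline (one of three copies lost). DOC locates the
deletion to window resolution (230,201–278,100); the junction module pins
both junctions to the exact simulated bases: the tandem junction joins
reference position 300,000 back to 200,001, and the deletion junction joins
230,000 to 278,001 (i.e. bases 230,001–278,000 deleted from one copy).

A command-line interface mirrors the library:
`ampliscan {simulate, depth, ratio, callcnv, junction, pcr, qpcr, activity,
aindex, probit, tally, report}` — see `ampliscan <cmd> --help`.

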