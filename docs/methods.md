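# Methods

`mirsort` re-implements, as a tested pipeline, the bespoke small-RNA
computations used to characterize the two Argonautes (AGO1, AGO2) of the
sea anemone *Nematostella vectensis*: stringent annotation of miRNAs from
AGO immunoprecipitation (IP) libraries, quantification of miRNA sorting
between the two AGOs, guide/star duplex signatures, knockdown direction
statistics, and detection of miRNA precursors that originated from their
own target genes. Every stage runs end to end on synthetic data with
planted ground truth, so each statistic can be checked against what was
planted.

## miRNA annotation from AGO-IP libraries

A candidate is a hairpin precursor with a read stack (collapsed reads
placed at exact-match offsets; multi-mapping reads are counted at every
matching locus and flagged, with a strict single-assignment mode available
by configuration). A bona-fide miRNA must satisfy, in its best-supporting
IP condition (the stage × AGO with most guide reads):

* **(a) enrichment** — replicate-averaged guide RPM in the IP more than
  3-fold above the stage-matched IgG control mean. The IgG denominator
  carries an additive pseudocount equal to the RPM of a single raw read,
  so an empty control yields a finite fold.
* **(b) 5' homogeneity** — the modal 5' offset carries at least 75 % of
  guide-read counts. The paper quantifies "homogeneous 5' end" only
  qualitatively; 0.75 is this package's default and is configurable.
* **(c) strand selection** — summed guide/star counts strictly above 2.
  Candidates with zero star reads pass and are held in the separate
  *starless* class.
* **(d) support** — guide reads in both biological replicates, with ≥ 70
  raw reads in at least one. Raw (not normalized) counts are used; the
  source analysis quantified with a read counter whose outputs are raw.
* **(e) duplex** — at least 16 hybridized nucleotides in the predicted
  guide/star duplex. "Hybridized" counts Watson-Crick plus G:U wobble
  pairs (wobbles pair thermodynamically; a `gu_is_mismatch` flag flips
  this reading).

plus an expression floor of ≥ 20 RPM in at least one library. RPM is
`count × 10⁶ / genome-mapped reads`; knockdown libraries are instead
normalized to the mean of the four synthetic spike-in miRNAs, which is
robust to the global composition shifts a knockdown causes.

Rejected candidates always carry the list of failed criteria with the
measured values, so audits and threshold-relaxation (monotonicity) checks
are cheap.

## Folding and duplex signatures

Precursors are folded with the Nussinov maximum-base-pair dynamic program
(AU/GC/GU pairs, minimum loop 3 nt) with a deterministic traceback
(pairing of the interval ends preferred over bifurcation, then the
smallest split index). This is deliberately not a thermodynamic model: it
is exactly checkable against exhaustive structure enumeration, which the
test suite and acceptance script do, and duplex topology is all the
annotation criteria need. A pre-computed pairing map (e.g. from an
external folder, or the generator's planted structure) can be attached to
a hairpin and overrides folding.

The guide/star duplex classifies every guide position (1-based from the
guide 5' end) as WC, G:U, mismatch, or uncovered. Uncovered positions —
typically the 2-nt 3' overhangs — are excluded from mismatch denominators.
Central-mismatch calls use positions 10–12 by default (the region override
`(9, 11)` reproduces the fly convention). Per-class signatures include the
per-position mismatch frequency profile, the 5'-nucleotide frequency
matrix, and mean guide lengths with a two-sample Student t-test.

## AGO preference and knockdown statistics

Per stage, replicate-averaged guide RPMs in the AGO1 and AGO2 IPs give the
preference fraction `f = AGO1 / (AGO1 + AGO2)` for every miRNA above
20 RPM in at least one library. Classes use strict thresholds — `f > 0.7`
preference, `f > 0.9` strong preference, mirrored for AGO2 — with exact
boundary values falling to the weaker class; the implementation
canonicalizes to the preferred side so classification is exactly
antisymmetric under `f → 1 − f`. A miRNA with no preference in any stage
is "no preference" overall; opposite directions across stages are flagged
"mixed".

Knockdown responses use an exact sign test: each miRNA is classed
down/up by its spike-in-normalized fold change (exact ties are
uninformative and excluded), and the p-value is the exact binomial tail
under P(down) = 0.5 — one-tailed, or doubled and capped at 1 for the
default two-tailed test. For 6 of 7 down these give 0.0625 and 0.125
respectively. Strand-selection shifts are summarized as per-miRNA
guide-FC/star-FC ratios with a two-tailed Wilcoxon signed-rank test on the
log-ratios (no normality assumption; a paired-t option is provided).
Methylation analysis compares periodate-oxidized to untreated libraries:
miRNAs under 50 raw reads in the untreated library are removed, per-miRNA
retention ratios are summarized per sorting class, and a paired two-tailed
t-test asks whether levels drop after oxidation.

## Origin-from-target signatures

Target sites are predicted with an Allen-type expectation score: sliding
a guide-length window over each transcript (antisense orientation,
no gaps), each guide position contributes 0 for a perfect complement, 0.5
for G:U, 1.0 for a mismatch, multiplied by 1.5 inside the seed region
(positions 2–13); windows scoring ≤ 2.5 are reported. The exact constants
of the web service used by the original study are not published; all
constants here are configurable, and an externally produced site table can
be imported instead.

For the origin scan, each guide is extracted with 7 nt of stem-side and
6 nt of loop-side precursor flank (mirrored for 3p-arm guides) and aligned
by Smith-Waterman (match +5, mismatch −4, affine gaps: 15 to open, 2 per
extension, a length-g gap costing `15 + 2(g−1)`) against the reverse
complement of each transcript with a predicted site, so target
complementarity appears as alignment identity. A signature requires

1. the alignment footprint to overlap a predicted site, and
2. at least 6 consecutive matched columns whose extended-guide coordinates
   lie in a flank, belonging to a matched run that crosses the guide/flank
   boundary.

Requirement 2's boundary rule automates the original study's manual check
that the guide *and* its flanks aligned to the correct site: without it,
the aligner occasionally buys a detached 6-match in nearby sequence with a
gap, which is homology near the site, not homology extending from it. A
miRNA homologous to several targets counts once.

Significance comes from a permutation null: 50 lists in which each
miRNA's flank letters are independently permuted (guide fixed, per-flank
nucleotide composition preserved exactly; a dinucleotide-preserving
rejection-sampling mode exists but is not the default, as the original
null is described only as sequence shuffling). The observed count is
compared with the null mean ± SE and maximum.

## The synthetic study

The generator's defaults are the study conditions: three developmental
stages, two biological replicates per pulldown per stage, 2 × 10⁶
genome-mapped reads per library, a flat IgG background of 2 RPM, four
spike-in species, 100 hairpins, and negative-binomial counts with
dispersion 0.1 (the variance model is this package's choice; means follow
expression × AGO preference). Guides are ~20–23 nt with a 5'-terminal U
bias; per-hairpin guide:star ratios are log-uniform in [4, 50],
reflecting the unusually strong strand selection in this system; expression
is log-uniform over 150–10⁴ RPM. Planted sorting classes mirror the
reported populations: 40 % AGO1-preferring, 40 % AGO2-preferring, 20 %
unpreferring, with preferring miRNAs split between a strong band
(0.95–0.995) and a moderate band (0.75–0.88) — the bimodal occupancy the
IP data show. Class-specific guide-length distributions have means 22.2,
21.0 and 21.5 nt, and central mismatches are planted with probability
26/40 (AGO1 class), 11/60 (AGO2 class) and 0.30 (no preference), so the
pipeline's recovered signatures can be compared against these planted
rates.

Precursor construction places guide and star antiparallel with 2-nt 3'
overhangs; a planted mismatch replaces the facing star base with a
non-pairing letter chosen to avoid pairing with neighbouring guide bases
(otherwise a ±1 register shift can zip the bubble). Loops are drawn from a
mutually non-pairing two-letter alphabet that also avoids the reachable
overhang bases, and 10-nt random pads on both sides emulate transcript
sequence beyond the Dicer products (they supply the stem-side flank of the
origin scan). The stored fold describes the excised core and is verified
against the Nussinov module at construction time; guides whose sequence
admits an equal-score alternative structure are resampled. Heavily
mismatched plants (the criterion-(e) failure class) keep their planted map
as a supplied fold, since a 15-pair stem is legitimately not the
maximum-pair structure.

For annotation validation, 20 of 100 hairpins are planted single-criterion
failures (four per criterion). These receive deterministic counts at their
defining margins — e.g. replicate guide reads of exactly 60 and 65 for the
read-count failure — because a near-threshold plant under negative-binomial
noise would fail its criterion only with coin-flip probability and the
planted label would be meaningless. Origin validation plants full-flank
homology runs (7 nt stem-side or 6 nt loop-side) into the transcripts of
10 miRNAs; the remaining transcripts are decoys carrying only the
guide-complementary site in random backbone. (A composition-preserving
shuffled decoy context is available, but with the reduced pad/loop
alphabets it would share letters with the true flank far more often than
natural sequence and plant spurious homology into the no-homology class.)

What the generator does **not** emulate: sequencing error, adapter
artifacts, piRNA/siRNA background classes beyond the flat IgG floor,
genome-scale multi-mapping, thermodynamically realistic loops (reduced
alphabet), or natural flank composition (pads are i.i.d. uniform). Passing
the synthetic-recovery suite therefore demonstrates correctness of the
computations and thresholds under the stated noise model, not performance
on real libraries.

## Problem sizes and numerics

The shipped analyses use 100 hairpins, 18 IP libraries, ~400-nt
transcripts and 50-list nulls; the origin sweep repeats the full
observed-vs-null comparison over 20 seeds. These sizes make every result
reproducible in minutes on one core while keeping binomial sampling error
on recovered fractions a few percent. The Smith-Waterman kernel is
numba-compiled when numba is importable and falls back to pure Python
otherwise. Ties are resolved deterministically throughout (documented
traceback orders; sorted iteration everywhere); all randomness flows
through seeded `numpy.random.Generator` instances, and re-running any
stage with the same seed is byte-identical.

## Known limitations

* Nussinov folding ignores stacking energies; duplexes with many
  mismatches have degenerate maximum-pair structures, which is why
  supplied folds are first-class inputs.
* The expectation-score constants approximate a web service whose exact
  parameterization is unpublished; results that depend on the seed-region
  factor should be reported with the constants used.
* The 70-read support threshold is applied to raw counts and criterion (a)
  enrichment per stage; the source description leaves both choices open
  (config-overridable).
* `smith_waterman` reports a single optimal alignment; co-optimal
  alignments are resolved by the documented tie-break, not enumerated.
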