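# Methods

This note documents the models, parameters and design decisions behind
srna-seeker, and what the synthetic-data tests do and do not establish.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and BED6 (0-based half-open) convert at the I/O boundary. A single circular
replicon is assumed: the gap spanning the origin is treated as one IGR, and
the synthetic generator guarantees alignments never wrap. Strandless BED
lines default to '+' with a warning, because read counting is unstranded
throughout.

## IGR extraction

Occupied blocks are built from protein-coding (and "other") features,
merged where they overlap so gaps can never have negative length; tRNA/rRNA
features do not bound gaps but veto any trimmed IGR they intersect — this
mirrors an ORF-derived IGR definition followed by removal of structured-RNA
loci. Trimming is a flat 40 bp per gap side; the ≥ 120 bp length filter is
applied *after* trimming and is inclusive (a 200 bp raw gap → 120 bp trimmed
IGR passes). Duplicate trimmed intervals collapse. Linear-genome edge gaps
are retained but flagged: with only one flanking gene the 15% expression
rule below is undefined, so they are excluded from sRNA calling.

## Transcription signals

The promoter and terminator scanners are deliberately transparent scoring
schemes whose role is a boolean gate per IGR ("is a promoter/terminator
present?"), not bit-faithful reimplementations of neural-network or
thermodynamic predictors.

**Promoters.** Two log-odds PWMs (log2, uniform background) built from the
sigma-70 consensus hexamers with consensus-base probability 0.85 (shipped as
`data/sigma70_pwm.json`), joined over a spacer of 15–19 nt with a penalty
of 0.5 bits per bp of deviation from 17. Score = PWM(−35) + PWM(−10) +
spacer penalty; maximum 21.19. Overlapping hits reduce to best-scoring local
maxima. Default calling threshold: **14.0** — roughly "one mismatch from
consensus at any legal spacer".

**Terminators.** Exhaustive enumeration of hairpins with stem 4–15 bp
(≤ 1 mismatch, no bulges) and loop 3–10 nt. Pair scores G:C = +2, A:T = +1,
G:U = +0.5, mismatch = −2; loop penalty 0.5 per nt beyond 3. The U-tract
score over the 8 nt after the stem uses weights (1.0, 1.0, 0.9, 0.8, 0.7,
0.6, 0.5, 0.4) on T positions; total = hairpin + 2 × tail. Defaults:
**hairpin ≥ 12.0 and tail ≥ 4.0**.

Thresholds were calibrated once on random GC-60% sequence (400 draws of
520 nt, both strands): the defaults give ≈ 0.25% (promoter) and ≈ 0.5%
(terminator) false hits per IGR, while planted signals score 21.19 and
15.5/5.9 — the gates are therefore far from both distributions. Much looser
terminator settings (e.g. hairpin ≥ 8, tail ≥ 2.5) admit a spurious
terminator in most GC-rich IGRs and are unusable for calling; all values
are exposed in `TerminatorParams` and the pipeline config.

A **complete transcriptional unit** requires ≥ 1 promoter with ≥ 1
terminator downstream of it in the same strand's transcription direction;
if both strands qualify, '+' is reported.

## Expression

FASTQ QC first trims read ends with quality ≤ 2 (the end-trimming threshold
is this package's choice; the decisive filter is the published one), then
keeps reads with length strictly > 20 and ≥ 80% of bases strictly above
Q20. PCR duplicates collapse by identical (start, end, strand). A read
counts toward every feature covering ≥ 50% of its length (strand-agnostic,
multi-assignment allowed) — a simple, deterministic, oracle-testable
assignment rule. `total_mapped` per sample is the deduplicated library
size, not the per-feature sum. RPKM is zero when the count is zero.

## sRNA calling

Called iff complete unit AND RPKM(IGR) ≥ 1.15 × RPKM(flank) for *both*
flanks, inclusive — inclusivity keeps the rule monotone-closed (raising the
IGR's expression can never un-call it). The comparison is within-sample;
the final set is the union of per-sample calls, matching a
union-across-conditions catalogue. Reported coordinates are
strand-polarized (minus-strand rows print start > end) with a three-glyph
orientation string (left flank / sRNA / right flank; → for '+').

## Differential expression without replicates

Median normalization rescales each sample so that its median RPKM over
expressed features (RPKM > 0) equals the geometric mean of the sample
medians — a symmetric choice among the family of "median methods"; it is
idempotent and leaves equal samples untouched. Fold changes use a 0.5-RPKM
pseudocount to avoid infinities at zeros. Significance is an exact
conditional binomial test on deduplicated counts (Audic–Claverie style):
given n = a + b, a ~ Binomial(n, T_a/(T_a+T_b)) under the null; the
two-sided p sums probabilities of outcomes no more likely than the observed
one (ties included with a 1e−7 relative tolerance). Status: up if
log2 FC > 1 and p < 0.05; down if < −1 and p < 0.05; else ns — both cutoffs
strict. A Benjamini–Hochberg FDR column is reported for information only.
DEG-set overlaps are reported per direction against a reference condition
with the denominator named explicitly (|A ∩ R| / |A|).

At a simulated equal-proportion null (Poisson(200) count pairs, equal
library sizes) the test's empirical size at α = 0.05 is ≈ 0.042 over
10,000 replicates — slightly conservative, as expected for a discrete
exact test.

## Target prediction and networks

Maximal perfect reverse-complement matches ≥ 8 nt between the sRNA
transcript and the −30..+20 window around each start codon (the region
where antisense pairing occludes ribosome binding), scored G:C = 2 /
A:T = 1 with an edge threshold of 10; one best edge per (sRNA, gene). This
perfect-seed model finds every planted antisense seed by construction but,
unlike a hybridization-energy model, also admits short spurious seeds in
random sequence — network-level claims on synthetic data concern planted
edges (recall) and degree bookkeeping, not edge-level precision. COG
categories are consumed as input labels (gene → letter string), never
computed.

## Synthetic data: what it emulates, and what it does not

`SimConfig` defaults: 50 kb circular genome at GC 0.60, 45 CDS genes
(540–640 bp) plus tRNA/rRNA features, 11 planted sRNAs and 21 decoys in
560–620 bp inter-gene gaps, four conditions (control, acid, bile, git),
7,000 reads of 50 nt per sample, negative-binomial counts with size 25
(CV² = 1/mean + 0.04, typical bulk-RNA-seq overdispersion), 20% exact PCR
duplicates, and a 10% QC-failing FASTQ fraction.

Planted sRNAs carry a consensus promoter (spacer 17), an 8-bp all-GC stem
terminator with an 8-T tail, and base expression 2.0 × their higher flank;
decoys omit exactly one requirement (no promoter / no terminator /
expression 0.25 × the lower flank, signal-bearing decoys at 1.6 ×). Planted
sRNA fold changes across conditions default to the published 11 × 3 stress
matrix, so one sRNA carries the 4.12× acid response; ten genes far from any
planted IGR receive ±4-fold (|log2 FC| = 2) changes with staggered
membership across conditions to exercise DEG calling and overlap counts.

Reads are emitted as already-aligned intervals (alignment is out of scope)
at *distinct* (position, strand) slots within each feature, with the PCR
duplicate fraction layered on as exact copies. This makes deduplication
recover exactly the drawn negative-binomial counts. The depth default
follows from this design: each feature supports at most 2 × (length − 49)
distinct alignments, and per-feature counts — including the largest planted
fold change — must stay well below that capacity; 7,000 reads/sample keeps
the most extreme feature below ~65% of capacity. The generator does not
model sequencing errors, rRNA carry-over, coverage bias within features or
multi-mapping; passing tests therefore establish the pipeline's rule logic
and statistical calibration, not robustness to real-library artifacts.

## Problem sizes used in tests and the acceptance script

Planted-recovery checks run the full pipeline over 20 seeds at the default
configuration (~1 minute); the null calibration uses 10,000 simulated
contrasts; scanner-vs-brute-force equivalence uses dozens of short (≤ 25 nt
terminator, 60 nt promoter) fixtures where exhaustive enumeration is
trivial. The published-catalogue reductions run on the bundled 13-row and
11×3 tables. Genome-scale checks against the real CP007423 accession are
available via `srna_seeker.reference` when the user supplies the files; the
genome is not bundled.

## Known limitations

Single replicon only; no replicate-aware dispersion modeling (the exact
test conditions on totals and is anti-conservative under strong biological
overdispersion); no free-energy folding for terminators or targets; sRNA
boundaries are IGR boundaries (no 5'/3' refinement from coverage); the
promoter scanner at default threshold accepts at most one mismatch from
consensus, trading sensitivity for the precision the calling rule needs.
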