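# Methods

This note documents the models, conventions, and numerical choices behind
`utrome`. It is written for users who need to know exactly what the toolkit
computes and what its tests do and do not demonstrate.

## The cloning model

### Locus anatomy

For each protein-coding gene the cloning insert is the genomic interval
from the first base of the STOP codon through the annotated 3' end of the
transcript plus a fixed downstream offset (default 150 nt):

    insert = STOP codon (3 nt) + 3'UTR + downstream offset
    insert length = 3 + UTR length + 150

Anchoring at the STOP keeps the insert in frame with STOP-less ORF clone
collections, so an ORF entry and its 3'UTR entry can be recombined into a
single reporter with the natural termination codon at the junction. The
downstream offset captures 3'-end processing elements (cleavage and
polyadenylation signals) that can lie past the annotated transcript end;
it also subsumes short 3'UTR extensions from alternative polyadenylation,
which is why the toolkit does no APA inference of its own.

Coordinates are 0-based half-open everywhere inside the package. GTF and
GFF3 input (1-based closed) is converted on read, BED output is 0-based
half-open. The downstream offset is applied as `end + 150` half-open, so
its contribution to the insert length is exactly 150 bases.

### Transcript choice

When a gene has several transcripts, the one whose 3' end is most distal
in the direction of transcription wins. Total exonic length is
deliberately not the criterion: the rule exists to place the downstream
cloning boundary, so only 3'-end distality matters. Ties break on
lexicographically smallest transcript ID, making the choice deterministic.

### STOP codon resolution

The CDS end is taken from an explicit `stop_codon` feature when present.
Without one, the last three CDS bases are checked for a STOP (annotations
that fold the STOP into the CDS), then the three bases immediately past
the CDS (annotations that exclude it). A transcript whose STOP cannot be
resolved, is split across exons, or does not lie inside the last exon is
emitted as a design-failure record with a reason code — never silently
skipped, because genomic PCR needs a contiguous template for the forward
primer and downstream bookkeeping needs the full accounting of the panel.
An insert that would run past the contig end is a `downstream overflow`
failure.

`N` bases are allowed inside an insert but not inside a primer core:
ambiguity only matters where oligos anneal.

## Primer design

### Growth rule

Primer cores are grown deterministically rather than optimized:

* The forward core's 3' terminus is pinned to the last base of the STOP
  codon; the core grows 5'-ward into the coding tail of the last exon, one
  base at a time, from 18 nt up to 35 nt, stopping at the first length
  whose melting temperature reaches the 60 degC target.
* The reverse core's outer boundary is pinned to the downstream end of the
  insert (3' end + 150); it grows gene-ward along the opposite strand
  under the same rule. Pinning the outer boundary is what fixes the
  amplicon's downstream edge at the +150 position.

A core that never reaches the target is capped at 35 nt and flagged.
Cores with Tm outside the 50–76 degC window are flagged, not rejected: a
touchdown PCR program tolerates a wide Tm range, and rejecting would
silently shrink the panel. A STOP closer than 18 nt to the last exon's
start leaves no runway and is a design failure.

The grow-until-Tm rule, its bounds, and the 60 degC target are declared
conventions of this package chosen for reproducibility; fixed-length
designs could be emulated by setting `min_len == max_len`.

### Melting temperature

Nearest-neighbor thermodynamics with the unified parameter set, 50 mM
monovalent salt, 500 nM total oligo (C_T/4 duplex term), and the entropic
salt correction `0.368·(N−1)·ln[Na+]`; computed via Biopython's
`MeltingTemp`. Below 14 nt the Wallace rule `2(A+T)+4(G+C)` applies. The
test suite checks the nearest-neighbor path against an independent
hand-summed implementation of the published parameters to ±0.1 degC.

### Gateway tails

The attB2 (28 nt) and attB3 (26 nt) recombination sequences are prepended
verbatim to forward and reverse cores. Tails never participate in genomic
annealing checks — they only recombine — but they do count toward product
length. Double-tailing is a hard error.

### Panel filter

Inserts outside 200–2,500 nt are excluded with reason `length filter`
(configurable). The filter is applied to the full insert length (STOP +
UTR + 150).

## In-silico touchdown PCR

### Schedule

The touchdown phase enumerates annealing temperatures from the start down
to, but excluding, the floor (floor-exclusive convention): 66→50 degC at
1 degC/cycle yields exactly 16 cycles (66..51), followed by a constant
phase (default 15 cycles at 55 degC), 31 cycles total. The floor-exclusive
convention is a deliberate choice: an inclusive enumeration of 66..50
would contain 17 values, and the program is defined by its cycle count.
A pair's *first productive cycle* is the first cycle whose annealing
temperature both core Tms meet; it is non-increasing in Tm.

### Binding and products

Cores bind where they match the genome exactly (default). When internal
mismatches are allowed, the five bases at the 3' terminus must still match
exactly — polymerase extension requires a paired 3' end. Convergent
forward/reverse site pairs within a size cap are enumerated; the number of
alternative pairings minus one is reported as ambiguity. Single-primer
(F/F or R/R) products and non-specific smearing are not modeled.

The reported product is the *cloning insert prediction*: attB2 tail + the
genomic span from the forward core's 3'-terminal codon (the STOP, for
designed pairs) through the reverse core's outer boundary + the
reverse-complemented attB3 tail, in mRNA sense. Its length is therefore
insert length + 54 for uniquely-binding designed pairs. The physical
amplicon additionally carries the forward-primer bases that overlap the
ORF upstream of the STOP; they are excluded from the reported product so
that product accounting matches the insert definition used everywhere
else in the toolkit.

### Size screen

Gel-style screening passes a product when `|observed − expected| /
expected ≤ 0.15`. The 15% default approximates agarose resolution and is
configurable; the relative error is deliberately asymmetric in its
arguments (the expected length is the denominator).

## Clone verification

### Seeded alignment

A BLAT-style two-stage search, implemented in the package (not a wrapper):
an 11-mer index over the panel's expected inserts nominates candidate
references ranked by best shared-seed diagonal count; the top candidates
are re-scored with a banded affine-gap local alignment (numba kernel)
centered on the dominant diagonal, band half-width 32, scoring match +1,
mismatch −1, gap open −2, gap extend −1. Hits below 0.5 identity over
aligned columns are discarded; ordering is score-descending with target-ID
tie-break. The test suite checks the seeded search against an exhaustive
unbanded local alignment over all read × reference pairs (independent C
implementation with identical scoring); agreement is required for ≥ 99% of
reads — the seeded path can only miss when no seed survives, which the
read simulator's ≤ 5% substitution rate makes vanishingly rare.

### Verdicts

After trimming the vector flank (located with up to 2 mismatches; a read
without the flank passes through flagged), a read is

* `verified` — best hit is the claimed gene, identity ≥ 0.95, read
  coverage ≥ 0.90, and score margin over the runner-up ≥ 10%;
* `misassigned` — same thresholds met but the best hit is a different
  gene (a well swap; the evidence names the actual gene);
* `sequence_fail` — a hit exists but thresholds are unmet;
* `no_hit` — nothing aligns (including reads shorter than the seed).

The thresholds are conventions chosen for Sanger-quality error profiles
and are configurable. One verified well suffices per gene; genes with no
verified call go to the second-pass re-array list with their original
primer pairs, mirroring the two-pass cloning flow.

## Dual-luciferase screen analysis

### Model

Firefly luciferase carries the test 3'UTR; Renilla on the same construct
is the transfection control. Per-well normalized signal is
`r = firefly / renilla`; the repression index of a 3'UTR for a query
miRNA is the replicate-paired ratio `RI_i = r(query, i) / r(control, i)`,
with the mean RI the arithmetic mean over replicates. Pairing by replicate
cancels plate-level batch effects; a pooled-control mode (divide by the
mean control ratio) is available by flag. Wells with Renilla at or below
a floor are dropped and recorded, decrementing the replicate count; a
replicate present on only one side without a recorded drop is an error.

### Hit calling

Two-sided one-sample t-test of per-replicate log2(RI) against 0 — the log
scale symmetrizes ratio noise. `repressed_hit` requires mean RI < 0.8 and
p < 0.05; `enhanced` requires mean RI > 1.25 (the reciprocal cutoff,
making the qualitatively observed enhancement direction testable) with the
same alpha. Fewer than two replicates yields `none` with an
`underpowered` flag. No multiple-testing correction is applied by default,
matching the raw-p convention of this assay family; Benjamini–Hochberg is
available by flag. A Welch two-sample mode on raw ratios is not offered;
the paired design makes the one-sample log-ratio test the natural choice,
and the pooled-control flag covers unpaired layouts.

### Control constructs

Positive/negative miRNA controls insert the reverse complement of the
first 22 nt of the mature 3p arm (positive) or 5p arm (negative) into an
SV40-derived reporter 3'UTR at a chosen offset — a perfect-complement
target site that must repress, next to an arm that should not load into
the silencing complex. Arms are taken as input (RNA or DNA alphabet);
arms shorter than 22 nt are used whole and flagged.

## QC statistics

Medians use the lower-middle convention for even counts, so a reported
median is always an observed length. Histogram edges start at 0 with a
fixed bin width. Per-contig coverage is the fraction of annotated genes
present in the cloned library. Success-by-length bins default to
[0,500), [500,1000), [1000,1500), [1500,2000), [2000,inf); empty bins
report an undefined (NaN) percentage, deliberately distinct from 0%.

## Synthetic fixtures

The generators emulate the *structure* the pipeline depends on, with
known truth and byte-identical regeneration under a fixed seed:

* **Genomes** — two-exon genes on both strands, STOP inside the last
  exon, UTR lengths uniform on 150–3,000 nt (straddling the panel filter
  so both passing and filtered genes exist), ≥ 220 nt intergenic runway
  on the downstream side of every 3' end, and a 3'-shorter second isoform
  for a quarter of genes. Base composition is uniform random; there are
  no repeats, no pseudogenes, no N runs, and no sequence homology between
  genes, so off-target priming and paralog cross-alignment are *not*
  exercised — passing tests bound algorithmic correctness, not
  specificity on real genomes.
* **Reads** — substitution-only errors at a configurable rate (indels are
  not simulated; the alignment layer handles them but the error model
  stays simple so the exhaustive oracle is meaningful), random start
  inside a fixed synthetic vector flank whose final 30 nt are the
  published sequencing-primer site, and optional planted well swaps
  recorded in truth.
* **Plates** — multiplicative lognormal noise with unit mean and
  coefficient of variation `cv` (the standard model for luminescence),
  replicate-paired wells, planted true RI per UTR. Note that the
  arithmetic mean of a null ratio estimate is not exactly 1: with four
  noise factors (two inverted) the expectation is `(1+cv^2)^2` (about
  1.02 at cv = 0.10). The estimator is exactly unbiased on the log scale,
  which is what the calibration tests check; hit calling is likewise
  log-scale and unaffected.

Monte-Carlo calibration, run at 1,000 simulated UTRs, 5 replicates,
cv = 0.10: the null repressed-hit fraction stays within three Monte-Carlo
standard errors of the nominal alpha, and a planted true RI of 0.6 is
recovered as a hit in well over 80% of simulations (observed ≈ 99%).
These are properties of the pipeline under the simulator's idealized
noise; real screens have plate effects, transfection variability, and
heavier tails that the simulator does not model.

## Problem sizes and determinism

Default test and acceptance workloads — ~100-gene fixture genomes, a
50-reference × 200-read alignment-oracle comparison, and 1,000-UTR
Monte-Carlo screens — were chosen as the smallest sizes at which the
statistical assertions have negligible flake probability; the whole suite
runs in a couple of minutes on one CPU. All randomness flows through
`numpy.random.default_rng` seeds; every generator is a pure function of
its parameters and seed.

## Known limitations

* No off-target/specificity screening of primers against a background
  genome, and no hairpin/dimer thermodynamics beyond Tm.
* No polymerase kinetics or amplification-efficiency modeling; the first
  productive cycle is a threshold statement about annealing only.
* No chromatogram base-calling; reads enter as sequences (with optional
  qualities used only for tail trimming).
* No transcript assembly or APA inference; the annotation is trusted.
* The repression analysis assumes the firefly reporter carries the test
  UTR and that controls share the construct backbone; it does not model
  transfection-efficiency differences beyond what Renilla normalization
  removes.
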