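# Methods

This note records the models, conventions, numerical choices and known
limitations behind `mitocomp`, in the order the pipeline applies them.

## Coordinates, strands and the gene vocabulary

All coordinates are 0-based half-open on the linearised circle; GenBank's
1-based inclusive convention exists only at the file boundary. A feature
spanning the origin of a circular genome is stored with `end > length`
("wraparound"); consumers normalise modulo the length, and the GenBank
writer emits such features as origin-spanning `join` locations. Strands are
labelled J (majority, GenBank `+`) and N (minority), the convention of the
insect-mitogenome literature; control features carry J by definition.

The vocabulary is the canonical 37-gene set — 13 PCGs, 22 tRNAs with the
duplicated leucine/serine pairs resolved as trnL1 = Leu(CUN), trnL2 =
Leu(UUR), trnS1 = Ser(AGN), trnS2 = Ser(UCN) — plus rrnS/rrnL and the
control-region markers CR, CR1, CR2. The GenBank name map covers gene
symbols, product names and anticodon notes; unmappable features degrade to
kind `noncoding` with a warning rather than failing, so foreign records
still parse.

The embedded ancestral order is the *Drosophila*-type insect ground
pattern, stored with strands as versioned data. Named tRNA clusters (IQM,
WCY, ARNS1EF, TP) label the classical rearrangement hotspots; a
rearrangement report names the cluster when every event falls inside one,
otherwise the minimal contiguous ancestral block.

## Composition statistics

Skews are computed on uppercase sequence with N ignored entirely; a zero
denominator yields an undefined (`None`) skew, never 0. Report output
rounds skews to 3 decimals and percentages to 1 decimal, the printed
precision of the descriptive-genomics literature, so comparisons against
published tables are well defined.

Codon statistics use NCBI translation table 5 (invertebrate mitochondrial):
AUA is Met, AGR is Ser, so the Met family is {ATA, ATG} and serine has an
eight-codon family. RSCU for codon *c* in family *F* is
`count(c)·|F| / Σ count(F)`; terminal stops and incomplete trailing bases
are excluded from counts, stop codons never enter amino-acid percentages,
and the family-sum identity Σ RSCU = |F| is enforced to 1e−9 in tests.

Start codons ATN/GTG/TTG are "standard". An incomplete stop (trailing T or
TA, completed to UAA by polyadenylation) is only called when the gene
length is not a codon multiple *and* the next feature in transcription
direction starts within 2 bp — a bare trailing T in the middle of a long
spacer is not a stop.

Junction accounting reports the signed gap for every adjacent feature pair
on the circle (negative = overlap, with the shared sequence extracted); the
signed gaps satisfy the closure identity Σ lengths + Σ gaps = genome
length on every genome, which the tests assert.

NCR homology scanning uses Biopython's local `PairwiseAligner` with a fixed
scheme — match +1, mismatch −1, gap open −2, gap extend −1 — on both
strands of each candidate gene; identity is matches over alignment columns
(gaps included), with a 55% floor below which no hit is reported. The
scheme is pinned so reported identities are reproducible; identity values
for diverged gene remnants are alignment-parameter dependent by a few
points, which is why the benchmark band for the ND1-derived NCR is
[65%, 80%] rather than a point value.

## Gene-order comparison

Equality of signed orders is rotation-invariant; serialisation linearises
at trnI's slot. Inversions are sign flips. Translocations are the union of
all minimal gene sets whose removal makes the remaining signed orders
cyclically equal — signs of inverted genes are normalised first, so a pure
in-place inversion is not also counted as a translocation — plus any gene
whose immediate neighbours became control-region segments on both sides
(moved into the CR) or stopped being so. The exact subset search covers up
to 4 moved genes, far beyond any reported insect case; beyond that a
greedy peel is used and flagged. Breakpoints are orientation-aware signed
adjacencies, counting (a, b) and (−b, −a) as the same junction; the count
is symmetric because both adjacency sets have the same cardinality.

## TDRL search

`apply_tdrl` duplicates a window in tandem and keeps, per gene, the first
or second copy; signs are untouched by construction, which is the formal
content of "TDRL cannot generate inversions". Control markers inside a
window do not count toward retention and default to surviving in both
copies, modelling split control regions as duplication remnants.

The search enumerates events as (window, retention mask) over the
*differing block* only: for every rotation alignment of the two circular
orders, the mismatching positions are rotated into a contiguous block
starting at index 0, and blocks larger than `max_block` (default 12) genes
are not searched because event enumeration is exponential in block size —
every rearrangement cluster reported in insects involves far fewer genes.
Searching every rotation framing keeps the minimal event count correct
under circular equality; this was verified exhaustively against the
independent reachability oracle on all sign-free permutations of 2–7 genes
at depth ≤ 2 (5,912 cases, exact agreement).

All minimal scenarios are returned, deduplicated by their sequence of
intermediate orders (two event lists that visit the same orders are the
same scenario); the retained representative is the first in the canonical
event ordering (window start, window length, retention encoded
first < second). Every scenario re-validates itself at construction: the
events are applied and the result compared to the target, never assumed.
Event enumeration per order is cached module-wide, which is what makes the
exhaustive 7-gene verification run in seconds.

The mechanism decision rule: identical → none; no inversions and a TDRL
scenario within `max_events` (default 2; the reported insect cases need 1)
→ TDRL; inverted genes that also translocated → recombination
(inversion + translocation); inversions in place → recombination
(inversion); otherwise unexplained.

## Tandem-repeat detection

Candidate periods are distances between repeated 8-mers; a distance below
`min_unit` contributes its smallest in-bounds multiple, and the primitive-
period reduction at the end may therefore report a unit below `min_unit`
when a longer candidate is explained by a shorter sub-period (a 4 bp exact
repeat is found via its 8 bp candidate and reported as 4 bp — the
smallest-period convention, matching how such arrays are printed).

For each candidate period p the boolean lag-match profile `s[i] == s[i+p]`
is scored +2/−7 (match/mismatch), and maximal positive excursions of the
score walk reaching 24 seed candidate arrays. The −7 mismatch penalty gives
the walk a strongly negative drift on random sequence; threshold 24 keeps
the per-trial false-positive probability on 2 kb of i.i.d. sequence well
below 1% across all candidate periods (measured: 0/200 trials), while a
perfect 2 × 12 bp array still scores exactly 24 and is found.

A seeded segment is snapped to unit tiling and extended copy by copy while
adjacent copies match above `(min_identity/100)²` (adjacent copies of
units each diverged d from the consensus match at roughly (1−d)²); the
column-majority consensus is built, identity gated at `min_identity`
(default 80%, reflecting the near-identical units maintained by concerted
evolution), the primitive period substituted if it explains the consensus,
and fractional boundary copies attached. Copy number is reported both as
the real span/unit ratio and rounded to the nearest integer for
"N × L bp"-style comparison. Overlapping candidates are resolved greedily
by copies × identity, ties to the smaller unit then leftmost start.
Detection on a circular control region doubles the sequence once and
reports modulo the original length. The detector handles substitution
divergence only (no indel realignment); planted-recovery guarantees are
stated for units 20–200 bp, 3–12 copies, divergence ≤ 5%, where 200-trial
recovery is ≥ 95% (measured 100%).

## The synthetic generator

The generator is the package's stand-in for sequenced specimens; its
defaults are fixed to the observed structure of stick-insect mitogenomes
and not revisited: target length 16,000 bp within the observed
15,011–17,761 bp range, A+T 0.75 (observed 73.8–79.3%), J-strand AT-skew
+0.20 and GC-skew −0.19 (observed 0.160–0.236 and −0.255 to −0.118), tRNAs
66 bp (observed totals 1425–1485 bp), rRNAs 1285/780 bp, COX1 the longest
PCG at 1534 bp with an incomplete stop T (as in COX2), ND1 starting TTG,
planted ATAA (ATP8/ATP6) and AAGCCTTA (trnW/trnC) overlaps, and a default
control-region array of 5 × 109 bp at 2% divergence. The nine-config
`study_cohort_configs` cohort spans those ranges and plants one trnA/trnR
TDRL swap, one split control region with an inverted, translocated trnI,
one 198 bp ND1-derived NCR at 73% target identity, and the observed
variety of repeat arrays.

Sequences are i.i.d. given the base probabilities; N-strand genes are
drawn with complement-mirrored probabilities so the physical strand
carries the configured skews genome-wide. PCGs are drawn codon-wise from
the 60 non-stop codons weighted by base composition, with start and stop
codons enforced; junction motifs are planted only when the involved genes
sit on their ancestral-like strands (an inverted trnC flips which end of
its coding sequence carries the shared overlap). Rearrangement events are
applied through the same `apply_tdrl`/inversion/translocation operations
the analysis uses; a translocation with destination "CR" splits the
control region around the gene. One seeded stream is consumed in a fixed
order — gene sequences in ancestral gene order, junction gap sizes, NCR
mutation, control-region content, spacer bases — so the same config is
byte-identical and adding config fields does not silently shift existing
draws.

What the generator does *not* emulate: codon-position substitution
structure, selection on amino-acid usage (so the generated Met fraction is
the i.i.d.-composition value, around 7–8%, not the >10% seen in real
mitogenomes), tRNA secondary structure, and indel divergence in repeat
arrays. Passing the planted-recovery suites therefore demonstrates
correctness of the annotation-, order- and period-driven analyses, not
robustness to every feature of real sequence evolution.

`perturb_composition` retargets A+T content (±1 percentage point) by
resampling third codon positions and non-coding bases, never touching
annotations, start/stop codons, or creating internal stops; repeat arrays
inside the control region may drift, so it is applied before relying on a
truth manifest's array identities, or not at all.

## Pipeline and benchmarks

`run_pipeline` runs every stage per genome, quarantines failures without
affecting other genomes, summarises lengths, skew ranges, mechanism calls
and junction motifs shared identically across all inputs, and stamps
provenance (version, config hash, input checksums). Reports are JSON-first;
re-running on identical inputs is byte-identical.

`mitocomp.benchmarks` recomputes the headline cohort statistics from real
deposited GenBank records supplied by the user in `data/deposited/` (the
package never downloads). The corresponding acceptance test fails — it is
deliberately not skipped — when the records are absent, so the untested
benchmark surface stays visible.

## Problem sizes used by the test and acceptance runs

Exhaustive TDRL verification covers all sign-free permutations of 2–7
genes at depth ≤ 2; scenario soundness uses 1,000 random cases; sign-flip
infeasibility 200 pairs; planted-repeat recovery and the false-positive
control 200 trials each; mechanism round-trips 200 seeded genomes; the
pipeline cohort is the nine study-condition genomes. These sizes make the
full suite run in well under a minute while keeping every guarantee
measured at the scale it is stated.
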