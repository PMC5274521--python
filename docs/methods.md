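# Methods

## Scope and model

`tecaller` detects *non-reference* TE insertions: loci where a sample
carries a TE copy absent from the reference assembly. The signal model is
purely junction-based. A read that crosses an insertion boundary is a
concatenation of genomic flank and TE sequence; trimming the TE portion
leaves a flank whose end-to-end placement on the reference marks the
breakpoint to the base. Integration duplicates the target site, so the
left-flank alignments end at the last base of the first TSD copy and the
right-flank alignments start at the first base of the second copy; on the
(insertion-free) reference these two coordinates overlap by exactly the
TSD, which is therefore read off the reference rather than from error-prone
reads. Read pairs with one mate entirely inside the element contribute
their genomic mate as supporting evidence that localises the insertion to
within an insert size.

Assumptions: substitution-dominated sequencing errors (the internal
matcher and mapper are ungapped), a TE library whose consensi actually
end where the inserted elements end (the junction definition depends on
consensus termini), and insert sizes small relative to the clustering
window. TE absences (reference copy missing in the sample), nested or
internally deleted elements, and insertion-frequency estimation are out
of scope.

## The hit predicate

A read/consensus hit is a maximal ungapped diagonal window with

* length ≥ `len_cut_match` (10),
* mismatches ≤ `mismatch` (2),
* score = matches − mismatches ≥ `min_score` (10),
* ≥ `min_seed_count` (2) disjoint exact runs of `seed_len` (7) bases.

"Maximal" means bounded by matches and not properly contained in any
other window satisfying the mismatch budget. The score and two-seed
conditions are what a seeded local aligner at sensitive settings
(tile size 7, minimum score 10) effectively imposes, and they are not
cosmetic: measured on random 100 bp reads against a random 40 kb library,
dropping them inflates the background from ≈0.1 to ≈1,200 coincidental
windows per read, at which point every read looks informative and
read-pair bookkeeping (supporting-read promotion, junction detection)
collapses. The two-seed requirement also makes seeded search exact: any
qualifying window contains two same-diagonal 7-mer seeds with offsets ≥ 7
apart, so scanning only such diagonals loses nothing. The unit tests
verify exact equivalence against a brute-force enumeration of all
diagonals.

A hit "reaches" a consensus terminus if it comes within
`terminus_tolerance_bp` (3) of it — a base-call error at the extreme
junction base would otherwise disqualify the read. Reads matching several
families are resolved to the highest-scoring family (ties: fewer
mismatches, then lexicographic name) for determinism.

## False-junction control

A junction classification is vetoed when the *untrimmed* read maps
end-to-end to the reference within the mismatch budget: a read whose TE
match was coincidental is an ordinary genomic read and must not seed a
call. This single rule is what makes the null experiment (reads from an
unmodified reference) produce zero confident calls: without it, a read
carrying a chance 14–20 bp TE-like stretch at a terminus-compatible
position, together with its own mate, would fabricate two-sided evidence.
For the same reason supporting status is granted only to mates of
full-TE reads, never to mates of junction reads.

## Mapping contract

The internal mapper reports end-to-end placements with ≤ 2 substitutions
(flanks are pre-trimmed, so local alignment would re-introduce TE bases;
the simulator produces no indels). mapq is two-valued — 60 for a unique
best placement, 0 when co-optimal placements exist — because the only
downstream use is the threshold test against `mapq_min` (29): repeat-
ambiguous placements must land below it, unique ones above. Completeness
is by pigeonhole: fragments ≥ 30 bp use three disjoint exact 10-mer
probes (≤ 2 mismatches leave one probe intact); shorter fragments
enumerate all ≤ 2-substitution neighbours of their 10-mer prefix. An
adapter (`read_sam_alignments`) accepts SAM from an external aligner with
its native 0–60 mapq instead.

## Clustering and breakpoints

Sorted alignments chain into clusters while consecutive starts stay
within `window_bp` (2,000); clusters without a junction read are
discarded. Within a cluster, junctions sharing a family and lying within
`tsd_slack_bp` (25) of each other form a subcluster; 25 bp exceeds any
expected TSD (≤ 9 bp here) yet separates independent nearby insertions.
Supporting reads attach to the nearest subcluster within the window, on
the side their strand faces.

The per-side breakpoint is the **modal** coordinate among that side's
junction reads (ties resolved outward). An extremal rule (rightmost left
end / leftmost right start) is attractive on error-free data but fragile:
with 1% substitution error, a read with a miscalled base at the TE edge
trims 1–2 bases late, still maps within budget, and would stretch the TSD
on its own — at 10× this would corrupt roughly a fifth of sites, versus
~1% under the modal rule. Candidate orientation is voted from
(junction side, consensus end) when both TE ends are observed, else
reported unknown.

Cleaning rules run in the order (i) mapq, (iii) annotation proximity,
(ii) minor-candidate-in-shared-window, because rule (ii) is defined
relative to candidates that pass the other two. Rule (ii) counts left and
right junction reads summed; `rule2_per_flank` switches to per-flank
counting. Confident calls require a junction read on one side plus any
junction or supporting read on the other; singletons never leave the raw
output.

## Synthetic benchmark

`fixtures.rice_like_library()` is a deterministic synthetic stand-in for
the 14 rice families usually used for this kind of validation (7 DNA
transposons: mPing, nDart, Gaijin, spmlike, Truncator, mGing, nDarz; 7
retroelements: Bajie, Dasheng, Retro1, RIRE2, RIRE3, Copia2, karma).
Sequences are random; lengths are type-realistic (MITEs/DNA transposons
380–1,100 bp, retroelements 4,800–8,000 bp) and TSD lengths follow the
family type (Tourist-like and CACTA 3 bp, hAT-like 9 bp, Truncator 2 bp,
LTR retroelements 5 bp). The benchmark genome is uniform random —
euchromatin-like in the sense that flanks map uniquely almost everywhere.

`plant_insertions` draws sites uniformly with ≥ 2 × `window_bp` spacing
(truth-to-call matching stays unambiguous under the 100 bp criterion) and
1,000 bp from chromosome ends (on a 2 Mb desk-scale chromosome, edge
truncation of flank coverage would otherwise dominate the error budget;
on a real 36 Mb chromosome the effect is negligible). The read simulator
uses N = ceil(coverage·G / (2·100)) pairs, insert ~ Normal(500, 100)
truncated to [100, 1000], a uniform 1% per-base substitution rate and
flat Q30 qualities.

What passing therefore shows: the junction logic, trimming, TSD
extraction, clustering and filters are correct under substitution noise
and unique flanking sequence. What it does not show: behaviour under
indel errors, quality-dependent error profiles, diverged (non-consensus)
element copies, repeat-dense flanks where most of the genome
cross-matches the library, or structural noise — on repeat-rich
chromosomes sensitivity is expected to drop several points, as
heterochromatin evaluations of junction callers generally find.

## Benchmark scale and numbers

The acceptance benchmark plants 200 insertions per replicate (3
replicates) in a 2 Mb genome and scores 3×/10×/20× coverage; one full
sweep runs in ≈ 2 minutes on one CPU. Measured with
`scripts/acceptance.py --seed 1`: sensitivity 100.0% at 10×, 98.3% at 3×,
specificity 100.0% at every coverage, TSD recall 99.7% at 10× (all
3-replicate means; the test suite asserts the corresponding bounds).

## Numerical / degenerate-input choices

* Coordinates are 0-based half-open in memory, 1-based inclusive in
  GFF3; conversion happens only at the I/O boundary and is round-trip
  tested at both layers.
* All tie-breaks (family assignment, best placement, modal breakpoints,
  output ordering) are total orders, so a fixed input and seed give
  byte-identical GFF output.
* Fragments containing N, or shorter than the 10-mer probe, are treated
  as unplaceable; non-ACGTN input bases become N on read-in.
* Zero reads, an empty candidate list, or an annotation-free run are all
  legal and produce header-only/empty outputs; an empty library or
  reference raises immediately.
* Seeds are plain integers < 2^31; every random draw in the simulator and
  benchmark descends from the caller-provided seed.
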