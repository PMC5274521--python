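# tecaller

Junction-read discovery of non-reference transposable element (TE)
insertions from paired-end short reads, with a built-in simulation
benchmark.

## The problem

TE polymorphisms are a sizeable component of genetic variation in plant
and animal populations, but a new insertion is invisible to SNP/indel
callers: the inserted element is absent from the reference assembly, and
its repetitive sequence confounds read mapping. `tecaller` targets users
doing population resequencing who want each non-reference insertion
located to base-pair precision, including its target site duplication
(TSD) — the short (2–9 bp) direct repeat of host sequence that
integration leaves on both sides of the element and that pins the
insertion point exactly.

## How it works

Given a TE consensus library, a reference genome and paired FASTQ:

1. **Match** every read against all consensi at once (seeded, ungapped;
   a hit needs length ≥ 10, ≤ 2 mismatches, matches − mismatches ≥ 10
   and two disjoint exact 7-mers).
2. **Classify** each mate: *junction* (read crosses a TE boundary; the
   TE portion is trimmed off, the genomic flank kept), *full* (read
   entirely TE), *supporting* (the non-TE mate of a full read),
   or uninformative. A junction read whose **untrimmed** sequence maps
   cleanly end-to-end to the reference is a false junction and is
   discarded.
3. **Map** flanks, full and supporting reads end-to-end onto the
   reference (mapq 60 = unique best placement, 0 = ambiguous).
4. **Cluster** sorted alignments into 2,000 bp windows, refine
   subclusters by junction breakpoint, and call each subcluster: with
   junction reads on both sides, the left flanks end at base *b_L* and
   the right flanks start at *b_R*; if *b_R* ≤ *b_L* the interval
   [*b_R*, *b_L*] is the TSD and its sequence is read off the reference.
5. **Filter**: (i) drop candidates supported only by low-quality
   junctions (mapq < 29); (iii) drop junction-only candidates within
   10 bp of an annotated reference TE; (ii) drop candidates with < 3
   junction reads when another candidate in the same window survives.
   Calls with a junction read on one side and a junction or supporting
   read on the other are **confident** (`ALL.all_nonref_insert.gff`);
   everything else stays in the raw output only.

Sensitivity (SN) and specificity (SP) are scored against simulated truth
as: SN = fraction of planted insertions recalled within 100 bp,
SP = fraction of calls within 100 bp of a planted insertion, TSD recall =
fraction of true-positive calls whose TSD string matches the planted
motif.

## Worked example

```python
from tecaller import (RunConfig, evaluate, random_genome,
                      rice_like_library, run_pipeline)
from tecaller.simulator import ReadSimParams, plant_insertions, simulate_reads

library = rice_like_library()               # 14 synthetic families
reference = random_genome(300_000, seed=5)
mutated, truth = plant_insertions(reference, library, n=20, seed=3)
pairs = simulate_reads(mutated, ReadSimParams(coverage=20, seed=4,
                                              error_rate=0.01))
result = run_pipeline(pairs, library, reference, RunConfig())
ev = evaluate(result.confident, truth)
```

This prints (see `examples/01_simulate_and_call.py`):

```
20 confident calls (25 raw candidates)
  chr1:12741-12743 mPing      strand=+ TSD=TAA junctions L/R=10/17 support L/R=20/21
  ...
sensitivity=1.00 specificity=1.00 TSD recall=1.00
```

Each call line is one insertion locus: the 1-based TSD interval
(chr1:12741–12743, a 3 bp `TAA` duplication — mPing's signature), the
family, the element's orientation, and the junction/supporting read
counts on each side. All 20 planted insertions were recovered at their
exact positions with correct TSDs, and no false call was made.

The same workflow is available from the shell:

```bash
te-caller simulate --ref ref.fa --te-lib te.fa -n 200 --coverage 10 --seed 1 --out sim/
te-caller call --reads1 sim/sim_1.fq --reads2 sim/sim_2.fq \
               --te-lib te.fa --ref ref.fa --out calls/
te-caller evaluate --calls calls/ALL.all_nonref_insert.gff --truth sim/truth.gff3
te-caller benchmark --ref ref.fa --te-lib te.fa --coverages 2,5,10,20 --replicates 3 --seed 7
```

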