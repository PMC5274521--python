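"""The same workflow through files — what the `te-caller` command line
does: FASTA/FASTQ in, GFF3 out.
"""

import json
import tempfile
from pathlib import Path

from tecaller import (ReferenceGenome, RunConfig, TELibrary, random_genome,
                      read_fastq_pair, read_gff3, rice_like_library,
                      run_pipeline, write_fasta, write_fastq_pair, write_gff3)
from tecaller.simulator import (ReadSimParams, plant_insertions,
                                simulate_reads, truth_to_gff)

work = Path(tempfile.mkdtemp())
library = rice_like_library()
reference = random_genome(150_000, seed=11)

# --- simulate (te-caller simulate)
mutated, truth = plant_insertions(reference, library, n=10, seed=2)
pairs = simulate_reads(mutated, ReadSimParams(coverage=15, seed=2))
write_fasta({f.name: f.consensus for f in library}, work / "te.fa")
write_fasta(reference.sequences, work / "ref.fa")
write_gff3(truth_to_gff(truth), work / "truth.gff3")
write_fastq_pair(pairs, work / "sim_1.fq", work / "sim_2.fq")

# --- call (te-caller call)
lib = TELibrary.from_fasta(work / "te.fa")
ref = ReferenceGenome.from_fasta(work / "ref.fa")
reads = read_fastq_pair(work / "sim_1.fq", work / "sim_2.fq")
result = run_pipeline(reads, lib, ref, RunConfig())
write_gff3(result.confident_gff(), work / "ALL.all_nonref_insert.gff")
write_gff3(result.raw_gff(), work / "ALL.all_nonref_insert.raw.gff")
(work / "run_summary.json").write_text(json.dumps(result.summary, indent=2))

print(f"outputs in {work}:")
for line in (work / "ALL.all_nonref_insert.gff").read_text().splitlines()[:4]:
    print(" ", line)
print(f"  ... {len(result.confident)} confident records; truth had "
      f"{len(read_gff3(work / 'truth.gff3'))}")
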