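"""Generate a synthetic fractionation study and write it as a file bundle.

The generator plants every effect the pipeline detects: transcript-usage
switches between cytoplasm and nucleus, one local splicing event per gene,
nucleus-biased retained introns that are short, GC-rich, stem-bearing and
motif-bearing, and SINE repeats enriched in those introns.
"""
from pathlib import Path

import isoloc as il

out = Path("scratch/example_fixture")
pwms = il.make_test_pwms(3, seed=7)
cfg = il.SimulationConfig(n_genes=100, planted_motifs=(pwms[0],), seed=7)
paths = il.bundle_fixture(cfg, out)

models = il.read_gtf(paths["gtf"])
genome = il.read_fasta(paths["fasta"])
print(f"wrote {len(paths)} files to {out}/")
print(f"  transcripts: {len(models)}  genes: {len(il.group_by_gene(models))}")
print(f"  genome: {sum(map(len, genome.values())):,} nt over "
      f"{len(genome)} chromosomes")
# the ground-truth tables list the planted switches and events, so any
# downstream result can be scored for recall/precision
print(f"  ground truth: {paths['truth_switching'].name}, "
      f"{paths['truth_events'].name}")
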