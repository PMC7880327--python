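"""Fragment counting, FPKM, sample correlation, and DEG calling.

Run 01_simulate_dataset.py first (or any dataset directory will do).
"""

from pathlib import Path

from ripsplice import SimulationConfig, simulate_dataset
from ripsplice.alignments import AlignmentTable
from ripsplice.annotation import parse_gtf
from ripsplice.expression import (
    correlation_matrix, count_fragments, detect_degs, fpkm_matrix,
    gene_lengths,
)

out = Path("example_output/dataset")
if not (out / "annotation.gtf").exists():
    simulate_dataset(SimulationConfig(seed=7, n_genes=20,
                                      genome_length=250_000,
                                      rnaseq_depth=20_000, rip_depth=10_000),
                     out)

genes = parse_gtf(out / "annotation.gtf")
samples = {}
for cond in ("A", "B"):
    for rep in (1, 2, 3):
        name = f"{cond}_rep{rep}"
        table = AlignmentTable.from_sam(out / f"rnaseq_{cond}_rep{rep}.sam")
        samples[name] = count_fragments(table, genes)

fpkm = fpkm_matrix(samples, gene_lengths(genes))
corr, order = correlation_matrix(fpkm)
print("FPKM (fragments per kb of exon model per million fragments), head:")
print(fpkm.round(1).head())
print("\nPearson correlation between samples (clustered order:", order, ")")
print(corr.round(3))
# Replicates of the same condition correlate near 1 and cluster together.

import pandas as pd
counts = pd.DataFrame({n: s.counts for n, s in samples.items()})
degs = detect_degs(counts, {n: n[0] for n in counts},
                   totals={n: s.total for n, s in samples.items()})
print("\ndifferential genes (|FC| >= 2 and BH-FDR <= 0.05):")
print(degs.round(4))
# 'up' means higher in condition B; log2FC of ~2 recovers the planted 4x.
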