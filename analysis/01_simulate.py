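#!/usr/bin/env python
"""Generate the default synthetic NET-seq dataset and write it to disk.

Emits the four real-data-shaped inputs (genome FASTA, gene BED, per-strand
bedGraph tracks for WT and dst1-delta, nucleosome TSV) plus the planted
truth tables under results/dataset/, and prints the dataset's vital
statistics.
"""

import sys
from pathlib import Path

import numpy as np

from tecpause.synthetic_data import SyntheticSpec, generate_dataset, write_dataset

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/dataset")

ds = generate_dataset(SyntheticSpec(seed=SEED))
write_dataset(ds, OUT)

truth = ds.truth.pauses
print(f"seed {SEED}: {len(ds.genes)} genes, {len(ds.transcriptome):,} transcribed positions")
print(f"planted dst1-delta pauses: {len(truth):,} "
      f"({100 * len(truth) / len(ds.transcriptome):.1f}% of positions)")
print(f"  long backtracks: {truth.is_long.mean():.1%}  "
      f"mean WT offset: {truth.offset.mean():.2f} nt")
print(f"dTEC (dst1 convention): sd {np.nanstd(ds.dtec_dst1):.2f} kJ/mol over "
      f"{np.isfinite(ds.dtec_dst1).sum():,} valid positions")
print(f"coverage: WT {ds.wt.counts.sum():,} reads, dst1 {ds.dst1.counts.sum():,} reads")
print(f"wrote dataset to {OUT}/")
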