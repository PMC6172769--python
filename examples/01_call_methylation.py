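"""Quality-filtered CpG methylation calling from a bisulfite alignment.

Builds a miniature genome with known per-CpG methylation, simulates a
paired-end bisulfite SAM file, streams it into pileup columns and calls
per-strand methylation ratios under the calling filters (C-position
quality >= 30, flanking qualities >= 20, >= 3 reads per strand).
"""

import tempfile
from pathlib import Path

import numpy as np

from gbmethyl import io_formats as iof
from gbmethyl import meth_calling as mc
from gbmethyl import synthetic_data as sd

cfg = sd.paper_like(seed=5, n_scaffolds=1, scaffold_length=40_000, n_genes=8)
rng = np.random.default_rng(cfg.seed)
genome, annotation, truth = sd.generate_genome(cfg, rng)

workdir = Path(tempfile.mkdtemp())
sam = workdir / "wgbs.sam"
sd.generate_alignments(genome, truth, sam, rng, n_pairs=4000)

columns = list(iof.read_alignments_to_pileup(sam, genome))
cpg = set(map(int, iof.cpg_positions(genome)["scaffold_1"]))


def is_cpg(col):
    return col.pos in cpg if col.strand == "+" else col.pos - 1 in cpg


sites = mc.call_sites(c for c in columns if is_cpg(c))
iof.write_bedgraph(sites, workdir / "methylation")
conversion = mc.estimate_conversion(c for c in columns if not is_cpg(c))

print(f"pileup columns:          {len(columns)}")
print(f"retained CpG sites:      {len(sites)}")
print(f"mean methylation ratio:  {sites['ratio'].mean():.3f}")
print(f"conversion rate:         {conversion.rate:.4f} "
      f"(simulated at {cfg.conversion})")
print(f"bedGraph tracks written to {workdir}/methylation.*.bedGraph")
# The conversion estimate comes from non-CpG cytosines (assumed
# unmethylated); it should sit within sampling error of the simulated rate.
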