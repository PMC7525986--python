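"""Allele calling from amplicon reads.

Simulates two PCR runs of tagged, primer-decorated reads from three true
alleles with sequencing errors, then runs the full read-processing chain:
MID demultiplexing, primer sorting, primer trimming, 0.99-identity
clustering with majority consensus, and the two-independent-source
validation rule.
"""

import numpy as np

from equimhc.alleles import (
    call_alleles_from_runs,
    demultiplex,
    sort_by_primer,
    trim_primers,
)
from equimhc.seq_io import LocusConfig
from equimhc.synthetic import simulate_amplicon_reads

FWD, REV = "CCTCTGGGGTAACGTTCCAG", "CGGCCTTGCTTTAGGTTTATC"
MIDS = ["ACGAGTGCGT", "ACGCTCGACA"]  # one tag per PCR run

rng = np.random.default_rng(7)
base = "".join(rng.choice(list("ACGT"), size=269))
alleles = []
for _ in range(3):
    b = list(base)
    for pos in rng.choice(269, size=5, replace=False):
        b[pos] = str(rng.choice([c for c in "ACGT" if c != b[pos]]))
    alleles.append("".join(b))

reads, provenance = simulate_amplicon_reads(
    alleles, copies_per_allele=25, error_rate=0.003, mids=MIDS,
    primer_pair=(FWD, REV), seed=7,
)
print(f"simulated {len(reads)} reads from {len(alleles)} true alleles "
      f"({provenance['n_errors'].sum()} substitution errors in total)")

config = LocusConfig("DQB1", 269, primer_fwd=FWD, primer_rev=REV)
bins, unmatched = demultiplex(reads, MIDS)
runs = {}
for mid, tagged_reads in bins.items():
    assigned, _, _ = sort_by_primer(tagged_reads, [config])
    trimmed, dropped = trim_primers(assigned["DQB1"], (FWD, REV))
    runs[mid] = trimmed
    print(f"  run {mid}: {len(trimmed)} usable reads, {dropped} dropped")

result = call_alleles_from_runs(runs, config, species_tag="Eqca")
print(f"\nvalidated alleles ({len(result.alleles)}):")
for allele in result.alleles:
    sources = sorted(src for _, src in allele.evidence)
    print(f"  {allele.name}  seen in runs {sources}")
print(f"candidates discarded by the two-source rule: {len(result.discarded)}")
print("\nEach validated allele was recovered as an identical consensus in two")
print("independent PCR runs; error-only clusters never replicate across runs.")
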