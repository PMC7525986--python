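"""Site-wise selection with the two-method consensus rule.

Simulates an alignment in which 30% of codons (the ABS class) evolve with
omega = 5, runs the counting (SLAC-style) and per-site likelihood
(FEL-style) methods on the NJ tree, and reports the codons where both
methods agree — the consensus rule for calling a selected amino acid site
(SAAS).
"""

import numpy as np

from equimhc.phylo import jc_distance_matrix, nj_tree
from equimhc.selection import consensus_sites, fel_sites, slac_sites
from equimhc.synthetic import (
    allele_genealogy,
    simulate_codon_alignment,
    two_class_model,
)

model = two_class_model(90, abs_fraction=0.3, omega_abs=5.0,
                        omega_background=0.5, seed=3)
aln = simulate_codon_alignment(allele_genealogy(20, seed=3), model, seed=9)

mat, ids = jc_distance_matrix(aln)
tree = nj_tree(mat, ids)
slac = slac_sites(aln, tree)
fel = fel_sites(aln, tree)
true_abs = {i + 1 for i, c in enumerate(model.class_of_codon) if c == "ABS"}
consensus = consensus_sites({"SLAC": slac, "FEL": fel}, abs_codons=true_abs)

n_slac = (slac["class"] == "positive").sum()
n_fel = (fel["class"] == "positive").sum()
positive = consensus[consensus["consensus"] == "positive"]
hits = positive["is_ABS"].sum()
print(f"SLAC flags {n_slac} positive sites; FEL flags {n_fel}")
print(f"consensus (>= 2 methods): {len(positive)} sites: "
      f"{sorted(positive['site'])}")
print(f"of these, {hits} fall in the true elevated-omega (ABS) class "
      f"({len(true_abs)} of 90 codons)")
print()
print("Requiring two methods to agree trades sensitivity for specificity:")
print("fewer sites are called, but they concentrate in the truly selected class.")
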