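"""Diversity indices and the global codon Z-test of positive selection.

Simulates one locus evolving neutrally and one with antigen-binding-site
(ABS) codons under positive selection (omega = 4), then prints variable
nucleotide positions (VNP), parsimony-informative positions (PIP), and the
one-tailed Z-test of dN > dS (Nei-Gojobori counting, Jukes-Cantor
correction, bootstrap variance over codon sites).
"""

from equimhc.diversity import summarize
from equimhc.selection import global_z_test
from equimhc.synthetic import (
    allele_genealogy,
    neutral_model,
    simulate_codon_alignment,
    two_class_model,
)

alignments = {}
tree = allele_genealogy(16, seed=5)
alignments["neutral_locus"] = simulate_codon_alignment(
    tree, neutral_model(90), seed=11
)
alignments["selected_locus"] = simulate_codon_alignment(
    tree, two_class_model(90, abs_fraction=0.3, omega_abs=4.0,
                          omega_background=1.0, seed=5),
    seed=12,
)

table = summarize(alignments)
for name, aln in alignments.items():
    z = global_z_test(aln, n_boot=1000, seed=1)
    row = table.set_index("locus").loc[name]
    print(f"{name}: N={row['N']}  VNP={row['VNP']}  PIP={row['PIP']}  "
          f"Z={z.Z:+.3f}  p(dN>dS)={z.p_one_tailed:.3f}")

print()
print("The selected locus shows an excess of nonsynonymous substitution")
print("(positive Z, small one-tailed p); the neutral locus does not (p = 1")
print("is the one-tailed convention whenever dN <= dS).")
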