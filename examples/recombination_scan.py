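"""Single-breakpoint recombination screen.

Builds a recombinant alignment whose first 45 codons follow one topology
and last 45 another, then scans every interior codon boundary comparing
the small-sample AIC (cAIC) of a single-tree fit against two independent
per-partition fits.  Recombination is declared when the best two-partition
cAIC beats the single-tree cAIC.
"""

from equimhc.recomb import sbp_scan
from equimhc.synthetic import (
    conflicting_tree,
    demo_tree,
    make_recombinant,
    neutral_model,
    simulate_codon_alignment,
)

left = simulate_codon_alignment(demo_tree(0.3), neutral_model(90), seed=1)
right = simulate_codon_alignment(conflicting_tree(0.3), neutral_model(90), seed=2)
recombinant = make_recombinant(left, right, breakpoint=45)

scan = sbp_scan(recombinant)
print(f"true breakpoint: codon 45 of 90")
print(f"single-tree cAIC:     {scan.caic_single:9.1f}")
print(f"best two-partition:   {scan.caic_two_partition:9.1f} "
      f"at codon {scan.trace.loc[scan.trace['cAIC'].idxmin(), 'breakpoint']}")
print(f"delta cAIC:           {scan.delta_caic:9.1f}")
print(f"verdict: breakpoint at codon {scan.best_breakpoint}"
      if scan.best_breakpoint else "verdict: no recombination")

control = simulate_codon_alignment(demo_tree(0.3), neutral_model(90), seed=3)
null_scan = sbp_scan(control)
print(f"\nsingle-topology control: delta cAIC = {null_scan.delta_caic:+.1f} "
      f"-> {'breakpoint ' + str(null_scan.best_breakpoint) if null_scan.best_breakpoint else 'no recombination'}")
print("\nA large negative delta cAIC localizes the topology switch; on")
print("recombination-free data the extra parameters of the two-tree model")
print("are penalized and the delta stays non-negative.")
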