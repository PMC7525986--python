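"""Gene presence/absence from per-base coverage.

Simulates depth tracks for two genes — one present, one deleted — and calls
presence from the non-zero-coverage statistic: the fraction of positions
covered by at least one read.  A gene is called absent when under 10% of
its bases are covered.
"""

from equimhc.presence import call_presence, nonzero_coverage_fraction
from equimhc.synthetic import simulate_depth_track

for gene, present in (("DQB1", True), ("DQB2", False)):
    track = simulate_depth_track(500, present=present, mean_depth=15.0, seed=42)
    frac = nonzero_coverage_fraction(track)
    call = call_presence(frac, gene=gene)
    print(f"{gene}: {100 * frac:5.1f}% non-zero-coverage bases -> {call.call}")

print()
print("A present gene at 15x coverage leaves essentially no base uncovered;")
print("an absent gene shows only sparse spurious coverage, far below the 10%")
print("threshold, so the two calls separate cleanly.")
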