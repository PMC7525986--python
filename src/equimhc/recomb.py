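"""Single-breakpoint recombination screen with small-sample AIC.

The screen compares a one-tree fit of the whole alignment against
two-partition fits at every candidate codon boundary.  Each fit is a
neighbor-joining topology with JC69 branch lengths re-optimized by maximum
likelihood; per-partition topologies are re-estimated, not fixed — a
desk-scale surrogate for genetic-algorithm breakpoint searches.  The
decision criterion is the small-sample AIC,

    cAIC = -2 lnL + 2k + 2k(k+1)/(n - k - 1),

with k the number of branch lengths plus one per tree for topology
bookkeeping and n the number of alignment sites; recombination is declared
iff the best two-partition cAIC beats the single-tree cAIC (delta < 0),
with no secondary significance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Tree, jc_distance_matrix, nj_tree, optimize_branch_lengths
from .seq_io import CodonAlignment

DEFAULT_MIN_PARTITION = 10  # codons


@dataclass
class BreakpointScan:
    best_breakpoint: int | None
    caic_single: float
    caic_two_partition: float
    delta_caic: float
    trace: pd.DataFrame = field(repr=False, default=None)


def caic(log_likelihood: float, k: int, n_sites: int) -> float:
    """Small-sample AIC; +inf when the correction denominator is not positive."""
    denom = n_sites - k - 1
    if denom <= 0:
        return np.inf
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / denom


def _fit(aln: CodonAlignment) -> tuple[Tree, float, int]:
    mat, ids = jc_distance_matrix(aln)
    tree = nj_tree(mat, ids)
    # the cAIC differences the screen decides on are orders of magnitude
    # larger than 1e-3 log-units, so the screen uses a looser convergence
    # threshold than the library default
    tree, logl = optimize_branch_lengths(aln, tree, tol=1e-3, max_sweeps=10)
    n_edges = sum(1 for n in tree.postorder() if n is not tree.root)
    return tree, logl, n_edges + 1  # +1: topology bookkeeping


def partition_alignment(
    aln: CodonAlignment, breakpoint: int
) -> tuple[CodonAlignment, CodonAlignment]:
    """Column-exact split at a codon boundary (0 < breakpoint < n_codons)."""
    if not 0 < breakpoint < aln.n_codons:
        raise ValueError(
            f"breakpoint {breakpoint} outside (0, {aln.n_codons})"
        )
    return aln.slice_codons(0, breakpoint), aln.slice_codons(breakpoint, aln.n_codons)


def sbp_scan(
    aln: CodonAlignment, min_partition: int = DEFAULT_MIN_PARTITION
) -> BreakpointScan:
    """Scan all interior codon boundaries for a single recombination breakpoint.

    Candidates keep at least ``min_partition`` codons on each side.  Returns
    the argmin-cAIC candidate and the delta against the single-tree fit; a
    breakpoint is reported only when delta < 0.
    """
    if aln.n_seqs < 4:
        raise ValueError("breakpoint scan needs at least 4 sequences")
    n_codons = aln.n_codons
    if n_codons < 2 * min_partition:
        raise ValueError(
            f"alignment of {n_codons} codons too short for "
            f"min_partition={min_partition}"
        )
    n_sites = 3 * n_codons
    _, logl_single, k_single = _fit(aln)
    caic_single = caic(logl_single, k_single, n_sites)

    records = []
    for bp in range(min_partition, n_codons - min_partition + 1):
        left, right = partition_alignment(aln, bp)
        _, logl_l, k_l = _fit(left)
        _, logl_r, k_r = _fit(right)
        c = caic(logl_l + logl_r, k_l + k_r, n_sites)
        records.append((bp, logl_l + logl_r, k_l + k_r, c))
    trace = pd.DataFrame(records, columns=["breakpoint", "logL", "k", "cAIC"])

    best_idx = int(trace["cAIC"].idxmin())
    best_caic = float(trace.loc[best_idx, "cAIC"])
    delta = best_caic - caic_single
    best_bp = int(trace.loc[best_idx, "breakpoint"]) if delta < 0 else None
    return BreakpointScan(
        best_breakpoint=best_bp,
        caic_single=caic_single,
        caic_two_partition=best_caic,
        delta_caic=delta,
        trace=trace,
    )
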