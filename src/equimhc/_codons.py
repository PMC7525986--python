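"""Universal genetic-code tables used by the codon simulator and selection statistics.

Codons are indexed 0..63 in lexicographic order over the base order A < C < G < T.
Stop codons keep their index but are excluded from site/difference counting and
carry zero frequency in simulation models.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

CODONS: tuple[str, ...] = tuple("".join(c) for c in itertools.product(BASES, repeat=3))
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)
SENSE_INDEX = np.array([CODON_INDEX[c] for c in SENSE_CODONS])  # 61 entries

AMINO_ACID = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}

#: sentinel for codons containing a gap/N (excluded from codon statistics)
MISSING = -1

_PURINES = {"A", "G"}


def is_transition(b1: str, b2: str) -> bool:
    """True if the substitution b1->b2 is a transition (purine<->purine or pyr<->pyr)."""
    return b1 != b2 and ((b1 in _PURINES) == (b2 in _PURINES))


def translate(codon: str) -> str | None:
    """One-letter amino acid, or None for a stop codon."""
    return AMINO_ACID.get(codon)


@lru_cache(maxsize=1)
def synonymous_site_fractions() -> np.ndarray:
    """Per-codon count of synonymous sites, Nei–Gojobori style.

    For each codon position the fraction of one-step changes that are synonymous
    is computed among changes that do not create a stop codon, so that every
    sense codon contributes exactly 3 sites split between S and N.  Stop codons
    get NaN.
    """
    s = np.full(64, np.nan)
    for codon in SENSE_CODONS:
        aa = AMINO_ACID[codon]
        total = 0.0
        for pos in range(3):
            syn = 0
            nonstop = 0
            for b in BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if mut in STOP_CODONS:
                    continue
                nonstop += 1
                if AMINO_ACID[mut] == aa:
                    syn += 1
            if nonstop:
                total += syn / nonstop
        s[CODON_INDEX[codon]] = total
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Mean (synonymous, nonsynonymous) step counts over minimal mutation pathways.

    Pathways passing through a stop codon are excluded; if every ordering is
    blocked (does not occur for sense codon pairs under the universal code, but
    guarded anyway) all orderings are used with stop-involving steps counted as
    nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        syn = nsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                if not allow_stops:
                    return None
                if translate(cur) is not None and translate(nxt) == translate(cur):
                    syn += 1
                else:
                    nsyn += 1
            elif AMINO_ACID[nxt] == AMINO_ACID[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        return syn, nsyn

    results = [r for order in itertools.permutations(diff) if (r := walk(order, False))]
    if not results:
        results = [walk(order, True) for order in itertools.permutations(diff)]
    syn = float(np.mean([r[0] for r in results]))
    nsyn = float(np.mean([r[1] for r in results]))
    return syn, nsyn


@lru_cache(maxsize=1)
def difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """64x64 tables of mean synonymous / nonsynonymous differences per codon pair.

    Entries involving stop codons are NaN.
    """
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for c1 in SENSE_CODONS:
        i = CODON_INDEX[c1]
        for c2 in SENSE_CODONS:
            j = CODON_INDEX[c2]
            s, n = _pathway_counts(c1, c2)
            sd[i, j] = s
            nd[i, j] = n
    return sd, nd


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as codon indices.

    Codons containing anything outside {A,C,G,T} (gaps, N) map to MISSING.
    """
    n = len(seq) // 3
    out = np.full(n, MISSING, dtype=np.int64)
    for k in range(n):
        codon = seq[3 * k: 3 * k + 3].upper()
        idx = CODON_INDEX.get(codon)
        if idx is not None:
            out[k] = idx
    return out
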