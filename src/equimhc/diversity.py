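"""Alignment diversity indices and trans-species allele sharing.

Variable nucleotide positions (VNP) count columns with at least two distinct
bases; parsimony-informative positions (PIP) additionally require at least
two of those bases to occur in at least two sequences.  Under the default
complete-deletion policy columns containing a gap or N in any included row
are excluded; under pairwise-deletion only the gap-free rows of each column
are considered.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import encode_nucleotides
from .seq_io import CodonAlignment


@dataclass(frozen=True)
class DiversitySummary:
    locus: str
    n: int
    length: int
    vnp: int | None  # None rendered as NA
    pip: int | None


def _column_states(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    arr = encode_nucleotides(aln)
    valid = arr < 4
    return arr, valid


def _usable_columns(valid: np.ndarray, gap_policy: str) -> np.ndarray:
    if gap_policy == "complete-deletion":
        return valid.all(axis=0)
    return valid.any(axis=0)


def variable_sites(aln: CodonAlignment) -> int:
    """Count of columns with >= 2 distinct bases under the gap policy."""
    if aln.n_seqs < 2:
        raise ValueError("variable_sites needs at least 2 sequences")
    arr, valid = _column_states(aln)
    count = 0
    for col in np.nonzero(_usable_columns(valid, aln.gap_policy))[0]:
        bases = arr[valid[:, col], col]
        if len(np.unique(bases)) >= 2:
            count += 1
    return count


def parsimony_informative_sites(aln: CodonAlignment) -> int:
    """Columns with >= 2 distinct bases each occurring in >= 2 sequences."""
    if aln.n_seqs < 2:
        raise ValueError("parsimony_informative_sites needs at least 2 sequences")
    arr, valid = _column_states(aln)
    count = 0
    for col in np.nonzero(_usable_columns(valid, aln.gap_policy))[0]:
        bases = arr[valid[:, col], col]
        _, freq = np.unique(bases, return_counts=True)
        if (freq >= 2).sum() >= 2:
            count += 1
    return count


def allele_sharing(
    sequences: dict[str, list[tuple[str, str]]]
) -> pd.DataFrame:
    """Trans-species sharing of identical nucleotide sequences.

    ``sequences`` maps locus -> list of (species_tag, sequence).  Returns one
    row per (locus, shared sequence) with the set of species carrying it;
    sequences found in a single species only are omitted.  Identical
    sequences occurring at two loci within one species are inter-locus
    identities, not trans-species sharing, and are reported by
    :func:`interlocus_identities`.
    """
    rows = []
    for locus, entries in sequences.items():
        by_seq: dict[str, set[str]] = {}
        for species, seq in entries:
            by_seq.setdefault(seq.upper(), set()).add(species)
        for seq, species_set in sorted(by_seq.items()):
            if len(species_set) >= 2:
                rows.append(
                    {
                        "locus": locus,
                        "sequence": seq,
                        "n_species": len(species_set),
                        "species": ",".join(sorted(species_set)),
                    }
                )
    return pd.DataFrame(rows, columns=["locus", "sequence", "n_species", "species"])


def shared_counts(sequences: dict[str, list[tuple[str, str]]]) -> pd.Series:
    """Per-locus count of sequences shared by at least two species."""
    sharing = allele_sharing(sequences)
    counts = Counter(sharing["locus"]) if len(sharing) else Counter()
    return pd.Series({locus: counts.get(locus, 0) for locus in sequences},
                     name="n_shared")


def interlocus_identities(
    sequences: dict[str, list[tuple[str, str]]]
) -> pd.DataFrame:
    """Identical sequences carried by two loci within the same species."""
    by_species_seq: dict[tuple[str, str], set[str]] = {}
    for locus, entries in sequences.items():
        for species, seq in entries:
            by_species_seq.setdefault((species, seq.upper()), set()).add(locus)
    rows = [
        {"species": sp, "sequence": seq, "loci": ",".join(sorted(loci))}
        for (sp, seq), loci in sorted(by_species_seq.items())
        if len(loci) >= 2
    ]
    return pd.DataFrame(rows, columns=["species", "sequence", "loci"])


def summarize(
    alignments: dict[str, CodonAlignment],
    pooled: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Diversity table: one row per locus plus one per pooled sub-region.

    ``pooled`` maps sub-region name -> list of locus names whose alignments
    are concatenated row-wise (they must share the alignment length).
    Single-sequence entries report VNP/PIP as NA.
    """
    entries: dict[str, CodonAlignment] = dict(alignments)
    for region, loci in (pooled or {}).items():
        parts = [alignments[loc] for loc in loci]
        lengths = {p.length for p in parts}
        if len(lengths) != 1:
            raise ValueError(f"pooled region {region}: unequal lengths {lengths}")
        entries[region] = CodonAlignment(
            ids=[i for p in parts for i in p.ids],
            seqs=[s for p in parts for s in p.seqs],
            species_tags=[t for p in parts for t in p.species_tags],
            locus_tags=[t for p in parts for t in p.locus_tags],
            gap_policy=parts[0].gap_policy,
        )
    rows = []
    for name, aln in entries.items():
        if aln.n_seqs < 2:
            vnp = pip = None
        else:
            vnp = variable_sites(aln)
            pip = parsimony_informative_sites(aln)
        rows.append(
            {"locus": name, "length": aln.length, "N": aln.n_seqs,
             "VNP": vnp if vnp is not None else pd.NA,
             "PIP": pip if pip is not None else pd.NA}
        )
    return pd.DataFrame(rows)
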