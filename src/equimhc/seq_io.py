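"""Sequence, depth-table and locus-configuration I/O.

Conventions
-----------
* Coordinates are 0-based half-open internally; 1-based in human-readable
  reports.
* Sequence IDs carry metadata as ``Species|Locus|AlleleName`` by default; a
  regex with named groups ``species``/``locus``/``allele`` in the locus config
  supports other dialects.
* FASTA is canonicalized on write: upper case, 60-column wrapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import STOP_CODONS

ALLOWED_CHARS = frozenset("ACGTN-")
DEFAULT_ID_PATTERN = r"(?P<species>[^|]+)\|(?P<locus>[^|]+)\|(?P<allele>.+)"


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class GeneInterval:
    """0-based half-open interval on a named reference sequence."""

    reference: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LocusConfig:
    """Per-locus analysis configuration.

    ``exon2_length`` is the analyzed amplicon length: DQB loci carry the full
    269-bp exon 2 while DRB amplicons miss the nine 3' exon nucleotides and are
    260 bp.  ``abs_codons`` are 1-based codon positions of the putative antigen
    binding site within the trimmed exon.
    """

    name: str
    exon2_length: int
    abs_codons: frozenset[int] = frozenset()
    primer_fwd: str = ""
    primer_rev: str = ""
    gene_interval: GeneInterval | None = None
    id_pattern: str = DEFAULT_ID_PATTERN

    def __post_init__(self):
        if self.exon2_length <= 0:
            raise ValueError("exon2_length must be positive")
        n_codons = -(-self.exon2_length // 3)
        bad = [p for p in self.abs_codons if not 1 <= p <= n_codons]
        if bad:
            raise ValueError(f"ABS codon positions out of range: {bad}")


def load_locus_configs(path: str | Path) -> dict[str, LocusConfig]:
    """Read a YAML locus configuration file into LocusConfig objects."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    configs = {}
    for name, spec in raw.get("loci", raw).items():
        interval = None
        if "gene_interval" in spec:
            gi = spec["gene_interval"]
            interval = GeneInterval(gi["reference"], int(gi["start"]), int(gi["end"]))
        configs[name] = LocusConfig(
            name=name,
            exon2_length=int(spec["exon2_length"]),
            abs_codons=frozenset(spec.get("abs_codons", [])),
            primer_fwd=spec.get("primer_fwd", ""),
            primer_rev=spec.get("primer_rev", ""),
            gene_interval=interval,
            id_pattern=spec.get("id_pattern", DEFAULT_ID_PATTERN),
        )
    return configs


@dataclass
class CodonAlignment:
    """An aligned, frame-trimmed set of nucleotide sequences.

    The object all diversity and selection statistics act on.  Rows whose
    in-frame sequence contains an internal stop codon are recorded in
    ``stop_flagged``: they stay in the alignment (diversity counts keep them)
    but selection analyses exclude them.
    """

    ids: list[str]
    seqs: list[str]
    species_tags: list[str] = field(default_factory=list)
    locus_tags: list[str] = field(default_factory=list)
    frame_offset: int = 0
    gap_policy: str = "complete-deletion"
    stop_flagged: set[int] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            raise FormatError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise FormatError(f"unequal sequence lengths: {sorted(lengths)}")
        bad = set("".join(self.seqs)) - ALLOWED_CHARS
        if bad:
            raise FormatError(
                f"unsupported characters {sorted(bad)}; only A,C,G,T,N,- are accepted"
            )
        if not self.species_tags:
            self.species_tags = [""] * len(self.ids)
        if not self.locus_tags:
            self.locus_tags = [""] * len(self.ids)
        if self.gap_policy not in ("complete-deletion", "pairwise-deletion"):
            raise ValueError(f"unknown gap policy {self.gap_policy!r}")

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_offset) // 3

    def in_frame(self, i: int) -> str:
        """Row i restricted to complete in-frame codons."""
        start = self.frame_offset
        return self.seqs[i][start: start + 3 * self.n_codons]

    def subset(self, indices) -> "CodonAlignment":
        indices = list(indices)
        remap = {old: new for new, old in enumerate(indices)}
        return CodonAlignment(
            ids=[self.ids[i] for i in indices],
            seqs=[self.seqs[i] for i in indices],
            species_tags=[self.species_tags[i] for i in indices],
            locus_tags=[self.locus_tags[i] for i in indices],
            frame_offset=self.frame_offset,
            gap_policy=self.gap_policy,
            stop_flagged={remap[i] for i in self.stop_flagged if i in remap},
        )

    def without_stop_flagged(self) -> "CodonAlignment":
        return self.subset([i for i in range(self.n_seqs) if i not in self.stop_flagged])

    def slice_codons(self, start: int, end: int) -> "CodonAlignment":
        """Columns of codons [start, end), 0-based, relative to the frame."""
        a = self.frame_offset + 3 * start
        b = self.frame_offset + 3 * end
        return replace(
            self,
            ids=list(self.ids),
            seqs=[s[a:b] for s in self.seqs],
            frame_offset=0,
            stop_flagged=set(self.stop_flagged),
            warnings=[],
        )

    def to_array(self) -> np.ndarray:
        """(n_seqs, length) array of single characters."""
        return np.array([list(s) for s in self.seqs])


def _find_internal_stops(seq: str, n_codons: int, frame_offset: int) -> bool:
    for k in range(n_codons - 1):  # terminal codon may legitimately be a stop
        codon = seq[frame_offset + 3 * k: frame_offset + 3 * k + 3]
        if codon in STOP_CODONS:
            return True
    return False


def trim_to_frame(seq: str, frame_offset: int) -> str:
    """Drop leading bases before the frame offset and trailing partial codon."""
    n = (len(seq) - frame_offset) // 3
    return seq[frame_offset: frame_offset + 3 * n]


def read_alignment(
    path: str | Path,
    config: LocusConfig | None = None,
    frame_offset: int = 0,
    gap_policy: str = "complete-deletion",
) -> CodonAlignment:
    """Read an aligned FASTA file into a CodonAlignment.

    Species/locus tags are parsed from record IDs with the config's regex (a
    non-matching ID leaves the tags empty).  Records with an internal in-frame
    stop codon are flagged but retained.  A length differing from the config's
    expected exon-2 length is recorded as a warning, not an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]

    pattern = re.compile(config.id_pattern if config else DEFAULT_ID_PATTERN)
    species, loci = [], []
    for rid in ids:
        m = pattern.match(rid)
        species.append(m.group("species") if m else "")
        loci.append(m.group("locus") if m else "")

    aln = CodonAlignment(
        ids=ids, seqs=seqs, species_tags=species, locus_tags=loci,
        frame_offset=frame_offset, gap_policy=gap_policy,
    )
    for i, s in enumerate(seqs):
        if _find_internal_stops(s, aln.n_codons, frame_offset):
            aln.stop_flagged.add(i)
    if config is not None and aln.length != config.exon2_length:
        aln.warnings.append(
            f"alignment length {aln.length} differs from configured "
            f"exon2_length {config.exon2_length} for locus {config.name}"
        )
    return aln


def write_alignment(aln: CodonAlignment, path: str | Path) -> None:
    """Write canonical FASTA: upper case, 60-column wrapped."""
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


@dataclass
class DepthTable:
    """Per-base read depth over named gene intervals."""

    depths: dict[str, np.ndarray]  # gene name -> vector over its interval
    intervals: dict[str, GeneInterval]

    def __post_init__(self):
        for gene, vec in self.depths.items():
            if len(vec) != self.intervals[gene].length:
                raise FormatError(
                    f"{gene}: depth vector length {len(vec)} != interval "
                    f"length {self.intervals[gene].length}"
                )
            if (vec < 0).any():
                raise FormatError(f"{gene}: negative depth values")


def read_depth_table(
    path: str | Path, intervals: dict[str, GeneInterval]
) -> DepthTable:
    """Read a TSV of (reference, 1-based position, depth) rows.

    Positions absent from the file get depth 0; duplicate rows for a position
    are resolved by taking the maximum depth (documented dialect decision —
    deterministic and conservative for presence calling).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "pos", "depth"])
    if len(df) and (df["depth"] < 0).any():
        raise FormatError("negative depth in depth table")

    depths = {}
    for gene, iv in intervals.items():
        vec = np.zeros(iv.length, dtype=np.int64)
        sub = df[df["chrom"] == iv.reference]
        if len(sub):
            pos0 = sub["pos"].to_numpy() - 1  # file is 1-based
            mask = (pos0 >= iv.start) & (pos0 < iv.end)
            np.maximum.at(vec, pos0[mask] - iv.start, sub["depth"].to_numpy()[mask])
        depths[gene] = vec
    return DepthTable(depths=depths, intervals=dict(intervals))


def write_depth_table(table: DepthTable, path: str | Path) -> None:
    """Inverse of read_depth_table (only non-zero positions are written)."""
    rows = []
    for gene, iv in table.intervals.items():
        vec = table.depths[gene]
        for off in np.nonzero(vec)[0]:
            rows.append((iv.reference, iv.start + off + 1, vec[off]))
    pd.DataFrame(rows, columns=["chrom", "pos", "depth"]).to_csv(
        path, sep="\t", header=False, index=False
    )
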