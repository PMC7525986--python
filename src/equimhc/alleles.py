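"""Amplicon-read processing and allelic-haplotype determination.

Processing mirrors a standard amplicon workflow: exact MID demultiplexing,
primer-based locus assignment at 90% identity, primer trimming, greedy
centroid clustering at 0.99 identity with per-column majority consensus, and
a two-independent-source validation rule: a sequence counts as an allelic
haplotype only when supported by at least two independent sources (two PCR
runs, or one PCR run plus a Sanger trace, clone or genome-derived
haplotype).

Identity between same-length amplicons is matches / alignment length under
ungapped end-to-end comparison; clustering is deterministic given the
canonical read ordering (length descending, then lexicographic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .seq_io import LocusConfig

#: evidence source kinds that can pair with a single PCR run
NON_PCR_SOURCES = ("sanger", "clone", "genome")


Read = tuple[str, str]  # (read_id, sequence)


def demultiplex(
    reads: list[Read], mids: list[str]
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Exact-prefix MID assignment; tags clipped from assigned reads.

    Returns (tag -> reads, unmatched reads).  Tags must be unique and
    mutually non-prefix so assignment is unambiguous.
    """
    if len(set(mids)) != len(mids):
        raise ValueError("duplicate MID tags")
    for a in mids:
        for b in mids:
            if a != b and b.startswith(a):
                raise ValueError(f"MID {a!r} is a prefix of {b!r}")
    bins: dict[str, list[Read]] = {m: [] for m in mids}
    unmatched: list[Read] = []
    for rid, seq in reads:
        for mid in mids:
            if seq.startswith(mid):
                bins[mid].append((rid, seq[len(mid):]))
                break
        else:
            unmatched.append((rid, seq))
    return bins, unmatched


def _ungapped_identity(a: str, b: str) -> float:
    n = max(len(a), len(b))
    if n == 0:
        return 1.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / n


def _primer_identity(seq: str, config: LocusConfig) -> float:
    """Identity of the read's primer-facing ends to a locus's primer pair."""
    fwd = config.primer_fwd
    rev_rc = str(Seq(config.primer_rev).reverse_complement())
    total = len(fwd) + len(rev_rc)
    if total == 0:
        return 0.0
    matches = sum(x == y for x, y in zip(seq[: len(fwd)], fwd))
    if rev_rc:
        tail = seq[-len(rev_rc):]
        matches += sum(x == y for x, y in zip(tail, rev_rc))
    return matches / total


def sort_by_primer(
    reads: list[Read],
    configs: list[LocusConfig],
    identity_cutoff: float = 0.90,
) -> tuple[dict[str, list[Read]], list[Read], list[str]]:
    """Assign reads to loci by primer identity at a 90% cutoff.

    Ties go to the highest identity, then to the first locus in config
    order (logged).  Returns (locus -> reads, unassigned, tie log).
    """
    bins: dict[str, list[Read]] = {c.name: [] for c in configs}
    unassigned: list[Read] = []
    ties: list[str] = []
    for rid, seq in reads:
        scores = [(c.name, _primer_identity(seq, c)) for c in configs]
        best = max(s for _, s in scores)
        if best < identity_cutoff:
            unassigned.append((rid, seq))
            continue
        winners = [name for name, s in scores if s == best]
        if len(winners) > 1:
            ties.append(f"{rid}: tie between {winners}, assigned {winners[0]}")
        bins[winners[0]].append((rid, seq))
    return bins, unassigned, ties


def _match_with_mismatches(fragment: str, primer: str, max_mismatches: int) -> bool:
    if len(fragment) < len(primer):
        return False
    mism = sum(x != y for x, y in zip(fragment, primer))
    return mism <= max_mismatches


def trim_primers(
    reads: list[Read],
    primer_pair: tuple[str, str],
    max_mismatches: int = 2,
) -> tuple[list[Read], int]:
    """Remove leading forward and trailing reverse-complemented reverse primer.

    Reads where either primer cannot be matched within ``max_mismatches`` are
    dropped; returns (trimmed reads, dropped count).
    """
    fwd, rev = primer_pair
    rev_rc = str(Seq(rev).reverse_complement())
    out, dropped = [], 0
    for rid, seq in reads:
        ok_fwd = _match_with_mismatches(seq[: len(fwd)], fwd, max_mismatches)
        ok_rev = not rev_rc or _match_with_mismatches(
            seq[len(seq) - len(rev_rc):], rev_rc, max_mismatches
        )
        if ok_fwd and ok_rev and len(seq) > len(fwd) + len(rev_rc):
            out.append((rid, seq[len(fwd): len(seq) - len(rev_rc)]))
        else:
            dropped += 1
    return out, dropped


@dataclass
class ReadCluster:
    member_ids: list[str]
    consensus: str
    size: int
    identity_cutoff: float
    centroid: str = ""
    warnings: list[str] = field(default_factory=list)


def _majority_consensus(seqs: list[str]) -> tuple[str, list[str]]:
    warnings = []
    length = max(len(s) for s in seqs)
    out = []
    for col in range(length):
        counts = Counter(s[col] for s in seqs if col < len(s))
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        if len(winners) > 1:
            warnings.append(
                f"consensus tie at column {col + 1}: {winners}, took {winners[0]}"
            )
        out.append(winners[0])
    return "".join(out), warnings


def cluster_and_consensus(
    reads: list[Read], identity_cutoff: float = 0.99
) -> list[ReadCluster]:
    """Greedy centroid clustering with per-column majority consensus.

    Reads are processed in canonical order (length descending, then
    lexicographic); each read joins the first centroid within the identity
    cutoff or founds a new cluster.  Clusters are returned by size
    descending (ties keep founding order).
    """
    ordered = sorted(reads, key=lambda r: (-len(r[1]), r[1], r[0]))
    centroids: list[str] = []
    members: list[list[Read]] = []
    for rid, seq in ordered:
        for k, cen in enumerate(centroids):
            if _ungapped_identity(seq, cen) >= identity_cutoff:
                members[k].append((rid, seq))
                break
        else:
            centroids.append(seq)
            members.append([(rid, seq)])
    clusters = []
    for cen, mem in zip(centroids, members):
        consensus, warns = _majority_consensus([s for _, s in mem])
        clusters.append(
            ReadCluster(
                member_ids=[r for r, _ in mem], consensus=consensus,
                size=len(mem), identity_cutoff=identity_cutoff,
                centroid=cen, warnings=warns,
            )
        )
    clusters.sort(key=lambda c: -c.size)
    return clusters


@dataclass
class AlleleCandidate:
    """A candidate haplotype with its evidence provenance.

    ``evidence`` entries are (kind, source_id) pairs, e.g. ("pcr", "runA"),
    ("sanger", "trace12"), ("genome", "EquCab3").  Distinct PCR run IDs are
    independent sources; non-PCR kinds each count as one further source.
    """

    sequence: str
    locus_tag: str
    species_tag: str
    evidence: set[tuple[str, str]] = field(default_factory=set)
    validated: bool = False
    name: str = ""

    def n_independent_sources(self) -> int:
        pcr_runs = {src for kind, src in self.evidence if kind == "pcr"}
        other = {kind for kind, _ in self.evidence if kind != "pcr"}
        return len(pcr_runs) + len(other)


@dataclass
class AlleleSet:
    alleles: list[AlleleCandidate]
    discarded: list[AlleleCandidate] = field(default_factory=list)

    def sequences(self) -> list[str]:
        return [a.sequence for a in self.alleles]


def validate_alleles(candidates: list[AlleleCandidate]) -> AlleleSet:
    """Keep candidates with >= 2 independent sources and assign names.

    Names follow Klein-style nomenclature: species tag + locus + "*" +
    zero-padded serial (e.g. ``Eqca-DQB1*0001``), serials assigned by
    first-seen order within each species/locus.
    """
    kept, discarded = [], []
    serial: Counter = Counter()
    for cand in candidates:
        if cand.n_independent_sources() >= 2:
            key = (cand.species_tag, cand.locus_tag)
            serial[key] += 1
            cand.validated = True
            cand.name = f"{cand.species_tag}-{cand.locus_tag}*{serial[key]:04d}"
            kept.append(cand)
        else:
            cand.validated = False
            discarded.append(cand)
    return AlleleSet(alleles=kept, discarded=discarded)


def call_alleles_from_runs(
    runs: dict[str, list[Read]],
    locus: LocusConfig,
    species_tag: str,
    identity_cutoff: float = 0.99,
    min_cluster_size: int = 1,
) -> AlleleSet:
    """End-to-end allele calling from primer-trimmed reads of several PCR runs.

    Each run is clustered independently; identical consensus sequences seen
    in different runs accumulate evidence and survive the two-source rule.
    """
    candidates: dict[str, AlleleCandidate] = {}
    for run_id, reads in runs.items():
        for cluster in cluster_and_consensus(reads, identity_cutoff):
            if cluster.size < min_cluster_size:
                continue
            cand = candidates.setdefault(
                cluster.consensus,
                AlleleCandidate(
                    sequence=cluster.consensus, locus_tag=locus.name,
                    species_tag=species_tag,
                ),
            )
            cand.evidence.add(("pcr", run_id))
    return validate_alleles(list(candidates.values()))
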