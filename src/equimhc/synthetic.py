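"""Synthetic inputs with the statistical structure the analysis assumes.

The codon simulator is an MG94xHKY-style process: one-nucleotide codon
exchanges at rate proportional to the target codon frequency, multiplied by
kappa for transitions and by the site class's omega for nonsynonymous
changes.  Each class's generator is scaled to one expected substitution per
codon per unit branch length, so branch lengths are in expected
substitutions/codon.  Defaults are kappa = 1 and uniform codon frequencies:
the Nei–Gojobori counting used downstream assumes no transition/transversion
or compositional bias, so these defaults make omega = 1 simulations genuinely
neutral for that statistic (a kappa > 1 process is supported and documented
as inducing conservative dN - dS).

Reads are decorated as MID + forward primer + allele + reverse-complemented
reverse primer, with i.i.d. substitution errors on the allele part only
(the allele-calling logic under test is identity clustering, not gapped
alignment; indels and chimeras are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._codons import AMINO_ACID, BASES, CODON_INDEX, SENSE_CODONS, is_transition
from .phylo import Node, Tree
from .seq_io import CodonAlignment, DepthTable, GeneInterval

_SENSE = np.array([CODON_INDEX[c] for c in SENSE_CODONS])


@dataclass
class SiteClassModel:
    """Codon substitution model with site-class-specific omega.

    ``class_of_codon`` assigns each alignment codon to a key of
    ``omega_by_class`` (e.g. "ABS" vs "background").
    """

    omega_by_class: dict[str, float]
    class_of_codon: list[str]
    kappa: float = 1.0
    codon_frequencies: np.ndarray | None = None  # over the 61 sense codons

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if any(w < 0 for w in self.omega_by_class.values()):
            raise ValueError("omega must be >= 0")
        unknown = set(self.class_of_codon) - set(self.omega_by_class)
        if unknown:
            raise ValueError(f"codon classes without omega: {sorted(unknown)}")
        if self.codon_frequencies is None:
            self.codon_frequencies = np.full(61, 1.0 / 61)
        self.codon_frequencies = np.asarray(self.codon_frequencies, dtype=float)
        if self.codon_frequencies.shape != (61,):
            raise ValueError("codon_frequencies must have 61 entries")
        if abs(self.codon_frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must sum to 1")

    @property
    def n_codons(self) -> int:
        return len(self.class_of_codon)


def neutral_model(n_codons: int, kappa: float = 1.0) -> SiteClassModel:
    """All sites omega = 1."""
    return SiteClassModel({"neutral": 1.0}, ["neutral"] * n_codons, kappa=kappa)


def two_class_model(
    n_codons: int,
    abs_fraction: float = 0.3,
    omega_abs: float = 3.0,
    omega_background: float = 0.5,
    kappa: float = 1.0,
    seed: int = 0,
) -> SiteClassModel:
    """Background sites plus a fraction of ABS-like sites with elevated omega."""
    rng = np.random.default_rng(seed)
    n_abs = int(round(abs_fraction * n_codons))
    abs_idx = set(rng.choice(n_codons, size=n_abs, replace=False).tolist())
    classes = ["ABS" if i in abs_idx else "background" for i in range(n_codons)]
    return SiteClassModel(
        {"ABS": omega_abs, "background": omega_background}, classes, kappa=kappa
    )


def mg94_rate_matrix(omega: float, kappa: float = 1.0,
                     frequencies: np.ndarray | None = None,
                     normalize: bool = True) -> np.ndarray:
    """61x61 MG94xHKY generator, scaled to unit expected rate by default."""
    if frequencies is None:
        frequencies = np.full(61, 1.0 / 61)
    q = np.zeros((61, 61))
    for a, ca in enumerate(SENSE_CODONS):
        for b, cb in enumerate(SENSE_CODONS):
            if a == b:
                continue
            diff = [k for k in range(3) if ca[k] != cb[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            rate = frequencies[b]
            if is_transition(ca[k], cb[k]):
                rate *= kappa
            if AMINO_ACID[ca] != AMINO_ACID[cb]:
                rate *= omega
            q[a, b] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        mean_rate = float(-(frequencies * np.diag(q)).sum())
        if mean_rate > 0:
            q /= mean_rate
    return q


def _spectral(q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible generator via pi-symmetrization."""
    sq = np.sqrt(pi)
    sym = (q * sq[:, None]) / sq[None, :]
    lam, v = np.linalg.eigh(0.5 * (sym + sym.T))
    left = v.T * sq[None, :]
    right = v / sq[:, None]
    return lam, right, left


def transition_probabilities(lam, right, left, t: float) -> np.ndarray:
    p = (right * np.exp(lam * t)[None, :]) @ left
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def simulate_codon_alignment(
    tree: Tree, model: SiteClassModel, n_codons: int | None = None,
    seed: int = 0,
) -> CodonAlignment:
    """Evolve codons independently along ``tree`` under ``model``.

    Branch lengths are expected substitutions per codon.  Deterministic for a
    given seed; never produces stop codons (the state space is the 61 sense
    codons).
    """
    tips = tree.tips()
    if not tips or tree.root.is_tip:
        raise ValueError("empty tree")
    if n_codons is None:
        n_codons = model.n_codons
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if n_codons != model.n_codons:
        raise ValueError("n_codons does not match the model's class vector")

    rng = np.random.default_rng(seed)
    pi = model.codon_frequencies
    class_sites = {}
    for c in set(model.class_of_codon):
        class_sites[c] = np.array(
            [i for i, k in enumerate(model.class_of_codon) if k == c]
        )
    # single mixture-wide normalization (the usual site-class convention):
    # branch lengths are expected substitutions/codon averaged over classes,
    # so high-omega classes evolve proportionally faster
    raw_q = {
        c: mg94_rate_matrix(model.omega_by_class[c], model.kappa, pi,
                            normalize=False)
        for c in class_sites
    }
    weights = {c: len(sites) / n_codons for c, sites in class_sites.items()}
    mixture_rate = sum(
        weights[c] * float(-(pi * np.diag(q)).sum()) for c, q in raw_q.items()
    )
    spectra = {
        c: _spectral(q / mixture_rate, pi) for c, q in raw_q.items()
    }

    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(61, size=n_codons, p=pi)
    }
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        out = parent_states.copy()
        if node.length > 0:
            for c, sites in class_sites.items():
                p = transition_probabilities(*spectra[c], node.length)
                cum = np.cumsum(p, axis=1)
                u = rng.random(len(sites))
                rows = cum[parent_states[sites]]
                out[sites] = (rows < u[:, None]).sum(axis=1)
        states[id(node)] = out

    ids, seqs, species = [], [], []
    for tip in tips:
        ids.append(tip.name)
        species.append(tip.name.split("|")[0])
        seqs.append("".join(SENSE_CODONS[s] for s in states[id(tip)]))
    return CodonAlignment(ids=ids, seqs=seqs, species_tags=species)


def make_recombinant(
    aln_left: CodonAlignment, aln_right: CodonAlignment, breakpoint: int
) -> CodonAlignment:
    """Concatenate codons [0, breakpoint) of left with [breakpoint, end) of right.

    Both alignments must share tip labels; rows of the right alignment are
    reordered to match the left.  The true breakpoint is recorded on the
    result as ``true_breakpoint`` for test oracles.
    """
    if set(aln_left.ids) != set(aln_right.ids):
        raise ValueError("tip label mismatch between the two alignments")
    if not 0 <= breakpoint <= min(aln_left.n_codons, aln_right.n_codons):
        raise ValueError("breakpoint outside the alignment")
    right_index = {rid: i for i, rid in enumerate(aln_right.ids)}
    seqs = []
    for i, rid in enumerate(aln_left.ids):
        left_part = aln_left.in_frame(i)[: 3 * breakpoint]
        right_part = aln_right.in_frame(right_index[rid])[3 * breakpoint:]
        seqs.append(left_part + right_part)
    out = CodonAlignment(
        ids=list(aln_left.ids), seqs=seqs,
        species_tags=list(aln_left.species_tags),
        locus_tags=list(aln_left.locus_tags),
    )
    out.true_breakpoint = breakpoint
    return out


def simulate_amplicon_reads(
    alleles: list[str],
    copies_per_allele: int,
    error_rate: float,
    mids: list[str],
    primer_pair: tuple[str, str],
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Decorated amplicon reads with substitution errors.

    Each MID tag plays the role of one PCR run: for every tag, every allele
    contributes ``copies_per_allele`` reads.  Returns (reads, provenance)
    where reads are (read_id, sequence) pairs and the provenance table maps
    read_id -> (mid, allele_index, n_errors).
    """
    if not alleles:
        raise ValueError("empty allele list")
    if not 0 <= error_rate < 0.05:
        raise ValueError("error_rate must be in [0, 0.05)")
    fwd, rev = primer_pair
    rev_rc = str(Seq(rev).reverse_complement())
    rng = np.random.default_rng(seed)
    reads, prov = [], []
    counter = 0
    for mid in mids:
        for ai, allele in enumerate(alleles):
            for _ in range(copies_per_allele):
                bases = list(allele)
                errs = np.nonzero(rng.random(len(bases)) < error_rate)[0]
                for pos in errs:
                    alternatives = [b for b in BASES if b != bases[pos]]
                    bases[pos] = alternatives[rng.integers(3)]
                seq = mid + fwd + "".join(bases) + rev_rc
                rid = f"read_{counter:05d}"
                reads.append((rid, seq))
                prov.append((rid, mid, ai, len(errs)))
                counter += 1
    prov_df = pd.DataFrame(prov, columns=["read_id", "mid", "allele_index", "n_errors"])
    return reads, prov_df


def simulate_depth_track(
    interval_length: int,
    present: bool,
    mean_depth: float = 20.0,
    dropout_fraction: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-base depth vector for one gene.

    Present genes: Poisson(mean_depth) per base with ``dropout_fraction`` of
    positions zeroed.  Absent genes: at least 90% zero positions with sparse
    depth-1..2 noise on the rest.
    """
    if not 0 <= dropout_fraction <= 1:
        raise ValueError("dropout_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vec = np.zeros(interval_length, dtype=np.int64)
    if present:
        vec = rng.poisson(mean_depth, size=interval_length)
        n_drop = int(round(dropout_fraction * interval_length))
        if n_drop:
            vec[rng.choice(interval_length, size=n_drop, replace=False)] = 0
    else:
        noise_fraction = rng.uniform(0.0, 0.09)
        n_noise = int(noise_fraction * interval_length)
        if n_noise:
            pos = rng.choice(interval_length, size=n_noise, replace=False)
            vec[pos] = rng.integers(1, 3, size=n_noise)
    return vec


def simulate_depth_table(
    genes: dict[str, tuple[int, bool]],
    mean_depth: float = 20.0,
    dropout_fraction: float = 0.0,
    seed: int = 0,
    reference: str = "chr20",
) -> DepthTable:
    """DepthTable over several genes laid end-to-end on one reference."""
    rng = np.random.default_rng(seed)
    depths, intervals = {}, {}
    offset = 0
    for gene, (length, present) in genes.items():
        depths[gene] = simulate_depth_track(
            length, present, mean_depth, dropout_fraction,
            seed=int(rng.integers(2**31)),
        )
        intervals[gene] = GeneInterval(reference, offset, offset + length)
        offset += length
    return DepthTable(depths=depths, intervals=intervals)


def random_tree(
    n_tips: int, seed: int = 0, mean_branch_length: float = 0.1,
    prefix: str = "T",
) -> Tree:
    """Random unrooted binary topology with exponential branch lengths.

    Built by attaching tips one at a time to a uniformly chosen existing
    edge; branch lengths are i.i.d. Exponential(mean_branch_length), in
    expected substitutions/codon.  Tips are named ``T01..Tnn``.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)

    def bl() -> float:
        return float(rng.exponential(mean_branch_length))

    root = Node()
    names = [f"{prefix}{i + 1:02d}" for i in range(n_tips)]
    for name in names[:3]:
        root.add(Node(name, bl()))
    tree = Tree(root)
    for name in names[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        mid = Node("", target.length / 2)
        target.length /= 2
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(Node(name, bl()))
    return tree


def allele_genealogy(
    n_tips: int,
    seed: int = 0,
    terminal_branch_length: float = 0.4,
    internal_scale: float = 0.1,
    prefix: str = "A",
) -> Tree:
    """MHC-like allele genealogy: deep, near-star shape.

    Long-term balancing selection keeps allelic lineages segregating far
    beyond neutral coalescence times, so allele genealogies at MHC loci are
    comb/star-like with long terminal branches.  This generator emulates
    that: a random topology whose internal branches are short
    (Exponential(internal_scale)) and whose terminal branches are long
    (Exponential(terminal_branch_length)), lengths in expected
    substitutions/codon.
    """
    tree = random_tree(n_tips, seed=seed, mean_branch_length=internal_scale,
                       prefix=prefix)
    rng = np.random.default_rng(seed + 1)
    for node in tree.postorder():
        if node.is_tip:
            node.length = float(rng.exponential(terminal_branch_length))
    return tree


# ---------------------------------------------------------------------------
# demo topologies
# ---------------------------------------------------------------------------

#: 12-tip equid-like topology: a caballine clade and non-caballine ass and
#: zebra clades.  A testing fixture, not a claim about the true tree.
DEMO_TOPOLOGY = (
    "((E_caballus_1:1,E_caballus_2:1):1,E_przewalskii:1.5):2,"
    "(((E_asinus:1,E_africanus:1):1,(E_hemionus:1,E_kiang:1):1):1.5),"
    "((E_grevyi:1.5,(E_zebra_hartmannae:1,((E_quagga_1:0.5,E_quagga_2:0.5):0.5,"
    "E_quagga_3:1):0.5):0.5):1.5)"
)

#: same 12 labels, strongly conflicting clade structure
CONFLICTING_TOPOLOGY = (
    "((E_caballus_1:1,E_grevyi:1):1,E_hemionus:1.5):2,"
    "(((E_caballus_2:1,E_zebra_hartmannae:1):1,(E_quagga_1:1,E_asinus:1):1):1.5),"
    "((E_przewalskii:1.5,(E_kiang:1,((E_africanus:0.5,E_quagga_2:0.5):0.5,"
    "E_quagga_3:1):0.5):0.5):1.5)"
)


def demo_tree(scale: float = 0.1) -> Tree:
    """The bundled 12-tip topology with branch lengths multiplied by scale."""
    return _scaled(DEMO_TOPOLOGY, scale)


def conflicting_tree(scale: float = 0.1) -> Tree:
    """A topology over the same 12 tips conflicting with demo_tree."""
    return _scaled(CONFLICTING_TOPOLOGY, scale)


def _scaled(template: str, scale: float) -> Tree:
    tree = Tree.from_newick(f"({template});")
    for node in tree.postorder():
        node.length *= scale
    return tree
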