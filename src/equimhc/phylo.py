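"""Distance trees and a JC69 likelihood engine.

Neighbor joining (via scikit-bio) on Jukes–Cantor distances provides the
working topologies; Felsenstein pruning under JC69 with per-branch 1-D
likelihood maximization provides the fits consumed by the single-breakpoint
recombination screen and the per-site selection methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .seq_io import CodonAlignment

#: distances at or beyond JC saturation (p >= 0.75) are capped here
SATURATION_CAP = 5.0

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class Node:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name: str = "", length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.support: float | None = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary (typically trifurcating) root."""

    root: Node
    warnings: list[str] = field(default_factory=list)

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out[::-1]

    def preorder(self):
        return self.postorder()[::-1]

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            c = Node(n.name, n.length)
            c.support = n.support
            for ch in n.children:
                c.add(clone(ch))
            return c

        return Tree(clone(self.root), list(self.warnings))

    # -- newick ------------------------------------------------------------
    def to_newick(self, with_supports: bool = False) -> str:
        def fmt(n: Node) -> str:
            if n.is_tip:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = ""
            if with_supports and n.support is not None:
                label = f"{n.support:g}"
            return f"({inner}){label}:{n.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )

        def convert(dn) -> Node:
            name = dn.taxon.label if dn.taxon else (dn.label or "")
            n = Node(name=name, length=dn.edge.length or 0.0)
            if dn.label and not dn.is_leaf():
                try:
                    n.support = float(dn.label)
                    n.name = ""
                except ValueError:
                    pass
            for c in dn.child_nodes():
                n.add(convert(c))
            return n

        root = convert(dt.seed_node)
        root.length = 0.0
        return cls(root)

    # -- topology ----------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions of the unrooted topology.

        Each is represented by the side not containing the alphabetically
        first tip, making the representation rooting-invariant.
        """
        all_tips = frozenset(self.tip_names())
        anchor = min(all_tips)
        out = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_tip:
                below[id(n)] = frozenset([n.name])
            else:
                clade = frozenset().union(*(below[id(c)] for c in n.children))
                below[id(n)] = clade
                if n is self.root:
                    continue
                side = all_tips - clade if anchor in clade else clade
                if 1 < len(side) < len(all_tips) - 1:
                    out.add(side)
        return out


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

def jc_correct(p: np.ndarray | float) -> np.ndarray | float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3), capped at saturation."""
    p = np.asarray(p, dtype=float)
    d = np.where(p < 0.75, -0.75 * np.log(np.clip(1 - 4 * p / 3, 1e-300, None)),
                 SATURATION_CAP)
    return np.minimum(d, SATURATION_CAP)


_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_CODE.items():
    _ENCODE_LUT[ord(_b)] = _i


def encode_nucleotides(aln: CodonAlignment) -> np.ndarray:
    """(n, L) integer matrix; 4 marks gap/ambiguous positions."""
    raw = np.frombuffer("".join(aln.seqs).encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw].reshape(aln.n_seqs, aln.length)


def jc_distance_matrix(aln: CodonAlignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise JC69 distances under the alignment's gap policy.

    Returns (matrix, ids).  Saturated pairs (p >= 0.75) are capped at
    SATURATION_CAP and a warning is recorded on the alignment.
    """
    if aln.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    arr = encode_nucleotides(aln)
    valid = arr < 4
    if aln.gap_policy == "complete-deletion":
        keep = valid.all(axis=0)
        arr = arr[:, keep]
        valid = valid[:, keep]
    n = aln.n_seqs
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no overlapping sites for pair {aln.ids[i]}, {aln.ids[j]}"
                )
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if p >= 0.75:
                aln.warnings.append(
                    f"saturated distance for pair {aln.ids[i]}, {aln.ids[j]}"
                )
            d[i, j] = d[j, i] = float(jc_correct(p))
    return d, list(aln.ids)


def _clamp_negative_branches(tree: Tree) -> None:
    """Set negative branch lengths to 0, moving the deficit to a sibling."""
    for node in tree.postorder():
        if node is tree.root or node.length >= 0:
            continue
        deficit = node.length
        node.length = 0.0
        siblings = [s for s in node.parent.children if s is not node]
        if siblings:
            siblings[0].length = max(0.0, siblings[0].length + deficit)


def nj_tree(matrix: np.ndarray, ids: list[str]) -> Tree:
    """Neighbor joining; negative branch lengths clamped to zero with the
    deficit moved to the adjacent (sibling) branch."""
    matrix = np.asarray(matrix, dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if n == 3:
        d_ab, d_ac, d_bc = matrix[0, 1], matrix[0, 2], matrix[1, 2]
        root = Node()
        for name, length in zip(
            ids,
            [(d_ab + d_ac - d_bc) / 2, (d_ab + d_bc - d_ac) / 2,
             (d_ac + d_bc - d_ab) / 2],
        ):
            root.add(Node(name, length))
        tree = Tree(root)
        _clamp_negative_branches(tree)
        return tree
    dm = DistanceMatrix(matrix, ids)
    sk = _skbio_nj(dm, neg_as_zero=False)
    tree = Tree.from_newick(str(sk))
    # skbio returns a bifurcating rooted shape; merge the root's short edge to
    # get the canonical unrooted (trifurcating) representation
    if len(tree.root.children) == 2:
        a, b = tree.root.children
        keep, fold = (a, b) if not a.is_tip else (b, a)
        if not keep.is_tip:
            fold.length += keep.length
            tree.root.children = keep.children + [fold]
            for c in tree.root.children:
                c.parent = tree.root
    _clamp_negative_branches(tree)
    return tree


# ---------------------------------------------------------------------------
# JC69 likelihood
# ---------------------------------------------------------------------------

def jc_transition(t: float) -> np.ndarray:
    x = np.exp(-4.0 * max(t, 0.0) / 3.0)
    p = np.full((4, 4), (1.0 - x) / 4.0)
    np.fill_diagonal(p, (1.0 + 3.0 * x) / 4.0)
    return p


def _tip_partials(aln: CodonAlignment) -> dict[str, np.ndarray]:
    arr = encode_nucleotides(aln)
    eye = np.vstack([np.eye(4), np.ones(4)])
    return {name: eye[arr[i]] for i, name in enumerate(aln.ids)}


def _lift(d: np.ndarray, t: float) -> np.ndarray:
    """P(t) applied to per-site partials, using the JC closed form.

    (P(t) d)_i = b*S + x*d_i with x = exp(-4t/3), b = (1-x)/4, S = sum(d).
    """
    x = np.exp(-4.0 * max(t, 0.0) / 3.0)
    return x * d + ((1.0 - x) / 4.0) * d.sum(axis=1, keepdims=True)


def _down_partials(tree: Tree, tips: dict[str, np.ndarray]) -> dict[int, np.ndarray]:
    down = {}
    for node in tree.postorder():
        if node.is_tip:
            down[id(node)] = tips[node.name]
        else:
            part = None
            for c in node.children:
                lifted = _lift(down[id(c)], c.length)
                part = lifted if part is None else part * lifted
            down[id(node)] = part
    return down


def jc69_log_likelihood(
    aln: CodonAlignment, tree: Tree
) -> tuple[float, np.ndarray]:
    """Felsenstein pruning under JC69 with uniform base frequencies.

    Returns (total log-likelihood, per-site log-likelihoods).
    """
    missing = set(tree.tip_names()) - set(aln.ids)
    if missing:
        raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
    tips = _tip_partials(aln)
    down = _down_partials(tree, tips)
    site_l = 0.25 * down[id(tree.root)].sum(axis=1)
    logs = np.log(np.clip(site_l, 1e-300, None))
    return float(logs.sum()), logs


def _optimize_edge(a: np.ndarray, d: np.ndarray, t_max: float) -> float:
    """Exact 1-D branch-length maximization of the JC edge likelihood.

    With JC, (P(t) d)_i = b(t)*S + x(t)*d_i where x = exp(-4t/3) and
    b = (1-x)/4, so the per-site edge likelihood is linear in x:
    0.25*(S*T/4) + x*(U/4 - S*T/16).  The log-likelihood is concave in x;
    a safeguarded Newton iteration on x is exact and fast.
    """
    s = d.sum(axis=1)
    t_ = a.sum(axis=1)
    u = (a * d).sum(axis=1)
    c0 = s * t_ / 16.0
    c1 = u / 4.0 - c0
    x_min = float(np.exp(-4.0 * t_max / 3.0))

    def slope(x: float) -> float:
        return float((c1 / np.maximum(c0 + c1 * x, 1e-300)).sum())

    if slope(1.0) >= 0.0:
        return 0.0
    if slope(x_min) <= 0.0:
        return t_max
    lo, hi = x_min, 1.0
    x = 0.5 * (lo + hi)
    for _ in range(30):
        ratio = c1 / np.maximum(c0 + c1 * x, 1e-300)
        g = float(ratio.sum())
        h = -float((ratio * ratio).sum())
        if g > 0:
            lo = x
        else:
            hi = x
        x_new = x - g / h if h < 0 else 0.5 * (lo + hi)
        if not lo < x_new < hi:
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) < 1e-8:
            x = x_new
            break
        x = x_new
    return float(-0.75 * np.log(x))


def optimize_branch_lengths(
    aln: CodonAlignment,
    tree: Tree,
    tol: float = 1e-6,
    max_sweeps: int = 20,
    t_max: float = 8.0,
) -> tuple[Tree, float]:
    """Coordinate-wise branch-length maximization of the JC69 likelihood.

    Sweeps over edges until the total log-likelihood improves by less than
    ``tol`` or ``max_sweeps`` is reached; a sweep that would decrease the
    total (possible because partials are refreshed per sweep, not per edge)
    is rolled back, guaranteeing monotone sweeps.
    """
    tree = tree.copy()
    tips = _tip_partials(aln)
    nodes = [n for n in tree.postorder() if n is not tree.root]
    best, _ = jc69_log_likelihood(aln, tree)

    for _ in range(max_sweeps):
        saved = [n.length for n in nodes]
        down = _down_partials(tree, tips)
        lifted = {id(n): _lift(down[id(n)], n.length) for n in nodes}
        up: dict[int, np.ndarray] = {}
        for node in tree.preorder():
            for child in node.children:
                part = None
                for s in node.children:
                    if s is child:
                        continue
                    part = lifted[id(s)] if part is None else part * lifted[id(s)]
                if node is not tree.root:
                    lifted_up = _lift(up[id(node)], node.length)
                    part = lifted_up if part is None else part * lifted_up
                up[id(child)] = part
        for node in nodes:
            node.length = _optimize_edge(up[id(node)], down[id(node)], t_max)
            if node.length < 1e-8:
                node.length = 0.0
        total, _ = jc69_log_likelihood(aln, tree)
        if total < best - 1e-9:
            for n, length in zip(nodes, saved):
                n.length = length
            break
        gain = total - best
        best = total
        if gain < tol:
            break
    return tree, best


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: CodonAlignment, n_reps: int = 1000, seed: int = 0
) -> Tree:
    """NJ tree with bootstrap supports from column resampling.

    Support of each bipartition of the point-estimate tree is the percentage
    of replicate NJ trees containing it.  Alignments without variable sites
    yield a star-like tree; this is flagged in the tree's warnings.
    """
    rng = np.random.default_rng(seed)
    mat, ids = jc_distance_matrix(aln)
    tree = nj_tree(mat, ids)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    L = aln.length
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = CodonAlignment(
            ids=list(aln.ids),
            seqs=["".join(s[c] for c in cols) for s in aln.seqs],
            gap_policy=aln.gap_policy,
        )
        try:
            rep_mat, rep_ids = jc_distance_matrix(rep)
        except ValueError:
            continue
        rep_bps = nj_tree(rep_mat, rep_ids).bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    below: dict[int, frozenset[str]] = {}
    all_tips = frozenset(tree.tip_names())
    anchor = min(all_tips)
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.name])
            continue
        clade = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = clade
        if node is tree.root:
            continue
        side = all_tips - clade if anchor in clade else clade
        if side in counts:
            node.support = 100.0 * counts[side] / n_reps
    if not target:
        tree.warnings.append("no internal bipartitions (star-like tree)")
    mat_max = mat[np.triu_indices_from(mat, 1)]
    if mat_max.size and mat_max.max() == 0:
        tree.warnings.append("no variable sites; tree is star-like")
    return tree
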