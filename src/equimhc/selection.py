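"""Global and site-wise selection inference on codon alignments.

Pairwise rates follow Nei–Gojobori (1986) counting: per-codon synonymous
site fractions from the universal code (changes to stop codons excluded),
differences averaged over all minimal substitution pathways (pathways
through stops excluded), and the Jukes–Cantor correction
d = -(3/4) ln(1 - 4p/3) applied to the proportions.

The global test is the one-tailed codon-based Z-test of positive selection
(alternative dN > dS) with a bootstrap-over-codon-sites variance.  Two
site-wise methods are provided: a counting method in the SLAC mould (Fitch
ancestral reconstruction plus a per-site binomial test) and a per-site
likelihood method in the FEL mould (two-rate MG94xJC fit on a fixed tree
with a 1-df likelihood-ratio test).  A site is called selected by consensus
only when at least two methods agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import chi2, norm

from ._codons import (
    MISSING,
    SENSE_CODONS,
    CODON_INDEX,
    AMINO_ACID,
    difference_tables,
    encode_codons,
    synonymous_site_fractions,
)
from .phylo import Tree, jc_correct
from .seq_io import CodonAlignment
from .synthetic import mg94_rate_matrix

_SENSE_SET = frozenset(CODON_INDEX[c] for c in SENSE_CODONS)
_CODON_TO_SENSE = {CODON_INDEX[c]: k for k, c in enumerate(SENSE_CODONS)}

DEFAULT_SITE_P = 0.1


# ---------------------------------------------------------------------------
# pairwise NG86
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseRates:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    n_codons: int
    saturated: bool = False


def _codon_matrix(aln: CodonAlignment) -> np.ndarray:
    return np.vstack([encode_codons(aln.in_frame(i)) for i in range(aln.n_seqs)])


def _pair_site_arrays(c1: np.ndarray, c2: np.ndarray):
    """Per-codon (Sd, Nd, S, N) contributions for one sequence pair.

    Codons that are missing or stops in either sequence contribute zeros.
    """
    sfrac = synonymous_site_fractions()
    sd_tab, nd_tab = difference_tables()
    valid = (c1 != MISSING) & (c2 != MISSING)
    a = np.where(valid, c1, 0)
    b = np.where(valid, c2, 0)
    s_pair = 0.5 * (sfrac[a] + sfrac[b])
    sd = sd_tab[a, b]
    nd = nd_tab[a, b]
    ok = valid & np.isfinite(s_pair) & np.isfinite(sd)
    zero = np.zeros_like(s_pair)
    s_sites = np.where(ok, s_pair, zero)
    n_sites = np.where(ok, 3.0 - s_pair, zero)
    return (np.where(ok, sd, zero), np.where(ok, nd, zero), s_sites, n_sites)


def ng86_pair(seq1: str, seq2: str) -> PairwiseRates:
    """Nei–Gojobori rates for a pair of in-frame codon sequences.

    Gapped/ambiguous codons are excluded pairwise; a proportion at or beyond
    JC saturation (p >= 0.75) caps the rate and sets ``saturated``.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequence length mismatch")
    if len(seq1) % 3:
        raise ValueError("length must be a multiple of 3")
    c1, c2 = encode_codons(seq1), encode_codons(seq2)
    for c in (c1, c2):
        if any(k not in _SENSE_SET for k in c[:-1] if k != MISSING):
            raise ValueError("internal stop codon in input")
    sd, nd, s_sites, n_sites = _pair_site_arrays(c1, c2)
    S, N = float(s_sites.sum()), float(n_sites.sum())
    Sd, Nd = float(sd.sum()), float(nd.sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    saturated = pS >= 0.75 or pN >= 0.75
    return PairwiseRates(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        dS=float(jc_correct(pS)), dN=float(jc_correct(pN)),
        n_codons=int(((c1 != MISSING) & (c2 != MISSING)).sum()),
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# global Z-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZTestResult:
    dN: float
    dS: float
    mean_dN_minus_dS: float
    Z: float
    p_one_tailed: float
    n_boot: int
    seed: int
    se: float


def _alignment_pair_arrays(aln: CodonAlignment):
    codons = _codon_matrix(aln)
    n = aln.n_seqs
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    sd = np.empty((len(pairs), aln.n_codons))
    nd = np.empty_like(sd)
    ss = np.empty_like(sd)
    nn = np.empty_like(sd)
    for k, (i, j) in enumerate(pairs):
        sd[k], nd[k], ss[k], nn[k] = _pair_site_arrays(codons[i], codons[j])
    return sd, nd, ss, nn


def _mean_rates(sd, nd, ss, nn):
    """Mean dN and dS over pairs given per-pair totals (vectors or matrices)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(ss > 0, sd / np.where(ss > 0, ss, 1.0), 0.0)
        pn = np.where(nn > 0, nd / np.where(nn > 0, nn, 1.0), 0.0)
    ds = jc_correct(ps)
    dn = jc_correct(pn)
    return np.mean(dn, axis=0), np.mean(ds, axis=0)


def global_z_test(
    aln: CodonAlignment, n_boot: int = 1000, seed: int = 0
) -> ZTestResult:
    """Codon-based Z-test of positive selection averaged over all pairs.

    dN and dS are averaged over all sequence pairs (rows flagged for internal
    stop codons are excluded); the variance of dN - dS comes from ``n_boot``
    bootstrap resamplings of codon sites; Z = (dN - dS)/SE with a one-tailed
    normal p-value for the alternative dN > dS.  When dN <= dS or the
    statistic is degenerate (no variation, SE = 0) the reported p is 1.0,
    matching the one-tailed convention.
    """
    work = aln.without_stop_flagged()
    if work.n_seqs < 2:
        raise ValueError("need at least 2 analyzable sequences")
    sd, nd, ss, nn = _alignment_pair_arrays(work)
    dn, ds = _mean_rates(sd.sum(1), nd.sum(1), ss.sum(1), nn.sum(1))
    diff = float(dn - ds)

    rng = np.random.default_rng(seed)
    L = work.n_codons
    counts = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T.astype(float)
    dn_b, ds_b = _mean_rates(sd @ counts, nd @ counts, ss @ counts, nn @ counts)
    se = float(np.std(dn_b - ds_b, ddof=1))

    if se == 0.0 or not np.isfinite(se):
        z = 0.0
        p = 1.0
    else:
        z = diff / se
        p = float(norm.sf(z)) if z > 0 else 1.0
    return ZTestResult(
        dN=float(dn), dS=float(ds), mean_dN_minus_dS=diff, Z=float(z),
        p_one_tailed=p, n_boot=n_boot, seed=seed, se=se,
    )


# ---------------------------------------------------------------------------
# SLAC-style counting method
# ---------------------------------------------------------------------------

def _fitch_states(tree: Tree, tip_codons: dict[str, int]) -> dict[int, int]:
    """Fitch parsimony codon states for one site; ties take the lowest codon index."""
    sets: dict[int, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            c = tip_codons[node.name]
            sets[id(node)] = (
                frozenset([c]) if c in _SENSE_SET else frozenset(_SENSE_SET)
            )
        else:
            child_sets = [sets[id(c)] for c in node.children]
            inter = frozenset.intersection(*child_sets)
            sets[id(node)] = inter if inter else frozenset.union(*child_sets)
    states: dict[int, int] = {}
    for node in tree.preorder():
        if node is tree.root:
            states[id(node)] = min(sets[id(node)])
        else:
            p_state = states[id(node.parent)]
            s = sets[id(node)]
            states[id(node)] = p_state if p_state in s else min(s)
    return states


def slac_sites(
    aln: CodonAlignment, tree: Tree, p_threshold: float = DEFAULT_SITE_P
) -> pd.DataFrame:
    """Per-codon counting test of selection on a fixed tree.

    Ancestral codons come from Fitch parsimony (ties resolved to the first
    codon in lexicographic order); per-branch changes are decomposed into
    synonymous/nonsynonymous fractions by NG86 pathway averaging; the
    expected nonsynonymous fraction per site derives from the NG86 site
    counts of the node states; observed Nd is tested against it with a
    binomial tail (extended to fractional counts via the regularized
    incomplete beta function).
    """
    missing = set(tree.tip_names()) - set(aln.ids)
    if missing:
        raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
    sfrac = synonymous_site_fractions()
    sd_tab, nd_tab = difference_tables()
    codons = _codon_matrix(aln)
    row = {rid: i for i, rid in enumerate(aln.ids)}
    nodes = tree.postorder()

    records = []
    for site in range(aln.n_codons):
        tip_codons = {name: int(codons[row[name], site]) for name in tree.tip_names()}
        observed = {c for c in tip_codons.values() if c in _SENSE_SET}
        if len(observed) <= 1:
            records.append((site + 1, 0.0, 0.0, np.nan, 1.0, 1.0, 1.0, "none"))
            continue
        states = _fitch_states(tree, tip_codons)
        sd = nd = 0.0
        for node in nodes:
            if node is tree.root:
                continue
            a, b = states[id(node.parent)], states[id(node)]
            if a != b:
                sd += sd_tab[a, b]
                nd += nd_tab[a, b]
        state_list = [states[id(n)] for n in nodes]
        e_syn = float(np.mean([sfrac[c] / 3.0 for c in state_list]))
        e_non = 1.0 - e_syn
        total = sd + nd
        if total == 0:
            p_pos = p_neg = p_two = 1.0
            cls = "none"
        else:
            p_pos = float(betainc(nd, sd + 1.0, e_non)) if nd > 0 else 1.0
            p_neg = float(betainc(sd, nd + 1.0, e_syn)) if sd > 0 else 1.0
            p_two = min(1.0, 2.0 * min(p_pos, p_neg))
            if p_pos <= p_threshold and nd / total > e_non:
                cls = "positive"
            elif p_neg <= p_threshold and sd / total > e_syn:
                cls = "negative"
            else:
                cls = "none"
        records.append((site + 1, sd, nd, e_non, p_pos, p_neg, p_two, cls))
    return pd.DataFrame(
        records,
        columns=["site", "Sd", "Nd", "expected_nonsyn_fraction",
                 "p_positive", "p_negative", "p", "class"],
    )


# ---------------------------------------------------------------------------
# FEL-style per-site likelihood method
# ---------------------------------------------------------------------------

def _codon_tip_partials(aln: CodonAlignment, tree: Tree) -> dict[str, np.ndarray]:
    codons = _codon_matrix(aln)
    row = {rid: i for i, rid in enumerate(aln.ids)}
    partials = {}
    for name in tree.tip_names():
        mat = np.ones((aln.n_codons, 61))
        for site, c in enumerate(codons[row[name]]):
            k = _CODON_TO_SENSE.get(int(c))
            if k is not None:
                mat[site] = 0.0
                mat[site, k] = 1.0
        partials[name] = mat
    return partials


def _prune_sites(tree: Tree, tips: dict[str, np.ndarray],
                 edge_p: dict[int, np.ndarray]) -> np.ndarray:
    """Per-site log-likelihood, uniform codon frequencies at the root."""
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            down[id(node)] = tips[node.name]
        else:
            part = None
            for c in node.children:
                lifted = down[id(c)] @ edge_p[id(c)].T
                part = lifted if part is None else part * lifted
            down[id(node)] = part
    site_l = down[id(tree.root)].sum(axis=1) / 61.0
    return np.log(np.clip(site_l, 1e-300, None))


def fel_sites(
    aln: CodonAlignment,
    tree: Tree,
    p_threshold: float = DEFAULT_SITE_P,
    omega_grid: np.ndarray | None = None,
    rate_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site two-rate likelihood test of selection on a fixed tree.

    For each codon site an MG94xJC likelihood with synonymous rate alpha and
    nonsynonymous rate beta = omega * alpha is profiled over an
    (omega, alpha) grid; the null fixes omega = 1.  The likelihood-ratio
    statistic is referred to chi-square with 1 df.  Sites with at most one
    distinct observed codon report alpha = beta = 0 and p = 1.
    """
    missing = set(tree.tip_names()) - set(aln.ids)
    if missing:
        raise ValueError(f"tree tips absent from alignment: {sorted(missing)}")
    if omega_grid is None:
        omega_grid = np.unique(np.concatenate([np.geomspace(0.05, 20.0, 13), [1.0]]))
    if rate_grid is None:
        rate_grid = np.geomspace(0.02, 15.0, 12)
    tips = _codon_tip_partials(aln, tree)
    edges = [n for n in tree.postorder() if n is not tree.root]
    n_sites = aln.n_codons

    codons = _codon_matrix(aln)
    n_distinct = np.array([
        len({int(c) for c in codons[:, s] if int(c) in _SENSE_SET})
        for s in range(n_sites)
    ])

    logl = np.full((len(omega_grid), len(rate_grid), n_sites), -np.inf)
    for wi, omega in enumerate(omega_grid):
        q = mg94_rate_matrix(float(omega))
        lam, vec = np.linalg.eigh(0.5 * (q + q.T))
        for ri, rate in enumerate(rate_grid):
            edge_p = {}
            for node in edges:
                p = (vec * np.exp(lam * rate * node.length)[None, :]) @ vec.T
                np.clip(p, 0.0, None, out=p)
                edge_p[id(node)] = p
            logl[wi, ri] = _prune_sites(tree, tips, edge_p)

    null_wi = int(np.argmin(np.abs(omega_grid - 1.0)))
    l0 = logl[null_wi].max(axis=0)
    flat = logl.reshape(-1, n_sites)
    best = flat.argmax(axis=0)
    l1 = flat[best, np.arange(n_sites)]
    wi_hat, ri_hat = np.unravel_index(best, (len(omega_grid), len(rate_grid)))
    lrt = np.clip(2.0 * (l1 - l0), 0.0, None)
    pvals = chi2.sf(lrt, df=1)

    records = []
    for s in range(n_sites):
        if n_distinct[s] <= 1:
            records.append((s + 1, 0.0, 0.0, 0.0, 1.0, "none"))
            continue
        alpha = float(rate_grid[ri_hat[s]])
        omega = float(omega_grid[wi_hat[s]])
        beta = omega * alpha
        p = float(pvals[s])
        if p <= p_threshold and omega > 1.0:
            cls = "positive"
        elif p <= p_threshold and omega < 1.0:
            cls = "negative"
        else:
            cls = "none"
        records.append((s + 1, alpha, beta, float(lrt[s]), p, cls))
    return pd.DataFrame(
        records, columns=["site", "alpha", "beta", "LRT", "p", "class"]
    )


# ---------------------------------------------------------------------------
# consensus and reports
# ---------------------------------------------------------------------------

def consensus_sites(
    method_tables: dict[str, pd.DataFrame],
    abs_codons: frozenset[int] | set[int] = frozenset(),
) -> pd.DataFrame:
    """Combine per-site calls: selected only where >= 2 methods agree.

    ``method_tables`` maps method name -> table with ``site`` and ``class``
    columns.  The result has one row per site with per-method classes, the
    consensus class, and ABS membership.
    """
    if len(method_tables) < 2:
        raise ValueError("consensus requires at least 2 method tables")
    sites = sorted(
        set().union(*(set(t["site"]) for t in method_tables.values()))
    )
    per_method = {
        name: dict(zip(t["site"], t["class"])) for name, t in method_tables.items()
    }
    rows = []
    for site in sites:
        classes = {name: per_method[name].get(site, "none") for name in per_method}
        n_pos = sum(c == "positive" for c in classes.values())
        n_neg = sum(c == "negative" for c in classes.values())
        consensus = "positive" if n_pos >= 2 else "negative" if n_neg >= 2 else "none"
        rows.append(
            {"site": site, **{f"{m}_class": c for m, c in classes.items()},
             "consensus": consensus, "is_ABS": site in abs_codons}
        )
    return pd.DataFrame(rows)


def variant_substitutions(
    aln: CodonAlignment,
    consensus: pd.DataFrame | None = None,
    abs_codons: frozenset[int] | set[int] = frozenset(),
) -> pd.DataFrame:
    """Observed amino acid substitutions with ABS/SAAS annotation.

    The majority amino acid at each codon site is the reference; every other
    observed amino acid yields one substitution row.
    """
    codons = _codon_matrix(aln)
    saas = set()
    if consensus is not None:
        saas = set(consensus.loc[consensus["consensus"] == "positive", "site"])
    rows = []
    for site in range(aln.n_codons):
        aas = [
            AMINO_ACID[SENSE_CODONS[_CODON_TO_SENSE[int(c)]]]
            for c in codons[:, site] if int(c) in _CODON_TO_SENSE
        ]
        if not aas:
            continue
        counts = pd.Series(aas).value_counts()
        ref = counts.index[0]
        for alt in counts.index[1:]:
            rows.append(
                {"site": site + 1, "substitution": f"{ref}->{alt}",
                 "is_ABS": (site + 1) in abs_codons,
                 "is_SAAS": (site + 1) in saas}
            )
    return pd.DataFrame(rows, columns=["site", "substitution", "is_ABS", "is_SAAS"])


def read_predictor_table(path) -> pd.DataFrame:
    """External predictor TSV: site, substitution, tool, deleterious (0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"site", "substitution", "tool", "deleterious"}
    if not required <= set(df.columns):
        raise ValueError(
            f"predictor table must have columns {sorted(required)}, "
            f"got {sorted(df.columns)}"
        )
    return df


def deleterious_by_all_tools(predictors: pd.DataFrame) -> pd.DataFrame:
    """Substitutions flagged deleterious by every supplied tool (>= 2 tools)."""
    tools = predictors["tool"].unique()
    flagged = predictors[predictors["deleterious"].astype(bool)]
    counts = flagged.groupby(["site", "substitution"])["tool"].nunique()
    keep = counts[counts >= max(2, len(tools))].reset_index()[["site", "substitution"]]
    return keep


def saas_report(
    consensus_tables: dict[str, pd.DataFrame],
    alignments: dict[str, CodonAlignment],
    abs_config: dict[str, frozenset[int] | set[int]],
    predictor_table: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-locus selected-site counts and substitution cross-tabulations.

    Returns ``summary`` (positive/negative site counts per locus),
    ``variants`` (substitutions with ABS/SAAS flags) and, when a predictor
    table is supplied, ``deleterious`` (substitutions deleterious by all
    tools, annotated with ABS/SAAS).
    """
    summary_rows, variant_frames = [], []
    for locus, cons in consensus_tables.items():
        abs_codons = frozenset(abs_config.get(locus, frozenset()))
        n_pos = int((cons["consensus"] == "positive").sum())
        n_neg = int((cons["consensus"] == "negative").sum())
        variants = variant_substitutions(alignments[locus], cons, abs_codons)
        variants.insert(0, "locus", locus)
        variant_frames.append(variants)
        summary_rows.append(
            {"locus": locus, "length_aa": alignments[locus].n_codons,
             "n_positive": n_pos, "n_negative": n_neg,
             "n_variants": len(variants),
             "n_variants_in_ABS": int(variants["is_ABS"].sum()),
             "n_SAAS": int(
                 cons.loc[cons["consensus"] == "positive", "site"].nunique()
             )}
        )
    out = {
        "summary": pd.DataFrame(summary_rows),
        "variants": pd.concat(variant_frames, ignore_index=True)
        if variant_frames else pd.DataFrame(),
    }
    if predictor_table is not None:
        both = deleterious_by_all_tools(predictor_table)
        merged = out["variants"].merge(both, on=["site", "substitution"])
        out["deleterious"] = merged
    return out
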