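"""Distance and maximum-likelihood phylogenetics.

Provides pairwise nucleotide distances (JC69/K80), neighbor joining with a
deterministic tie-break, GTR+I+Gamma likelihood via Felsenstein pruning
with per-site log-likelihoods, coordinate-ascent parameter/branch-length
optimization, constrained NNI hill-climbing, and topology comparison
utilities (monophyly, gene-tree/species-tree conflicts).

Trees cross the module boundary as dendropy.Tree objects; internally they
are flattened to indexed arrays for the numerics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .seqio import Alignment, parse_newick, write_newick

__all__ = [
    "GTRGammaParams",
    "DistanceMatrix",
    "SiteLnL",
    "Constraint",
    "nucleotide_distance",
    "nj_tree",
    "log_likelihood",
    "optimize",
    "nni_search",
    "is_monophyletic",
    "conflicting_bipartitions",
    "tree_bipartitions",
]

NUC_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


# ------------------------------------------------------------ parameters

@dataclass
class GTRGammaParams:
    """GTR+I+Gamma substitution model.

    ``rates`` are the six exchangeabilities in order AC, AG, AT, CG, CT,
    GT with GT conventionally fixed to 1; ``freqs`` are stationary base
    frequencies (A,C,G,T); ``alpha`` the gamma shape; ``ncat`` the number
    of discrete mean-of-quantile rate categories; ``p_inv`` the
    invariant-sites proportion.
    """

    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    ncat: int = 4
    p_inv: float = 0.0

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.alpha <= 0 or not (0 <= self.p_inv < 1):
            raise ValueError("need alpha > 0 and p_inv in [0,1)")

    def q_matrix(self) -> np.ndarray:
        """GTR rate matrix scaled to mean rate 1."""
        s = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(self.rates, idx):
            s[i, j] = s[j, i] = r
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        return q / mu

    def eigen(self):
        """Symmetric eigendecomposition of the (reversible) Q matrix."""
        q = self.q_matrix()
        d = np.sqrt(self.freqs)
        sym = q * d[:, None] / d[None, :]
        sym = (sym + sym.T) / 2
        lam, u = np.linalg.eigh(sym)
        left = u.T * d[None, :]       # U^T D^{1/2}
        right = u / d[:, None]        # D^{-1/2} U
        return lam, right, left

    def gamma_rates(self) -> np.ndarray:
        """Mean-of-quantile discrete gamma category rates (mean 1)."""
        return discrete_gamma_rates(self.alpha, self.ncat)


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Yang (1994)-style category rates: mean of equal-probability bins."""
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, ncat) / ncat, alpha, scale=1.0 / alpha)
    # mean of X over each bin via incomplete-gamma identity
    upper = np.concatenate([edges, [np.inf]])
    lower = np.concatenate([[0.0], edges])
    cdf1 = gamma_dist.cdf(upper, alpha + 1, scale=1.0 / alpha)
    cdf0 = gamma_dist.cdf(lower, alpha + 1, scale=1.0 / alpha)
    rates = ncat * (cdf1 - cdf0)
    return rates / rates.mean()


# -------------------------------------------------------------- distances

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal; np.inf marks saturation

    def __getitem__(self, pair):
        a, b = pair
        return self.matrix[self.ids.index(a), self.ids.index(b)]


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nucleotide_distance(aln: Alignment, model: str = "JC") -> DistanceMatrix:
    """Pairwise-deletion JC69 or K80 distances; saturated pairs are inf."""
    if model not in ("JC", "K80"):
        raise ValueError(f"unknown model {model!r}")
    n = len(aln)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    rows = [np.frombuffer(r.residues.upper().encode(), dtype=np.uint8)
            for r in aln.records]
    valid = [np.isin(r, np.frombuffer(b"ACGT", dtype=np.uint8)) for r in rows]
    purine = [np.isin(r, np.frombuffer(b"AG", dtype=np.uint8)) for r in rows]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = both.sum()
            if m == 0:
                d[i, j] = d[j, i] = math.inf
                continue
            diff = (rows[i] != rows[j]) & both
            ndiff = diff.sum()
            if model == "JC":
                dij = _jc(ndiff / m)
            else:
                ts = (diff & (purine[i] == purine[j])).sum()
                P, Q = ts / m, (ndiff - ts) / m
                w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
                dij = (math.inf if w1 <= 0 or w2 <= 0
                       else -0.5 * math.log(w1) - 0.25 * math.log(w2))
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(aln.ids), d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining; ties broken by lexicographically smallest pair."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError(
            "infinite distances present (saturated pairs); use another model")
    d = dm.matrix.astype(float).copy()
    nodes = [f"{name}" for name in dm.ids]  # newick fragments
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((nodes[active[a]], nodes[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        ia, ib = active[a], active[b]
        dab = sub[a, b]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        new = len(nodes)
        newd = np.zeros(new + 1)
        row = np.zeros((1, d.shape[1]))
        d = np.vstack([d, row])
        d = np.hstack([d, np.zeros((d.shape[0], 1))])
        for c in active:
            if c in (ia, ib):
                continue
            d[new, c] = d[c, new] = 0.5 * (d[ia, c] + d[ib, c] - dab)
        nodes.append(f"({nodes[ia]}:{la:.10f},{nodes[ib]}:{lb:.10f})")
        active = [c for c in active if c not in (ia, ib)] + [new]
    ia, ib = active
    l = max(d[ia, ib], 0.0)
    text = f"({nodes[ia]}:{l / 2:.10f},{nodes[ib]}:{l / 2:.10f});"
    return parse_newick(text)


# --------------------------------------------------------- indexed trees

class _ITree:
    """Flat rooted-binary view of a dendropy tree for the numerics."""

    def __init__(self, tree: dendropy.Tree):
        seed = tree.seed_node
        self.children: list[list[int]] = []
        self.parent: list[int] = []
        self.lengths: list[float] = []
        self.names: list[str | None] = []
        self._build(seed, -1)
        self.postorder = self._postorder_ids()
        self.n_nodes = len(self.names)
        self.leaves = [i for i in range(self.n_nodes) if not self.children[i]]

    def _build(self, node, parent_id) -> int:
        my = len(self.names)
        label = None
        if node.taxon is not None:
            label = node.taxon.label
        elif node.is_leaf():
            label = str(node)
        self.names.append(label)
        self.parent.append(parent_id)
        self.lengths.append(node.edge.length if node.edge.length else 0.0)
        self.children.append([])
        for ch in node.child_nodes():
            cid = self._build(ch, my)
            self.children[my].append(cid)
        return my

    def _postorder_ids(self):
        order, stack = [], [0]
        seen = set()
        while stack:
            nid = stack[-1]
            if nid not in seen:
                seen.add(nid)
                stack.extend(self.children[nid])
            else:
                stack.pop()
                order.append(nid)
        return order

    def to_newick(self) -> str:
        def rec(nid):
            if not self.children[nid]:
                return f"{self.names[nid]}:{self.lengths[nid]:.10f}"
            inner = ",".join(rec(c) for c in self.children[nid])
            return f"({inner}):{self.lengths[nid]:.10f}"
        inner = ",".join(rec(c) for c in self.children[0])
        return f"({inner});"

    def to_dendropy(self) -> dendropy.Tree:
        return parse_newick(self.to_newick())


def _compress(aln: Alignment):
    """Site-pattern compression: (pattern matrix, counts, site->pattern)."""
    cols = np.array(
        [[NUC_INDEX.get(ch, 4) for ch in rec.residues.upper()]
         for rec in aln.records], dtype=np.int8)
    patterns, site_to_pat, counts = np.unique(
        cols.T, axis=0, return_inverse=True, return_counts=True)
    return patterns, counts, site_to_pat


# ------------------------------------------------------------- likelihood

@dataclass
class SiteLnL:
    """Per-site log-likelihood matrix [n_trees x n_sites]."""

    matrix: np.ndarray
    tree_ids: list[str]
    alignment_id: str = ""

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


class LikelihoodEngine:
    """Felsenstein pruning for GTR+I+Gamma on a fixed topology.

    Branch lengths are mutable (``set_branch``); the alignment is pattern
    compressed once. Gaps/ambiguity codes are missing data (all-ones
    partials).
    """

    def __init__(self, tree: dendropy.Tree | _ITree, aln: Alignment,
                 params: GTRGammaParams):
        self.it = tree if isinstance(tree, _ITree) else _ITree(tree)
        leaf_names = {self.it.names[i] for i in self.it.leaves}
        missing = leaf_names.symmetric_difference(aln.ids)
        if missing:
            raise ValueError(
                f"tree/alignment taxon mismatch: {sorted(missing)}")
        self.aln = aln
        self.params = params
        self.patterns, self.counts, self.site_to_pat = _compress(aln)
        self.n_pat = len(self.counts)
        row_of = {rid: k for k, rid in enumerate(aln.ids)}
        # leaf partials (n_pat x 4) per leaf
        self.leaf_partials = {}
        for leaf in self.it.leaves:
            states = self.patterns[:, row_of[self.it.names[leaf]]]
            part = np.zeros((self.n_pat, 4))
            known = states < 4
            part[known, states[known]] = 1.0
            part[~known] = 1.0
            self.leaf_partials[leaf] = part
        # invariant-site likelihoods for the +I class
        self._inv = self._invariant_likelihood()
        self._update_model()

    def _invariant_likelihood(self):
        inv = np.zeros(self.n_pat)
        freqs = self.params.freqs
        for p in range(self.n_pat):
            obs = set(int(s) for s in self.patterns[p] if s < 4)
            if len(obs) == 0:
                inv[p] = 1.0
            elif len(obs) == 1:
                inv[p] = freqs[obs.pop()]
        return inv

    def _update_model(self):
        self.lam, self.right, self.left = self.params.eigen()
        self.cat_rates = self.params.gamma_rates()
        self._inv = self._invariant_likelihood()

    def set_params(self, params: GTRGammaParams):
        self.params = params
        self._update_model()

    def set_branch(self, node_id: int, t: float):
        self.it.lengths[node_id] = max(t, 0.0)

    def _pmat(self, t: float, rate: float) -> np.ndarray:
        e = np.exp(self.lam * t * rate)
        p = (self.right * e[None, :]) @ self.left
        return np.clip(p, 0.0, None)

    def site_likelihoods(self) -> np.ndarray:
        """Per-pattern likelihoods mixed over rate categories and +I."""
        freqs = self.params.freqs
        mix = np.zeros(self.n_pat)
        for rate in self.cat_rates:
            partials = {}
            for nid in self.it.postorder:
                if not self.it.children[nid]:
                    partials[nid] = self.leaf_partials[nid]
                    continue
                acc = None
                for ch in self.it.children[nid]:
                    pm = self._pmat(self.it.lengths[ch], rate)
                    contrib = partials.pop(ch) @ pm.T
                    acc = contrib if acc is None else acc * contrib
                partials[nid] = acc
            mix += partials[self.it.postorder[-1]] @ freqs
        mix /= len(self.cat_rates)
        p_inv = self.params.p_inv
        return (1 - p_inv) * mix + p_inv * self._inv

    def lnl(self) -> tuple[float, np.ndarray]:
        """(total lnL, per-site lnL vector in original site order)."""
        like = self.site_likelihoods()
        like = np.clip(like, 1e-300, None)
        logs = np.log(like)
        total = float((logs * self.counts).sum())
        return total, logs[self.site_to_pat]


def log_likelihood(tree: dendropy.Tree, aln: Alignment,
                   params: GTRGammaParams) -> tuple[float, np.ndarray]:
    return LikelihoodEngine(tree, aln, params).lnl()


def _brent_branch(engine: LikelihoodEngine, nid: int, upper=10.0,
                  xatol=1e-6):
    t0 = engine.it.lengths[nid]

    def neg(t):
        engine.set_branch(nid, t)
        return -engine.lnl()[0]

    res = minimize_scalar(neg, bounds=(1e-9, upper), method="bounded",
                          options={"xatol": xatol})
    if -res.fun >= -neg(t0) - 1e-12:
        engine.set_branch(nid, float(res.x))
    else:
        engine.set_branch(nid, t0)


def optimize(tree: dendropy.Tree, aln: Alignment,
             params: GTRGammaParams | None = None,
             optimize_branches: bool = True,
             optimize_alpha: bool = True,
             optimize_pinv: bool = False,
             optimize_rates: bool = False,
             tol: float = 1e-6, max_rounds: int = 100,
             brent_xatol: float = 1e-6,
             ) -> tuple[dendropy.Tree, GTRGammaParams, float]:
    """Coordinate-ascent ML fit: Brent on each branch, then model knobs.

    Stops when the lnL improvement over a full round drops below ``tol``
    or after ``max_rounds``. lnL is non-decreasing across iterations.
    Returns (tree with fitted branch lengths, fitted params, lnL).
    """
    if params is None:
        params = empirical_params(aln)
    engine = LikelihoodEngine(tree, aln, params)
    prev, _ = engine.lnl()
    if not np.isfinite(prev):
        raise ValueError("non-finite log-likelihood at start")
    for _ in range(max_rounds):
        if optimize_branches:
            for nid in engine.it.postorder:
                if nid == engine.it.postorder[-1]:
                    continue  # root has no branch
                _brent_branch(engine, nid, xatol=brent_xatol)
        if optimize_alpha:
            _opt_scalar(engine, "alpha", 0.02, 50.0, log=True)
        if optimize_pinv:
            _opt_scalar(engine, "p_inv", 0.0, 0.95, log=False)
        if optimize_rates:
            for k in range(5):  # GT (last) fixed to 1
                _opt_rate(engine, k)
        cur, _ = engine.lnl()
        if cur - prev < tol:
            prev = cur
            break
        prev = cur
    fitted = parse_newick(engine.it.to_newick())
    return fitted, engine.params, prev


def _opt_scalar(engine, attr, lo, hi, log=False):
    base = getattr(engine.params, attr)

    def neg(x):
        val = math.exp(x) if log else x
        p = replace(engine.params, **{attr: val})
        try:
            engine.set_params(p)
            return -engine.lnl()[0]
        except ValueError:
            return 1e18

    bounds = (math.log(lo), math.log(hi)) if log else (lo, hi)
    res = minimize_scalar(neg, bounds=bounds, method="bounded",
                          options={"xatol": 1e-4})
    best = math.exp(res.x) if log else float(res.x)
    if neg(res.x) > neg(math.log(base) if log else base):
        best = base
    engine.set_params(replace(engine.params, **{attr: best}))


def _opt_rate(engine, k):
    base = engine.params.rates.copy()

    def neg(x):
        r = base.copy()
        r[k] = math.exp(x)
        engine.set_params(replace(engine.params, rates=r))
        return -engine.lnl()[0]

    res = minimize_scalar(neg, bounds=(math.log(1e-3), math.log(100)),
                          method="bounded", options={"xatol": 1e-4})
    if neg(res.x) > neg(math.log(max(base[k], 1e-3))):
        engine.set_params(replace(engine.params, rates=base))


def empirical_params(aln: Alignment, alpha: float = 1.0,
                     ncat: int = 4, p_inv: float = 0.0) -> GTRGammaParams:
    """GTR params with empirical base frequencies and unit exchangeabilities."""
    counts = np.zeros(4)
    for rec in aln.records:
        arr = np.frombuffer(rec.residues.upper().encode(), np.uint8)
        for b, i in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
            counts[i] += (arr == ord(b)).sum()
    freqs = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    freqs = np.clip(freqs, 1e-4, None)
    freqs /= freqs.sum()
    return GTRGammaParams(np.ones(6), freqs, alpha, ncat, p_inv)


# ------------------------------------------------------------ topology ops

def tree_bipartitions(tree: dendropy.Tree, restrict: set[str] | None = None
                      ) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as frozensets of leaf names.

    Each split is represented by the side NOT containing the
    lexicographically smallest leaf, restricted to ``restrict`` if given.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if restrict is not None:
        leaves = leaves & restrict
    if not leaves:
        return set()
    ref = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {l.taxon.label for l in node.leaf_iter()} & leaves
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(side))
    return out


def is_monophyletic(tree: dendropy.Tree, leafset: set[str]) -> bool:
    """Whether ``leafset`` induces a bipartition of the unrooted tree."""
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(leafset) - leaves
    if unknown:
        raise ValueError(f"leaves not in tree: {sorted(unknown)}")
    if len(leafset) in (0, 1, len(leaves)):
        return True
    target = frozenset(leafset)
    complement = frozenset(leaves - leafset)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if side == target or side == complement:
            return True
    return False


def _compatible(a: frozenset, b: frozenset, universe: frozenset) -> bool:
    ac, bc = universe - a, universe - b
    return (not (a & b) or not (a & bc) or not (ac & b) or not (ac & bc))


def conflicting_bipartitions(gene_tree: dendropy.Tree,
                             species_tree: dendropy.Tree,
                             leaf_map: dict[str, str]) -> set[frozenset]:
    """Gene-tree splits (mapped to species, duplicates collapsed) that are
    incompatible with the species tree.

    A gene split whose two sides share a species after mapping is not a
    species-level split and is skipped.
    """
    gleaves = {l.taxon.label for l in gene_tree.leaf_node_iter()}
    unmapped = gleaves - set(leaf_map)
    if unmapped:
        raise ValueError(f"unmapped gene leaves: {sorted(unmapped)}")
    sleaves = frozenset(l.taxon.label for l in species_tree.leaf_node_iter())
    shared = frozenset(set(leaf_map.values()) & sleaves)
    ssplits = tree_bipartitions(species_tree, set(shared))
    conflicts = set()
    ref = min(shared) if shared else None
    for node in gene_tree.preorder_node_iter():
        if node is gene_tree.seed_node or node.is_leaf():
            continue
        side_g = {l.taxon.label for l in node.leaf_iter()}
        a = frozenset(leaf_map[x] for x in side_g) & shared
        b = frozenset(leaf_map[x] for x in gleaves - side_g) & shared
        if a & b or not a or not b:
            continue  # collapses to a non-split after species mapping
        split = a if ref not in a else frozenset(shared - a)
        if not (2 <= len(split) <= len(shared) - 2):
            continue
        for s in ssplits:
            if not _compatible(split, s, shared):
                conflicts.add(split)
                break
    return conflicts


# --------------------------------------------------------------- NNI search

@dataclass
class Constraint:
    """Leaf subsets that must each stay monophyletic (as unrooted splits)."""

    clades: list[set[str]]

    def satisfied(self, tree: dendropy.Tree) -> bool:
        return all(is_monophyletic(tree, set(c)) for c in self.clades)


def _nni_neighbors(newick: str) -> list[str]:
    """All NNI rearrangements of a tree given as newick (lengths kept)."""
    tree = parse_newick(newick)
    out = []
    nodes = list(tree.preorder_node_iter())
    for idx, v in enumerate(nodes):
        if v is tree.seed_node or v.is_leaf():
            continue
        u = v.parent_node
        sibs = [s for s in u.child_nodes() if s is not v]
        if not sibs:
            continue
        s = sibs[0]
        for ci in range(len(v.child_nodes())):
            t2 = parse_newick(newick)
            nodes2 = list(t2.preorder_node_iter())
            v2 = nodes2[idx]
            u2 = v2.parent_node
            s2 = [x for x in u2.child_nodes() if x is not v2][0]
            c2 = v2.child_nodes()[ci]
            u2.remove_child(s2)
            v2.remove_child(c2)
            u2.add_child(c2)
            v2.add_child(s2)
            out.append(write_newick(t2))
    return out


def nni_search(aln: Alignment, start_tree: dendropy.Tree,
               params: GTRGammaParams,
               constraints: Constraint | None = None,
               max_iter: int = 50, branch_rounds: int = 1,
               ) -> tuple[dendropy.Tree, float]:
    """NNI hill-climbing under the likelihood, honoring clade constraints.

    Each iteration screens every NNI neighbor at its carried branch
    lengths (cheap plain likelihood), then re-optimizes branch lengths
    (``branch_rounds`` coordinate-ascent rounds) for the most promising
    candidates until one improves on the current tree. Moves violating a
    constraint are never taken. Deterministic: moves are generated in
    preorder and ties go to the earlier move.
    """
    if constraints and not constraints.satisfied(start_tree):
        raise ValueError("start tree violates constraints")

    def refine(nwk: str) -> tuple[float, str]:
        fitted, _, lnl = optimize(
            parse_newick(nwk), aln, params, optimize_alpha=False,
            optimize_rates=False, max_rounds=branch_rounds,
            brent_xatol=1e-3)
        return lnl, write_newick(fitted)

    cur_lnl, cur_nwk = refine(write_newick(start_tree))
    for _ in range(max_iter):
        screened = []
        for k, cand in enumerate(_nni_neighbors(cur_nwk)):
            if constraints and not constraints.satisfied(parse_newick(cand)):
                continue
            quick, _ = log_likelihood(parse_newick(cand), aln, params)
            screened.append((quick, k, cand))
        screened.sort(key=lambda x: (-x[0], x[1]))
        accepted = False
        for quick, _, cand in screened[:3]:
            lnl, fitted_nwk = refine(cand)
            if lnl - cur_lnl > 1e-6:
                cur_lnl, cur_nwk = lnl, fitted_nwk
                accepted = True
                break
        if not accepted:
            break
    return parse_newick(cur_nwk), cur_lnl
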