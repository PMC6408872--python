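"""Ground-truth generators: planted MSDIN contigs, species/gene trees with
replacing transfers, GTR+Gamma sequence evolution, codon pairs under a
simple omega-scaled process, and noisy MS1 peak lists.

Every generator is a pure function of (parameters, seed) and emits a
SyntheticTruth record sufficient to score the corresponding analysis stage
without re-deriving anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import expm

from .msdin_miner import revcomp, translate, _CODON_TABLE
from .phylo import GTRGammaParams, _ITree
from .seqio import Alignment, PeakList, SeqRecord, parse_newick

__all__ = [
    "SyntheticTruth",
    "plant_msdin_contig",
    "plant_multiexon_gene",
    "simulate_species_tree",
    "simulate_gene_tree",
    "evolve_sequences",
    "evolve_codon_pair",
    "synth_peaks",
]

# canonical leaders per genus style (conserved across each family, ending
# in the POPB-cleaved proline) and a conserved P-free follower segment
LEADER_STYLES = {
    "MSDIN": "MSDINATRLP",
    "MFDTN": "MFDTNATRLP",
    "MDAN": "MDANATRLP",
}
CANONICAL_FOLLOWER = "WTAESVNDTLTKDLS"

_AA_NO_P = "ACDEFGHIKLMNQRSTVWY"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _v in _CODONS_BY_AA.values():
    _v.sort()

SENSE_CODONS = sorted(c for c, a in _CODON_TABLE.items() if a != "*")
STOP_CODONS = sorted(c for c, a in _CODON_TABLE.items() if a == "*")


@dataclass
class SyntheticTruth:
    """Ground-truth record emitted by every generator."""

    kind: str
    seed: int
    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        return json.dumps({"kind": self.kind, "seed": self.seed,
                           "data": self.data}, default=default, indent=2)


# ---------------------------------------------------------- MSDIN contigs

def _gc_weights(gc: float) -> dict[str, float]:
    return {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}


def _reverse_translate(aa_seq: str, gc: float, rng) -> str:
    """Pick synonymous codons with probability tilted toward the target GC."""
    w = _gc_weights(gc)
    out = []
    for aa in aa_seq:
        codons = _CODONS_BY_AA[aa]
        probs = np.array([w[c[0]] * w[c[1]] * w[c[2]] for c in codons])
        probs /= probs.sum()
        out.append(codons[rng.choice(len(codons), p=probs)])
    return "".join(out)


def _random_dna(n: int, gc: float, rng) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(bases[rng.choice(4, size=n, p=p)])


def plant_msdin_contig(length: int, gc: float, core: str,
                       leader_style: str = "MSDIN", n_introns: int = 0,
                       seed: int = 0, mutation_rate: float = 0.0,
                       intron_len_range: tuple[int, int] = (40, 120),
                       strand: str | None = None,
                       ) -> tuple[SeqRecord, SyntheticTruth]:
    """Embed one MSDIN precursor gene in an iid background contig.

    The precursor is the style's canonical conserved leader (ending in the
    POPB-cleaved proline), the requested hypervariable core (ending in P),
    and a conserved follower; ``mutation_rate`` substitutes residues
    outside the anchor positions (the style prefix, the two prolines and
    the core). It is reverse-translated with GC-biased codon choice,
    optionally interrupted by one GT..AG intron, and planted at a random
    position and strand.
    """
    core = core.upper()
    if not core.endswith("P"):
        raise ValueError("core must end with P")
    if not (7 <= len(core) <= 10):
        raise ValueError("core length must be 7-10")
    if not (0.2 < gc < 0.8):
        raise ValueError("gc out of (0.2, 0.8)")
    if n_introns not in (0, 1):
        raise ValueError("n_introns must be 0 or 1")
    rng = np.random.default_rng(seed)
    leader = LEADER_STYLES[leader_style]
    follower = CANONICAL_FOLLOWER

    def mutate(seq: str, n_anchor: int) -> str:
        out = list(seq)
        for i in range(n_anchor, len(seq) - 1):
            if rng.random() < mutation_rate:
                out[i] = str(rng.choice(list(_AA_NO_P)))
        return "".join(out)

    if mutation_rate > 0:
        leader = mutate(leader, 5) [:-1] + "P"
        follower = mutate(follower + "X", 0)[:-1]
    precursor = leader + core + follower

    cds = _reverse_translate(precursor, gc, rng) + str(
        rng.choice(["TAA", "TAG", "TGA"]))
    gene = cds
    intron_span_local = None
    if n_introns == 1:
        ilen = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        pos = int(rng.integers(3, len(cds) - 3))
        intron = "GT" + _random_dna(ilen - 4, gc, rng) + "AG"
        gene = cds[:pos] + intron + cds[pos:]
        intron_span_local = (pos, pos + ilen)

    if len(gene) + 20 > length:
        raise ValueError("contig length too small for the gene")
    start = int(rng.integers(10, length - len(gene) - 10))
    contig_seq = (_random_dna(start, gc, rng) + gene
                  + _random_dna(length - start - len(gene), gc, rng))
    use_strand = strand or str(rng.choice(["+", "-"]))
    if use_strand == "-":
        contig_seq = revcomp(contig_seq)
        gstart = length - (start + len(gene))
    else:
        gstart = start

    # genomic exon coordinates (forward-genome coordinates)
    if intron_span_local is None:
        exons_local = [(0, len(cds))]
    else:
        a, b = intron_span_local
        exons_local = [(0, a), (b, b + len(cds) - a)]
    if use_strand == "+":
        exons = [(gstart + s, gstart + e) for s, e in exons_local]
    else:
        glen = len(gene)
        exons = sorted((gstart + glen - e, gstart + glen - s)
                       for s, e in exons_local)
    contig = SeqRecord(f"synth_contig_{seed}", contig_seq)
    truth = SyntheticTruth("msdin_contig", seed, {
        "precursor": precursor,
        "leader": leader,
        "core": core,
        "follower": follower,
        "cds": cds,
        "strand": use_strand,
        "gene_span": (gstart, gstart + len(gene)),
        "exons": exons,
        "intron_len": (0 if intron_span_local is None
                       else intron_span_local[1] - intron_span_local[0]),
        "gc": gc,
    })
    return contig, truth


def plant_multiexon_gene(protein_len: int = 731, n_introns: int = 17,
                         intron_total_bp: int = 922, gc: float = 0.5,
                         seed: int = 0, min_intron: int = 40,
                         ) -> tuple[str, str, SyntheticTruth]:
    """Synthetic multi-exon coding gene (a POPB-scale structure stand-in).

    Returns (genomic gene sequence ATG..stop, spliced CDS, truth with the
    gene-local exon spans). The protein is random with a leading M; the
    ``n_introns`` GT..AG introns have random lengths >= ``min_intron``
    summing to ``intron_total_bp``, at random in-gene positions.
    """
    if intron_total_bp < n_introns * min_intron:
        raise ValueError("intron_total_bp too small for n_introns")
    rng = np.random.default_rng(seed)
    prot = "M" + "".join(rng.choice(list(_AA_NO_P + "P"),
                                    size=protein_len - 1))
    cds = _reverse_translate(prot, gc, rng) + str(
        rng.choice(["TAA", "TAG", "TGA"]))
    if n_introns == 0:
        truth = SyntheticTruth("multiexon_gene", seed, {
            "protein": prot, "exons": [(0, len(cds))], "cds_len": len(cds)})
        return cds, cds, truth
    # random composition of intron lengths with a floor
    extra = rng.multinomial(intron_total_bp - n_introns * min_intron,
                            np.full(n_introns, 1.0 / n_introns))
    ilens = [min_intron + int(e) for e in extra]
    pos = sorted(int(p) for p in rng.choice(
        np.arange(10, len(cds) - 10), size=n_introns, replace=False))
    gene = ""
    prev = 0
    exons = []
    cursor = 0
    for p, il in zip(pos, ilens):
        gene += cds[prev:p]
        exons.append((cursor, cursor + (p - prev)))
        cursor += (p - prev) + il
        gene += "GT" + _random_dna(il - 4, gc, rng) + "AG"
        prev = p
    gene += cds[prev:]
    exons.append((cursor, cursor + len(cds) - prev))
    truth = SyntheticTruth("multiexon_gene", seed, {
        "protein": prot, "exons": exons, "cds_len": len(cds),
        "intron_lens": ilens, "gene_len": len(gene)})
    return gene, cds, truth


# ------------------------------------------------------------------ trees

def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0,
                          seed: int = 0) -> dendropy.Tree:
    """Ultrametric Yule tree with leaves t1..tn at age zero."""
    if n_taxa < 3:
        raise ValueError("need n_taxa >= 3")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    # waiting times while k lineages are extant
    t = 0.0
    split_times = []
    for k in range(1, n_taxa):
        t += rng.exponential(1.0 / (birth_rate * k))
        split_times.append(t)
    height = split_times[-1] + rng.exponential(1.0 / (birth_rate * n_taxa))
    ages = [height - s for s in split_times]  # ages of internal nodes, desc

    # sequential splitting: pick a random active tip to split at each event
    class _N:
        __slots__ = ("age", "children", "name")

        def __init__(self, age, name=None):
            self.age, self.children, self.name = age, [], name

    root = _N(None)
    active = [root]
    for age in ages:
        node = active.pop(int(rng.integers(len(active))))
        node.age = age
        node.children = [_N(None), _N(None)]
        active.extend(node.children)
    # remaining actives are the leaves; name deterministically in DFS order
    counter = [0]

    def label(n):
        if not n.children:
            counter[0] += 1
            n.name = f"t{counter[0]}"
            n.age = 0.0
        for c in n.children:
            label(c)

    label(root)

    def newick(n):
        if not n.children:
            return f"{n.name}"
        parts = []
        for c in n.children:
            bl = n.age - c.age
            parts.append(f"{newick(c)}:{bl:.10f}")
        return "(" + ",".join(parts) + ")"

    return parse_newick(newick(root) + ";")


def _node_ages(it: _ITree) -> list[float]:
    """Ages from branch lengths assuming an ultrametric tree."""
    depth = [0.0] * it.n_nodes
    for i in range(1, it.n_nodes):
        depth[i] = depth[it.parent[i]] + it.lengths[i]
    height = max(depth[i] for i in it.leaves)
    return [height - d for d in depth]


class _GNode:
    __slots__ = ("time", "children", "name", "parent")

    def __init__(self, time, name=None):
        self.time, self.children, self.name, self.parent = time, [], name, None

    def add(self, child):
        child.parent = self
        self.children.append(child)


def simulate_gene_tree(species_tree: dendropy.Tree,
                       rates: dict[str, float] | None = None,
                       seed: int = 0, max_retries: int = 50,
                       ) -> tuple[dendropy.Tree, SyntheticTruth]:
    """Evolve a gene top-down inside a dated species tree.

    Duplications copy a lineage in place; losses prune it; transfers move
    a copy onto a contemporaneous incomparable species branch where it
    REPLACES the resident copy (replacing HGT, the single-copy scenario).
    Events are sampled as Poisson processes per species branch. The truth
    records every applied event and flags the transfers that are
    identifiable from topology (recipient not the donor's live sister and
    transferred copy surviving to the present).
    """
    rates = {"dup": 0.0, "transfer": 0.0, "loss": 0.0, **(rates or {})}
    if min(rates.values()) < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    it = _ITree(species_tree)
    ages = _node_ages(it)
    for attempt in range(max_retries):
        result = _simulate_gene_once(it, ages, rates, rng)
        if result is not None:
            tree, truth_data = result
            truth = SyntheticTruth("gene_tree", seed, truth_data)
            return tree, truth
    raise RuntimeError("all gene lineages lost in every retry")


def _simulate_gene_once(it: _ITree, ages, rates, rng):
    # species branch = (child-end node id); interval (ages[parent], ages[node])
    root = 0
    rchildren = it.children[root]
    if len(rchildren) != 2:
        raise ValueError("species tree root must be binary")

    # sample stochastic events per branch
    events = []  # (age, kind, branch)
    total = rates["dup"] + rates["transfer"] + rates["loss"]
    for v in range(it.n_nodes):
        if v == root:
            continue
        top, bottom = ages[it.parent[v]], ages[v]
        if total > 0:
            n_ev = rng.poisson(total * (top - bottom))
            for _ in range(n_ev):
                age = rng.uniform(bottom, top)
                u = rng.random() * total
                if u < rates["dup"]:
                    kind = "dup"
                elif u < rates["dup"] + rates["transfer"]:
                    kind = "transfer"
                else:
                    kind = "loss"
                events.append((age, kind, v))
    events.sort(key=lambda e: -e[0])

    groot = _GNode(ages[root])
    copies: dict[int, list[_GNode]] = {}  # species branch -> pending edges
    for c in rchildren:
        child = _GNode(None)
        groot.add(child)
        copies.setdefault(c, []).append(child)

    speciations = sorted(
        ((ages[v], v) for v in range(it.n_nodes)
         if it.children[v] and v != root), key=lambda x: -x[0])
    applied = []
    si = ei = 0
    moments = []
    while si < len(speciations) or ei < len(events):
        if ei >= len(events) or (si < len(speciations)
                                 and speciations[si][0] >= events[ei][0]):
            moments.append(("spec", *speciations[si]))
            si += 1
        else:
            moments.append(("ev", *events[ei]))
            ei += 1

    def alive(branch, age):
        return (branch != root and ages[it.parent[branch]] > age >= ages[branch]
                and branch in copies and copies[branch])

    for m in moments:
        if m[0] == "spec":
            _, age, v = m
            for edge in copies.pop(v, []):
                edge.time = age
                for c in it.children[v]:
                    child = _GNode(None)
                    edge.add(child)
                    copies.setdefault(c, []).append(child)
        else:
            _, age, kind, v = m
            pool = copies.get(v, [])
            if not pool:
                continue
            idx = int(rng.integers(len(pool)))
            edge = pool[idx]
            if kind == "loss":
                pool.pop(idx)
                _kill_edge(edge)
                applied.append({"kind": "loss", "age": age,
                                "branch": _branch_label(it, v)})
            elif kind == "dup":
                edge.time = age
                pool.pop(idx)
                for _ in range(2):
                    child = _GNode(None)
                    edge.add(child)
                    pool.append(child)
                applied.append({"kind": "dup", "age": age,
                                "branch": _branch_label(it, v)})
            else:  # transfer: v is the donor branch
                recips = [r for r in range(it.n_nodes)
                          if r != v and alive(r, age)
                          and not it.comparable_nodes(r, v)]
                if not recips:
                    continue
                r = recips[int(rng.integers(len(recips)))]
                edge.time = age
                pool.pop(idx)
                cont = _GNode(None)
                edge.add(cont)
                pool.append(cont)
                moved = _GNode(None)
                edge.add(moved)
                rpool = copies[r]
                killed = rpool.pop(int(rng.integers(len(rpool))))
                _kill_edge(killed)
                rpool.append(moved)
                sister_alive = it.parent[r] == it.parent[v]
                applied.append({
                    "kind": "transfer", "age": age,
                    "donor": _branch_label(it, v),
                    "recipient": _branch_label(it, r),
                    "silent_sister": bool(sister_alive),
                    "node": moved,
                })

    # terminate at species leaves (age 0)
    leaf_map = {}
    for v in it.leaves:
        pool = copies.get(v, [])
        sp = it.names[v]
        for k, edge in enumerate(pool):
            name = sp if len(pool) == 1 else f"{sp}_{k + 1}"
            edge.time = 0.0
            edge.name = name
            leaf_map[name] = sp

    # prune dead lineages, suppress unary nodes
    def has_leaf(n):
        if n.name is not None:
            return True
        n.children = [c for c in n.children if has_leaf(c)]
        return bool(n.children)

    if not has_leaf(groot):
        return None
    surviving_leaves = sum(1 for v in it.leaves for _ in copies.get(v, []))
    if surviving_leaves < 3:
        return None

    for ev in applied:
        if ev["kind"] == "transfer":
            node = ev.pop("node")
            survives = _node_survives(node)
            ev["survives"] = survives
            ev["identifiable"] = survives and not ev["silent_sister"]

    def suppress(n):
        while len(n.children) == 1 and n.name is None:
            child = n.children[0]
            n.children = child.children
            n.name = child.name
            n.time = child.time
            for c in n.children:
                c.parent = n
        for c in n.children:
            suppress(c)

    suppress(groot)

    def newick(n):
        if not n.children:
            return n.name
        parts = []
        for c in n.children:
            parts.append(f"{newick(c)}:{max(n.time - c.time, 0.0):.10f}")
        return "(" + ",".join(parts) + ")"

    tree = parse_newick(newick(groot) + ";")
    truth_data = {
        "events": [e for e in applied],
        "n_transfers": sum(1 for e in applied if e["kind"] == "transfer"),
        "n_transfers_identifiable": sum(
            1 for e in applied
            if e["kind"] == "transfer" and e.get("identifiable")),
        "n_dups": sum(1 for e in applied if e["kind"] == "dup"),
        "n_losses": sum(1 for e in applied if e["kind"] == "loss"),
        "leaf_map": leaf_map,
    }
    return tree, truth_data


def _kill_edge(edge: _GNode):
    parent = edge.parent
    if parent is not None and edge in parent.children:
        parent.children.remove(edge)


def _node_survives(n: _GNode) -> bool:
    if n.name is not None:
        return True
    return any(_node_survives(c) for c in n.children)


def _branch_label(it: _ITree, v: int) -> str:
    if it.names[v]:
        return it.names[v]
    leaves = []

    def rec(i):
        if not it.children[i]:
            leaves.append(it.names[i])
        for c in it.children[i]:
            rec(c)
    rec(v)
    return "+".join(sorted(leaves))


# monkey-free helper: ancestor/descendant test on _ITree node ids
def _comparable_nodes(self: _ITree, a: int, b: int) -> bool:
    x = a
    while x != -1:
        if x == b:
            return True
        x = self.parent[x]
    x = b
    while x != -1:
        if x == a:
            return True
        x = self.parent[x]
    return False


_ITree.comparable_nodes = _comparable_nodes


# -------------------------------------------------------------- sequences

def evolve_sequences(tree: dendropy.Tree, params: GTRGammaParams,
                     n_sites: int, seed: int = 0,
                     ) -> tuple[Alignment, SyntheticTruth]:
    """Forward GTR+I+Gamma simulation along a tree with branch lengths."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    it = _ITree(tree)
    lam, right, left = params.eigen()
    cat_rates = params.gamma_rates()
    site_cat = rng.integers(len(cat_rates), size=n_sites)
    rate_of_site = cat_rates[site_cat]
    if params.p_inv > 0:
        inv_mask = rng.random(n_sites) < params.p_inv
        rate_of_site = np.where(inv_mask, 0.0, rate_of_site)
    states = {0: rng.choice(4, size=n_sites, p=params.freqs)}
    preorder = list(reversed(it.postorder))
    for nid in preorder:
        if nid == 0:
            continue
        t = it.lengths[nid]
        parent_states = states[it.parent[nid]]
        child = np.empty(n_sites, dtype=np.int64)
        for rate in np.unique(rate_of_site):
            mask = rate_of_site == rate
            if rate == 0.0:
                child[mask] = parent_states[mask]
                continue
            p = (right * np.exp(lam * t * rate)[None, :]) @ left
            p = np.clip(p, 0.0, None)
            p /= p.sum(axis=1, keepdims=True)
            cum = np.cumsum(p, axis=1)
            u = rng.random(mask.sum())
            child[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
        states[nid] = child
    bases = np.array(list("ACGT"))
    records = [
        SeqRecord(it.names[leaf], "".join(bases[states[leaf]]))
        for leaf in it.leaves
    ]
    aln = Alignment(records, "nucleotide")
    truth = SyntheticTruth("alignment", seed, {
        "n_sites": n_sites,
        "alpha": params.alpha,
        "p_inv": params.p_inv,
        "freqs": params.freqs.tolist(),
        "rates": params.rates.tolist(),
    })
    return aln, truth


def evolve_codon_pair(omega: float, t: float, n_codons: int, seed: int = 0,
                      ) -> tuple[str, str, SyntheticTruth]:
    """Simulate an aligned CDS pair under a simple omega-scaled codon model.

    Single-nucleotide exchanges between sense codons at rate 1
    (synonymous) or omega (nonsynonymous), uniform codon frequencies, no
    ts/tv bias; Q is scaled to one expected nucleotide substitution per
    codon per unit time at omega = 1. Divergence t is split evenly around
    an ancestor drawn uniformly over sense codons.
    """
    if omega < 0 or t < 0 or n_codons < 1:
        raise ValueError("bad omega/t/n_codons")
    rng = np.random.default_rng(seed)
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for pos in range(3):
            for b in "ACGT":
                if b == c1[pos]:
                    continue
                c2 = c1[:pos] + b + c1[pos + 1:]
                j = idx.get(c2)
                if j is None:
                    continue
                q[i, j] = 1.0 if translate(c1) == translate(c2) else omega
    np.fill_diagonal(q, -q.sum(axis=1))
    # neutral scaling: mean rate 1 substitution/codon at omega=1 reference
    q0 = np.zeros((n, n))
    q0[q > 0] = 1.0
    mu = q0.sum() / n
    q /= mu
    p_half = expm(q * (t / 2.0))
    p_half = np.clip(p_half, 0, None)
    p_half /= p_half.sum(axis=1, keepdims=True)
    anc = rng.integers(n, size=n_codons)
    cum = np.cumsum(p_half, axis=1)
    s1 = (rng.random(n_codons)[:, None] > cum[anc]).sum(axis=1)
    s2 = (rng.random(n_codons)[:, None] > cum[anc]).sum(axis=1)
    cds1 = "".join(SENSE_CODONS[i] for i in s1)
    cds2 = "".join(SENSE_CODONS[i] for i in s2)
    truth = SyntheticTruth("codon_pair", seed, {
        "omega": omega, "t": t, "n_codons": n_codons})
    return cds1, cds2, truth


# ------------------------------------------------------------------ peaks

def synth_peaks(true_masses, ppm_sigma: float = 2.0, n_decoys: int = 50,
                mz_range: tuple[float, float] = (200.0, 1500.0), seed: int = 0,
                ) -> tuple[PeakList, SyntheticTruth]:
    """True masses perturbed by Gaussian ppm noise plus uniform decoys.

    Decoys are rejected from +-3 sigma (ppm) windows around every true
    mass so a correct matcher at a sane tolerance finds exactly the
    planted peaks.
    """
    if ppm_sigma < 0:
        raise ValueError("ppm_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    peaks = []
    for m in true_masses:
        noisy = m * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6)
        peaks.append((noisy, float(rng.uniform(1e4, 1e6))))
    guard = max(3.0 * ppm_sigma, 15.0)
    n_put = 0
    while n_put < n_decoys:
        mz = float(rng.uniform(*mz_range))
        if any(abs(1e6 * (mz - m) / m) < guard for m in true_masses):
            continue
        peaks.append((mz, float(rng.uniform(1e3, 1e5))))
        n_put += 1
    truth = SyntheticTruth("peaks", seed, {
        "true_masses": list(map(float, true_masses)),
        "ppm_sigma": ppm_sigma,
        "n_decoys": n_decoys,
    })
    return PeakList(peaks, source="synthetic"), truth
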