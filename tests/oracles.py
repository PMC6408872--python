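"""Independent oracles shared across test modules.

These deliberately avoid the library code paths they check: likelihoods by
exhaustive enumeration of ancestral states, codon differences by pathway
enumeration.
"""

import itertools
import math

import numpy as np

from amatox import phylo
from amatox.msdin_miner import translate


def brute_force_lnl(tree, aln, params):
    """Exhaustive enumeration of ancestral states (<=4 taxa practical)."""
    it = phylo._ITree(tree)
    lam, right, left = params.eigen()
    cat_rates = params.gamma_rates()
    nuc = {"A": 0, "C": 1, "G": 2, "T": 3}
    rows = {i: aln.row(it.names[i]) for i in it.leaves}
    internal = [i for i in range(it.n_nodes) if it.children[i]]
    root = it.postorder[-1]
    site_lnl = []
    for s in range(aln.length):
        tot = 0.0
        for r in cat_rates:
            P = {i: np.clip((right * np.exp(lam * it.lengths[i] * r)) @ left,
                            0, None) for i in range(it.n_nodes)}
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = dict(zip(internal, assign))
                ok = True
                for i in it.leaves:
                    b = rows[i][s]
                    if b not in nuc:
                        ok = False
                        break
                    st[i] = nuc[b]
                if not ok:
                    continue
                pr = params.freqs[st[root]]
                for i in range(it.n_nodes):
                    if i == root:
                        continue
                    pr *= P[i][st[it.parent[i]], st[i]]
                acc += pr
            tot += acc / len(cat_rates)
        site_lnl.append(math.log(tot))
    return sum(site_lnl), np.array(site_lnl)


def enumerate_codon_counts(c1, c2):
    """Synonymous/nonsynonymous differences by pathway enumeration."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd_, nd_, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if translate(cur) == "*" or translate(nxt) == "*":
                blocked = True
            if translate(cur) == translate(nxt):
                sd_ += 1
            else:
                nd_ += 1
            cur = nxt
        paths.append((blocked, sd_, nd_))
    clean = [(s, n) for b, s, n in paths if not b]
    use = clean if clean else [(s, n) for _, s, n in paths]
    return (sum(s for s, _ in use) / len(use),
            sum(n for _, n in use) / len(use))


def pop_reconciliation_standin():
    """Synthetic stand-in for the study's 31-taxon rpb2 species tree and
    20-taxon POP gene tree: the POPB clade (Lepiota basal, Amanita
    terminal) conflicts with a species phylogeny in which Amanita diverges
    early and Galerina+Lepiota are sisters; POPA and the generic POPs
    follow the species phylogeny."""
    from amatox.seqio import parse_newick
    am = "((Am1,Am2),(Am3,(Am4,Am5)))"
    ga = "(Ga1,(Ga2,Ga3))"
    le = "(Le1,(Le2,Le3))"
    backbone = f"({ga},{le})"
    for i in range(18, 0, -1):
        backbone = f"(X{i:02d},{backbone})"
    species = parse_newick(f"(O1,(O2,({am},{backbone})));")
    popb = "(POPB_Le1,((POPB_Ga1,POPB_Ga2),(POPB_Am1,(POPB_Am2,POPB_Am3))))"
    popa = "(POPA_Am1,(POPA_Am2,POPA_Am3))"
    generic = "(POP_Ga1,POP_Le1)"
    for i in range(9, 0, -1):
        generic = f"(POP_X{i:02d},{generic})"
    gene = parse_newick(f"({popa},({popb},{generic}));")
    leaf_map = {l.taxon.label: l.taxon.label.split("_")[1]
                for l in gene.leaf_node_iter()}
    return gene, species, leaf_map
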