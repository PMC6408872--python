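"""Pairwise codon statistics (Nei-Gojobori 1986 counting) and genus-level
distance-ratio tables.

NG86 counts synonymous (S) and nonsynonymous (N) sites per codon from the
fraction of the three possible changes at each position that preserve the
amino acid (changes creating stop codons count as nonsynonymous, so S+N is
exactly 3 per ungapped codon), averages differences over all substitution
pathways for codons differing at more than one position (pathways passing
through stop codons are skipped when any stop-free pathway exists), and
applies the Jukes-Cantor multiple-hit correction to the proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .msdin_miner import translate
from .phylo import nucleotide_distance
from .seqio import Alignment

__all__ = ["CodonPairStats", "ng86", "genus_distance_ratios"]

BASES = "ACGT"


@dataclass
class CodonPairStats:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float | None
    dN: float | None
    omega: float | None
    n_codons: int
    saturated_s: bool = False
    saturated_n: bool = False


def _codon_ok(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops = nonsyn)."""
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        nsyn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if translate(mut) == aa:
                nsyn += 1
        s += nsyn / 3.0
    return s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over substitution pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            a_from, a_to = translate(cur), translate(nxt)
            if a_to == "*" or a_from == "*":
                blocked = True
            if a_from == a_to:
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((blocked, sd, nd))
    clean = [(s, n) for b, s, n in results if not b]
    use = clean if clean else [(s, n) for _, s, n in results]
    sd = sum(s for s, _ in use) / len(use)
    nd = sum(n for _, n in use) / len(use)
    return sd, nd


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86(cds1: str, cds2: str) -> CodonPairStats:
    """NG86 dN/dS for an aligned in-frame CDS pair.

    Gapped or ambiguous codons are dropped pairwise; internal stop codons
    raise with the offending codon index. Symmetric in its arguments.
    """
    c1, c2 = cds1.upper(), cds2.upper()
    if len(c1) != len(c2):
        raise ValueError("CDS lengths differ")
    if len(c1) % 3:
        raise ValueError(f"CDS length {len(c1)} not divisible by 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for k in range(0, len(c1), 3):
        a, b = c1[k : k + 3], c2[k : k + 3]
        if not (_codon_ok(a) and _codon_ok(b)):
            continue
        if translate(a) == "*" or translate(b) == "*":
            if k + 3 < len(c1):  # terminal stop codons are fine
                raise ValueError(f"internal stop codon at codon {k // 3 + 1}")
            continue
        n_codons += 1
        sa, sb = _syn_sites(a), _syn_sites(b)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = _pathway_diffs(a, b)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = _jc(pS), _jc(pN)
    omega = None
    if dS is not None and dN is not None and dS > 0:
        omega = dN / dS
    return CodonPairStats(S, N, Sd, Nd, pS, pN, dS, dN, omega, n_codons,
                          saturated_s=dS is None, saturated_n=dN is None)


# --------------------------------------------------------- genus ratios

def genus_distance_ratios(locus_alignments: dict[str, Alignment],
                          genus_map: dict[str, str],
                          reference_locus: str = "rpb2",
                          model: str = "JC") -> dict:
    """Mean inter-genus corrected nucleotide distances per locus and the
    reference/locus fold ratios.

    For each genus pair present in an alignment, distance is the mean
    pairwise corrected distance between cross-genus taxon pairs (pairwise
    gap deletion). A vertically inherited housekeeping reference locus
    divided by a recently transferred locus yields ratios well above 1.
    """
    if reference_locus not in locus_alignments:
        raise ValueError(f"reference locus {reference_locus!r} missing")
    table: dict[str, dict[tuple, float]] = {}
    warnings = []
    for locus, aln in locus_alignments.items():
        dm = nucleotide_distance(aln, model)
        by_genus: dict[str, list[int]] = {}
        for i, tid in enumerate(dm.ids):
            genus = genus_map.get(tid)
            if genus is None:
                continue
            by_genus.setdefault(genus, []).append(i)
        entry = {}
        for ga, gb in itertools.combinations(sorted(by_genus), 2):
            vals = [dm.matrix[i, j]
                    for i in by_genus[ga] for j in by_genus[gb]
                    if math.isfinite(dm.matrix[i, j])]
            if not vals:
                warnings.append(f"{locus}: no finite {ga}-{gb} distances")
                continue
            entry[(ga, gb)] = sum(vals) / len(vals)
        table[locus] = entry
    ref = table[reference_locus]
    ratios: dict[str, dict[tuple, float]] = {}
    for locus, entry in table.items():
        if locus == reference_locus:
            continue
        ratios[locus] = {}
        for pair, dist in entry.items():
            if pair in ref and dist > 0 and ref[pair] > 0:
                ratios[locus][pair] = ref[pair] / dist
            else:
                warnings.append(f"{locus}: ratio undefined for {pair}")
    return {"distances": table, "ratios": ratios, "warnings": warnings,
            "reference": reference_locus}
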