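"""Mining MSDIN-family toxin-precursor genes and POP homologs from contigs.

MSDIN precursors are short (25-45 aa) ribosomal peptides laid out as
leader | core | follower, where the leader ends in a proline, the core is
the 7-10 residue segment (ending in proline) that is excised and
macrocyclized by POPB, and the follower is the C-terminal remainder.
Mining is a translated six-frame scan: ATG..stop open reading frames,
optionally reassembled across one canonical GT..AG intron, are scored
against a position weight matrix trained on known precursor leaders.

The spliced aligner maps a coding sequence onto genomic DNA with an
explicit intron state that may open only at GT and close only at AG, used
to recover multi-exon gene structures (e.g. the 18-exon POPB gene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import GenomicInterval, SeqRecord

__all__ = [
    "MotifProfile",
    "MsdinPrecursor",
    "GeneModel",
    "MineHit",
    "NoCoreFound",
    "NoModel",
    "build_leader_profile",
    "extract_core",
    "scan_orfs",
    "spliced_align",
    "toxin_gene_distance",
    "translate",
    "revcomp",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table():
    # standard genetic code, table 1
    bases = "TCAG"
    aas = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()

_COMPLEMENT = str.maketrans("ACGTNRYKMSWacgtn", "TGCANYRMKSWtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a DNA string (standard code); stops as '*', ambiguous as 'X'."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        out.append(_CODON_TABLE.get(cds[i : i + 3].upper(), "X"))
    return "".join(out)


class NoCoreFound(ValueError):
    """Precursor has no admissible proline-delimited core."""


class NoModel(ValueError):
    """Spliced alignment score below the acceptance floor."""


# ------------------------------------------------------------ precursor

@dataclass(frozen=True)
class MsdinPrecursor:
    peptide: str
    leader: str
    core: str
    follower: str
    core_span: tuple[int, int]  # 1-based inclusive residue interval

    def __post_init__(self):
        assert self.leader + self.core + self.follower == self.peptide
        assert self.leader.endswith("P")
        assert self.core.endswith("P")
        assert 7 <= len(self.core) <= 10


def extract_core(precursor_aa: str) -> MsdinPrecursor:
    """Decompose a precursor into leader | core | follower.

    The core is the stretch strictly after a leader-terminal proline up to
    and including the next proline, with 7-10 residues. Among admissible
    (P_i, P_j) pairs the one whose leader length is closest to 9 wins
    (ties toward the shorter leader) — MSDIN leaders are ~9 residues and
    the Lepiota variant is one shorter.
    """
    seq = precursor_aa.upper()
    candidates = []
    for i, aa in enumerate(seq):
        if aa != "P":
            continue
        j = seq.find("P", i + 1)
        if j == -1:
            continue
        core_len = j - i
        if 7 <= core_len <= 10 and j < len(seq) - 1:
            # leader = seq[:i+1]; core = seq[i+1:j+1]
            candidates.append((abs((i + 1) - 9), i + 1, j + 1))
    if not candidates:
        raise NoCoreFound(f"no admissible P..P core in {precursor_aa!r}")
    _, lead_end, core_end = min(candidates)
    return MsdinPrecursor(
        peptide=seq,
        leader=seq[:lead_end],
        core=seq[lead_end:core_end],
        follower=seq[core_end:],
        core_span=(lead_end + 1, core_end),
    )


# -------------------------------------------------------------- profile

@dataclass
class MotifProfile:
    """Position weight matrix (log-odds, bits) for the leader region.

    The training precursors are retained: full-length identity to the
    nearest training sequence breaks ties among splice variants of one
    locus that share a leader.
    """

    pwm: np.ndarray  # (leader_len, 20) probabilities, columns sum to 1
    threshold: float
    pseudocount: float = 1.0
    training: list[str] = field(default_factory=list)

    def identity(self, peptide: str) -> float:
        """Best ungapped identity of ``peptide`` to a training precursor."""
        best = 0.0
        for t in self.training:
            n = min(len(t), len(peptide))
            if n == 0:
                continue
            same = sum(a == b for a, b in zip(t, peptide))
            best = max(best, same / max(len(t), len(peptide)))
        return best

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    def score(self, leader: str) -> float:
        if len(leader) < self.length:
            return -math.inf
        s = 0.0
        for pos in range(self.length):
            aa = leader[pos]
            if aa not in AA_INDEX:
                return -math.inf
            s += math.log2(self.pwm[pos, AA_INDEX[aa]] * 20.0)
        return s


def build_leader_profile(known_precursors: Sequence[str], leader_len: int = 9,
                         pseudocount: float = 1.0,
                         margin: float = 1.0) -> MotifProfile:
    """Train a leader PWM with Laplace pseudocounts.

    The score threshold is set to the minimum training-set score minus
    ``margin`` bits, so every training precursor scores above it.
    """
    if len(known_precursors) < 2:
        raise ValueError("need at least 2 training precursors")
    if any(len(p) < leader_len for p in known_precursors):
        raise ValueError("leader_len exceeds a training sequence length")
    counts = np.full((leader_len, 20), pseudocount)
    for seq in known_precursors:
        for pos in range(leader_len):
            aa = seq[pos].upper()
            if aa in AA_INDEX:
                counts[pos, AA_INDEX[aa]] += 1
    pwm = counts / counts.sum(axis=1, keepdims=True)
    profile = MotifProfile(pwm, threshold=-math.inf, pseudocount=pseudocount,
                           training=[p.upper() for p in known_precursors])
    min_score = min(profile.score(p[:leader_len].upper())
                    for p in known_precursors)
    profile.threshold = min_score - margin
    return profile


# ------------------------------------------------------------ gene model

@dataclass
class GeneModel:
    """A coding gene on the genome: ATG..stop span and coding exons."""

    interval: GenomicInterval
    exons: list[GenomicInterval]
    protein: str
    name: str = ""

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError("overlapping exons in gene model")

    @property
    def introns(self) -> list[GenomicInterval]:
        iv = self.interval
        return [
            GenomicInterval(iv.contig, a.end, b.start, iv.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    @property
    def coding_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def check_invariant(self):
        assert self.coding_length == 3 * (len(self.protein) + 1), (
            f"coding length {self.coding_length} != 3*({len(self.protein)}+1)"
        )


@dataclass
class MineHit:
    gene_model: GeneModel
    precursor: MsdinPrecursor | None
    score: float
    family: str = "MSDIN"


# ----------------------------------------------------------------- scan

def _orf_candidates(seq: str, atg: int, min_aa: int, max_aa: int,
                    max_introns: int, intron_len: tuple[int, int],
                    gt_pos: np.ndarray, ag_end: np.ndarray):
    """Yield (aa, exon spans in strand-local coords) for one ATG.

    Exon spans cover ATG..stop inclusive of the stop codon.
    """
    max_cds = 3 * (max_aa + 1)
    # unspliced
    aa = translate(seq[atg : atg + max_cds])
    stop = aa.find("*")
    if stop != -1 and min_aa <= stop <= max_aa:
        end = atg + 3 * (stop + 1)
        yield aa[:stop], [(atg, end)]
    if max_introns < 1:
        return
    ilo, ihi = intron_len
    window_end = atg + max_cds + ihi
    # candidate donor sites strictly inside the coding region
    for p in gt_pos[np.searchsorted(gt_pos, atg + 1):]:
        if p >= window_end:
            break
        lo = np.searchsorted(ag_end, p + ilo)
        for q in ag_end[lo:]:
            if q - p > ihi:
                break
            spliced = seq[atg:p] + seq[q : q + max_cds - (p - atg)]
            aa = translate(spliced)
            stop = aa.find("*")
            if stop == -1 or not (min_aa <= stop <= max_aa):
                continue
            cds_len = 3 * (stop + 1)
            first_len = p - atg
            if cds_len <= first_len:
                continue  # intron not inside the coding region
            yield aa[:stop], [(atg, p), (q, q + cds_len - first_len)]


def _to_genomic(spans, strand: str, contig_len: int, contig: str):
    """Map strand-local half-open spans to genome coordinates."""
    out = []
    for s, e in spans:
        s, e = int(s), int(e)
        if strand == "+":
            out.append(GenomicInterval(contig, s, e, "+"))
        else:
            out.append(GenomicInterval(contig, contig_len - e, contig_len - s, "-"))
    return sorted(out, key=lambda iv: iv.start)


def scan_orfs(contig: SeqRecord, profile: MotifProfile,
              min_aa: int = 25, max_aa: int = 45, max_introns: int = 1,
              intron_len: tuple[int, int] = (40, 200)) -> list[MineHit]:
    """Six-frame translated scan for MSDIN precursor genes.

    A hit is an ATG..stop candidate (optionally spliced across one GT..AG
    intron) whose leader scores at or above the profile threshold and
    whose peptide decomposes into leader|core|follower. Splice variants of
    one locus (same strand and ATG) are collapsed to the best candidate:
    highest leader score, then highest full-precursor identity to the
    training set, then fewest introns, then shortest genomic span.
    """
    best_at_locus: dict[tuple, tuple] = {}
    L = len(contig.residues)
    for strand in ("+", "-"):
        seq = contig.residues.upper() if strand == "+" else revcomp(
            contig.residues.upper())
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        gt_pos = np.flatnonzero((arr[:-1] == ord("G")) & (arr[1:] == ord("T")))
        ag_end = np.flatnonzero((arr[:-1] == ord("A")) & (arr[1:] == ord("G"))) + 2
        atg_pos = np.flatnonzero(
            (arr[:-2] == ord("A")) & (arr[1:-1] == ord("T")) & (arr[2:] == ord("G"))
        )
        for atg in atg_pos:
            for aa, spans in _orf_candidates(
                seq, int(atg), min_aa, max_aa, max_introns, intron_len,
                gt_pos, ag_end,
            ):
                score = profile.score(aa)
                if score < profile.threshold:
                    continue
                try:
                    prec = extract_core(aa)
                except NoCoreFound:
                    continue
                rank = (score, profile.identity(aa), -(len(spans) - 1),
                        -(spans[-1][1] - spans[0][0]))
                locus = (strand, int(atg))
                if locus not in best_at_locus or rank > best_at_locus[locus][0]:
                    best_at_locus[locus] = (rank, aa, spans, prec, score,
                                            strand)
    hits: list[MineHit] = []
    seen: set[tuple] = set()
    for _, aa, spans, prec, score, strand in best_at_locus.values():
        exons = _to_genomic(spans, strand, L, contig.id)
        key = (strand, tuple((e.start, e.end) for e in exons))
        if key in seen:
            continue
        seen.add(key)
        model = GeneModel(
            interval=GenomicInterval(
                contig.id, exons[0].start, exons[-1].end, strand),
            exons=exons,
            protein=aa,
            name=f"msdin_{contig.id}_{exons[0].start}",
        )
        model.check_invariant()
        hits.append(MineHit(model, prec, score))
    hits.sort(key=lambda h: (-h.score, h.gene_model.interval.start))
    return hits


# -------------------------------------------------------- spliced align

NEG = -1e18


def spliced_align(genomic: str, reference_cds: str,
                  intron_len: tuple[int, int] = (40, 2000),
                  match: float = 2.0, mismatch: float = -3.0,
                  gap_open: float = -8.0, gap_extend: float = -2.0,
                  intron_open: float = -10.0,
                  min_score_frac: float = 0.5,
                  contig: str = "genomic", offset: int = 0,
                  strand: str = "+") -> GeneModel:
    """Align a coding sequence onto genomic DNA allowing GT..AG introns.

    Dynamic programming with match/mismatch, affine exon gaps, and an
    intron state that opens only at GT and closes only at AG, charged a
    fixed opening penalty and no per-base cost (minimum intron length
    enforced; the upper bound is advisory since zero-cost introns make a
    hard cap non-binding in practice). Genomic flanks are free (fit
    alignment of the full CDS into the genomic region). Ties resolve to
    the leftmost intron start.

    Returns a GeneModel whose exons cover the aligned genomic segments.
    Raises NoModel when the best score falls below
    ``min_score_frac * match * len(reference_cds)``.
    """
    g = genomic.upper()
    c = reference_cds.upper()
    Lg, Lc = len(g), len(c)
    if Lg == 0 or Lc == 0:
        raise ValueError("empty input sequence")
    ilo = max(2, intron_len[0])

    carr = np.frombuffer(c.encode(), dtype=np.uint8)
    garr = np.frombuffer(g.encode(), dtype=np.uint8)
    # substitution score of genomic char i vs every cds position
    jrange = np.arange(Lc + 1)

    # state rows over j = 0..Lc
    M = np.full(Lc + 1, NEG)
    X = np.full(Lc + 1, NEG)
    Y = np.full(Lc + 1, NEG)
    N = np.full(Lc + 1, NEG)
    M[0] = 0.0  # free genomic prefix / start

    # backpointers: 0=M,1=X,2=Y,3=N(exit),4=START
    bpM = np.zeros((Lg + 1, Lc + 1), dtype=np.int8)
    bpX = np.zeros((Lg + 1, Lc + 1), dtype=np.int8)
    bpY = np.zeros((Lg + 1, Lc + 1), dtype=np.int8)
    nfrom = np.full((Lg + 1, Lc + 1), -1, dtype=np.int32)
    estate = np.zeros((Lg + 1, Lc + 1), dtype=np.int8)

    # cds deletion before any genomic is consumed
    _y_scan(M, Y, gap_open, gap_extend, jrange, bpY_row=bpY[0])

    # ring buffer of intron-entry rows E[p] (valid only at GT starts)
    E_ring = np.full((ilo + 1, Lc + 1), NEG)
    is_gt = np.zeros(Lg + 1, dtype=bool)
    is_gt[: Lg - 1] = (garr[:-1] == ord("G")) & (garr[1:] == ord("T"))
    exit_ok = np.zeros(Lg + 2, dtype=bool)
    # intron ending at row i consumed genomic[:i] with g[i-2:i] == AG
    exit_ok[2 : Lg + 1] = (garr[:-1] == ord("A")) & (garr[1:] == ord("G"))

    rowsM = np.full((Lg + 1, Lc + 1), NEG)
    rowsY = np.full((Lg + 1, Lc + 1), NEG)
    rowsM[0] = M
    rowsY[0] = Y

    for i in range(1, Lg + 1):
        # record intron entry from previous row state (intron starts at p=i-1)
        p = i - 1
        if is_gt[p]:
            stacked = np.vstack([M, X, Y])
            which = np.argmax(stacked, axis=0)
            E = stacked[which, jrange] + intron_open
            estate[p] = which
        else:
            E = np.full(Lc + 1, NEG)
        E_ring[p % (ilo + 1)] = E

        sub = np.where(carr == garr[i - 1], match, mismatch)

        # M: consume genomic[i-1] vs cds[j-1]
        exitN = N if exit_ok[i - 1] else np.full(Lc + 1, NEG)
        stackM = np.vstack([M[:-1], X[:-1], Y[:-1], exitN[:-1]])
        argM = np.argmax(stackM, axis=0)
        newM = np.full(Lc + 1, NEG)
        newM[1:] = stackM[argM, np.arange(Lc)] + sub
        newM[0] = 0.0  # free genomic prefix continues
        bpM[i, 1:] = argM
        # where predecessor was the start cell (M[i-1,0]==0 with bp START)
        # handled implicitly: bpM value 0 at j==1 with prev M[0]==0

        # X: genomic insertion (consume genomic only)
        exitNX = N if exit_ok[i - 1] else np.full(Lc + 1, NEG)
        fromM = M + gap_open
        fromX = X + gap_extend
        fromN = exitNX + gap_open
        newX = np.maximum(np.maximum(fromM, fromX), fromN)
        bpX[i] = np.where(fromM >= newX, 0, np.where(fromX >= newX, 1, 3))
        newX[0] = NEG

        # N: inside intron (consume genomic only, no per-base cost)
        newN = N.copy()
        nfrom[i] = nfrom[i - 1]
        if i - ilo >= 0:
            pe = i - ilo
            Epast = E_ring[pe % (ilo + 1)]
            better = Epast > newN
            newN = np.where(better, Epast, newN)
            nfrom[i][better] = pe
        newN[0] = NEG

        # Y: cds deletion (consume cds only) — scan within current row
        newY = np.full(Lc + 1, NEG)
        _y_scan(newM, newY, gap_open, gap_extend, jrange, bpY_row=bpY[i])

        M, X, Y, N = newM, newX, newY, newN
        rowsM[i] = M
        rowsY[i] = Y

    # best end: full CDS consumed, genomic suffix free
    endM = rowsM[:, Lc]
    endY = rowsY[:, Lc]
    best_i = int(np.argmax(np.maximum(endM, endY)))
    end_state = 0 if endM[best_i] >= endY[best_i] else 2
    best = max(endM[best_i], endY[best_i])
    floor = min_score_frac * match * Lc
    if best < floor:
        raise NoModel(f"best spliced-alignment score {best:.1f} < floor {floor:.1f}")

    exon_rows = _traceback(
        best_i, end_state, bpM, bpX, bpY, nfrom, estate, ilo, Lc)

    exons = [
        GenomicInterval(contig, offset + s, offset + e, strand)
        for s, e in exon_rows
    ]
    spliced = "".join(g[s:e] for s, e in exon_rows)
    aa = translate(spliced)
    protein = aa[:-1] if aa.endswith("*") else aa
    model = GeneModel(
        interval=GenomicInterval(contig, exons[0].start, exons[-1].end, strand),
        exons=exons,
        protein=protein,
    )
    return model


def _y_scan(M_row, Y_row, gap_open, gap_extend, jrange, bpY_row=None):
    """Fill Y (cds-deletion) state for one row from that row's M values.

    Y[j] = max_{k<j} source[k] + gap_open + (j-1-k)*gap_extend, a prefix-max
    scan over A[k] = source[k] - gap_extend*k.
    """
    Lc = len(M_row) - 1
    if Lc == 0:
        return
    A = M_row - gap_extend * jrange
    pref = np.maximum.accumulate(A[:-1])
    Y_row[1:] = gap_open + gap_extend * (jrange[1:] - 1) + pref
    if bpY_row is not None:
        # whether Y[j] came directly from M[j-1] (open) or extends Y[j-1]
        direct = A[:-1] >= pref - 1e-12
        bpY_row[1:] = np.where(direct, 0, 2)


def _traceback(i, state, bpM, bpX, bpY, nfrom, estate, ilo, Lc):
    """Recover exon spans (strand-local, half-open) from backpointers."""
    j = Lc
    consumed: list[int] = []  # genomic indices consumed in exon states
    while True:
        if state == 0:  # M
            if j == 0:
                break  # free prefix start
            consumed.append(i - 1)
            prev = bpM[i, j]
            i, j, state = i - 1, j - 1, int(prev)
            if j == 0 and state == 0:
                # predecessor is the free-start cell
                break
        elif state == 1:  # X
            consumed.append(i - 1)
            prev = bpX[i, j]
            i, state = i - 1, int(prev)
        elif state == 2:  # Y
            prev = bpY[i, j]
            j, state = j - 1, int(prev)
        elif state == 3:  # N (intron): jump to entry row
            p = int(nfrom[i, j])
            if p < 0:
                raise RuntimeError("broken intron traceback")
            state = int(estate[p, j])
            i = p
        else:
            break
    consumed.reverse()
    spans: list[tuple[int, int]] = []
    for idx in consumed:
        if spans and idx == spans[-1][1]:
            spans[-1] = (spans[-1][0], idx + 1)
        else:
            spans.append((idx, idx + 1))
    return spans


# ------------------------------------------------------------- distance

def toxin_gene_distance(hits: Sequence[MineHit | GeneModel],
                        cluster_threshold: int = 50_000) -> dict:
    """Pairwise genomic separation report for mined toxin genes.

    Same-contig pairs report the bp gap and a clustering verdict
    (clustered iff gap < threshold, strictly); cross-contig pairs are
    unlinked at assembly level.
    """
    models = [h.gene_model if isinstance(h, MineHit) else h for h in hits]
    if len(models) < 2:
        return {"verdict": "single gene", "pairs": []}
    pairs = []
    any_clustered = False
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            iva, ivb = models[a].interval, models[b].interval
            entry = {"a": iva.contig, "b": ivb.contig}
            if iva.contig == ivb.contig:
                gap = max(iva.start, ivb.start) - min(iva.end, ivb.end)
                gap = max(gap, 0)
                entry["gap_bp"] = gap
                entry["clustered"] = gap < cluster_threshold
                any_clustered |= entry["clustered"]
            else:
                entry["gap_bp"] = None
                entry["clustered"] = False
                entry["note"] = "unlinked at assembly level"
            pairs.append(entry)
    return {
        "verdict": "clustered" if any_clustered else "not clustered",
        "pairs": pairs,
    }
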