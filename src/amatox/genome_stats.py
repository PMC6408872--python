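"""Assembly summary statistics (N50/N90, GC) and windowed GC / GC-skew tracks.

Track export is a 4-column TSV (contig, start, end, value) — a flat file a
Circos configuration can consume directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import SeqRecord

__all__ = [
    "AssemblyStats",
    "WindowTrack",
    "nxx",
    "gc_content",
    "gc_skew",
    "gc_track",
    "assembly_summary",
    "write_track_tsv",
]


@dataclass(frozen=True)
class AssemblyStats:
    total_bp: int
    n_contigs: int
    n50: int
    n90: int
    max_len: int
    gc_fraction: float

    def __post_init__(self):
        assert self.n90 <= self.n50 <= self.max_len <= self.total_bp
        assert 0.0 <= self.gc_fraction <= 1.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class WindowRow:
    contig: str
    start: int  # 0-based half-open
    end: int
    value: float
    flag: str = ""


@dataclass
class WindowTrack:
    name: str
    rows: list[WindowRow]


def nxx(lengths: Sequence[int], x: float) -> int:
    """Smallest length L such that contigs >= L cover >= x% of the total.

    Ties resolve toward the larger contig (the common assembler-report
    convention): lengths are accumulated in decreasing order and the first
    contig reaching the threshold defines the statistic.
    """
    if not lengths:
        raise ValueError("nxx of an empty length list")
    if not (0 < x < 100):
        raise ValueError(f"x must be in (0,100), got {x}")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    total = sum(lengths)
    threshold = total * x / 100.0
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= threshold:
            return l
    return min(lengths)  # unreachable


def _counts(seq: str) -> tuple[int, int, int]:
    """(G, C, A+T) counts, ambiguity codes excluded."""
    g = seq.count("G")
    c = seq.count("C")
    at = seq.count("A") + seq.count("T")
    return g, c, at


def gc_content(seqs: Iterable[SeqRecord | str]) -> float:
    """(G+C)/(A+C+G+T) over all records; N and other ambiguity codes are
    excluded from both numerator and denominator."""
    g = c = at = 0
    for s in seqs:
        residues = s.residues if isinstance(s, SeqRecord) else s
        gi, ci, ati = _counts(residues.upper())
        g, c, at = g + gi, c + ci, at + ati
    denom = g + c + at
    if denom == 0:
        raise ValueError("no unambiguous bases: GC content undefined")
    return (g + c) / denom


def gc_skew(seq: SeqRecord | str, window: int, step: int | None = None,
            contig: str | None = None) -> WindowTrack:
    """Per-window (G-C)/(G+C). Zero-GC windows emit value 0 with flag."""
    residues = (seq.residues if isinstance(seq, SeqRecord) else seq).upper()
    name = contig or (seq.id if isinstance(seq, SeqRecord) else "seq")
    step = step or window
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    if window > len(residues):
        window = len(residues)
    rows = []
    for start in range(0, max(len(residues) - window, 0) + 1, step):
        sub = residues[start : start + window]
        g, c, _ = _counts(sub)
        if g + c == 0:
            rows.append(WindowRow(name, start, start + window, 0.0, "zero-gc"))
        else:
            rows.append(WindowRow(name, start, start + window, (g - c) / (g + c)))
    return WindowTrack("gc_skew", rows)


def gc_track(seq: SeqRecord | str, window: int, step: int | None = None,
             contig: str | None = None) -> WindowTrack:
    """Per-window GC fraction (ambiguity codes excluded per window)."""
    residues = (seq.residues if isinstance(seq, SeqRecord) else seq).upper()
    name = contig or (seq.id if isinstance(seq, SeqRecord) else "seq")
    step = step or window
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    if window > len(residues):
        window = len(residues)
    rows = []
    for start in range(0, max(len(residues) - window, 0) + 1, step):
        g, c, at = _counts(residues[start : start + window])
        if g + c + at == 0:
            rows.append(WindowRow(name, start, start + window, 0.0, "all-ambiguous"))
        else:
            rows.append(WindowRow(name, start, start + window, (g + c) / (g + c + at)))
    return WindowTrack("gc_content", rows)


def assembly_summary(contigs: Sequence[SeqRecord]) -> AssemblyStats:
    if not contigs:
        raise ValueError("assembly_summary of zero contigs")
    lengths = [len(c) for c in contigs]
    return AssemblyStats(
        total_bp=sum(lengths),
        n_contigs=len(lengths),
        n50=nxx(lengths, 50),
        n90=nxx(lengths, 90),
        max_len=max(lengths),
        gc_fraction=gc_content(contigs),
    )


def write_track_tsv(track: WindowTrack, path):
    path = Path(path)
    with open(path, "w") as fh:
        for r in track.rows:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.value:.6f}\n")
    return path
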