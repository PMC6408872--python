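"""Readers/writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open; GFF3 output (and any
human-facing report) is 1-based inclusive. Unknown residues are kept as
N/X, never dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO as _BioSeqIO

__all__ = [
    "SeqRecord",
    "Alignment",
    "GenomicInterval",
    "PeakList",
    "SeqIOError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "parse_newick",
    "write_newick",
    "write_gff3",
    "read_peak_table",
]


class SeqIOError(ValueError):
    """Malformed input file or inconsistent records."""


@dataclass(frozen=True)
class SeqRecord:
    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise SeqIOError("sequence record with empty id")
        if not self.residues:
            raise SeqIOError(f"sequence record {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """Ordered equal-length rows keyed by unique taxon ids."""

    records: list[SeqRecord]
    type: str = "nucleotide"  # or "protein"

    def __post_init__(self):
        if not self.records:
            raise SeqIOError("empty alignment")
        width = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != width:
                raise SeqIOError(
                    f"ragged alignment: taxon {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {width}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SeqIOError(f"duplicate taxon id {dup!r} in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, taxon: str) -> str:
        for r in self.records:
            if r.id == taxon:
                return r.residues
        raise KeyError(taxon)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise SeqIOError(
                f"bad interval [{self.start},{self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_gff_coords(self) -> tuple[int, int]:
        """Convert to 1-based inclusive (GFF3) coordinates."""
        return self.start + 1, self.end

    @staticmethod
    def from_gff_coords(contig: str, start1: int, end1: int, strand: str = "+"):
        return GenomicInterval(contig, start1 - 1, end1, strand)


@dataclass
class PeakList:
    """MS1 peaks as (m/z in Da, intensity) pairs, sorted by m/z."""

    peaks: list[tuple[float, float]] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        for mz, _ in self.peaks:
            if mz <= 0:
                raise SeqIOError(f"non-positive m/z {mz}")
        self.peaks = sorted(self.peaks)

    def mzs(self) -> list[float]:
        return [p[0] for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file; residues uppercased, duplicate ids rejected."""
    path = Path(path)
    records = []
    seen = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(rec.id, str(rec.seq).upper(), desc))
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path, wrap: int = 60):
    records = list(records)
    if not records:
        raise SeqIOError("refusing to write empty FASTA")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")
    return path


# ------------------------------------------------------------- PHYLIP

_PROTEIN_ONLY = set("EFILPQZ")


def _guess_type(rows: Sequence[str]) -> str:
    residues = set("".join(rows).upper()) - set("-?.")
    return "protein" if residues & _PROTEIN_ONLY else "nucleotide"


def read_alignment(path, dialect: str = "auto") -> Alignment:
    """Read relaxed sequential PHYLIP or aligned FASTA.

    Relaxed PHYLIP means whitespace-delimited taxon names of any length,
    one taxon per (possibly wrapped) block, sequential layout — the format
    of the study's supplementary .PHY files. Interleaved PHYLIP is
    rejected with a clear message.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "auto":
        dialect = "fasta" if text.lstrip().startswith(">") else "phylip"
    if dialect == "fasta":
        recs = read_fasta(path)
        return Alignment(recs, _guess_type([r.residues for r in recs]))

    tokens_by_line = [ln.split() for ln in text.splitlines() if ln.strip()]
    if not tokens_by_line:
        raise SeqIOError(f"empty alignment file {path}")
    header = tokens_by_line[0]
    try:
        ntax, nchar = int(header[0]), int(header[1])
    except (IndexError, ValueError):
        raise SeqIOError(f"bad PHYLIP header in {path}: {' '.join(header)!r}")

    # sequential: name then residue chunks until nchar residues are read
    flat: list[str] = [t for line in tokens_by_line[1:] for t in line]
    records: list[SeqRecord] = []
    i = 0
    for _ in range(ntax):
        if i >= len(flat):
            raise SeqIOError(f"{path}: expected {ntax} taxa, file truncated")
        name = flat[i]
        i += 1
        chunks: list[str] = []
        got = 0
        while got < nchar:
            if i >= len(flat):
                raise SeqIOError(
                    f"{path}: taxon {name!r} has {got} characters, "
                    f"expected {nchar} (interleaved PHYLIP is not supported)"
                )
            chunk = flat[i]
            if got + len(chunk) > nchar:
                raise SeqIOError(
                    f"{path}: taxon {name!r} row overruns {nchar} columns "
                    "(ragged row or interleaved PHYLIP, which is not supported)"
                )
            chunks.append(chunk)
            got += len(chunk)
            i += 1
        records.append(SeqRecord(name, "".join(chunks).upper()))
    if i != len(flat):
        raise SeqIOError(f"{path}: trailing tokens after {ntax} taxa "
                         "(interleaved PHYLIP is not supported)")
    return Alignment(records, _guess_type([r.residues for r in records]))


def write_alignment_phylip(aln: Alignment, path):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{len(aln)} {aln.length}\n")
        for rec in aln.records:
            fh.write(f"{rec.id}  {rec.residues}\n")
    return path


# ------------------------------------------------------------- Newick

_UNQUOTED_LABEL = re.compile(r"^[A-Za-z0-9_.\-]+$")


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree into a dendropy Tree.

    Raises SeqIOError (with the offending position where dendropy reports
    one) for unbalanced or empty input.
    """
    if not text or not text.strip():
        raise SeqIOError("empty Newick string")
    s = text.strip()
    if s.count("(") != s.count(")"):
        # report first unmatched position
        depth = 0
        pos = len(s)
        for i, ch in enumerate(s):
            depth += ch == "("
            depth -= ch == ")"
            if depth < 0:
                pos = i
                break
        raise SeqIOError(f"unbalanced parentheses in Newick near position {pos}")
    try:
        tree = dendropy.Tree.get(
            data=s, schema="newick", suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise SeqIOError(f"Newick parse error: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


# --------------------------------------------------------------- GFF3

def write_gff3(gene_models, path, source: str = "amatox"):
    """Serialize gene models (see msdin_miner.GeneModel) as GFF3 v3.

    Emits gene/mRNA/exon/CDS rows with 1-based inclusive coordinates,
    exons sorted 5'->3' on the genome.
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    for n, model in enumerate(gene_models, start=1):
        exons = sorted(model.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise SeqIOError(
                    f"overlapping exons [{a.start},{a.end}) and "
                    f"[{b.start},{b.end}) in gene {n}"
                )
        iv = model.interval
        gid = getattr(model, "name", "") or f"gene{n}"
        s1, e1 = iv.to_gff_coords()
        base = f"{iv.contig}\t{source}\t"
        tail = f"\t.\t{iv.strand}\t.\t"
        lines.append(base + f"gene\t{s1}\t{e1}" + tail + f"ID={gid}")
        lines.append(base + f"mRNA\t{s1}\t{e1}" + tail +
                     f"ID={gid}.t1;Parent={gid}")
        for k, exon in enumerate(exons, start=1):
            xs, xe = exon.to_gff_coords()
            lines.append(base + f"exon\t{xs}\t{xe}" + tail +
                         f"ID={gid}.t1.exon{k};Parent={gid}.t1")
            lines.append(base + f"CDS\t{xs}\t{xe}" + tail +
                         f"ID={gid}.t1.cds;Parent={gid}.t1")
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def read_gff3_intervals(path) -> dict[str, list[GenomicInterval]]:
    """Read exon intervals back from a GFF3 file (keyed by Parent mRNA)."""
    out: dict[str, list[GenomicInterval]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] != "exon":
            continue
        parent = next(
            (kv.split("=", 1)[1] for kv in f[8].split(";") if kv.startswith("Parent=")),
            "?",
        )
        out.setdefault(parent, []).append(
            GenomicInterval.from_gff_coords(f[0], int(f[3]), int(f[4]), f[6])
        )
    return out


# ---------------------------------------------------------- peak table

def read_peak_table(path) -> PeakList:
    """Read a TSV/CSV MS1 peak table with an mz column (intensity optional)."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return PeakList([], source=str(path))
    sep = "\t" if "\t" in lines[0] else ","
    header = [h.strip().lower() for h in lines[0].split(sep)]
    if "mz" not in header and "m/z" not in header:
        raise SeqIOError(f"{path}: no mz column in header {header}")
    mz_col = header.index("mz") if "mz" in header else header.index("m/z")
    int_col = header.index("intensity") if "intensity" in header else None
    peaks = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in ln.split(sep)]
        try:
            mz = float(fields[mz_col])
        except (ValueError, IndexError):
            raise SeqIOError(f"{path}:{lineno}: non-numeric mz field")
        inten = 1.0
        if int_col is not None and int_col < len(fields) and fields[int_col]:
            try:
                inten = float(fields[int_col])
            except ValueError:
                raise SeqIOError(f"{path}:{lineno}: non-numeric intensity")
        peaks.append((mz, inten))
    return PeakList(peaks, source=str(path))


def write_peak_table(peaklist: PeakList, path):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("mz\tintensity\n")
        for mz, inten in peaklist.peaks:
            fh.write(f"{mz:.6f}\t{inten:g}\n")
    return path
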