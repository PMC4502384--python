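"""Readers, writers and coordinate conventions for every external format.

All internal coordinates are 0-based half-open.  1-based conventions exist
only at format boundaries: wiggle (1-based), the gene-table ``tss`` column
(1-based), and GFF3 (1-based inclusive).  Sequences are stored uppercase;
``N`` bases are preserved and downstream scanners decide how to treat them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

IUPAC_OK = set("ACGTN")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file violated the grammar or invariants of its declared format."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """A set of named chromosome sequences (uppercase A/C/G/T/N)."""

    chroms: dict[str, str]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chroms.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented when strand is '−'."""
        s = self.chroms[chrom][max(start, 0):max(end, 0)]
        return revcomp(s) if strand == "-" else s


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its TSS (1-based) and body span (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int     # 1-based genomic coordinate
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"unknown strand {self.strand!r} for gene {self.gene_id}")
        if self.span[0] >= self.span[1]:
            raise FormatError(f"empty span for gene {self.gene_id}")

    @property
    def tss0(self) -> int:
        """TSS as a 0-based index."""
        return self.tss - 1


@dataclass(frozen=True)
class Peak:
    """A ChIP peak interval (0-based half-open) with score and optional summit."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    summit: Optional[int] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"peak end <= start: {self.chrom}:{self.start}-{self.end}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise FormatError(
                f"summit {self.summit} outside peak {self.chrom}:{self.start}-{self.end}")

    @property
    def anchor(self) -> int:
        """Point estimate of the binding position: summit, else midpoint."""
        return self.summit if self.summit is not None else (self.start + self.end) // 2


@dataclass
class CoverageTrack:
    """Per-chromosome base-resolution signal vectors (0-based indices)."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, chrom: str, length: Optional[int] = None) -> np.ndarray:
        """Vector for ``chrom``; zero-padded/truncated to ``length`` if given."""
        vec = self.data.get(chrom)
        if vec is None:
            vec = np.zeros(0)
        if length is not None and len(vec) != length:
            out = np.zeros(length)
            n = min(length, len(vec))
            out[:n] = vec[:n]
            return out
        return vec

    def pad_to(self, lengths: Mapping[str, int]) -> "CoverageTrack":
        """Conform every chromosome vector to the genome's lengths."""
        return CoverageTrack({c: self.get(c, n) for c, n in lengths.items()})


@dataclass
class PWMRecord:
    """A position weight matrix with background model.

    ``matrix`` holds the probabilities as parsed (rows sum to 1);
    ``regularized`` adds the pseudocount and renormalizes, guaranteeing
    strictly positive entries for log-odds work.
    """

    motif_id: str
    matrix: np.ndarray          # width x 4, columns in A,C,G,T order
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise FormatError(f"motif {self.motif_id}: matrix must be width x 4")
        if self.pseudocount <= 0:
            raise FormatError(f"motif {self.motif_id}: pseudocount must be > 0")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise FormatError(f"motif {self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def regularized(self) -> np.ndarray:
        reg = self.matrix + self.pseudocount
        return reg / reg.sum(axis=1, keepdims=True)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into a :class:`GenomeSequence`.

    The header token before the first whitespace becomes the chromosome name.
    Raises :class:`FormatError` on empty files, duplicate headers, or
    non-IUPAC characters (only A/C/G/T/N are accepted).
    """
    chroms: dict[str, str] = {}
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or invalid FASTA file")
    for rec in records:
        name = rec.id
        if name in chroms:
            raise FormatError(f"{path}: duplicate FASTA header {name!r}")
        seq = str(rec.seq).upper()
        if len(seq) < 1:
            raise FormatError(f"{path}: zero-length record {name!r}")
        bad = set(seq) - IUPAC_OK
        if bad:
            raise FormatError(
                f"{path}: record {name!r} contains non-IUPAC characters {sorted(bad)}")
        chroms[name] = seq
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.chroms.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------

def read_bed_peaks(path, summit_col: Optional[int] = None,
                   summit_relative: bool = True) -> list[Peak]:
    """Read peaks from a BED3+ file (0-based half-open, taken verbatim).

    Column 5 (index 4) becomes the score when present, else 0.  When
    ``summit_col`` is given (0-based column index), that column supplies the
    summit, interpreted as an offset from ``start`` when ``summit_relative``
    (narrowPeak convention) or as an absolute coordinate otherwise.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name = cols[3] if len(cols) > 3 else None
            score = 0.0
            if len(cols) > 4:
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            summit = None
            if summit_col is not None and len(cols) > summit_col:
                summit = int(cols[summit_col])
                if summit_relative:
                    summit += start
            peaks.append(Peak(chrom, start, end, score, summit, name))
    return peaks


def write_bed_peaks(peaks: Sequence[Peak], path) -> None:
    """Write BED6-like lines; summits go to column 7 as offsets from start."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            name = p.name if p.name is not None else f"peak_{i + 1}"
            cols = [p.chrom, str(p.start), str(p.end), name, f"{p.score:g}", "."]
            if p.summit is not None:
                cols.append(str(p.summit - p.start))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = ("gene_id", "chrom", "strand", "tss", "start", "end")


def read_gene_table(path) -> list[GeneRecord]:
    """Read genes from a tab-separated table or a GFF3 subset.

    Tab-separated: columns gene_id, chrom, strand, tss (1-based), start, end
    (1-based inclusive, converted internally to 0-based half-open).  GFF3:
    ``gene`` feature lines with an ``ID=`` attribute; the TSS is the start
    field on '+' genes and the end field on '−' genes.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        text = fh.read()
    is_gff = text.startswith("##gff-version") or any(
        len(l.split("\t")) == 9 for l in text.splitlines()[:5] if l and l[0] != "#")
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if is_gff:
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[2] != "gene":
                continue
            chrom, start, end, strand = cols[0], int(cols[3]), int(cols[4]), cols[6]
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: gene line without ID attribute")
            tss = start if strand == "+" else end
        else:
            if cols == list(GENE_TABLE_COLUMNS):
                continue  # header row
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            gene_id, chrom, strand = cols[0], cols[1], cols[2]
            try:
                tss, start, end = int(cols[3]), int(cols[4]), int(cols[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if strand not in "+-":
            raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        genes.append(GeneRecord(gene_id, chrom, strand, tss, (start - 1, end)))
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}"
                     f"\t{g.span[0] + 1}\t{g.span[1]}\n")


# ---------------------------------------------------------------------------
# Coverage: wiggle (fixedStep / variableStep) and bedGraph
# ---------------------------------------------------------------------------

def read_coverage(path) -> CoverageTrack:
    """Read a wiggle or bedGraph coverage file at base resolution.

    The dialect is auto-detected: files containing ``fixedStep`` /
    ``variableStep`` declaration lines are parsed as UCSC wiggle (1-based);
    everything else is parsed as bedGraph (0-based half-open).  Unspecified
    bases are 0.
    """
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    is_wig = any(l.lstrip().startswith(("fixedStep", "variableStep")) for l in lines)
    if is_wig:
        return _read_wiggle(lines, str(path))
    return _read_bedgraph(lines, str(path))


def _grow(buf: dict[str, list], chrom: str) -> list:
    if chrom not in buf:
        buf[chrom] = []
    return buf[chrom]


def _materialize(intervals: dict[str, list], check_overlap: bool, path: str) -> CoverageTrack:
    data: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        if not ivs:
            data[chrom] = np.zeros(0)
            continue
        length = max(e for _, e, _ in ivs)
        vec = np.zeros(length)
        if check_overlap:
            seen = np.zeros(length, dtype=bool)
        for s, e, v in ivs:
            if check_overlap:
                if seen[s:e].any():
                    raise FormatError(f"{path}: overlapping bedGraph intervals on {chrom}")
                seen[s:e] = True
            vec[s:e] = v
        data[chrom] = vec
    return CoverageTrack(data)


def _read_wiggle(lines: list[str], path: str) -> CoverageTrack:
    intervals: dict[str, list] = {}
    mode = None  # ("fixed", chrom, next_start0, step, span) | ("var", chrom, span)
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            kv = dict(t.split("=", 1) for t in line.split()[1:])
            chrom = kv["chrom"]
            start0 = int(kv["start"]) - 1
            step = int(kv.get("step", 1))
            span = int(kv.get("span", 1))
            if step < 1 or span < 1:
                raise FormatError(f"{path}:{lineno}: invalid step/span")
            if span > step:
                raise FormatError(f"{path}:{lineno}: span {span} exceeds step {step}")
            mode = ["fixed", chrom, start0, step, span]
            _grow(intervals, chrom)
        elif line.startswith("variableStep"):
            kv = dict(t.split("=", 1) for t in line.split()[1:])
            mode = ["var", kv["chrom"], int(kv.get("span", 1))]
            _grow(intervals, kv["chrom"])
        else:
            if mode is None:
                raise FormatError(f"{path}:{lineno}: data before declaration line")
            if mode[0] == "fixed":
                _, chrom, start0, step, span = mode
                value = float(line)
                intervals[chrom].append((start0, start0 + span, value))
                mode[2] = start0 + step
            else:
                _, chrom, span = mode
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 'pos value'")
                pos0 = int(parts[0]) - 1
                intervals[chrom].append((pos0, pos0 + span, float(parts[1])))
    return _materialize(intervals, check_overlap=False, path=path)


def _read_bedgraph(lines: list[str], path: str) -> CoverageTrack:
    intervals: dict[str, list] = {}
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom, s, e, v = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
        if e <= s:
            raise FormatError(f"{path}:{lineno}: end <= start")
        _grow(intervals, chrom).append((s, e, v))
    return _materialize(intervals, check_overlap=True, path=path)


def write_wiggle(track: CoverageTrack, path, precision: int = 6) -> None:
    """Write as fixedStep step=1 wiggle (full vectors, 1-based starts)."""
    with open(path, "w") as fh:
        for chrom, vec in track.data.items():
            if len(vec) == 0:
                continue
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            for v in vec:
                fh.write(f"{v:.{precision}g}\n")


def write_bedgraph(track: CoverageTrack, path, precision: int = 6) -> None:
    """Write run-length-encoded bedGraph, omitting zero runs."""
    with open(path, "w") as fh:
        for chrom, vec in track.data.items():
            n = len(vec)
            i = 0
            while i < n:
                j = i + 1
                while j < n and vec[j] == vec[i]:
                    j += 1
                if vec[i] != 0.0:
                    fh.write(f"{chrom}\t{i}\t{j}\t{vec[i]:.{precision}g}\n")
                i = j


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def read_meme_motifs(path, pseudocount: float = 0.01) -> list[PWMRecord]:
    """Read PWMs from a MEME minimal-format file.

    The file-level background is used when present, else uniform.  Each
    probability row must sum to 1 within 1e-3 as written; rows are
    renormalized exactly on read, and the pseudocount regularization is
    applied lazily via :attr:`PWMRecord.regularized`.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    background = np.full(4, 0.25)
    motifs: list[PWMRecord] = []
    i = 0
    n = len(lines)
    saw_version = False
    while i < n:
        line = lines[i].strip()
        if line.startswith("MEME version"):
            saw_version = True
        elif line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freq = {toks[k]: float(toks[k + 1]) for k in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in BASES])
            background = background / background.sum()
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while i < n and not lines[i].strip().startswith("letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {motif_id!r} has no matrix")
                i += 1
            if i >= n:
                raise FormatError(f"{path}: motif {motif_id!r} has no matrix")
            header = lines[i].strip()
            kv = dict(t.split("=", 1) for t in header.replace("= ", "=").split()
                      if "=" in t)
            declared_w = int(kv["w"]) if "w" in kv else None
            rows = []
            i += 1
            while i < n:
                row_line = lines[i].strip()
                if not row_line or row_line.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in row_line.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}: motif {motif_id!r}: row with "
                                      f"{len(vals)} values (want 4)")
                if abs(sum(vals) - 1.0) > 1e-3:
                    raise FormatError(f"{path}: motif {motif_id!r}: row sums to "
                                      f"{sum(vals):.6f}, not 1")
                rows.append(vals)
                i += 1
            if declared_w is not None and len(rows) != declared_w:
                raise FormatError(f"{path}: motif {motif_id!r}: {len(rows)} rows "
                                  f"but w={declared_w}")
            if not rows:
                raise FormatError(f"{path}: motif {motif_id!r}: empty matrix")
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)
            motifs.append(PWMRecord(motif_id, mat, background, pseudocount))
            continue
        i += 1
    if not saw_version:
        raise FormatError(f"{path}: missing 'MEME version' header")
    if not motifs:
        raise FormatError(f"{path}: no motifs found")
    return motifs


def write_meme_motifs(motifs: Sequence[PWMRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(BASES)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 1000000 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{x:.10f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Promoter windows
# ---------------------------------------------------------------------------

def promoter_interval(gene: GeneRecord, upstream: int = 500, downstream: int = 0,
                      chrom_length: Optional[int] = None) -> Optional[tuple[int, int]]:
    """0-based half-open promoter window of a gene, truncated to the chromosome.

    On the '+' strand the window is ``[tss-1-upstream, tss-1+downstream)``;
    on '−' it mirrors to ``[tss-downstream, tss+upstream)`` (``tss`` 1-based).
    Returns ``None`` when the truncated window is empty — a signal distinct
    from an error.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValueError("upstream and downstream cannot both be 0")
    if gene.strand == "+":
        start, end = gene.tss - 1 - upstream, gene.tss - 1 + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        return None
    return start, end


def promoter_sequence(genome: GenomeSequence, gene: GeneRecord,
                      upstream: int = 500, downstream: int = 0) -> str:
    """Strand-oriented promoter sequence ('−' genes are reverse-complemented)."""
    iv = promoter_interval(gene, upstream, downstream, genome.length(gene.chrom))
    if iv is None:
        return ""
    return genome.fetch(gene.chrom, iv[0], iv[1], gene.strand)
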