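"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) internally;
GTF input (1-based, closed) is converted on read. Readers validate strictly
and raise :class:`FormatError` naming the offending line rather than
silently repairing records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomicInterval",
    "FragmentRecord",
    "PeakCall",
    "GeneRecord",
    "PWM",
    "read_bed",
    "write_bed",
    "read_fragments",
    "read_peak_calls",
    "write_peak_calls",
    "read_fasta",
    "write_fasta",
    "read_pfm",
    "write_pfm",
    "read_gene_model",
    "write_gene_model",
    "read_gmt",
]

VALID_BASES = frozenset("ACGTN")

DEFAULT_PSEUDOCOUNT = 0.001


class FormatError(ValueError):
    """Malformed record in an external file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``[start, end)``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlap in bp with ``other``; 0 on different chromosomes."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced fragment; its length is the interval length."""

    interval: GenomicInterval

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class PeakCall:
    """A called accessibility peak from one condition."""

    interval: GenomicInterval
    score: float = 0.0
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its transcription start site (0-based)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities (A,C,G,T).

    ``probs`` has shape (L, 4); every cell is strictly positive after
    pseudocounting and every row sums to 1.  ``file_threshold`` carries a
    log-odds detection threshold read from a HOMER-style motif file, if any.
    """

    name: str
    probs: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    file_threshold: float | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(f"probs must be (L>=1, 4), got {probs.shape}")
        if not np.all(probs > 0):
            raise ValueError("all probabilities must be > 0 after pseudocounting")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1 within 1e-9")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def _split_line(line: str, lineno: int, min_cols: int, path: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_cols:
        raise FormatError(
            f"{path}:{lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    return fields


def _parse_interval(fields: list[str], lineno: int, path: str,
                    with_strand: bool) -> GenomicInterval:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    strand = "."
    if with_strand:
        strand = fields[5]
        if strand not in ("+", "-", "."):
            raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
    try:
        return GenomicInterval(fields[0], start, end, strand)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path: str, expected_columns: int = 3) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into validated intervals, preserving file order."""
    if expected_columns not in (3, 6):
        raise ValueError("expected_columns must be 3 or 6")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, lineno, expected_columns, path)
            intervals.append(
                _parse_interval(fields, lineno, path, expected_columns == 6)
            )
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str,
              names: list[str] | None = None) -> None:
    """Write intervals as BED; 6 columns when any interval is stranded or
    ``names`` is given, else 3."""
    six = names is not None or any(iv.strand != "." for iv in intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if six:
                name = names[i] if names is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fragments(path: str) -> list[GenomicInterval]:
    """Read a 3-column fragment BED (one fragment span per line)."""
    return read_bed(path, expected_columns=3)


def read_peak_calls(path: str, source_label: str) -> list[PeakCall]:
    """Read per-condition peak calls from BED (score from column 5 if present)."""
    calls: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, lineno, 3, path)
            iv = _parse_interval(fields, lineno, path, False)
            score = 0.0
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            calls.append(PeakCall(iv, score=score, source_label=source_label))
    return calls


def write_peak_calls(calls: list[PeakCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in calls:
            iv = c.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.source_label}\t{c.score:g}\t.\n")


def read_fasta(path: str, on_invalid: str = "error") -> dict[str, str]:
    """Read FASTA into ``{chrom: uppercase sequence}``.

    Characters outside A,C,G,T,N raise :class:`FormatError` by default;
    ``on_invalid='mask'`` replaces them with N.
    """
    if on_invalid not in ("error", "mask"):
        raise ValueError("on_invalid must be 'error' or 'mask'")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        name = rec.id
        if name in genome:
            raise FormatError(f"duplicate chromosome name {name!r} in {path}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            if on_invalid == "error":
                raise FormatError(
                    f"{path}: record {name!r} contains invalid characters "
                    f"{sorted(bad)}"
                )
            seq = "".join(b if b in VALID_BASES else "N" for b in seq)
        genome[name] = seq
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _pseudocount_normalize(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Counts (L,4) -> probabilities, adding ``pseudocount`` per cell first."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise FormatError("negative matrix cell")
    sums = counts.sum(axis=1)
    if np.any(sums == 0):
        raise FormatError("matrix column summing to 0")
    padded = counts + pseudocount
    return padded / padded.sum(axis=1, keepdims=True)


def _read_jaspar(path: str, pseudocount: float) -> list[PWM]:
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    base_order = "ACGT"

    def flush() -> None:
        if name is None:
            return
        missing = [b for b in base_order if b not in rows]
        if missing:
            raise FormatError(f"{path}: motif {name!r} missing rows {missing}")
        if len({len(rows[b]) for b in base_order}) != 1:
            raise FormatError(f"{path}: motif {name!r} has ragged rows")
        mat = np.array([rows[b] for b in base_order], dtype=float).T
        pwms.append(PWM(name, _pseudocount_normalize(mat, pseudocount),
                        pseudocount=pseudocount))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rows = {}
                name = line[1:].split()[0] if line[1:].split() else f"motif_{lineno}"
            else:
                parts = line.replace("[", " ").replace("]", " ").split()
                if not parts or parts[0] not in "ACGT":
                    raise FormatError(f"{path}:{lineno}: expected 'A [ counts ]' row")
                try:
                    rows[parts[0]] = [float(x) for x in parts[1:]]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
    flush()
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def _read_homer(path: str, pseudocount: float) -> list[PWM]:
    pwms: list[PWM] = []
    name = None
    threshold: float | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        if name is None:
            return
        if not rows:
            raise FormatError(f"{path}: motif {name!r} has no probability rows")
        mat = np.array(rows, dtype=float)
        if mat.shape[1] != 4:
            raise FormatError(f"{path}: motif {name!r} rows must have 4 columns")
        pwms.append(PWM(name, _pseudocount_normalize(mat, pseudocount),
                        pseudocount=pseudocount, file_threshold=threshold))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rows = []
                parts = line[1:].split()
                if len(parts) < 2:
                    raise FormatError(
                        f"{path}:{lineno}: HOMER header needs '>consensus name "
                        f"[threshold]'"
                    )
                name = parts[1]
                threshold = float(parts[2]) if len(parts) >= 3 else None
            else:
                try:
                    rows.append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
    flush()
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def read_pfm(path: str, dialect: str = "jaspar",
             pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Read motif matrices.

    ``jaspar``: count matrices as ``A [ 8 0 ... ]`` rows; ``homer``:
    ``>consensus name threshold`` headers followed by per-position
    probability rows. Both are pseudocounted per cell then renormalized
    column-wise.
    """
    if dialect == "jaspar":
        return _read_jaspar(path, pseudocount)
    if dialect == "homer":
        return _read_homer(path, pseudocount)
    raise ValueError(f"unknown PFM dialect {dialect!r}")


def write_pfm(pwms: list[PWM], path: str) -> None:
    """Write motifs in the JASPAR probability layout (A/C/G/T rows)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for b, base in enumerate("ACGT"):
                vals = " ".join(f"{x:.6f}" for x in pwm.probs[:, b])
                fh.write(f"{base} [ {vals} ]\n")


def _gene_from_bed6(fields: list[str], lineno: int, path: str) -> GeneRecord:
    iv = _parse_interval(fields, lineno, path, True)
    if iv.strand == ".":
        raise FormatError(f"{path}:{lineno}: gene record missing strand")
    tss = iv.start if iv.strand == "+" else iv.end - 1
    return GeneRecord(fields[3], iv.chrom, tss, iv.strand)


def _gene_from_gtf(fields: list[str], lineno: int, path: str) -> GeneRecord | None:
    if len(fields) < 9:
        raise FormatError(f"{path}:{lineno}: GTF line has fewer than 9 fields")
    if fields[2] != "gene":
        return None
    strand = fields[6]
    if strand not in ("+", "-"):
        raise FormatError(f"{path}:{lineno}: gene record missing strand")
    try:
        start1, end1 = int(fields[3]), int(fields[4])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
    # GTF is 1-based closed; internal frame is 0-based half-open.
    start0, end0 = start1 - 1, end1
    gene_id = None
    for attr in fields[8].split(";"):
        attr = attr.strip()
        if attr.startswith("gene_id"):
            gene_id = attr.split(None, 1)[1].strip().strip('"')
            break
    if not gene_id:
        raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
    tss = start0 if strand == "+" else end0 - 1
    return GeneRecord(gene_id, fields[0], tss, strand)


def read_gene_model(path: str, fmt: str = "auto") -> list[GeneRecord]:
    """Read a gene model from BED6 (start/end−1 is the TSS by strand) or a
    minimal GTF restricted to ``gene`` features."""
    if fmt == "auto":
        fmt = "gtf" if str(path).endswith((".gtf", ".gff")) else "bed6"
    if fmt not in ("bed6", "gtf"):
        raise ValueError(f"unknown gene model format {fmt!r}")
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if fmt == "bed6":
                if len(fields) < 6:
                    raise FormatError(
                        f"{path}:{lineno}: BED6 gene record needs 6 columns"
                    )
                genes.append(_gene_from_bed6(fields, lineno, path))
            else:
                rec = _gene_from_gtf(fields, lineno, path)
                if rec is not None:
                    genes.append(rec)
    if not genes:
        raise FormatError(f"{path}: no gene records found")
    return genes


def write_gene_model(genes: list[GeneRecord], path: str,
                     gene_length: int = 400) -> None:
    """Write genes as BED6, reconstructing a span from the TSS so that
    reading the file back recovers the same TSS and strand."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss, g.tss + gene_length
            else:
                start, end = max(0, g.tss + 1 - gene_length), g.tss + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gmt(path: str) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT-like TSV: term_id, description, then member genes."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT record needs term, description and "
                    f">= 1 gene"
                )
            term = fields[0]
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            terms[term] = (fields[1], frozenset(g for g in fields[2:] if g))
    if not terms:
        raise FormatError(f"{path}: no gene sets found")
    return terms
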