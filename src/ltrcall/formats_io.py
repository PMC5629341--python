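"""Shared genomic data structures and readers/writers for the standard formats.

Internal coordinates are 0-based half-open throughout the package. File I/O
speaks each format's native convention: SAM and GFF3 are 1-based inclusive,
BED/bedGraph are 0-based half-open. Interval length is ``end - start`` in
both systems.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"degenerate interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class GenomeAssembly:
    """Ordered map of chromosome name -> uppercase sequence string."""

    def __init__(self, sequences: dict[str, str]):
        clean: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for {name!r}")
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                raise FormatError(f"non-ACGTN characters in {name!r}")
            clean[name] = seq
        self._seqs = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self._seqs[iv.chrom]
        if iv.end > len(seq):
            raise ValueError(f"{iv} exceeds chromosome length {len(seq)}")
        return seq[iv.start : iv.end]

    def with_sequences(self, sequences: dict[str, str]) -> "GenomeAssembly":
        """New assembly with some chromosomes replaced."""
        merged = dict(self._seqs)
        merged.update(sequences)
        return GenomeAssembly(merged)


@dataclass
class AlignmentRecord:
    """One SAM alignment line, decoded.

    ``pos`` is 0-based leftmost mapped position. ``match_len`` plus the two
    soft-clip lengths equals the read length for mapped records.
    """

    qname: str
    mate: int  # 1 or 2
    mapped: bool
    chrom: str | None
    pos: int | None
    strand: str
    match_len: int
    clip_left: int
    clip_right: int
    mate_mapped: bool
    mate_chrom: str | None
    mate_pos: int | None
    seq: str
    unique: bool = True

    def __post_init__(self) -> None:
        if self.mapped:
            if self.chrom is None or self.pos is None:
                raise ValueError("mapped record without coordinates")
            if self.clip_left + self.match_len + self.clip_right != len(self.seq):
                raise ValueError(
                    f"CIGAR lengths {self.clip_left}+{self.match_len}+"
                    f"{self.clip_right} != read length {len(self.seq)} ({self.qname})"
                )
        elif self.chrom is not None or self.pos is not None:
            raise ValueError("unmapped record carries coordinates")

    @property
    def reference_end(self) -> int:
        return self.pos + self.match_len


@dataclass
class Gene:
    """A protein-coding gene with its exon/intron/UTR structure.

    ``exons`` are the coding exon intervals; ``introns`` are the gaps between
    consecutive exons and are derived, never read from file.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: GenomicInterval | None = None
    utr3: GenomicInterval | None = None

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.interval.chrom, a.end, b.start, self.strand))
        return out

    @property
    def tss(self) -> int:
        """Transcription-start position (strand-aware gene boundary)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class TEFeature:
    te_id: str
    interval: GenomicInterval
    family: str = "."


class AnnotationModel:
    """Gene and TE annotation with per-chromosome overlap indexes."""

    def __init__(self, genes: Iterable[Gene], te_features: Iterable[TEFeature] = ()):
        self.genes = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
        self.te_features = sorted(te_features, key=lambda t: (t.interval.chrom, t.interval.start))
        for g in self.genes:
            for child in [*g.exons, g.utr5, g.utr3]:
                if child is None:
                    continue
                if child.start < g.interval.start or child.end > g.interval.end:
                    raise FormatError(f"feature {child} outside gene {g.gene_id} span")
        self._gene_index: dict[str, IntervalTree] = {}
        self._te_index: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._gene_index.setdefault(g.interval.chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g
            )
        for t in self.te_features:
            self._te_index.setdefault(t.interval.chrom, IntervalTree()).addi(
                t.interval.start, t.interval.end, t
            )

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        tree = self._gene_index.get(chrom)
        return [iv.data for iv in tree[pos]] if tree is not None else []

    def genes_in(self, chrom: str, start: int, end: int) -> list[Gene]:
        tree = self._gene_index.get(chrom)
        return [iv.data for iv in tree[start:end]] if tree is not None else []

    def tes_at(self, chrom: str, pos: int) -> list[TEFeature]:
        tree = self._te_index.get(chrom)
        return [iv.data for iv in tree[pos]] if tree is not None else []

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.interval.chrom == chrom]


class TileTrack:
    """Fixed-width tile values per chromosome, contiguous from position 0."""

    def __init__(self, tile_width: int, values: dict[str, np.ndarray]):
        if tile_width <= 0:
            raise ValueError("tile width must be positive")
        self.tile_width = int(tile_width)
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values)

    def n_tiles(self, chrom: str) -> int:
        return len(self.values[chrom])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Load a FASTA file into a :class:`GenomeAssembly`.

    Raises :class:`FormatError` on duplicate record names, empty sequences,
    or an empty file.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeAssembly(seqs)


def write_fasta(assembly_or_seqs, path: str | Path, width: int = 80) -> None:
    items = assembly_or_seqs.items()
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# SAM


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read a text SAM file into :class:`AlignmentRecord` objects.

    Flags are decoded into mapped/strand/mate fields; 1-based positions are
    converted to 0-based. Uniqueness is taken from the ``NH`` tag when
    present, else a record is unique by default (single-best-alignment
    reporting).
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        refs = set(sam.references)
        for aln in sam:
            mapped = not aln.is_unmapped
            if mapped and aln.reference_name not in refs:
                raise FormatError(f"record {aln.query_name} on unknown reference")
            clip_left = clip_right = 0
            match_len = 0
            if mapped and aln.cigartuples:
                cig = aln.cigartuples
                if cig[0][0] == 4:
                    clip_left = cig[0][1]
                if len(cig) > 1 and cig[-1][0] == 4:
                    clip_right = cig[-1][1]
                match_len = sum(n for op, n in cig if op in (0, 7, 8))
            unique = True
            if aln.has_tag("NH"):
                unique = aln.get_tag("NH") == 1
            records.append(
                AlignmentRecord(
                    qname=aln.query_name,
                    mate=2 if aln.is_read2 else 1,
                    mapped=mapped,
                    chrom=aln.reference_name if mapped else None,
                    pos=aln.reference_start if mapped else None,
                    strand="-" if (mapped and aln.is_reverse) else "+",
                    match_len=match_len,
                    clip_left=clip_left,
                    clip_right=clip_right,
                    mate_mapped=not aln.mate_is_unmapped,
                    mate_chrom=aln.next_reference_name if not aln.mate_is_unmapped else None,
                    mate_pos=aln.next_reference_start if not aln.mate_is_unmapped else None,
                    seq=aln.query_sequence or "",
                    unique=unique,
                )
            )
    return records


def write_sam(records: Iterable[AlignmentRecord], path: str | Path, chrom_lengths: dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.query_sequence = rec.seq
            flag = 0x1  # paired
            flag |= 0x40 if rec.mate == 1 else 0x80
            if not rec.mapped:
                flag |= 0x4
            elif rec.strand == "-":
                flag |= 0x10
            if not rec.mate_mapped:
                flag |= 0x8
            a.flag = flag
            if rec.mapped:
                a.reference_name = rec.chrom
                a.reference_start = rec.pos
                a.mapping_quality = 42
                cigar = []
                if rec.clip_left:
                    cigar.append((4, rec.clip_left))
                cigar.append((0, rec.match_len))
                if rec.clip_right:
                    cigar.append((4, rec.clip_right))
                a.cigar = cigar
            if rec.mate_mapped and rec.mate_chrom is not None:
                a.next_reference_name = rec.mate_chrom
                a.next_reference_start = rec.mate_pos
            out.write(a)


def group_pairs(records: Iterable[AlignmentRecord]) -> dict[str, dict[int, list[AlignmentRecord]]]:
    """Group alignment records by read name, then mate index."""
    pairs: dict[str, dict[int, list[AlignmentRecord]]] = {}
    for rec in records:
        pairs.setdefault(rec.qname, {}).setdefault(rec.mate, []).append(rec)
    return pairs


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> AnnotationModel:
    """Parse a GFF3 annotation into an :class:`AnnotationModel`.

    Recognized feature types: ``gene``, ``exon``, ``five_prime_UTR``,
    ``three_prime_UTR`` (attached to genes via ``Parent``/``ID`` chains) and
    ``transposable_element``. GFF3 coordinates (1-based inclusive) are
    converted to internal 0-based half-open.
    """
    genes: dict[str, Gene] = {}
    parent_of: dict[str, str] = {}  # mRNA id -> gene id
    tes: list[TEFeature] = []
    pending: list[tuple[str, str, GenomicInterval]] = []  # (type, parent, iv)

    def get_attr(attrs: str, key: str) -> str | None:
        for part in attrs.strip().split(";"):
            if part.startswith(key + "="):
                return part[len(key) + 1 :]
        return None

    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = cols
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand if strand in STRANDS else ".")
            fid = get_attr(attrs, "ID")
            parent = get_attr(attrs, "Parent")
            if ftype == "gene":
                if fid is None:
                    raise FormatError("gene feature without ID")
                genes[fid] = Gene(gene_id=fid, interval=iv, strand=iv.strand)
            elif ftype == "mRNA":
                if fid and parent:
                    parent_of[fid] = parent
            elif ftype in ("exon", "five_prime_UTR", "three_prime_UTR"):
                if parent is None:
                    raise FormatError(f"{ftype} without Parent")
                pending.append((ftype, parent, iv))
            elif ftype in ("transposable_element", "transposon_fragment"):
                fam = get_attr(attrs, "family") or "."
                tes.append(TEFeature(te_id=fid or f"te{len(tes)}", interval=iv, family=fam))

    for ftype, parent, iv in pending:
        gene_id = parent_of.get(parent, parent)
        gene = genes.get(gene_id)
        if gene is None:
            raise FormatError(f"feature parent {parent!r} not found")
        if iv.start < gene.interval.start or iv.end > gene.interval.end:
            raise FormatError(f"{ftype} {iv} outside parent gene {gene_id}")
        if ftype == "exon":
            gene.exons.append(iv)
        elif ftype == "five_prime_UTR":
            gene.utr5 = iv
        else:
            gene.utr3 = iv
    for gene in genes.values():
        gene.exons.sort(key=lambda e: e.start)
    return AnnotationModel(genes.values(), tes)


def write_gff3(annotation: AnnotationModel, path: str | Path) -> None:
    def line(chrom, ftype, iv, strand, attrs):
        return f"{chrom}\t.\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            chrom = g.interval.chrom
            fh.write(line(chrom, "gene", g.interval, g.strand, f"ID={g.gene_id}"))
            mrna = f"{g.gene_id}.1"
            fh.write(line(chrom, "mRNA", g.interval, g.strand, f"ID={mrna};Parent={g.gene_id}"))
            if g.utr5 is not None:
                fh.write(line(chrom, "five_prime_UTR", g.utr5, g.strand, f"Parent={mrna}"))
            for i, ex in enumerate(g.exons, 1):
                fh.write(line(chrom, "exon", ex, g.strand, f"ID={mrna}.exon{i};Parent={mrna}"))
            if g.utr3 is not None:
                fh.write(line(chrom, "three_prime_UTR", g.utr3, g.strand, f"Parent={mrna}"))
        for t in annotation.te_features:
            fh.write(
                line(t.interval.chrom, "transposable_element", t.interval, t.interval.strand,
                     f"ID={t.te_id};family={t.family}")
            )


# ---------------------------------------------------------------------------
# bedGraph tiles


def read_bedgraph_tiles(
    path: str | Path, tile_width: int = 60, chrom_lengths: dict[str, int] | None = None
) -> TileTrack:
    """Read a bedGraph of fixed-width tiles into a :class:`TileTrack`.

    Every interval must start and end on multiples of ``tile_width`` (the
    final tile of a chromosome may be truncated by the chromosome end when
    ``chrom_lengths`` is given). Tiles absent from the file get value 0.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    max_tile: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            try:
                chrom, s, e, v = line.split()
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from exc
            end_ok = end % tile_width == 0 or (
                chrom_lengths is not None and end == chrom_lengths.get(chrom)
            )
            if start % tile_width != 0 or not end_ok:
                raise FormatError(
                    f"{path}:{lineno}: interval {start}-{end} not aligned to {tile_width}-bp tiles"
                )
            d = per_chrom.setdefault(chrom, {})
            for t in range(start // tile_width, -(-end // tile_width)):
                d[t] = value
            max_tile[chrom] = max(max_tile.get(chrom, 0), -(-end // tile_width))
    values: dict[str, np.ndarray] = {}
    for chrom, d in per_chrom.items():
        n = max_tile[chrom]
        if chrom_lengths is not None and chrom in chrom_lengths:
            n = max(n, -(-chrom_lengths[chrom] // tile_width))
        arr = np.zeros(n)
        for t, v in d.items():
            arr[t] = v
        values[chrom] = arr
    return TileTrack(tile_width, values)


def write_bedgraph(track: TileTrack, path: str | Path, chrom_lengths: dict[str, int] | None = None) -> None:
    w = track.tile_width
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            limit = chrom_lengths.get(chrom) if chrom_lengths else None
            for i, v in enumerate(vals):
                end = (i + 1) * w
                if limit is not None:
                    end = min(end, limit)
                fh.write(f"{chrom}\t{i * w}\t{end}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Insertion-call tables

CALL_COLUMNS = [
    "chrom", "start", "end", "orientation", "tsd_len", "tsd_seq",
    "n_discordant", "n_junction5", "n_junction3", "status",
]


def write_calls_tsv(calls, path: str | Path) -> None:
    rows = [
        {
            "chrom": c.chrom, "start": c.start, "end": c.end,
            "orientation": c.orientation, "tsd_len": c.tsd_len, "tsd_seq": c.tsd_seq or ".",
            "n_discordant": c.n_discordant, "n_junction5": c.n_junction5,
            "n_junction3": c.n_junction3, "status": c.status,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"insertion-call table missing columns: {sorted(missing)}")
    return df


def dataclass_fields(obj) -> dict:
    return dataclasses.asdict(obj)
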