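"""Readers and writers for the plain-text genomic formats the pipeline consumes.

All coordinates are 0-based half-open (BED convention) internally.  One-based
inputs (Bismark-style CpG coverage tables) are converted on read via an
explicit dialect flag.  CpG sites are represented strand-symmetrically by the
forward-strand position of the C in each CG dinucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import numpy as np

__all__ = [
    "GenomicInterval",
    "ReadAlignment",
    "GeneModel",
    "AnnotationTrack",
    "CpGRecord",
    "GeneSetCollection",
    "read_bed",
    "write_bed",
    "read_bed12",
    "write_bed12",
    "cpg_positions",
    "cpg_positions_from_sequences",
    "read_cpg_table",
    "write_cpg_table",
    "read_gmt",
    "write_gmt",
    "normalize_chrom",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open arithmetic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReadAlignment:
    """One uniquely mapped read (or fragment start) for one sample."""

    interval: GenomicInterval
    sample_id: str


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        prev_end = self.interval.start - 1
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError("exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene body {self.interval}")
            if ex.start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.interval.start if self.strand == "+" else self.interval.end


@dataclass
class AnnotationTrack:
    """A named set of intervals, e.g. a repeat class or chromatin-state track."""

    name: str
    intervals: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


@dataclass(frozen=True)
class CpGRecord:
    """Methylated/unmethylated read counts at one CpG for one sample."""

    chrom: str
    pos: int
    meth: int
    unmeth: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError(f"negative count at {self.chrom}:{self.pos}")

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth

    @property
    def level(self) -> float:
        """Methylation level meth/(meth+unmeth); NaN at zero coverage."""
        cov = self.coverage
        return self.meth / cov if cov > 0 else float("nan")


class GeneSetCollection:
    """Named gene sets over a declared gene universe.

    Every set is stored as its intersection-free membership; construction
    enforces set <= universe.
    """

    def __init__(self, sets: Mapping[str, Set[str]], universe: Optional[Set[str]] = None):
        self.sets: Dict[str, Set[str]] = {k: set(v) for k, v in sets.items()}
        if universe is None:
            universe = set().union(*self.sets.values()) if self.sets else set()
        self.universe: Set[str] = set(universe)
        for name, genes in self.sets.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"gene set {name!r} contains {len(extra)} genes outside the universe"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneSetCollection)
            and self.sets == other.sets
            and self.universe == other.universe
        )


def normalize_chrom(chrom: str, style: Optional[str] = None) -> str:
    """Normalize chromosome naming: style 'chr' adds the prefix, 'plain' strips it."""
    if style is None:
        return chrom
    if style == "chr":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    if style == "plain":
        return chrom[3:] if chrom.startswith("chr") else chrom
    raise ValueError(f"unknown chromosome-name style {style!r}")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(
    path: Union[str, Path], chrom_style: Optional[str] = None
) -> Union[List[GenomicInterval], List[ReadAlignment]]:
    """Read BED3/BED6 into sorted intervals.

    A 7th column, when present on every line, is interpreted as a sample id
    and the return value becomes a list of :class:`ReadAlignment`.
    """
    intervals: List[GenomicInterval] = []
    samples: List[Optional[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom = normalize_chrom(fields[0], chrom_style)
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else "."
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            samples.append(fields[6] if len(fields) >= 7 else None)
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
    intervals = [intervals[i] for i in order]
    samples = [samples[i] for i in order]
    if intervals and all(s is not None for s in samples):
        return [ReadAlignment(iv, s) for iv, s in zip(intervals, samples)]
    return intervals


def write_bed(
    path: Union[str, Path],
    records: Sequence[Union[GenomicInterval, ReadAlignment]],
    extra_columns: Optional[Sequence[Sequence]] = None,
) -> None:
    """Write intervals (or alignments, carrying the sample in column 7) as BED."""
    with open(path, "w") as fh:
        for i, rec in enumerate(records):
            if isinstance(rec, ReadAlignment):
                iv, sample = rec.interval, rec.sample_id
            else:
                iv, sample = rec, None
            cols = [iv.chrom, str(iv.start), str(iv.end), f"r{i}", "0", iv.strand]
            if sample is not None:
                cols.append(sample)
            if extra_columns is not None:
                cols.extend(str(c) for c in extra_columns[i])
            fh.write("\t".join(cols) + "\n")


def read_bed12(path: Union[str, Path], chrom_style: Optional[str] = None) -> List[GeneModel]:
    """Read gene models from BED12 (blocks are the exons)."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(f)}")
            try:
                chrom = normalize_chrom(f[0], chrom_style)
                start, end, name, strand = int(f[1]), int(f[2]), f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise ValueError("block count mismatch")
                exons = tuple(
                    GenomicInterval(chrom, start + s, start + s + sz, strand)
                    for s, sz in zip(starts, sizes)
                )
                genes.append(
                    GeneModel(name, GenomicInterval(chrom, start, end, strand), strand, exons)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def write_bed12(path: Union[str, Path], genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            sizes = ",".join(str(len(e)) for e in g.exons)
            starts = ",".join(str(e.start - iv.start) for e in g.exons)
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(iv.start),
                        str(iv.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Reference CpG index
# ---------------------------------------------------------------------------

def cpg_positions_from_sequences(sequences: Mapping[str, str]) -> Dict[str, np.ndarray]:
    """0-based forward-strand C positions of every CG dinucleotide, per chromosome."""
    out: Dict[str, np.ndarray] = {}
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        if arr.size < 2:
            out[chrom] = np.empty(0, dtype=np.int64)
            continue
        hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        out[chrom] = np.flatnonzero(hits).astype(np.int64)
    return out


def cpg_positions(fasta_path: Union[str, Path]) -> Dict[str, np.ndarray]:
    """Scan a FASTA file for CG dinucleotides (case-insensitive)."""
    from pyfaidx import Fasta

    try:
        fa = Fasta(str(fasta_path), rebuild=True, build_index=True)
    except Exception as exc:  # pragma: no cover - pyfaidx error classes vary
        raise ValueError(f"cannot read FASTA {fasta_path}: {exc}") from exc
    return cpg_positions_from_sequences({name: str(fa[name][:]) for name in fa.keys()})


# ---------------------------------------------------------------------------
# CpG count tables (Bismark-coverage-like TSV)
# ---------------------------------------------------------------------------

def read_cpg_table(
    path: Union[str, Path],
    one_based: bool = False,
    sample_id: str = "",
    chrom_style: Optional[str] = None,
) -> List[CpGRecord]:
    """Read a per-CpG count table: chrom, pos, meth, unmeth [, sample].

    ``one_based=True`` converts Bismark-style 1-based positions to the internal
    0-based convention.
    """
    records: List[CpGRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            try:
                chrom = normalize_chrom(f[0], chrom_style)
                pos = int(f[1]) - (1 if one_based else 0)
                meth, unmeth = int(f[2]), int(f[3])
                sid = f[4] if len(f) >= 5 else sample_id
                if pos < 0:
                    raise ValueError("negative position after dialect conversion")
                records.append(CpGRecord(chrom, pos, meth, unmeth, sid))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_cpg_table(
    path: Union[str, Path], records: Sequence[CpGRecord], one_based: bool = False
) -> None:
    with open(path, "w") as fh:
        for r in records:
            pos = r.pos + (1 if one_based else 0)
            cols = [r.chrom, str(pos), str(r.meth), str(r.unmeth)]
            if r.sample_id:
                cols.append(r.sample_id)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(
    path: Union[str, Path], universe: Optional[Iterable[str]] = None
) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, gene, gene, ...).

    The universe defaults to the union of all genes seen; pass an explicit
    universe (e.g. all annotated genes) for enrichment against a genome-wide
    background.
    """
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise ValueError(f"{path}:{lineno}: GMT requires name and description columns")
            name = f[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in f[2:] if g}
    uni = set(universe) if universe is not None else None
    if uni is not None:
        # genes outside a supplied universe cannot be scored; keep construction strict
        sets = {k: v & uni for k, v in sets.items()}
    return GeneSetCollection(sets, uni)


def write_gmt(path: Union[str, Path], collection: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, "na", *genes]) + "\n")
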