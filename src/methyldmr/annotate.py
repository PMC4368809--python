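"""Genomic-context classification and repeat/regulatory annotation of DMRs.

Each DMR gets exactly one location label with precedence
promoter > exonic > intronic > intergenic, where the promoter is the 2-kb
region immediately upstream of a transcription start site (strand-aware).
Repeat, chromatin-state, TFBS and motif tracks are overlapped at >= 1 bp, and
the hyper-vs-hypo enrichment of a track (e.g. SINE/Alu) is tested with
Fisher's exact test on the 2x2 direction-by-overlap table.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .genomic_io import AnnotationTrack, GeneModel, GenomicInterval
from .medip import DMR
from .wgbs import fisher_exact_2x2

__all__ = [
    "DMRAnnotation",
    "ContingencyTable2x2",
    "promoter_interval",
    "classify_location",
    "annotate_dmrs",
    "overlap_tracks",
    "direction_enrichment",
    "assign_genes",
    "intersect_gene_lists",
    "location_fractions",
]

LOCATIONS = ("promoter", "exonic", "intronic", "intergenic")


@dataclass
class DMRAnnotation:
    dmr: DMR
    location: str
    repeat_classes: Set[str] = field(default_factory=set)
    regulatory: Set[str] = field(default_factory=set)
    genes: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    rows: Tuple[str, str] = ("hyper", "hypo")
    cols: Tuple[str, str] = ("overlap", "no_overlap")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be >= 0")


class _IntervalIndex:
    """Per-chromosome sorted interval lookup for >=1-bp overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._starts: Dict[str, List[int]] = {}
        self._ivs: Dict[str, List[GenomicInterval]] = {}
        self._max_len: Dict[str, int] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda v: v.start)
            self._ivs[chrom] = ivs
            self._starts[chrom] = [v.start for v in ivs]
            self._max_len[chrom] = max(len(v) for v in ivs)

    def overlapping(self, query: GenomicInterval) -> List[GenomicInterval]:
        ivs = self._ivs.get(query.chrom)
        if not ivs:
            return []
        starts = self._starts[query.chrom]
        lo = bisect_left(starts, query.start - self._max_len[query.chrom])
        hi = bisect_right(starts, query.end - 1)
        return [iv for iv in ivs[lo:hi] if iv.start < query.end and query.start < iv.end]

    def any_overlap(self, query: GenomicInterval) -> bool:
        return bool(self.overlapping(query))


def promoter_interval(gene: GeneModel, promoter_bp: int = 2000) -> Optional[GenomicInterval]:
    """The ``promoter_bp`` region immediately upstream of the TSS, by strand."""
    iv = gene.interval
    if gene.strand == "+":
        start, end = max(iv.start - promoter_bp, 0), iv.start
    else:
        start, end = iv.end, iv.end + promoter_bp
    return GenomicInterval(iv.chrom, start, end, gene.strand) if start < end else None


def classify_location(
    dmr_interval: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_bp: int = 2000,
) -> str:
    """Single location label with precedence promoter > exonic > intronic > intergenic."""
    in_promoter = in_exon = in_body = False
    for g in genes:
        if g.interval.chrom != dmr_interval.chrom:
            continue
        prom = promoter_interval(g, promoter_bp)
        if prom is not None and prom.overlaps(dmr_interval):
            in_promoter = True
        if g.interval.overlaps(dmr_interval):
            in_body = True
            if any(ex.overlaps(dmr_interval) for ex in g.exons):
                in_exon = True
    if in_promoter:
        return "promoter"
    if in_exon:
        return "exonic"
    if in_body:
        return "intronic"
    return "intergenic"


_REPEAT_PREFIXES = ("SINE", "LINE", "LTR", "DNA", "Satellite")


def overlap_tracks(
    dmrs: Sequence[DMR], tracks: Mapping[str, AnnotationTrack]
) -> Tuple[List[Set[str]], Dict[str, float]]:
    """Per-DMR overlapping track names (>= 1 bp) and per-track DMR fractions."""
    indexes = {
        name: _IntervalIndex(track.intervals) for name, track in tracks.items() if track.intervals
    }
    per_dmr: List[Set[str]] = []
    for d in dmrs:
        hits = {name for name, idx in indexes.items() if idx.any_overlap(d.interval)}
        per_dmr.append(hits)
    fractions = {
        name: (sum(1 for hits in per_dmr if name in hits) / len(dmrs) if dmrs else 0.0)
        for name in tracks
    }
    return per_dmr, fractions


def annotate_dmrs(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    tracks: Optional[Mapping[str, AnnotationTrack]] = None,
    promoter_bp: int = 2000,
) -> List[DMRAnnotation]:
    """Full annotation: location label, track overlaps, and overlapping genes."""
    tracks = tracks or {}
    per_dmr_hits, _ = overlap_tracks(dmrs, tracks)
    gene_map = assign_genes(dmrs, genes, promoter_bp)
    dmr_genes: List[Set[str]] = [set() for _ in dmrs]
    for gene_id, (dmr_idx, _dirs) in gene_map.items():
        for i in dmr_idx:
            dmr_genes[i].add(gene_id)
    out: List[DMRAnnotation] = []
    for i, d in enumerate(dmrs):
        hits = per_dmr_hits[i]
        out.append(
            DMRAnnotation(
                dmr=d,
                location=classify_location(d.interval, genes, promoter_bp),
                repeat_classes={h for h in hits if h.split("/")[0] in _REPEAT_PREFIXES},
                regulatory={h for h in hits if h.split("/")[0] not in _REPEAT_PREFIXES},
                genes=dmr_genes[i],
            )
        )
    return out


def location_fractions(annotations: Sequence[DMRAnnotation]) -> Dict[str, float]:
    """Fractions of DMRs per location label; they partition the set (sum = 1)."""
    if not annotations:
        raise ValueError("no annotations")
    n = len(annotations)
    return {loc: sum(1 for a in annotations if a.location == loc) / n for loc in LOCATIONS}


def direction_enrichment(
    annotations: Sequence[DMRAnnotation], track_name: str
) -> Tuple[ContingencyTable2x2, float, float]:
    """Hyper-vs-hypo overlap enrichment for one track (Fisher's exact test).

    Table rows are hyper/hypo DMRs, columns overlap/no-overlap with the track;
    returns (table, sample odds ratio, two-sided p).
    """
    hyper = [a for a in annotations if a.dmr.direction == "hyper"]
    hypo = [a for a in annotations if a.dmr.direction == "hypo"]
    if not hyper or not hypo:
        raise ValueError("need at least one hyper and one hypo DMR")

    def _hit(a: DMRAnnotation) -> bool:
        return track_name in a.repeat_classes or track_name in a.regulatory

    a = sum(1 for x in hyper if _hit(x))
    b = len(hyper) - a
    c = sum(1 for x in hypo if _hit(x))
    d = len(hypo) - c
    p, odds = fisher_exact_2x2(a, b, c, d)
    return ContingencyTable2x2(a, b, c, d), odds, p


def assign_genes(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    promoter_bp: int = 2000,
) -> Dict[str, Tuple[List[int], Set[str]]]:
    """Assign every DMR to each gene whose body or promoter it overlaps.

    Returns gene_id -> (list of DMR indices, set of direction labels); a gene
    overlapping both hyper and hypo DMRs carries both labels.
    """
    out: Dict[str, Tuple[List[int], Set[str]]] = {}
    for g in genes:
        prom = promoter_interval(g, promoter_bp)
        hit_idx: List[int] = []
        dirs: Set[str] = set()
        for i, d in enumerate(dmrs):
            if g.interval.overlaps(d.interval) or (prom is not None and prom.overlaps(d.interval)):
                hit_idx.append(i)
                dirs.add(d.direction)
        if hit_idx:
            out[g.gene_id] = (hit_idx, dirs)
    return out


def intersect_gene_lists(list_1: Iterable[str], list_2: Iterable[str]) -> Set[str]:
    """Genes present in both lists."""
    return set(list_1) & set(list_2)
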