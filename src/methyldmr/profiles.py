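"""Metagene methylation profiles and sequencing QC.

The metagene profile averages relative methylation (extended-fragment depth
density) over genes rescaled to a common coordinate: 20 upstream windows,
40 gene-body windows, 20 downstream windows, oriented 5'->3' so minus-strand
genes are reversed.  QC covers reference CpG coverage by extended fragments
and a saturation curve (window-profile correlation under read subsampling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genomic_io import GeneModel, GenomicInterval

__all__ = [
    "MetageneProfile",
    "SaturationCurve",
    "metagene_profile",
    "cpg_coverage",
    "saturation",
]

N_FLANK_WINDOWS = 20
N_BODY_WINDOWS = 40


@dataclass
class MetageneProfile:
    """Mean relative methylation per metagene window (5'->3')."""

    sample_id: str
    upstream: np.ndarray   # N_FLANK_WINDOWS values
    body: np.ndarray       # N_BODY_WINDOWS values
    downstream: np.ndarray  # N_FLANK_WINDOWS values

    def __post_init__(self) -> None:
        self.upstream = np.asarray(self.upstream, dtype=float)
        self.body = np.asarray(self.body, dtype=float)
        self.downstream = np.asarray(self.downstream, dtype=float)
        if (
            self.upstream.size != N_FLANK_WINDOWS
            or self.body.size != N_BODY_WINDOWS
            or self.downstream.size != N_FLANK_WINDOWS
        ):
            raise ValueError("profile must have 20/40/20 windows")
        if (self.values < 0).any():
            raise ValueError("profile values must be >= 0")

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


@dataclass
class SaturationCurve:
    fractions: np.ndarray
    correlations: np.ndarray


def _sorted_bounds(fragments: Sequence[GenomicInterval]) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(pairs, dtype=np.int64)
        out[chrom] = (np.sort(arr[:, 0]), np.sort(arr[:, 1]))
    return out


def _counts_in_windows(
    bounds: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    chrom: str,
    edges: np.ndarray,
) -> np.ndarray:
    """Fragments overlapping each [edges[i], edges[i+1]) window (>= 1 bp)."""
    if chrom not in bounds:
        return np.zeros(edges.size - 1, dtype=np.int64)
    starts, ends = bounds[chrom]
    n_start_before = np.searchsorted(starts, edges[1:], side="left")
    n_end_at_or_before = np.searchsorted(ends, edges[:-1], side="right")
    return n_start_before - n_end_at_or_before


def _window_edges(start: int, end: int, n: int) -> np.ndarray:
    """n near-equal integer windows over [start, end); remainder goes last."""
    width = (end - start) // n
    edges = start + width * np.arange(n + 1, dtype=np.int64)
    edges[-1] = end
    return edges


def metagene_profile(
    extended_fragments: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
    sample_id: str = "",
) -> MetageneProfile:
    """Average depth-density profile over genes in metagene coordinates.

    Per gene, the body is split into 40 equal windows and each flank of
    ``flank_bp`` into 20; a window's value is the count of overlapping
    fragments divided by (window length x library size), and the profile
    averages over genes with minus-strand genes reversed so the axis runs
    5'->3'.
    """
    if not genes:
        raise ValueError("no genes supplied")
    for g in genes:
        if len(g.interval) < N_BODY_WINDOWS:
            raise ValueError(f"gene {g.gene_id} shorter than {N_BODY_WINDOWS} bp")
    library_size = len(extended_fragments)
    bounds = _sorted_bounds(extended_fragments)
    total = np.zeros(2 * N_FLANK_WINDOWS + N_BODY_WINDOWS)
    for g in genes:
        iv = g.interval
        left_edges = _window_edges(max(iv.start - flank_bp, 0), iv.start, N_FLANK_WINDOWS)
        body_edges = _window_edges(iv.start, iv.end, N_BODY_WINDOWS)
        right_edges = _window_edges(iv.end, iv.end + flank_bp, N_FLANK_WINDOWS)
        vals = []
        for edges in (left_edges, body_edges, right_edges):
            counts = _counts_in_windows(bounds, iv.chrom, edges)
            lengths = np.diff(edges)
            with np.errstate(divide="ignore", invalid="ignore"):
                dens = np.where(
                    lengths > 0,
                    counts / (np.maximum(lengths, 1) * max(library_size, 1)),
                    0.0,
                )
            vals.append(dens)
        row = np.concatenate(vals)
        if g.strand == "-":
            row = row[::-1]
        total += row
    mean = total / len(genes)
    return MetageneProfile(
        sample_id,
        mean[:N_FLANK_WINDOWS],
        mean[N_FLANK_WINDOWS : N_FLANK_WINDOWS + N_BODY_WINDOWS],
        mean[N_FLANK_WINDOWS + N_BODY_WINDOWS :],
    )


def cpg_coverage(
    extended_fragments: Sequence[GenomicInterval],
    cpg_map: Mapping[str, np.ndarray],
) -> float:
    """Fraction of reference CpG sites overlapped by >= 1 extended fragment."""
    n_total = sum(len(p) for p in cpg_map.values())
    if n_total == 0:
        raise ValueError("empty CpG map")
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for f in extended_fragments:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    covered = 0
    for chrom, pairs in by_chrom.items():
        pos = cpg_map.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        pairs.sort()
        # merge fragments, then count CpG positions inside merged intervals
        merged: List[Tuple[int, int]] = []
        for s, e in pairs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            covered += int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
    return covered / n_total


def _flat_window_counts(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int,
    subset: Optional[np.ndarray] = None,
) -> np.ndarray:
    n_per_chrom = {c: -(-chrom_sizes[c] // window) for c in chrom_sizes}
    offsets: Dict[str, int] = {}
    total = 0
    for c in chrom_sizes:
        offsets[c] = total
        total += n_per_chrom[c]
    diff = np.zeros(total + 1, dtype=np.int64)
    indices = range(len(fragments)) if subset is None else subset
    for i in indices:
        f = fragments[i]
        size = chrom_sizes[f.chrom]
        first = offsets[f.chrom] + max(f.start, 0) // window
        last = offsets[f.chrom] + (min(f.end, size) - 1) // window
        diff[first] += 1
        diff[last + 1] -= 1
    return np.cumsum(diff[:-1])


def saturation(
    extended_fragments: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    window: int = 200,
    fractions: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
) -> SaturationCurve:
    """Window-profile reproducibility under read subsampling.

    At each fraction, fragments are subsampled without replacement (seeded)
    and the Pearson correlation of the window count vector against the
    full-data vector is recorded; the fraction-1 point is exactly 1.
    """
    if not extended_fragments:
        raise ValueError("need at least one fragment")
    if fractions is None:
        fractions = np.round(np.arange(0.1, 1.01, 0.1), 10)
    fractions = np.asarray(sorted(fractions), dtype=float)
    if (fractions <= 0).any() or (fractions > 1).any():
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    full = _flat_window_counts(extended_fragments, chrom_sizes, window)
    n = len(extended_fragments)
    corrs = np.empty(fractions.size)
    for i, frac in enumerate(fractions):
        k = max(1, int(round(frac * n)))
        if k >= n:
            corrs[i] = 1.0
            continue
        subset = rng.choice(n, size=k, replace=False)
        sub = _flat_window_counts(extended_fragments, chrom_sizes, window, subset)
        with np.errstate(invalid="ignore"):
            corrs[i] = float(np.corrcoef(full, sub)[0, 1])
    return SaturationCurve(fractions, corrs)
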