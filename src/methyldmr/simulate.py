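"""Synthetic methylomes with planted differentially methylated regions.

Generates a toy genome, two-group MeDIP-style read alignments, two-sample
WGBS-style per-CpG count tables, and gene/repeat/regulatory annotation, all
with known ground truth so every downstream stage of the pipeline can be
scored against planted signal.

Design of the MeDIP generator
-----------------------------
Window read counts are negative-binomially distributed (variance m + phi*m^2)
around a per-window mean of ``mean_depth`` read anchors per 200-bp window.
Because the caller extends every read to a 400-bp fragment, a read anchored
in one window contributes counts to the two windows downstream of it as well;
uniformly placed background reads therefore produce a *uniform* extended
background.  Differential signal is planted as extra reads whose 400-bp
extension lies entirely inside the planted region (which must therefore be at
least 400 bp wide): hypermethylation adds reads to the centenarian-like group
C, hypomethylation adds the same excess to the control group Y.  Either way
the group ratio of extended window counts inside a planted region equals the
configured fold change while windows outside remain at background, which
keeps window-level truth sharp for recall/precision scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genomic_io import (
    AnnotationTrack,
    CpGRecord,
    GeneModel,
    GeneSetCollection,
    GenomicInterval,
    ReadAlignment,
    cpg_positions_from_sequences,
)

__all__ = [
    "SimulationConfig",
    "PlantedDMR",
    "Genome",
    "simulate_genome",
    "plant_dmrs",
    "simulate_medip",
    "simulate_wgbs",
    "simulate_annotation",
    "AnnotationBundle",
]

READ_LENGTH = 49
WINDOW = 200
FRAGMENT_LENGTH = 400

# distinct substreams per generator so each is independently reproducible
_SALT_GENOME, _SALT_MEDIP, _SALT_WGBS, _SALT_ANNOT = 11, 13, 17, 19


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic methylomes.

    Defaults emulate the two-group MeDIP design (4 centenarians vs 4
    middle-aged controls) and the two-individual WGBS comparison.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_samples_per_group: int = 4
    mean_depth: float = 15.0          # read anchors per 200-bp window per sample
    nb_dispersion: float = 0.1        # phi in var = m + phi m^2
    n_dmrs: int = 50
    dmr_width: int = 600              # bp, multiple of 200
    dmr_fold_change: float = 3.0
    wgbs_depth: float = 20.0          # mean per-CpG coverage
    wgbs_delta: float = 0.4           # planted methylation difference
    cpg_rate: float = 0.02            # probability a position starts a CpG
    n_genes: int = 100
    n_repeats: int = 400
    n_regulatory: int = 80
    n_gene_sets: int = 10
    gene_set_size: int = 20
    spike_fraction: float = 0.5       # fraction of the spiked set drawn from DMR genes

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_length < WINDOW:
            raise ValueError("need at least one chromosome of >= one window")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        if self.mean_depth < 0 or self.wgbs_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_dmrs < 0 or self.n_genes < 0 or self.n_repeats < 0:
            raise ValueError("counts must be >= 0")
        if self.dmr_width % WINDOW != 0 or self.dmr_width < WINDOW:
            raise ValueError(f"dmr_width must be a positive multiple of {WINDOW}")
        if self.dmr_fold_change < 1:
            raise ValueError("dmr_fold_change must be >= 1 (1 = null, no planted signal)")
        if not (0 <= self.wgbs_delta <= 1):
            raise ValueError("wgbs_delta must be in [0, 1] (0 = null)")
        if not (0 <= self.cpg_rate <= 0.5):
            raise ValueError("cpg_rate must be in [0, 0.5]")
        if not (0 <= self.spike_fraction <= 1):
            raise ValueError("spike_fraction must be in [0, 1]")

    @property
    def sample_ids(self) -> List[str]:
        n = self.n_samples_per_group
        return [f"C{i+1}" for i in range(n)] + [f"Y{i+1}" for i in range(n)]

    @property
    def group_labels(self) -> Dict[str, str]:
        return {s: s[0] for s in self.sample_ids}


@dataclass(frozen=True)
class PlantedDMR:
    """Ground-truth differential region; direction is for group C relative to Y."""

    interval: GenomicInterval
    direction: str  # "hyper" | "hypo"

    def __post_init__(self) -> None:
        if self.direction not in {"hyper", "hypo"}:
            raise ValueError("direction must be 'hyper' or 'hypo'")


@dataclass
class Genome:
    sequences: Dict[str, str]
    cpg_map: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cpg_map:
            self.cpg_map = cpg_positions_from_sequences(self.sequences)

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def simulate_genome(config: SimulationConfig) -> Genome:
    """Random genome whose only CG dinucleotides are injected at ``cpg_rate``.

    The background sequence is sampled uniformly from A/C/G/T and scrubbed of
    accidental CG pairs, then CpG sites are planted independently per position,
    so the CpG count per chromosome is (near-)Binomial(length, cpg_rate).
    """
    rng = _rng(config, _SALT_GENOME)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    sequences: Dict[str, str] = {}
    for ci in range(config.n_chroms):
        L = config.chrom_length
        arr = bases[rng.integers(0, 4, size=L)].copy()
        # scrub accidental CG: C followed by G -> G becomes A (cannot create a new CG)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        arr[cg + 1] = ord("A")
        if config.cpg_rate > 0 and L >= 2:
            picks = np.flatnonzero(rng.random(L - 1) < config.cpg_rate)
            if picks.size:
                # drop picks adjacent to an accepted pick (CG occupies 2 bp)
                keep = [picks[0]]
                for p in picks[1:]:
                    if p > keep[-1] + 1:
                        keep.append(p)
                sites = np.asarray(keep)
                arr[sites] = ord("C")
                arr[sites + 1] = ord("G")
        sequences[f"chr{ci + 1}"] = arr.tobytes().decode("ascii")
    return Genome(sequences)


def plant_dmrs(
    genome: Genome,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    min_cpgs: int = 1,
    max_cpg_gap: Optional[int] = None,
) -> List[PlantedDMR]:
    """Choose non-overlapping 200-bp-aligned regions hosting planted signal.

    Regions are kept >= 2 windows apart and away from chromosome ends, must
    contain at least ``min_cpgs`` CpG sites and, when ``max_cpg_gap`` is given,
    no internal CpG spacing at or above that many bp.
    """
    if rng is None:
        rng = _rng(config, _SALT_MEDIP)
    k = config.dmr_width // WINDOW
    margin = 3  # windows kept clear at each chromosome end
    candidates: List[Tuple[str, int]] = []
    for chrom, size in genome.chrom_sizes.items():
        n_w = size // WINDOW
        for wi in range(margin, n_w - k - margin):
            candidates.append((chrom, wi))
    order = rng.permutation(len(candidates))
    taken: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome.chrom_sizes}
    chosen: List[GenomicInterval] = []
    for idx in order:
        if len(chosen) >= config.n_dmrs:
            break
        chrom, wi = candidates[idx]
        lo, hi = wi, wi + k
        # require a >= 2-window gap to every already-placed region
        if any(not (hi + 2 <= a or b + 2 <= lo) for a, b in taken[chrom]):
            continue
        start, end = lo * WINDOW, hi * WINDOW
        pos = genome.cpg_map.get(chrom, np.empty(0, dtype=np.int64))
        inside = pos[(pos >= start) & (pos < end)]
        if inside.size < min_cpgs:
            continue
        if max_cpg_gap is not None and inside.size >= 2:
            if np.max(np.diff(inside)) >= max_cpg_gap:
                continue
        taken[chrom].append((lo, hi))
        chosen.append(GenomicInterval(chrom, start, end))
    if len(chosen) < config.n_dmrs:
        raise ValueError(
            f"could only place {len(chosen)} of {config.n_dmrs} non-overlapping "
            f"regions with >= {min_cpgs} CpGs; shrink n_dmrs or enlarge the genome"
        )
    chosen.sort(key=lambda iv: (iv.chrom, iv.start))
    directions = np.where(rng.random(len(chosen)) < 0.5, "hyper", "hypo")
    return [PlantedDMR(iv, d) for iv, d in zip(chosen, directions)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) counts via the gamma-Poisson mixture; Poisson when phi = 0."""
    mean = np.asarray(mean, dtype=float)
    if phi > 0:
        lam = mean * rng.gamma(shape=1.0 / phi, scale=phi, size=mean.shape)
    else:
        lam = mean
    return rng.poisson(lam)


def simulate_medip(
    config: SimulationConfig,
    genome: Genome,
    planted: Optional[Sequence[PlantedDMR]] = None,
) -> Tuple[Dict[str, List[ReadAlignment]], List[PlantedDMR]]:
    """Two-group MeDIP-style 49-bp read alignments with planted fold-change DMRs.

    Background reads: per window per sample, NB(mean_depth, nb_dispersion)
    anchors placed uniformly inside the window on the forward strand.  Planted
    signal: extra reads whose 400-bp extension fits inside the planted region,
    added to group C for hyper regions and to group Y for hypo regions, sized
    so the extended-count ratio equals ``dmr_fold_change``.
    """
    rng = _rng(config, _SALT_MEDIP)
    if planted is None:
        planted = plant_dmrs(genome, config, rng, min_cpgs=1)
    else:
        planted = list(planted)
        for a, b in zip(planted, planted[1:]):
            if a.interval.overlaps(b.interval):
                raise ValueError("planted DMRs must be non-overlapping")
    if config.dmr_width < FRAGMENT_LENGTH and planted:
        raise ValueError(
            f"dmr_width must be >= {FRAGMENT_LENGTH} bp so planted fragments "
            "can be confined to the region"
        )
    phi = config.nb_dispersion
    m = config.mean_depth
    # expected extended-fragment count per window contributed by uniform anchors:
    # a 400-bp fragment anchored in a window covers it, the next, and (w.p.
    # ~1 - 1/152) the one after that.
    span = FRAGMENT_LENGTH // WINDOW
    n_offsets = WINDOW - READ_LENGTH + 1
    kappa = span + (n_offsets - 1) / n_offsets
    excess = (config.dmr_fold_change - 1.0) * kappa * m  # extra reads per DMR per sample

    by_dmr: Dict[str, List[PlantedDMR]] = {}
    for d in planted:
        by_dmr.setdefault(d.interval.chrom, []).append(d)

    reads: Dict[str, List[ReadAlignment]] = {}
    for sample in config.sample_ids:
        group = config.group_labels[sample]
        parts: List[ReadAlignment] = []
        for chrom, size in genome.chrom_sizes.items():
            n_w = size // WINDOW  # trailing partial window gets no reads
            counts = _nb_counts(rng, np.full(n_w, m), phi)
            starts = np.repeat(np.arange(n_w) * WINDOW, counts)
            offsets = rng.integers(0, n_offsets, size=starts.size)
            anchors = starts + offsets
            parts.extend(
                ReadAlignment(GenomicInterval(chrom, int(a), int(a) + READ_LENGTH, "+"), sample)
                for a in anchors
            )
            for d in by_dmr.get(chrom, []):
                elevated = "C" if d.direction == "hyper" else "Y"
                if group != elevated:
                    continue
                n_extra = int(_nb_counts(rng, np.array([excess]), phi)[0])
                if n_extra == 0:
                    continue
                lo = d.interval.start
                hi = d.interval.end - FRAGMENT_LENGTH
                pos = rng.integers(lo, hi + 1, size=n_extra)
                parts.extend(
                    ReadAlignment(GenomicInterval(chrom, int(p), int(p) + READ_LENGTH, "+"), sample)
                    for p in pos
                )
        parts.sort(key=lambda r: (r.interval.chrom, r.interval.start))
        reads[sample] = parts
    return reads, list(planted)


def simulate_wgbs(
    config: SimulationConfig,
    genome: Genome,
    planted: Optional[Sequence[PlantedDMR]] = None,
) -> Tuple[List[CpGRecord], List[CpGRecord], List[PlantedDMR]]:
    """Two-sample bisulfite-style per-CpG count tables with planted delta DMRs.

    Per CpG, a baseline methylation level is drawn Beta(7, 3); coverage is
    Poisson(wgbs_depth) and methylated counts Binomial(coverage, pi).  Inside a
    hyper region the control-like sample is shifted down by ``wgbs_delta``
    (and inside a hypo region the centenarian-like sample is), so the
    centenarian-minus-control difference is +delta / -delta respectively while
    levels stay inside [0, 1] for the high Beta(7,3) baseline.
    """
    rng = _rng(config, _SALT_WGBS)
    if planted is None:
        planted = plant_dmrs(config=config, genome=genome, rng=rng, min_cpgs=5, max_cpg_gap=1000)
    records_a: List[CpGRecord] = []
    records_b: List[CpGRecord] = []
    for chrom, pos in genome.cpg_map.items():
        if pos.size == 0:
            continue
        base = rng.beta(7.0, 3.0, size=pos.size)
        pi_a = base.copy()  # centenarian-like
        pi_b = base.copy()  # control-like
        for d in planted:
            if d.interval.chrom != chrom:
                continue
            mask = (pos >= d.interval.start) & (pos < d.interval.end)
            if d.direction == "hyper":
                pi_b[mask] = base[mask] - config.wgbs_delta
            else:
                pi_a[mask] = base[mask] - config.wgbs_delta
        pi_a = np.clip(pi_a, 0.0, 1.0)
        pi_b = np.clip(pi_b, 0.0, 1.0)
        cov_a = rng.poisson(config.wgbs_depth, size=pos.size)
        cov_b = rng.poisson(config.wgbs_depth, size=pos.size)
        meth_a = rng.binomial(cov_a, pi_a)
        meth_b = rng.binomial(cov_b, pi_b)
        for i, p in enumerate(pos):
            records_a.append(
                CpGRecord(chrom, int(p), int(meth_a[i]), int(cov_a[i] - meth_a[i]), "centenarian")
            )
            records_b.append(
                CpGRecord(chrom, int(p), int(meth_b[i]), int(cov_b[i] - meth_b[i]), "control")
            )
    return records_a, records_b, list(planted)


@dataclass
class AnnotationBundle:
    genes: List[GeneModel]
    tracks: Dict[str, AnnotationTrack]
    gene_sets: GeneSetCollection
    spiked_set: Optional[str] = None


_REPEAT_CLASSES = ["SINE/Alu", "LINE/L1", "LINE/L2", "LTR"]
_REPEAT_WEIGHTS = [0.35, 0.30, 0.10, 0.25]


def simulate_annotation(
    config: SimulationConfig,
    genome: Genome,
    planted_dmrs: Optional[Sequence[PlantedDMR]] = None,
) -> AnnotationBundle:
    """Gene models, repeat/regulatory tracks, and gene sets over the gene universe.

    When planted DMRs are supplied and ``spike_fraction`` > 0, the first gene
    set draws that fraction of its members from genes overlapping a planted
    DMR (body or 2-kb promoter), creating a true enrichment signal.
    """
    rng = _rng(config, _SALT_ANNOT)
    genes: List[GeneModel] = []
    gid = 0
    min_gap = 2100  # leaves room for a 2-kb promoter between neighbours
    for chrom, size in genome.chrom_sizes.items():
        cursor = min_gap
        while gid < config.n_genes and cursor + 8000 + min_gap < size:
            cursor += int(rng.integers(0, 2000))
            length = int(rng.integers(2000, 6001))
            if cursor + length + min_gap >= size:
                break
            start, end = cursor, cursor + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 5))
            block = length // n_ex
            exons = tuple(
                GenomicInterval(chrom, start + i * block, start + i * block + max(block * 2 // 5, 20), strand)
                for i in range(n_ex)
            )
            genes.append(GeneModel(f"G{gid:04d}", GenomicInterval(chrom, start, end, strand), strand, exons))
            gid += 1
            cursor = end + min_gap
        if gid >= config.n_genes:
            break
    if config.n_genes > 0 and gid < config.n_genes:
        raise ValueError(f"genome too small to place {config.n_genes} genes (placed {gid})")

    tracks: Dict[str, AnnotationTrack] = {name: AnnotationTrack(name, []) for name in _REPEAT_CLASSES}
    tracks["chromatin"] = AnnotationTrack("chromatin", [])
    tracks["TFBS"] = AnnotationTrack("TFBS", [])
    tracks["motif"] = AnnotationTrack("motif", [])
    chroms = list(genome.chrom_sizes)
    cls_idx = rng.choice(len(_REPEAT_CLASSES), size=config.n_repeats, p=_REPEAT_WEIGHTS)
    for i in range(config.n_repeats):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(150, 500))
        start = int(rng.integers(0, max(genome.chrom_sizes[chrom] - length, 1)))
        tracks[_REPEAT_CLASSES[cls_idx[i]]].intervals.append(
            GenomicInterval(chrom, start, start + length)
        )
    for name in ("chromatin", "TFBS", "motif"):
        for _ in range(config.n_regulatory):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(200, 1200))
            start = int(rng.integers(0, max(genome.chrom_sizes[chrom] - length, 1)))
            tracks[name].intervals.append(GenomicInterval(chrom, start, start + length))
    for tr in tracks.values():
        tr.intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    universe = sorted(g.gene_id for g in genes)
    dmr_genes: List[str] = []
    if planted_dmrs:
        for g in genes:
            iv = g.interval
            if g.strand == "+":
                prom = GenomicInterval(iv.chrom, max(iv.start - 2000, 0), iv.start) if iv.start > 0 else None
            else:
                prom = GenomicInterval(iv.chrom, iv.end, iv.end + 2000)
            for d in planted_dmrs:
                if d.interval.overlaps(iv) or (prom is not None and d.interval.overlaps(prom)):
                    dmr_genes.append(g.gene_id)
                    break
    sets: Dict[str, set] = {}
    spiked_name: Optional[str] = None
    size = min(config.gene_set_size, len(universe))
    for si in range(config.n_gene_sets):
        name = f"set{si:02d}"
        if si == 0 and config.spike_fraction > 0 and dmr_genes:
            n_spike = min(int(round(config.spike_fraction * size)), len(dmr_genes))
            spike = list(rng.choice(dmr_genes, size=n_spike, replace=False))
            rest_pool = [g for g in universe if g not in set(spike)]
            rest = list(rng.choice(rest_pool, size=size - n_spike, replace=False))
            sets[name] = set(spike) | set(rest)
            spiked_name = name
        else:
            sets[name] = set(rng.choice(universe, size=size, replace=False)) if universe else set()
    collection = GeneSetCollection(sets, set(universe))
    return AnnotationBundle(genes, tracks, collection, spiked_name)
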