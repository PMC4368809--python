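"""MeDIP-seq window-based differential methylation calling.

The pipeline: extend uniquely mapped reads to the immunoprecipitated fragment
length (400 bp), tile the genome into non-overlapping 200-bp windows, count
extended fragments per window per sample, keep windows covered in every
sample with mean depth above threshold, test each window for a two-group
difference with a conditional exact negative-binomial test, keep significant
CpG-containing windows, merge adjacent same-direction windows into DMRs, and
estimate a per-DMR false discovery rate by balanced group-label permutation.

The two-group test conditions on the total normalized count of a window: with
a common dispersion phi, the group sums are negative binomial with size
n_g / phi and a shared per-sample mean, and the two-sided p-value is the
probability mass of all splits of the total no more likely than the observed
one.  At phi = 0 the conditional law is binomial and the test reduces to the
exact binomial test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom as _binom

from .genomic_io import GenomicInterval, ReadAlignment

__all__ = [
    "WindowCountMatrix",
    "SegmentTestResult",
    "DMR",
    "extend_reads",
    "count_windows",
    "filter_windows",
    "normalize_counts",
    "estimate_common_dispersion",
    "exact_nb_test",
    "call_segments",
    "merge_dmrs",
    "permutation_fdr",
    "direction_fractions",
    "MedipDMRModel",
    "MedipDMRResults",
]

# relative tie tolerance when summing probabilities "no more likely than
# observed" (the convention used by R's fisher.test / exact binomial test)
_REL_ERR = 1e-7


@dataclass
class WindowCountMatrix:
    """Per-window read counts across samples, with group labels and library sizes."""

    windows: List[GenomicInterval]
    counts: np.ndarray  # (n_windows, n_samples) non-negative ints
    sample_ids: List[str]
    group_labels: Dict[str, str]  # sample -> "C" (case) or "Y" (control)
    library_sizes: np.ndarray  # fragments per sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.shape != (len(self.windows), len(self.sample_ids)):
            raise ValueError("counts shape must be (n_windows, n_samples)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if set(self.group_labels) != set(self.sample_ids):
            raise ValueError("group_labels must cover exactly the sample ids")
        if set(self.group_labels.values()) - {"C", "Y"}:
            raise ValueError("group labels must be 'C' or 'Y'")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.sample_ids) if self.group_labels[s] == group],
            dtype=int,
        )

    def subset(self, mask: np.ndarray) -> "WindowCountMatrix":
        idx = np.flatnonzero(mask)
        return WindowCountMatrix(
            [self.windows[i] for i in idx],
            self.counts[idx],
            list(self.sample_ids),
            dict(self.group_labels),
            self.library_sizes.copy(),
        )


@dataclass(frozen=True)
class SegmentTestResult:
    window: GenomicInterval
    p_value: float
    log2_fold_change: float
    mean_normalized_count: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class DMR:
    """A merged differentially methylated region."""

    interval: GenomicInterval
    direction: str  # "hyper" | "hypo" in the case group
    n_windows: int
    min_p: float
    n_cpgs: int
    fdr: float = float("nan")

    def __post_init__(self) -> None:
        if self.direction not in {"hyper", "hypo"}:
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if self.n_windows < 1:
            raise ValueError("a DMR must contain at least one window")


# ---------------------------------------------------------------------------
# Read extension and window counting
# ---------------------------------------------------------------------------

def extend_reads(
    alignments: Sequence[Union[ReadAlignment, GenomicInterval]],
    fragment_length: int = 400,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> List[GenomicInterval]:
    """Extend each read to ``fragment_length`` bp from its 5' end.

    Forward-strand (and strandless) reads extend rightward from ``start``;
    minus-strand reads extend leftward from ``end``.  Fragments are clipped to
    [0, chromosome size).
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be > 0")
    out: List[GenomicInterval] = []
    for rec in alignments:
        iv = rec.interval if isinstance(rec, ReadAlignment) else rec
        if iv.strand == "-":
            start, end = iv.end - fragment_length, iv.end
        else:
            start, end = iv.start, iv.start + fragment_length
        start = max(start, 0)
        if chrom_sizes is not None:
            size = chrom_sizes.get(iv.chrom)
            if size is None:
                raise KeyError(f"unknown chromosome {iv.chrom!r}")
            end = min(end, size)
        out.append(GenomicInterval(iv.chrom, start, end, iv.strand))
    return out


def make_windows(chrom_sizes: Mapping[str, int], window: int = 200) -> List[GenomicInterval]:
    """Tile each chromosome with ``window``-bp non-overlapping windows."""
    out: List[GenomicInterval] = []
    for chrom in chrom_sizes:
        size = chrom_sizes[chrom]
        for start in range(0, size, window):
            out.append(GenomicInterval(chrom, start, min(start + window, size)))
    return out


def count_windows(
    fragments_by_sample: Mapping[str, Sequence[GenomicInterval]],
    chrom_sizes: Mapping[str, int],
    window: int = 200,
    group_labels: Optional[Mapping[str, str]] = None,
) -> WindowCountMatrix:
    """Count, per sample, the fragments overlapping (>= 1 bp) each window.

    Library size per sample is its total fragment count.
    """
    chroms = list(chrom_sizes)
    n_per_chrom = {c: -(-chrom_sizes[c] // window) for c in chroms}
    offsets: Dict[str, int] = {}
    total = 0
    for c in chroms:
        offsets[c] = total
        total += n_per_chrom[c]
    sample_ids = list(fragments_by_sample)
    counts = np.zeros((total, len(sample_ids)), dtype=np.int64)
    for si, sample in enumerate(sample_ids):
        diff = np.zeros(total + 1, dtype=np.int64)
        for frag in fragments_by_sample[sample]:
            if frag.chrom not in offsets:
                raise KeyError(f"unknown chromosome {frag.chrom!r}")
            size = chrom_sizes[frag.chrom]
            first = offsets[frag.chrom] + max(frag.start, 0) // window
            last = offsets[frag.chrom] + (min(frag.end, size) - 1) // window
            diff[first] += 1
            diff[last + 1] -= 1
        counts[:, si] = np.cumsum(diff[:-1])
    windows = make_windows(chrom_sizes, window)
    library_sizes = np.array([len(fragments_by_sample[s]) for s in sample_ids], dtype=float)
    if group_labels is None:
        group_labels = {s: s[0] for s in sample_ids}
    return WindowCountMatrix(windows, counts, sample_ids, dict(group_labels), library_sizes)


def filter_windows(
    matrix: WindowCountMatrix, min_per_sample: int = 1, min_mean_depth: float = 10.0
) -> WindowCountMatrix:
    """Keep windows covered by >= ``min_per_sample`` reads in every sample whose
    mean count across all samples is strictly greater than ``min_mean_depth``."""
    every = (matrix.counts >= min_per_sample).all(axis=1)
    deep = matrix.counts.mean(axis=1) > min_mean_depth
    return matrix.subset(every & deep)


# ---------------------------------------------------------------------------
# Conditional exact negative-binomial test
# ---------------------------------------------------------------------------

def normalize_counts(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """Scale counts to a common (geometric-mean) library size, rounding to ints."""
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    geo = math.exp(float(np.mean(np.log(library_sizes))))
    return np.rint(np.asarray(counts) * (geo / library_sizes)).astype(np.int64)


def _conditional_pvalues(
    y_a: np.ndarray, y_b: np.ndarray, n_a: int, n_b: int, phi: float
) -> np.ndarray:
    """Vectorized two-sided conditional exact test of group sums given totals.

    For each row, conditional on N = y_a + y_b, sums the probabilities of all
    splits (a, N - a) whose conditional probability does not exceed that of
    the observed split (relative tie tolerance 1e-7).
    """
    y_a = np.asarray(y_a, dtype=np.int64)
    y_b = np.asarray(y_b, dtype=np.int64)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    n_rows = y_a.size
    totals = y_a + y_b
    pvals = np.ones(n_rows)
    order = np.argsort(totals, kind="stable")
    order = order[totals[order] > 0]  # N = 0 rows are degenerate with p = 1
    chunk = 512
    for c0 in range(0, len(order), chunk):
        rows = order[c0 : c0 + chunk]
        N = totals[rows]
        n_max = int(N.max(initial=0))
        a = np.arange(n_max + 1)
        mask = a[None, :] <= N[:, None]
        n_minus_a = np.where(mask, N[:, None] - a[None, :], 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            if phi == 0:
                prob = n_a / (n_a + n_b)
                logf = _binom.logpmf(a[None, :], N[:, None], prob)
            else:
                # unnormalized log pmf of f_A(a) f_B(N-a) via the NB recurrence
                # f(j)/f(j-1) = (j-1+r)(1-p)/j, so constants cancel in the
                # conditional normalization below
                r_a, r_b = n_a / phi, n_b / phi
                mu = N / (n_a + n_b)
                log_q_a = np.log(n_a * mu) - np.log(r_a + n_a * mu)
                log_q_b = np.log(n_b * mu) - np.log(r_b + n_b * mu)
                j = np.arange(1, n_max + 1)
                s_a = np.concatenate([[0.0], np.cumsum(np.log((j - 1 + r_a) / j))])
                s_b = np.concatenate([[0.0], np.cumsum(np.log((j - 1 + r_b) / j))])
                logf = (
                    s_a[None, :]
                    + a[None, :] * log_q_a[:, None]
                    + s_b[n_minus_a]
                    + n_minus_a * log_q_b[:, None]
                )
        logf = np.where(mask, logf, -np.inf)
        log_z = logsumexp(logf, axis=1)
        pmf = np.exp(logf - log_z[:, None])
        p_obs = pmf[np.arange(len(rows)), y_a[rows]]
        include = pmf <= p_obs[:, None] * (1.0 + _REL_ERR)
        pvals[rows] = np.minimum((pmf * include).sum(axis=1), 1.0)
    return pvals


def exact_nb_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    library_sizes: Sequence[float],
    dispersion: float,
) -> Tuple[float, float]:
    """Two-sided conditional exact NB test for one window.

    ``library_sizes`` lists group-A samples first, then group-B.  Returns the
    p-value and the log2 fold change (A over B) of the normalized group means
    with a 0.5 pseudocount.  An all-zero window returns p = 1.
    """
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    libs = np.asarray(library_sizes, dtype=float)
    if libs.size != counts_a.size + counts_b.size:
        raise ValueError("library_sizes must cover every sample of both groups")
    norm = normalize_counts(np.concatenate([counts_a, counts_b]), libs)
    na, nb = counts_a.size, counts_b.size
    norm_a, norm_b = norm[:na], norm[na:]
    lfc = float(np.log2((norm_a.mean() + 0.5) / (norm_b.mean() + 0.5)))
    y_a, y_b = int(norm_a.sum()), int(norm_b.sum())
    if y_a + y_b == 0:
        return 1.0, lfc
    p = float(_conditional_pvalues(np.array([y_a]), np.array([y_b]), na, nb, dispersion)[0])
    return p, lfc


def estimate_common_dispersion(matrix: WindowCountMatrix) -> float:
    """Method-of-moments common dispersion over windows of normalized counts.

    Per window: m = overall mean, v = pooled within-group variance; the
    estimate is the median across windows of max(0, (v - m)/m^2), floored at 0.
    """
    idx_c, idx_y = matrix.group_indices("C"), matrix.group_indices("Y")
    if idx_c.size < 2 or idx_y.size < 2:
        raise ValueError("need >= 2 samples per group to estimate dispersion")
    norm = normalize_counts(matrix.counts, matrix.library_sizes).astype(float)
    m = norm.mean(axis=1)
    v_c = norm[:, idx_c].var(axis=1, ddof=1)
    v_y = norm[:, idx_y].var(axis=1, ddof=1)
    dof_c, dof_y = idx_c.size - 1, idx_y.size - 1
    v = (dof_c * v_c + dof_y * v_y) / (dof_c + dof_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m > 0, np.maximum(0.0, (v - m) / np.square(m)), 0.0)
    if phi.size == 0:
        return 0.0
    return float(max(0.0, np.median(phi)))


def call_segments(
    matrix: WindowCountMatrix,
    alpha: float = 5e-4,
    dispersion: Optional[float] = None,
) -> Tuple[pd.DataFrame, List[SegmentTestResult]]:
    """Test every retained window; significant means p strictly below ``alpha``.

    Returns the full per-window table and the significant subset as
    :class:`SegmentTestResult` records sorted by genome position.
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix)
    idx_c, idx_y = matrix.group_indices("C"), matrix.group_indices("Y")
    norm = normalize_counts(matrix.counts, matrix.library_sizes)
    y_c = norm[:, idx_c].sum(axis=1)
    y_y = norm[:, idx_y].sum(axis=1)
    pvals = _conditional_pvalues(y_c, y_y, idx_c.size, idx_y.size, dispersion)
    mean_c = norm[:, idx_c].mean(axis=1)
    mean_y = norm[:, idx_y].mean(axis=1)
    lfc = np.log2((mean_c + 0.5) / (mean_y + 0.5))
    table = pd.DataFrame(
        {
            "chrom": [w.chrom for w in matrix.windows],
            "start": [w.start for w in matrix.windows],
            "end": [w.end for w in matrix.windows],
            "p_value": pvals,
            "log2_fold_change": lfc,
            "mean_normalized_count": norm.mean(axis=1),
        }
    )
    sig = [
        SegmentTestResult(matrix.windows[i], float(pvals[i]), float(lfc[i]), float(norm[i].mean()))
        for i in np.flatnonzero(pvals < alpha)
    ]
    sig.sort(key=lambda s: (s.window.chrom, s.window.start))
    return table, sig


# ---------------------------------------------------------------------------
# Merging and permutation FDR
# ---------------------------------------------------------------------------

def _cpgs_in(cpg_map: Mapping[str, np.ndarray], iv: GenomicInterval) -> int:
    pos = cpg_map.get(iv.chrom)
    if pos is None or len(pos) == 0:
        return 0
    return int(np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start))


def merge_dmrs(
    significant_segments: Sequence[SegmentTestResult],
    cpg_map: Mapping[str, np.ndarray],
) -> List[DMR]:
    """Drop CpG-free windows, then merge bookended same-direction windows.

    Windows are merged only when genomically adjacent (next.start == prev.end)
    and their fold changes share a sign; any gap or direction flip starts a
    new DMR.  The DMR p-value is the minimum member p.
    """
    kept = [s for s in significant_segments if _cpgs_in(cpg_map, s.window) > 0]
    for s in kept:
        if s.log2_fold_change == 0:
            raise ValueError(f"cannot orient segment {s.window} with zero fold change")
    kept.sort(key=lambda s: (s.window.chrom, s.window.start))
    dmrs: List[DMR] = []
    run: List[SegmentTestResult] = []

    def _flush() -> None:
        if not run:
            return
        iv = GenomicInterval(run[0].window.chrom, run[0].window.start, run[-1].window.end)
        dmrs.append(
            DMR(
                interval=iv,
                direction="hyper" if run[0].log2_fold_change > 0 else "hypo",
                n_windows=len(run),
                min_p=min(s.p_value for s in run),
                n_cpgs=_cpgs_in(cpg_map, iv),
            )
        )

    for seg in kept:
        if run and (
            seg.window.chrom == run[-1].window.chrom
            and seg.window.start == run[-1].window.end
            and (seg.log2_fold_change > 0) == (run[-1].log2_fold_change > 0)
        ):
            run.append(seg)
        else:
            _flush()
            run = [seg]
    _flush()
    return dmrs


def _balanced_splits(matrix: WindowCountMatrix) -> Tuple[Tuple[int, ...], List[Tuple[int, ...]]]:
    """All balanced relabelings (as index tuples of the pseudo-case group),
    excluding the observed one.  When group sizes are equal, a split and its
    complement define the same two-sided test and are collapsed."""
    idx_c = tuple(matrix.group_indices("C"))
    n_c = len(idx_c)
    n = len(matrix.sample_ids)
    equal = 2 * n_c == n
    splits: List[Tuple[int, ...]] = []
    for combo in combinations(range(n), n_c):
        if equal and 0 not in combo:
            continue  # canonical representative contains sample 0
        splits.append(combo)
    observed = tuple(sorted(idx_c))
    if equal and 0 not in observed:
        observed = tuple(sorted(set(range(n)) - set(observed)))
    splits = [s for s in splits if s != observed]
    return observed, splits


def permutation_fdr(
    matrix: WindowCountMatrix,
    observed_dmrs: Sequence[DMR],
    cpg_map: Mapping[str, np.ndarray],
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 5e-4,
    dispersion: Optional[float] = None,
) -> List[DMR]:
    """Estimate per-DMR FDR by re-running the caller under permuted labels.

    Each permutation draws a balanced group relabeling (with replacement from
    all balanced splits, excluding the observed one), repeats the segment test
    and merge, and records the null DMR p-values.  For an observed DMR with
    min_p = p, FDR = (mean null DMRs with min_p <= p) / (observed DMRs with
    min_p <= p), clamped to [0, 1] and made monotone non-decreasing in p.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix)
    _, splits = _balanced_splits(matrix)
    if not splits:
        raise ValueError("no balanced relabeling differs from the observed grouping")
    rng = np.random.default_rng(seed)
    norm = normalize_counts(matrix.counts, matrix.library_sizes)
    n = len(matrix.sample_ids)
    n_c = matrix.group_indices("C").size
    n_y = n - n_c
    null_minp: List[float] = []
    for _ in range(n_permutations):
        combo = splits[int(rng.integers(0, len(splits)))]
        idx_a = np.array(combo, dtype=int)
        idx_b = np.array(sorted(set(range(n)) - set(combo)), dtype=int)
        y_a = norm[:, idx_a].sum(axis=1)
        y_b = norm[:, idx_b].sum(axis=1)
        pvals = _conditional_pvalues(y_a, y_b, n_c, n_y, dispersion)
        sig_idx = np.flatnonzero(pvals < alpha)
        segs = []
        for i in sig_idx:
            mean_a = norm[i, idx_a].mean()
            mean_b = norm[i, idx_b].mean()
            lfc = float(np.log2((mean_a + 0.5) / (mean_b + 0.5)))
            if lfc == 0:
                continue  # unorientable null window carries no direction
            segs.append(
                SegmentTestResult(matrix.windows[i], float(pvals[i]), lfc, float(norm[i].mean()))
            )
        null_minp.extend(d.min_p for d in merge_dmrs(segs, cpg_map))
    null_arr = np.sort(np.asarray(null_minp))
    obs_p = np.array([d.min_p for d in observed_dmrs])
    order = np.argsort(obs_p, kind="stable")
    fdr_sorted = np.empty(len(observed_dmrs))
    for rank, i in enumerate(order):
        p = obs_p[i]
        n_null = np.searchsorted(null_arr, p, side="right")
        n_obs = int((obs_p <= p).sum())
        fdr_sorted[rank] = min(1.0, (n_null / n_permutations) / n_obs) if n_obs else 0.0
    fdr_sorted = np.maximum.accumulate(fdr_sorted)
    out = list(observed_dmrs)
    for rank, i in enumerate(order):
        out[i] = replace(out[i], fdr=float(fdr_sorted[rank]))
    return out


def direction_fractions(
    dmrs_or_counts: Union[Sequence[DMR], Tuple[int, int]]
) -> Dict[str, int]:
    """Percentages of hyper- and hypomethylated DMRs, rounded to integer percent.

    Accepts either a DMR list or a ``(n_hyper, n_hypo)`` pair.
    """
    if isinstance(dmrs_or_counts, tuple):
        n_hyper, n_hypo = dmrs_or_counts
    else:
        n_hyper = sum(1 for d in dmrs_or_counts if d.direction == "hyper")
        n_hypo = sum(1 for d in dmrs_or_counts if d.direction == "hypo")
    total = n_hyper + n_hypo
    if total == 0:
        raise ValueError("no DMRs to summarize")
    return {
        "hyper_pct": int(round(100.0 * n_hyper / total)),
        "hypo_pct": int(round(100.0 * n_hypo / total)),
    }


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class MedipDMRModel:
    """Two-group MeDIP differential-methylation model over window counts.

    Parameters
    ----------
    matrix : WindowCountMatrix
        Raw (unfiltered) window counts with group labels and library sizes.
    cpg_map : mapping chrom -> sorted CpG positions
        Reference CpG index used for the CpG-retention rule.
    """

    def __init__(self, matrix: WindowCountMatrix, cpg_map: Mapping[str, np.ndarray]):
        self.matrix = matrix
        self.cpg_map = dict(cpg_map)

    @classmethod
    def from_reads(
        cls,
        reads_by_sample: Mapping[str, Sequence[ReadAlignment]],
        chrom_sizes: Mapping[str, int],
        cpg_map: Mapping[str, np.ndarray],
        group_labels: Optional[Mapping[str, str]] = None,
        fragment_length: int = 400,
        window: int = 200,
    ) -> "MedipDMRModel":
        fragments = {
            s: extend_reads(reads, fragment_length, chrom_sizes)
            for s, reads in reads_by_sample.items()
        }
        matrix = count_windows(fragments, chrom_sizes, window, group_labels)
        return cls(matrix, cpg_map)

    def fit(
        self,
        alpha: float = 5e-4,
        min_per_sample: int = 1,
        min_mean_depth: float = 10.0,
        dispersion: Optional[float] = None,
        n_permutations: int = 1000,
        seed: Optional[int] = 0,
    ) -> "MedipDMRResults":
        filtered = filter_windows(self.matrix, min_per_sample, min_mean_depth)
        if dispersion is None:
            dispersion = estimate_common_dispersion(filtered)
        table, significant = call_segments(filtered, alpha, dispersion)
        dmrs = merge_dmrs(significant, self.cpg_map)
        if dmrs and n_permutations > 0:
            dmrs = permutation_fdr(
                filtered, dmrs, self.cpg_map, n_permutations, seed, alpha, dispersion
            )
        return MedipDMRResults(
            model=self,
            filtered_matrix=filtered,
            segment_table=table,
            significant_segments=significant,
            dmrs=dmrs,
            dispersion=dispersion,
            alpha=alpha,
            n_permutations=n_permutations,
        )


@dataclass
class MedipDMRResults:
    """Fitted MeDIP DMR results: per-window tests, merged DMRs, and FDRs."""

    model: MedipDMRModel
    filtered_matrix: WindowCountMatrix
    segment_table: pd.DataFrame
    significant_segments: List[SegmentTestResult]
    dmrs: List[DMR]
    dispersion: float
    alpha: float
    n_permutations: int

    @property
    def dmr_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [d.interval.chrom for d in self.dmrs],
                "start": [d.interval.start for d in self.dmrs],
                "end": [d.interval.end for d in self.dmrs],
                "direction": [d.direction for d in self.dmrs],
                "n_windows": [d.n_windows for d in self.dmrs],
                "min_p": [d.min_p for d in self.dmrs],
                "n_cpgs": [d.n_cpgs for d in self.dmrs],
                "fdr": [d.fdr for d in self.dmrs],
            }
        )

    def summary(self) -> str:
        n_hyper = sum(1 for d in self.dmrs if d.direction == "hyper")
        n_hypo = len(self.dmrs) - n_hyper
        lines = [
            "MeDIP differential methylation",
            "==============================",
            f"windows tested          {len(self.segment_table):>10d}",
            f"common dispersion       {self.dispersion:>10.4f}",
            f"significant segments    {len(self.significant_segments):>10d}  (p < {self.alpha:g})",
            f"DMRs                    {len(self.dmrs):>10d}",
        ]
        if self.dmrs:
            pct = direction_fractions((n_hyper, n_hypo))
            lines.append(
                f"  hypermethylated       {n_hyper:>10d}  ({pct['hyper_pct']}%)"
            )
            lines.append(
                f"  hypomethylated        {n_hypo:>10d}  ({pct['hypo_pct']}%)"
            )
            fdrs = [d.fdr for d in self.dmrs if not math.isnan(d.fdr)]
            if fdrs:
                lines.append(f"max permutation FDR     {max(fdrs):>10.3f}  ({self.n_permutations} permutations)")
        return "\n".join(lines)
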