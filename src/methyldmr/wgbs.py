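"""Pairwise per-CpG DMR calling for whole-genome bisulfite data.

Two individuals are compared CpG by CpG: sites covered by fewer than 5 reads
in either sample are removed, each remaining site is tested with Fisher's
exact test on the 2x2 table of methylated/unmethylated counts, and a site is
differential when p < 0.05 and the methylation-level difference exceeds 20%.
Adjacent differential CpGs closer than 1000 bp with the same direction of
change are merged, and merged runs with at least 5 CpGs become DMRs.

``fisher_exact_2x2`` uses exact integer arithmetic so the two-sided p-value
(the summed hypergeometric mass of all tables with the same margins that are
no more probable than the observed one) is enumeration-exact, with ties
resolved by exact integer comparison rather than a floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, inf, nan
from typing import Dict, List, Sequence, Tuple

from .genomic_io import CpGRecord, GenomicInterval
from .medip import DMR

__all__ = [
    "CpGTestResult",
    "fisher_exact_2x2",
    "compare_cpgs",
    "call_diff_cpgs",
    "merge_cpg_dmrs",
    "WgbsDMRModel",
    "WgbsDMRResults",
]


@dataclass(frozen=True)
class CpGTestResult:
    chrom: str
    pos: int
    meth_a: int
    unmeth_a: int
    meth_b: int
    unmeth_b: int
    level_a: float
    level_b: float
    delta: float  # level_a - level_b
    p_value: float
    differential: bool


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Returns (p, odds_ratio) where the odds ratio is the sample estimate
    a*d / (b*c) (+inf when b*c = 0 with a*d > 0, NaN for the empty table).
    The p-value sums the conditional probabilities of every table with the
    observed margins whose probability is <= the observed table's.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    m = a + c
    n_total = r1 + r2
    if b * c == 0:
        odds = nan if a * d == 0 else inf
    else:
        odds = (a * d) / (b * c)
    if n_total == 0:
        return 1.0, odds
    lo, hi = max(0, m - r2), min(m, r1)
    # integer numerators of the hypergeometric pmf (common denominator C(N, m))
    nums = [comb(r1, x) * comb(r2, m - x) for x in range(lo, hi + 1)]
    observed = nums[a - lo]
    total = comb(n_total, m)
    p = float(Fraction(sum(v for v in nums if v <= observed), total))
    return min(p, 1.0), odds


def _index(records: Sequence[CpGRecord]) -> Dict[Tuple[str, int], CpGRecord]:
    out: Dict[Tuple[str, int], CpGRecord] = {}
    for r in records:
        out[(r.chrom, r.pos)] = r
    return out


def compare_cpgs(
    table_a: Sequence[CpGRecord],
    table_b: Sequence[CpGRecord],
    min_coverage: int = 5,
    alpha: float = 0.05,
    min_delta: float = 0.20,
) -> List[CpGTestResult]:
    """Test every CpG present with coverage >= ``min_coverage`` in both samples.

    A CpG is flagged differential when p < alpha and |delta| > min_delta
    (both strict).  CpGs absent from either sample are excluded.
    """
    idx_b = _index(table_b)
    results: List[CpGTestResult] = []
    for rec_a in table_a:
        rec_b = idx_b.get((rec_a.chrom, rec_a.pos))
        if rec_b is None:
            continue
        if rec_a.coverage < min_coverage or rec_b.coverage < min_coverage:
            continue
        p, _ = fisher_exact_2x2(rec_a.meth, rec_a.unmeth, rec_b.meth, rec_b.unmeth)
        delta = rec_a.level - rec_b.level
        results.append(
            CpGTestResult(
                chrom=rec_a.chrom,
                pos=rec_a.pos,
                meth_a=rec_a.meth,
                unmeth_a=rec_a.unmeth,
                meth_b=rec_b.meth,
                unmeth_b=rec_b.unmeth,
                level_a=rec_a.level,
                level_b=rec_b.level,
                delta=delta,
                p_value=p,
                differential=bool(p < alpha and abs(delta) > min_delta),
            )
        )
    results.sort(key=lambda r: (r.chrom, r.pos))
    return results


def call_diff_cpgs(
    table_a: Sequence[CpGRecord],
    table_b: Sequence[CpGRecord],
    min_coverage: int = 5,
    alpha: float = 0.05,
    min_delta: float = 0.20,
) -> List[CpGTestResult]:
    """The differential subset of :func:`compare_cpgs`."""
    return [r for r in compare_cpgs(table_a, table_b, min_coverage, alpha, min_delta) if r.differential]


def merge_cpg_dmrs(
    diff_cpgs: Sequence[CpGTestResult],
    max_gap: int = 1000,
    min_cpgs: int = 5,
) -> List[DMR]:
    """Chain same-direction differential CpGs with gaps < ``max_gap`` bp.

    Runs with >= ``min_cpgs`` members become DMRs spanning the first to last
    CpG (end = last C position + 2, covering the final CG dinucleotide).
    Direction is hyper when delta > 0 (sample A higher).
    """
    cpgs = [c for c in diff_cpgs if getattr(c, "differential", True)]
    cpgs.sort(key=lambda c: (c.chrom, c.pos))
    dmrs: List[DMR] = []
    run: List[CpGTestResult] = []

    def _flush() -> None:
        if len(run) >= min_cpgs:
            iv = GenomicInterval(run[0].chrom, run[0].pos, run[-1].pos + 2)
            dmrs.append(
                DMR(
                    interval=iv,
                    direction="hyper" if run[0].delta > 0 else "hypo",
                    n_windows=1,
                    min_p=min(c.p_value for c in run),
                    n_cpgs=len(run),
                )
            )

    for c in cpgs:
        assert c.delta != 0, "differential CpG with zero delta"
        if run and (
            c.chrom == run[-1].chrom
            and c.pos - run[-1].pos < max_gap
            and (c.delta > 0) == (run[-1].delta > 0)
        ):
            run.append(c)
        else:
            _flush()
            run = [c]
    _flush()
    return dmrs


class WgbsDMRModel:
    """Pairwise WGBS differential-methylation model for two individuals.

    Sample A is the centenarian-like individual, sample B the control; a
    hyper DMR means higher methylation in A.
    """

    def __init__(self, table_a: Sequence[CpGRecord], table_b: Sequence[CpGRecord]):
        self.table_a = list(table_a)
        self.table_b = list(table_b)

    def fit(
        self,
        min_coverage: int = 5,
        alpha: float = 0.05,
        min_delta: float = 0.20,
        max_gap: int = 1000,
        min_cpgs: int = 5,
    ) -> "WgbsDMRResults":
        tested = compare_cpgs(self.table_a, self.table_b, min_coverage, alpha, min_delta)
        diff = [r for r in tested if r.differential]
        dmrs = merge_cpg_dmrs(diff, max_gap, min_cpgs)
        return WgbsDMRResults(self, tested, diff, dmrs, alpha, min_delta, min_coverage)


@dataclass
class WgbsDMRResults:
    model: "WgbsDMRModel"
    tested_cpgs: List[CpGTestResult]
    diff_cpgs: List[CpGTestResult]
    dmrs: List[DMR]
    alpha: float
    min_delta: float
    min_coverage: int

    def cpg_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.tested_cpgs],
                "pos": [r.pos for r in self.tested_cpgs],
                "meth_a": [r.meth_a for r in self.tested_cpgs],
                "unmeth_a": [r.unmeth_a for r in self.tested_cpgs],
                "meth_b": [r.meth_b for r in self.tested_cpgs],
                "unmeth_b": [r.unmeth_b for r in self.tested_cpgs],
                "level_a": [r.level_a for r in self.tested_cpgs],
                "level_b": [r.level_b for r in self.tested_cpgs],
                "delta": [r.delta for r in self.tested_cpgs],
                "p_value": [r.p_value for r in self.tested_cpgs],
                "differential": [r.differential for r in self.tested_cpgs],
            }
        )

    def summary(self) -> str:
        n_hyper = sum(1 for d in self.dmrs if d.direction == "hyper")
        return "\n".join(
            [
                "WGBS pairwise differential methylation",
                "======================================",
                f"CpGs tested (cov >= {self.min_coverage})   {len(self.tested_cpgs):>10d}",
                f"differential CpGs        {len(self.diff_cpgs):>10d}  "
                f"(p < {self.alpha:g}, |delta| > {self.min_delta:g})",
                f"DMRs                     {len(self.dmrs):>10d}",
                f"  hypermethylated        {n_hyper:>10d}",
                f"  hypomethylated         {len(self.dmrs) - n_hyper:>10d}",
            ]
        )
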