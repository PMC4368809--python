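"""Window counting, the conditional exact NB test, merging and permutation FDR."""

import math

import numpy as np
import pytest
from scipy.stats import binomtest

from methyldmr.genomic_io import GenomicInterval
from methyldmr.medip import (
    MedipDMRModel,
    SegmentTestResult,
    _conditional_pvalues,
    call_segments,
    count_windows,
    estimate_common_dispersion,
    exact_nb_test,
    extend_reads,
    filter_windows,
    merge_dmrs,
    direction_fractions,
    normalize_counts,
    permutation_fdr,
)
from methyldmr.simulate import simulate_medip

from conftest import make_matrix


def nb_conditional_oracle(ya, yb, n_a, n_b, phi):
    """Independent enumeration of the conditional two-group NB test via lgamma."""
    N = ya + yb
    if N == 0:
        return 1.0

    def log_nb_pmf(k, r, mean):
        p = r / (r + mean)
        return (
            math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
            + r * math.log(p) + k * math.log1p(-p)
        )

    mu = N / (n_a + n_b)
    logs = [
        log_nb_pmf(a, n_a / phi, n_a * mu) + log_nb_pmf(N - a, n_b / phi, n_b * mu)
        for a in range(N + 1)
    ]
    mx = max(logs)
    probs = [math.exp(x - mx) for x in logs]
    z = sum(probs)
    probs = [p / z for p in probs]
    obs = probs[ya]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-7)))


class TestExtendReads:
    def test_plus_strand_anchor(self):
        (f,) = extend_reads([GenomicInterval("chr1", 100, 149, "+")], 400)
        assert (f.start, f.end) == (100, 500)

    def test_minus_strand_anchor(self):
        (f,) = extend_reads([GenomicInterval("chr1", 600, 649, "-")], 400)
        assert (f.start, f.end) == (249, 649)

    def test_strandless_treated_as_forward(self):
        (f,) = extend_reads([GenomicInterval("chr1", 10, 59)], 400)
        assert (f.start, f.end) == (10, 410)

    def test_clipped_to_chromosome(self):
        (f,) = extend_reads(
            [GenomicInterval("chr1", 800, 849, "+")], 450, chrom_sizes={"chr1": 1000}
        )
        assert (f.start, f.end) == (800, 1000)
        (g,) = extend_reads([GenomicInterval("chr1", 10, 59, "-")], 400)
        assert (g.start, g.end) == (0, 59)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValueError):
            extend_reads([], 0)


class TestCountWindows:
    def test_fragment_increments_every_overlapped_window(self):
        mat = count_windows(
            {"C1": [GenomicInterval("chr1", 100, 500)], "Y1": []},
            {"chr1": 1000},
            200,
            {"C1": "C", "Y1": "Y"},
        )
        assert mat.counts[:, 0].tolist() == [1, 1, 1, 0, 0]
        assert mat.counts[:, 1].tolist() == [0, 0, 0, 0, 0]  # empty sample: zero column
        assert mat.library_sizes.tolist() == [1, 0]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            count_windows(
                {"C1": [GenomicInterval("chrX", 0, 100)]}, {"chr1": 1000}, 200, {"C1": "C"}
            )

    def test_matches_naive_overlap_count(self, rng):
        sizes = {"chr1": 20_000, "chr2": 10_000}
        frags = []
        for _ in range(1000):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            start = int(rng.integers(0, sizes[chrom] - 400))
            frags.append(GenomicInterval(chrom, start, start + int(rng.integers(1, 400))))
        mat = count_windows({"C1": frags, "Y1": []}, sizes, 200, {"C1": "C", "Y1": "Y"})
        naive = np.array(
            [sum(1 for f in frags if f.overlaps(w)) for w in mat.windows]
        )
        assert np.array_equal(mat.counts[:, 0], naive)


class TestFilterWindows:
    @pytest.mark.parametrize(
        "row,kept",
        [
            ([1, 1, 1, 1, 1, 1, 1, 1], False),        # mean 1: fails "more than 10"
            ([0, 20, 20, 20, 20, 20, 20, 20], False),  # a zero sample
            ([11, 11, 11, 11, 11, 11, 11, 11], True),  # all >=1, mean 11 > 10
            ([10, 10, 10, 10, 10, 10, 10, 10], False),  # mean exactly 10 is not > 10
        ],
    )
    def test_literal_coverage_rules(self, row, kept):
        mat = make_matrix(np.array([row]))
        out = filter_windows(mat, min_per_sample=1, min_mean_depth=10)
        assert (out.n_windows == 1) is kept


class TestExactNbTest:
    def test_perfectly_balanced_pair_gives_p_one(self):
        p, lfc = exact_nb_test([3], [3], [100, 100], 0.0)
        assert p == 1.0
        assert lfc == 0.0

    def test_extreme_split_matches_binomial_closed_form(self):
        # group sums 10 vs 0 with equal libraries: two-sided Binomial(10, 1/2)
        p, lfc = exact_nb_test([3, 3, 2, 2], [0, 0, 0, 0], [100] * 8, 0.0)
        assert p == pytest.approx(2 / 1024, abs=1e-15)
        assert lfc > 0

    def test_matches_enumeration_oracle_at_positive_dispersion(self, rng):
        for _ in range(50):
            N = int(rng.integers(1, 31))
            ya = int(rng.integers(0, N + 1))
            phi = float(rng.choice([0.05, 0.1, 0.3]))
            ours = _conditional_pvalues(np.array([ya]), np.array([N - ya]), 4, 4, phi)[0]
            assert ours == pytest.approx(nb_conditional_oracle(ya, N - ya, 4, 4, phi), abs=1e-10)

    def test_zero_dispersion_equals_exact_binomial(self):
        for N in range(1, 51):
            ya = np.arange(N + 1)
            ours = _conditional_pvalues(ya, N - ya, 4, 4, 0.0)
            for a in range(N + 1):
                assert abs(ours[a] - binomtest(a, N, 0.5).pvalue) < 1e-12

    def test_unbalanced_groups_use_group_size_proportion(self):
        # n_a=2 vs n_b=6: conditional law Binomial(N, 1/4)
        p = _conditional_pvalues(np.array([8]), np.array([0]), 2, 6, 0.0)[0]
        assert p == pytest.approx(binomtest(8, 8, 0.25).pvalue, abs=1e-12)

    def test_group_swap_symmetry(self, rng):
        for _ in range(20):
            ca = rng.integers(0, 40, size=4)
            cb = rng.integers(0, 40, size=4)
            libs = rng.integers(500, 1500, size=8).astype(float)
            p1, l1 = exact_nb_test(ca, cb, libs, 0.1)
            p2, l2 = exact_nb_test(cb, ca, np.concatenate([libs[4:], libs[:4]]), 0.1)
            assert p1 == pytest.approx(p2, abs=1e-12)
            assert l1 == pytest.approx(-l2, abs=1e-12)

    def test_all_zero_window_returns_p_one(self):
        p, _ = exact_nb_test([0, 0], [0, 0], [100] * 4, 0.1)
        assert p == 1.0

    def test_normalization_rounds_to_common_library_size(self):
        # doubling one library halves its normalized counts
        norm = normalize_counts(np.array([[10, 20]]), np.array([100.0, 400.0]))
        assert norm.tolist() == [[20, 10]]


class TestDispersionEstimate:
    def test_constant_matrix_gives_zero(self):
        mat = make_matrix(np.full((50, 8), 12))
        assert estimate_common_dispersion(mat) == 0.0

    def test_poisson_data_estimates_near_zero(self, rng):
        counts = rng.poisson(15, size=(2000, 8))
        mat = make_matrix(counts)
        assert estimate_common_dispersion(mat) <= 0.02

    def test_nb_data_recovers_dispersion_scale(self, rng):
        lam = 15 * rng.gamma(10.0, 0.1, size=(2000, 8))  # phi = 0.1
        counts = rng.poisson(lam)
        mat = make_matrix(counts)
        assert 0.05 <= estimate_common_dispersion(mat) <= 0.2

    def test_requires_two_samples_per_group(self):
        mat = make_matrix(np.ones((10, 2), dtype=int), n_case=1)
        with pytest.raises(ValueError):
            estimate_common_dispersion(mat)


class TestCallSegments:
    def test_alpha_zero_yields_no_significant_windows(self, rng):
        mat = make_matrix(rng.poisson(20, size=(100, 8)))
        table, sig = call_segments(mat, alpha=0.0)
        assert sig == []
        assert len(table) == 100

    def test_null_matrix_is_calibrated(self, rng):
        from scipy.stats import kstest

        lam = 15 * rng.gamma(10.0, 0.1, size=(2000, 8))
        mat = make_matrix(rng.poisson(lam))
        table, sig = call_segments(mat, alpha=5e-4)
        assert kstest(table.p_value.values, "uniform").statistic < 0.1
        assert len(sig) <= 4  # Binomial(2000, 5e-4) 99% upper bound

    def test_planted_windows_mostly_significant(self, small_config, small_genome):
        reads, truth = simulate_medip(small_config, small_genome)
        model = MedipDMRModel.from_reads(
            reads, small_genome.chrom_sizes, small_genome.cpg_map, small_config.group_labels
        )
        res = model.fit(n_permutations=0)
        truth_w = {
            (d.interval.chrom, s)
            for d in truth
            for s in range(d.interval.start, d.interval.end, 200)
        }
        called = {(s.window.chrom, s.window.start) for s in res.significant_segments}
        assert len(truth_w & called) / len(truth_w) > 0.5


def seg(start, p, lfc, chrom="chr1", width=200):
    return SegmentTestResult(GenomicInterval(chrom, start, start + width), p, lfc, 20.0)


CPGS = {"chr1": np.arange(50, 10_000, 100)}  # a CpG in every window


class TestMergeDmrs:
    def test_gap_breaks_run(self):
        dmrs = merge_dmrs([seg(0, 1e-5, 1.0), seg(200, 1e-6, 1.0), seg(600, 1e-4, 1.0)], CPGS)
        assert [(d.interval.start, d.interval.end) for d in dmrs] == [(0, 400), (600, 800)]
        assert dmrs[0].min_p == 1e-6
        assert dmrs[0].n_windows == 2

    def test_direction_change_breaks_run(self):
        dmrs = merge_dmrs([seg(0, 1e-5, 1.0), seg(200, 1e-5, -1.0)], CPGS)
        assert len(dmrs) == 2
        assert [d.direction for d in dmrs] == ["hyper", "hypo"]

    def test_cpg_free_windows_removed_before_merging(self):
        cpgs = {"chr1": np.array([250])}  # only the second window holds a CpG
        dmrs = merge_dmrs([seg(0, 1e-5, 1.0), seg(200, 1e-5, 1.0)], cpgs)
        assert [(d.interval.start, d.interval.end) for d in dmrs] == [(200, 400)]
        assert dmrs[0].n_cpgs == 1

    def test_zero_fold_change_is_unorientable(self):
        with pytest.raises(ValueError, match="orient"):
            merge_dmrs([seg(0, 1e-5, 0.0)], CPGS)

    def test_output_disjoint_and_union_of_inputs(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 9800, 200), size=20, replace=False))
        segs = [
            seg(int(s), 10.0 ** -float(rng.integers(4, 9)), float(rng.choice([-1, 1])))
            for s in starts
        ]
        dmrs = merge_dmrs(segs, CPGS)
        assert sum(d.n_windows for d in dmrs) == len(segs)
        for a, b in zip(dmrs, dmrs[1:]):
            assert a.interval.end <= b.interval.start


@pytest.fixture(scope="module")
def fitted(small_config, small_genome):
    reads, truth = simulate_medip(small_config, small_genome)
    model = MedipDMRModel.from_reads(
        reads, small_genome.chrom_sizes, small_genome.cpg_map, small_config.group_labels
    )
    return model, model.fit(n_permutations=30, seed=5), truth


class TestPermutationFdr:
    def test_deterministic_under_seed(self, fitted):
        model, res, _ = fitted
        again = permutation_fdr(
            res.filtered_matrix, res.dmrs, model.cpg_map, 30, seed=5,
            alpha=res.alpha, dispersion=res.dispersion,
        )
        assert [d.fdr for d in again] == [d.fdr for d in res.dmrs]

    def test_fdr_in_unit_interval_and_monotone_in_p(self, fitted):
        _, res, _ = fitted
        dmrs = sorted(res.dmrs, key=lambda d: d.min_p)
        fdrs = [d.fdr for d in dmrs]
        assert all(0 <= f <= 1 for f in fdrs)
        assert all(a <= b for a, b in zip(fdrs, fdrs[1:]))

    def test_planted_signal_gets_low_fdr(self, fitted):
        _, res, truth = fitted
        recovered = [
            d for d in res.dmrs
            if any(d.interval.overlaps(t.interval) for t in truth)
        ]
        assert recovered and all(d.fdr < 0.1 for d in recovered)

    def test_requires_at_least_one_permutation(self, fitted):
        model, res, _ = fitted
        with pytest.raises(ValueError):
            permutation_fdr(res.filtered_matrix, res.dmrs, model.cpg_map, 0, seed=1)

    def test_requires_an_alternative_relabeling(self):
        mat = make_matrix(np.ones((10, 2), dtype=int) * 20, n_case=1)
        with pytest.raises(ValueError, match="relabeling"):
            permutation_fdr(mat, [], {}, 10, seed=1, dispersion=0.1)

    def test_null_data_dmrs_get_high_fdr(self, rng):
        lam = 20 * rng.gamma(10.0, 0.1, size=(3000, 8))
        mat = make_matrix(rng.poisson(lam))
        cpgs = {"chr1": np.arange(50, 3000 * 200, 100)}
        table, sig = call_segments(mat, alpha=0.05)  # loose alpha to surface null DMRs
        dmrs = merge_dmrs(sig, cpgs)
        assert dmrs, "expected some null calls at alpha=0.05"
        out = permutation_fdr(mat, dmrs, cpgs, 40, seed=2, alpha=0.05)
        assert np.median([d.fdr for d in out]) > 0.5


class TestDirectionFractions:
    def test_reported_direction_split_rounds_to_integer_percent(self):
        assert direction_fractions((274, 350)) == {"hyper_pct": 44, "hypo_pct": 56}

    def test_accepts_dmr_list(self):
        d = [
            merge_dmrs([seg(0, 1e-5, 1.0)], CPGS)[0],
            merge_dmrs([seg(400, 1e-5, -1.0)], CPGS)[0],
        ]
        assert direction_fractions(d) == {"hyper_pct": 50, "hypo_pct": 50}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            direction_fractions((0, 0))
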