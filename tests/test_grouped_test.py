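"""Partitioning, d.f. collapsing, kernel CDFs and the permutation test."""

import numpy as np
import pytest
from scipy import stats

from priorpart import (
    GenotypeMatrix,
    InvalidInputError,
    annotation_partition,
    collapse_group,
    combined_partition,
    combined_statistic,
    decorrelate,
    fit_smoothed_cdf,
    generalized_cholesky,
    group_statistics,
    maf_partition,
    partition_from_labels,
    permutation_test,
    pseudoinverse,
    score_statistic,
)
from conftest import random_pd


def gm_with_mafs(mafs, n=1000, annotations=None, seed=0):
    """Genotype matrix whose observed MAFs hit the requested values exactly."""
    mafs = np.asarray(mafs)
    values = np.zeros((n, len(mafs)), dtype=int)
    for j, m in enumerate(mafs):
        k = int(round(m * 2 * n))
        values[:k, j] = 1  # k minor alleles among 2n -> sample MAF = m
    return GenotypeMatrix(
        values=values,
        variant_ids=[f"v{j}" for j in range(len(mafs))],
        positions=np.arange(1, len(mafs) + 1),
        annotations=annotations,
    )


class TestPartitions:
    def test_maf_split_at_one_percent(self):
        part = maf_partition(gm_with_mafs([0.005, 0.02]), threshold=0.01)
        assert part.K == 2
        assert [list(g) for g in part.groups] == [[0], [1]]

    def test_all_rare_collapses_to_single_group(self):
        part = maf_partition(gm_with_mafs([0.002, 0.004, 0.006]), threshold=0.01)
        assert part.K == 1 and part.sizes[0] == 3

    def test_threshold_half_with_no_common_side(self):
        part = maf_partition(gm_with_mafs([0.1, 0.2]), threshold=0.499)
        assert part.K == 1

    def test_threshold_bounds(self):
        with pytest.raises(InvalidInputError):
            maf_partition(gm_with_mafs([0.1]), threshold=0.5)

    def test_annotation_groups(self):
        gm = gm_with_mafs([0.1, 0.1, 0.1], annotations=["nonsynonymous", "synonymous", "unknown"])
        part = annotation_partition(gm)
        assert part.K == 2
        assert [list(g) for g in part.groups] == [[0], [1, 2]]

    def test_annotation_all_nonsynonymous(self):
        gm = gm_with_mafs([0.1, 0.2], annotations=["ns", "missense"])
        assert annotation_partition(gm).K == 1

    def test_unrecognized_annotation_becomes_unknown(self, caplog):
        gm = gm_with_mafs([0.1, 0.2], annotations=["nonsynonymous", "frobnicating"])
        with caplog.at_level("WARNING"):
            part = annotation_partition(gm)
        assert part.K == 2
        assert "vocabulary" in caplog.text

    def test_missing_annotations_rejected(self):
        with pytest.raises(InvalidInputError, match="annotation"):
            annotation_partition(gm_with_mafs([0.1]))

    def test_combined_four_cells(self):
        gm = gm_with_mafs(
            [0.005, 0.005, 0.2, 0.2],
            annotations=["nonsynonymous", "synonymous", "nonsynonymous", "unknown"],
        )
        assert combined_partition(gm, 0.01).K == 4

    def test_combined_prunes_empty_cells(self):
        gm = gm_with_mafs(
            [0.005, 0.2, 0.2],
            annotations=["nonsynonymous", "nonsynonymous", "synonymous"],
        )
        assert combined_partition(gm, 0.01).K == 3

    def test_combined_degenerate_single_cell(self):
        gm = gm_with_mafs([0.005, 0.004], annotations=["ns", "ns"])
        assert combined_partition(gm, 0.01).K == 1


class TestGroupStatistics:
    def test_hand_case(self):
        part = partition_from_labels(["a", "b", "b"])
        np.testing.assert_allclose(
            group_statistics(np.array([1.0, 2.0, 2.0]), part), [1.0, 8.0]
        )

    def test_singletons_square_elementwise(self, rng):
        s = rng.normal(size=5)
        part = partition_from_labels([str(i) for i in range(5)])
        np.testing.assert_allclose(group_statistics(s, part), s**2)

    def test_single_group_recovers_t0(self, rng):
        s = rng.normal(size=6)
        part = partition_from_labels(["g"] * 6)
        assert group_statistics(s, part)[0] == pytest.approx(s @ s)

    def test_sum_invariant(self, rng):
        s = rng.normal(size=8)
        part = partition_from_labels(["a", "b", "a", "c", "b", "c", "a", "b"])
        assert group_statistics(s, part).sum() == pytest.approx(s @ s)


class TestCollapseGroup:
    def test_one_df_identity(self):
        assert collapse_group(3.7, 1) == pytest.approx(3.7)

    def test_zero_statistic(self):
        assert collapse_group(0.0, 4) == pytest.approx(0.0)

    def test_median_maps_to_median(self):
        med2 = stats.chi2.median(2)
        assert collapse_group(med2, 2) == pytest.approx(stats.chi2.median(1), rel=1e-10)

    def test_large_statistic_finite_and_monotone(self):
        h1 = collapse_group(5000.0, 10)
        h2 = collapse_group(6000.0, 10)
        assert np.isfinite(h1) and np.isfinite(h2) and h2 > h1 > 100

    def test_combined_statistic_sums(self):
        assert combined_statistic(np.array([0.0, 0.0])) == 0.0
        assert combined_statistic(np.array([2.5])) == pytest.approx(2.5)
        with pytest.raises(InvalidInputError):
            combined_statistic(np.array([1.0, -0.5]))


class TestSmoothedCDF:
    def test_too_few_draws_rejected(self, rng):
        with pytest.raises(InvalidInputError, match="B=100"):
            fit_smoothed_cdf(rng.chisquare(2, size=50))

    def test_upper_and_lower_clamping(self, rng):
        draws = rng.chisquare(2, size=200)
        cdf = fit_smoothed_cdf(draws)
        assert cdf(1e6) == pytest.approx(200 / 201)
        assert cdf(-1e6) == pytest.approx(1 / 201)

    def test_median_of_symmetric_sample(self, rng):
        draws = rng.normal(size=2001)
        cdf = fit_smoothed_cdf(draws)
        assert cdf(np.median(draws)) == pytest.approx(0.5, abs=0.02)

    def test_monotone(self, rng):
        cdf = fit_smoothed_cdf(rng.chisquare(3, size=500))
        x = np.linspace(-1, 20, 200)
        assert (np.diff(cdf(x)) >= 0).all()

    def test_sup_norm_consistency_chisq2(self, rng):
        draws = rng.chisquare(2, size=10_000)
        cdf = fit_smoothed_cdf(draws)
        x = np.linspace(0.0, 15.0, 400)
        assert np.abs(cdf(x) - stats.chi2.cdf(x, 2)).max() < 0.02


class TestAlgebraicIdentity:
    def test_singleton_partition_recovers_t0(self, rng):
        """All-singleton partition with theoretical CDFs: T1 = T0 exactly."""
        for _ in range(10):
            l = rng.integers(2, 10)
            v = random_pd(rng, l)
            u = rng.normal(size=l) * 3
            s = decorrelate(u, generalized_cholesky(v))
            part = partition_from_labels([str(i) for i in range(l)])
            t = group_statistics(s, part)
            h = np.array([collapse_group(tk, 1) for tk in t])
            t1 = combined_statistic(h)
            t0 = score_statistic(u, v)
            assert t1 == pytest.approx(t0, rel=1e-8)

    def test_t1_null_chi_squared_k_df(self, rng):
        """Theoretical-CDF T1 on simulated null scores fits chi2(K), K in {1,2,5}."""
        reps, l = 5000, 10
        s = rng.normal(size=(reps, l))
        for k, labels in [
            (1, ["g"] * l),
            (2, ["a"] * 4 + ["b"] * 6),
            (5, ["a", "a", "b", "b", "c", "c", "d", "d", "e", "e"]),
        ]:
            part = partition_from_labels(labels)
            t = group_statistics(s, part)
            h = np.column_stack(
                [collapse_group(t[:, j], int(part.sizes[j])) for j in range(part.K)]
            )
            t1 = h.sum(axis=1)
            assert stats.kstest(t1, stats.chi2(k).cdf).pvalue > 0.01


class TestPermutationTest:
    def test_requires_enough_permutations(self, null_region):
        gm, y = null_region
        with pytest.raises(InvalidInputError, match="B"):
            permutation_test(gm, y, maf_partition(gm), B=50)

    def test_constant_phenotype_rejected(self, null_region):
        gm, _ = null_region
        with pytest.raises(InvalidInputError, match="constant"):
            permutation_test(gm, np.ones(gm.n_samples), maf_partition(gm), B=100)

    def test_extreme_rank_gives_minimum_p(self, rng):
        """A planted strong effect should reach the permutation floor 1/(B+1)."""
        n, l = 400, 6
        g = rng.binomial(2, 0.3, size=(n, l))
        y = g[:, 0] * 2.0 + rng.normal(scale=0.3, size=n)
        gm = GenotypeMatrix(
            values=g, variant_ids=[f"v{i}" for i in range(l)], positions=np.arange(l)
        )
        part = partition_from_labels(["a"] * 3 + ["b"] * 3)
        res = permutation_test(gm, y, part, B=200, seed=5, mode="theoretical")
        assert res.p_value == pytest.approx(1 / 201)
        assert res.p_value_score == pytest.approx(1 / 201)

    def test_result_invariants(self, null_region):
        gm, y = null_region
        res = permutation_test(gm, y, maf_partition(gm, 0.2), B=150, seed=1)
        assert res.T1 == pytest.approx(res.H.sum(), rel=1e-10)
        assert res.t.sum() == pytest.approx(res.T0, rel=1e-8)
        assert 0 < res.p_value <= 1
        assert res.df == len(res.group_names)

    def test_single_group_rank_matches_score_test(self, rng):
        """K=1: T1 is a monotone transform of T0, so permutation p-values agree."""
        n, l = 200, 5
        g = rng.binomial(2, 0.3, size=(n, l))
        gm = GenotypeMatrix(
            values=g, variant_ids=[f"v{i}" for i in range(l)], positions=np.arange(l)
        )
        y = rng.normal(size=n) + 0.3 * g[:, 1]
        part = partition_from_labels(["g"] * l)
        res = permutation_test(gm, y, part, B=300, seed=2, mode="theoretical")
        assert res.p_value == pytest.approx(res.p_value_score)

    def test_seed_reproducibility(self, null_region):
        gm, y = null_region
        part = maf_partition(gm, 0.2)
        r1 = permutation_test(gm, y, part, B=120, seed=9)
        r2 = permutation_test(gm, y, part, B=120, seed=9)
        assert r1.p_value == r2.p_value and r1.T1 == r2.T1

    def test_split_cdf_mode_runs(self, null_region):
        gm, y = null_region
        res = permutation_test(
            gm, y, maf_partition(gm, 0.2), B=200, seed=3, split_cdf=True
        )
        assert 0 < res.p_value <= 1

    def test_null_calibration_both_modes(self, rng):
        """Type-I error at 0.05 within the binomial 99% band; p stochastically >= uniform."""
        n_reps, n, l, b = 400, 120, 8, 150
        maf = rng.uniform(0.05, 0.4, size=l)
        alpha = 0.05
        for mode in ("theoretical", "empirical-cdf"):
            pvals = []
            for i in range(n_reps):
                g = rng.binomial(2, maf, size=(n, l))
                g[:, g.std(axis=0) == 0] = rng.binomial(2, 0.3, size=n)[:, None]
                gm = GenotypeMatrix(
                    values=g, variant_ids=[f"v{i}" for i in range(l)], positions=np.arange(l)
                )
                y = rng.normal(size=n)
                part = partition_from_labels(["a"] * 4 + ["b"] * 4)
                pvals.append(
                    permutation_test(gm, y, part, B=b, seed=int(rng.integers(2**31)), mode=mode).p_value
                )
            pvals = np.asarray(pvals)
            rej = (pvals <= alpha).mean()
            lo = stats.binom.ppf(0.005, n_reps, alpha) / n_reps
            hi = stats.binom.ppf(0.995, n_reps, alpha) / n_reps
            assert lo <= rej <= hi, f"{mode}: rejection {rej} outside [{lo}, {hi}]"
            # permutation validity: P(p <= u) <= u + noise, check at a few u
            for u in (0.1, 0.25, 0.5):
                assert (pvals <= u).mean() <= u + 3 * np.sqrt(u * (1 - u) / n_reps)
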