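"""Subgroup partitioning, moments, and Fisher-z correlation samples."""

import logging
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from gdaa import (
    ConfigError,
    DegenerateDataError,
    FISHER_CLAMP,
    compute_subgroup_moments,
    correlation_sample,
    fisher_transform,
    partition_subgroups,
    pearson_correlation,
    prepare_group,
)
from helpers import naive_correlation_matrices


class TestPartition:
    def test_even_split(self):
        part = partition_subgroups(100, 10)
        assert part.sizes == (10,) * 10

    def test_uneven_split_spreads_remainder(self):
        assert partition_subgroups(7, 3).sizes == (3, 2, 2)

    def test_subgroup_of_one_rejected(self):
        with pytest.raises(ConfigError):
            partition_subgroups(5, 3)
        with pytest.raises(ConfigError):
            partition_subgroups(10, 0)

    @given(n=st.integers(4, 60), data=st.data())
    def test_partition_properties(self, n, data):
        G = data.draw(st.integers(1, n // 2))
        part = partition_subgroups(n, G)
        sizes = part.sizes
        assert min(sizes) >= 2
        assert max(sizes) - min(sizes) <= 1
        all_idx = np.concatenate(part.subgroups)
        assert np.array_equal(np.sort(all_idx), np.arange(n))


class TestMoments:
    def test_direct_arithmetic(self):
        part = partition_subgroups(4, 2)
        mom = compute_subgroup_moments(np.array([[1.0, 2.0, 3.0, 4.0]]), part)
        assert np.array_equal(mom.sums, [[3.0, 7.0]])
        assert np.array_equal(mom.sums_sq, [[5.0, 25.0]])

    def test_zero_matrix(self):
        part = partition_subgroups(6, 2)
        mom = compute_subgroup_moments(np.zeros((3, 6)), part)
        assert not mom.sums.any() and not mom.sums_sq.any()

    def test_matches_naive_double_loop(self, rng):
        values = rng.normal(size=(10, 8))
        part = partition_subgroups(8, 2)
        mom = compute_subgroup_moments(values, part)
        for i in range(10):
            for j, idx in enumerate(part.subgroups):
                s = sq = 0.0
                for l in idx:
                    s += values[i, l]
                    sq += values[i, l] ** 2
                assert mom.sums[i, j] == pytest.approx(s, abs=1e-12)
                assert mom.sums_sq[i, j] == pytest.approx(sq, abs=1e-12)

    def test_cauchy_schwarz_bound(self, rng):
        values = rng.normal(size=(6, 12))
        part = partition_subgroups(12, 3)
        mom = compute_subgroup_moments(values, part)
        sizes = np.array(part.sizes, dtype=float)
        assert np.all(mom.sums_sq >= mom.sums**2 / sizes[None, :] - 1e-9)


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (6, 4, 2), -1.0),
            ((1, 2, 3), (1, 3, 2), 0.5),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_convention(self, caplog):
        with caplog.at_level(logging.WARNING, logger="gdaa"):
            assert pearson_correlation((1, 2, 3), (5, 5, 5)) == 0.0
        assert "zero-variance" in caplog.text
        with pytest.raises(DegenerateDataError):
            pearson_correlation((1, 2, 3), (5, 5, 5), strict=True)

    def test_usage_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0], [2.0])
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_matches_scipy(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 9))
            expected = scipy.stats.pearsonr(x, y).statistic
            assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-10)

    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 100),
    )
    def test_affine_equivariance(self, a, b, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=(2, 8))
        base = pearson_correlation(x, y)
        assert pearson_correlation(a * x + b, y) == pytest.approx(base, abs=1e-9)
        assert pearson_correlation(-a * x + b, y) == pytest.approx(-base, abs=1e-9)


class TestFisher:
    def test_known_values(self):
        assert fisher_transform(0.0) == 0.0
        assert fisher_transform(math.tanh(1.0)) == pytest.approx(1.0, abs=1e-12)

    def test_clamp_keeps_extremes_finite(self):
        w = fisher_transform(1.0)
        assert math.isfinite(w)
        # rel 1e-6: 1 − (1 − 1e-12) does not reproduce 1e-12 exactly in floats
        assert w == pytest.approx(0.5 * math.log((2.0 - 1e-12) / 1e-12), rel=1e-6)
        assert fisher_transform(-1.0) == -w

    def test_odd_and_monotone(self):
        grid = np.linspace(-0.99, 0.99, 41)
        vals = [fisher_transform(r) for r in grid]
        assert np.all(np.diff(vals) > 0)
        for r in grid:
            assert fisher_transform(-r) == -fisher_transform(r)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_transform(1.001)


class TestCorrelationSample:
    def test_matches_naive_pairwise_oracle(self, rng):
        values = rng.normal(size=(6, 8))
        part = partition_subgroups(8, 2)
        sample = correlation_sample(values, part)
        naive = naive_correlation_matrices(values, part)
        for k in range(2):
            assert np.max(np.abs(sample.w[k] - naive[k])) < 1e-10

    def test_symmetric_with_zero_diagonal(self, rng):
        values = rng.normal(size=(5, 12))
        part = partition_subgroups(12, 3)
        sample = correlation_sample(values, part)
        for w in sample.w:
            assert np.array_equal(w, w.T)
            assert not np.diag(w).any()
            assert np.isfinite(w).all()

    def test_identical_genes_hit_the_clamp(self):
        values = np.vstack([[1.0, 2.0, 3.0, 4.0]] * 2)
        part = partition_subgroups(4, 1)
        sample = correlation_sample(values, part)
        assert sample.w[0][0, 1] == pytest.approx(float(np.arctanh(FISHER_CLAMP)))

    def test_moments_path_matches_two_pass_formula(self, rng):
        values = rng.normal(loc=3.0, size=(8, 16))
        part = partition_subgroups(16, 2)
        sample = correlation_sample(values, part)
        for k, idx in enumerate(part.subgroups):
            r_two_pass = np.clip(np.corrcoef(values[:, idx]), -FISHER_CLAMP, FISHER_CLAMP)
            w = np.arctanh(r_two_pass)
            np.fill_diagonal(w, 0.0)
            assert np.allclose(sample.w[k], w, rtol=1e-9, atol=1e-9)

    def test_strict_mode_raises_on_flat_gene(self):
        values = np.vstack([np.ones(8), np.arange(8.0)])
        part = partition_subgroups(8, 2)
        with pytest.raises(DegenerateDataError):
            prepare_group(values, part, strict=True)
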