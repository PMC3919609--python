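"""Expected-unique formula, diversity reports and positional bias."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfselect import (
    VariantCounts,
    diversity_report,
    expected_unique,
    positional_bias,
    simulate_library,
    theoretical_size,
)
from zfselect.diversity import subsample_unique
from zfselect.reads import InputError


@pytest.mark.parametrize("i,expected", [(1, 32), (5, 33_554_432),
                                        (6, 1_073_741_824)])
def test_theoretical_size(scheme, i, expected):
    assert theoretical_size(i, scheme) == expected


def test_theoretical_size_rejects_nonpositive(scheme):
    with pytest.raises(InputError):
        theoretical_size(0, scheme)


def test_expected_unique_boundaries():
    assert expected_unique(0, 10) == 0.0
    for N in (1, 2, 100, 1e9):
        assert expected_unique(1, N) == pytest.approx(1.0)
    with pytest.raises(InputError):
        expected_unique(-1, 10)


def test_expected_unique_saturation_limit():
    n = N = 10**6
    assert expected_unique(n, N) / N == pytest.approx(1 - math.exp(-1), abs=1e-3)


def test_expected_unique_stable_at_large_N():
    """Stable evaluation agrees with exact rational arithmetic up to N=1e10."""
    from fractions import Fraction

    for N, n in [(100, 50), (32**5, 1000), (10**10, 1000)]:
        exact = float(N * (1 - (Fraction(N - 1, N)) ** n))
        assert expected_unique(n, N) == pytest.approx(exact, rel=1e-12)
    # the naive float form loses the leading digits at this scale
    assert expected_unique(1000, 10**10) < 1000


def test_expected_unique_against_monte_carlo_oracle():
    """Agreement with direct uniform-sampling simulation at N=100, n=50."""
    N, n, reps = 100, 50, 100_000
    rng = np.random.default_rng(2024)
    draws = rng.integers(0, N, size=(reps, n))
    uniques = np.array([len(np.unique(row)) for row in draws])
    mc_mean = uniques.mean()
    se = uniques.std(ddof=1) / math.sqrt(reps)
    assert abs(expected_unique(n, N) - mc_mean) <= 3 * se


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    n=st.integers(min_value=2, max_value=10**6),
    N=st.integers(min_value=2, max_value=10**9),
)
def test_expected_unique_monotone(n, N):
    u = expected_unique(n, N)
    assert 0 < u <= min(n, N)
    u_deeper = expected_unique(n + 1, N)
    # ΔU for N -> N+1 is O(n²/N²), unresolvable in floats at large N, so
    # monotonicity in pool size is checked over a doubling instead
    u_bigger = expected_unique(n, 2 * N)
    assert u_deeper >= u
    if u < N * (1 - 1e-9):  # strict until float saturation at U -> N
        assert u_deeper > u
        assert u_bigger > u


@settings(max_examples=30, derandomize=True, deadline=None)
@given(N=st.integers(min_value=10**6, max_value=10**9))
def test_shallow_depth_nearly_all_unique(N):
    # U/n ~= 1 - (n-1)/(2N), so at n = sqrt(N) the all-unique regime needs
    # library-scale N; deep-sequencing pools are comfortably in it
    n = int(math.isqrt(N))
    assert expected_unique(n, N) / n >= 0.999


def test_diversity_report_uniform_pool(scheme):
    """A uniform draw from N=32^3 matches the expectation within ~1%."""
    n = 100_000
    reads = simulate_library(n, 3, scheme, seed=11)
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    report = diversity_report(VariantCounts(counts), 3, scheme, seed=0)
    assert report["total_reads"] == n
    assert report["theoretical_size"] == 32**3
    assert 0.99 <= report["observed_over_expected"] <= 1.01


def test_diversity_report_degenerate_pool(scheme):
    pool = VariantCounts({"CAGGGCAACAAGTCC": 5000})
    report = diversity_report(pool, 5, scheme, seed=0)
    assert report["observed_unique"] == 1
    assert report["observed_over_expected"] < 0.01
    # 4.5e7 reads over 32^6: the fraction-of-max bookkeeping at 1 dp
    assert round(100 * 4.5e7 / theoretical_size(6, scheme), 1) == 4.2


def test_diversity_report_validates_input(scheme):
    with pytest.raises(InputError):
        diversity_report(VariantCounts({}), 5, scheme)
    with pytest.raises(InputError):
        diversity_report(VariantCounts({"ACGACG": 1}), 5, scheme)


def test_subsampling_full_depth_is_exact(scheme):
    reads = simulate_library(5000, 2, scheme, seed=3)
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    pool = VariantCounts(counts)
    rng = np.random.default_rng(0)
    assert subsample_unique(pool, pool.total, rng) == pool.n_unique
    assert subsample_unique(pool, 0, rng) == 0
    half = subsample_unique(pool, pool.total // 2, rng)
    assert 0 < half <= pool.n_unique


def test_positional_bias_recovers_planted_skew(scheme):
    """A 0.7/0.3 G:C skew at one S slot shows up in the table."""
    n = 40_000
    bias = {3: {"G": 0.7, "C": 0.3}}
    reads = simulate_library(n, 2, scheme, bias=bias, seed=5)
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    table = positional_bias(VariantCounts(counts), scheme)
    s_slots = table[(table.codon_slot == 3) & (table.base == "G")]
    sigma = math.sqrt(0.7 * 0.3 / n)
    for freq in s_slots.observed_freq:
        assert abs(freq - 0.7) < 5 * sigma
    # disallowed bases at the S slot carry expected frequency 0
    disallowed = table[(table.codon_slot == 3) & table.base.isin(["A", "T"])]
    assert (disallowed.expected_freq == 0).all()
    assert (disallowed.observed_freq == 0).all()


def test_positional_bias_uniform_pool_unbiased(scheme):
    n = 40_000
    reads = simulate_library(n, 2, scheme, seed=8)
    counts: dict[str, int] = {}
    for r in reads:
        counts[r] = counts.get(r, 0) + 1
    table = positional_bias(VariantCounts(counts), scheme)
    n_slots = table[(table.codon_slot != 3)]
    sigma = math.sqrt(0.25 * 0.75 / n)
    assert (abs(n_slots.observed_freq - 0.25) < 5 * sigma).all()
    # every position's observed frequencies sum to 1
    sums = table.groupby("position").observed_freq.sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
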