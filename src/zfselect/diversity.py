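"""Library diversity: expected-unique curves, observed diversity, positional bias.

For a library with ``i`` NNS-randomized codons the number of possible DNA
variants is N = 32^i.  When n reads are drawn uniformly at random from such a
pool the expected number of distinct variants is

    U(n, N) = N * (1 - (1 - 1/N)^n)

which rises from U ≈ n at shallow depth (every read unique) and saturates at
N.  Observed pools are compared against this uniform expectation, both at
full depth and along a subsampled depth grid, and per-position base
frequencies are tested against the uniform-over-allowed-bases expectation of
the scheme to quantify synthesis bias at N and S slots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codons import DegenerateScheme
from .reads import InputError, VariantCounts


def theoretical_size(i: int, scheme: DegenerateScheme) -> int:
    """Number of possible DNA variants for ``i`` variable codons: |codons|^i."""
    if i <= 0:
        raise InputError("number of variable codons must be >= 1")
    return len(scheme.codons) ** i


def expected_unique(n: float, N: float) -> float:
    """Expected distinct variants among n uniform draws from N possibilities.

    Evaluated as ``-N * expm1(n * log1p(-1/N))`` so that the (1 - 1/N)^n
    factor keeps full relative precision at N ~ 1e9 and beyond, where the
    naive power underflows to 1 - tiny.
    """
    if n < 0:
        raise InputError("sequencing depth must be >= 0")
    if N < 1:
        raise InputError("theoretical size must be >= 1")
    if n == 0:
        return 0.0
    if N == 1:
        return 1.0
    return -N * math.expm1(n * math.log1p(-1.0 / N))


@dataclass
class DiversityCurve:
    """Expected (and optionally observed) unique counts along a depth grid."""

    theoretical_size: int
    depths: np.ndarray
    expected: np.ndarray
    observed: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"depth": self.depths, "expected_unique": self.expected}
        if self.observed is not None:
            data["observed_unique"] = self.observed
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def subsample_unique(
    pool: VariantCounts, depth: int, rng: np.random.Generator
) -> int:
    """Unique variants in a without-replacement subsample of ``depth`` reads.

    Models how diversity accumulates as sequencing depth grows: reads are
    drawn from the observed multiset without replacement (multivariate
    hypergeometric), so subsampling at full depth reproduces the observed
    unique count exactly.
    """
    total = pool.total
    if not 0 <= depth <= total:
        raise InputError("subsample depth must be in [0, total reads]")
    if depth == total:
        return pool.n_unique
    counts = np.fromiter(pool.counts.values(), dtype=np.int64)
    draw = rng.multivariate_hypergeometric(counts, depth)
    return int(np.count_nonzero(draw))


def diversity_report(
    pool: VariantCounts,
    i: int,
    scheme: DegenerateScheme,
    depth_grid: list[int] | None = None,
    seed: int | None = None,
) -> dict:
    """Full-depth diversity summary plus a subsampled observed/expected curve.

    Reports total reads n, observed unique count, the uniform expectation
    U(n, N), their ratio, and the sequencing depth as a percentage of the
    theoretical maximum N (1 decimal place, full precision kept alongside).
    """
    if pool.total == 0:
        raise InputError("empty pool")
    if pool.variant_length != 3 * i:
        raise InputError(
            "pool variant length %r != 3*i = %d" % (pool.variant_length, 3 * i)
        )
    N = theoretical_size(i, scheme)
    n = pool.total
    u_obs = pool.n_unique
    u_exp = expected_unique(n, N)
    fraction = n / N
    rng = np.random.default_rng(seed)
    if depth_grid is None:
        depth_grid = [int(round(n * f)) for f in (0.1, 0.25, 0.5, 0.75, 1.0)]
    depth_grid = sorted(set(min(d, n) for d in depth_grid if d >= 0))
    observed = np.array([subsample_unique(pool, d, rng) for d in depth_grid])
    expected = np.array([expected_unique(d, N) for d in depth_grid])
    curve = DiversityCurve(N, np.array(depth_grid), expected, observed)
    return {
        "total_reads": n,
        "theoretical_size": N,
        "observed_unique": u_obs,
        "expected_unique": u_exp,
        "observed_over_expected": u_obs / u_exp,
        "fraction_of_max": fraction,
        "percent_of_max_1dp": round(100.0 * fraction, 1),
        "curve": curve,
    }


def positional_bias(pool: VariantCounts, scheme: DegenerateScheme) -> pd.DataFrame:
    """Observed vs expected base frequencies per codon-position slot.

    Frequencies are read-count weighted.  Expected frequencies are uniform
    over the scheme's allowed bases at each slot (0 for disallowed bases).
    A chi-square statistic against that expectation is attached per position
    (computed over allowed bases only).
    """
    if pool.total == 0:
        raise InputError("empty pool")
    length = pool.variant_length
    assert length is not None and length % 3 == 0
    counts = np.zeros((length, 4), dtype=np.int64)
    base_index = {b: k for k, b in enumerate("ACGT")}
    for variant, c in pool.counts.items():
        for pos, base in enumerate(variant):
            counts[pos, base_index[base]] += c
    rows = []
    for pos in range(length):
        slot = pos % 3
        allowed = sorted(scheme.position_bases[slot])
        expected_freq = {
            b: (1.0 / len(allowed) if b in allowed else 0.0) for b in "ACGT"
        }
        obs = counts[pos]
        total = obs.sum()
        obs_allowed = np.array([obs[base_index[b]] for b in allowed], dtype=float)
        chi2, pval = stats.chisquare(obs_allowed)
        for b in "ACGT":
            rows.append(
                {
                    "position": pos,
                    "codon_slot": slot + 1,
                    "base": b,
                    "observed_freq": obs[base_index[b]] / total,
                    "expected_freq": expected_freq[b],
                    "chi2": chi2,
                    "p_value": pval,
                }
            )
    return pd.DataFrame(rows)
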