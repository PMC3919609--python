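"""Shared fixtures: schemes and seeded planted-signal pools."""

from __future__ import annotations

import numpy as np
import pytest

from zfselect import (
    ArtifactClone,
    BinderFamily,
    VariantCounts,
    nns_scheme,
    simulate_selection_pool,
)

# family centers verified to have normalized BLOSUM62 similarity 0.0
FAMILY_CENTERS = ("QGNKS", "WLFPM")
SELECTION_DEPTH = 10_000
SUBSTITUTION_RATE = 0.1
FAMILY_SHARE = 0.45
N_ARTIFACTS = 20
ARTIFACT_SHARE = 0.005  # x20 clones = 0.10 of the pool


@pytest.fixture(scope="session")
def scheme():
    return nns_scheme()


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def make_artifacts(scheme, n=N_ARTIFACTS, share=ARTIFACT_SHARE, seed=42):
    """Random multi-encoding proteins, each pinned to one fixed encoding.

    Kept at Hamming distance >= 3 from both family centers so artifact reads
    cannot merge into a planted binder protein.
    """
    rng = np.random.default_rng(seed)
    encodable = sorted(
        aa for aa, d in scheme.degeneracy_map.items() if aa != "*" and d > 0
    )
    artifacts = []
    seen = set()
    while len(artifacts) < n:
        protein = "".join(rng.choice(encodable, 5))
        if protein in seen:
            continue
        if scheme.encoding_count(protein) < 2:
            continue
        if any(_hamming(protein, c) < 3 for c in FAMILY_CENTERS):
            continue
        seen.add(protein)
        encoding = next(iter(scheme.enumerate_encodings(protein)))
        artifacts.append(ArtifactClone(protein, encoding, share))
    return artifacts


@pytest.fixture(scope="session")
def planted_selection(scheme):
    """The two-family planted selection pool used across filter/cluster tests.

    Two binder families at cross-similarity 0, 45% of reads each; twenty
    single-encoding artifact clones at 0.5% each; depth 10^4.
    """
    families = [
        BinderFamily(c, SUBSTITUTION_RATE, FAMILY_SHARE) for c in FAMILY_CENTERS
    ]
    artifacts = make_artifacts(scheme)
    reads, labels = simulate_selection_pool(
        families, artifacts, SELECTION_DEPTH, scheme=scheme, seed=7
    )
    counts: dict[str, int] = {}
    for read in reads:
        counts[read] = counts.get(read, 0) + 1
    return {
        "pool": VariantCounts(counts),
        "labels": labels,
        "families": families,
        "artifacts": artifacts,
    }
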