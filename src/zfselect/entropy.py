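"""Coding-entropy enrichment filter for selection pools.

A truly enriched protein in an NNS-library selection is sampled through many
of its synonymous DNA encodings, because independent library members carrying
different codons for the same helix all survive selection.  Background
artifacts (e.g. a clone amplified by jackpot PCR, or a contaminant) arrive
through a single DNA sequence.  The filter scores each protein by the Shannon
entropy of its observed encoding usage, normalized by the log of the number
of possible NNS encodings N:

    E = - sum_i p_i * ln(p_i) / ln(N)

where p_i is the relative observation frequency of encoding i within the
protein (unobserved encodings contribute 0).  E lies in [0, 1]; proteins are
retained iff E >= 0.25 or they admit only a single NNS encoding (N = 1, for
which E is defined as 0 but the criterion cannot apply).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .codons import DegenerateScheme, TranslationFlag, translate_variable_region
from .reads import VariantCounts

ENTROPY_THRESHOLD = 0.25


@dataclass
class ProteinObservation:
    """One protein with the per-encoding DNA read counts it was seen through."""

    aa_seq: str
    encoding_counts: dict[str, int]
    n_possible: int
    entropy: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.encoding_counts:
            raise ValueError("protein observed through zero encodings")
        if len(self.encoding_counts) > self.n_possible:
            raise ValueError(
                "%s observed via %d encodings but only %d are possible"
                % (self.aa_seq, len(self.encoding_counts), self.n_possible)
            )
        self.entropy = normalized_entropy(self.encoding_counts, self.n_possible)

    @property
    def total_count(self) -> int:
        return sum(self.encoding_counts.values())

    @property
    def single_encoding(self) -> bool:
        """True when only one NNS encoding exists for this protein."""
        return self.n_possible == 1


def normalized_entropy(encoding_counts: dict[str, int], n_possible: int) -> float:
    """Shannon entropy of encoding usage over ln(n_possible), in [0, 1].

    Base-invariant: any consistent log base gives the same ratio.  For
    n_possible == 1 the normalizer vanishes and E is defined as 0.
    """
    if n_possible < 1:
        raise ValueError("n_possible must be >= 1")
    total = sum(encoding_counts.values())
    if total < 1:
        raise ValueError("total count must be >= 1")
    if n_possible == 1:
        return 0.0
    h = 0.0
    for count in encoding_counts.values():
        if count > 0:
            p = count / total
            h -= p * math.log(p)
    e = h / math.log(n_possible)
    # guard tiny float excursions above 1 with uniform counts
    return min(e, 1.0)


def aggregate_by_protein(
    pool: VariantCounts, scheme: DegenerateScheme
) -> tuple[list[ProteinObservation], dict[str, int]]:
    """Group DNA variants by translated protein; exclude stop / non-scheme reads.

    Returns the observations (sorted by descending total count, then
    sequence) and a tally ``{"stop": reads, "non_scheme": reads}`` of
    excluded read counts; the conservation invariant
    ``sum(total_count) + stop + non_scheme == pool.total`` always holds.
    """
    by_protein: dict[str, dict[str, int]] = {}
    tally = {"stop": 0, "non_scheme": 0}
    for variant, count in pool.counts.items():
        protein, flag = translate_variable_region(variant, scheme)
        if flag is TranslationFlag.STOP:
            tally["stop"] += count
        elif flag is TranslationFlag.NON_SCHEME:
            tally["non_scheme"] += count
        else:
            assert protein is not None
            by_protein.setdefault(protein, {})[variant] = count
    observations = [
        ProteinObservation(aa, enc, scheme.encoding_count(aa))
        for aa, enc in by_protein.items()
    ]
    observations.sort(key=lambda o: (-o.total_count, o.aa_seq))
    return observations, tally


def entropy_filter(
    observations: list[ProteinObservation],
    threshold: float = ENTROPY_THRESHOLD,
) -> tuple[list[ProteinObservation], list[ProteinObservation]]:
    """Partition observations into (retained, discarded).

    Retained iff normalized entropy >= threshold (inclusive) OR the protein
    has a single possible NNS encoding.  No minimum read count is applied.
    """
    retained, discarded = [], []
    for obs in observations:
        if obs.single_encoding or obs.entropy >= threshold:
            retained.append(obs)
        else:
            discarded.append(obs)
    return retained, discarded


def retention_reason(obs: ProteinObservation,
                     threshold: float = ENTROPY_THRESHOLD) -> str:
    if obs.single_encoding:
        return "single_encoding"
    if obs.entropy >= threshold:
        return "entropy"
    return "low_entropy"


def observations_to_frame(
    observations: list[ProteinObservation],
    threshold: float = ENTROPY_THRESHOLD,
) -> pd.DataFrame:
    """Per-protein table: counts, possible/observed encodings, E, verdict."""
    rows = []
    for obs in observations:
        reason = retention_reason(obs, threshold)
        rows.append(
            {
                "aa_seq": obs.aa_seq,
                "total_count": obs.total_count,
                "n_possible": obs.n_possible,
                "observed_encodings": len(obs.encoding_counts),
                "entropy": obs.entropy,
                "retained": reason != "low_entropy",
                "reason": reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "aa_seq", "total_count", "n_possible", "observed_encodings",
            "entropy", "retained", "reason",
        ],
    )
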