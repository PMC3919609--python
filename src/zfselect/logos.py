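"""Position frequency matrices and sequence-logo data.

Protein logos summarize the helices that survived the entropy and clustering
filters, weighting each sequence by its read count.  DNA logos summarize
motif matches from binding-site pools; there the default sequence weight is
ln(1 + count) ("log" policy) so that a handful of jackpot sequences do not
dominate the column frequencies — raw-count and unit-weight policies are
available.  Output is a frequency matrix plus per-position information
content in bits; rendering is left to standard plotting tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

WEIGHT_POLICIES = ("log", "raw", "unit")


@dataclass
class FrequencyMatrix:
    """Positions x symbols frequency table with information content."""

    alphabet: str
    frequencies: np.ndarray  # (positions, |alphabet|), rows sum to 1
    weight_policy: str = "raw"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.shape[1] != len(self.alphabet):
            raise ValueError("matrix width must equal alphabet size")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")

    @property
    def n_positions(self) -> int:
        return self.frequencies.shape[0]

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits: log2|alphabet| - column Shannon entropy.

        No small-sample correction is applied.
        """
        p = self.frequencies
        h = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0).sum(axis=1)
        return math.log2(len(self.alphabet)) - h

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frequencies, columns=list(self.alphabet))

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(0, "position", np.arange(1, self.n_positions + 1))
        frame["information_bits"] = self.information_content()
        frame.to_csv(path, sep="\t", index=False)

    def to_transfac(self, name: str = "logo") -> str:
        """A transfac-like text block (integer-scaled weights) for logo tools."""
        lines = ["ID %s" % name, "BF synthetic", "P0 " + " ".join(self.alphabet)]
        scaled = np.round(self.frequencies * 1000).astype(int)
        for k, row in enumerate(scaled, start=1):
            lines.append("%02d " % k + " ".join(str(x) for x in row))
        lines.append("XX")
        lines.append("//")
        return "\n".join(lines) + "\n"


def _weighted_matrix(
    seq_weights: Mapping[str, float], alphabet: str, policy: str
) -> np.ndarray:
    if not seq_weights:
        raise ValueError("empty input")
    lengths = {len(s) for s in seq_weights}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    (length,) = lengths
    index = {a: k for k, a in enumerate(alphabet)}
    matrix = np.zeros((length, len(alphabet)))
    for seq, weight in seq_weights.items():
        if weight <= 0:
            raise ValueError("weights must be positive")
        for pos, symbol in enumerate(seq):
            try:
                matrix[pos, index[symbol]] += weight
            except KeyError:
                raise ValueError(
                    "symbol %r not in alphabet %r" % (symbol, alphabet)
                ) from None
    return matrix / matrix.sum(axis=1, keepdims=True)


def _apply_policy(counts: Mapping[str, int], policy: str) -> dict[str, float]:
    if policy not in WEIGHT_POLICIES:
        raise ValueError("unknown weight policy %r" % policy)
    if policy == "raw":
        return {s: float(c) for s, c in counts.items()}
    if policy == "unit":
        return {s: 1.0 for s in counts}
    return {s: math.log1p(c) for s, c in counts.items()}


def protein_logo(seq_counts: Mapping[str, int]) -> FrequencyMatrix:
    """Count-weighted residue frequencies for equal-length helix sequences."""
    weights = _apply_policy(seq_counts, "raw")
    return FrequencyMatrix(
        PROTEIN_ALPHABET, _weighted_matrix(weights, PROTEIN_ALPHABET, "raw"),
        weight_policy="raw",
    )


def dna_logo(
    match_counts: Mapping[str, int], weight_policy: str = "log"
) -> FrequencyMatrix:
    """Base frequencies for motif matches, weighted per the chosen policy.

    Default "log" weights each distinct sequence by ln(1 + count); "raw"
    uses counts directly and "unit" ignores counts.
    """
    weights = _apply_policy(match_counts, weight_policy)
    return FrequencyMatrix(
        DNA_ALPHABET, _weighted_matrix(weights, DNA_ALPHABET, weight_policy),
        weight_policy=weight_policy,
    )
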