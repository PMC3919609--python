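"""Binding-site pool processing: mismatch grouping, EM motif discovery, matches.

Binding-site selections recover 28-bp randomized promoter regions that
survived selection by a candidate zinc-finger protein.  After the >=2-count
filter, near-duplicate 28-mers (sequencing/PCR echoes of one site) are
greedily merged: variants are visited in descending count order and join the
first existing group whose representative is within 2 mismatches, else found
a new group.  The group representatives, weighted by their counts, feed a
fixed-width (10 bp, the footprint of three fingers) motif search: a
multi-start expectation-maximization under the one-occurrence-per-sequence
(OOPS) model with a uniform zero-order background.  The fitted motif is then
used to pull the best-matching 10-mer out of every original 28-mer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import InputError, VariantCounts

MOTIF_WIDTH = 10
MAX_MISMATCH = 2
_BASES = "ACGT"
_BASE_INDEX = {b: k for k, b in enumerate(_BASES)}
_PSEUDOCOUNT = 0.25


class InsufficientDataError(ValueError):
    """Too few sequences to fit a motif."""


@dataclass
class SiteGroup:
    """A set of near-identical 28-mers represented by its highest-count member."""

    representative: str
    members: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.members.values())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InputError("length mismatch in Hamming distance")
    return sum(x != y for x, y in zip(a, b))


def greedy_group(
    site_counts: VariantCounts, max_mismatch: int = MAX_MISMATCH
) -> list[SiteGroup]:
    """Greedy single-pass grouping of sites within ``max_mismatch`` mismatches.

    Variants are processed in descending count order (ties lexicographic);
    each joins the first existing group — groups scanned in creation order —
    whose *representative* is within the mismatch budget, else it founds a
    new group.  Because of the processing order the founder is always the
    highest-count member, hence the representative.  Deterministic and
    invariant to input ordering.
    """
    lengths = {len(v) for v in site_counts.counts}
    if len(lengths) > 1:
        raise InputError("mixed variant lengths: %r" % sorted(lengths))
    ordered = sorted(site_counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    groups: list[SiteGroup] = []
    for variant, count in ordered:
        for group in groups:
            if hamming(variant, group.representative) <= max_mismatch:
                group.members[variant] = count
                break
        else:
            groups.append(SiteGroup(variant, {variant: count}))
    return groups


# ---------------------------------------------------------------------------
# motif model


@dataclass
class Motif:
    """A fixed-width nucleotide position frequency matrix.

    ``pfm`` has shape (width, 4) with columns ordered A, C, G, T; every row
    sums to 1.  For EM-fitted motifs ``ll_trajectory`` records the EM
    objective (data log-likelihood plus the Dirichlet-smoothing log prior
    implied by the pseudocounts) at each iteration — non-decreasing by the
    EM guarantee — and ``log_likelihood`` is its final value.
    """

    pfm: np.ndarray
    log_likelihood: float = float("nan")
    ll_trajectory: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4:
            raise InputError("pfm must be (width, 4)")
        if not np.allclose(self.pfm.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("pfm rows must sum to 1")

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[k] for k in self.pfm.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (vs uniform background)."""
        p = self.pfm
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        return 2.0 - h

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pfm, columns=list(_BASES))

    def to_meme_text(self, name: str = "MOTIF_1") -> str:
        """Render in MEME minimal motif format."""
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25",
            "",
            "MOTIF %s" % name,
            "letter-probability matrix: alength= 4 w= %d" % self.width,
        ]
        for row in self.pfm:
            lines.append(" ".join("%.6f" % x for x in row))
        return "\n".join(lines) + "\n"


def load_meme_motif(path) -> Motif:
    """Read the first motif from a MEME minimal-format text file."""
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        in_matrix = False
        for line in fh:
            line = line.strip()
            if line.startswith("letter-probability matrix"):
                in_matrix = True
                parts = line.split()
                if "w=" in parts:
                    width = int(parts[parts.index("w=") + 1])
                continue
            if in_matrix:
                if not line or line.startswith("MOTIF"):
                    break
                rows.append([float(x) for x in line.split()])
                if width is not None and len(rows) == width:
                    break
    if not rows:
        raise InputError("no letter-probability matrix found in %s" % path)
    return Motif(np.array(rows))


def _encode(sequences: list[str]) -> np.ndarray:
    try:
        return np.array(
            [[_BASE_INDEX[b] for b in seq] for seq in sequences], dtype=np.int64
        )
    except KeyError as exc:
        raise InputError("non-ACGT base %s in site sequence" % exc) from exc


def _oops_em(
    encoded: np.ndarray,
    weights: np.ndarray,
    pfm0: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> Motif:
    """EM for the OOPS model: one motif occurrence per sequence, uniform
    offset prior, uniform 0-order background outside the motif window."""
    n_seq, seq_len = encoded.shape
    width = pfm0.shape[0]
    n_offsets = seq_len - width + 1
    # windows[s, o, j] = base at offset o + position j of sequence s
    idx = np.arange(n_offsets)[:, None] + np.arange(width)[None, :]
    windows = encoded[:, idx]  # (n_seq, n_offsets, width)
    onehot = np.eye(4)[windows]  # (n_seq, n_offsets, width, 4)
    pfm = pfm0.copy()
    log_bg = np.log(0.25)
    obj_prev = -np.inf
    trajectory: list[float] = []
    for _ in range(max_iter):
        log_pfm = np.log(pfm)
        # log P(window | motif) - log P(window | background)
        log_odds = np.einsum("sowb,wb->so", onehot, log_pfm) - width * log_bg
        # posterior over offsets; background part of the sequence cancels
        m = log_odds.max(axis=1, keepdims=True)
        post = np.exp(log_odds - m)
        norm = post.sum(axis=1, keepdims=True)
        post /= norm
        # weighted log-likelihood up to a constant background term
        ll = float(
            (weights * (np.log(norm[:, 0]) + m[:, 0] - np.log(n_offsets))).sum()
        )
        # pseudocounts act as a Dirichlet prior; the EM objective that is
        # guaranteed non-decreasing is the penalized log-likelihood
        obj = ll + _PSEUDOCOUNT * float(log_pfm.sum())
        trajectory.append(obj)
        # M-step: expected weighted base counts per motif column
        counts = np.einsum("so,sowb->wb", post * weights[:, None], onehot)
        counts += _PSEUDOCOUNT
        pfm = counts / counts.sum(axis=1, keepdims=True)
        if obj - obj_prev < tol and np.isfinite(obj_prev):
            break
        obj_prev = obj
    return Motif(pfm, log_likelihood=trajectory[-1], ll_trajectory=trajectory)


def find_motif(
    site_counts: VariantCounts | dict[str, int],
    width: int = MOTIF_WIDTH,
    n_starts: int = 8,
    seed: int | None = None,
    min_sequences: int = 5,
) -> Motif:
    """Multi-start OOPS EM motif discovery over weighted representatives.

    Each start seeds the position frequency matrix from a randomly chosen
    window of a randomly chosen sequence (smoothed toward uniform), runs EM
    to convergence, and the fit with the highest final log-likelihood wins.
    Seeded and reproducible; the per-run log-likelihood trajectory is kept on
    the returned motif (it is non-decreasing, an EM guarantee used as a
    self-check).
    """
    counts = site_counts.counts if isinstance(site_counts, VariantCounts) else site_counts
    items = sorted(counts.items())
    if len(items) < min_sequences:
        raise InsufficientDataError(
            "need at least %d sequences to fit a motif, got %d"
            % (min_sequences, len(items))
        )
    sequences = [s for s, _ in items]
    weights = np.array([c for _, c in items], dtype=float)
    seq_len = len(sequences[0])
    if any(len(s) != seq_len for s in sequences):
        raise InputError("site sequences must share one length")
    if width > seq_len:
        raise InputError("motif width exceeds sequence length")
    encoded = _encode(sequences)
    rng = np.random.default_rng(seed)
    best: Motif | None = None
    n_offsets = seq_len - width + 1
    for _ in range(n_starts):
        s = rng.integers(len(sequences))
        o = rng.integers(n_offsets)
        seed_window = encoded[s, o : o + width]
        pfm0 = np.full((width, 4), 0.15)
        pfm0[np.arange(width), seed_window] = 0.55
        fit = _oops_em(encoded, weights, pfm0)
        fit = _shift_refine(fit, encoded, weights)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def _shift_refine(fit: Motif, encoded: np.ndarray, weights: np.ndarray,
                  max_shift: int = 2) -> Motif:
    """Escape phase-shifted local optima by re-fitting from shifted columns.

    EM on offset models often converges to the planted motif slid by a
    column or two.  Each candidate shift rolls the converged matrix and
    fills the vacated columns with uniform frequencies; if a re-fit from the
    shifted start improves the objective it is accepted and the search
    restarts from the improvement.
    """
    improved = True
    while improved:
        improved = False
        for shift in range(-max_shift, max_shift + 1):
            if shift == 0:
                continue
            shifted = np.full_like(fit.pfm, 0.25)
            if shift > 0:
                shifted[shift:] = fit.pfm[:-shift]
            else:
                shifted[:shift] = fit.pfm[-shift:]
            candidate = _oops_em(encoded, weights, shifted)
            if candidate.log_likelihood > fit.log_likelihood + 1e-9:
                fit = candidate
                improved = True
    return fit


def extract_matches(
    motif: Motif, site_counts: VariantCounts | dict[str, int]
) -> pd.DataFrame:
    """Best-scoring motif match per original 28-mer.

    Scores every offset by log-odds against the uniform background and
    returns, per sequence, the best offset and its 10-mer together with the
    originating read count.  Ties go to the smallest offset.
    """
    counts = site_counts.counts if isinstance(site_counts, VariantCounts) else site_counts
    sequences = sorted(counts)
    if not sequences:
        raise InputError("no sequences to extract matches from")
    encoded = _encode(sequences)
    width = motif.width
    n_offsets = encoded.shape[1] - width + 1
    idx = np.arange(n_offsets)[:, None] + np.arange(width)[None, :]
    windows = encoded[:, idx]
    log_odds_matrix = np.log(motif.pfm) - np.log(0.25)
    scores = log_odds_matrix[np.arange(width)[None, None, :], windows].sum(axis=2)
    best_offsets = scores.argmax(axis=1)
    rows = []
    for s_idx, (seq, offset) in enumerate(zip(sequences, best_offsets)):
        offset = int(offset)
        rows.append(
            {
                "sequence": seq,
                "offset": offset,
                "match": seq[offset : offset + width],
                "count": counts[seq],
                "score": float(scores[s_idx, offset]),
            }
        )
    return pd.DataFrame(rows, columns=["sequence", "offset", "match", "count", "score"])
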