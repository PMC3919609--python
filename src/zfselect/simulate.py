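"""Synthetic selection pools with planted signal and full ground truth.

Three generators mirror the three kinds of pools the pipeline consumes:

* ``simulate_library`` — an unselected degenerate library: variable regions
  drawn i.i.d. from the scheme's per-position base distributions (optionally
  biased, emulating oligo-synthesis bias), optionally wrapped in constant
  flanks with a controlled constant-region error rate.
* ``simulate_selection_pool`` — a post-selection pool: planted binder
  families (a center helix observed through randomly substituted variants,
  each read expressed through an NNS encoding sampled uniformly at random —
  the diverse-coding signature the entropy filter keys on), plus background
  artifact clones (a multi-encoding protein seen through one fixed DNA
  sequence), plus uniform library background.
* ``simulate_binding_site_pool`` — 28-mers carrying a 10-bp motif sampled
  from a position frequency matrix at a random offset, with geometric
  duplicate counts so the >=2-count filter has something to do.

Every generator is driven by a single integer seed and returns ground-truth
labels alongside the reads, so recovery rates can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import AMINO_ACIDS, DegenerateScheme, nns_scheme
from .reads import SelectionLayout

_DNA = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Inconsistent simulation specification."""


@dataclass(frozen=True)
class BinderFamily:
    """A planted specificity family around a center helix.

    ``substitution_rate`` is the per-position probability that a read's
    protein differs from the center at that position (substitutions drawn
    uniformly over the other scheme-encodable residues); ``share`` is the
    family's fraction of pool reads.
    """

    center: str
    substitution_rate: float = 0.1
    share: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise SimulationError("substitution_rate must be in [0, 1]")
        if not 0.0 < self.share <= 1.0:
            raise SimulationError("share must be in (0, 1]")


@dataclass(frozen=True)
class ArtifactClone:
    """A background clone: one protein always observed via one fixed encoding."""

    protein: str
    encoding: str
    share: float

    def __post_init__(self) -> None:
        if len(self.encoding) != 3 * len(self.protein):
            raise SimulationError("encoding length must be 3x protein length")


def _position_probs(
    scheme: DegenerateScheme,
    bias: Mapping[int, Mapping[str, float]] | None,
) -> list[np.ndarray]:
    """Per-codon-slot base probabilities over ACGT (slots keyed 1..3)."""
    probs = []
    for slot in (1, 2, 3):
        allowed = scheme.position_bases[slot - 1]
        if bias and slot in bias:
            p = dict(bias[slot])
            if set(p) - allowed:
                raise SimulationError(
                    "bias at slot %d assigns mass to disallowed bases %r"
                    % (slot, sorted(set(p) - allowed))
                )
            total = sum(p.values())
            vec = np.array([p.get(b, 0.0) / total for b in "ACGT"])
        else:
            vec = np.array([1.0 / len(allowed) if b in allowed else 0.0
                            for b in "ACGT"])
        probs.append(vec)
    return probs


def simulate_library(
    n: int,
    i: int,
    scheme: DegenerateScheme | None = None,
    bias: Mapping[int, Mapping[str, float]] | None = None,
    seed: int | None = None,
    layout: SelectionLayout | None = None,
    constant_error_rate: float = 0.0,
) -> list[str]:
    """Draw ``n`` unselected-library reads with ``i`` variable codons.

    Without a layout, reads are bare variable regions (3i nt).  With a
    layout, each read is upstream + variable + downstream and every constant
    position is independently corrupted to a random other base with
    probability ``constant_error_rate`` (emulating the reads the structural
    filter is meant to reject).
    """
    if n < 0:
        raise SimulationError("read count must be >= 0")
    scheme = scheme or nns_scheme()
    rng = np.random.default_rng(seed)
    probs = _position_probs(scheme, bias)
    columns = []
    for pos in range(3 * i):
        p = probs[pos % 3]
        columns.append(rng.choice(4, size=n, p=p))
    variable = ["".join(_DNA[idx] for idx in row) for row in np.array(columns).T] \
        if n else []
    if layout is None:
        return variable
    reads = []
    for var in variable:
        read = layout.upstream + var + layout.downstream
        if constant_error_rate > 0:
            read = _corrupt_constant(read, layout, constant_error_rate, rng)
        reads.append(read)
    return reads


def _corrupt_constant(
    read: str, layout: SelectionLayout, rate: float, rng: np.random.Generator
) -> str:
    vstart, vend = layout.variable_span
    chars = list(read)
    for pos in list(range(vstart)) + list(range(vend, len(chars))):
        if rng.random() < rate:
            others = [b for b in "ACGT" if b != chars[pos]]
            chars[pos] = others[rng.integers(3)]
    return "".join(chars)


def simulate_selection_pool(
    families: Sequence[BinderFamily],
    artifacts: Sequence[ArtifactClone],
    depth: int,
    scheme: DegenerateScheme | None = None,
    seed: int | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """A selection pool of bare variable regions with per-read ground truth.

    Pool composition follows the family/artifact shares; the remaining share
    is uniform library background.  Family reads substitute the center
    protein per-position at the family rate, then encode each residue with a
    codon drawn uniformly from its scheme codons (uniform over the NNS
    encoding set).  Artifact reads are the clone's fixed DNA.  Returns
    ``(reads, labels)`` where labels has one row per read: source
    ("binder"/"artifact"/"background"), family center or artifact protein,
    the emitted protein and DNA.
    """
    if not families and not artifacts:
        raise SimulationError("need at least one planted family or artifact")
    scheme = scheme or nns_scheme()
    shares = [f.share for f in families] + [a.share for a in artifacts]
    if sum(shares) > 1.0 + 1e-9:
        raise SimulationError("shares sum to more than 1")
    background_share = max(0.0, 1.0 - sum(shares))
    rng = np.random.default_rng(seed)
    encodable = sorted(
        aa for aa in AMINO_ACIDS if scheme.degeneracy_map.get(aa, 0) > 0
    )
    codon_pools = {aa: scheme.codons_for(aa) for aa in encodable}
    n_sources = len(families) + len(artifacts) + 1
    counts = rng.multinomial(depth, np.array(shares + [background_share]))
    reads: list[str] = []
    rows: list[dict] = []
    for fam, n_reads in zip(families, counts[: len(families)]):
        for _ in range(n_reads):
            protein = _mutate(fam.center, fam.substitution_rate, encodable, rng)
            dna = "".join(
                codon_pools[aa][rng.integers(len(codon_pools[aa]))]
                for aa in protein
            )
            reads.append(dna)
            rows.append({"source": "binder", "origin": fam.center,
                         "protein": protein, "dna": dna})
    for art, n_reads in zip(artifacts, counts[len(families): n_sources - 1]):
        for _ in range(n_reads):
            reads.append(art.encoding)
            rows.append({"source": "artifact", "origin": art.protein,
                         "protein": art.protein, "dna": art.encoding})
    n_background = counts[-1]
    if n_background:
        fam_len = len(families[0].center) if families else len(artifacts[0].protein)
        for dna in simulate_library(int(n_background), fam_len, scheme,
                                    seed=int(rng.integers(2**31))):
            reads.append(dna)
            rows.append({"source": "background", "origin": None,
                         "protein": None, "dna": dna})
    order = rng.permutation(len(reads))
    reads = [reads[k] for k in order]
    labels = pd.DataFrame([rows[k] for k in order]).reset_index(drop=True)
    return reads, labels


def _mutate(center: str, rate: float, encodable: list[str],
            rng: np.random.Generator) -> str:
    if rate == 0:
        return center
    out = []
    for aa in center:
        if rng.random() < rate:
            alternatives = [x for x in encodable if x != aa]
            out.append(alternatives[rng.integers(len(alternatives))])
        else:
            out.append(aa)
    return "".join(out)


def motif_pfm_from_consensus(consensus: str, noise: float = 0.0) -> np.ndarray:
    """A PFM placing 1-noise on the consensus base, noise/3 elsewhere."""
    if not 0.0 <= noise <= 0.75:
        raise SimulationError("noise must be in [0, 0.75]")
    index = {b: k for k, b in enumerate("ACGT")}
    pfm = np.full((len(consensus), 4), noise / 3.0)
    for pos, base in enumerate(consensus):
        pfm[pos, index[base]] = 1.0 - noise
    return pfm


def simulate_binding_site_pool(
    motif_pfm: np.ndarray,
    n_sites: int = 200,
    site_length: int = 28,
    duplicate_p: float = 0.5,
    seed: int | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """28-mers carrying a planted motif, with geometric duplicate counts.

    Each distinct site is a uniform-random background of ``site_length`` nt
    with a motif instance (sampled column-wise from ``motif_pfm``) written at
    an offset drawn uniformly from the feasible range; its read count is
    geometric with success probability ``duplicate_p`` (mean 1/p), so a
    fraction of sites are singletons and exercise the >=2-count filter.
    Set ``duplicate_p = 1`` for all-unique reads.  Returns
    ``(site_counts, truth)``; truth rows give each site's planted offset and
    motif instance.
    """
    motif_pfm = np.asarray(motif_pfm, dtype=float)
    width = motif_pfm.shape[0]
    if width > site_length:
        raise SimulationError("motif wider than the site")
    rng = np.random.default_rng(seed)
    max_offset = site_length - width
    counts: dict[str, int] = {}
    rows = []
    for _ in range(n_sites):
        flanks = rng.integers(4, size=site_length)
        offset = int(rng.integers(max_offset + 1))
        instance = [int(rng.choice(4, p=motif_pfm[j] / motif_pfm[j].sum()))
                    for j in range(width)]
        site_idx = flanks.copy()
        site_idx[offset : offset + width] = instance
        site = "".join(_DNA[site_idx])
        count = int(rng.geometric(duplicate_p))
        counts[site] = counts.get(site, 0) + count
        rows.append({"site": site, "offset": offset,
                     "instance": "".join(_DNA[instance]), "count": count})
    truth = pd.DataFrame(rows)
    return counts, truth


def write_fastq(reads: Sequence[str], path, quality: str = "I") -> None:
    """Write reads as FASTQ with a flat quality string (structure-only data)."""
    with open(path, "w") as fh:
        for k, read in enumerate(reads):
            fh.write("@read_%d\n%s\n+\n%s\n" % (k, read, quality * len(read)))


def write_truth(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)
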