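"""Genetic-code model for degenerate codon schemes.

Degenerate library oligos randomize codons with a restricted base set per
codon position.  The default scheme here is NNS — any base at positions 1
and 2, C or G at position 3 — which yields 32 codons covering all 20 amino
acids plus a single stop codon (TAG).  This module enumerates scheme codons,
computes per-residue degeneracy d(aa) (how many scheme codons encode a
residue), counts and enumerates the synonymous DNA encodings of an
amino-acid sequence, and translates variable-region DNA while flagging
stop-containing and non-scheme variants.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

import yaml
from Bio.Data import CodonTable as _BioCodonTable

DNA_BASES = frozenset("ACGT")

#: standard one-letter amino-acid alphabet (no X, no stop)
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

STOP = "*"


class SchemeError(ValueError):
    """A degenerate scheme definition is malformed."""


class ResidueError(ValueError):
    """A residue symbol outside the 20-letter amino-acid alphabet."""


class DnaError(ValueError):
    """A DNA string with bad length or non-ACGT characters."""


def standard_code() -> dict[str, str]:
    """The standard genetic code (NCBI table 1) as codon -> residue or '*'.

    Exactly 64 entries, with the three stops TAA, TAG, TGA mapped to '*'.
    """
    table = _BioCodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = STOP
    assert len(code) == 64
    return code


@dataclass(frozen=True)
class DegenerateScheme:
    """A triplet degenerate-codon scheme: allowed bases per codon position.

    Parameters
    ----------
    name
        Label for the scheme (e.g. ``"NNS"``).
    position_bases
        Three sets of allowed bases, one per codon position.
    """

    name: str
    position_bases: tuple[frozenset[str], frozenset[str], frozenset[str]]
    _code: Mapping[str, str] = field(
        default_factory=standard_code, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if len(self.position_bases) != 3:
            raise SchemeError("a scheme needs exactly three base sets")
        for bases in self.position_bases:
            if not bases:
                raise SchemeError("empty base set in scheme %r" % self.name)
            bad = set(bases) - DNA_BASES
            if bad:
                raise SchemeError("non-ACGT bases in scheme: %r" % sorted(bad))

    @property
    def codons(self) -> tuple[str, ...]:
        """All position-wise base combinations, lexicographically sorted."""
        return tuple(
            "".join(c)
            for c in itertools.product(*(sorted(b) for b in self.position_bases))
        )

    @property
    def degeneracy_map(self) -> dict[str, int]:
        """Residue (or '*') -> number of scheme codons encoding it."""
        return dict(Counter(self._code[c] for c in self.codons))

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """The scheme codons translating to residue ``aa``, sorted."""
        _check_residue(aa)
        return tuple(c for c in self.codons if self._code[c] == aa)

    def degeneracy(self, aa: str) -> int:
        """Number of scheme codons encoding residue ``aa`` (0 if unencodable)."""
        _check_residue(aa)
        return self.degeneracy_map.get(aa, 0)

    def encoding_count(self, aa_seq: str) -> int:
        """Total synonymous DNA encodings of ``aa_seq`` under this scheme.

        The product over positions of per-residue degeneracy.  Raises
        :class:`ResidueError` if any residue has degeneracy 0 (unencodable).
        """
        if not aa_seq:
            raise ResidueError("empty amino-acid sequence")
        n = 1
        for aa in aa_seq:
            d = self.degeneracy(aa)
            if d == 0:
                raise ResidueError(
                    "residue %r not encodable under scheme %s" % (aa, self.name)
                )
            n *= d
        return n

    def enumerate_encodings(self, aa_seq: str) -> Iterator[str]:
        """Yield every DNA encoding of ``aa_seq``, in sorted order."""
        if not aa_seq:
            raise ResidueError("empty amino-acid sequence")
        pools = [self.codons_for(aa) for aa in aa_seq]
        for aa, pool in zip(aa_seq, pools):
            if not pool:
                raise ResidueError(
                    "residue %r not encodable under scheme %s" % (aa, self.name)
                )
        for combo in itertools.product(*pools):
            yield "".join(combo)


class TranslationFlag(Enum):
    """Outcome of translating a variable region under a scheme."""

    OK = "ok"
    STOP = "stop"
    NON_SCHEME = "non_scheme"


def translate_variable_region(
    dna: str, scheme: DegenerateScheme
) -> tuple[str | None, TranslationFlag]:
    """Translate a 3k-nt variable region codon-wise under ``scheme``.

    Returns ``(protein, OK)`` for clean variants.  Variants containing any
    codon outside the scheme (e.g. A or T at the S position under NNS) are
    flagged ``NON_SCHEME`` without translation; in-scheme variants with an
    in-frame stop are flagged ``STOP``.  Non-scheme takes precedence so that
    sequencing artifacts are never reported as stop-containing clones.
    """
    if len(dna) == 0 or len(dna) % 3 != 0:
        raise DnaError("variable region length %d not divisible by 3" % len(dna))
    if set(dna) - DNA_BASES:
        raise DnaError("non-ACGT characters in %r" % dna)
    codons = [dna[i : i + 3] for i in range(0, len(dna), 3)]
    scheme_set = set(scheme.codons)
    if any(c not in scheme_set for c in codons):
        return None, TranslationFlag.NON_SCHEME
    code = scheme._code
    residues = [code[c] for c in codons]
    if STOP in residues:
        return None, TranslationFlag.STOP
    return "".join(residues), TranslationFlag.OK


def _check_residue(aa: str) -> None:
    if len(aa) != 1 or aa not in AMINO_ACIDS:
        raise ResidueError("unknown residue symbol %r" % aa)


def nns_scheme() -> DegenerateScheme:
    """The NNS scheme: N at codon positions 1-2, S (C/G) at position 3."""
    return DegenerateScheme(
        "NNS", (frozenset("ACGT"), frozenset("ACGT"), frozenset("CG"))
    )


def scheme_from_config(path_or_mapping) -> DegenerateScheme:
    """Load a scheme from a YAML/JSON-style config.

    Expected shape: ``{name: {pos1: "ACGT", pos2: "ACGT", pos3: "CG"}}``
    or a flat ``{name: ..., pos1: ...}`` mapping.
    """
    if isinstance(path_or_mapping, Mapping):
        cfg = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh)
    if "name" not in cfg:
        if len(cfg) != 1:
            raise SchemeError("config must define exactly one scheme")
        name, body = next(iter(cfg.items()))
        cfg = {"name": name, **body}
    try:
        bases = tuple(frozenset(cfg["pos%d" % i]) for i in (1, 2, 3))
    except KeyError as exc:
        raise SchemeError("scheme config missing %s" % exc) from exc
    return DegenerateScheme(str(cfg["name"]), bases)  # type: ignore[arg-type]
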