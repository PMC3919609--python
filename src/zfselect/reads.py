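"""Amplicon read processing: demultiplexing, structural filtering, variant counting.

Selection pools are sequenced as fixed-layout amplicons: an optional sample
barcode, a 5' constant segment, the variable region (15/18 nt recognition-helix
codons or the 28 nt randomized binding-site region), and a 3' constant /
adapter segment.  Reads are kept only if every constant segment matches the
template exactly (configurable mismatch tolerance, default 0); the variable
span of the survivors is tallied into a :class:`VariantCounts` table.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml
from Bio import SeqIO


class LayoutError(ValueError):
    """Inconsistent selection-layout definition."""


class InputError(ValueError):
    """Malformed input data."""


@dataclass(frozen=True)
class SelectionLayout:
    """Template of a selection amplicon read.

    The read (after barcode removal) is expected to be
    ``upstream + variable (variable_length nt) + downstream``; ``upstream``
    and ``downstream`` are constant segments (primer/adapter sequence included)
    that must match exactly for a read to pass.  Coordinates are 0-based,
    half-open on the barcode-stripped read.
    """

    upstream: str
    variable_length: int
    downstream: str

    def __post_init__(self) -> None:
        if self.variable_length <= 0:
            raise LayoutError("variable_length must be positive")
        for seg in (self.upstream, self.downstream):
            if set(seg) - set("ACGT"):
                raise LayoutError("constant segments must be ACGT only")

    @property
    def variable_span(self) -> tuple[int, int]:
        """0-based half-open coordinates of the variable region."""
        start = len(self.upstream)
        return start, start + self.variable_length

    @property
    def template_length(self) -> int:
        return len(self.upstream) + self.variable_length + len(self.downstream)

    @classmethod
    def from_config(cls, path_or_mapping) -> "SelectionLayout":
        if isinstance(path_or_mapping, Mapping):
            cfg = dict(path_or_mapping)
        else:
            with open(path_or_mapping) as fh:
                cfg = yaml.safe_load(fh)
        return cls(
            upstream=str(cfg["upstream"]),
            variable_length=int(cfg["variable_length"]),
            downstream=str(cfg["downstream"]),
        )


@dataclass
class VariantCounts:
    """Counts of fixed-length DNA variants observed in one pool."""

    counts: dict[str, int] = field(default_factory=dict)
    sample: str | None = None
    stringency: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.counts}
        if len(lengths) > 1:
            raise InputError("mixed variant lengths: %r" % sorted(lengths))
        if any(c < 1 for c in self.counts.values()):
            raise InputError("variant counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def variant_length(self) -> int | None:
        return len(next(iter(self.counts))) if self.counts else None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("variant\tcount\n")
            for v in sorted(self.counts):
                fh.write("%s\t%d\n" % (v, self.counts[v]))

    @classmethod
    def from_tsv(cls, path, sample: str | None = None,
                 stringency: str | None = None) -> "VariantCounts":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("variant"):
                raise InputError("expected 'variant<TAB>count' header")
            for line in fh:
                if not line.strip():
                    continue
                variant, count = line.rstrip("\n").split("\t")
                counts[variant] = int(count)
        return cls(counts, sample=sample, stringency=stringency)


# ---------------------------------------------------------------------------
# read ingestion


def read_sequences(path) -> Iterator[str]:
    """Yield read sequences from FASTQ (.gz accepted) or one-per-line text."""
    path = Path(path)
    name = path.name.lower()
    opener = gzip.open if name.endswith(".gz") else open
    stem = name[:-3] if name.endswith(".gz") else name
    if stem.endswith((".fastq", ".fq")):
        with opener(path, "rt") as fh:
            for record in SeqIO.parse(fh, "fastq"):
                yield str(record.seq).upper()
    else:
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.strip().upper()
                if line:
                    yield line


def demultiplex(
    reads: Iterable[str], barcodes: Mapping[str, str]
) -> tuple[dict[str, list[str]], list[str]]:
    """Assign reads to samples by exact barcode prefix; strip the barcode.

    Returns ``(per_sample_reads, unassigned_reads)``.  Barcodes must be the
    same length and mutually distinct.  No error correction is attempted:
    a 1-mismatch barcode lands in the unassigned bin.
    """
    if not barcodes:
        raise LayoutError("no barcodes given")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise LayoutError("barcodes must all have the same length")
    if len(set(barcodes.values())) != len(barcodes):
        raise LayoutError("duplicate barcode sequences")
    (blen,) = lengths
    lookup = {b: s for s, b in barcodes.items()}
    per_sample: dict[str, list[str]] = {s: [] for s in barcodes}
    unassigned: list[str] = []
    for read in reads:
        sample = lookup.get(read[:blen])
        if sample is None:
            unassigned.append(read)
        else:
            per_sample[sample].append(read[blen:])
    return per_sample, unassigned


def filter_reads(
    reads: Iterable[str], layout: SelectionLayout, max_mismatch: int = 0
) -> tuple[list[str], dict[str, int]]:
    """Keep reads whose constant segments match the layout template.

    A read passes iff it is at least template length and each constant
    segment (upstream, downstream/adapter) has at most ``max_mismatch``
    mismatches against the template — the default 0 removes every read with
    any mismatch in a constant or adapter position.  The tally reports
    rejects by failing segment; pass + rejects = input total.
    """
    vstart, vend = layout.variable_span
    down_end = vend + len(layout.downstream)
    clean: list[str] = []
    tally = Counter(passed=0, too_short=0, upstream_mismatch=0,
                    downstream_mismatch=0)
    for read in reads:
        if len(read) < layout.template_length:
            tally["too_short"] += 1
            continue
        if _mismatches(read[:vstart], layout.upstream) > max_mismatch:
            tally["upstream_mismatch"] += 1
            continue
        if _mismatches(read[vend:down_end], layout.downstream) > max_mismatch:
            tally["downstream_mismatch"] += 1
            continue
        tally["passed"] += 1
        clean.append(read)
    return clean, dict(tally)


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_variants(
    clean_reads: Iterable[str],
    layout: SelectionLayout,
    min_count: int = 1,
    sample: str | None = None,
    stringency: str | None = None,
) -> VariantCounts:
    """Slice the variable span of clean reads and count exact variants.

    Variants seen fewer than ``min_count`` times are dropped (the binding-site
    pipeline keeps sequences observed at least twice; recognition-helix pools
    default to keeping everything).
    """
    vstart, vend = layout.variable_span
    counter: Counter[str] = Counter()
    for read in clean_reads:
        if len(read) < vend:
            raise InputError("read shorter than variable span end")
        counter[read[vstart:vend]] += 1
    counts = {v: c for v, c in counter.items() if c >= min_count}
    return VariantCounts(counts, sample=sample, stringency=stringency)


def write_tally(tally: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(tally), fh, indent=2, sort_keys=True)
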