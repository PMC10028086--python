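"""Genomic interval arithmetic: the coordinate conventions used everywhere else.

Coordinates are 1-based, as printed in clinical microarray reports
(``chr15:22,838,642-28,314,382``).  The length of an interval is defined as
``end - start``, i.e. the interval is treated as half-open on the 1-based
axis.  This convention applied directly to printed report coordinates
reproduces the sizes quoted alongside them (e.g. the 15q11.2q13.1 deletion
above: 28,314,382 - 22,838,642 = 5,475,740 bp = 5.476 Mb), and it makes
interval arithmetic (overlap, intersection, BED conversion) closed-form with
no +/-1 bookkeeping.

All overlap arithmetic used by frequency annotation, classification and
gene-level analyses lives here:

* :func:`overlap_length` / :func:`reciprocal_overlap` -- the ">50% reciprocal
  overlap" match criterion used for population-frequency annotation,
* :func:`minimal_critical_region` -- the intersection of overlapping patient
  variants, localising the candidate dosage-sensitive element,
* :func:`is_subtelomeric` -- proximity of a variant to either chromosome end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "IntervalError",
    "UnknownChromosomeError",
    "MixedChromosomeError",
    "ChromosomeTable",
    "GenomicInterval",
    "interval_length",
    "overlap_length",
    "reciprocal_overlap",
    "ro_qualifies",
    "minimal_critical_region",
    "is_subtelomeric",
    "round_half_up",
]


class IntervalError(ValueError):
    """Invalid genomic interval or interval operation."""


class UnknownChromosomeError(IntervalError):
    """Chromosome not present in the active chromosome-length table."""


class MixedChromosomeError(IntervalError):
    """Operation requiring a single chromosome got intervals from several."""


_HG38_CANONICAL = tuple(f"chr{c}" for c in [*range(1, 23), "X", "Y"])


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (the convention of printed reports)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChromosomeTable:
    """Assembly name plus chromosome -> length (bp) mapping."""

    assembly: str
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise IntervalError("chromosome table is empty")
        for chrom, length in self.lengths.items():
            if int(length) <= 0:
                raise IntervalError(f"non-positive length for {chrom}: {length}")
        if self.assembly == "hg38":
            missing = [c for c in _HG38_CANONICAL if c not in self.lengths]
            if missing:
                raise IntervalError(
                    f"hg38 table missing canonical chromosomes: {missing}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return int(self.lengths[chrom])
        except KeyError:
            raise UnknownChromosomeError(
                f"chromosome {chrom!r} not in {self.assembly} table"
            ) from None

    @classmethod
    def from_tsv(cls, path, assembly: str = "custom") -> "ChromosomeTable":
        lengths: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\r\n").split("\t")
            if header[:2] != ["chrom", "length"]:
                raise IntervalError(
                    f"{path}: expected header 'chrom\\tlength', got {header!r}"
                )
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\r\n").split("\t")
                if len(parts) < 2:
                    raise IntervalError(f"{path}:{lineno}: malformed row {line!r}")
                lengths[parts[0]] = int(parts[1])
        return cls(assembly=assembly, lengths=lengths)

    @classmethod
    def hg38(cls) -> "ChromosomeTable":
        """The bundled GRCh38/hg38 chromosome lengths (chr1-22, X, Y)."""
        ref = resources.files("cnvland.data").joinpath("hg38_chrom_lengths.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path, assembly="hg38")


_COORD_RE = re.compile(r"^\s*(\S+?)\s*:\s*([\d,]+)\s*[-–]\s*([\d,]+)\s*$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored coordinate pair (1-based; length = end - start)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("empty chromosome name")
        if self.start < 1:
            raise IntervalError(f"start must be >= 1, got {self.start}")
        if self.end <= self.start:
            raise IntervalError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @classmethod
    def from_string(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end``; thousands separators are tolerated."""
        m = _COORD_RE.match(text)
        if m is None:
            raise IntervalError(f"cannot parse interval {text!r}")
        chrom, start, end = m.groups()
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))

    @property
    def length(self) -> int:
        return self.end - self.start

    def length_mb(self, decimals: int = 1) -> float:
        return round_half_up(self.length / 1e6, decimals)

    def length_kb(self, decimals: int = 1) -> float:
        return round_half_up(self.length / 1e3, decimals)

    def validate_against(self, chroms: ChromosomeTable) -> None:
        # end may be length + 1 because end is exclusive on the 1-based axis
        if self.end > chroms.length(self.chrom) + 1:
            raise IntervalError(
                f"{self} extends past {self.chrom} "
                f"(length {chroms.length(self.chrom)})"
            )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Length in bp under the end - start convention."""
    return iv.length


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length of the intersection; 0 for different chromosomes or disjoint."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); symmetric, in [0, 1]."""
    ovl = overlap_length(a, b)
    if ovl == 0:
        return 0.0
    return min(ovl / a.length, ovl / b.length)


def ro_qualifies(
    a: GenomicInterval, b: GenomicInterval, threshold: float = 0.5
) -> bool:
    """True when the reciprocal overlap strictly exceeds ``threshold``.

    Strict inequality implements the ">50% reciprocal overlap" match rule.
    """
    return reciprocal_overlap(a, b) > threshold


def minimal_critical_region(
    ivs: Sequence[GenomicInterval],
) -> Optional[GenomicInterval]:
    """Intersection of all intervals; ``None`` when it vanishes.

    All intervals must share one chromosome.  The result (max of starts, min
    of ends) is the minimal critical region localising the element shared by
    overlapping patient variants.
    """
    if not ivs:
        raise IntervalError("minimal_critical_region of an empty list")
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise MixedChromosomeError(f"intervals span several chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in ivs)
    end = min(iv.end for iv in ivs)
    if end <= start:
        return None
    return GenomicInterval(ivs[0].chrom, start, end)


def is_subtelomeric(
    iv: GenomicInterval,
    chroms: ChromosomeTable,
    window: int = 5_000_000,
) -> bool:
    """True when the interval lies within ``window`` bp of either chromosome end.

    The proximal test is on the interval start (distance from position 1), the
    distal test on the interval end (distance from the chromosome end).
    """
    if window < 0:
        raise IntervalError(f"window must be >= 0, got {window}")
    chrom_len = chroms.length(iv.chrom)
    return (iv.start - 1) <= window or (chrom_len - iv.end) <= window
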