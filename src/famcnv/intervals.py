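"""Genomic interval primitives.

Every coordinate inside the package is 1-based and inclusive at both ends,
matching the convention of array-probe CNV tables.  BED files are the only
0-based half-open surface and are converted at the I/O boundary
(:mod:`famcnv.io`).  Chromosome labels are normalized by stripping a leading
``chr`` prefix; autosomes are ``"1"``..``"22"``, sex chromosomes ``"X"`` and
``"Y"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .errors import ValidationError

AUTOSOMES = tuple(str(i) for i in range(1, 23))
SEX_CHROMOSOMES = ("X", "Y")
CHROMOSOMES = AUTOSOMES + SEX_CHROMOSOMES

OverlapMode = Literal["of_a", "reciprocal"]


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and validate the chromosome label."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    if lab in ("x", "y"):
        lab = lab.upper()
    if lab not in CHROMOSOMES:
        raise ValidationError(f"unknown chromosome label: {label!r}")
    return lab


def chrom_sort_key(chrom: str) -> int:
    """Numeric ordering with X, Y after the autosomes."""
    return CHROMOSOMES.index(chrom)


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval ``[start, end]`` on one chromosome.

    ``start`` and ``end`` are 1-based and both inclusive, so a single base is
    ``start == end`` and ``length == end - start + 1``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValidationError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"interval end ({self.end}) precedes start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bases(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 across chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_bases(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_fraction(
    a: GenomicInterval, b: GenomicInterval, mode: OverlapMode = "of_a"
) -> float:
    """Fraction of overlap between two intervals.

    ``of_a`` is directional: shared bases divided by the length of ``a``.
    ``reciprocal`` is the minimum of the two directional fractions, i.e. the
    usual reciprocal-overlap criterion.  Intervals on different chromosomes
    overlap by 0.
    """
    shared = a.overlap_bases(b)
    if shared == 0:
        return 0.0
    if mode == "of_a":
        return shared / a.length
    if mode == "reciprocal":
        return min(shared / a.length, shared / b.length)
    raise ValueError(f"unknown overlap mode: {mode!r}")


def union_covered_bases(
    target: GenomicInterval, others: Iterable[GenomicInterval]
) -> int:
    """Bases of ``target`` covered by the union of ``others``.

    Records on other chromosomes are ignored; overlapping records are merged
    before counting, so double coverage is not double counted.
    """
    clipped = sorted(
        (max(o.start, target.start), min(o.end, target.end))
        for o in others
        if o.chrom == target.chrom and o.overlap_bases(target) > 0
    )
    covered = 0
    cur_start: int | None = None
    cur_end = 0
    for s, e in clipped:
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    if cur_start is not None:
        covered += cur_end - cur_start + 1
    return covered


def union_coverage_fraction(
    target: GenomicInterval, others: Iterable[GenomicInterval]
) -> float:
    """Fraction of ``target`` covered by the union of ``others``."""
    return union_covered_bases(target, others) / target.length
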