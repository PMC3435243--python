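"""Two-caller CNV consensus merging.

A CNV is retained only when both callers report it for the same sample in the
same direction (loss with loss, gain with gain) with sufficient overlap; the
merged segment keeps the *outer* boundaries of the two source calls.  The
default retention rule is a 50-100% overlap of the two outputs with a merged
size of at least 20 kb and at least 5 probes.

Common copy-number polymorphisms need a population-level notion of "normal":
the normal state of a CNP locus is the rounded mean copy number over all
individuals, which may differ from two.  Rare and de novo calls are compared
to the fixed reference state instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .intervals import GenomicInterval, OverlapMode, overlap_fraction
from .io import CnvCall, Sex, State, reference_copy_number, round_half_away

DEFAULT_MIN_OVERLAP = 0.5
DEFAULT_MIN_SIZE = 20_000
DEFAULT_MIN_PROBES = 5
DEFAULT_MIN_CONFIDENCE_B = 10.0


@dataclass(frozen=True)
class MergedCnv:
    """Consensus CNV supported by one call from each caller."""

    sample_id: str
    family_id: str
    interval: GenomicInterval
    state: State
    copy_number: int
    n_probes: int
    sources: tuple[CnvCall, ...]
    overlap_fraction: float

    @property
    def cnv_id(self) -> str:
        return (
            f"{self.sample_id}:{self.interval.chrom}:"
            f"{self.interval.start}-{self.interval.end}:{self.state}"
        )


def canary_normal_state(
    copies: Mapping[str, int]
) -> tuple[int, dict[str, State]]:
    """Population normal state of a CNP locus and per-individual deltas.

    The normal state is the mean copy number over all individuals rounded to
    the closest integer (half away from zero); individuals above it are gains,
    below it losses.
    """
    if not copies:
        raise ValidationError("canary_normal_state requires at least one individual")
    normal = int(round_half_away(sum(copies.values()) / len(copies)))
    deltas: dict[str, State] = {}
    for ind, cn in copies.items():
        if cn > normal:
            deltas[ind] = "gain"
        elif cn < normal:
            deltas[ind] = "loss"
        else:
            deltas[ind] = "normal"
    return normal, deltas


def rare_cnv_delta(copy_number: int, chrom: str = "1", sex: Sex = "unknown") -> State:
    """State of a rare/de novo call against the fixed reference copy number."""
    if copy_number < 0:
        raise ValidationError("copy_number must be non-negative")
    ref = reference_copy_number(chrom, sex)
    if copy_number < ref:
        return "loss"
    if copy_number > ref:
        return "gain"
    return "normal"


def merge_two_callers(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    min_size: int = DEFAULT_MIN_SIZE,
    min_probes: int = DEFAULT_MIN_PROBES,
    mode: OverlapMode = "of_a",
    min_confidence_b: float = DEFAULT_MIN_CONFIDENCE_B,
) -> list[MergedCnv]:
    """Merge one sample's calls from the two callers.

    Pairs one call from each caller (same state, same chromosome) whenever the
    overlap fraction of the caller-A segment reaches ``min_overlap``
    (``mode="reciprocal"`` switches to reciprocal overlap).  Matching is
    one-to-one and greedy by descending overlap with leftmost-start
    tie-breaking; each source call contributes to at most one merged CNV.
    Merged CNVs shorter than ``min_size`` or with fewer than ``min_probes``
    probes are dropped.  Caller-B calls below ``min_confidence_b`` are
    pre-filtered.

    The merged copy number is taken from the caller-B source (integer total
    copies); the probe count is the maximum over the two sources.
    """
    samples = {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    if len(samples) > 1:
        raise ValidationError(
            f"merge_two_callers expects calls of a single sample, got {sorted(samples)}"
        )
    calls_b = [b for b in calls_b if b.confidence >= min_confidence_b]

    candidates: list[tuple[float, int, int, int, int]] = []
    for ia, a in enumerate(calls_a):
        for ib, b in enumerate(calls_b):
            if a.state != b.state or a.state == "normal":
                continue
            frac = overlap_fraction(a.interval, b.interval, mode)
            if frac >= min_overlap:
                candidates.append((-frac, a.interval.start, b.interval.start, ia, ib))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    merged: list[MergedCnv] = []
    for neg_frac, _, _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        a, b = calls_a[ia], calls_b[ib]
        envelope = GenomicInterval(
            a.interval.chrom,
            min(a.interval.start, b.interval.start),
            max(a.interval.end, b.interval.end),
        )
        n_probes = max(a.n_probes, b.n_probes)
        if envelope.length < min_size or n_probes < min_probes:
            continue
        merged.append(
            MergedCnv(
                sample_id=a.sample_id,
                family_id=a.family_id,
                interval=envelope,
                state=a.state,
                copy_number=b.copy_number,
                n_probes=n_probes,
                sources=(a, b),
                overlap_fraction=-neg_frac,
            )
        )
    merged.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end))
    return merged


MERGED_COLUMNS = [
    "FID", "IID", "CHR", "BP1", "BP2", "TYPE", "NPROBES", "SOURCE", "OVERLAP"
]


def write_merged_table(merged: Sequence[MergedCnv], path) -> None:
    """Write consensus CNVs as a ``.cnv``-style TSV (SOURCE column ``A+B``)."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("\t".join(MERGED_COLUMNS) + "\n")
        for m in merged:
            fh.write(
                "\t".join(
                    [
                        m.family_id, m.sample_id, m.interval.chrom,
                        str(m.interval.start), str(m.interval.end),
                        str(m.copy_number), str(m.n_probes), "A+B",
                        f"{m.overlap_fraction:.6f}",
                    ]
                )
                + "\n"
            )


def read_merged_table(path) -> list[MergedCnv]:
    """Read a consensus CNV table back (source calls are not reconstructed)."""
    from pathlib import Path

    from .errors import ParseError

    merged: list[MergedCnv] = []
    with Path(path).open() as fh:
        header = fh.readline().split()
        if header != MERGED_COLUMNS:
            raise ParseError(f"{path}: unexpected merged-table header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < len(MERGED_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: expected 9 fields")
            cn = int(f[5])
            merged.append(
                MergedCnv(
                    sample_id=f[1], family_id=f[0],
                    interval=GenomicInterval(f[2], int(f[3]), int(f[4])),
                    state="loss" if cn < 2 else "gain", copy_number=cn,
                    n_probes=int(f[6]), sources=(), overlap_fraction=float(f[8]),
                )
            )
    return merged


def merge_cohort(
    calls_a: Iterable[CnvCall],
    calls_b: Iterable[CnvCall],
    **kwargs,
) -> list[MergedCnv]:
    """Merge a whole cohort's calls, sample by sample."""
    by_sample_a: dict[str, list[CnvCall]] = {}
    by_sample_b: dict[str, list[CnvCall]] = {}
    for c in calls_a:
        by_sample_a.setdefault(c.sample_id, []).append(c)
    for c in calls_b:
        by_sample_b.setdefault(c.sample_id, []).append(c)
    merged: list[MergedCnv] = []
    for sample in sorted(set(by_sample_a) | set(by_sample_b)):
        merged.extend(
            merge_two_callers(
                by_sample_a.get(sample, []), by_sample_b.get(sample, []), **kwargs
            )
        )
    return merged
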