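"""The rarity filter chain.

Five ordered stages reduce the affected individuals' merged CNVs to those
plausibly private to the disease:

1. ``unaffected_cohort`` — a CNV overlapping *more than* ``thr`` (default 50%)
   of its length with any same-state CNV of an unaffected cohort member is
   removed; 50% or less is regarded as unique.
2. ``control_cohort`` — the same comparison against an external control
   cohort's CNVs.
3. ``segdup`` — removed when the union of segmental-duplication records covers
   50% *or more* of the CNV.
4. ``common`` — removed when any single known-variant record (a DGV-like
   track) covers 50% or more of the CNV.
5. ``family`` — removed when a same-state CNV overlapping >=50% is present in
   an unaffected member of the same family; surviving CNVs shared (>=50%
   overlap) among affected relatives are grouped into one familial event.

Note the deliberate boundary asymmetry: uniqueness keeps the exact-50% point
("50% or less is unique") while the segdup/common/family stages remove it
("50% or more"), following the stated operational definitions.  Comparisons
are state-stratified throughout; overlap fractions are directional, measured
as coverage of the query (affected individual's) CNV.

Sex-chromosomal CNVs use stricter any-overlap uniqueness semantics
(:func:`unique_sex_chromosomal`), mirroring the higher false-call rate there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError
from .intervals import is_autosome, overlap_fraction, union_coverage_fraction
from .io import Pedigree, TrackRecord
from .merge import MergedCnv

STAGES = ("unaffected_cohort", "control_cohort", "segdup", "common", "family")


@dataclass
class FilterTrace:
    """Per-CNV record of each stage's outcome; at most one stage removes."""

    cnv: MergedCnv
    stage_outcomes: list[tuple[str, bool, str, float]] = field(default_factory=list)

    def add(self, stage: str, kept: bool, reason: str = "", overlap: float = 0.0) -> None:
        self.stage_outcomes.append((stage, kept, reason, overlap))

    @property
    def kept(self) -> bool:
        return all(kept for _, kept, _, _ in self.stage_outcomes)

    @property
    def removing_stage(self) -> str | None:
        for stage, kept, _, _ in self.stage_outcomes:
            if not kept:
                return stage
        return None


@dataclass
class ChainResult:
    kept: list[MergedCnv]
    traces: dict[str, FilterTrace]
    stage_counts: dict[str, int]
    event_ids: dict[str, str]  # cnv_id -> familial event id


def _max_same_state_overlap(
    cnv: MergedCnv, comparison: Sequence[MergedCnv], mode: str = "of_a"
) -> float:
    best = 0.0
    for other in comparison:
        if other.state != cnv.state:
            continue
        frac = overlap_fraction(cnv.interval, other.interval, mode)
        if frac > best:
            best = frac
    return best


def unique_to_affected(
    affected_cnvs: Sequence[MergedCnv],
    unaffected_cnvs: Sequence[MergedCnv] = (),
    control_cnvs: Sequence[MergedCnv] = (),
    thr: float = 0.5,
    mode: str = "of_a",
    traces: dict[str, FilterTrace] | None = None,
) -> list[MergedCnv]:
    """Keep CNVs overlapping ``thr`` or less with every same-state comparison CNV.

    Strictly greater overlap with any same-state CNV of an unaffected cohort
    member or a control removes the CNV; the fraction is measured on the
    affected individual's CNV.
    """
    kept: list[MergedCnv] = []
    for cnv in affected_cnvs:
        trace = traces.setdefault(cnv.cnv_id, FilterTrace(cnv)) if traces is not None else None
        removed = False
        for stage, comparison in (
            ("unaffected_cohort", unaffected_cnvs),
            ("control_cohort", control_cnvs),
        ):
            if removed:
                if trace is not None:
                    trace.add(stage, True, "not reached")
                continue
            best = _max_same_state_overlap(cnv, comparison, mode)
            if best > thr:
                removed = True
                if trace is not None:
                    trace.add(stage, False, f"same-state overlap > {thr:.0%}", best)
            elif trace is not None:
                trace.add(stage, True, "unique", best)
        if not removed:
            kept.append(cnv)
    return kept


def unique_sex_chromosomal(
    affected_cnvs: Sequence[MergedCnv],
    comparison_cnvs: Sequence[MergedCnv],
) -> list[MergedCnv]:
    """Any-overlap uniqueness for X/Y CNVs (>=1 bp same-state overlap removes)."""
    for cnv in affected_cnvs:
        if is_autosome(cnv.interval.chrom):
            raise ValidationError(
                f"unique_sex_chromosomal received autosomal CNV {cnv.cnv_id}"
            )
    kept = []
    for cnv in affected_cnvs:
        hit = any(
            other.state == cnv.state and cnv.interval.overlaps(other.interval)
            for other in comparison_cnvs
        )
        if not hit:
            kept.append(cnv)
    return kept


def filter_segdup(
    cnvs: Sequence[MergedCnv],
    segdup_track: Sequence[TrackRecord],
    thr: float = 0.5,
    traces: dict[str, FilterTrace] | None = None,
) -> list[MergedCnv]:
    """Remove CNVs covered >= ``thr`` by the union of segmental duplications."""
    segdups = [r.interval for r in segdup_track]
    kept = []
    for cnv in cnvs:
        coverage = union_coverage_fraction(cnv.interval, segdups)
        removed = coverage >= thr
        if traces is not None:
            traces.setdefault(cnv.cnv_id, FilterTrace(cnv)).add(
                "segdup", not removed,
                "segdup union coverage" if removed else "clear", coverage,
            )
        if not removed:
            kept.append(cnv)
    return kept


def filter_common(
    cnvs: Sequence[MergedCnv],
    known_track: Sequence[TrackRecord],
    overlap_thr: float = 0.5,
    traces: dict[str, FilterTrace] | None = None,
) -> list[MergedCnv]:
    """Remove CNVs overlapped >= ``overlap_thr`` by any single known variant."""
    kept = []
    for cnv in cnvs:
        best = 0.0
        for rec in known_track:
            frac = overlap_fraction(cnv.interval, rec.interval, "of_a")
            best = max(best, frac)
            if best >= overlap_thr:
                break
        removed = best >= overlap_thr
        if traces is not None:
            traces.setdefault(cnv.cnv_id, FilterTrace(cnv)).add(
                "common", not removed,
                "known-variant overlap" if removed else "clear", best,
            )
        if not removed:
            kept.append(cnv)
    return kept


def family_consistency_filter(
    cnvs: Sequence[MergedCnv],
    pedigree: Pedigree,
    all_cohort_cnvs: Sequence[MergedCnv],
    thr: float = 0.5,
    traces: dict[str, FilterTrace] | None = None,
) -> tuple[list[MergedCnv], dict[str, str]]:
    """Remove CNVs mirrored in unaffected relatives; group familial events.

    A CNV is removed when any unaffected member of the same family carries a
    same-state CNV overlapping >= ``thr`` of it.  Among the survivors,
    same-state CNVs of affected relatives overlapping >= ``thr`` (in either
    direction) are regarded as one familial CNV event and share an event id;
    singletons form their own event.
    """
    by_sample: dict[str, list[MergedCnv]] = {}
    for c in all_cohort_cnvs:
        by_sample.setdefault(c.sample_id, []).append(c)

    kept: list[MergedCnv] = []
    for cnv in cnvs:
        unaffected_members = [
            m for m in pedigree.members(cnv.family_id)
            if m.phenotype == "unaffected" and m.individual_id != cnv.sample_id
        ]
        best = 0.0
        for member in unaffected_members:
            best = max(
                best,
                _max_same_state_overlap(cnv, by_sample.get(member.individual_id, [])),
            )
        removed = best >= thr
        if traces is not None:
            traces.setdefault(cnv.cnv_id, FilterTrace(cnv)).add(
                "family", not removed,
                "present in unaffected relative" if removed else "clear", best,
            )
        if not removed:
            kept.append(cnv)

    # group survivors into familial events by >=thr overlap closure
    event_ids: dict[str, str] = {}
    parent = list(range(len(kept)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            a, b = kept[i], kept[j]
            if a.family_id != b.family_id or a.state != b.state:
                continue
            if (
                overlap_fraction(a.interval, b.interval, "of_a") >= thr
                or overlap_fraction(b.interval, a.interval, "of_a") >= thr
            ):
                parent[find(i)] = find(j)
    roots: dict[int, str] = {}
    ordered = sorted(
        range(len(kept)),
        key=lambda i: (kept[i].interval.chrom, kept[i].interval.start, kept[i].sample_id),
    )
    for i in ordered:
        r = find(i)
        if r not in roots:
            roots[r] = f"E{len(roots) + 1:04d}"
        event_ids[kept[i].cnv_id] = roots[r]
    return kept, event_ids


def run_filter_chain(
    affected_cnvs: Sequence[MergedCnv],
    unaffected_cnvs: Sequence[MergedCnv],
    control_cnvs: Sequence[MergedCnv],
    segdup_track: Sequence[TrackRecord],
    known_track: Sequence[TrackRecord],
    pedigree: Pedigree,
    thr: float = 0.5,
    mode: str = "of_a",
) -> ChainResult:
    """Run the full fixed-order chain and report per-stage removal counts."""
    traces: dict[str, FilterTrace] = {}
    step1 = unique_to_affected(
        affected_cnvs, unaffected_cnvs, control_cnvs, thr=thr, mode=mode, traces=traces
    )
    step2 = filter_segdup(step1, segdup_track, thr=thr, traces=traces)
    step3 = filter_common(step2, known_track, overlap_thr=thr, traces=traces)
    all_cohort = list(affected_cnvs) + list(unaffected_cnvs)
    kept, event_ids = family_consistency_filter(
        step3, pedigree, all_cohort, thr=thr, traces=traces
    )
    stage_counts = {stage: 0 for stage in STAGES}
    for trace in traces.values():
        stage = trace.removing_stage
        if stage is not None:
            stage_counts[stage] += 1
    return ChainResult(
        kept=kept, traces=traces, stage_counts=stage_counts, event_ids=event_ids
    )
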