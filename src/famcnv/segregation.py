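"""Pedigree transmission classification and de novo rate estimation.

A CNV carried by an offspring is classified against its parents' calls: a
parent "carries" the CNV when any of the parent's same-state calls overlaps at
least ``thr`` (default 50%) of the *offspring's* CNV — the offspring
denominator is deliberate, since boundary jitter inflates parental envelopes.
With both parents genotyped and neither carrying, the call is de novo; one
carrier parent gives an inherited call from that parent; both carriers give
``inherited_either``; an ungenotyped parent with no genotyped carrier parent
leaves the call ``unknown``.

For de novo assertion, parental evidence may include raw single-caller calls
in addition to merged consensus calls (pass them in ``parental_calls``): being
lenient in the parents and stringent in the proband is what makes the
reported de novo rate a conservative minimum estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .intervals import GenomicInterval, overlap_fraction
from .io import Individual, Pedigree, State
from .merge import MergedCnv

TransmissionStatus = Literal[
    "de_novo", "inherited_paternal", "inherited_maternal", "inherited_either", "unknown"
]


@dataclass
class TransmissionCall:
    cnv: MergedCnv
    individual_id: str
    status: TransmissionStatus
    supporting_parent: str | None = None


@dataclass
class TrioSet:
    """Trios (offspring, father, mother) with all three members genotyped."""

    trios: list[tuple[Individual, Individual, Individual]]

    def by_offspring_phenotype(self) -> dict[str, list]:
        out: dict[str, list] = {"affected": [], "unaffected": [], "unknown": []}
        for trio in self.trios:
            out[trio[0].phenotype].append(trio)
        return out


def _parent_carries(
    cnv: MergedCnv,
    parent_id: str,
    parental_intervals: Mapping[str, Sequence[tuple[GenomicInterval, State]]],
    thr: float,
) -> bool:
    for interval, state in parental_intervals.get(parent_id, ()):
        if state == cnv.state and overlap_fraction(cnv.interval, interval, "of_a") >= thr:
            return True
    return False


def build_parental_index(
    merged: Sequence[MergedCnv],
    raw_calls: Sequence = (),
) -> dict[str, list[tuple[GenomicInterval, State]]]:
    """Sample -> [(interval, state)] over merged plus (optionally) raw calls."""
    index: dict[str, list[tuple[GenomicInterval, State]]] = {}
    for m in merged:
        index.setdefault(m.sample_id, []).append((m.interval, m.state))
    for c in raw_calls:
        if c.state != "normal":
            index.setdefault(c.sample_id, []).append((c.interval, c.state))
    return index


def classify_transmission(
    cnv: MergedCnv,
    pedigree: Pedigree,
    parental_calls: Mapping[str, Sequence[tuple[GenomicInterval, State]]],
    thr: float = 0.5,
    genotyped: set[str] | None = None,
) -> TransmissionCall:
    """Classify one CNV's transmission within its pedigree."""
    if cnv.sample_id not in pedigree:
        raise ValidationError(f"carrier {cnv.sample_id!r} absent from pedigree")
    ind = pedigree.get(cnv.sample_id)
    ok = genotyped if genotyped is not None else {i.individual_id for i in pedigree}

    father_genotyped = ind.father_id is not None and ind.father_id in ok
    mother_genotyped = ind.mother_id is not None and ind.mother_id in ok
    father_carries = father_genotyped and _parent_carries(
        cnv, ind.father_id, parental_calls, thr
    )
    mother_carries = mother_genotyped and _parent_carries(
        cnv, ind.mother_id, parental_calls, thr
    )

    if father_carries and mother_carries:
        return TransmissionCall(cnv, ind.individual_id, "inherited_either")
    if father_carries:
        return TransmissionCall(cnv, ind.individual_id, "inherited_paternal", ind.father_id)
    if mother_carries:
        return TransmissionCall(cnv, ind.individual_id, "inherited_maternal", ind.mother_id)
    if father_genotyped and mother_genotyped:
        return TransmissionCall(cnv, ind.individual_id, "de_novo")
    return TransmissionCall(cnv, ind.individual_id, "unknown")


def classify_all(
    cnvs: Sequence[MergedCnv],
    pedigree: Pedigree,
    parental_calls: Mapping[str, Sequence[tuple[GenomicInterval, State]]],
    thr: float = 0.5,
    genotyped: set[str] | None = None,
) -> list[TransmissionCall]:
    return [
        classify_transmission(c, pedigree, parental_calls, thr, genotyped) for c in cnvs
    ]


def trio_set(pedigree: Pedigree, genotyped: set[str] | None = None) -> TrioSet:
    return TrioSet(trios=pedigree.trios(genotyped))


def de_novo_rate(
    trios: TrioSet,
    offspring_calls: Mapping[str, Sequence[MergedCnv]],
    pedigree: Pedigree,
    parental_calls: Mapping[str, Sequence[tuple[GenomicInterval, State]]],
    thr: float = 0.5,
    stratify_by_phenotype: bool = True,
) -> pd.DataFrame:
    """Minimum estimated de novo rate per offspring per generation.

    The rate is the number of unambiguous de novo classifications among trio
    offsprings' calls divided by the number of trios in the stratum ("per
    trio" denominator; ambiguous calls are never imputed as de novo).
    """
    if not trios.trios:
        raise ValidationError("empty trio set")
    strata = (
        trios.by_offspring_phenotype()
        if stratify_by_phenotype
        else {"all": trios.trios}
    )
    genotyped = {
        iid
        for trio in trios.trios
        for iid in (trio[0].individual_id, trio[1].individual_id, trio[2].individual_id)
    }
    rows = []
    for stratum, stratum_trios in strata.items():
        if not stratum_trios:
            continue
        n_de_novo = 0
        for offspring, _, _ in stratum_trios:
            for cnv in offspring_calls.get(offspring.individual_id, ()):
                call = classify_transmission(
                    cnv, pedigree, parental_calls, thr, genotyped
                )
                if call.status == "de_novo":
                    n_de_novo += 1
        rows.append(
            {
                "stratum": stratum,
                "n_trios": len(stratum_trios),
                "n_de_novo": n_de_novo,
                "rate_per_trio": n_de_novo / len(stratum_trios),
            }
        )
    return pd.DataFrame(rows)


def cosegregation_scan(
    kept_cnvs: Sequence[MergedCnv],
    event_ids: Mapping[str, str],
    pedigree: Pedigree,
) -> pd.DataFrame:
    """Per-family accounting of familial CNV events.

    An event segregates when two or more affected members of one family carry
    it; events spanning several families get one row per family.
    """
    carriers: dict[tuple[str, str], set[str]] = {}
    for cnv in kept_cnvs:
        event = event_ids.get(cnv.cnv_id)
        if event is None:
            continue
        carriers.setdefault((event, cnv.family_id), set()).add(cnv.sample_id)
    rows = []
    for (event, family_id), samples in sorted(carriers.items()):
        n_affected = sum(
            1 for s in samples if pedigree.get(s).phenotype == "affected"
        )
        n_unaffected = sum(
            1 for s in samples if pedigree.get(s).phenotype == "unaffected"
        )
        rows.append(
            {
                "event_id": event,
                "family_id": family_id,
                "n_affected_carriers": n_affected,
                "n_unaffected_carriers": n_unaffected,
                "segregates": n_affected >= 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id", "family_id", "n_affected_carriers",
            "n_unaffected_carriers", "segregates",
        ],
    )
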