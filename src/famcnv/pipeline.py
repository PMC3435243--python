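"""End-to-end orchestration of the discovery pipeline.

Stages, in order: two-caller consensus merge; excessive-call sample QC;
burden comparison; pooled region association; the rarity filter chain;
transmission classification with de novo rates and cosegregation; gene-level
prioritization.  The same function serves simulated bundles and file-based
inputs (the CLI builds a :class:`famcnv.simulate.SimulatedCohort`-shaped
bundle from files).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .burden import BurdenSummary, burden_summary
from .merge import MergedCnv, merge_cohort
from .pools import build_pools, enrichment_screen
from .prioritize import (
    build_evidence_profiles,
    fuse_rankings,
    intersect_genes,
    profiles_to_frame,
    sage_fold_table,
)
from .qc import QcReport, exclude_outlier_samples
from .rarity import ChainResult, run_filter_chain
from .segregation import (
    build_parental_index,
    classify_all,
    cosegregation_scan,
    de_novo_rate,
    trio_set,
)
from .simulate import SimulatedCohort


@dataclass
class PipelineResult:
    merged: list[MergedCnv]
    control_merged: list[MergedCnv]
    qc: QcReport
    burden: BurdenSummary | None
    pool_table: pd.DataFrame
    chain: ChainResult
    transmissions: list
    de_novo_rates: pd.DataFrame
    cosegregation: pd.DataFrame
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)
    kept_genes: list[str] = field(default_factory=list)


def run_pipeline(
    bundle: SimulatedCohort,
    n_burden_permutations: int = 2000,
    fusion_null_draws: int = 10_000,
    run_burden: bool = True,
    seed: int = 0,
) -> PipelineResult:
    pedigree = bundle.pedigree
    truth = bundle.truth

    merged = merge_cohort(bundle.calls_a, bundle.calls_b)
    control_merged = merge_cohort(bundle.control_calls_a, bundle.control_calls_b)

    counts = {i.individual_id: 0 for i in pedigree}
    for m in merged:
        counts[m.sample_id] = counts.get(m.sample_id, 0) + 1
    qc = exclude_outlier_samples(counts)
    retained = set(qc.retained_samples)
    merged = [m for m in merged if m.sample_id in retained]

    burden_result = None
    if run_burden:
        burden_result = burden_summary(
            merged, pedigree, truth.gene_track,
            n_permutations=n_burden_permutations, seed=seed,
        )

    pools = build_pools(merged)
    pool_table = enrichment_screen(pools, pedigree)

    affected_ids = {i.individual_id for i in pedigree.affected()} & retained
    unaffected_ids = {i.individual_id for i in pedigree.unaffected()} & retained
    affected_cnvs = [m for m in merged if m.sample_id in affected_ids]
    unaffected_cnvs = [m for m in merged if m.sample_id in unaffected_ids]
    chain = run_filter_chain(
        affected_cnvs,
        unaffected_cnvs,
        control_merged,
        truth.segdup_track,
        truth.known_track,
        pedigree,
    )

    parental_index = build_parental_index(
        merged, list(bundle.calls_a) + list(bundle.calls_b)
    )
    genotyped = retained
    transmissions = classify_all(
        chain.kept, pedigree, parental_index, genotyped=genotyped
    )
    offspring_calls: dict[str, list[MergedCnv]] = {}
    for m in merged:
        offspring_calls.setdefault(m.sample_id, []).append(m)
    trios = trio_set(pedigree, genotyped)
    rates = de_novo_rate(trios, offspring_calls, pedigree, parental_index)
    coseg = cosegregation_scan(chain.kept, chain.event_ids, pedigree)

    kept_genes = sorted({g.name for _, g in intersect_genes(chain.kept, truth.gene_track)})
    evidence = pd.DataFrame()
    if len(kept_genes) >= 2 and not bundle.score_table.empty:
        scores = bundle.score_table[bundle.score_table["gene"].isin(kept_genes)]
        fused = fuse_rankings(scores, n_null=fusion_null_draws, seed=seed + 1)
        fusion_p = dict(zip(fused["gene"], fused["fusion_p"]))
        folds = sage_fold_table(
            bundle.sage_table[bundle.sage_table["gene"].isin(kept_genes)]
        )
        profiles = build_evidence_profiles(
            kept_genes, fusion_p, folds, bundle.flag_table
        )
        evidence = profiles_to_frame(profiles)

    return PipelineResult(
        merged=merged,
        control_merged=control_merged,
        qc=qc,
        burden=burden_result,
        pool_table=pool_table,
        chain=chain,
        transmissions=transmissions,
        de_novo_rates=rates,
        cosegregation=coseg,
        evidence=evidence,
        kept_genes=kept_genes,
    )


@dataclass
class TruthEvaluation:
    causal_recovery: float
    n_causal_recovered: int
    n_causal_planted: int
    n_cnp_survivors: int
    n_artifact_survivors: int
    n_unattributed_survivors: int
    transmission_accuracy: float
    n_transmission_checked: int


def evaluate_against_truth(result: PipelineResult, bundle: SimulatedCohort) -> TruthEvaluation:
    """Score a pipeline run against the generator's ground truth."""
    truth = bundle.truth
    recovered: set[str] = set()
    n_cnp = n_artifact = n_unattributed = 0
    for cnv in result.chain.kept:
        origin = truth.attribute(cnv.sample_id, cnv.interval)
        if origin == "cnp":
            n_cnp += 1
        elif origin == "artifact":
            n_artifact += 1
        elif origin is None:
            n_unattributed += 1
        elif origin == "causal":
            for locus_id, carriers in truth.causal_carriers.items():
                locus = truth.loci[locus_id]
                if cnv.sample_id in carriers and locus.interval.overlaps(cnv.interval):
                    recovered.add(locus_id)

    n_checked = n_correct = 0
    for call in result.transmissions:
        expected = truth.expected_transmission(call.individual_id, call.cnv.interval)
        if expected is None:
            continue
        observed = call.status
        if expected == "de_novo":
            ok = observed == "de_novo"
        elif expected == "inherited":
            ok = observed.startswith("inherited")
        else:  # founder carriage: parents out of pedigree -> unknown
            ok = observed == "unknown"
        n_checked += 1
        n_correct += int(ok)

    n_planted = len(truth.causal_carriers)
    return TruthEvaluation(
        causal_recovery=len(recovered) / n_planted if n_planted else 1.0,
        n_causal_recovered=len(recovered),
        n_causal_planted=n_planted,
        n_cnp_survivors=n_cnp,
        n_artifact_survivors=n_artifact,
        n_unattributed_survivors=n_unattributed,
        transmission_accuracy=n_correct / n_checked if n_checked else 1.0,
        n_transmission_checked=n_checked,
    )
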