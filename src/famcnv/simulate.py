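"""Seeded synthetic cohort generator with known ground truth.

The generator builds, deterministically from a mandatory seed:

* three-generation multiplex pedigrees (founder couple, their children, one
  or two married-in spouses, grandchildren) at a configurable family count;
* an abstract diploid genome (22 "autosomes" of uniform length — tests need
  controlled geometry, not real human coordinates) carrying non-overlapping
  loci: common copy-number polymorphisms (CNPs) drifting through the
  pedigrees by Mendelian allele transmission, rare planted causal CNVs
  transmitted with the phenotype, spontaneous de novo events per offspring,
  and segmental-duplication regions that spawn correlated artifact calls;
* two noisy caller outputs per individual (independent boundary jitter,
  false negatives per caller, uncorrelated false-positive calls) plus an
  external control cohort drawn from the same CNP frequencies;
* annotation tracks (segdups, known common variants, genes) and gene-level
  evidence tables (per-source scores, SAGE tag counts, expression flags) in
  which designated causal genes receive favorable evidence.

Phenotypes follow a two-parameter model: causal carriers are affected with
the configured penetrance, everyone else with a background prevalence solved
so the cohort-wide affected fraction hits its target.  Every simulated call
is attributable to exactly one truth source (causal, CNP, de novo, artifact,
or caller false positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .intervals import GenomicInterval
from .io import (
    CnvCall,
    Individual,
    Pedigree,
    TrackRecord,
    write_bed_track,
    write_cnv_table,
    write_pedigree,
)

Origin = Literal["causal", "cnp", "de_novo", "artifact"]

N_SIM_CHROMS = 22
CONTROL_FAMILY_ID = "CTRL"


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort; the seed is mandatory."""

    seed: int
    n_families: int = 60
    generations: int = 3
    affected_target_fraction: float = 0.375
    mean_calls_per_sample: float = 15.0
    n_common_cnps: int = 50
    cnp_frequency_range: tuple[float, float] = (0.05, 0.40)
    n_segdup_regions: int = 10
    n_segdup_artifacts: int = 10
    n_planted_causal: int = 5
    causal_penetrance: float = 1.0
    background_prevalence: float | None = None  # solved when None
    de_novo_probability: float = 0.02
    caller_jitter: float = 0.1
    caller_fp_rate: float = 1.0  # mean uncorrelated false calls per sample per caller
    caller_fn_rate: float = 0.02  # per true call per caller
    n_controls: int = 200
    n_genes: int = 300
    gene_size_range: tuple[int, int] = (10_000, 200_000)
    cnv_size_range: tuple[int, int] = (50_000, 300_000)
    chrom_length: int = 100_000_000
    n_score_sources: int = 3
    evidence_strength: float = 3.0  # causal-gene score shift, null-SD units

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValidationError("n_families must be >= 1")
        if self.generations < 2:
            raise ValidationError("generations must be >= 2")
        for name in ("affected_target_fraction", "causal_penetrance",
                     "de_novo_probability", "caller_fn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class Locus:
    locus_id: str
    interval: GenomicInterval
    origin: Origin
    state: str  # loss or gain for carriers
    copy_number: int  # carrier copy number (heterozygous single-allele state)
    frequency: float = 0.0  # CNP allele frequency; 0 for rare loci


@dataclass(frozen=True)
class TrueCall:
    """One individual's true carriage of one locus."""

    sample_id: str
    family_id: str
    locus: Locus
    copy_number: int

    @property
    def state(self) -> str:
        return "loss" if self.copy_number < 2 else "gain"


@dataclass
class GroundTruth:
    loci: dict[str, Locus]
    true_calls: dict[str, list[TrueCall]]  # sample -> carriages
    causal_carriers: dict[str, set[str]]  # causal locus -> carrier samples
    # offspring carriers of causal/de-novo loci with the transmitting parent,
    # or None for a spontaneous (de novo) event / founder carriage
    transmissions: dict[tuple[str, str], str | None]  # (sample, locus) -> parent
    artifact_calls: list[tuple[str, GenomicInterval]]  # (sample, interval)
    segdup_track: list[TrackRecord] = field(default_factory=list)
    known_track: list[TrackRecord] = field(default_factory=list)
    gene_track: list[TrackRecord] = field(default_factory=list)
    causal_genes: set[str] = field(default_factory=set)

    def attribute(self, sample_id: str, interval: GenomicInterval) -> str | None:
        """Truth origin of a call by maximal-overlap locus matching."""
        best, best_shared = None, 0
        for call in self.true_calls.get(sample_id, ()):
            shared = call.locus.interval.overlap_bases(interval)
            if shared > best_shared:
                best, best_shared = call.locus.origin, shared
        if best is None:
            for art_sample, art_interval in self.artifact_calls:
                if art_sample == sample_id and art_interval.overlaps(interval):
                    return "artifact"
        return best

    def expected_transmission(self, sample_id: str, interval: GenomicInterval) -> str | None:
        """Truth transmission class for a call: de_novo / inherited / founder."""
        for call in self.true_calls.get(sample_id, ()):
            if call.locus.interval.overlaps(interval):
                key = (sample_id, call.locus.locus_id)
                if call.locus.origin == "de_novo":
                    return "de_novo"
                if key in self.transmissions:
                    parent = self.transmissions[key]
                    return "inherited" if parent is not None else "founder"
                return "founder"
        return None


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    pedigree: Pedigree
    truth: GroundTruth
    calls_a: list[CnvCall]
    calls_b: list[CnvCall]
    control_calls_a: list[CnvCall]
    control_calls_b: list[CnvCall]
    control_samples: list[str]
    score_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    sage_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    flag_table: dict[str, str] = field(default_factory=dict)

    def write_bundle(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_pedigree(self.pedigree, directory / "cohort.ped")
        write_cnv_table(self.calls_a + self.control_calls_a, directory / "caller_a.cnv")
        write_cnv_table(self.calls_b + self.control_calls_b, directory / "caller_b.cnv")
        write_bed_track(self.truth.segdup_track, directory / "segdups.bed")
        write_bed_track(self.truth.known_track, directory / "known_cnvs.bed")
        write_bed_track(self.truth.gene_track, directory / "genes.bed")
        self.score_table.to_csv(directory / "gene_scores.tsv", sep="\t", index=False)
        self.sage_table.to_csv(directory / "sage_counts.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gene": list(self.flag_table), "flag": list(self.flag_table.values())}
        ).to_csv(directory / "expression_flags.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gene": sorted(self.truth.causal_genes)}
        ).to_csv(directory / "causal_genes.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


def simulate_pedigrees(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Three-generation multiplex family structures (phenotypes still unknown)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    individuals: list[Individual] = []
    for f in range(config.n_families):
        fid = f"F{f + 1:03d}"
        counter = [0]

        def new_id() -> str:
            counter[0] += 1
            return f"{fid}I{counter[0]:02d}"

        father = Individual(new_id(), fid, None, None, "male", "unknown")
        mother = Individual(new_id(), fid, None, None, "female", "unknown")
        individuals.extend([father, mother])
        n_children = int(rng.integers(2, 4))
        children = []
        for _ in range(n_children):
            sex = "male" if rng.random() < 0.5 else "female"
            child = Individual(
                new_id(), fid, father.individual_id, mother.individual_id, sex, "unknown"
            )
            children.append(child)
            individuals.append(child)
        if config.generations >= 3:
            n_marrying = 1 + int(rng.random() < 0.25)
            for child in children[:n_marrying]:
                spouse_sex = "female" if child.sex == "male" else "male"
                spouse = Individual(new_id(), fid, None, None, spouse_sex, "unknown")
                individuals.append(spouse)
                pat = child if child.sex == "male" else spouse
                mat = spouse if child.sex == "male" else child
                for _ in range(int(rng.integers(1, 3))):
                    sex = "male" if rng.random() < 0.5 else "female"
                    individuals.append(
                        Individual(
                            new_id(), fid, pat.individual_id, mat.individual_id,
                            sex, "unknown",
                        )
                    )
    return Pedigree(individuals)


# ---------------------------------------------------------------------------
# Genome and true CNVs
# ---------------------------------------------------------------------------


class _GenomePlacer:
    """Rejection-samples non-overlapping loci on the abstract genome."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator, margin: int = 50_000):
        self.config = config
        self.rng = rng
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {}

    def place(self, length: int) -> GenomicInterval:
        for _ in range(10_000):
            chrom = str(int(self.rng.integers(1, N_SIM_CHROMS + 1)))
            start = int(self.rng.integers(1, self.config.chrom_length - length))
            lo, hi = start - self.margin, start + length + self.margin
            if all(e < lo or s > hi for s, e in self.occupied.get(chrom, [])):
                self.occupied.setdefault(chrom, []).append((start, start + length - 1))
                return GenomicInterval(chrom, start, start + length - 1)
        raise ValidationError("genome too crowded to place another locus")

    def place_sized(self, size_range: tuple[int, int]) -> GenomicInterval:
        length = int(self.rng.integers(size_range[0], size_range[1] + 1))
        return self.place(length)


def _family_order(pedigree: Pedigree, family_id: str) -> list[Individual]:
    """Members in parents-before-children order."""
    members = pedigree.members(family_id)
    done: dict[str, Individual] = {}
    pending = list(members)
    while pending:
        progressed = False
        for ind in list(pending):
            if all(p is None or p.individual_id in done for p in pedigree.parents_of(ind)):
                done[ind.individual_id] = ind
                pending.remove(ind)
                progressed = True
        if not progressed:  # pragma: no cover - guarded by pedigree validation
            raise ValidationError("unresolvable pedigree ordering")
    return list(done.values())


def simulate_genome_and_cnvs(
    config: SimulationConfig,
    pedigree: Pedigree,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Plant loci, drop alleles through the pedigrees, assign phenotypes.

    Phenotypes are written back onto the pedigree's individuals.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    placer = _GenomePlacer(config, rng)
    loci: dict[str, Locus] = {}
    true_calls: dict[str, list[TrueCall]] = {}
    transmissions: dict[tuple[str, str], str | None] = {}
    causal_carriers: dict[str, set[str]] = {}

    # segdup regions first so artifact placement can target them
    segdup_track = []
    for i in range(config.n_segdup_regions):
        iv = placer.place(int(rng.integers(100_000, 500_000)))
        segdup_track.append(TrackRecord(iv, f"segdup{i + 1:03d}"))

    # CNP loci; frequencies scaled so expected carrier calls/sample match the
    # configured mean (carrier probability 1-(1-f)^2 per locus)
    raw_freqs = rng.uniform(*config.cnp_frequency_range, size=config.n_common_cnps)
    target = config.mean_calls_per_sample
    for _ in range(40):
        expected = float(np.sum(1.0 - (1.0 - raw_freqs) ** 2))
        if expected <= 0:
            break
        raw_freqs = np.clip(raw_freqs * (target / expected), 0.005, 0.6)
        if abs(expected - target) / target < 1e-6:
            break
    known_track = []
    cnp_loci: list[Locus] = []
    for i, freq in enumerate(raw_freqs):
        iv = placer.place_sized(config.cnv_size_range)
        delta = 1 if rng.random() < 0.5 else -1
        locus = Locus(
            locus_id=f"CNP{i + 1:03d}", interval=iv, origin="cnp",
            state="gain" if delta > 0 else "loss", copy_number=2 + delta,
            frequency=float(freq),
        )
        loci[locus.locus_id] = locus
        cnp_loci.append(locus)
        known_track.append(TrackRecord(iv, locus.locus_id, {"freq": f"{freq:.3f}"}))

    # causal loci, one per selected family
    families = pedigree.families()
    if config.n_planted_causal > len(families):
        raise ValidationError("more causal loci than families")
    causal_families = list(
        rng.choice(families, size=config.n_planted_causal, replace=False)
    )
    causal_loci: list[Locus] = []
    for i, fam in enumerate(causal_families):
        iv = placer.place_sized(config.cnv_size_range)
        delta = 1 if rng.random() < 0.5 else -1
        locus = Locus(
            locus_id=f"CAUSAL{i + 1:02d}", interval=iv, origin="causal",
            state="gain" if delta > 0 else "loss", copy_number=2 + delta,
        )
        loci[locus.locus_id] = locus
        causal_loci.append(locus)
        causal_carriers[locus.locus_id] = set()

    def add_call(ind: Individual, locus: Locus, copy_number: int) -> None:
        true_calls.setdefault(ind.individual_id, []).append(
            TrueCall(ind.individual_id, ind.family_id, locus, copy_number)
        )

    # CNP allele drop: founders from the population frequency, offspring by
    # Mendelian transmission of allele counts
    cnp_alleles: dict[tuple[str, str], int] = {}  # (sample, locus) -> allele count
    for fam in families:
        ordered = _family_order(pedigree, fam)
        for ind in ordered:
            father, mother = pedigree.parents_of(ind)
            for locus in cnp_loci:
                if ind.is_founder:
                    a = int(rng.binomial(2, locus.frequency))
                else:
                    a = int(
                        rng.random() < cnp_alleles[(father.individual_id, locus.locus_id)] / 2.0
                    ) + int(
                        rng.random() < cnp_alleles[(mother.individual_id, locus.locus_id)] / 2.0
                    )
                cnp_alleles[(ind.individual_id, locus.locus_id)] = a
                if a > 0:
                    delta = locus.copy_number - 2
                    cn = max(0, 2 + delta * a)
                    add_call(ind, locus, cn)
                    if not ind.is_founder:
                        carrier_parent = None
                        for parent in (father, mother):
                            if cnp_alleles[(parent.individual_id, locus.locus_id)] > 0:
                                carrier_parent = parent.individual_id
                                break
                        transmissions[(ind.individual_id, locus.locus_id)] = carrier_parent

    # causal allele drop: seed the founder father, force the lineage through
    # the reproducing child so every causal CNV is multiplex-transmitted
    for locus, fam in zip(causal_loci, causal_families):
        ordered = _family_order(pedigree, fam)
        has_children = {
            pid
            for ind in ordered
            for pid in (ind.father_id, ind.mother_id)
            if pid is not None
        }
        carrier: dict[str, bool] = {}
        for ind in ordered:
            father, mother = pedigree.parents_of(ind)
            if ind.is_founder:
                # seed carrier: the founder father of generation 1
                carrier[ind.individual_id] = (
                    ind.sex == "male" and ind.father_id is None and
                    not any(carrier.values()) and ind.individual_id in has_children
                )
                continue
            parent_carrier = next(
                (
                    p.individual_id
                    for p in (father, mother)
                    if p is not None and carrier.get(p.individual_id, False)
                ),
                None,
            )
            if parent_carrier is None:
                carrier[ind.individual_id] = False
                continue
            # transmit with probability 1/2, but force transmission to the
            # reproducing child so the variant reaches generation 3
            inherit = rng.random() < 0.5 or ind.individual_id in has_children
            carrier[ind.individual_id] = inherit
            if inherit:
                transmissions[(ind.individual_id, locus.locus_id)] = parent_carrier
        # guarantee a multiplex (>=2 carrier) event even in 2-generation runs
        if sum(carrier.values()) < 2:
            seed_id = next(i for i, c in carrier.items() if c)
            fallback = next(
                ind for ind in ordered
                if ind.father_id == seed_id or ind.mother_id == seed_id
            )
            carrier[fallback.individual_id] = True
            transmissions[(fallback.individual_id, locus.locus_id)] = seed_id
        for ind in ordered:
            if carrier[ind.individual_id]:
                add_call(ind, locus, locus.copy_number)
                causal_carriers[locus.locus_id].add(ind.individual_id)

    # spontaneous de novo events per offspring with two in-pedigree parents
    de_novo_counter = 0
    for fam in families:
        for ind in pedigree.members(fam):
            if ind.father_id is None or ind.mother_id is None:
                continue
            if rng.random() < config.de_novo_probability:
                de_novo_counter += 1
                iv = placer.place_sized(config.cnv_size_range)
                delta = 1 if rng.random() < 0.5 else -1
                locus = Locus(
                    locus_id=f"DN{de_novo_counter:03d}", interval=iv,
                    origin="de_novo", state="gain" if delta > 0 else "loss",
                    copy_number=2 + delta,
                )
                loci[locus.locus_id] = locus
                add_call(ind, locus, locus.copy_number)

    # phenotypes: carriers via penetrance, background solved to hit the target
    all_causal_carriers = set().union(*causal_carriers.values()) if causal_carriers else set()
    n_total = len(pedigree)
    n_carriers = len(all_causal_carriers)
    if config.background_prevalence is not None:
        background = config.background_prevalence
    else:
        expected_carrier_affected = n_carriers * config.causal_penetrance
        background = (
            config.affected_target_fraction * n_total - expected_carrier_affected
        ) / max(1, n_total - n_carriers)
        background = min(1.0, max(0.0, background))
    for ind in pedigree:
        if ind.individual_id in all_causal_carriers:
            affected = rng.random() < config.causal_penetrance
        else:
            affected = rng.random() < background
        ind.phenotype = "affected" if affected else "unaffected"

    # correlated artifact calls inside segdup regions, assigned to affecteds
    affected_ids = [i.individual_id for i in pedigree.affected()]
    artifact_calls: list[tuple[str, GenomicInterval]] = []
    for _ in range(config.n_segdup_artifacts):
        region = segdup_track[int(rng.integers(0, len(segdup_track)))].interval
        length = max(25_000, int(region.length * rng.uniform(0.5, 0.9)))
        start = int(rng.integers(region.start, max(region.start + 1, region.end - length)))
        iv = GenomicInterval(region.chrom, start, min(region.end, start + length - 1))
        sample = str(rng.choice(affected_ids))
        artifact_calls.append((sample, iv))

    # gene track: one designated causal gene inside every causal locus, the
    # rest placed uniformly
    gene_track: list[TrackRecord] = []
    causal_genes: set[str] = set()
    gene_counter = 0
    for locus in causal_loci:
        gene_counter += 1
        name = f"G{gene_counter:04d}"
        margin = max(1, locus.interval.length // 10)
        g_start = locus.interval.start + margin
        g_end = min(locus.interval.end, g_start + max(5_000, locus.interval.length // 3))
        gene_track.append(
            TrackRecord(GenomicInterval(locus.interval.chrom, g_start, g_end), name)
        )
        causal_genes.add(name)
    while gene_counter < config.n_genes:
        gene_counter += 1
        length = int(rng.integers(*config.gene_size_range))
        chrom = str(int(rng.integers(1, N_SIM_CHROMS + 1)))
        start = int(rng.integers(1, config.chrom_length - length))
        gene_track.append(
            TrackRecord(
                GenomicInterval(chrom, start, start + length - 1), f"G{gene_counter:04d}"
            )
        )

    return GroundTruth(
        loci=loci,
        true_calls=true_calls,
        causal_carriers=causal_carriers,
        transmissions=transmissions,
        artifact_calls=artifact_calls,
        segdup_track=segdup_track,
        known_track=known_track,
        gene_track=gene_track,
        causal_genes=causal_genes,
    )


# ---------------------------------------------------------------------------
# Caller outputs
# ---------------------------------------------------------------------------


def _jittered(iv: GenomicInterval, jitter: float, rng: np.random.Generator) -> GenomicInterval:
    shift = jitter * iv.length
    start = max(1, int(round(iv.start + rng.uniform(-shift, shift))))
    end = int(round(iv.end + rng.uniform(-shift, shift)))
    if end <= start:
        end = start + 1
    return GenomicInterval(iv.chrom, start, end)


def _probes(length: int, rng: np.random.Generator) -> int:
    return max(3, int(round(length / 1500.0 * rng.uniform(0.9, 1.1))))


def simulate_caller_outputs(
    truth: GroundTruth,
    config: SimulationConfig,
    pedigree: Pedigree,
    rng: np.random.Generator | None = None,
) -> tuple[list[CnvCall], list[CnvCall]]:
    """Two noisy call sets for the pedigree cohort.

    True carriages are emitted by each caller independently (jitter per end,
    dropped at the false-negative rate); correlated segdup artifacts are
    emitted by both callers; uncorrelated false positives are added per
    caller at the configured rate.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    calls_a: list[CnvCall] = []
    calls_b: list[CnvCall] = []

    def emit(sample: str, family: str, iv: GenomicInterval, cn: int,
             out: list[CnvCall], caller: str) -> None:
        jit = _jittered(iv, config.caller_jitter, rng)
        out.append(
            CnvCall(
                sample_id=sample, family_id=family, interval=jit,
                copy_number=cn, state="loss" if cn < 2 else "gain",
                n_probes=_probes(jit.length, rng),
                confidence=float(rng.uniform(15.0, 60.0)), caller=caller,
            )
        )

    for ind in pedigree:
        for call in truth.true_calls.get(ind.individual_id, ()):
            for caller, out in (("A", calls_a), ("B", calls_b)):
                if rng.random() < config.caller_fn_rate:
                    continue
                emit(ind.individual_id, ind.family_id, call.locus.interval,
                     call.copy_number, out, caller)
        # uncorrelated false positives at random novel locations
        for caller, out in (("A", calls_a), ("B", calls_b)):
            for _ in range(int(rng.poisson(config.caller_fp_rate))):
                length = int(rng.integers(*config.cnv_size_range))
                chrom = str(int(rng.integers(1, N_SIM_CHROMS + 1)))
                start = int(rng.integers(1, config.chrom_length - length))
                cn = 1 if rng.random() < 0.5 else 3
                iv = GenomicInterval(chrom, start, start + length - 1)
                out.append(
                    CnvCall(
                        sample_id=ind.individual_id, family_id=ind.family_id,
                        interval=iv, copy_number=cn,
                        state="loss" if cn < 2 else "gain",
                        n_probes=_probes(iv.length, rng),
                        confidence=float(rng.uniform(5.0, 40.0)), caller=caller,
                    )
                )

    # correlated artifacts: both callers emit
    for sample, iv in truth.artifact_calls:
        family = pedigree.get(sample).family_id
        emit(sample, family, iv, 3, calls_a, "A")
        emit(sample, family, iv, 3, calls_b, "B")
    return calls_a, calls_b


def simulate_control_cohort(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[CnvCall], list[CnvCall], list[str]]:
    """Caller outputs for unrelated controls drawn from the CNP frequencies."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    cnp_loci = [l for l in truth.loci.values() if l.origin == "cnp"]
    calls_a: list[CnvCall] = []
    calls_b: list[CnvCall] = []
    samples = [f"C{i + 1:04d}" for i in range(config.n_controls)]
    for sample in samples:
        for locus in cnp_loci:
            a = int(rng.binomial(2, locus.frequency))
            if a == 0:
                continue
            delta = locus.copy_number - 2
            cn = max(0, 2 + delta * a)
            for caller, out in (("A", calls_a), ("B", calls_b)):
                if rng.random() < config.caller_fn_rate:
                    continue
                jit = _jittered(locus.interval, config.caller_jitter, rng)
                out.append(
                    CnvCall(
                        sample_id=sample, family_id=CONTROL_FAMILY_ID, interval=jit,
                        copy_number=cn, state="loss" if cn < 2 else "gain",
                        n_probes=_probes(jit.length, rng),
                        confidence=float(rng.uniform(15.0, 60.0)), caller=caller,
                    )
                )
    return calls_a, calls_b, samples


# ---------------------------------------------------------------------------
# Evidence tables
# ---------------------------------------------------------------------------


def simulate_evidence_tables(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Per-source gene scores, SAGE tag counts, and expression flags.

    Causal genes draw scores from a distribution shifted by
    ``evidence_strength`` null standard deviations, an outflow-tract SAGE
    rate eight times the chamber rate, and a ``+`` flag with probability 0.9;
    background genes draw from exchangeable nulls (flag ``+`` rate 0.1).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    genes = [g.name for g in truth.gene_track]
    causal = truth.causal_genes

    score_rows = []
    for source_idx in range(config.n_score_sources):
        source = f"source{source_idx + 1}"
        for gene in genes:
            mu = config.evidence_strength if gene in causal else 0.0
            score_rows.append(
                {"gene": gene, "source": source, "score": float(rng.normal(mu, 1.0))}
            )
    score_table = pd.DataFrame(score_rows)

    library_sizes = {"outflow_tract": 180_000, "atrium": 200_000, "ventricle": 220_000}
    sage_rows = []
    for gene in genes:
        base_tpm = float(rng.lognormal(mean=3.0, sigma=1.0))  # ~20 tpm median
        for compartment, lib in library_sizes.items():
            tpm = base_tpm * (8.0 if (gene in causal and compartment == "outflow_tract") else 1.0)
            lam = tpm * lib / 1e6
            sage_rows.append(
                {
                    "gene": gene, "compartment": compartment,
                    "tag_count": int(rng.poisson(lam)), "library_size": lib,
                }
            )
    sage_table = pd.DataFrame(sage_rows)

    flags = {
        gene: "+" if rng.random() < (0.9 if gene in causal else 0.1) else "-"
        for gene in genes
    }
    return score_table, sage_table, flags


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Deterministically generate the full input bundle from one seed."""
    root = np.random.default_rng(config.seed)
    streams = [np.random.default_rng(s) for s in root.integers(0, 2**31 - 1, size=5)]
    pedigree = simulate_pedigrees(config, streams[0])
    truth = simulate_genome_and_cnvs(config, pedigree, streams[1])
    calls_a, calls_b = simulate_caller_outputs(truth, config, pedigree, streams[2])
    ctrl_a, ctrl_b, control_samples = simulate_control_cohort(truth, config, streams[3])
    score_table, sage_table, flags = simulate_evidence_tables(truth, config, streams[4])
    return SimulatedCohort(
        config=config,
        pedigree=pedigree,
        truth=truth,
        calls_a=calls_a,
        calls_b=calls_b,
        control_calls_a=ctrl_a,
        control_calls_b=ctrl_b,
        control_samples=control_samples,
        score_table=score_table,
        sage_table=sage_table,
        flag_table=flags,
    )
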