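"""Readers and writers for every external file the pipeline touches.

Formats
-------
* CNV tables: PLINK ``.cnv``-style TSV with a header row
  ``FID IID CHR BP1 BP2 TYPE NPROBES CONF [SOURCE]``, coordinates 1-based
  inclusive, ``TYPE`` the integer copy number.
* Pedigrees: 6-column PED (``FID IID PAT MAT SEX PHENO``), whitespace
  delimited, no header; ``PHENO`` 2=affected, 1=unaffected, 0/-9=unknown;
  ``SEX`` 1=male, 2=female, 0=unknown; founder parent ids are ``"0"``.
* Annotation tracks: BED3+ (0-based half-open), converted to the internal
  1-based inclusive convention on read and back on write.
* Evidence tables: simple TSVs for SAGE tag counts, per-source gene scores,
  and curated expression flags.

All validation errors carry the offending line number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .intervals import GenomicInterval, is_autosome, normalize_chrom

Sex = Literal["male", "female", "unknown"]
Phenotype = Literal["affected", "unaffected", "unknown"]
State = Literal["loss", "gain", "normal"]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_PHENO_CODES = {"2": "affected", "1": "unaffected", "0": "unknown", "-9": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}
_PHENO_TO_CODE = {"affected": "2", "unaffected": "1", "unknown": "0"}


def reference_copy_number(chrom: str, sex: Sex = "unknown") -> int:
    """Reference (expected diploid) copy number for a chromosome.

    Autosomes: 2.  X: 1 in males, 2 otherwise.  Y: 1 in males, 0 in females;
    an unknown sex on Y defaults to the male reference of 1.
    """
    if is_autosome(chrom):
        return 2
    if chrom == "X":
        return 1 if sex == "male" else 2
    return 0 if sex == "female" else 1


def state_from_copy_number(copy_number: int, reference: int = 2) -> State:
    if copy_number < reference:
        return "loss"
    if copy_number > reference:
        return "gain"
    return "normal"


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV segment for one sample."""

    sample_id: str
    family_id: str
    interval: GenomicInterval
    copy_number: int
    state: State
    n_probes: int
    confidence: float
    caller: str  # "A" or "B"

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValidationError("copy_number must be non-negative")
        if self.n_probes < 1:
            raise ValidationError("n_probes must be >= 1")
        if self.confidence < 0:
            raise ValidationError("confidence must be non-negative")


@dataclass
class Individual:
    """One pedigree member."""

    individual_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    phenotype: Phenotype

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A collection of individuals keyed by (family, individual) id.

    Individual ids are additionally required to be unique across families so
    that CNV sample ids resolve without ambiguity.  Parent references must
    point into the same family, respect the recorded sexes, and be acyclic
    (pedigrees with marriage loops or inbreeding are rejected).
    """

    def __init__(self, individuals: Iterable[Individual]):
        self._by_key: dict[tuple[str, str], Individual] = {}
        self._by_iid: dict[str, Individual] = {}
        for ind in individuals:
            key = (ind.family_id, ind.individual_id)
            if key in self._by_key:
                raise ValidationError(f"duplicate individual {key}")
            if ind.individual_id in self._by_iid:
                raise ValidationError(
                    f"individual id {ind.individual_id!r} reused across families"
                )
            self._by_key[key] = ind
            self._by_iid[ind.individual_id] = ind
        self._validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_iid

    # -- lookups ------------------------------------------------------------
    def get(self, individual_id: str) -> Individual:
        try:
            return self._by_iid[individual_id]
        except KeyError:
            raise ValidationError(f"unknown individual {individual_id!r}") from None

    def families(self) -> list[str]:
        return sorted({fid for fid, _ in self._by_key})

    def members(self, family_id: str) -> list[Individual]:
        return [i for i in self if i.family_id == family_id]

    def affected(self) -> list[Individual]:
        return [i for i in self if i.phenotype == "affected"]

    def unaffected(self) -> list[Individual]:
        return [i for i in self if i.phenotype == "unaffected"]

    def phenotyped(self) -> list[Individual]:
        return [i for i in self if i.phenotype != "unknown"]

    def parents_of(
        self, individual: Individual
    ) -> tuple[Individual | None, Individual | None]:
        father = self._by_iid.get(individual.father_id) if individual.father_id else None
        mother = self._by_iid.get(individual.mother_id) if individual.mother_id else None
        return father, mother

    def trios(self, genotyped: set[str] | None = None) -> list[tuple[Individual, Individual, Individual]]:
        """All (offspring, father, mother) triples with every member genotyped.

        ``genotyped`` defaults to the full membership.
        """
        ok = genotyped if genotyped is not None else {i.individual_id for i in self}
        out = []
        for ind in self:
            if ind.father_id and ind.mother_id:
                if {ind.individual_id, ind.father_id, ind.mother_id} <= ok:
                    out.append((ind, self.get(ind.father_id), self.get(ind.mother_id)))
        return out

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        for ind in self:
            for pid, want_sex, role in (
                (ind.father_id, "male", "father"),
                (ind.mother_id, "female", "mother"),
            ):
                if pid is None:
                    continue
                parent = self._by_key.get((ind.family_id, pid))
                if parent is None:
                    raise ValidationError(
                        f"{role} {pid!r} of {ind.individual_id!r} not found in "
                        f"family {ind.family_id!r}"
                    )
                if parent.sex != want_sex:
                    raise ValidationError(
                        f"{role} {pid!r} of {ind.individual_id!r} is not {want_sex}"
                    )
        # cycle detection by DFS over parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        color = {iid: WHITE for iid in self._by_iid}

        def visit(iid: str) -> None:
            color[iid] = GREY
            ind = self._by_iid[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                if color[pid] == GREY:
                    raise ValidationError(f"pedigree cycle through {pid!r}")
                if color[pid] == WHITE:
                    visit(pid)
            color[iid] = BLACK

        for iid in list(color):
            if color[iid] == WHITE:
                visit(iid)


@dataclass(frozen=True)
class TrackRecord:
    """One record of an annotation track (segdup, known CNV, gene, ...)."""

    interval: GenomicInterval
    name: str
    attributes: Mapping[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CNV tables
# ---------------------------------------------------------------------------

CNV_COLUMNS = ["FID", "IID", "CHR", "BP1", "BP2", "TYPE", "NPROBES", "CONF"]


def read_cnv_table(
    path: str | Path,
    caller_tag: str,
    sexes: Mapping[str, Sex] | None = None,
    allow_normal: bool = False,
) -> list[CnvCall]:
    """Read a PLINK-style ``.cnv`` TSV into :class:`CnvCall` records.

    ``TYPE`` is the integer copy number; the loss/gain state is derived
    against the sex-aware reference copy number.  Rows whose copy number
    equals the reference are rejected unless ``allow_normal`` is set (raw
    common-CNP caller output legitimately contains reference-state rows whose
    population normal state is resolved later).
    """
    path = Path(path)
    calls: list[CnvCall] = []
    with path.open() as fh:
        header = fh.readline().split()
        if header[: len(CNV_COLUMNS)] != CNV_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header starting with "
                f"{' '.join(CNV_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < len(CNV_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: expected >=8 fields")
            fid, iid, chrom, bp1, bp2, cn, nprobes, conf = fields[:8]
            try:
                start, end = int(bp1), int(bp2)
                copy_number = int(cn)
                n_probes = int(nprobes)
                confidence = float(conf)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if end < start:
                raise ParseError(f"{path}: line {lineno}: BP1 > BP2")
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            sex = (sexes or {}).get(iid, "unknown")
            ref = reference_copy_number(interval.chrom, sex)
            state = state_from_copy_number(copy_number, ref)
            if state == "normal" and not allow_normal:
                raise ValidationError(
                    f"{path}: line {lineno}: copy number {copy_number} equals the "
                    f"reference state on chromosome {interval.chrom}"
                )
            try:
                calls.append(
                    CnvCall(
                        sample_id=iid,
                        family_id=fid,
                        interval=interval,
                        copy_number=copy_number,
                        state=state,
                        n_probes=n_probes,
                        confidence=confidence,
                        caller=caller_tag,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return calls


def write_cnv_table(calls: Sequence[CnvCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(CNV_COLUMNS + ["SOURCE"]) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.family_id,
                        c.sample_id,
                        c.interval.chrom,
                        str(c.interval.start),
                        str(c.interval.end),
                        str(c.copy_number),
                        str(c.n_probes),
                        repr(c.confidence),
                        c.caller,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PED file into a validated :class:`Pedigree`."""
    path = Path(path)
    individuals: list[Individual] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns")
            fid, iid, pat, mat, sex_code, pheno_code = fields[:6]
            if sex_code not in _SEX_CODES:
                raise ValidationError(f"{path}: line {lineno}: bad sex code {sex_code!r}")
            if pheno_code not in _PHENO_CODES:
                raise ValidationError(
                    f"{path}: line {lineno}: bad phenotype code {pheno_code!r}"
                )
            if iid in (pat, mat):
                raise ValidationError(f"{path}: line {lineno}: {iid!r} is its own parent")
            individuals.append(
                Individual(
                    individual_id=iid,
                    family_id=fid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_SEX_CODES[sex_code],
                    phenotype=_PHENO_CODES[pheno_code],
                )
            )
    try:
        return Pedigree(individuals)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for ind in pedigree:
            fh.write(
                "\t".join(
                    [
                        ind.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        _PHENO_TO_CODE[ind.phenotype],
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED tracks
# ---------------------------------------------------------------------------


def read_bed_track(path: str | Path) -> list[TrackRecord]:
    """Read a BED3+ file, converting to 1-based inclusive coordinates.

    ``internal_start = bed_start + 1``, ``internal_end = bed_end``.  Column 4
    is the record name when present; columns 5 and 6 are stored as ``score``
    and ``strand`` attributes.
    """
    path = Path(path)
    records: list[TrackRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                bed_start, bed_end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if bed_start < 0 or bed_end < 0:
                raise ValidationError(f"{path}: line {lineno}: negative coordinate")
            if bed_end <= bed_start:
                raise ValidationError(f"{path}: line {lineno}: end <= start")
            try:
                interval = GenomicInterval(chrom, bed_start + 1, bed_end)
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 else f"{interval.chrom}:{bed_start}-{bed_end}"
            attributes = {}
            if len(fields) > 4:
                attributes["score"] = fields[4]
            if len(fields) > 5:
                attributes["strand"] = fields[5]
            records.append(TrackRecord(interval=interval, name=name, attributes=attributes))
    return records


def write_bed_track(records: Sequence[TrackRecord], path: str | Path) -> None:
    """Write records as BED, re-adding the ``chr`` prefix and 0-based starts."""
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                f"chr{r.interval.chrom}\t{r.interval.start - 1}\t{r.interval.end}"
                f"\t{r.name}\n"
            )


# ---------------------------------------------------------------------------
# Evidence tables
# ---------------------------------------------------------------------------

SAGE_COMPARTMENTS = ("outflow_tract", "atrium", "ventricle")


def read_sage_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, compartment, tag_count, library_size."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "compartment", "tag_count", "library_size"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = set(df["compartment"]) - set(SAGE_COMPARTMENTS)
    if bad:
        raise ValidationError(f"{path}: unknown compartments {sorted(bad)}")
    if (df["tag_count"] < 0).any() or (df["library_size"] <= 0).any():
        raise ValidationError(f"{path}: negative tag counts or non-positive library size")
    if (df["tag_count"] > df["library_size"]).any():
        raise ValidationError(f"{path}: tag_count exceeds library_size")
    return df


def read_score_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, source, score (higher = more training-like)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "source", "score"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df


def read_flag_table(path: str | Path) -> dict[str, str]:
    """TSV with columns gene, flag (``+`` or ``-``); returns a gene->flag map."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "flag"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    bad = set(df["flag"].astype(str)) - {"+", "-"}
    if bad:
        raise ValidationError(f"{path}: flags must be '+' or '-', got {sorted(bad)}")
    return dict(zip(df["gene"], df["flag"]))


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in all printed reports)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
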