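"""Core data types for multi-stage tumor somatic-mutation cohorts.

A cohort holds, per patient, one matched-normal sample plus an ordered set of
tumor samples taken at successive steps of malignant progression (pre-invasive
DCIS, primary tumor, synchronous axillary-lymph-node metastasis, asynchronous
distant metastasis).  Each somatic mutation is one record per patient carrying
per-sample read-count observations and functional annotation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "Stage",
    "RegionClass",
    "Consequence",
    "CurationFlag",
    "SampleObservation",
    "MutationRecord",
    "Patient",
    "PatientCohort",
    "GeneSetCollection",
    "MutationKey",
    "PipelineError",
    "SchemaError",
    "RowValidationError",
    "NS_SNV_CLASSES",
    "PROTEIN_ALTERING_CLASSES",
]


class PipelineError(Exception):
    """Base class for validation and pipeline errors."""


class SchemaError(PipelineError):
    """An input table is missing a mandatory column or field."""


class RowValidationError(PipelineError):
    """A row of an input table violates a record invariant."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class Stage(str, enum.Enum):
    """Tissue stage of a sequenced sample within one patient's progression."""

    NORMAL = "NORMAL"
    DCIS = "DCIS"
    PRIMARY = "PRIMARY"
    ALN_MET = "ALN_MET"
    DISTANT_MET = "DISTANT_MET"


#: Tumor stages (everything except the matched normal).
TUMOR_STAGES = (Stage.DCIS, Stage.PRIMARY, Stage.ALN_MET, Stage.DISTANT_MET)
#: Stages counted as "metastasis" when partitioning progression categories.
METASTASIS_STAGES = (Stage.ALN_MET, Stage.DISTANT_MET)
#: Stages counted as "early" (pre-metastatic) for the same purpose.
EARLY_STAGES = (Stage.DCIS, Stage.PRIMARY)


class RegionClass(str, enum.Enum):
    EXONIC = "EXONIC"
    SPLICING = "SPLICING"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"
    DOWNSTREAM = "DOWNSTREAM"
    NCRNA_INTRONIC = "NCRNA_INTRONIC"
    OTHER = "OTHER"


class Consequence(str, enum.Enum):
    SYNONYMOUS = "SYNONYMOUS"
    MISSENSE = "MISSENSE"
    STOPGAIN = "STOPGAIN"
    STOPLOSS = "STOPLOSS"
    FRAMESHIFT_INS = "FRAMESHIFT_INS"
    FRAMESHIFT_DEL = "FRAMESHIFT_DEL"
    NONFRAMESHIFT_INDEL = "NONFRAMESHIFT_INDEL"
    SPLICE_SITE = "SPLICE_SITE"
    OTHER = "OTHER"


#: Non-synonymous SNV classes entering the NS count of the NS:S selection test.
NS_SNV_CLASSES = frozenset(
    {Consequence.MISSENSE, Consequence.STOPGAIN, Consequence.STOPLOSS}
)

#: Protein-altering classes (everything except silent/unknown) used for
#: progression categories, concordance and recurrence tables.
PROTEIN_ALTERING_CLASSES = frozenset(
    c for c in Consequence if c not in (Consequence.SYNONYMOUS, Consequence.OTHER)
)


class CurationFlag(str, enum.Enum):
    REPEAT_REGION = "REPEAT_REGION"
    ADJACENT_CLUSTER = "ADJACENT_CLUSTER"
    ERROR_PRONE_REGION = "ERROR_PRONE_REGION"


#: (patient_id, chrom, pos, ref, alt) — the identity of one somatic mutation.
MutationKey = tuple


@dataclass(frozen=True)
class SampleObservation:
    """Read-count evidence for one mutation in one sequenced sample."""

    sample_id: str
    stage: Stage
    depth: int
    alt_reads: int

    def __post_init__(self):
        if self.depth < 0 or self.alt_reads < 0:
            raise RowValidationError(
                f"negative read counts in sample {self.sample_id!r}"
            )
        if self.alt_reads > self.depth:
            raise RowValidationError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth}) "
                f"in sample {self.sample_id!r}"
            )

    @property
    def baf(self) -> float:
        """B-allele frequency, alt_reads / depth.  Undefined at zero depth."""
        if self.depth == 0:
            raise ZeroDivisionError(
                f"BAF undefined at zero depth (sample {self.sample_id!r})"
            )
        return self.alt_reads / self.depth

    def baf_or(self, default: float = 0.0) -> float:
        """BAF, or `default` when depth is zero (no evidence either way)."""
        return self.alt_reads / self.depth if self.depth > 0 else default


@dataclass
class MutationRecord:
    """One somatic mutation in one patient, with per-sample observations."""

    patient_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene: str = ""
    region_class: RegionClass = RegionClass.EXONIC
    consequence: Consequence = Consequence.OTHER
    cdna_change: str = ""
    aa_change: str = ""
    pop_af: Optional[float] = None
    observations: dict = field(default_factory=dict)  # sample_id -> SampleObservation
    curation_flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.pos < 1:
            raise RowValidationError(
                f"position must be >= 1 (got {self.pos} at {self.chrom})"
            )
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise RowValidationError(f"pop_af {self.pop_af} outside [0, 1]")

    @property
    def key(self) -> MutationKey:
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != "-" and self.alt != "-"

    def observation(self, sample_id: str) -> SampleObservation:
        return self.observations[sample_id]

    def add_observation(self, obs: SampleObservation) -> None:
        if obs.sample_id in self.observations:
            raise RowValidationError(
                f"duplicate observation for sample {obs.sample_id!r} at "
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"
            )
        self.observations[obs.sample_id] = obs


@dataclass
class Patient:
    """Sample topology of one patient: one normal plus staged tumor samples."""

    patient_id: str
    samples: dict = field(default_factory=dict)  # sample_id -> Stage, insertion-ordered

    @property
    def normal_samples(self) -> list:
        return [s for s, st in self.samples.items() if st is Stage.NORMAL]

    @property
    def normal_sample(self) -> str:
        normals = self.normal_samples
        if len(normals) != 1:
            raise PipelineError(
                f"patient {self.patient_id!r} has {len(normals)} NORMAL samples, "
                "expected exactly 1"
            )
        return normals[0]

    @property
    def tumor_samples(self) -> list:
        return [s for s, st in self.samples.items() if st is not Stage.NORMAL]

    def stage_of(self, sample_id: str) -> Stage:
        return self.samples[sample_id]


@dataclass
class PatientCohort:
    """A collection of patients and their somatic mutation records."""

    patients: dict = field(default_factory=dict)  # patient_id -> Patient
    mutations: list = field(default_factory=list)  # list[MutationRecord]

    def validate(self) -> "PatientCohort":
        seen = set()
        for mut in self.mutations:
            if mut.key in seen:
                raise RowValidationError(
                    f"duplicate mutation {mut.key} within patient {mut.patient_id!r}"
                )
            seen.add(mut.key)
            if mut.patient_id not in self.patients:
                raise PipelineError(
                    f"mutation {mut.key} references unknown patient {mut.patient_id!r}"
                )
            patient = self.patients[mut.patient_id]
            for sample_id in mut.observations:
                if sample_id not in patient.samples:
                    raise PipelineError(
                        f"observation in unknown sample {sample_id!r} for "
                        f"mutation {mut.key}"
                    )
        for patient in self.patients.values():
            patient.normal_sample  # raises unless exactly one NORMAL
        return self

    def patient_of(self, mut: MutationRecord) -> Patient:
        return self.patients[mut.patient_id]

    def mutations_of(self, patient_id: str) -> Iterator[MutationRecord]:
        return (m for m in self.mutations if m.patient_id == patient_id)

    def __len__(self) -> int:
        return len(self.mutations)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the total number of tested sets.

    ``collection_size`` is the multiple-testing family size m.  It may exceed
    the number of stored sets when only a subset of a larger collection is
    held in memory (the remaining sets are still counted as performed tests).
    """

    name: str
    sets: dict = field(default_factory=dict)  # set name -> set[str] of gene symbols
    collection_size: Optional[int] = None

    def __post_init__(self):
        self.sets = {
            name: {str(g).upper() for g in genes} for name, genes in self.sets.items()
        }
        if self.collection_size is None:
            self.collection_size = len(self.sets)
        if self.collection_size < len(self.sets):
            raise PipelineError(
                f"collection_size ({self.collection_size}) smaller than the "
                f"number of stored sets ({len(self.sets)})"
            )

    def __len__(self) -> int:
        return len(self.sets)


def build_cohort(
    mutations: Iterable[MutationRecord], patients: Optional[Iterable[Patient]] = None
) -> PatientCohort:
    """Assemble and validate a cohort; infer patient topology if not given."""
    mutations = list(mutations)
    if patients is None:
        inferred: dict = {}
        for mut in mutations:
            patient = inferred.setdefault(mut.patient_id, Patient(mut.patient_id))
            for obs in mut.observations.values():
                patient.samples.setdefault(obs.sample_id, obs.stage)
        patients = inferred.values()
    cohort = PatientCohort(
        patients={p.patient_id: p for p in patients}, mutations=mutations
    )
    return cohort.validate()
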