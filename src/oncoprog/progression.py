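"""Progression-category partitioning, concordance counts and recurrence tables.

Retained protein-altering mutations are partitioned by where in the disease
course they are observed:

* Category 1 — exclusively in pre-invasive (DCIS) and/or primary tumor tissue;
* Category 2 — shared between primary-lineage tissue and at least one
  metastasis (axillary lymph node or distant);
* Category 3 — exclusively in metastases.

Presence is the post-rescue per-sample call from the validation filter, i.e.
what the deep-sequencing evidence supports, not raw caller output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import (
    EARLY_STAGES,
    METASTASIS_STAGES,
    MutationKey,
    PatientCohort,
    PipelineError,
    PROTEIN_ALTERING_CLASSES,
    Stage,
)

__all__ = ["Category", "CategoryAssignment", "RecurrenceTable", "categorize",
           "concordance_counts", "recurrence"]


class Category(str, enum.Enum):
    CAT1_EARLY_ONLY = "CAT1_EARLY_ONLY"
    CAT2_SHARED = "CAT2_SHARED"
    CAT3_MET_ONLY = "CAT3_MET_ONLY"


@dataclass
class CategoryAssignment:
    key: MutationKey
    category: Category
    stage_presence: dict = field(default_factory=dict)  # Stage -> bool
    gene: str = ""


def _stage_presence(mut, patient, decision) -> dict:
    present = {st: False for st in Stage}
    for sample_id, ok in decision.presence.items():
        if ok:
            present[patient.stage_of(sample_id)] = True
    return present


def assign_category(stage_presence: dict) -> Category:
    early = any(stage_presence.get(st, False) for st in EARLY_STAGES)
    met = any(stage_presence.get(st, False) for st in METASTASIS_STAGES)
    if early and met:
        return Category.CAT2_SHARED
    if early:
        return Category.CAT1_EARLY_ONLY
    if met:
        return Category.CAT3_MET_ONLY
    raise PipelineError("mutation present in no tumor sample cannot be categorized")


def categorize(cohort: PatientCohort, decisions: dict,
               classes: Optional[Iterable] = None) -> list:
    """Assign each retained, class-included mutation to exactly one category.

    ``classes`` defaults to the protein-altering consequence classes
    (everything except synonymous/unknown, splice sites included).  The three
    categories partition the retained class-included mutations.
    """
    classes = frozenset(classes) if classes is not None else PROTEIN_ALTERING_CLASSES
    out = []
    for mut in cohort.mutations:
        decision = decisions.get(mut.key)
        if decision is None or not decision.retained:
            continue
        if mut.consequence not in classes:
            continue
        patient = cohort.patient_of(mut)
        presence = _stage_presence(mut, patient, decision)
        out.append(
            CategoryAssignment(
                key=mut.key,
                category=assign_category(presence),
                stage_presence=presence,
                gene=mut.gene,
            )
        )
    return out


def concordance_counts(cohort: PatientCohort, decisions: dict, patient_id: str,
                       classes: Optional[Iterable] = None) -> dict:
    """Venn-partition counts of per-sample presence for one patient.

    Returns a mapping frozenset(tumor sample ids) -> number of distinct
    retained mutations present in exactly that sample combination.  Cell
    counts sum to the total number of retained class-included mutations.
    """
    classes = frozenset(classes) if classes is not None else PROTEIN_ALTERING_CLASSES
    patient = cohort.patients[patient_id]
    if len(patient.tumor_samples) < 2:
        raise PipelineError(
            f"patient {patient_id!r} has fewer than two tumor samples; "
            "concordance is undefined"
        )
    counts: dict = {}
    for mut in cohort.mutations_of(patient_id):
        decision = decisions.get(mut.key)
        if decision is None or not decision.retained:
            continue
        if mut.consequence not in classes:
            continue
        cell = frozenset(s for s, ok in decision.presence.items() if ok)
        if cell:
            counts[cell] = counts.get(cell, 0) + 1
    return counts


@dataclass
class RecurrenceTable:
    """Recurrently mutated genes, within samples and across patients.

    ``within`` maps (gene, patient, sample) to the number of distinct
    protein-altering mutations of that gene called present in that sample
    (the x / 2x / 3x multiplicity notation).  ``across`` maps gene to the set
    of patients carrying at least one such mutation anywhere.
    """

    within: dict = field(default_factory=dict)   # (gene, patient, sample) -> int
    across: dict = field(default_factory=dict)   # gene -> frozenset of patients

    def to_frame(self):
        import pandas as pd

        rows = [
            {"gene": g, "patient": p, "sample": s, "multiplicity": f"{n}x"}
            for (g, p, s), n in sorted(self.within.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "patient", "sample", "multiplicity"])


def recurrence(cohort: PatientCohort, decisions: dict, min_within: int = 2,
               min_across: int = 2, classes: Optional[Iterable] = None) -> RecurrenceTable:
    """Tabulate recurrently mutated genes.

    Only protein-altering (non-synonymous and splice-site) mutations count.
    Multiplicity counts distinct genomic variants, not reads or samples.
    """
    classes = frozenset(classes) if classes is not None else PROTEIN_ALTERING_CLASSES
    within_counts: dict = {}
    gene_patients: dict = {}
    for mut in cohort.mutations:
        decision = decisions.get(mut.key)
        if decision is None or not decision.retained:
            continue
        if mut.consequence not in classes or not mut.gene:
            continue
        for sample_id, ok in decision.presence.items():
            if ok:
                k = (mut.gene, mut.patient_id, sample_id)
                within_counts[k] = within_counts.get(k, 0) + 1
        if any(decision.presence.values()):
            gene_patients.setdefault(mut.gene, set()).add(mut.patient_id)
    return RecurrenceTable(
        within={k: n for k, n in within_counts.items() if n >= min_within},
        across={
            g: frozenset(ps) for g, ps in gene_patients.items() if len(ps) >= min_across
        },
    )
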