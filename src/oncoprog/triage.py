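"""Rule-based triage of putative metastasis-progression driver mutations.

A mutation qualifies as a putative progression driver if it is protein
truncating or splice disrupting (frameshift, stopgain or splice-site), or if
a per-mutation driver scorer flags it (in the original analysis an external
SVM-based classifier; here a pluggable interface).  Cancer-gene-list
membership (COSMIC Cancer Gene Census, KEGG cancer pathway) is annotated but
never qualifies a mutation by itself.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import pandas as pd

from .model import Consequence, MutationKey, PatientCohort, Stage

__all__ = ["QualifyingRule", "DriverCall", "TableScorer", "null_scorer",
           "truncating_only_scorer", "triage", "summarize_counts"]


#: Consequence classes that qualify regardless of any score.
TRUNCATING_OR_SPLICE_CLASSES = frozenset(
    {Consequence.FRAMESHIFT_INS, Consequence.FRAMESHIFT_DEL,
     Consequence.STOPGAIN, Consequence.SPLICE_SITE}
)


class QualifyingRule(str, enum.Enum):
    TRUNCATING_OR_SPLICE = "TRUNCATING_OR_SPLICE"
    SCORE_DRIVER = "SCORE_DRIVER"


@dataclass
class DriverCall:
    key: MutationKey
    gene: str
    rule: QualifyingRule
    category: object  # progression.Category
    score: Optional[float] = None
    annotations: frozenset = frozenset()  # gene-list names the gene belongs to
    aln_present: bool = False
    distant_present: bool = False


def null_scorer(mut) -> tuple:
    """Scorer that never flags a driver (score unknown)."""
    return (None, False)


def truncating_only_scorer(mut) -> tuple:
    """Conservative fallback: only the rule-forced truncating classes qualify."""
    return (None, mut.consequence in TRUNCATING_OR_SPLICE_CLASSES)


class TableScorer:
    """Deterministic scorer backed by a TSV of pre-computed scores.

    Columns: chrom, pos, ref, alt, score, is_driver.  Mutations absent from
    the table score as unknown (not flagged).
    """

    def __init__(self, path):
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"chrom", "pos", "ref", "alt", "score", "is_driver"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"scorer table missing columns: {sorted(missing)}")
        self._table = {}
        for row in df.itertuples(index=False):
            d = dict(zip(df.columns, row))
            key = (str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]))
            score = float(d["score"]) if d["score"] not in ("", ".") else None
            flag = str(d["is_driver"]).strip().lower() in ("1", "true", "yes")
            self._table[key] = (score, flag)

    def __call__(self, mut) -> tuple:
        return self._table.get((mut.chrom, mut.pos, mut.ref, mut.alt), (None, False))


def triage(assignments: Iterable, cohort: PatientCohort,
           scorer: Optional[Callable] = None,
           gene_lists: Optional[dict] = None) -> list:
    """Select putative progression drivers among categorized mutations.

    ``assignments`` is a list of CategoryAssignment (typically the Category 2
    and Category 3 mutations); ``scorer`` maps a mutation to
    ``(score, is_driver_flag)``; ``gene_lists`` maps a list name (e.g.
    "COSMIC_CGC", "KEGG_CANCER") to a set of gene symbols for annotation.
    """
    scorer = scorer or null_scorer
    gene_lists = gene_lists or {}
    by_key = {m.key: m for m in cohort.mutations}
    calls = []
    for a in assignments:
        mut = by_key[a.key]
        score, flagged = scorer(mut)
        if mut.consequence in TRUNCATING_OR_SPLICE_CLASSES:
            rule = QualifyingRule.TRUNCATING_OR_SPLICE
        elif flagged:
            rule = QualifyingRule.SCORE_DRIVER
        else:
            continue
        gene_upper = mut.gene.upper()
        annotations = frozenset(
            name for name, genes in gene_lists.items()
            if gene_upper in {g.upper() for g in genes}
        )
        calls.append(
            DriverCall(
                key=a.key,
                gene=mut.gene,
                rule=rule,
                category=a.category,
                score=score,
                annotations=annotations,
                aln_present=a.stage_presence.get(Stage.ALN_MET, False),
                distant_present=a.stage_presence.get(Stage.DISTANT_MET, False),
            )
        )
    return calls


def summarize_counts(calls: Iterable) -> dict:
    """Per-category totals: number of qualifying mutations and distinct genes."""
    per_cat: dict = {}
    for call in calls:
        muts, genes = per_cat.setdefault(call.category, [0, set()])
        per_cat[call.category][0] += 1
        per_cat[call.category][1].add(call.gene)
    return {cat: (muts, len(genes)) for cat, (muts, genes) in per_cat.items()}


def calls_to_frame(calls: Iterable) -> pd.DataFrame:
    """Driver calls as a table in the printed-report layout."""
    rows = [
        {
            "patient": c.key[0],
            "gene": c.gene,
            "chrom": c.key[1],
            "pos": c.key[2],
            "ref": c.key[3],
            "alt": c.key[4],
            "rule": c.rule.value,
            "category": c.category.value,
            "score": "" if c.score is None else c.score,
            "annotations": ",".join(sorted(c.annotations)),
            "aln_present": c.aln_present,
            "distant_present": c.distant_present,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["patient", "gene", "chrom", "pos", "ref", "alt", "rule",
                 "category", "score", "annotations", "aln_present",
                 "distant_present"],
    )
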