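"""Synthetic multi-stage tumor cohorts with known ground truth.

The generator emulates the sampling design of a multi-step breast-cancer
sequencing study: per patient a matched normal plus tumor samples from up to
four progression stages (DCIS, primary, axillary-lymph-node metastasis,
distant metastasis), with a simple clonal structure — truncal mutations
present in every tumor sample, private mutations confined to one stage's
lineage, and optionally a branch shared by the two metastases.  Read counts
follow negative-binomial depths and binomial allele counts at the expected
heterozygous-diploid allele fraction 0.5 x purity; the matched normal (and
any sample the clone does not reach) yields alt reads at the sequencing
error rate only.  Neutral mutations are non-synonymous with probability 2/3
(the 2:1 passenger expectation); injected drivers are all non-synonymous and
recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from intervaltree import IntervalTree

from .model import (
    Consequence,
    MutationRecord,
    Patient,
    PatientCohort,
    PipelineError,
    RegionClass,
    SampleObservation,
    Stage,
    build_cohort,
)
from .progression import Category, assign_category

__all__ = ["CohortSimConfig", "TruthRecord", "GroundTruth", "simulate",
           "truth_compare", "RecoveryReport"]

_BASES = np.array(list("ACGT"))

#: Per-assay mean target depths: whole-exome discovery vs targeted panel
#: validation sequencing.
ASSAY_DEPTHS = {"exome": 100, "panel": 465}


def _default_private():
    return {Stage.DCIS: 15, Stage.PRIMARY: 120, Stage.ALN_MET: 25,
            Stage.DISTANT_MET: 45}


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameterization of the synthetic cohort generator.

    Defaults mirror the study conditions: targeted-panel depth (~465x, the
    mean validation coverage), tumor cellularity of at least 50% (0.8 here),
    a neutral non-synonymous fraction of 2/3, and per-patient mutation totals
    in the low hundreds.
    """

    seed: int = 0
    n_patients: int = 1
    stages: tuple = (Stage.DCIS, Stage.PRIMARY, Stage.ALN_MET, Stage.DISTANT_MET)
    n_truncal: int = 60
    n_private: Optional[dict] = None           # Stage -> count; defaults per stage
    n_met_shared: int = 0                      # branch shared by ALN and distant
    injected_drivers: Optional[dict] = None    # Stage -> driver count (all NS)
    neutral_ns_fraction: float = 2.0 / 3.0
    missense_fraction: float = 0.9             # within non-synonymous
    mean_depth: int = ASSAY_DEPTHS["panel"]
    depth_dispersion: float = 10.0             # negative-binomial size r
    purity: float = 0.8
    het_baf: float = 0.5
    normal_error_rate: float = 0.001
    pop_snp_rate: float = 0.02
    blacklist_rate: float = 0.01

    def resolved_private(self) -> dict:
        defaults = _default_private()
        chosen = self.n_private if self.n_private is not None else defaults
        return {st: chosen.get(st, 0) for st in self.stages}

    def validate(self) -> "CohortSimConfig":
        for prob in (self.neutral_ns_fraction, self.missense_fraction,
                     self.purity, self.het_baf, self.normal_error_rate,
                     self.pop_snp_rate, self.blacklist_rate):
            if not (0.0 <= prob <= 1.0):
                raise PipelineError(f"probability {prob} outside [0, 1]")
        if self.n_truncal < 0 or self.n_met_shared < 0:
            raise PipelineError("mutation counts must be non-negative")
        if Stage.NORMAL in self.stages:
            raise PipelineError("stages lists tumor stages only")
        for source in (self.n_private, self.injected_drivers):
            if source:
                for st in source:
                    if st not in self.stages:
                        raise PipelineError(
                            f"mutations requested for absent stage {st}"
                        )
        if self.n_met_shared and not (
            Stage.ALN_MET in self.stages and Stage.DISTANT_MET in self.stages
        ):
            raise PipelineError("n_met_shared requires both metastasis stages")
        if self.depth_dispersion <= 0:
            raise PipelineError("depth_dispersion must be positive")
        return self


@dataclass
class TruthRecord:
    key: tuple
    clone: str                     # "TRUNCAL", a Stage value, or "MET_SHARED"
    consequence: Consequence
    is_driver: bool
    is_pop_snp: bool
    is_blacklisted: bool
    true_presence: frozenset      # tumor sample_ids the clone reaches
    expected_category: Category


@dataclass
class GroundTruth:
    records: dict = field(default_factory=dict)   # key -> TruthRecord
    blacklist_bed: list = field(default_factory=list)  # (chrom, start0, end0)
    config: Optional[CohortSimConfig] = None

    def blacklist_trees(self) -> dict:
        trees: dict = {}
        for chrom, start0, end0 in self.blacklist_bed:
            trees.setdefault(chrom, IntervalTree()).addi(start0 + 1, end0 + 1)
        return trees

    def write_blacklist_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start0, end0 in self.blacklist_bed:
                fh.write(f"{chrom}\t{start0}\t{end0}\n")

    def injected_driver_total(self) -> int:
        return sum(1 for r in self.records.values() if r.is_driver)


def _draw_consequence(rng, config, is_driver: bool) -> Consequence:
    if is_driver or rng.random() < config.neutral_ns_fraction:
        return (Consequence.MISSENSE
                if rng.random() < config.missense_fraction
                else Consequence.STOPGAIN)
    return Consequence.SYNONYMOUS


def simulate(config: CohortSimConfig):
    """Generate a cohort and its ground truth.  Same config => same output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_private = config.resolved_private()
    drivers = {st: (config.injected_drivers or {}).get(st, 0) for st in config.stages}

    patients = []
    mutations = []
    truth = GroundTruth(config=config)

    for pidx in range(config.n_patients):
        pid = f"P{pidx + 1}"
        sample_ids = {st: f"{pid}_{st.value}" for st in config.stages}
        normal_id = f"{pid}_NORMAL"
        samples = {normal_id: Stage.NORMAL}
        samples.update({sample_ids[st]: st for st in config.stages})
        patients.append(Patient(patient_id=pid, samples=samples))
        all_tumor = list(sample_ids.values())

        # clone plan: (clone label, samples reached, count, driver count)
        plan = [("TRUNCAL", all_tumor, config.n_truncal, 0)]
        for st in config.stages:
            plan.append((st.value, [sample_ids[st]], n_private[st], drivers[st]))
        if config.n_met_shared:
            plan.append((
                "MET_SHARED",
                [sample_ids[Stage.ALN_MET], sample_ids[Stage.DISTANT_MET]],
                config.n_met_shared, 0,
            ))

        pos_counter: dict = {}
        sample_order = [normal_id] + all_tumor
        for clone, reach, n_neutral, n_driver in plan:
            total = n_neutral + n_driver
            if total == 0:
                continue
            chroms = rng.integers(1, 23, size=total)
            depth_p = config.depth_dispersion / (config.depth_dispersion
                                                 + config.mean_depth)
            depths = rng.negative_binomial(
                config.depth_dispersion, depth_p, size=(total, len(sample_order))
            )
            present_baf = config.het_baf * config.purity
            reach_set = set(reach)
            p_alt = np.array([
                [present_baf if (s in reach_set) else config.normal_error_rate
                 for s in sample_order]
            ])
            p_alt = np.repeat(p_alt, total, axis=0)
            p_alt[:, 0] = config.normal_error_rate  # matched normal
            alts = rng.binomial(depths, p_alt)

            for i in range(total):
                chrom = str(chroms[i])
                pos = pos_counter.get(chrom, 0) + int(rng.integers(5_000, 50_000))
                pos_counter[chrom] = pos
                ref, alt_base = rng.choice(_BASES, size=2, replace=False)
                is_driver = i >= n_neutral
                consequence = _draw_consequence(rng, config, is_driver)
                is_pop_snp = (not is_driver) and rng.random() < config.pop_snp_rate
                is_blacklisted = rng.random() < config.blacklist_rate
                pop_af = float(rng.uniform(0.02, 0.5)) if is_pop_snp else None
                gene = f"G{int(rng.integers(0, 5000)):04d}"
                rec = MutationRecord(
                    patient_id=pid, chrom=chrom, pos=pos, ref=str(ref),
                    alt=str(alt_base), gene=gene,
                    region_class=RegionClass.EXONIC, consequence=consequence,
                    pop_af=pop_af,
                )
                for j, sid in enumerate(sample_order):
                    rec.add_observation(SampleObservation(
                        sample_id=sid, stage=samples[sid],
                        depth=int(depths[i, j]), alt_reads=int(alts[i, j]),
                    ))
                mutations.append(rec)
                if is_blacklisted:
                    truth.blacklist_bed.append((chrom, pos - 1, pos))
                stage_presence = {st: False for st in Stage}
                for sid in reach:
                    stage_presence[samples[sid]] = True
                truth.records[rec.key] = TruthRecord(
                    key=rec.key, clone=clone, consequence=consequence,
                    is_driver=is_driver, is_pop_snp=is_pop_snp,
                    is_blacklisted=is_blacklisted,
                    true_presence=frozenset(reach),
                    expected_category=assign_category(stage_presence),
                )

    cohort = build_cohort(mutations, patients)
    return cohort, truth


@dataclass
class RecoveryReport:
    """How faithfully the pipeline recovered the generator's ground truth."""

    n_mutations: int = 0
    n_clean: int = 0                 # neither population SNP nor blacklisted
    n_artifacts: int = 0
    filter_sensitivity: Optional[float] = None   # retained clean / clean
    artifact_exclusion: Optional[float] = None   # rejected artifacts / artifacts
    category_accuracy: Optional[float] = None
    confusion: dict = field(default_factory=dict)  # (true, called) -> count
    injected_drivers: int = 0
    driver_estimate: Optional[int] = None


def truth_compare(cohort: PatientCohort, decisions: dict, truth: GroundTruth,
                  assignments: Optional[list] = None,
                  driver_estimate: Optional[int] = None) -> RecoveryReport:
    """Score pipeline outputs against the generator's ground truth."""
    for key in decisions:
        if key not in truth.records:
            raise PipelineError(f"decision for unknown mutation {key}")
    report = RecoveryReport(
        n_mutations=len(truth.records),
        injected_drivers=truth.injected_driver_total(),
        driver_estimate=driver_estimate,
    )
    if not truth.records:
        return report
    retained = {k for k, d in decisions.items() if d.retained}
    clean = [r for r in truth.records.values()
             if not (r.is_pop_snp or r.is_blacklisted)]
    artifacts = [r for r in truth.records.values()
                 if r.is_pop_snp or r.is_blacklisted]
    report.n_clean = len(clean)
    report.n_artifacts = len(artifacts)
    if clean:
        report.filter_sensitivity = (
            sum(1 for r in clean if r.key in retained) / len(clean)
        )
    if artifacts:
        report.artifact_exclusion = (
            sum(1 for r in artifacts if r.key not in retained) / len(artifacts)
        )
    if assignments is not None:
        correct = total = 0
        for a in assignments:
            true_cat = truth.records[a.key].expected_category
            report.confusion[(true_cat, a.category)] = (
                report.confusion.get((true_cat, a.category), 0) + 1
            )
            total += 1
            correct += true_cat is a.category
        report.category_accuracy = correct / total if total else None
    return report
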