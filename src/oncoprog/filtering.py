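"""Multi-sample validation filter for deep-sequenced somatic candidates.

A candidate mutation within one patient is retained only if the matched
normal shows essentially no alternate allele (BAF < 0.02), every sample is
deeply covered (>= 50x), and at least one tumor sample shows a clear signal
(BAF >= 0.05).  A retained mutation is additionally called present in the
remaining tumor samples either at the full signal threshold, or under the
rescue rule: BAF >= 0.025 provided the sample's depth exceeds 200x.
Candidates outside exonic/splicing regions, known population SNPs
(AF > 1%), blacklisted sites and tight variant clusters are excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

from .io import in_blacklist
from .model import (
    CurationFlag,
    MutationKey,
    MutationRecord,
    PatientCohort,
    PipelineError,
    RegionClass,
)

__all__ = ["FilterConfig", "FilterDecision", "ReasonCode", "apply_filters",
           "flag_clusters", "retained_keys"]


class ReasonCode(str, enum.Enum):
    NORMAL_CONTAMINATION = "NORMAL_CONTAMINATION"
    LOW_DEPTH = "LOW_DEPTH"
    NO_TUMOR_SIGNAL = "NO_TUMOR_SIGNAL"
    REGION_EXCLUDED = "REGION_EXCLUDED"
    POPULATION_SNP = "POPULATION_SNP"
    BLACKLISTED = "BLACKLISTED"
    CLUSTERED = "CLUSTERED"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the validated-mutation criteria.

    Boundary semantics follow the criteria's wording: the normal-BAF bound is
    exclusive ("less than 0.02"), depth and tumor-BAF minima are inclusive
    ("min. 50x", "0.05 at minimum"), the rescue depth is strictly greater
    ("exceeded 200x"), and the population-AF bound excludes only AF strictly
    above 1%.
    """

    normal_baf_max: float = 0.02       # exclusive
    min_depth_all: int = 50            # inclusive, all samples incl. normal
    tumor_baf_min: float = 0.05        # inclusive, max over tumor samples
    rescue_baf_min: float = 0.025      # inclusive
    rescue_depth_min: int = 200        # exclusive (depth must exceed)
    pop_af_max: float = 0.01           # exclusive (> 1% excluded)
    allowed_regions: frozenset = frozenset({RegionClass.EXONIC, RegionClass.SPLICING})
    adjacent_cluster_window: int = 10  # bp
    adjacent_cluster_count: int = 3

    def __post_init__(self):
        if self.rescue_baf_min > self.tumor_baf_min:
            raise PipelineError("rescue_baf_min must not exceed tumor_baf_min")
        for name in ("normal_baf_max", "min_depth_all", "tumor_baf_min",
                     "rescue_baf_min", "rescue_depth_min", "pop_af_max"):
            if getattr(self, name) < 0:
                raise PipelineError(f"{name} must be non-negative")

    @classmethod
    def from_file(cls, path) -> "FilterConfig":
        """Load thresholds from a plain-text key=value config file."""
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key == "allowed_regions":
                    kwargs[key] = frozenset(
                        RegionClass(v.strip().upper()) for v in value.split(",")
                    )
                elif key in ("min_depth_all", "rescue_depth_min",
                             "adjacent_cluster_window", "adjacent_cluster_count"):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)


@dataclass
class FilterDecision:
    """Verdict for one mutation plus per-tumor-sample presence calls."""

    key: MutationKey
    reasons: list = field(default_factory=list)  # ordered ReasonCodes
    presence: dict = field(default_factory=dict)  # tumor sample_id -> bool

    @property
    def retained(self) -> bool:
        return not self.reasons


def _presence(obs, config: FilterConfig) -> bool:
    baf = obs.baf_or(0.0)
    if baf >= config.tumor_baf_min:
        return True
    return baf >= config.rescue_baf_min and obs.depth > config.rescue_depth_min


def decide(mut: MutationRecord, cohort: PatientCohort, config: FilterConfig,
           blacklist: Optional[dict] = None) -> FilterDecision:
    """Apply the validated-mutation criteria to one mutation."""
    patient = cohort.patient_of(mut)
    normal_id = patient.normal_sample
    if normal_id not in mut.observations:
        raise PipelineError(
            f"mutation {mut.key} lacks an observation in the matched normal "
            f"{normal_id!r}"
        )
    reasons = []
    normal = mut.observations[normal_id]
    # no reads in the normal is no evidence of contamination
    if normal.depth > 0 and normal.baf >= config.normal_baf_max:
        reasons.append(ReasonCode.NORMAL_CONTAMINATION)
    if any(obs.depth < config.min_depth_all for obs in mut.observations.values()):
        reasons.append(ReasonCode.LOW_DEPTH)
    tumor_obs = [
        mut.observations[s] for s in patient.tumor_samples if s in mut.observations
    ]
    if not any(o.baf_or(0.0) >= config.tumor_baf_min for o in tumor_obs):
        reasons.append(ReasonCode.NO_TUMOR_SIGNAL)
    if mut.region_class not in config.allowed_regions:
        reasons.append(ReasonCode.REGION_EXCLUDED)
    if mut.pop_af is not None and mut.pop_af > config.pop_af_max:
        reasons.append(ReasonCode.POPULATION_SNP)
    if (
        in_blacklist(blacklist, mut.chrom, mut.pos)
        or CurationFlag.REPEAT_REGION in mut.curation_flags
        or CurationFlag.ERROR_PRONE_REGION in mut.curation_flags
    ):
        reasons.append(ReasonCode.BLACKLISTED)
    if CurationFlag.ADJACENT_CLUSTER in mut.curation_flags:
        reasons.append(ReasonCode.CLUSTERED)
    presence = {
        s: (s in mut.observations and _presence(mut.observations[s], config))
        for s in patient.tumor_samples
    }
    return FilterDecision(key=mut.key, reasons=reasons, presence=presence)


def apply_filters(cohort: PatientCohort, config: Optional[FilterConfig] = None,
                  blacklist: Optional[dict] = None) -> dict:
    """Filter every mutation; returns mutation key -> FilterDecision.

    Decisions are per-mutation independent given curation flags, so the
    result does not depend on mutation order.
    """
    config = config or FilterConfig()
    return {mut.key: decide(mut, cohort, config, blacklist) for mut in cohort.mutations}


def retained_keys(decisions: dict) -> set:
    return {k for k, d in decisions.items() if d.retained}


def write_decisions(decisions: dict, path) -> None:
    """Write filter decisions as TSV (one row per mutation)."""
    import pandas as pd

    rows = []
    for key in sorted(decisions):
        d = decisions[key]
        rows.append(
            {
                "patient": key[0],
                "chrom": key[1],
                "pos": key[2],
                "ref": key[3],
                "alt": key[4],
                "verdict": "RETAINED" if d.retained else "REJECTED",
                "reasons": ",".join(r.value for r in d.reasons),
                "presence": ",".join(
                    f"{s}:{int(ok)}" for s, ok in d.presence.items()
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=["patient", "chrom", "pos", "ref", "alt", "verdict", "reasons",
                 "presence"],
    ).to_csv(path, sep="\t", index=False)


def read_decisions(path) -> dict:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        key = (d["patient"], d["chrom"], int(d["pos"]), d["ref"], d["alt"])
        reasons = [ReasonCode(r) for r in d["reasons"].split(",") if r]
        presence = {}
        for item in d["presence"].split(","):
            if item:
                sid, _, ok = item.rpartition(":")
                presence[sid] = bool(int(ok))
        out[key] = FilterDecision(key=key, reasons=reasons, presence=presence)
    return out


def flag_clusters(cohort: PatientCohort, window: int = 10, count: int = 3) -> PatientCohort:
    """Flag mutations with >= count-1 neighbors within +/- window bp.

    Tight clusters of candidate variants are a signature of systematic
    misalignment; flagged mutations are rejected with reason CLUSTERED.
    Flags are added in place (same patient, same chromosome).
    """
    by_group: dict = {}
    for mut in cohort.mutations:
        by_group.setdefault((mut.patient_id, mut.chrom), []).append(mut)
    for group in by_group.values():
        group.sort(key=lambda m: m.pos)
        positions = [m.pos for m in group]
        for i, mut in enumerate(group):
            neighbors = sum(
                1
                for j, p in enumerate(positions)
                if j != i and abs(p - mut.pos) <= window
            )
            if neighbors >= count - 1:
                mut.curation_flags.add(CurationFlag.ADJACENT_CLUSTER)
    return cohort
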