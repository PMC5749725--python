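import pytest
from hypothesis import HealthCheck, settings

from oncoprog.model import (
    Consequence,
    MutationRecord,
    RegionClass,
    SampleObservation,
    Stage,
    build_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(
    pos,
    observations,
    patient="PT1",
    chrom="1",
    ref="A",
    alt="T",
    gene="GENE1",
    consequence=Consequence.MISSENSE,
    region=RegionClass.EXONIC,
    pop_af=None,
):
    """Build a MutationRecord from compact (sample, stage, depth, alt) tuples."""
    rec = MutationRecord(
        patient_id=patient,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        region_class=region,
        consequence=consequence,
        pop_af=pop_af,
    )
    for sample_id, stage, depth, alt_reads in observations:
        rec.add_observation(
            SampleObservation(
                sample_id=sample_id, stage=stage, depth=depth, alt_reads=alt_reads
            )
        )
    return rec


def two_tumor_record(
    pos=1000,
    normal=(60, 0),
    tumor1=(60, 6),
    tumor2=(60, 0),
    stages=(Stage.PRIMARY, Stage.DISTANT_MET),
    **kwargs,
):
    """One mutation observed in a normal and two tumor samples."""
    return make_record(
        pos,
        [
            ("N", Stage.NORMAL, *normal),
            ("T1", stages[0], *tumor1),
            ("T2", stages[1], *tumor2),
        ],
        **kwargs,
    )


@pytest.fixture
def two_tumor_cohort():
    """Single patient, normal + primary + distant metastasis, one mutation."""
    return build_cohort([two_tumor_record()])
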