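"""Data model invariants and file-format round trips."""

import random

import pytest

from oncoprog.io import (
    read_bed_blacklist,
    read_category_assignments,
    read_enrichment_results,
    read_gmt,
    read_selection_results,
    read_variant_table,
    read_vcf,
    write_results,
    write_variant_table,
)
from oncoprog.io import in_blacklist
from oncoprog.model import (
    Consequence,
    PipelineError,
    RowValidationError,
    SampleObservation,
    SchemaError,
    Stage,
    build_cohort,
)
from oncoprog.enrichment import enrich
from oncoprog.model import GeneSetCollection
from oncoprog.progression import categorize
from oncoprog.filtering import apply_filters
from oncoprog.selection import selection_test
from oncoprog.simulate import CohortSimConfig, simulate

from conftest import make_record


HEADER = (
    "#patient\tsample\tstage\tchrom\tpos\tref\talt\tgene\tregion_class\t"
    "consequence\tdepth\talt_reads\tpop_af\tcdna_change\taa_change\tflags\n"
)


def _row(sample, stage, depth, alt_reads, pos=1000, patient="PT1"):
    return (
        f"{patient}\t{sample}\t{stage}\t1\t{pos}\tA\tT\tGENE1\tEXONIC\t"
        f"MISSENSE\t{depth}\t{alt_reads}\t\t\t\t\n"
    )


def test_sample_observation_invariants():
    obs = SampleObservation("S1", Stage.PRIMARY, depth=100, alt_reads=25)
    assert obs.baf == 0.25
    with pytest.raises(RowValidationError):
        SampleObservation("S1", Stage.PRIMARY, depth=10, alt_reads=12)
    zero = SampleObservation("S1", Stage.PRIMARY, depth=0, alt_reads=0)
    with pytest.raises(ZeroDivisionError):
        zero.baf
    assert zero.baf_or(0.0) == 0.0


def test_read_variant_table_merges_samples(tmp_path):
    path = tmp_path / "table.tsv"
    path.write_text(
        HEADER
        + _row("N", "NORMAL", 80, 0)
        + _row("T1", "PRIMARY", 90, 30)
        + _row("T2", "DISTANT_MET", 70, 20)
    )
    cohort = read_variant_table(path)
    assert len(cohort) == 1
    (mut,) = cohort.mutations
    assert set(mut.observations) == {"N", "T1", "T2"}
    assert cohort.patients["PT1"].normal_sample == "N"


def test_read_variant_table_rejects_alt_exceeding_depth(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(HEADER + _row("T1", "PRIMARY", 10, 12))
    with pytest.raises(RowValidationError, match="row 2"):
        read_variant_table(path)


def test_read_variant_table_empty(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text(HEADER)
    cohort = read_variant_table(path)
    assert len(cohort) == 0


def test_read_variant_table_missing_column(tmp_path):
    path = tmp_path / "noalt.tsv"
    path.write_text("#patient\tsample\tstage\tchrom\tpos\tref\n")
    with pytest.raises(SchemaError, match="alt"):
        read_variant_table(path)


def test_row_order_invariance(tmp_path):
    rows = [
        _row("N", "NORMAL", 80, 0, pos=1000),
        _row("T1", "PRIMARY", 90, 30, pos=1000),
        _row("N", "NORMAL", 75, 1, pos=2000),
        _row("T1", "PRIMARY", 85, 40, pos=2000),
    ]
    shuffled = rows[:]
    random.Random(7).shuffle(shuffled)
    a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.write_text(HEADER + "".join(rows))
    b.write_text(HEADER + "".join(shuffled))
    ca, cb = read_variant_table(a), read_variant_table(b)
    assert [m.key for m in ca.mutations] == [m.key for m in cb.mutations]
    assert [m.observations for m in ca.mutations] == [
        m.observations for m in cb.mutations
    ]


def test_variant_table_round_trip(tmp_path):
    cohort, _ = simulate(CohortSimConfig(seed=5, n_patients=1))
    path = tmp_path / "cohort.tsv"
    write_variant_table(cohort, path)
    back = read_variant_table(path)
    assert len(back) == len(cohort)
    orig = {m.key: m for m in cohort.mutations}
    for mut in back.mutations:
        src = orig[mut.key]
        assert mut.consequence is src.consequence
        assert mut.pop_af == src.pop_af
        assert mut.observations == src.observations


def test_duplicate_observation_rejected():
    rec = make_record(100, [("N", Stage.NORMAL, 60, 0)])
    with pytest.raises(RowValidationError):
        rec.add_observation(SampleObservation("N", Stage.NORMAL, 60, 0))


def test_cohort_requires_one_normal():
    rec = make_record(100, [("T1", Stage.PRIMARY, 60, 10)])
    with pytest.raises(PipelineError):
        build_cohort([rec])


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SET_A\tdesc\tTP53\tbrca2\tTP53\n"  # duplicate symbol, mixed case
        "SET_B\tdesc\tPIK3CA\n"
    )
    coll = read_gmt(path)
    assert len(coll) == 2 and coll.collection_size == 2
    assert coll.sets["SET_A"] == {"TP53", "BRCA2"}
    big = read_gmt(path, collection_size_override=186)
    assert big.collection_size == 186


def test_read_gmt_malformed_line(tmp_path):
    path = tmp_path / "bad.gmt"
    path.write_text("SET_A\tdesc\tTP53\nBROKEN\n")
    with pytest.raises(PipelineError, match="line 2"):
        read_gmt(path)


def test_collection_size_cannot_undercount():
    with pytest.raises(PipelineError):
        GeneSetCollection(name="x", sets={"A": {"G1"}, "B": {"G2"}},
                          collection_size=1)


def test_bed_blacklist_coordinates(tmp_path):
    path = tmp_path / "black.bed"
    path.write_text("1\t9\t20\n")
    trees = read_bed_blacklist(path)
    # BED 0-based half-open [9, 20) = 1-based closed [10, 20]
    assert not in_blacklist(trees, "1", 9)
    assert in_blacklist(trees, "1", 10)
    assert in_blacklist(trees, "1", 20)
    assert not in_blacklist(trees, "1", 21)
    assert not in_blacklist(trees, "2", 10)


def test_read_vcf(tmp_path):
    path = tmp_path / "calls.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n'
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORM\tTUM\n"
        "1\t1500\t.\tG\tA\t.\t.\tGENE=TP53;CSQ=MISSENSE\tAD\t78,1\t60,30\n"
    )
    cohort = read_vcf(
        path,
        sample_map={"NORM": ("PT1", "NORMAL"), "TUM": ("PT1", "PRIMARY")},
    )
    (mut,) = cohort.mutations
    assert mut.gene == "TP53" and mut.consequence is Consequence.MISSENSE
    assert mut.observations["TUM"].depth == 90
    assert mut.observations["TUM"].alt_reads == 30


@pytest.mark.parametrize("fmt", ["TSV", "JSON"])
def test_selection_results_round_trip(tmp_path, fmt):
    results = [selection_test(177, 47, label="PT4"),
               selection_test(29, 13, label="PT15")]
    path = tmp_path / f"sel.{fmt.lower()}"
    write_results(results, path, format=fmt)
    assert read_selection_results(path, format=fmt) == results


@pytest.mark.parametrize("fmt", ["TSV", "JSON"])
def test_enrichment_results_round_trip(tmp_path, fmt):
    coll = GeneSetCollection(name="c", sets={"S1": {"A", "B", "C"}, "S2": {"D"}})
    results = enrich({"A", "B", "X"}, coll, N=100)
    path = tmp_path / f"enr.{fmt.lower()}"
    write_results(results, path, format=fmt)
    assert read_enrichment_results(path, format=fmt) == results


def test_category_assignments_round_trip(tmp_path):
    cohort, truth = simulate(CohortSimConfig(seed=11, n_patients=1))
    decisions = apply_filters(cohort, blacklist=truth.blacklist_trees())
    assignments = categorize(cohort, decisions)
    path = tmp_path / "cats.tsv"
    write_results(assignments, path)
    back = read_category_assignments(path)
    assert [(a.key, a.category) for a in back] == [
        (a.key, a.category) for a in assignments
    ]
    # presence survives at stage resolution
    for orig, rt in zip(assignments, back):
        for stage in Stage:
            assert rt.stage_presence[stage] == orig.stage_presence.get(stage, False)


def test_write_results_unsupported_type(tmp_path):
    with pytest.raises(PipelineError):
        write_results([object()], tmp_path / "x.tsv")
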