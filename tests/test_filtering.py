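"""Validated-mutation filter: threshold boundaries, rescue rule, filter laws."""

import pytest
from hypothesis import given, strategies as st

from oncoprog.filtering import (
    FilterConfig,
    ReasonCode,
    apply_filters,
    flag_clusters,
    read_decisions,
    retained_keys,
    write_decisions,
)
from oncoprog.model import (
    CurationFlag,
    PipelineError,
    RegionClass,
    Stage,
    build_cohort,
)

from conftest import make_record, two_tumor_record


def decide_one(record, config=None, blacklist=None):
    cohort = build_cohort([record])
    return apply_filters(cohort, config, blacklist)[record.key]


class TestThresholdBoundaries:
    def test_clean_mutation_retained_with_presence(self):
        d = decide_one(two_tumor_record(normal=(60, 0), tumor1=(60, 6),
                                        tumor2=(60, 0)))
        assert d.retained
        assert d.presence == {"T1": True, "T2": False}

    def test_rescue_rule_grants_presence_above_200x(self):
        # second tumor BAF 0.03 >= 0.025 at depth 250 > 200 -> present
        d = decide_one(two_tumor_record(tumor1=(60, 6), tumor2=(250, 8)))
        assert d.retained
        assert d.presence == {"T1": True, "T2": True}

    def test_rescue_rule_requires_depth_exceeding_200x(self):
        # same BAF 0.03 but depth 150 (and exactly 200) -> absent
        d = decide_one(two_tumor_record(tumor2=(150, 5)))
        assert d.presence["T2"] is False
        d = decide_one(two_tumor_record(tumor2=(200, 6)))
        assert d.presence["T2"] is False

    def test_normal_baf_bound_is_exclusive(self):
        # BAF 0.025 >= 0.02 -> contaminated; 0.0199 < 0.02 -> clean
        d = decide_one(two_tumor_record(normal=(1000, 25)))
        assert ReasonCode.NORMAL_CONTAMINATION in d.reasons
        d = decide_one(two_tumor_record(normal=(1000, 19)))
        assert d.retained

    def test_depth_threshold_is_inclusive(self):
        d = decide_one(two_tumor_record(normal=(50, 0), tumor1=(50, 5),
                                        tumor2=(50, 0)))
        assert d.retained
        d = decide_one(two_tumor_record(normal=(49, 0)))
        assert ReasonCode.LOW_DEPTH in d.reasons

    def test_tumor_baf_threshold_is_inclusive(self):
        d = decide_one(two_tumor_record(tumor1=(100, 5)))  # BAF exactly 0.05
        assert d.retained
        d = decide_one(two_tumor_record(tumor1=(100, 4), tumor2=(100, 4)))
        assert ReasonCode.NO_TUMOR_SIGNAL in d.reasons

    def test_population_snp_bound_is_exclusive(self):
        assert decide_one(two_tumor_record(pop_af=0.01)).retained
        d = decide_one(two_tumor_record(pop_af=0.011))
        assert d.reasons == [ReasonCode.POPULATION_SNP]

    def test_region_restriction(self):
        d = decide_one(two_tumor_record(region=RegionClass.INTRONIC))
        assert d.reasons == [ReasonCode.REGION_EXCLUDED]
        assert decide_one(two_tumor_record(region=RegionClass.SPLICING)).retained

    def test_curation_flags(self):
        rec = two_tumor_record()
        rec.curation_flags.add(CurationFlag.REPEAT_REGION)
        assert ReasonCode.BLACKLISTED in decide_one(rec).reasons
        rec = two_tumor_record()
        rec.curation_flags.add(CurationFlag.ADJACENT_CLUSTER)
        assert decide_one(rec).reasons == [ReasonCode.CLUSTERED]

    def test_missing_normal_observation_errors(self):
        rec = make_record(
            100,
            [("T1", Stage.PRIMARY, 60, 10), ("T2", Stage.DISTANT_MET, 60, 0)],
        )
        norm = make_record(
            200, [("N", Stage.NORMAL, 60, 0), ("T1", Stage.PRIMARY, 60, 10),
                  ("T2", Stage.DISTANT_MET, 60, 0)]
        )
        cohort = build_cohort([norm, rec])
        with pytest.raises(PipelineError, match="normal"):
            apply_filters(cohort)


class TestClusterFlagging:
    def test_three_in_window_all_flagged(self):
        base = [("N", Stage.NORMAL, 60, 0), ("T1", Stage.PRIMARY, 60, 10)]
        recs = [make_record(p, base, alt=a)
                for p, a in ((100, "T"), (105, "G"), (108, "C"))]
        cohort = build_cohort(recs)
        flag_clusters(cohort, window=10, count=3)
        assert all(CurationFlag.ADJACENT_CLUSTER in m.curation_flags
                   for m in cohort.mutations)

    def test_distant_pair_not_flagged(self):
        base = [("N", Stage.NORMAL, 60, 0), ("T1", Stage.PRIMARY, 60, 10)]
        recs = [make_record(100, base), make_record(1100, base, alt="G")]
        cohort = build_cohort(recs)
        flag_clusters(cohort, window=10, count=3)
        assert not any(m.curation_flags for m in cohort.mutations)

    def test_empty_cohort_unchanged(self):
        cohort = build_cohort([])
        assert flag_clusters(cohort) is cohort and len(cohort) == 0


def _random_cohort(draw_data):
    """Cohort of independent two-tumor mutations from hypothesis data."""
    records = []
    for i, (nd, na_frac, t1d, t1f, t2d, t2f) in enumerate(draw_data):
        na = min(int(nd * na_frac), nd)
        records.append(
            two_tumor_record(
                pos=1000 + 5000 * i,
                normal=(nd, na),
                tumor1=(t1d, min(int(t1d * t1f), t1d)),
                tumor2=(t2d, min(int(t2d * t2f), t2d)),
            )
        )
    return build_cohort(records)


obs_tuple = st.tuples(
    st.integers(1, 400), st.floats(0, 0.05),
    st.integers(1, 400), st.floats(0, 0.6),
    st.integers(1, 400), st.floats(0, 0.6),
)


class TestFilterLaws:
    @given(st.lists(obs_tuple, min_size=1, max_size=8),
           st.floats(0.0, 0.2), st.floats(0.0, 0.2))
    def test_monotone_in_tumor_baf_threshold(self, data, lo, hi):
        lo, hi = sorted((lo, hi))
        cohort = _random_cohort(data)
        strict = FilterConfig(tumor_baf_min=hi, rescue_baf_min=min(0.025, hi))
        loose = FilterConfig(tumor_baf_min=lo, rescue_baf_min=min(0.025, lo))
        assert retained_keys(apply_filters(cohort, strict)) <= retained_keys(
            apply_filters(cohort, loose)
        )

    @given(st.lists(obs_tuple, min_size=1, max_size=8),
           st.integers(0, 300), st.integers(0, 300))
    def test_monotone_in_depth_threshold(self, data, lo, hi):
        lo, hi = sorted((lo, hi))
        cohort = _random_cohort(data)
        assert retained_keys(
            apply_filters(cohort, FilterConfig(min_depth_all=hi))
        ) <= retained_keys(apply_filters(cohort, FilterConfig(min_depth_all=lo)))

    @given(st.lists(obs_tuple, min_size=1, max_size=8))
    def test_degenerate_passthrough(self, data):
        cohort = _random_cohort(data)
        config = FilterConfig(
            normal_baf_max=1.1, min_depth_all=0, tumor_baf_min=0.0,
            rescue_baf_min=0.0, pop_af_max=1.0,
            allowed_regions=frozenset(RegionClass),
        )
        decisions = apply_filters(cohort, config)
        assert all(d.retained for d in decisions.values())
        assert all(all(d.presence.values()) for d in decisions.values())

    @given(st.lists(obs_tuple, min_size=2, max_size=8))
    def test_verdicts_invariant_under_mutation_order(self, data):
        cohort = _random_cohort(data)
        reversed_cohort = build_cohort(list(reversed(cohort.mutations)))
        a = apply_filters(cohort)
        b = apply_filters(reversed_cohort)
        assert {k: d.reasons for k, d in a.items()} == {
            k: d.reasons for k, d in b.items()
        }

    def test_retained_implies_presence_somewhere(self):
        d = decide_one(two_tumor_record())
        assert d.retained and any(d.presence.values())


def test_config_validation():
    with pytest.raises(PipelineError):
        FilterConfig(rescue_baf_min=0.06, tumor_baf_min=0.05)
    with pytest.raises(PipelineError):
        FilterConfig(min_depth_all=-1)


def test_config_from_file(tmp_path):
    path = tmp_path / "filter.cfg"
    path.write_text(
        "# thresholds\nnormal_baf_max = 0.03\nmin_depth_all = 30\n"
        "allowed_regions = EXONIC\n"
    )
    config = FilterConfig.from_file(path)
    assert config.normal_baf_max == 0.03
    assert config.min_depth_all == 30
    assert config.allowed_regions == frozenset({RegionClass.EXONIC})


def test_decisions_round_trip(tmp_path):
    cohort = build_cohort([
        two_tumor_record(pos=1000),
        two_tumor_record(pos=2000, alt="G", normal=(1000, 30)),
    ])
    decisions = apply_filters(cohort)
    path = tmp_path / "decisions.tsv"
    write_decisions(decisions, path)
    back = read_decisions(path)
    assert set(back) == set(decisions)
    for key, d in decisions.items():
        assert back[key].reasons == d.reasons
        assert back[key].presence == d.presence
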