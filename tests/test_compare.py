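import numpy as np
import pandas as pd
import pytest

from pbflex import (
    GeneratorSpec,
    compare_profiles,
    compare_systems,
    divergence_summary,
    flex_profile,
    generate_string_mode,
    inject_variant_effect,
    long_range_flag,
    pb_frequencies,
    profile_correlation,
    replicate_neq_correlations,
    SystemRun,
)
from pbflex.compare import ComparisonRecord


def _system(label, spec, seed=None):
    from dataclasses import replace

    if seed is not None:
        spec = replace(spec, seed=seed)
    profile = pb_frequencies(generate_string_mode(spec))
    return SystemRun(label=label, pb_profile=profile, flex=flex_profile(profile))


def _heterogeneous_spec(n_frames=2000, seed=0):
    return GeneratorSpec.uniform_background(
        20,
        overrides={
            5: {"b": 0.5, "h": 0.5},
            10: {"m": 0.7, "n": 0.2, "o": 0.1},
            15: {"b": 0.4, "c": 0.3, "h": 0.3},
        },
        n_frames=n_frames,
        seed=seed,
    )


class TestProfileCorrelation:
    def test_track_vs_itself_is_one(self):
        track = pd.Series([1.0, 2.5, 3.0, 1.2], index=[1, 2, 3, 4])
        assert profile_correlation(track, track) == pytest.approx(1.0)

    def test_track_vs_negation_is_minus_one(self):
        track = pd.Series([1.0, 2.5, 3.0, 1.2], index=[1, 2, 3, 4])
        assert profile_correlation(track, -track) == pytest.approx(-1.0)

    def test_prescribed_correlation_recovered(self):
        rng = np.random.default_rng(17)
        rho, n = 0.8, 500
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        idx = np.arange(n)
        r = profile_correlation(
            pd.Series(xy[:, 0], index=idx), pd.Series(xy[:, 1], index=idx)
        )
        assert r == pytest.approx(rho, abs=0.05)

    def test_constant_track_is_undefined(self):
        a = pd.Series([1.0, 1.0, 1.0], index=[1, 2, 3])
        b = pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3])
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(profile_correlation(a, b))

    def test_too_few_shared_positions_rejected(self):
        a = pd.Series([1.0, 2.0], index=[1, 2])
        with pytest.raises(ValueError, match="3 shared"):
            profile_correlation(a, a)


def _record_from_values(delta_pbs, delta_neqs=None):
    n = len(delta_pbs)
    table = pd.DataFrame(
        {
            "delta_neq": delta_neqs if delta_neqs is not None else np.zeros(n),
            "delta_pb": delta_pbs,
        },
        index=pd.Index(np.arange(700, 700 + n), name="residue"),
    )
    return ComparisonRecord(label_a="wt", label_b="var", table=table)


class TestDivergenceSummary:
    def test_all_zero_record_flags_nothing(self):
        summary = divergence_summary(_record_from_values(np.zeros(10)))
        assert summary.flagged.empty
        assert summary.fraction == 0.0

    def test_single_divergent_position_among_ten(self):
        values = np.zeros(10)
        values[4] = 1.6
        summary = divergence_summary(_record_from_values(values), threshold=1.0)
        assert list(summary.flagged.index) == [704]
        assert summary.fraction == pytest.approx(0.1)
        assert summary.argmax_delta_pb == 704

    def test_threshold_two_flags_only_totally_disjoint(self):
        values = np.array([0.0, 1.9, 2.0, 0.5])
        summary = divergence_summary(_record_from_values(values), threshold=2.0)
        assert list(summary.flagged.index) == [702]

    def test_flagged_positions_carry_region_annotation(self):
        values = np.zeros(20)
        values[11] = 1.5  # residue 711, Calf-1 loop 8
        summary = divergence_summary(_record_from_values(values))
        assert summary.flagged.loc[711, "region"] == "Calf-1 loop 8"


class TestLongRangeFlag:
    def test_only_local_divergence_is_not_long_range(self):
        values = np.zeros(20)
        values[9] = 1.5  # site at 710, flag at 709: local
        record = _record_from_values(values)
        summary = divergence_summary(record)
        out = long_range_flag(record, summary, mutation_site=710, window=5)
        assert (out.labels == "local").all()
        assert out.long_range is False

    def test_stable_site_with_distant_divergence_is_long_range(self):
        # the canonical pattern: mutation site nearly unchanged
        # (dPB 0.02) while a far position diverges
        values = np.zeros(160)
        values[0] = 0.02  # site, residue 700
        values[145] = 1.8  # residue 845, 145 residues away
        record = _record_from_values(values)
        summary = divergence_summary(record)
        out = long_range_flag(record, summary, mutation_site=700)
        assert out.site_delta_pb == pytest.approx(0.02)
        assert (out.labels == "distant").all()
        assert out.long_range is True

    def test_no_flagged_positions_is_not_long_range(self):
        record = _record_from_values(np.zeros(10))
        summary = divergence_summary(record)
        out = long_range_flag(record, summary, mutation_site=705)
        assert out.long_range is False

    def test_unstable_site_suppresses_the_headline(self):
        values = np.zeros(160)
        values[0] = 1.4  # site itself diverges
        values[145] = 1.8
        record = _record_from_values(values)
        summary = divergence_summary(record)
        out = long_range_flag(record, summary, mutation_site=700)
        assert out.long_range is False

    def test_site_outside_numbering_rejected(self):
        record = _record_from_values(np.zeros(10))
        summary = divergence_summary(record)
        with pytest.raises(ValueError, match="site"):
            long_range_flag(record, summary, mutation_site=9999)


class TestSystemComparison:
    def test_swapping_systems_leaves_all_measures_unchanged(self):
        spec = _heterogeneous_spec(seed=21)
        a = _system("wt", spec, seed=21)
        b = _system("var", spec, seed=22)
        fwd = compare_systems(a, b, mutation_site=10)
        rev = compare_systems(b, a, mutation_site=10)
        assert np.allclose(fwd.record.delta_pb, rev.record.delta_pb)
        assert np.allclose(fwd.record.delta_neq, rev.record.delta_neq)
        assert fwd.neq_correlation == pytest.approx(rev.neq_correlation)
        assert fwd.summary.fraction == rev.summary.fraction
        if fwd.assessment and rev.assessment:
            assert fwd.assessment.long_range == rev.assessment.long_range

    def test_identical_distributions_rarely_trigger_long_range(self):
        # calibration at 10,000 frames: independent draws from the same
        # targets must not produce a long-range call at default thresholds
        spec = _heterogeneous_spec(n_frames=10_000)
        calls = []
        for seed in (31, 32, 33, 34, 35):
            a = _system("wt", spec, seed=seed)
            b = _system("var", spec, seed=seed + 1000)
            report = compare_systems(a, b, mutation_site=10)
            calls.append(report.assessment.long_range)
        assert not any(calls)

    def test_injected_distant_swap_is_flagged_and_site_is_not(self):
        base = _heterogeneous_spec(n_frames=3000, seed=50)
        wt_spec, var_spec = inject_variant_effect(
            base, site=3, distant=18, effect="h"
        )
        wt = _system("wt", wt_spec, seed=50)
        var = _system("var", var_spec, seed=51)
        report = compare_systems(wt, var, mutation_site=3)
        assert list(report.summary.flagged.index) == [18]
        assert report.record.delta_pb.loc[18] == pytest.approx(2.0, abs=0.05)
        assert report.assessment.long_range is True

    def test_report_dict_is_json_serializable(self):
        import json

        spec = _heterogeneous_spec(seed=60)
        report = compare_systems(
            _system("wt", spec, seed=60), _system("var", spec, seed=61),
            mutation_site=10,
        )
        blob = json.dumps(report.to_dict(), sort_keys=True)
        assert "config_hash" in blob


def test_replicate_neq_correlations_pairwise_table():
    spec = _heterogeneous_spec(n_frames=4000)
    profiles = [
        pb_frequencies(generate_string_mode(spec, replicate=r)) for r in range(3)
    ]
    table = replicate_neq_correlations(profiles)
    assert len(table) == 3  # C(3, 2)
    # replicates of one distribution sample near-identical Neq profiles
    assert (table["pearson_r"] > 0.9).all()


def test_compare_profiles_restricts_to_shared_positions():
    spec_a = _heterogeneous_spec(seed=70)
    spec_b = GeneratorSpec.uniform_background(
        20, first_resid=11, n_frames=2000, seed=71
    )
    a = _system("a", spec_a)
    b = SystemRun(
        label="b",
        pb_profile=pb_frequencies(generate_string_mode(spec_b)),
        flex=flex_profile(pb_frequencies(generate_string_mode(spec_b))),
    )
    record = compare_profiles(a, b)
    assert record.table.index.min() >= 11
    assert record.table.index.max() <= 20
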