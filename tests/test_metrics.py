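import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pbflex import (
    PB_LETTERS,
    PBEnsemble,
    classify_flexibility,
    delta_neq,
    delta_pb,
    delta_pb_profile,
    distribution,
    flex_profile,
    generate_string_mode,
    GeneratorSpec,
    logo_export,
    neq,
    occurrence_map,
    pb_frequencies,
)


def _pb(letter_rows, first_resid=1):
    letters = np.array([list(r) for r in letter_rows], dtype="U1")
    return PBEnsemble(
        letters=letters,
        resids=np.arange(first_resid, first_resid + letters.shape[1]),
    )


def _random_rows(rng, n):
    return rng.dirichlet(np.full(16, 0.5), size=n)


class TestNeq:
    def test_pure_distribution_is_one(self):
        assert neq(distribution("d")) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_distribution_is_sixteen(self):
        assert neq(np.full(16, 1 / 16)) == pytest.approx(16.0, abs=1e-9)

    def test_three_letter_mixture_closed_form(self):
        # {0.6, 0.2, 0.2}: Neq = exp(0.6 ln(1/0.6) + 0.4 ln 5)
        expected = np.exp(0.6 * np.log(1 / 0.6) + 0.4 * np.log(5.0))
        value = neq(distribution({"b": 0.6, "d": 0.2, "h": 0.2}))
        assert value == pytest.approx(expected, abs=1e-12)
        assert value == pytest.approx(2.586, abs=5e-4)

    def test_matches_independent_entropy_oracle(self):
        rng = np.random.default_rng(42)
        for row in _random_rows(rng, 1000):
            assert abs(neq(row) - np.exp(stats.entropy(row))) < 1e-12

    def test_range_is_1_to_16(self):
        rng = np.random.default_rng(1)
        values = [neq(row) for row in _random_rows(rng, 200)]
        assert min(values) >= 1.0 - 1e-12
        assert max(values) <= 16.0 + 1e-12

    def test_non_normalized_row_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            neq(np.full(16, 0.1))


class TestClassification:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (9.0, "disordered"),
            (8.0, "highly_flexible"),
            (7.0, "highly_flexible"),
            (6.0, "flexible"),
            (4.0, "flexible"),
            (3.0, "flexible"),
            (2.9, "rigid"),
            (1.0, "rigid"),
        ],
    )
    def test_threshold_bands(self, value, expected):
        assert classify_flexibility(value) == expected

    @pytest.mark.parametrize("value", [0.5, 16.5, float("nan")])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(ValueError):
            classify_flexibility(value)


class TestFrequencies:
    def test_single_letter_position(self):
        profile = pb_frequencies(_pb(["ddddd"] * 10))
        assert (profile.frequencies[:, PB_LETTERS.index("d")] == 1.0).all()
        assert (profile.counts == 10).all()

    def test_z_frames_excluded_from_denominator(self):
        profile = pb_frequencies(_pb(["ddddd", "ddddd", "hhhhh", "ZZZZZ"]))
        d, h = PB_LETTERS.index("d"), PB_LETTERS.index("h")
        assert profile.frequencies[0, d] == pytest.approx(2 / 3)
        assert profile.frequencies[0, h] == pytest.approx(1 / 3)
        assert (profile.counts == 3).all()

    def test_all_z_position_flagged_empty(self):
        profile = pb_frequencies(_pb(["dZddd", "dZddd"]))
        assert profile.empty[1]
        assert not profile.empty[0]
        assert np.isnan(profile.neq_track().iloc[1])

    def test_sampling_recovers_target_within_binomial_bound(self):
        target = {"b": 0.6, "d": 0.2, "h": 0.2}
        spec = GeneratorSpec.uniform_background(
            5, background=target, n_frames=10_000, seed=7
        )
        profile = pb_frequencies(generate_string_mode(spec))
        assert np.abs(profile.frequencies - spec.targets).max() < 0.02

    def test_adding_consensus_frames_never_increases_neq(self):
        rng = np.random.default_rng(8)
        spec = GeneratorSpec.uniform_background(
            6, background={"b": 0.4, "d": 0.3, "h": 0.3}, n_frames=50, seed=9
        )
        pb = generate_string_mode(spec)
        before = pb_frequencies(pb).neq_track()
        consensus = np.array(PB_LETTERS, dtype="U1")[
            np.argmax(pb_frequencies(pb).frequencies, axis=1)
        ]
        extended = PBEnsemble(
            letters=np.vstack([pb.letters, np.tile(consensus, (20, 1))]),
            resids=pb.resids,
        )
        after = pb_frequencies(extended).neq_track()
        assert (after <= before + 1e-12).all()


class TestDeltaPB:
    def test_identical_rows_zero(self):
        rng = np.random.default_rng(3)
        row = rng.dirichlet(np.ones(16))
        total, per_letter = delta_pb(row, row)
        assert total == 0.0
        assert (per_letter == 0).all()

    def test_disjoint_support_is_two(self):
        total, _ = delta_pb(distribution("d"), distribution("h"))
        assert total == pytest.approx(2.0, abs=1e-12)

    def test_residue_796_worked_example(self):
        # one forcefield samples b/d/h at 60/20/20%, the other pure h
        total, per_letter = delta_pb(
            distribution({"b": 0.6, "d": 0.2, "h": 0.2}),
            distribution({"h": 1.0}),
        )
        assert total == pytest.approx(1.6, abs=1e-12)
        assert per_letter[PB_LETTERS.index("h")] == pytest.approx(0.8, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_l1_distance_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.dirichlet(np.ones(16), size=3)
        d_ab, _ = delta_pb(a, b)
        d_ba, _ = delta_pb(b, a)
        d_ac, _ = delta_pb(a, c)
        d_cb, _ = delta_pb(c, b)
        assert d_ab == pytest.approx(d_ba, abs=1e-12)  # symmetry
        assert 0.0 <= d_ab <= 2.0  # bounds
        assert d_ab <= d_ac + d_cb + 1e-12  # triangle inequality


class TestDeltaNeq:
    def test_identical_profiles_zero(self):
        spec = GeneratorSpec.uniform_background(
            8, background={"b": 0.5, "m": 0.5}, n_frames=30, seed=4
        )
        flex = flex_profile(pb_frequencies(generate_string_mode(spec)))
        assert (delta_neq(flex, flex) == 0).all()

    def test_absolute_difference(self):
        import pandas as pd

        a = pd.Series([2.5, 3.0], index=[10, 11])
        b = pd.Series([1.5, 3.0], index=[10, 11])
        out = delta_neq(a, b)
        assert out.loc[10] == 1.0
        assert out.loc[11] == 0.0

    def test_sampling_noise_bound_at_large_frame_count(self):
        target = {"b": 0.4, "d": 0.3, "h": 0.2, "m": 0.1}
        spec_a = GeneratorSpec.uniform_background(
            6, background=target, n_frames=10_000, seed=100
        )
        spec_b = GeneratorSpec.uniform_background(
            6, background=target, n_frames=10_000, seed=200
        )
        flex_a = flex_profile(pb_frequencies(generate_string_mode(spec_a)))
        flex_b = flex_profile(pb_frequencies(generate_string_mode(spec_b)))
        assert delta_neq(flex_a, flex_b).max() < 0.1

    def test_disjoint_numbering_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="share"):
            delta_neq(pd.Series([1.0], index=[1]), pd.Series([1.0], index=[9]))


class TestProfileExports:
    @pytest.fixture()
    def mixture_profile(self):
        spec = GeneratorSpec.uniform_background(
            5, overrides={3: {"b": 0.6, "d": 0.2, "h": 0.2}},
            n_frames=400, seed=5,
        )
        return pb_frequencies(generate_string_mode(spec))

    def test_occurrence_map_whole_region(self, mixture_profile):
        m = occurrence_map(mixture_profile, (1, 5))
        assert m.shape == (5, 16)
        assert np.allclose(m.sum(axis=1), 1.0)

    def test_occurrence_map_is_profile_restriction(self, mixture_profile):
        m = occurrence_map(mixture_profile, (2, 4))
        assert np.allclose(
            m.to_numpy(), mixture_profile.frequencies[1:4]
        )

    def test_single_pure_position(self):
        profile = pb_frequencies(_pb(["ddddd"] * 3))
        m = occurrence_map(profile, (2, 2))
        assert m.shape == (1, 16)
        assert m.iloc[0]["d"] == 1.0

    def test_region_outside_profile_rejected(self, mixture_profile):
        with pytest.raises(ValueError, match="outside"):
            occurrence_map(mixture_profile, (4, 9))

    def test_logo_heights_are_frequencies_sorted_descending(self, mixture_profile):
        logo = logo_export(mixture_profile, (3, 3))
        heights = logo["height"].to_numpy()
        assert logo.iloc[0]["pb"] == "b"  # majority letter on top
        assert (np.diff(heights) <= 0).all()
        assert heights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_logo_heights_sum_to_one_per_position(self, mixture_profile):
        logo = logo_export(mixture_profile, (1, 5))
        sums = logo.groupby("residue")["height"].sum()
        assert np.allclose(sums, 1.0)


def test_delta_pb_profile_restricted_to_mutually_assignable():
    a = pb_frequencies(_pb(["Zdddd", "Zdddd"]))
    b = pb_frequencies(_pb(["hhhhZ", "hhhhZ"]))
    table = delta_pb_profile(a, b)
    # position 1 unassignable in a, position 5 in b
    assert list(table.index) == [2, 3, 4]
    assert np.allclose(table["delta_pb"], 2.0)
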