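import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbflex.alphabet import PB_LABELS, PBTrajectory
from pbflex.stats import (
    FrequencyProfile,
    FlexibilityProfile,
    category_summary,
    categorize,
    delta_neq,
    delta_pb,
    frequency_map,
    logo_matrix,
    neq,
    neq_profile,
    pearson,
)


def vec(**weights):
    """16-vector of PB frequencies from keyword weights, e.g. vec(m=0.5, d=0.5)."""
    out = np.zeros(16)
    for label, w in weights.items():
        out[PB_LABELS.index(label)] = w
    return out


def random_simplex(rng, n=1):
    x = rng.dirichlet(np.ones(16) * 0.5, size=n)
    return x[0] if n == 1 else x


class TestFrequencyMap:
    def test_three_quarter_mixture(self):
        labels = np.array([list("ZZmZZ"), list("ZZmZZ"), list("ZZmZZ"), list("ZZdZZ")])
        freq = frequency_map(PBTrajectory(labels=labels, resids=np.arange(1, 6)))
        assert freq.freqs[2, PB_LABELS.index("m")] == pytest.approx(0.75)
        assert freq.freqs[2, PB_LABELS.index("d")] == pytest.approx(0.25)
        assert freq.counts[2] == 4

    def test_pure_position(self):
        labels = np.array([list("ZZmZZ")] * 5)
        freq = frequency_map(PBTrajectory(labels=labels, resids=np.arange(1, 6)))
        row = freq.freqs[2]
        assert row[PB_LABELS.index("m")] == 1.0
        assert row.sum() == 1.0

    def test_all_unassigned_is_empty_flag(self):
        labels = np.array([list("ZZZZZ")] * 3)
        freq = frequency_map(PBTrajectory(labels=labels, resids=np.arange(1, 6)))
        assert freq.empty.all()
        assert np.isnan(freq.freqs).all()

    def test_pooling_invariance(self):
        rng = np.random.default_rng(9)
        choices = np.array(list(PB_LABELS))
        rep1 = choices[rng.integers(0, 16, size=(30, 7))]
        rep2 = choices[rng.integers(0, 16, size=(50, 7))]
        resids = np.arange(1, 8)
        pooled = frequency_map(PBTrajectory(labels=np.vstack([rep1, rep2]), resids=resids))
        f1 = frequency_map(PBTrajectory(labels=rep1, resids=resids))
        f2 = frequency_map(PBTrajectory(labels=rep2, resids=resids))
        weighted = (30 * f1.freqs + 50 * f2.freqs) / 80
        np.testing.assert_allclose(pooled.freqs, weighted, atol=1e-12)


class TestNeq:
    def test_single_pb_gives_one(self):
        assert neq(vec(m=1.0)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_gives_sixteen(self):
        assert neq(np.full(16, 1 / 16)) == pytest.approx(16.0, abs=1e-9)

    def test_even_two_way_split_gives_two(self):
        assert neq(vec(m=0.5, d=0.5)) == pytest.approx(2.0, abs=1e-12)

    def test_empty_row_is_nan(self):
        assert np.isnan(neq(np.full(16, np.nan)))

    def test_unnormalized_row_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            neq(vec(m=0.9))

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        row = random_simplex(rng)
        value = neq(row)
        assert 1.0 - 1e-9 <= value <= 16.0 + 1e-9
        assert neq(rng.permutation(row)) == pytest.approx(value, rel=1e-12)


class TestDeltaNeq:
    def test_identical_profiles_zero(self):
        a = np.array([1.0, 2.5, 8.0])
        np.testing.assert_allclose(delta_neq(a, a), 0.0)

    def test_drop_from_8_7_to_5_7(self):
        # the E-helix/D-helix loop signature change at residue 950
        assert delta_neq(np.array([8.7]), np.array([5.7]))[0] == pytest.approx(3.0)

    def test_symmetry_and_nan_propagation(self):
        a = np.array([2.0, np.nan, 4.0])
        b = np.array([3.5, 2.0, np.nan])
        d1, d2 = delta_neq(a, b), delta_neq(b, a)
        np.testing.assert_allclose(d1[0], d2[0])
        assert np.isnan(d1[1]) and np.isnan(d1[2])


class TestDeltaPb:
    def test_identical_distributions_zero(self):
        assert delta_pb(vec(m=0.5, d=0.5), vec(m=0.5, d=0.5))[0] == 0.0

    def test_disjoint_single_pbs_two(self):
        assert delta_pb(vec(m=1.0), vec(d=1.0))[0] == pytest.approx(2.0)

    def test_half_overlap_is_one(self):
        assert delta_pb(vec(m=1.0), vec(m=0.5, d=0.5))[0] == pytest.approx(1.0)

    def test_equal_neq_nonzero_delta_pb(self):
        # same entropy (N_eq = 1 both sides), different blocks: deltaPB sees it
        a, b = vec(m=1.0), vec(d=1.0)
        assert neq(a) == pytest.approx(neq(b))
        assert delta_pb(a, b)[0] > 0

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = random_simplex(rng, 3)
        dab = delta_pb(a, b)[0]
        assert dab == pytest.approx(delta_pb(b, a)[0])
        assert 0.0 <= dab <= 2.0
        assert delta_pb(a, a)[0] == 0.0
        assert delta_pb(a, c)[0] <= dab + delta_pb(b, c)[0] + 1e-12


class TestCategorize:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.0, "rigid"),
            (1.0 + 5e-7, "rigid"),
            (1.5, "quite_rigid"),
            (2.0, "quite_rigid"),
            (2.0001, "moderate"),
            (4.5, "flexible"),
            (7.0, "extremely_flexible"),
            (8.09, "disordered"),
            (16.0, "disordered"),
        ],
    )
    def test_bins(self, value, expected):
        assert categorize(value) == expected

    @pytest.mark.parametrize("value", [0.5, 16.5])
    def test_out_of_range_signals_upstream_bug(self, value):
        with pytest.raises(ValueError):
            categorize(value)

    def test_nan_maps_to_empty_label(self):
        assert categorize(float("nan")) == ""


class TestCategorySummary:
    def test_all_rigid(self):
        summary = category_summary(np.array(["rigid"] * 5, dtype=object))
        assert summary["rigid"] == 100.0
        assert summary.drop("rigid").sum() == 0.0

    def test_even_split(self):
        summary = category_summary(np.array(["rigid", "disordered"], dtype=object))
        assert summary["rigid"] == 50.0
        assert summary["disordered"] == 50.0

    def test_percentages_sum_to_100(self):
        cats = np.array(
            ["rigid", "quite_rigid", "moderate", "flexible", "rigid", ""], dtype=object
        )
        assert category_summary(cats).sum() == pytest.approx(100.0, abs=1e-6)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_constant_series_undefined(self):
        assert np.isnan(pearson(np.arange(5.0), np.ones(5)))

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 100.0, 8.0, np.nan])
        assert pearson(x, y) == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            pearson(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, np.nan]))


class TestLogoMatrix:
    def make_profile(self):
        freqs = np.vstack([vec(f=1.0), vec(m=0.5, d=0.5), vec(a=1.0)])
        return FrequencyProfile(freqs=freqs, counts=np.array([10, 10, 10]),
                                resids=np.array([100, 101, 102]))

    def test_single_position(self):
        df = logo_matrix(self.make_profile(), (100, 100))
        assert len(df) == 1
        assert df.loc[100, "f"] == 1.0

    def test_row_sums(self):
        df = logo_matrix(self.make_profile())
        np.testing.assert_allclose(df.sum(axis=1), 1.0)

    def test_out_of_range_warns_and_empty(self):
        with pytest.warns(UserWarning, match="outside"):
            df = logo_matrix(self.make_profile(), (500, 600))
        assert df.empty


def test_neq_profile_respects_empty_positions():
    freqs = np.vstack([vec(m=1.0), np.full(16, np.nan)])
    prof = FrequencyProfile(freqs=freqs, counts=np.array([3, 0]), resids=np.array([1, 2]))
    values = neq_profile(prof)
    assert values[0] == pytest.approx(1.0)
    assert np.isnan(values[1])
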