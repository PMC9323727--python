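import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import alpha as skbio_alpha
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from oronasal.diversity import (
    ace,
    ace_with_fallback,
    alpha_diversity,
    bray_curtis,
    chao1,
    compare_alpha,
    pcoa,
    shannon,
)
from conftest import make_table


def random_count_vector(rng, max_taxa=80):
    lam = np.exp(rng.uniform(np.log(0.2), np.log(40), size=rng.integers(5, max_taxa)))
    x = rng.poisson(lam)
    return x if x.sum() > 0 else np.array([1])


class TestShannon:
    def test_uniform_closed_form(self):
        assert shannon([5, 5, 5, 5, 5]) == pytest.approx(math.log(5), abs=1e-12)

    def test_single_taxon_is_zero(self):
        assert shannon([10]) == 0.0

    def test_hand_computed_oracle(self):
        expected = -(0.8 * math.log(0.8) + 2 * 0.1 * math.log(0.1))
        assert shannon([8, 1, 1]) == pytest.approx(expected, abs=1e-12)

    def test_base_two(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_permutation_invariant_and_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 50, size=12)
        assert shannon(x) == pytest.approx(shannon(rng.permutation(x)), abs=1e-12)
        assert shannon(x) <= math.log(12) + 1e-12
        assert shannon(np.full(12, 7)) == pytest.approx(math.log(12), abs=1e-12)

    def test_all_zero_vector_is_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            shannon([0, 0])


class TestChao1:
    def test_no_singletons_returns_observed_richness(self):
        assert chao1([2, 3, 10, 4]) == 4

    def test_bias_corrected_formula(self):
        # S_obs=6, F1=3, F2=2 -> 6 + 3*2/(2*3) = 7
        assert chao1([1, 1, 1, 2, 2, 5]) == pytest.approx(7.0)

    def test_no_doubletons_defined_by_bias_correction(self):
        assert chao1([1, 1, 1, 1]) == pytest.approx(10.0)

    def test_never_below_observed_richness_and_matches_skbio(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = random_count_vector(rng)
            c = chao1(x)
            assert c >= (x > 0).sum()
            assert c == pytest.approx(skbio_alpha.chao1(x, bias_corrected=True), abs=1e-9)


class TestAce:
    def test_no_rare_class_returns_observed_richness(self):
        assert ace([11, 20, 30]) == 3.0

    def test_all_singletons_falls_back_to_chao1_with_flag(self):
        value, fallback = ace_with_fallback([1, 1, 1])
        assert fallback and value == pytest.approx(chao1([1, 1, 1]))

    def test_stepwise_formula_oracle(self):
        x = np.array([1, 1, 2, 3, 12, 15])
        # independent step-by-step evaluation
        rare = x[(x > 0) & (x <= 10)]
        s_abund, s_rare, n_rare = 2, 4, rare.sum()
        f = {i: int((rare == i).sum()) for i in range(1, 11)}
        c_ace = 1 - f[1] / n_rare
        gamma = max(
            (s_rare / c_ace) * sum(i * (i - 1) * f[i] for i in f) / (n_rare * (n_rare - 1)) - 1,
            0.0,
        )
        expected = s_abund + s_rare / c_ace + f[1] / c_ace * gamma
        assert ace(x) == pytest.approx(expected, abs=1e-12)

    def test_never_below_observed_richness_and_matches_skbio(self):
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(80):
            x = random_count_vector(rng)
            value, fallback = ace_with_fallback(x)
            assert value >= (x > 0).sum() - 1e-9
            rare = x[(x > 0) & (x <= 10)]
            if not fallback and rare.size:
                assert value == pytest.approx(skbio_alpha.ace(x, rare_threshold=10), rel=1e-9)
                checked += 1
        assert checked > 20


class TestCompareAlpha:
    def test_identical_groups_give_p_one(self):
        stat, p = compare_alpha({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_welch_t_matches_textbook_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        stat, _ = compare_alpha({"a": a, "b": b}, design="two_group_t")
        se = math.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert stat == pytest.approx((a.mean() - b.mean()) / se, abs=1e-12)

    def test_three_group_anova_null_calibration(self):
        rng = np.random.default_rng(9)
        rejections = sum(
            compare_alpha({g: rng.normal(size=8) for g in "abc"}, design="anova")[1] < 0.05
            for _ in range(2000)
        )
        assert 0.05 - 0.015 < rejections / 2000 < 0.05 + 0.015

    def test_single_value_group_is_an_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_alpha({"a": [1.0], "b": [1.0, 2.0]})


class TestBrayCurtis:
    def test_identical_columns_distance_zero(self):
        dm = bray_curtis(make_table([[3, 3], [7, 7]]))
        assert dm.data[0, 1] == 0.0

    def test_disjoint_support_distance_one(self):
        dm = bray_curtis(make_table([[5, 0], [0, 9]]))
        assert dm.data[0, 1] == 1.0

    def test_formula_oracle(self):
        dm = bray_curtis(make_table([[6, 2], [4, 8]]))
        assert dm.data[0, 1] == pytest.approx(0.4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10**6))
    def test_symmetric_zero_diagonal_unit_range(self, seed):
        rng = np.random.default_rng(seed)
        table = make_table(rng.integers(0, 30, size=(6, 5)) + 1)
        d = bray_curtis(table).data
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_invariant_to_joint_column_rescaling(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 40, size=(7, 2))
        d1 = bray_curtis(make_table(counts)).data[0, 1]
        d2 = bray_curtis(make_table(counts * 13)).data[0, 1]
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_two_all_zero_samples_are_an_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(make_table([[0, 0, 1], [0, 0, 2]]))


class TestPcoa:
    def test_points_on_a_line_reproduce_distances_on_axis_one(self):
        d = np.array([[0.0, 1, 3], [1, 0, 2], [3, 2, 0]])
        ordination = pcoa(DistanceMatrix(d, ids=list("abc")), k=3)
        axis1 = ordination.coordinates["PC1"].to_numpy()
        got = np.abs(axis1[:, None] - axis1[None, :])
        np.testing.assert_allclose(got, d, atol=1e-9)
        assert ordination.n_negative_eigenvalues == 0

    def test_equilateral_triangle_has_two_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        ordination = pcoa(DistanceMatrix(d, ids=list("abc")), k=2)
        assert ordination.eigenvalues[0] == pytest.approx(ordination.eigenvalues[1], rel=1e-9)

    def test_reconstructs_euclidean_point_cloud_and_matches_skbio(self):
        rng = np.random.default_rng(6)
        points = rng.normal(size=(10, 4))
        d = squareform(pdist(points))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(10)])
        ordination = pcoa(dm, k=10)
        reconstructed = squareform(pdist(ordination.coordinates.to_numpy()))
        np.testing.assert_allclose(reconstructed, d, atol=1e-8)
        reference = skbio_pcoa(dm, method="eigh")
        ref_vals = np.sort(reference.eigvals.values)[::-1]
        np.testing.assert_allclose(
            ref_vals[: ordination.eigenvalues.size], ordination.eigenvalues, atol=1e-8
        )

    def test_requesting_too_many_axes_sets_truncated_flag(self):
        d = np.array([[0.0, 1, 3], [1, 0, 2], [3, 2, 0]])
        ordination = pcoa(DistanceMatrix(d, ids=list("abc")), k=5)
        assert ordination.truncated


def test_alpha_diversity_table_requires_counts_and_labels_samples(cohort):
    table, _, _ = cohort
    frame = alpha_diversity(table)
    assert set(frame.columns) == {"shannon", "chao1", "ace", "ace_fallback"}
    assert list(frame.index) == table.samples
    with pytest.raises(ValueError, match="counts-mode"):
        from oronasal.tables import to_relative

        alpha_diversity(to_relative(table))
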