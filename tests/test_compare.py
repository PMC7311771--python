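import numpy as np
import pytest

from mmspike.compare import (
    cohen_d,
    effect_magnitude,
    effect_size_report,
    excursion_ttest,
    glass_delta,
    kruskal_wallis_matrix,
    ks_matrix,
    star,
)
from mmspike.errors import ValidationError


class TestKruskalWallisMatrix:
    def test_symmetric_unit_diagonal_with_stars(self, rng):
        groups = {
            "a": rng.normal(0, 1, 50),
            "b": rng.normal(0, 1, 50),
            "c": rng.normal(5, 1, 50),
        }
        mat = kruskal_wallis_matrix(groups)
        vals = mat.values
        assert np.allclose(vals.to_numpy(), vals.to_numpy().T)
        assert all(vals.loc[g, g] == 1.0 for g in groups)
        for i in groups:
            for j in groups:
                assert mat.annotation.loc[i, j] == star(vals.loc[i, j])

    def test_separated_ranks_highly_significant(self):
        groups = {"lo": np.arange(1.0, 26.0), "hi": np.arange(101.0, 126.0)}
        mat = kruskal_wallis_matrix(groups)
        assert mat.values.loc["lo", "hi"] < 0.01
        assert mat.annotation.loc["lo", "hi"] == "**"

    def test_rank_invariance_under_permutation(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(1, 1, 40)
        m1 = kruskal_wallis_matrix({"a": a, "b": b})
        m2 = kruskal_wallis_matrix({"a": rng.permutation(a), "b": rng.permutation(b)})
        assert m1.values.loc["a", "b"] == pytest.approx(m2.values.loc["a", "b"])

    def test_identical_samples_p_one(self, rng):
        x = rng.normal(size=30)
        mat = kruskal_wallis_matrix({"a": x, "b": x.copy()})
        assert mat.values.loc["a", "b"] == 1.0
        assert mat.annotation.loc["a", "b"] == ""

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValidationError):
            kruskal_wallis_matrix({"a": [1.0], "b": rng.normal(size=10)})

    def test_cross_layout(self, rng):
        rows = {"r1": rng.normal(0, 1, 30), "r2": rng.normal(0, 1, 30)}
        cols = {"c1": rng.normal(0, 1, 30), "c2": rng.normal(9, 1, 30), "c3": rng.normal(0, 1, 30)}
        mat = kruskal_wallis_matrix(rows, columns=cols)
        assert mat.values.shape == (2, 3)
        assert mat.values.loc["r1", "c2"] < 0.01


class TestKSMatrix:
    def test_identical_samples(self, rng):
        x = rng.normal(size=50)
        mat = ks_matrix({"a": x, "b": x.copy()})
        assert mat.values.loc["a", "b"] == pytest.approx(1.0)

    def test_disjoint_support_fully_separated(self):
        from scipy import stats

        a = np.linspace(0, 1, 100)
        b = np.linspace(10, 11, 100)
        assert stats.ks_2samp(a, b).statistic == 1.0
        mat = ks_matrix({"a": a, "b": b})
        assert mat.values.loc["a", "b"] < 0.01

    def test_type_one_error_rate_near_alpha(self):
        nonsig = 0
        for rep in range(100):
            rng = np.random.default_rng(3000 + rep)
            a = rng.gamma(2.0, 0.1, size=100)
            b = rng.gamma(2.0, 0.1, size=100)
            nonsig += ks_matrix({"a": a, "b": b}).values.loc["a", "b"] >= 0.05
        assert nonsig >= 90


class TestTTest:
    def test_identical_groups_p_one(self):
        x = np.arange(10.0)
        assert excursion_ttest(x, x.copy()) == pytest.approx(1.0)

    def test_large_separation(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(10, 1, 100)
        assert excursion_ttest(a, b) < 1e-10

    def test_symmetric_in_group_order(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 30)
        assert excursion_ttest(a, b) == pytest.approx(excursion_ttest(b, a))

    def test_zero_variance_both_unequal_means_rejected(self):
        with pytest.raises(ValidationError):
            excursion_ttest([1.0, 1.0], [2.0, 2.0])


class TestEffectSizes:
    def test_cohen_d_formula_and_label(self, rng):
        a = rng.normal(1, 2, size=200000)
        b = rng.normal(3, 2, size=200000)
        d = cohen_d(a, b)
        assert d == pytest.approx(1.0, abs=0.02)
        assert effect_magnitude(d) == "large"

    def test_cohen_d_exact_on_constructed_groups(self):
        # groups with exact means 1, 3 and exact sample SDs 2, 2
        a = np.array([-1.0, -1.0, 1.0, 3.0, 3.0])
        b = a + 2.0
        assert np.std(a, ddof=1) == pytest.approx(2.0, rel=1e-12)
        assert cohen_d(a, b) == pytest.approx(1.0)

    def test_cohen_d_zero_and_linear(self, rng):
        x = rng.normal(size=50)
        assert cohen_d(x, x.copy()) == pytest.approx(0.0)
        a = np.array([0.0, 2.0] * 10)
        assert cohen_d(a, a + 4.0) == pytest.approx(2 * cohen_d(a, a + 2.0))

    def test_glass_delta_uses_control_sd_only(self):
        control = np.array([0.0, 2.0] * 8)  # mean 1, sd ~1.03
        sd_c = np.std(control, ddof=1)
        treatment = np.array([3.0] * 5 + [3.0] * 5)
        delta = glass_delta(treatment, control)
        assert delta == pytest.approx(2.0 / sd_c)
        # inflating the treatment variance leaves Delta unchanged
        treatment2 = np.array([0.0, 6.0] * 5)
        assert glass_delta(treatment2, control) == pytest.approx(delta)

    def test_glass_delta_equal_means_zero(self, rng):
        x = rng.normal(size=40)
        assert glass_delta(x, x.copy()) == pytest.approx(0.0)

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValidationError):
            glass_delta([1.0, 2.0], [3.0, 3.0])

    @pytest.mark.parametrize(
        "value,label",
        [
            (0.005, "very small"),
            (0.1, "very small"),
            (0.3, "small"),
            (0.6, "medium"),
            (1.0, "large"),
            (1.5, "very large"),
            (2.5, "huge"),
            (-2.5, "huge"),
        ],
    )
    def test_magnitude_ladder(self, value, label):
        assert effect_magnitude(value) == label

    def test_effect_size_report_sign_convention(self, rng):
        control = rng.normal(0, 1, 100)
        treatment = rng.normal(2, 1, 100)
        rep = effect_size_report("cell", "linear_excursion", treatment, control)
        assert rep.cohen_d > 0  # treatment above control
        assert rep.glass_delta > 0
        assert rep.p_value < 1e-6
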