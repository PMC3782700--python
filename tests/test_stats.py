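"""Group statistics: paired t, Cohen's d, mixed ANOVA, simple main effects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from actionprior import cohens_d, mixed_anova, paired_t, simple_main_effects


def oracle_mixed_ss(values, group):
    """Brute-force sums of squares from marginal means (independent coding)."""
    values = np.asarray(values, float)
    labels = np.unique(group)
    n, b = values.shape
    grand = values.mean()
    ss = {}
    ss["A"] = sum(
        b * (group == g).sum() * (values[group == g].mean() - grand) ** 2 for g in labels
    )
    ss["subj"] = b * sum((values[i].mean() - grand) ** 2 for i in range(n)) - ss["A"]
    ss["B"] = sum(n * (values[:, j].mean() - grand) ** 2 for j in range(b))
    ss["AB"] = sum(
        (group == g).sum()
        * (
            values[group == g][:, j].mean()
            - values[group == g].mean()
            - values[:, j].mean()
            + grand
        )
        ** 2
        for g in labels
        for j in range(b)
    )
    ss["err"] = (
        sum((values[i, j] - values[i].mean()) ** 2 for i in range(n) for j in range(b))
        - ss["B"]
        - ss["AB"]
    )
    a = labels.size
    df = {"A": a - 1, "subj": n - a, "B": b - 1, "AB": (a - 1) * (b - 1),
          "err": (n - a) * (b - 1)}
    F = {
        "A": (ss["A"] / df["A"]) / (ss["subj"] / df["subj"]),
        "B": (ss["B"] / df["B"]) / (ss["err"] / df["err"]),
        "AB": (ss["AB"] / df["AB"]) / (ss["err"] / df["err"]),
    }
    return ss, F


def random_balanced_design(rng, n_per_group=None, b=2):
    n_per_group = n_per_group or int(rng.integers(3, 12))
    values = rng.normal(size=(2 * n_per_group, b)) + rng.normal(size=(1, b))
    group = np.repeat(["g1", "g2"], n_per_group)
    return values, group


class TestPairedT:
    def test_identical_samples_raise_zero_variance(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_gives_zero_variance_error(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [0.0, 1.0])

    def test_hand_computed_example(self):
        res = paired_t([1, 2, 4], [0, 1, 1])
        assert res.t == pytest.approx(2.5)
        assert res.df == 2

    def test_antisymmetric_in_arguments(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert paired_t(x, y).t == pytest.approx(-paired_t(y, x).t)

    def test_type_one_error_calibrated_under_null(self):
        # 2000 replicate null "cohorts" of 10 paired observations
        rng = np.random.default_rng(2024)
        rejections = sum(
            paired_t(rng.normal(size=10), rng.normal(size=10)).p < 0.05
            for _ in range(2000)
        )
        se = np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rejections / 2000 - 0.05) < 3 * se


class TestCohensD:
    def test_equal_samples_give_zero(self):
        d, _ = cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_pooled_hand_computation(self):
        d, method = cohens_d([2, 4], [1, 3], "pooled")
        assert d == pytest.approx(1 / np.sqrt(2))
        assert method == "pooled"

    def test_diff_method_uses_difference_sd(self):
        x, y = [1.0, 2.0, 4.0], [0.0, 1.0, 1.0]
        d, _ = cohens_d(x, y, "diff")
        diffs = np.array(x) - np.array(y)
        assert d == pytest.approx(diffs.mean() / diffs.std(ddof=1))

    def test_scale_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        d0, _ = cohens_d(x, y)
        d1, _ = cohens_d(3.7 * x, 3.7 * y)
        assert d0 == pytest.approx(d1)

    def test_diff_exceeds_pooled_for_correlated_samples(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(scale=0.2, size=20) - 0.5
        assert abs(cohens_d(x, y, "diff")[0]) > abs(cohens_d(x, y, "pooled")[0])


class TestMixedAnova:
    def test_matches_brute_force_oracle_on_random_designs(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            values, group = random_balanced_design(rng)
            res = mixed_anova(values, group)
            _, F = oracle_mixed_ss(values, group)
            assert res.between.F == pytest.approx(F["A"], rel=1e-10)
            assert res.within.F == pytest.approx(F["B"], rel=1e-10)
            assert res.interaction.F == pytest.approx(F["AB"], rel=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        values, group = random_balanced_design(rng, n_per_group=10)
        res = mixed_anova(values, group)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 2),
                "group": np.repeat(group, 2),
                "within": np.tile(["w1", "w2"], 20),
                "value": values.ravel(),
            }
        )
        ref = pg.mixed_anova(
            data=long, dv="value", within="within", between="group", subject="subject"
        ).set_index("Source")
        assert res.between.F == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.within.F == pytest.approx(ref.loc["within", "F"], rel=1e-6)
        assert res.interaction.F == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-100.0, 100.0))
    def test_location_invariance(self, shift):
        rng = np.random.default_rng(3)
        values, group = random_balanced_design(rng, n_per_group=5)
        base = mixed_anova(values, group)
        moved = mixed_anova(values + shift, group)
        assert base.between.F == pytest.approx(moved.between.F, rel=1e-6, abs=1e-9)
        assert base.within.F == pytest.approx(moved.within.F, rel=1e-6, abs=1e-9)
        assert base.interaction.F == pytest.approx(moved.interaction.F, rel=1e-6, abs=1e-9)

    def test_all_equal_values_flagged_degenerate(self):
        values = np.full((6, 2), 3.14)
        group = np.repeat(["a", "b"], 3)
        res = mixed_anova(values, group)
        assert res.between.degenerate and res.within.degenerate

    def test_unbalanced_within_rejected(self):
        values = np.array([[1.0, np.nan], [2.0, 1.0], [0.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="unbalanced"):
            mixed_anova(values, np.repeat(["a", "b"], 2))

    def test_single_subject_group_rejected(self):
        values = np.zeros((3, 2))
        with pytest.raises(ValueError, match="2 subjects"):
            mixed_anova(values, np.array(["a", "a", "b"]))


class TestSimpleMainEffects:
    def test_data_with_flattened_cell_means_give_zero_f(self):
        # remove every cell mean: no main effects, no interaction, noise remains
        rng = np.random.default_rng(1)
        values = rng.normal(size=(8, 2))
        group = np.repeat(["a", "b"], 4)
        for g in ("a", "b"):
            values[group == g] -= values[group == g].mean(axis=0)
        for factor in ("within", "between"):
            for row in simple_main_effects(values, group, factor):
                assert row.F == pytest.approx(0.0, abs=1e-12)

    def test_slice_f_matches_brute_force_slice_oracle(self):
        rng = np.random.default_rng(42)
        values, group = random_balanced_design(rng, n_per_group=10)
        ss, _ = oracle_mixed_ss(values, group)
        rows = simple_main_effects(values, group, "within")
        for g, row in zip(np.unique(group), rows):
            sub = values[group == g]
            ss_slice = len(sub) * np.sum((sub.mean(axis=0) - sub.mean()) ** 2)
            f_expected = ss_slice / (ss["err"] / 18)
            assert row.F == pytest.approx(f_expected, rel=1e-10)
            assert row.df_den == 18

    @pytest.mark.parametrize("factor", ["within", "between"])
    def test_slices_pool_to_main_plus_interaction(self, factor):
        rng = np.random.default_rng(8)
        values, group = random_balanced_design(rng, n_per_group=6)
        ss, _ = oracle_mixed_ss(values, group)
        rows = simple_main_effects(values, group, factor)
        total = sum(r.ss for r in rows)
        main = ss["B"] if factor == "within" else ss["A"]
        assert total == pytest.approx(main + ss["AB"], rel=1e-10)

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            simple_main_effects(np.zeros((4, 2)) + np.arange(4)[:, None],
                                np.repeat(["a", "b"], 2), "diagonal")
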