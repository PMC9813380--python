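"""Factorial statistics: ANOVA decomposition, effect sizes, post-hoc, PAM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import semgmap as sm
from semgmap.exceptions import ValidationError
from semgmap.stats import classify_eta, kmedoids_elbow, tukey_kramer, two_way_anova


def balanced_design(rng, a_levels=3, b_levels=4, reps=5, effects=None):
    rows = []
    effects = effects or {}
    for a in range(a_levels):
        for b in range(b_levels):
            mean = effects.get("a", 0) * a + effects.get("b", 0) * b
            mean += effects.get("ab", 0) * a * b
            for _ in range(reps):
                rows.append(
                    {"window_ms": a, "overlap_pct": b, "y": mean + rng.normal()}
                )
    return pd.DataFrame(rows)


def anova_oracle(df):
    """Textbook balanced two-way sums of squares by direct summation."""
    y = df["y"].to_numpy()
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    a_means = df.groupby("window_ms")["y"].mean()
    b_means = df.groupby("overlap_pct")["y"].mean()
    cell_means = df.groupby(["window_ms", "overlap_pct"])["y"].mean()
    n = len(df)
    n_a = df["window_ms"].nunique()
    n_b = df["overlap_pct"].nunique()
    reps = n // (n_a * n_b)
    ss_a = reps * n_b * ((a_means - grand) ** 2).sum()
    ss_b = reps * n_a * ((b_means - grand) ** 2).sum()
    ss_cells = reps * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_res = ss_total - ss_cells
    return ss_a, ss_b, ss_ab, ss_res, ss_total


class TestTwoWayAnova:
    def test_matches_direct_sums_oracle(self, rng):
        df = balanced_design(rng, effects={"a": 0.5, "b": 0.3, "ab": 0.1})
        res = two_way_anova(df, "y")
        ss_a, ss_b, ss_ab, ss_res, ss_total = anova_oracle(df)
        assert res.effects["window_ms"].ss == pytest.approx(ss_a, abs=1e-9)
        assert res.effects["overlap_pct"].ss == pytest.approx(ss_b, abs=1e-9)
        assert res.effects["interaction"].ss == pytest.approx(ss_ab, abs=1e-9)
        assert res.effects["residual"].ss == pytest.approx(ss_res, abs=1e-9)
        # F against the standard ratio of mean squares
        ms_res = ss_res / res.effects["residual"].df
        f_a = (ss_a / res.effects["window_ms"].df) / ms_res
        assert res.effects["window_ms"].F == pytest.approx(f_a, rel=1e-9)

    def test_ss_decomposition_exact(self, rng):
        # unbalanced: replicate counts differ per cell, as map counts do
        rows = []
        for a in range(3):
            for b in range(4):
                for _ in range(3 + 2 * b):
                    rows.append({"window_ms": a, "overlap_pct": b, "y": rng.normal()})
        df = pd.DataFrame(rows)
        res = two_way_anova(df, "y")
        total = sum(e.ss for e in res.effects.values())
        assert total == pytest.approx(res.ss_total, rel=1e-9)
        eta_sum = sum(
            e.eta_sq for n, e in res.effects.items() if n != "residual"
        )
        assert eta_sum == pytest.approx(
            1 - res.effects["residual"].ss / res.ss_total, rel=1e-12
        )
        assert eta_sum <= 1

    def test_constant_response_zero_eta(self, rng):
        df = balanced_design(rng)
        df["y"] = 7.0
        res = two_way_anova(df, "y")
        assert all(
            e.eta_sq == 0 for n, e in res.effects.items() if n != "residual"
        )

    def test_additive_response_no_interaction(self):
        rows = [
            {"window_ms": a, "overlap_pct": b, "y": 2.0 * a + 3.0 * b}
            for a in range(3)
            for b in range(4)
            for _ in range(2)
        ]
        res = two_way_anova(pd.DataFrame(rows), "y")
        assert res.effects["interaction"].ss == pytest.approx(0.0, abs=1e-9)

    def test_empty_cell_named(self, rng):
        df = balanced_design(rng)
        df = df[~((df.window_ms == 1) & (df.overlap_pct == 2))]
        with pytest.raises(ValidationError, match=r"\(1, 2\)"):
            two_way_anova(df, "y")

    def test_single_level_factor_rejected(self, rng):
        df = balanced_design(rng, a_levels=1)
        with pytest.raises(ValidationError):
            two_way_anova(df, "y")


class TestClassifyEta:
    @pytest.mark.parametrize(
        "eta,label",
        [(0.998, "large"), (0.03, "small"), (0.5, "medium"), (0.04, "medium"),
         (0.64, "medium"), (0.641, "large"), (0.039, "small")],
    )
    def test_boundaries(self, eta, label):
        assert classify_eta(eta) == label

    @pytest.mark.parametrize("eta", [-0.1, 1.1])
    def test_out_of_range_rejected(self, eta):
        with pytest.raises(ValidationError):
            classify_eta(eta)


class TestTukeyKramer:
    def test_two_groups_reduce_to_t_statistic(self, rng):
        x = rng.normal(size=30)
        g = np.repeat(["a", "b"], 15)
        table = tukey_kramer(x, g)
        t, _ = sps.ttest_ind(x[g == "a"], x[g == "b"])
        assert table["q"].iloc[0] ** 2 == pytest.approx(2 * t**2, rel=1e-9)

    def test_matches_statsmodels_hsd(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        x = rng.normal(size=60) + np.repeat([0.0, 0.5, 2.0], 20)
        g = np.repeat(["a", "b", "c"], 20)
        ours = tukey_kramer(x, g)
        ref = pairwise_tukeyhsd(x, g)
        np.testing.assert_allclose(
            ours["p_adj"].to_numpy(), ref.pvalues, atol=1e-6
        )

    def test_separated_means_detected(self, rng):
        x = np.concatenate(
            [rng.normal(0, 0.01, 10), rng.normal(0, 0.01, 10), rng.normal(10, 0.01, 10)]
        )
        g = np.repeat(["l1", "l2", "l3"], 10)
        table = tukey_kramer(x, g).set_index(["level_a", "level_b"])
        assert table.loc[("l1", "l3"), "reject"]
        assert table.loc[("l2", "l3"), "reject"]
        assert not table.loc[("l1", "l2"), "reject"]

    def test_single_level_empty_table(self, rng):
        table = tukey_kramer(rng.normal(size=10), np.repeat("a", 10))
        assert table.empty

    def test_null_familywise_error_near_alpha(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=40)
            g = np.repeat(["a", "b", "c", "d"], 10)
            rejections += tukey_kramer(x, g)["reject"].any()
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


class TestKMedoids:
    def test_three_separated_blobs(self, rng):
        x = np.concatenate(
            [rng.normal(0, 0.05, 20), rng.normal(100, 0.05, 20), rng.normal(200, 0.05, 20)]
        )
        res = kmedoids_elbow(x, k_max=5, seed=0)
        assert res.k == 3
        groups = [set(np.flatnonzero(res.assignments == j)) for j in range(3)]
        expected = [set(range(0, 20)), set(range(20, 40)), set(range(40, 60))]
        assert sorted(map(sorted, groups)) == sorted(map(sorted, expected))

    def test_k1_medoid_matches_exhaustive_search(self, rng):
        x = rng.normal(size=(25, 2))
        res = kmedoids_elbow(x, k_max=1, seed=0)
        dists = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)).sum(1)
        assert res.medoid_indices[0] == int(np.argmin(dists))

    def test_identical_points_one_cluster(self):
        res = kmedoids_elbow(np.ones(20), k_max=5, seed=0)
        assert res.k == 1
        assert np.allclose(res.criterion_curve, res.criterion_curve[0])

    def test_within_distance_non_increasing_in_k(self, rng):
        x = rng.normal(size=40)
        res = kmedoids_elbow(x, k_max=6, seed=0)
        curve = res.criterion_curve
        assert np.all(np.diff(curve) <= 1e-12)

    def test_k_max_bound_enforced(self, rng):
        with pytest.raises(ValidationError):
            kmedoids_elbow(rng.normal(size=5), k_max=5, seed=0)

    def test_medoids_are_observations(self, rng):
        x = rng.normal(size=(30, 3))
        res = kmedoids_elbow(x, k_max=4, seed=0)
        for m in res.medoids:
            assert any(np.array_equal(m, row) for row in x)
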