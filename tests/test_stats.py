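"""Rank-sum and ANOVA implementations against independent oracles."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from shrimpglass.stats import fit_status_model, run_cleaner_contrasts, wilcoxon_exact
from shrimpglass.synthetic_data import synth_reflectance_dataset


def brute_force_wilcoxon_p(x, y):
    """Independent enumeration oracle: exact two-sided p as a Fraction.

    Ranks are midranks computed from scratch; the null enumerates every
    C(n+m, n) assignment of pooled values to the first group.
    """
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    sorted_vals = sorted(pooled)
    ranks = []
    for v in pooled:
        positions = [i + 1 for i, s in enumerate(sorted_vals) if s == v]
        ranks.append(sum(positions) / len(positions))
    w_obs = sum(ranks[:n])
    le = ge = 0
    total = comb(n + m, n)
    for idx in combinations(range(n + m), n):
        w = sum(ranks[i] for i in idx)
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    return min(Fraction(1), 2 * Fraction(min(le, ge), total))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        res = wilcoxon_exact([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0
        assert res.method == "exact"

    def test_complete_separation_three_vs_two(self):
        res = wilcoxon_exact([1, 2, 3], [4, 5])
        assert res.p_value == pytest.approx(2 / comb(5, 2), rel=1e-12)  # 0.2

    def test_complete_separation_eight_vs_six(self):
        res = wilcoxon_exact(np.arange(1, 9), np.arange(9, 15))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 3003, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_exact([], [1.0])

    def test_two_sided_p_symmetric_under_swap(self, rng):
        for _ in range(20):
            x = rng.integers(0, 6, size=int(rng.integers(2, 6))).astype(float)
            y = rng.integers(0, 6, size=int(rng.integers(2, 6))).astype(float)
            assert wilcoxon_exact(x, y).p_value == pytest.approx(
                wilcoxon_exact(y, x).p_value, rel=1e-12
            )

    def test_matches_enumeration_oracle_small_samples_with_ties(self, rng):
        """Every n+m <= 12, random integer data (ties common)."""
        for n in range(1, 11):
            for m in range(1, 12 - n + 1):
                for rep in range(2):
                    x = rng.integers(0, 5, size=n).astype(float)
                    y = rng.integers(0, 5, size=m).astype(float)
                    res = wilcoxon_exact(x, y)
                    assert res.method == "exact"
                    oracle = brute_force_wilcoxon_p(x, y)
                    assert res.p_value == pytest.approx(float(oracle), rel=1e-9), (x, y)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=5)
            ours = wilcoxon_exact(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        ours = wilcoxon_exact(x, y)
        assert ours.method == "normal-approximation"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def closed_form_oneway_f(groups):
    """Independent closed-form one-way ANOVA."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    k = len(groups)
    n = len(all_vals)
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, sps.f.sf(f, k - 1, n - k)


def _frame(groups):
    rows = []
    for label, vals in groups.items():
        for v in vals:
            rows.append({"status": label, "reflectance": v})
    return pd.DataFrame(rows)


class TestStatusModel:
    def test_two_groups_hand_computed_f(self):
        res = fit_status_model(_frame({"a": [1.0, 2.0], "b": [3.0, 4.0]}))
        assert res.f_statistic == pytest.approx(8.0, rel=1e-12)
        assert res.df == (1, 2)

    def test_equal_group_means_give_f_zero(self):
        res = fit_status_model(_frame({"a": [1.0, 3.0], "b": [2.0, 2.0]}))
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_on_random_data(self, rng):
        for _ in range(20):
            groups = {
                f"g{i}": rng.normal(loc=rng.uniform(0, 1), size=int(rng.integers(2, 6)))
                for i in range(int(rng.integers(2, 5)))
            }
            res = fit_status_model(_frame(groups))
            f_ref, p_ref = closed_form_oneway_f(list(groups.values()))
            assert res.f_statistic == pytest.approx(f_ref, abs=1e-10, rel=1e-10)
            assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_matches_statsmodels_model_comparison(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = _frame({
            "a": rng.normal(0.4, 0.05, 3), "b": rng.normal(0.5, 0.05, 3),
            "c": rng.normal(0.3, 0.05, 2),
        })
        res = fit_status_model(df)
        full = smf.ols("reflectance ~ C(status)", data=df).fit()
        null = smf.ols("reflectance ~ 1", data=df).fit()
        table = sm.stats.anova_lm(null, full)
        assert res.f_statistic == pytest.approx(table["F"].iloc[1], rel=1e-9)
        assert res.p_value == pytest.approx(table["Pr(>F)"].iloc[1], rel=1e-9)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            fit_status_model(_frame({"a": [1.0, 2.0]}))

    def test_constant_groups_handled(self):
        # degenerate: both groups constant and equal
        res = fit_status_model(_frame({"a": [0.5, 0.5], "b": [0.5, 0.5]}))
        assert res.p_value == pytest.approx(1.0)


class TestCleanerContrasts:
    def test_four_contrasts_on_synthetic_dataset(self):
        df = synth_reflectance_dataset(seed=0)
        res = run_cleaner_contrasts(df)
        assert set(res) == {
            "status_wilcoxon", "status_model",
            "ultrastructure_wilcoxon", "ultrastructure_model",
        }
        # published group separation is large: obligate > non-obligate
        assert res["status_wilcoxon"].method == "exact"
        assert res["status_wilcoxon"].p_value < 0.05
        assert res["status_wilcoxon"].n == 8 and res["status_wilcoxon"].m == 6
        assert res["ultrastructure_wilcoxon"].n == 8 and res["ultrastructure_wilcoxon"].m == 3

    def test_missing_species_listed(self):
        df = synth_reflectance_dataset(seed=0)
        df = df[df["species"] != "Lysmata boggessi"]
        with pytest.raises(ValueError, match="Lysmata boggessi"):
            run_cleaner_contrasts(df)

    def test_shuffled_labels_control_type_one_error(self, rng):
        """Permuting individuals across species yields non-extreme p most of the time."""
        df = synth_reflectance_dataset(seed=1)
        indiv = df.groupby("individual").agg(
            {"reflectance": "mean", "species": "first"}).reset_index()
        hits = 0
        n_perm = 200
        vals = indiv["reflectance"].to_numpy()
        obligate_n = 8
        for _ in range(n_perm):
            perm = rng.permutation(len(vals))
            p = wilcoxon_exact(vals[perm[:obligate_n]], vals[perm[obligate_n:]]).p_value
            hits += p < 0.05
        assert hits / n_perm < 0.12  # ~5% nominal, Monte-Carlo slack

    def test_degenerate_equal_groups_handled(self):
        df = synth_reflectance_dataset(
            species_params={k: {"mean": 0.5, "sd": 0.0, "n": 3}
                            for k in synth_reflectance_dataset(seed=0)["species"].unique()},
            seed=0,
        )
        res = run_cleaner_contrasts(df)
        assert res["status_wilcoxon"].p_value == 1.0
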