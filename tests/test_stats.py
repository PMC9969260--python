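"""Permutation ANOVA, post hoc tests and cohort-comparison utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from leidyn.stats import (
    AnovaSpec,
    bh_fdr,
    chi_square_2x2,
    group_mean_impute,
    impute_metric_cells,
    ks_two_sample,
    mixed_anova_F,
    paired_perm_ttest,
    pairwise_perm_ttests,
    perm_rm_anova,
    pooled_t_from_summaries,
    unpaired_perm_ttest,
)

# fixed 2 groups x 3 subjects x 2 conditions fixture (values enumerated)
FIXTURE = pd.DataFrame(
    [
        ("s1", "A", "event", 4.2), ("s1", "A", "rest", 3.1),
        ("s2", "A", "event", 5.0), ("s2", "A", "rest", 3.9),
        ("s3", "A", "event", 4.7), ("s3", "A", "rest", 4.1),
        ("s4", "B", "event", 6.3), ("s4", "B", "rest", 4.4),
        ("s5", "B", "event", 5.9), ("s5", "B", "rest", 5.1),
        ("s6", "B", "event", 6.8), ("s6", "B", "rest", 4.9),
    ],
    columns=["subject_id", "group", "condition", "value"],
)


def _oracle_mixed_anova(df):
    """From-scratch textbook sums-of-squares for one between x one within."""
    groups = sorted(df["group"].unique())
    conds = sorted(df["condition"].unique())
    subjects = sorted(df["subject_id"].unique())
    y = {(r.subject_id, r.condition): r.value for r in df.itertuples()}
    gof = {s: df[df.subject_id == s]["group"].iloc[0] for s in subjects}
    b = len(conds)
    N = len(subjects)
    G = len(groups)
    grand = np.mean(list(y.values()))
    subj_mean = {s: np.mean([y[s, c] for c in conds]) for s in subjects}
    grp_mean = {
        g: np.mean([y[s, c] for s in subjects if gof[s] == g for c in conds])
        for g in groups
    }
    cond_mean = {c: np.mean([y[s, c] for s in subjects]) for c in conds}
    cell_mean = {
        (g, c): np.mean([y[s, c] for s in subjects if gof[s] == g])
        for g in groups
        for c in conds
    }
    n_g = {g: sum(1 for s in subjects if gof[s] == g) for g in groups}
    ss_total = sum((y[s, c] - grand) ** 2 for s in subjects for c in conds)
    ss_between_subj = b * sum((subj_mean[s] - grand) ** 2 for s in subjects)
    ss_A = b * sum(n_g[g] * (grp_mean[g] - grand) ** 2 for g in groups)
    ss_SA = ss_between_subj - ss_A
    ss_B = N * sum((cond_mean[c] - grand) ** 2 for c in conds)
    ss_AB = sum(
        n_g[g] * (cell_mean[g, c] - grp_mean[g] - cond_mean[c] + grand) ** 2
        for g in groups
        for c in conds
    )
    ss_err = ss_total - ss_between_subj - ss_B - ss_AB
    return {
        "group": (ss_A / (G - 1)) / (ss_SA / (N - G)),
        "condition": (ss_B / (b - 1)) / (ss_err / ((N - G) * (b - 1))),
        "group:condition": (ss_AB / ((G - 1) * (b - 1))) / (ss_err / ((N - G) * (b - 1))),
    }


class TestMixedAnova:
    def test_observed_F_matches_sums_of_squares_oracle(self):
        res = {r.effect: r for r in mixed_anova_F(FIXTURE, AnovaSpec(within=("condition",)))}
        oracle = _oracle_mixed_anova(FIXTURE)
        for eff, f_expected in oracle.items():
            assert res[eff].F == pytest.approx(f_expected, abs=1e-10)
        assert res["group"].df_num == 1 and res["group"].df_den == 4
        assert res["condition"].df_den == 4

    def test_two_within_factor_dfs(self, rng):
        rows = [
            (f"s{i}", "A" if i < 4 else "B", c, s, rng.normal())
            for i in range(8)
            for c in ("e", "r")
            for s in (1, 2, 3)
        ]
        df = pd.DataFrame(rows, columns=["subject_id", "group", "condition", "state", "value"])
        res = {r.effect: r for r in mixed_anova_F(df, AnovaSpec())}
        assert res["state"].df_num == 2 and res["state"].df_den == 12
        assert res["group:condition:state"].df_num == 2
        assert set(res) == {
            "group", "condition", "group:condition", "state", "group:state",
            "condition:state", "group:condition:state",
        }

    def test_incomplete_cells_raise(self):
        df = FIXTURE.iloc[:-1]
        with pytest.raises(ValueError, match="incomplete cells"):
            mixed_anova_F(df, AnovaSpec(within=("condition",)))


class TestPermRmAnova:
    def test_p_values_bounded_below_and_F_seed_invariant(self):
        spec1 = AnovaSpec(within=("condition",), n_perm=99, seed=1)
        spec2 = AnovaSpec(within=("condition",), n_perm=99, seed=2)
        r1 = {r.effect: r for r in perm_rm_anova(FIXTURE, spec1)}
        r2 = {r.effect: r for r in perm_rm_anova(FIXTURE, spec2)}
        for eff in r1:
            assert r1[eff].p_perm >= 1 / 100
            assert r1[eff].F == pytest.approx(r2[eff].F)  # F independent of seed

    def test_planted_group_effect_detected(self, rng):
        rows = []
        for i in range(16):
            g = "A" if i < 8 else "B"
            shift = 0.0 if g == "A" else 3.0  # 3 pooled SDs
            for c in ("e", "r"):
                rows.append((f"s{i}", g, c, rng.normal() + shift))
        df = pd.DataFrame(rows, columns=["subject_id", "group", "condition", "value"])
        res = {r.effect: r for r in perm_rm_anova(df, AnovaSpec(within=("condition",), n_perm=999, seed=0))}
        assert res["group"].p_perm <= 0.01

    def test_null_type_one_error_is_controlled(self, rng):
        rejections = 0
        n_rep = 120
        for rep in range(n_rep):
            rows = [
                (f"s{i}", "A" if i < 5 else "B", c, rng.normal())
                for i in range(10)
                for c in ("e", "r")
            ]
            df = pd.DataFrame(rows, columns=["subject_id", "group", "condition", "value"])
            res = perm_rm_anova(df, AnovaSpec(within=("condition",), n_perm=99, seed=rep))
            rejections += sum(r.p_perm <= 0.05 for r in res if r.effect == "condition")
        lo, hi = sstats.binom.interval(0.999, n_rep, 0.05)
        assert lo <= rejections <= hi


class TestPairwisePermT:
    def test_identical_paired_samples(self):
        t, p = paired_perm_ttest(np.ones(6), np.ones(6))
        assert t == 0.0 and p == 1.0

    def test_paired_t_matches_closed_form(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        t, _ = paired_perm_ttest(x, y, n_perm=10)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        assert t == pytest.approx(t_oracle, abs=1e-10)

    def test_sign_permutation_matches_exact_enumeration(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        _, p = paired_perm_ttest(x, y, n_perm=2**6)
        d = x - y
        t_obs = abs(d.mean() / (d.std(ddof=1) / np.sqrt(6)))
        count = 0
        for signs in itertools.product((1, -1), repeat=6):
            ds = d * np.array(signs)
            count += abs(ds.mean() / (ds.std(ddof=1) / np.sqrt(6))) >= t_obs - 1e-12
        assert p == pytest.approx(count / 2**6)

    def test_unpaired_detects_separation(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(5, 1, 10)
        t, p = unpaired_perm_ttest(x, y, n_perm=499, seed=0)
        assert p <= 0.01 and t < 0

    def test_family_interface_with_fdr(self, rng):
        rows = []
        for i in range(8):
            g = "A" if i < 4 else "B"
            for c in ("e", "r"):
                rows.append((f"s{i}", g, c, rng.normal() + (1.0 if c == "e" else 0)))
        df = pd.DataFrame(rows, columns=["subject_id", "group", "condition", "value"])
        out = pairwise_perm_ttests(
            df,
            [
                ({"condition": "e"}, {"condition": "r"}),
                ({"group": "A", "condition": "e"}, {"group": "B", "condition": "e"}),
            ],
            n_perm=199,
            seed=0,
        )
        assert len(out) == 2
        assert out["paired"].tolist() == [True, False]
        assert (out["p_fdr"] >= out["p_perm"] - 1e-12).all()


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_stepup_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_statsmodels_and_monotone(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=25)
        adj = bh_fdr(p)
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, adj_sm, atol=1e-12)
        assert (adj >= p - 1e-15).all()
        # rejections nested across alpha levels
        assert set(np.flatnonzero(adj <= 0.01)) <= set(np.flatnonzero(adj <= 0.05))

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestChiSquare:
    def test_sex_table_reproduces_published_value(self):
        stat, dof = chi_square_2x2([[4, 17], [7, 14]], yates=True)
        assert stat == pytest.approx(0.49267, abs=5e-6)
        assert dof == 1

    def test_handedness_table_is_zero(self):
        stat, _ = chi_square_2x2([[14, 7], [13, 8]], yates=True)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_table_zero_either_way(self):
        for yates in (True, False):
            stat, _ = chi_square_2x2([[5, 9], [5, 9]], yates=yates)
            assert stat == pytest.approx(0.0, abs=1e-12)

    def test_uncorrected_matches_identity_oracle(self, rng):
        obs = rng.integers(3, 30, size=(2, 2)).astype(float)
        stat, _ = chi_square_2x2(obs, yates=False)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        oracle = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle, abs=1e-10)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [3, 4]])


class TestPooledT:
    def test_published_age_comparison(self):
        t, df = pooled_t_from_summaries(46.524, 11.622, 21, 39.952, 11.320, 21)
        assert t == pytest.approx(1.856, abs=1e-3)
        assert df == 40

    def test_equal_means_zero(self):
        t, _ = pooled_t_from_summaries(5, 1.0, 10, 5, 2.0, 12)
        assert t == 0.0

    def test_matches_raw_data_oracle(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.4, 1.3, 12)
        t, df = pooled_t_from_summaries(
            x.mean(), x.std(ddof=1), 15, y.mean(), y.std(ddof=1), 12
        )
        t_oracle, _ = sstats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(t_oracle, abs=1e-10) and df == 25

    def test_degenerate_flagged(self):
        t, _ = pooled_t_from_summaries(3, 0, 5, 3, 0, 5)
        assert np.isnan(t)


class TestKs:
    def test_identical_samples_zero(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3]) == 0.0

    def test_fully_separated_one(self):
        assert ks_two_sample([1, 2], [10, 11]) == 1.0

    def test_interleaved_matches_ecdf_grid_oracle(self):
        x, y = np.array([1.0, 3.0]), np.array([2.0, 4.0])
        grid = np.sort(np.concatenate([x, y]))
        d_oracle = max(
            abs((x <= g).mean() - (y <= g).mean()) for g in grid
        )
        assert ks_two_sample(x, y) == pytest.approx(d_oracle) == 0.5


class TestImputation:
    def test_no_missing_identity(self):
        v, log = group_mean_impute([1.0, 2.0], ["a", "a"])
        assert v.tolist() == [1.0, 2.0] and log == []

    def test_group_mean_fill(self):
        v, log = group_mean_impute([10.0, np.nan, 20.0, 5.0], ["A", "A", "A", "B"])
        assert v[1] == 15.0 and log == [1]
        assert v[0] == 10.0 and v[2] == 20.0

    def test_fully_missing_group_raises(self):
        with pytest.raises(ValueError, match="no observed"):
            group_mean_impute([np.nan, 1.0], ["A", "B"])

    def test_cell_mean_imputation_for_anova(self):
        df = pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3"],
                "group": ["A", "A", "A"],
                "condition": ["e"] * 3,
                "state": [1] * 3,
                "value": [2.0, np.nan, 4.0],
            }
        )
        out, n = impute_metric_cells(df)
        assert n == 1 and out["value"].tolist() == [2.0, 3.0, 4.0]
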