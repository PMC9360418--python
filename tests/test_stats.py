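import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n1dev import simulate as sim
from n1dev import stats as ST


def balanced_table(rng, n_sub=12, effects=None, subj_sd=1.0, noise_sd=1.0,
                   conditions=("DIG", "LET", "FF"), hemispheres=("LOT", "ROT")):
    effects = effects or {"DIG": -8.0, "LET": -7.0, "FF": -6.0}
    rows = []
    for i in range(n_sub):
        b = rng.normal(scale=subj_sd) if subj_sd else 0.0
        for c in conditions:
            for h in hemispheres:
                rows.append(
                    {"subject": f"s{i:02d}", "condition": c, "hemisphere": h,
                     "n1_mean_amplitude": effects[c] + b
                     + (rng.normal(scale=noise_sd) if noise_sd else 0.0)}
                )
    return pd.DataFrame(rows)


def rm_anova_oracle(table, factors):
    """Classical balanced within-subject ANOVA with a single error stratum.

    Computes F per fixed term from cell means; residual SS is what remains
    after the subject effect and all fixed terms.
    """
    y = table["n1_mean_amplitude"].to_numpy()
    n = len(y)
    gm = y.mean()
    ss_total = ((y - gm) ** 2).sum()
    subj_means = table.groupby("subject")["n1_mean_amplitude"].transform("mean")
    n_sub = table["subject"].nunique()
    ss_sub = ((subj_means - gm) ** 2).sum()

    ss_terms, df_terms = {}, {}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            cell = table.groupby(list(combo))["n1_mean_amplitude"].transform("mean")
            ss = ((cell - gm) ** 2).sum()
            df = 1
            for f in combo:
                df *= table[f].nunique() - 1
            # subtract lower-order terms contained in this margin
            for rr in range(1, r):
                for sub in itertools.combinations(combo, rr):
                    ss -= ss_terms[sub]
            ss_terms[combo] = ss
            df_terms[combo] = df
    ss_model = sum(ss_terms.values())
    df_model = sum(df_terms.values())
    ss_err = ss_total - ss_sub - ss_model
    df_err = n - n_sub - df_model
    out = {}
    for combo in ss_terms:
        out[combo] = (ss_terms[combo] / df_terms[combo]) / (ss_err / df_err), df_terms[combo], df_err
    return out


class TestLmmFit:
    def test_noiseless_data_recovers_injected_effects_exactly(self):
        rng = np.random.default_rng(0)
        effects = {"DIG": -8.0, "LET": -7.0, "FF": -6.0}
        table = balanced_table(rng, n_sub=8, effects=effects, subj_sd=0.0, noise_sd=0.0)
        # break exact singularity with a representable perturbation
        table["n1_mean_amplitude"] += rng.normal(scale=1e-7, size=len(table))
        lmm = ST.fit_lmm(table, ST.LmmSpec(factors=("hemisphere", "condition")))
        con = ST.posthoc_contrasts(lmm, pairs=(("DIG", "FF"), ("DIG", "LET")), by="timepoint")
        est = dict(zip(con["contrast"], con["estimate"]))
        assert est["DIG-FF"] == pytest.approx(-2.0, abs=1e-5)
        assert est["DIG-LET"] == pytest.approx(-1.0, abs=1e-5)

    def test_balanced_f_tests_match_rm_anova_oracle(self):
        rng = np.random.default_rng(42)
        table = balanced_table(rng, n_sub=14)
        lmm = ST.fit_lmm(table, ST.LmmSpec(factors=("hemisphere", "condition")))
        oracle = rm_anova_oracle(table, ["hemisphere", "condition"])
        got = {row["term"]: row for _, row in lmm.initial.anova.iterrows()}
        key_map = {
            ("hemisphere",): "C(hemisphere)",
            ("condition",): "C(condition)",
            ("hemisphere", "condition"): "C(hemisphere):C(condition)",
        }
        for combo, (f_oracle, df1, df2) in oracle.items():
            row = got[key_map[combo]]
            assert row["F"] == pytest.approx(f_oracle, rel=1e-4)
            assert row["df_num"] == df1
            assert row["df_den"] == df2

    def test_gross_outlier_is_excluded_alone(self):
        """+50 μV on one record trips the +/-3 normalized-residual rule and
        nothing else does (noise bounded below 2.5 sigma by construction)."""
        rng = np.random.default_rng(7)
        n_sub = 27
        rows = []
        for i in range(n_sub):
            b = rng.normal(scale=1.5)
            for c in ("DIG", "LET", "FF"):
                for h in ("LOT", "ROT"):
                    eps = np.clip(rng.normal(scale=2.0), -5.0, 5.0)
                    rows.append(
                        {"subject": f"s{i:02d}", "condition": c, "hemisphere": h,
                         "n1_mean_amplitude": {"DIG": -8.0, "LET": -7.0, "FF": -6.0}[c] + b + eps}
                    )
        table = pd.DataFrame(rows)
        table.loc[17, "n1_mean_amplitude"] += 50.0
        lmm = ST.fit_lmm(table, ST.LmmSpec(factors=("hemisphere", "condition")))
        assert lmm.n_excluded == 1
        assert lmm.excluded.index.tolist() == [17]
        # single-pass refit is stable: no cascade on the cleaned data
        again = ST.fit_lmm(lmm.data, ST.LmmSpec(factors=("hemisphere", "condition")))
        assert again.n_excluded == 0

    def test_empty_factor_level_named_in_error(self):
        rng = np.random.default_rng(1)
        table = balanced_table(rng, conditions=("DIG", "LET"))
        table["condition"] = pd.Categorical(table["condition"],
                                            categories=["DIG", "LET", "FF"])
        with pytest.raises(ValueError, match="FF"):
            ST.fit_lmm(table, ST.LmmSpec(factors=("hemisphere", "condition")))

    def test_requires_two_subjects(self):
        rng = np.random.default_rng(2)
        table = balanced_table(rng, n_sub=1)
        with pytest.raises(ValueError, match="subjects"):
            ST.fit_lmm(table, ST.LmmSpec(factors=("condition",)))


class TestContrasts:
    def test_equal_condition_means_give_near_zero_t(self):
        rng = np.random.default_rng(3)
        table = balanced_table(rng, n_sub=40, effects={"DIG": -7.0, "LET": -7.0, "FF": -7.0})
        lmm = ST.fit_lmm(table, ST.LmmSpec(factors=("hemisphere", "condition")))
        con = ST.posthoc_contrasts(lmm, pairs=(("DIG", "FF"),))
        assert abs(con["t"].iloc[0]) < 2.5

    def test_unknown_pair_rejected(self):
        rng = np.random.default_rng(4)
        lmm = ST.fit_lmm(balanced_table(rng), ST.LmmSpec(factors=("condition",)))
        with pytest.raises(ValueError, match="XX"):
            ST.posthoc_contrasts(lmm, pairs=(("DIG", "XX"),))

    def test_null_simulation_type_one_error_near_alpha(self):
        """No condition effect -> per-cohort contrast rejects at ~5%."""
        truth = sim.GroundTruth(
            condition_amplitude_uv={"DIG": -7.0, "LET": -7.0, "FF": -7.0},
            amplitude_overrides={},
            coarse_effect_subject_sd_uv=0.0,
        )
        cohort = sim.CohortSpec(timepoints=("T1",), group_size={"T1": 15}, n_subjects=15)
        rejections = 0
        n_rep = 120
        for i in range(n_rep):
            bundle = sim.simulate_amplitude_table(cohort, truth, seed=5000 + i)
            lmm = ST.fit_lmm(bundle["amplitudes"], ST.LmmSpec(factors=("hemisphere", "condition")))
            con = ST.posthoc_contrasts(lmm, pairs=(("DIG", "FF"),))
            if con["p"].iloc[0] < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestSpearman:
    def test_strictly_monotone_extremes(self):
        x = np.arange(10.0)
        assert ST.spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert ST.spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        x = rng.integers(0, 5, size=20).astype(float)
        y = rng.integers(0, 5, size=20).astype(float)
        rho, _ = ST.spearman(x, y)
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_scipy_at_moderate_n(self, rng):
        from scipy.stats import spearmanr

        x, y = rng.standard_normal(30), rng.standard_normal(30)
        rho, p = ST.spearman(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_p_small_n(self, rng):
        """n <= 9 uses the exact null; compare against direct enumeration."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p = ST.spearman(x, y)
        perms = np.array(list(itertools.permutations(range(6))), dtype=float)
        rhos = [np.corrcoef(x, pm)[0, 1] for pm in perms + 1]
        expected = np.mean(np.abs(rhos) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_zero_rank_variance_flagged(self):
        rho, p = ST.spearman(np.ones(6), np.arange(6.0))
        assert np.isnan(rho) and np.isnan(p)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        base = ST.spearman(x, y)[0]
        assert ST.spearman(np.exp(x), y)[0] == pytest.approx(base, abs=1e-12)
        assert ST.spearman(x, 3 * y - 7)[0] == pytest.approx(base, abs=1e-12)


class TestFdr:
    def test_single_p_unchanged(self):
        assert ST.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        adj = ST.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.allclose(ST.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50)
        adj = ST.bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            ST.bh_fdr([0.5, 1.5])


class TestCorrelationGrid:
    def make_inputs(self, seed=0, rho=0.6):
        truth = sim.GroundTruth()
        cohort = sim.CohortSpec()
        bundle = sim.simulate_amplitude_table(
            cohort, truth, sim.BehaviorTruth(brain_behavior_rho=rho), seed=seed
        )
        from n1dev.erp import sensitivity_differences

        diffs = sensitivity_differences(bundle["amplitudes"])
        return diffs, bundle["behavior"]

    def test_default_grid_has_36_cells_and_fdr_dominates_p(self):
        diffs, behavior = self.make_inputs()
        grid = ST.correlation_grid(diffs, behavior)
        assert len(grid) == 36
        ok = grid["p"].notna()
        assert ok.all()
        assert (grid.loc[ok, "p_fdr"] >= grid.loc[ok, "p"] - 1e-12).all()

    def test_insufficient_cells_marked(self):
        diffs, behavior = self.make_inputs()
        small = diffs[diffs["subject"] == diffs["subject"].iloc[0]]
        grid = ST.correlation_grid(small, behavior)
        assert grid["insufficient"].any()

    def test_mad_outlier_screen(self):
        vals = np.array([0.1, 0.2, -0.1, 0.0, 0.15, 25.0])
        mask = ST.mad_outliers(vals)
        assert mask.tolist() == [False, False, False, False, False, True]
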