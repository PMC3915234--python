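"""Association testing: ANOVA F-tests, thresholds, sentinels, t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylsmoke.behaviour import two_sample_power
from methylsmoke.ewas import (effect_size, fit_cpg_anova, fwer_threshold,
                              group_t_test, interaction_test, run_ewas,
                              select_sentinels)
from methylsmoke.preprocess import beta_to_m
from methylsmoke.simulate import CohortConfig, simulate_cohort


def _labels(n_never, n_current, rng):
    status = np.array(["never"] * n_never + ["current"] * n_current)
    eth = rng.permutation(np.array(["European", "SouthAsian"]
                                   * ((n_never + n_current) // 2 + 1)))[: len(status)]
    return status, eth


class TestFwerThreshold:
    def test_twelve_tests(self):
        assert fwer_threshold(0.05, 12) == pytest.approx(0.0041667, abs=5e-8)
        assert fwer_threshold(0.05, 12) <= 0.004167

    def test_single_test_returns_alpha(self):
        assert fwer_threshold(0.037, 1) == 0.037

    def test_genome_wide_threshold(self):
        # post-QC probe count: 485,577 platform probes minus the detection
        # and homology exclusions
        th = fwer_threshold(0.05, 485577 - 9769 - 25083)
        assert th == pytest.approx(1.11e-7, rel=0.005)

    @pytest.mark.parametrize("alpha,n", [(0.0, 5), (1.0, 5), (0.05, 0)])
    def test_invalid_inputs(self, alpha, n):
        with pytest.raises(ValueError):
            fwer_threshold(alpha, n)


class TestFitCpgAnova:
    def test_matches_statsmodels_type2_anova(self, rng):
        """Dual route: handwritten partial F equals statsmodels anova_lm."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        status, eth = _labels(30, 20, rng)
        y = rng.normal(size=50) + 0.5 * (status == "current")
        F, p = fit_cpg_anova(y, status, eth)
        df = pd.DataFrame({"y": y, "smoking": status, "eth": eth})
        fit = smf.ols("y ~ C(smoking) + C(eth)", df).fit()
        table = anova_lm(fit, typ=2)
        assert F == pytest.approx(table.loc["C(smoking)", "F"], rel=1e-10)
        assert p == pytest.approx(table.loc["C(smoking)", "PR(>F)"], rel=1e-10)

    def test_null_p_values_uniform(self):
        """Under no smoking effect the per-CpG p-values are uniform."""
        cfg = CohortConfig(n_probes=2000, n_signal_cpgs=0, n_cell_types=0,
                           n_cell_probes=0, batch_sd=0.0, seed=23)
        beta, sheet, _, _ = simulate_cohort(cfg)
        m = beta_to_m(beta)
        res = run_ewas(beta, m, sheet, beta.attrs["manifest"])
        ks = stats.kstest(res.table["p_value"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_perfect_separation_reports_below_representable(self, rng):
        status, eth = _labels(20, 20, rng)
        y = (status == "current").astype(float)
        F, p = fit_cpg_anova(y, status, eth)
        assert np.isinf(F)
        assert p < 1e-300

    def test_constant_outcome_flagged_not_raised(self, rng):
        status, eth = _labels(10, 10, rng)
        F, p = fit_cpg_anova(np.zeros(20), status, eth)
        assert np.isnan(F) and np.isnan(p)

    def test_empirical_power_matches_analytic(self, rng):
        """Cross-module check: rejection rate of the ANOVA smoking test on
        simulated M-values sits within 3 Monte-Carlo SEs of the analytic
        two-sample power."""
        delta, sd, n1, n2, alpha = 0.15, 0.25, 36, 65, 0.01
        reps = 800
        y = np.concatenate([
            rng.normal(0.0, sd, (n2, reps)),
            rng.normal(delta, sd, (n1, reps)),
        ])
        status = np.array(["never"] * n2 + ["current"] * n1)
        eth = np.tile(["European", "SouthAsian"], (n1 + n2) // 2 + 1)[: n1 + n2]
        from methylsmoke.ewas import _design, _partial_f
        Xf, Xr = _design(status, eth)
        _, p = _partial_f(y, Xf, Xr)
        empirical = (p < alpha).mean()
        analytic = two_sample_power(delta, sd, n1, n2, alpha)
        se = np.sqrt(analytic * (1 - analytic) / reps)
        assert abs(empirical - analytic) < 3 * se


class TestEffectSize:
    def test_identical_groups_zero(self):
        groups = np.array(["never"] * 5 + ["current"] * 5)
        vals = np.tile(np.arange(5.0), 2)
        assert effect_size(vals, groups) == 0.0

    def test_constant_shift(self):
        groups = np.array(["never"] * 4 + ["current"] * 4)
        vals = np.array([0.1, 0.2, 0.3, 0.4, 0.22, 0.32, 0.42, 0.52])
        assert effect_size(vals, groups) == pytest.approx(0.12)

    def test_simulated_ahrr_like_effect_recovered(self):
        diffs = []
        for seed in range(10):
            cfg = CohortConfig(n_probes=200, n_signal_cpgs=1,
                               effect_sizes=(-0.22,), signal_baselines=(0.77,),
                               n_cell_types=0, n_cell_probes=0, seed=seed)
            beta, sheet, _, _ = simulate_cohort(cfg)
            diffs.append(effect_size(beta.values[0],
                                     sheet["smoking_status"].values))
        assert np.mean(diffs) == pytest.approx(-0.22, abs=0.03)


class TestSentinels:
    def _manifest(self, probes, loci):
        return pd.DataFrame({"probe_id": probes, "locus": loci})

    def _table(self, probes, ps, effects=None):
        return pd.DataFrame({
            "probe_id": probes,
            "p_value": ps,
            "effect_size": effects if effects is not None else np.ones(len(probes)),
        })

    def test_single_cpg_is_its_own_sentinel(self):
        table = self._table(["cg1"], [1e-9])
        sent = select_sentinels(table, self._manifest(["cg1"], ["AHRR"]))
        assert sent["AHRR"] == "cg1"

    def test_smallest_p_wins_within_locus(self):
        table = self._table(["cg1", "cg2"], [1e-8, 1e-10])
        sent = select_sentinels(table, self._manifest(["cg1", "cg2"], ["L", "L"]))
        assert sent["L"] == "cg2"

    def test_ties_broken_by_effect_then_id(self):
        table = self._table(["cgB", "cgA"], [1e-8, 1e-8], [0.1, 0.3])
        sent = select_sentinels(table, self._manifest(["cgB", "cgA"], ["L", "L"]))
        assert sent["L"] == "cgA"  # larger |effect|

    def test_unmapped_probe_becomes_singleton_locus(self):
        table = self._table(["cg1", "cgX"], [1e-8, 1e-9])
        with pytest.warns(UserWarning, match="singleton"):
            sent = select_sentinels(table, self._manifest(["cg1"], ["L"]))
        assert sent["cgX"] == "cgX"

    def test_agrees_with_brute_force_argmin(self, rng):
        n = 200
        probes = [f"cg{i}" for i in range(n)]
        loci = [f"L{i % 37}" for i in range(n)]
        ps = rng.uniform(1e-12, 1e-6, n)
        table = self._table(probes, ps, rng.normal(size=n))
        sent = select_sentinels(table, self._manifest(probes, loci))
        for locus in set(loci):
            members = [i for i in range(n) if loci[i] == locus]
            best = probes[members[int(np.argmin(ps[members]))]]
            assert sent[locus] == best


class TestInteraction:
    def test_matches_statsmodels_nested_comparison(self, rng):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        status, eth = _labels(30, 20, rng)
        y = rng.normal(size=50) + 0.4 * ((status == "current") & (eth == "European"))
        F, p = interaction_test(y, status, eth)
        df = pd.DataFrame({"y": y, "s": status, "e": eth})
        add = smf.ols("y ~ C(s) + C(e)", df).fit()
        full = smf.ols("y ~ C(s) * C(e)", df).fit()
        cmp_ = anova_lm(add, full)
        assert F == pytest.approx(cmp_.loc[1, "F"], rel=1e-8)
        assert p == pytest.approx(cmp_.loc[1, "Pr(>F)"], rel=1e-8)

    def test_balanced_noiseless_additive_data_gives_zero_f(self):
        status = np.array(["never", "never", "current", "current"] * 2)
        eth = np.array(["European"] * 4 + ["SouthAsian"] * 4)
        y = 1.0 * (status == "current") + 0.5 * (eth == "SouthAsian") \
            + np.tile([0.0, 0.1], 4)  # replicate noise orthogonal to design
        F, _ = interaction_test(y, status, eth)
        assert F == pytest.approx(0.0, abs=1e-8)

    def test_null_interaction_p_uniform_under_additive_model(self):
        """Additive (no-interaction) simulation: interaction p is uniform."""
        ps = []
        for seed in range(4):
            cfg = CohortConfig(n_probes=500, n_signal_cpgs=50, n_cell_types=0,
                               n_cell_probes=0, batch_sd=0.0, seed=100 + seed)
            beta, sheet, _, _ = simulate_cohort(cfg)
            m = beta_to_m(beta)
            status = sheet["smoking_status"].values
            eth = sheet["ethnicity"].values
            keep = np.isin(status, ("never", "current"))
            from methylsmoke.ewas import _design, _partial_f
            Xf, Xa = _design(status[keep], eth[keep], interaction=True)
            _, p = _partial_f(m.values[:, keep].T, Xf, Xa)
            ps.append(p)
        ks = stats.kstest(np.concatenate(ps), "uniform")
        assert ks.pvalue > 0.01

    def test_empty_design_cell_warns_na(self):
        status = np.array(["never"] * 4 + ["current"] * 2)
        eth = np.array(["European"] * 2 + ["SouthAsian"] * 2 + ["European"] * 2)
        with pytest.warns(UserWarning, match="empty cell"):
            F, p = interaction_test(np.arange(6.0), status, eth)
        assert np.isnan(F) and np.isnan(p)


class TestGroupTTest:
    def test_identical_groups(self):
        vals = np.tile([1.0, 2.0, 3.0], 2)
        labels = ["a"] * 3 + ["b"] * 3
        t, p = group_t_test(vals, labels)
        assert t == 0.0 and p == 1.0

    def test_label_swap_negates_t(self, rng):
        vals = rng.normal(size=12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        t1, p1 = group_t_test(vals, labels)
        swapped = np.where(labels == "a", "b", "a")
        t2, p2 = group_t_test(vals, swapped)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_matches_arbitrary_precision_welch_oracle(self):
        # expected values computed independently with exact rational
        # arithmetic + mpmath's regularised incomplete beta
        a = [1.1, 2.3, 0.7, 1.9, 1.4]
        b = [2.0, 2.8, 3.1, 2.2, 2.6]
        t, p = group_t_test(a + b, ["x"] * 5 + ["y"] * 5)
        assert t == pytest.approx(-3.0599564267050168, rel=1e-12)
        assert p == pytest.approx(0.017788736891842506, rel=1e-9)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_t_test([1.0, 2.0, 3.0], ["a", "b", "b"])


class TestRunEwas:
    def test_rank_one_is_minimum_p(self, default_cohort):
        _, beta, sheet, _, _ = default_cohort
        m = beta_to_m(beta)
        res = run_ewas(beta, m, sheet, beta.attrs["manifest"])
        sig = res.significant
        top = sig.loc[sig["rank"] == 1.0]
        assert len(top) == 1
        assert top["p_value"].iloc[0] == sig["p_value"].min()

    def test_signal_recovered_and_no_false_positives(self, default_cohort):
        _, beta, sheet, _, truth = default_cohort
        m = beta_to_m(beta)
        res = run_ewas(beta, m, sheet, beta.attrs["manifest"])
        sig_probes = set(res.significant["probe_id"])
        assert set(truth.signal_probes) <= sig_probes
        extras = sig_probes - set(truth.signal_probes) - set(truth.cell_probes)
        assert len(extras) <= 1

    def test_sentinel_per_significant_locus(self, default_cohort):
        _, beta, sheet, _, _ = default_cohort
        m = beta_to_m(beta)
        res = run_ewas(beta, m, sheet, beta.attrs["manifest"])
        sig = res.significant
        assert sig.groupby("locus")["sentinel"].sum().eq(1).all()

    def test_p_monotone_in_f(self, default_cohort):
        _, beta, sheet, _, _ = default_cohort
        m = beta_to_m(beta)
        res = run_ewas(beta, m, sheet, beta.attrs["manifest"])
        t = res.table.dropna(subset=["p_value"])
        t = t[np.isfinite(t["F_statistic"])]
        order = t.sort_values("F_statistic")
        assert order["p_value"].is_monotonic_decreasing
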