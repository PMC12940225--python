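"""Derived scores and the statistical battery, checked against independent
oracles (enumeration, closed forms, simulation)."""

import numpy as np
import pandas as pd
import pytest

from gutwbm import (
    InputError,
    apoe_groups,
    bh_fdr,
    compute_prs,
    driver_attribution,
    fisher_exact_rxc,
    global_cognition,
    interaction_analysis,
    kruskal_dunn,
    regress_outcome,
    t_two_sample,
    wilcoxon_sex,
)
from oracles import hypergeom_2x2_two_sided, kruskal_exact_p, wilcoxon_exact_p


class TestApoeGroups:
    def test_grouping_rule(self):
        g = apoe_groups(pd.Series(["E2/E2", "E2/E3", "E3/E3", "E3/E4",
                                   "E4/E4", "E2/E4"]))
        assert g.tolist() == ["E2", "E2", "E3", "E4", "E4", "excluded"]

    def test_unknown_genotype_rejected(self):
        with pytest.raises(InputError):
            apoe_groups(pd.Series(["E5/E5"]))


class TestGlobalCognition:
    def test_perfectly_correlated_subtests(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"t1": x, "t2": 2 * x + 5})
        score, ve = global_cognition(df)
        assert ve == pytest.approx(1.0)
        assert np.corrcoef(score, x)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_subtests_split_variance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"t1": rng.normal(0, 1, 20000),
                           "t2": rng.normal(0, 1, 20000)})
        _, ve = global_cognition(df)
        assert ve == pytest.approx(0.5, abs=0.02)

    def test_one_factor_model_variance_explained(self):
        # five subtests x_j = 0.714 f + e (unit noise): first PC ~47%
        rng = np.random.default_rng(2)
        n = 20000
        f = rng.normal(0, 1, n)
        df = pd.DataFrame({f"t{j}": 0.714 * f + rng.normal(0, 1, n)
                           for j in range(5)})
        _, ve = global_cognition(df)
        assert ve == pytest.approx(0.47, abs=0.02)

    def test_sign_oriented_positively(self):
        rng = np.random.default_rng(3)
        f = rng.normal(0, 1, 500)
        df = pd.DataFrame({f"t{j}": 0.8 * f + rng.normal(0, 1, 500)
                           for j in range(4)})
        score, _ = global_cognition(df)
        z = (df - df.mean()) / df.std()
        assert np.corrcoef(score, z.mean(axis=1))[0, 1] > 0

    def test_constant_subtest_rejected(self):
        df = pd.DataFrame({"t1": [1.0, 1.0, 1.0], "t2": [1.0, 2.0, 3.0]})
        with pytest.raises(InputError, match="constant"):
            global_cognition(df)


class TestPrs:
    def test_weighted_dosage_sum(self):
        dos = pd.DataFrame({"snp_1": [0.0, 2.0], "snp_2": [1.0, 0.5]},
                           index=["a", "b"])
        w = pd.Series({"snp_1": 0.5, "snp_2": -1.0})
        prs = compute_prs(dos, w)
        assert prs["a"] == pytest.approx(-1.0)
        assert prs["b"] == pytest.approx(0.5)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(4)
        dos = pd.DataFrame(rng.integers(0, 3, (50, 28)).astype(float),
                           columns=[f"snp_{i}" for i in range(28)])
        w = pd.Series(rng.normal(0, 0.1, 28), index=dos.columns)
        np.testing.assert_allclose(compute_prs(dos, w).to_numpy(),
                                   dos.to_numpy() @ w.to_numpy())

    def test_missing_dosage_gives_missing_prs(self):
        dos = pd.DataFrame({"snp_1": [1.0, np.nan]}, index=["a", "b"])
        prs = compute_prs(dos, pd.Series({"snp_1": 1.0}))
        assert np.isnan(prs["b"]) and prs["a"] == 1.0


class TestRegression:
    def test_exact_linear_relation(self):
        x = pd.Series(np.linspace(0, 1, 50))
        res = regress_outcome(x, x, standardize=True)
        assert res.estimate == pytest.approx(1.0)
        assert res.p < 1e-30

    def test_null_estimate_small(self):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(0, 1, 1000))
        x = pd.Series(rng.normal(0, 1, 1000))
        res = regress_outcome(y, x)
        assert abs(res.estimate) < 0.1

    def test_planted_slope_recovered_over_replicates(self):
        rng = np.random.default_rng(6)
        estimates = []
        for _ in range(50):
            x = rng.normal(0, 1, 500)
            y = 0.3 * x + rng.normal(0, np.sqrt(1 - 0.09), 500)
            res = regress_outcome(pd.Series(y), pd.Series(x))
            estimates.append(res.estimate)
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.05)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(7)
        x = pd.Series(rng.normal(0, 1, 50))
        cov = pd.DataFrame({"dup": x})
        with pytest.raises(InputError, match="collinear"):
            regress_outcome(x * 2, x, cov, standardize=False)


class TestKruskalDunn:
    def test_exact_p_matches_enumeration_oracle(self):
        groups = [(1.0, 2.0, 3.0), (10.0, 11.0, 12.0), (20.0, 21.0, 22.0)]
        y = pd.Series([v for g in groups for v in g])
        labels = pd.Series(sum([[i] * 3 for i in range(3)], []))
        res = kruskal_dunn(y, labels, method="exact")
        assert res[0].p == pytest.approx(kruskal_exact_p(groups), abs=1e-12)

    def test_two_group_dunn_z_squared_reproduces_kw_h(self):
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(0, 1, 40))
        labels = pd.Series(["a"] * 18 + ["b"] * 22)
        res = kruskal_dunn(y, labels, method="asymptotic")
        kw, dunn = res[0], res[1]
        assert dunn.statistic ** 2 == pytest.approx(kw.statistic, rel=1e-9)

    def test_small_groups_dropped_with_warning(self, caplog):
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        labels = pd.Series(["a", "a", "b", "b", "c"])
        with caplog.at_level("WARNING"):
            res = kruskal_dunn(y, labels)
        assert "dropped" in caplog.text
        assert res[0].n == 4

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 2000
        labels = pd.Series([0] * 15 + [1] * 15 + [2] * 15)
        for _ in range(reps):
            y = pd.Series(rng.normal(0, 1, 45))
            res = kruskal_dunn(y, labels, method="asymptotic")
            rejections += res[0].p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        y = pd.Series([2.0] * 10)
        sex = pd.Series(["f"] * 5 + ["m"] * 5)
        assert wilcoxon_sex(y, sex).p == 1.0

    def test_matches_exact_enumeration_for_separated_groups(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        res = wilcoxon_sex(pd.Series(a + b),
                           pd.Series(["f"] * 3 + ["m"] * 3))
        assert res.p == pytest.approx(wilcoxon_exact_p(a, b), abs=1e-12)
        assert res.p == pytest.approx(2 / 20, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(InputError):
            wilcoxon_sex(pd.Series([1.0, 2.0]), pd.Series(["f", "f"]))


class TestInteraction:
    def test_sex_specific_slope_detected_and_stratified(self):
        rng = np.random.default_rng(10)
        detected = 0
        male_neg = 0
        female_null = 0
        reps = 50
        for _ in range(reps):
            n = 600
            sex = pd.Series(np.where(rng.random(n) < 0.5, "female", "male"))
            flux = pd.Series(rng.normal(0, 1, n))
            slope = np.where(sex == "male", -0.3, 0.0)
            y = pd.Series(slope * flux + rng.normal(0, 1, n))
            res = interaction_analysis(y, flux, sex)
            if res[0].p < 0.05:
                detected += 1
                per_sex = {r.predictor: r for r in res[1:]}
                male = [v for k, v in per_sex.items() if "male" in k
                        and "female" not in k][0]
                female = [v for k, v in per_sex.items() if "female" in k][0]
                male_neg += male.estimate < 0
                female_null += abs(female.estimate) < 0.15
        assert detected / reps >= 0.8
        assert male_neg == detected
        assert female_null / max(detected, 1) >= 0.9

    def test_equal_slopes_give_null_interaction(self):
        rng = np.random.default_rng(11)
        n = 2000
        sex = pd.Series(["female", "male"] * (n // 2))
        flux = pd.Series(rng.normal(0, 1, n))
        y = 0.4 * flux + pd.Series(rng.normal(0, 1, n))
        res = interaction_analysis(y, flux, sex)
        assert abs(res[0].estimate) < 0.1

    def test_single_sex_rejected(self):
        with pytest.raises(InputError):
            interaction_analysis(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]),
                                 pd.Series(["f", "f"]))


class TestFisher:
    def test_2x2_matches_hypergeometric_oracle(self):
        table = [[3, 1], [1, 3]]
        p = fisher_exact_rxc(table)
        assert p == pytest.approx(hypergeom_2x2_two_sided(table), abs=1e-12)
        assert p == pytest.approx(0.485714285, abs=1e-9)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_rxc([[4, 2, 3], [4, 2, 3]]) == pytest.approx(1.0)

    def test_monte_carlo_agrees_with_enumeration(self):
        table = [[12, 5, 9], [4, 11, 7]]
        p_enum = fisher_exact_rxc(table, method="enumerate")
        p_mc = fisher_exact_rxc(table, method="monte-carlo", n_mc=200_000,
                                seed=1)
        assert p_mc == pytest.approx(p_enum, abs=0.01)

    def test_enumeration_cap_advises_monte_carlo(self):
        table = [[1000, 1000, 1000, 1000], [1000, 1000, 1000, 1000]]
        with pytest.raises(InputError, match="monte-carlo"):
            fisher_exact_rxc(table, method="enumerate", max_tables=1e4)


class TestTTwoSample:
    def test_identical_groups(self):
        res = t_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_summary_statistics_input(self):
        # cohort-style age summaries: expect t ~ 0.06, p ~ 0.95
        res = t_two_sample((61.66, 5.38, 608), (61.64, 5.48, 456))
        assert res.statistic == pytest.approx(0.06, abs=0.01)
        assert res.p == pytest.approx(0.95, abs=0.01)

    def test_power_for_one_sd_shift(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 200
        for _ in range(reps):
            a = rng.normal(0, 1, 50)
            b = rng.normal(1, 1, 50)
            hits += t_two_sample(a, b).p < 0.01
        assert hits / reps >= 0.95


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 40)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDriverAttribution:
    def test_sole_producer_ranks_first(self, small_study):
        from gutwbm.pipeline import run_associations
        assoc = run_associations(small_study)
        ranking = assoc["attribution"]["arg_like"]
        assert ranking[0][0] == "arg_driver"
        assert ranking[0][1] >= 0.7

    def test_non_producers_excluded_from_candidates(self, small_study):
        from gutwbm.association_stats import candidate_species
        cands = candidate_species(small_study["pan_models"], "arg_like",
                                  small_study["manifest"]["precursors"])
        assert "arg_driver" in cands and "null_sp_1" in cands
        assert "null_producer_1" not in cands  # no route, however correlated

    def test_two_producer_ranking_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(14)
        n = 200
        a1 = pd.Series(rng.uniform(0.05, 0.4, n))
        a2 = pd.Series(rng.uniform(0.05, 0.4, n))
        flux = 400 * (0.8 * a1 + 0.2 * a2)
        abunds = pd.DataFrame({"sp1": a1, "sp2": a2})
        from gutwbm.model_assembly import StoichiometricModel
        models = {}
        for sp in ("sp1", "sp2"):
            m = StoichiometricModel(sp)
            m.add_reaction("SEC", {"x[c]": -1.0, "x[luM]": 1.0}, 0.0)
            m.add_reaction("PROD", {"diet[c]": -1.0, "x[c]": 1.0}, 0.0)
            models[sp] = m
        ranking = driver_attribution(pd.DataFrame({"x": flux}), abunds, models)
        # oracle: recompute R^2 by hand for each candidate
        def r2(a):
            la = np.log2(a)
            z = (la - la.mean()) / la.std(ddof=1)
            return float(np.corrcoef(z, flux)[0, 1] ** 2)
        expected = sorted([("sp1", r2(a1)), ("sp2", r2(a2))],
                          key=lambda t: -t[1])
        assert [s for s, _ in ranking["x"]] == [s for s, _ in expected]
        np.testing.assert_allclose([v for _, v in ranking["x"]],
                                   [v for _, v in expected], atol=1e-12)

    def test_no_candidates_logged(self, caplog):
        with caplog.at_level("WARNING"):
            out = driver_attribution(
                pd.DataFrame({"y": [1.0, 2.0, 3.0]}),
                pd.DataFrame({"sp": [0.1, 0.2, 0.3]}), {})
        assert out["y"] == []
        assert "no candidate species" in caplog.text
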