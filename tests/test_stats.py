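import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bscbmark import stats
from bscbmark.errors import CollinearityError, StatisticsError
from bscbmark.synthetic import generate_cohort, paper_like_cohort_spec, population_correlation


def minimal_table(**columns):
    n = len(next(iter(columns.values())))
    base = {"animal_id": [f"m{i}" for i in range(n)], "group": "isotype_control", "dpi": 7}
    base.update(columns)
    return pd.DataFrame(base)


class TestCorrelate:
    def test_monotone_function_gives_spearman_one(self):
        x = np.linspace(1, 5, 10)
        table = minimal_table(gd_leakage=x, clinical_score=np.exp(x))
        res = stats.correlate(table, "gd_leakage", "clinical_score")
        assert res.r == pytest.approx(1.0)

    def test_worked_rank_difference_example(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,1,1,0) -> sum d^2 = 4 -> r = 0.8
        table = minimal_table(gd_leakage=[1, 2, 3, 4, 5], pct_rd=[2, 1, 4, 3, 5])
        res = stats.correlate(table, "gd_leakage", "pct_rd")
        assert res.r == pytest.approx(0.8, abs=1e-12)

    def test_strong_band_example(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = x + 0.4 * rng.normal(size=200)
        table = minimal_table(gd_leakage=x, clinical_score=y)
        res = stats.correlate(table, "gd_leakage", "clinical_score")
        assert res.r > 0.7
        assert res.band == "strong correlation"

    def test_pearson_method(self):
        x = np.arange(10.0)
        table = minimal_table(gd_leakage=x, pct_rd=2 * x + 1)
        res = stats.correlate(table, "gd_leakage", "pct_rd", method="pearson")
        assert res.r == pytest.approx(1.0)
        assert res.method == "pearson"

    def test_exact_permutation_p_matches_enumeration(self):
        table = minimal_table(gd_leakage=[1, 2, 3, 4, 5], pct_rd=[2, 1, 4, 3, 5])
        res = stats.correlate(table, "gd_leakage", "pct_rd", p_method="exact")
        # oracle: scipy exact spearman p for untied small samples
        _, p_exact = sps.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], alternative="two-sided")
        # permutation count: 8 of 120 permutations reach |r| >= 0.8
        n_hits = sum(
            1
            for perm in __import__("itertools").permutations([2, 1, 4, 3, 5])
            if abs(sps.spearmanr([1, 2, 3, 4, 5], perm).statistic) >= 0.8 - 1e-12
        )
        assert res.p == pytest.approx(n_hits / 120)

    def test_ties_use_average_ranks(self):
        table = minimal_table(gd_leakage=[1, 2, 3, 4, 5, 6], clinical_score=[0, 0, 1, 1, 2, 2])
        res = stats.correlate(table, "gd_leakage", "clinical_score")
        oracle, _ = sps.pearsonr(
            sps.rankdata([1, 2, 3, 4, 5, 6]), sps.rankdata([0, 0, 1, 1, 2, 2])
        )
        assert res.r == pytest.approx(oracle)

    def test_pairwise_complete_deletion(self):
        table = minimal_table(
            gd_leakage=[1.0, 2.0, np.nan, 4.0, 5.0], pct_rd=[2.0, 1.0, 4.0, np.nan, 5.0]
        )
        res = stats.correlate(table, "gd_leakage", "pct_rd")
        assert res.n == 3

    def test_too_few_pairs_rejected(self):
        table = minimal_table(gd_leakage=[1.0, 2.0], pct_rd=[1.0, 2.0])
        with pytest.raises(StatisticsError):
            stats.correlate(table, "gd_leakage", "pct_rd")

    def test_zero_variance_rejected(self):
        table = minimal_table(gd_leakage=[1.0, 1.0, 1.0, 1.0], pct_rd=[1.0, 2.0, 3.0, 4.0])
        with pytest.raises(StatisticsError):
            stats.correlate(table, "gd_leakage", "pct_rd")

    @given(
        seed=st.integers(0, 2**16),
        power=st.floats(0.2, 3.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_spearman_invariant_under_monotone_transform(self, seed, power):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        table_a = minimal_table(gd_leakage=x, pct_rd=y)
        table_b = minimal_table(gd_leakage=np.exp(power * x), pct_rd=y)
        ra = stats.correlate(table_a, "gd_leakage", "pct_rd").r
        rb = stats.correlate(table_b, "gd_leakage", "pct_rd").r
        assert ra == pytest.approx(rb, abs=1e-12)


class TestClassifyStrength:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.0, "very weak to negligible correlation"),
            (0.19, "very weak to negligible correlation"),
            (0.2, "weak correlation"),
            (0.4, "moderate correlation"),
            (0.549, "moderate correlation"),
            (-0.549, "moderate correlation"),
            (0.7, "strong correlation"),
            (0.831, "strong correlation"),
            (-0.748, "strong correlation"),
            (1.0, "strong correlation"),
        ],
    )
    def test_correlation_bands(self, value, band):
        assert stats.classify_strength(value) == band

    @pytest.mark.parametrize(
        "value, band",
        [
            (0.045, "none or very weak effect size"),
            (0.105, "none or very weak effect size"),
            (0.489, "moderate effect size"),
            (0.769, "strong effect size"),
        ],
    )
    def test_effect_size_bands(self, value, band):
        assert stats.classify_strength(value, "effect_size") == band

    def test_out_of_range_rejected(self):
        with pytest.raises(StatisticsError):
            stats.classify_strength(1.2)


class TestStandardizedRegression:
    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        table = minimal_table(clinical_score=y, gd_leakage=x)
        res = stats.standardized_regression(table, predictors=("gd_leakage",))
        r, _ = sps.pearsonr(x, y)
        assert res.beta["gd_leakage"] == pytest.approx(r, abs=1e-12)

    def test_exact_fit_limit(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=60)
        x2 = rng.normal(size=60)
        table = minimal_table(clinical_score=x1, gd_leakage=x1, pct_rd=x2)
        res = stats.standardized_regression(table, predictors=("gd_leakage", "pct_rd"))
        assert res.beta["gd_leakage"] == pytest.approx(1.0, abs=1e-9)
        assert res.beta["pct_rd"] == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_predictors_betas_equal_simple_r(self):
        # normal-equations oracle: with a diagonal Gram matrix each beta is
        # the simple Pearson r with the response
        rng = np.random.default_rng(2)
        x1 = np.repeat([1.0, -1.0], 30)
        x2 = np.tile([1.0, -1.0], 30)  # exactly orthogonal, equal variance
        y = 0.5 * x1 - 0.25 * x2 + rng.normal(0, 0.5, 60)
        table = minimal_table(clinical_score=y, gd_leakage=x1, pct_rd=x2)
        res = stats.standardized_regression(table, predictors=("gd_leakage", "pct_rd"))
        for name, x in (("gd_leakage", x1), ("pct_rd", x2)):
            r, _ = sps.pearsonr(x, y)
            assert res.beta[name] == pytest.approx(r, abs=1e-10)

    def test_monte_carlo_beta_recovery(self):
        # population standardized beta (0.7, 0, 0, -0.2); n=500 x 100 seeds
        truth = np.array([0.7, 0.0, 0.0, -0.2])
        sigma = np.sqrt(1.0 - 0.7**2 - 0.2**2)
        names = ("gd_leakage", "pct_fa", "pct_ad", "pct_rd")
        betas = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(500, 4))
            y = x @ truth + sigma * rng.normal(size=500)
            table = minimal_table(clinical_score=y, **dict(zip(names, x.T)))
            res = stats.standardized_regression(table, predictors=names)
            betas.append([res.beta[n] for n in names])
        betas = np.asarray(betas)
        se = betas.std(axis=0, ddof=1) / np.sqrt(100)
        assert (np.abs(betas.mean(axis=0) - truth) < 3 * se + 1e-3).all()

    def test_collinearity_names_offenders(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        table = minimal_table(
            clinical_score=rng.normal(size=40),
            gd_leakage=x,
            pct_fa=2.0 * x,  # perfectly collinear with gd_leakage
            pct_rd=rng.normal(size=40),
        )
        with pytest.raises(CollinearityError) as err:
            stats.standardized_regression(table, predictors=("gd_leakage", "pct_fa", "pct_rd"))
        assert "gd_leakage" in str(err.value) and "pct_fa" in str(err.value)

    def test_too_few_cases_rejected(self):
        table = minimal_table(
            clinical_score=[1.0, 2.0, 3.0], gd_leakage=[1.0, 2.0, 3.0], pct_rd=[3.0, 1.0, 2.0]
        )
        with pytest.raises(StatisticsError):
            stats.standardized_regression(table, predictors=("gd_leakage", "pct_rd"))


class TestPredictivePower:
    def paired_table(self, x, y, input_dpi=7, output_dpi=14):
        rows = []
        for i, (xi, yi) in enumerate(zip(x, y)):
            rows.append({"animal_id": f"m{i}", "group": "isotype_control", "dpi": input_dpi,
                         "gd_leakage": xi, "pct_rd": np.nan})
            rows.append({"animal_id": f"m{i}", "group": "isotype_control", "dpi": output_dpi,
                         "gd_leakage": np.nan, "pct_rd": yi})
        return pd.DataFrame(rows)

    def test_exact_affine_relation_gives_r2_one(self):
        x = np.arange(10.0)
        table = self.paired_table(x, -3.0 * x + 7.0)
        res = stats.predictive_power(table, input_dpi=7)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-3.0)
        assert res.intercept == pytest.approx(7.0)

    def test_independent_output_gives_small_r2(self):
        rng = np.random.default_rng(4)
        table = self.paired_table(rng.normal(size=400), rng.normal(size=400))
        res = stats.predictive_power(table, input_dpi=7)
        assert res.r_squared < 0.03

    def test_r2_equals_squared_pearson_r(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        table = self.paired_table(x, y)
        res = stats.predictive_power(table, input_dpi=7)
        r, _ = sps.pearsonr(x, y)
        assert res.r_squared == pytest.approx(r**2, abs=1e-12)

    def test_pairing_is_within_animal(self):
        x = np.arange(8.0)
        table = self.paired_table(x, 2.0 * x)
        shuffled = table.sample(frac=1.0, random_state=0)  # row order must not matter
        res = stats.predictive_power(shuffled, input_dpi=7)
        assert res.r_squared == pytest.approx(1.0)

    def test_preset_cohort_r2_recovery(self):
        # population r^2 = 0.49 between gd(7) and pct_rd(14)
        r2s = []
        for seed in range(100):
            spec = paper_like_cohort_spec(n_animals=500, seed=seed)
            table = generate_cohort(spec).table
            r2s.append(stats.predictive_power(table, input_dpi=7).r_squared)
        r2s = np.asarray(r2s)
        pop = population_correlation(
            paper_like_cohort_spec(), "gd_leakage", 7, "pct_rd", 14
        ) ** 2
        assert pop == pytest.approx(0.49, abs=1e-12)
        se = r2s.std(ddof=1) / np.sqrt(r2s.size)
        assert abs(r2s.mean() - pop) < 3 * se + 1e-3

    def test_permutation_null_r2_is_one_over_n_minus_one(self):
        rng = np.random.default_rng(6)
        n = 20
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r2s = []
        for _ in range(2000):
            perm = rng.permutation(n)
            table = self.paired_table(x, y[perm])
            r2s.append(stats.predictive_power(table, input_dpi=7).r_squared)
        r2s = np.asarray(r2s)
        se = r2s.std(ddof=1) / np.sqrt(r2s.size)
        assert abs(r2s.mean() - 1.0 / (n - 1)) < 3 * se

    def test_too_few_pairs_rejected(self):
        table = self.paired_table(np.arange(2.0), np.arange(2.0))
        with pytest.raises(StatisticsError):
            stats.predictive_power(table, input_dpi=7)


class TestCohortIntegration:
    def test_regression_and_cross_tables_render(self):
        table = generate_cohort(paper_like_cohort_spec(n_animals=20, seed=8)).table
        reg = stats.regression_table(table)
        assert set(reg.columns) == {7, 14, 21}
        assert set(reg.index) == set(stats.MRI_PARAMETERS)
        cross = stats.cross_timepoint_table(table)
        assert {"dpi", "variable"}.issubset(cross.columns)

    def test_group_difference_reports(self):
        spec_a = paper_like_cohort_spec(n_animals=10, seed=1)
        spec_b = paper_like_cohort_spec(n_animals=10, seed=2)
        spec_b.group = "anti_rgma"
        table = pd.concat(
            [generate_cohort(spec_a).table, generate_cohort(spec_b).table], ignore_index=True
        )
        res = stats.group_difference(table, "gd_leakage", ("isotype_control", "anti_rgma"), dpi=7)
        assert 0.0 <= res["p"] <= 1.0
        assert res["n1"] == res["n2"] == 10

    def test_validate_cohort_table_catches_bad_scores(self):
        table = generate_cohort(paper_like_cohort_spec(n_animals=5, seed=0)).table
        table.loc[0, "clinical_score"] = 2.7
        with pytest.raises(StatisticsError):
            stats.validate_cohort_table(table)

    def test_holm_adjustment_matches_reference(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.03, 0.5]
        adj = stats.holm_adjust(p)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(adj, ref)
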