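import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ironsmoke import pheno
from ironsmoke.simulate import CohortSpec, simulate_cohort


class TestImpute:
    def test_continuous_mean(self):
        t = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
        out = pheno.impute_missing(t, ["x"], categorical=set())
        assert out["x"].tolist() == [1.0, 2.0, 3.0]

    def test_categorical_mode(self):
        t = pd.DataFrame({"x": ["a", "a", "b", None]})
        out = pheno.impute_missing(t, ["x"], categorical={"x"})
        assert out["x"].tolist() == ["a", "a", "b", "a"]

    def test_mode_tie_sorted_first(self):
        t = pd.DataFrame({"x": ["b", "a", None]})
        out = pheno.impute_missing(t, ["x"], categorical={"x"})
        assert out["x"].iloc[2] == "a"

    def test_all_missing_rejected(self):
        t = pd.DataFrame({"x": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            pheno.impute_missing(t, ["x"], categorical=set())


class TestMadFilter:
    def test_single_outlier_excluded(self):
        # median 3, MAD 1, bound 5 -> 100 is out, the rest in
        keep = pheno.mad_filter(np.array([1, 2, 3, 4, 100.0]), k=5)
        assert keep.tolist() == [True, True, True, True, False]

    def test_constant_vector_all_kept(self):
        keep = pheno.mad_filter(np.full(10, 7.0), k=5)
        assert keep.all()

    def test_mad_zero_keeps_only_median(self):
        keep = pheno.mad_filter(np.array([5.0, 5, 5, 5, 9]), k=5)
        assert keep.tolist() == [True, True, True, True, False]

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50),
           st.floats(0.5, 10))
    def test_agrees_with_direct_definition(self, values, k):
        x = np.asarray(values)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            expected = x == med
        else:
            expected = np.abs(x - med) <= k * mad
        np.testing.assert_array_equal(pheno.mad_filter(x, k), expected)


class TestLogTransform:
    def test_pack_years_zero_anchor(self):
        assert pheno.log_transform(np.array([0.0, 10.0]), shift=1.0)[0] == 0.0

    def test_negative_support_anchor(self):
        y = pheno.log_transform(np.array([-6.0, 0.0, 3.0]))
        assert y[0] == 0.0  # shift = 1 - (-6) = 7 maps the minimum to ln(1)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=30, unique=True))
    def test_monotonicity_preserved(self, values):
        x = np.asarray(values)
        y = pheno.log_transform(x)
        assert np.all(np.diff(y[np.argsort(x)]) >= 0)


class TestPackYears:
    @pytest.mark.parametrize("cigs,years,expected", [
        (20, 10, 10.0), (0, 30, 0.0), (10, 30, 15.0),
    ])
    def test_formula(self, cigs, years, expected):
        assert pheno.pack_years(cigs, years) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pheno.pack_years(-1, 5)


class TestDeconfound:
    def test_exact_linear_gives_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((50, 3)))
        y = 2 + X @ [1.0, -2.0, 0.5]
        resid = pheno.deconfound(y, X)
        assert np.abs(resid).max() < 1e-10

    def test_orthogonal_covariates_demean_only(self):
        n = 40
        y = np.arange(n, dtype=float)
        X = pd.DataFrame({"c": np.tile([1.0, -1.0], n // 2)})
        X["c"] -= X["c"].mean()
        y_centred = y - y.mean()
        y_orth = y_centred - (y_centred @ X["c"]) / (X["c"] @ X["c"]) * X["c"]
        resid = pheno.deconfound(y_orth + y.mean(), X)
        np.testing.assert_allclose(resid, y_orth, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 60
            X = pd.DataFrame(rng.standard_normal((n, 4)))
            y = rng.standard_normal(n)
            resid = pheno.deconfound(y, X)
            for j in range(4):
                assert abs(resid @ X[j]) <= 1e-8 * n

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.standard_normal(30)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="b"):
            pheno.deconfound(rng.standard_normal(30), X)


class TestIntTransform:
    def test_blom_values_n3(self):
        y = pheno.int_transform(np.array([10.0, -3.0, 5.0]))
        q = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        expected = (q - q.mean()) / q.std()
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_normalisation(self):
        y = pheno.int_transform(np.random.default_rng(3).uniform(size=200))
        assert abs(y.mean()) < 1e-10
        assert abs(y.std() - 1) < 1e-10

    def test_rank_order_preserved(self):
        x = np.array([3.0, -1.0, 7.0, 0.0])
        y = pheno.int_transform(x)
        np.testing.assert_array_equal(np.argsort(x), np.argsort(y))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pheno.int_transform(np.full(5, 1.0))


class TestBhFdr:
    def test_step_up_example(self):
        q = pheno.bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(pheno.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_single(self):
        assert pheno.bh_fdr([0.3])[0] == pytest.approx(0.3)

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=25))
    def test_matches_brute_force_step_up(self, pvals):
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(pheno.bh_fdr(p), expected, atol=1e-12)


class TestAsymmetry:
    def test_printed_value_convention(self):
        # the one-sided upper tail at z = 1.74 rounds to 0.04
        _, p = pheno.asymmetry_z(0.30, 0.1, 0.30 - 1.74 * np.sqrt(0.02), 0.1)
        z, _ = pheno.asymmetry_z(1.74, 1.0, 0.0, 0.0 + 1e-12)
        assert round(float(stats.norm.sf(1.74)), 2) == 0.04
        assert round(p, 2) == 0.04

    def test_symmetric_betas(self):
        z, p = pheno.asymmetry_z(0.2, 0.05, 0.2, 0.05)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_doubling_ses_halves_z(self):
        z1, _ = pheno.asymmetry_z(0.3, 0.05, 0.1, 0.05)
        z2, _ = pheno.asymmetry_z(0.3, 0.10, 0.1, 0.10)
        assert z2 == pytest.approx(z1 / 2)


class TestAssociation:
    def test_recovery_of_injected_effect(self):
        betas = []
        for seed in range(5):
            eff = {"qsm_putamen_L": {"current": 0.3}}
            table, _ = simulate_cohort(CohortSpec(n=5000, effects=eff), seed=seed)
            prep = pheno.prepare_table(table)
            betas.append(pheno.fit_association(
                prep, "qsm_putamen_L", "current_vs_never")[0].beta)
        assert np.mean(betas) == pytest.approx(0.3, abs=0.1)

    def test_null_pvalues_uniform(self):
        pvals = []
        for seed in range(60):
            table, _ = simulate_cohort(CohortSpec(n=400), seed=1000 + seed)
            prep = pheno.prepare_table(table)
            pvals.append(pheno.fit_association(
                prep, "t2s_caudate_R", "ever_smoked")[0].pval)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_contrast_equivalence_without_former(self):
        table, _ = simulate_cohort(CohortSpec(n=2000), seed=5)
        table = table[table["smoking_status"] != "former"].reset_index(drop=True)
        prep = pheno.prepare_table(table)
        a = pheno.fit_association(prep, "qsm_caudate_L", "current_vs_never")[0]
        b = pheno.fit_association(prep, "qsm_caudate_L", "ever_smoked")[0]
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_interaction_row_returned(self):
        table, _ = simulate_cohort(CohortSpec(n=2000), seed=6)
        prep = pheno.prepare_table(table)
        res = pheno.fit_association(prep, "qsm_putamen_R", "ever_smoked",
                                    interaction="sex")
        assert len(res) == 2
        assert res[1].predictor == "ever_smoked:sex"

    def test_battery_shape_and_fdr_monotone(self):
        table, _ = simulate_cohort(CohortSpec(n=1200), seed=7)
        res = pheno.association_battery(table)
        assert len(res) == 12 * 6
        assert (res["qval"] >= res["pval"] - 1e-12).all()


class TestDeconfoundingPipeline:
    def test_confounder_driven_association_centred_on_zero(self):
        """A confounder driving both smoking and the trait, with no direct
        effect, must leave the post-residualisation estimate centred on 0."""
        betas = []
        for seed in range(100):
            spec = CohortSpec(n=800, effects={}, confounding_smoking=0.8,
                              confounder_trait_effect=0.5)
            table, _ = simulate_cohort(spec, seed=2000 + seed)
            prep = pheno.prepare_table(table)
            betas.append(pheno.fit_association(
                prep, "qsm_caudate_L", "ever_smoked")[0].beta)
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 2 * betas.std() / np.sqrt(len(betas))

    def test_effect_grid_ordered(self):
        """Simulated effects {0, 0.1, 0.3} on three traits come back in
        the right order in nearly all cohorts at n = 5000."""
        correct = 0
        n_seeds = 20
        for seed in range(n_seeds):
            eff = {
                "qsm_putamen_L": {"current": 0.3, "former": 0.3},
                "qsm_caudate_L": {"current": 0.1, "former": 0.1},
                "qsm_accumbens_L": {},
            }
            table, _ = simulate_cohort(CohortSpec(n=5000, effects=eff),
                                       seed=3000 + seed)
            prep = pheno.prepare_table(table)
            b = [pheno.fit_association(prep, t, "ever_smoked")[0].beta
                 for t in ("qsm_accumbens_L", "qsm_caudate_L", "qsm_putamen_L")]
            correct += int(b[0] < b[1] < b[2])
        assert correct >= int(0.9 * n_seeds)


class TestFormerSmokerModel:
    def test_cessation_slope_recovery(self):
        betas = []
        for seed in range(3):
            eff = {"qsm_putamen_L": {"cessation": -0.1}}
            table, _ = simulate_cohort(CohortSpec(n=5000, effects=eff), seed=seed)
            prep = pheno.prepare_table(table)
            betas.append(pheno.former_smoker_model(prep, "qsm_putamen_L")[0].beta)
        assert np.mean(betas) == pytest.approx(-0.1, abs=0.05)

    def test_rank_invariance_to_constant_shift(self):
        table, _ = simulate_cohort(CohortSpec(n=3000), seed=8)
        prep_a = pheno.prepare_table(table)
        shifted = table.copy()
        shifted["cessation_years"] = shifted["cessation_years"] + 100.0
        prep_b = pheno.prepare_table(shifted)
        ra = pheno.former_smoker_model(prep_a, "t2s_putamen_L")
        rb = pheno.former_smoker_model(prep_b, "t2s_putamen_L")
        for a, b in zip(ra, rb):
            assert a.beta == pytest.approx(b.beta, abs=1e-9)


class TestRobustness:
    def _results(self, betas, qvals):
        return pd.DataFrame({
            "trait": [f"t{i}" for i in range(len(betas))],
            "predictor": "ever_smoked",
            "beta": betas, "qval": qvals,
        })

    def test_identical_runs(self):
        r = self._results([0.1, 0.2, 0.3], [0.01, 0.2, 0.04])
        m = pheno.robustness(r, r)
        assert m.beta_correlation == pytest.approx(1.0)
        assert m.jaccard == 1.0

    def test_disjoint_significant_sets(self):
        a = self._results([0.1, 0.2, -0.1], [0.01, 0.5, 0.9])
        b = self._results([0.2, 0.1, -0.2], [0.9, 0.01, 0.8])
        assert pheno.robustness(a, b).jaccard == 0.0

    def test_hand_built_overlap(self):
        a = self._results([0.1, 0.2, 0.3, 0.4, 0.5], [0.01, 0.01, 0.5, 0.01, 0.9])
        b = self._results([0.1, 0.2, 0.3, 0.4, 0.5], [0.01, 0.9, 0.5, 0.01, 0.01])
        # significant: A={0,1,3}, B={0,3,4}; intersection 2, union 4
        assert pheno.robustness(a, b).jaccard == pytest.approx(0.5)

    def test_misaligned_rejected(self):
        a = self._results([0.1], [0.01])
        b = self._results([0.1, 0.2], [0.01, 0.2])
        with pytest.raises(ValueError):
            pheno.robustness(a, b)

    def test_both_empty_sets_missing(self):
        a = self._results([0.1, 0.2], [0.9, 0.8])
        assert np.isnan(pheno.robustness(a, a).jaccard)
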