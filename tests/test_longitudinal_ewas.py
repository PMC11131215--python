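"""Regression-engine correctness: OLS oracle, BH oracle, calibration, stratification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from longewas.core_io import CellFractions, MethylationMatrix, ValidationError
from longewas.longitudinal_ewas import (
    bh_fdr,
    compare_cpg_list_significance,
    effect_concordance,
    fit_cross_sectional_ewas,
    fit_delta_ewas,
    inverse_normal_transform,
    select_top_cpgs,
    stratified_ewas,
)
from longewas.qc_preprocess import compute_delta_matrix
from longewas.synthetic_cohort import SimulationConfig, simulate_cohort


def brute_force_bh(p):
    """Independent BH oracle: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _pheno(rng, n, cohort="c1"):
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    b0 = rng.normal(24, 3, n).clip(16)
    deg = rng.normal(0.03, 0.07, n)
    return pd.DataFrame({
        "cohort": cohort, "sex": sex,
        "age": rng.normal(60, 8, n).clip(45),
        "interval_years": rng.normal(4, 0.3, n).clip(1),
        "bmi_baseline": b0, "bmi_followup": b0 * (1 + deg),
        "smoking": rng.integers(0, 2, n), "drinking": rng.integers(0, 2, n),
    }, index=pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id"))


def _fracs(rng, index, cells=("B", "CD4T", "Neutro")):
    raw = rng.dirichlet(np.ones(len(cells)) * 20, size=len(index))
    return CellFractions(fractions=pd.DataFrame(raw, index=index, columns=list(cells)))


class TestOlsEngine:
    def test_matches_normal_equations_oracle_to_1e10(self, rng):
        n, n_probes = 60, 25
        pheno = _pheno(rng, n)
        fracs = _fracs(rng, pheno.index)
        Y = rng.normal(0, 0.02, size=(n_probes, n))
        delta = pd.DataFrame(Y, index=[f"cg{i}" for i in range(n_probes)], columns=pheno.index)
        res = fit_delta_ewas(delta, pheno, fracs).set_index("probe_id")

        x = ((pheno["bmi_followup"] - pheno["bmi_baseline"]) / pheno["bmi_baseline"]).to_numpy()
        X = np.column_stack([
            np.ones(n), x, pheno["age"], pheno["interval_years"],
            (pheno["sex"] == "male").astype(float),
            fracs.fractions[["B", "CD4T"]].to_numpy(),  # Neutro dropped
        ])
        XtX_inv = np.linalg.inv(X.T @ X)
        p_cols = X.shape[1]
        for i in range(n_probes):
            y = Y[i]
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (n - p_cols)
            se = np.sqrt(s2 * XtX_inv[1, 1])
            row = res.loc[f"cg{i}"]
            assert abs(row["effect"] - beta[1]) < 1e-10
            assert abs(row["se"] - se) < 1e-10
            t = beta[1] / se
            assert abs(row["p_value"] - 2 * stats.t.sf(abs(t), n - p_cols)) < 1e-10
            assert row["n_used"] == n

    def test_spiked_slope_recovered_within_3_se(self, rng):
        n = 1000
        pheno = _pheno(rng, n)
        x = ((pheno["bmi_followup"] - pheno["bmi_baseline"]) / pheno["bmi_baseline"]).to_numpy()
        y = 0.5 * x + rng.normal(0, 0.02, n)
        delta = pd.DataFrame([y], index=["cg_spike"], columns=pheno.index)
        res = fit_delta_ewas(delta, pheno, None)
        row = res.iloc[0]
        assert abs(row["effect"] - 0.5) < 3 * row["se"]

    def test_missing_values_reduce_n_used_not_crash(self, rng):
        pheno = _pheno(rng, 40)
        Y = rng.normal(0, 0.02, size=(3, 40))
        Y[0, :5] = np.nan
        Y[1] = np.nan  # too few complete cases -> missing result
        delta = pd.DataFrame(Y, index=["a", "b", "c"], columns=pheno.index)
        res = fit_delta_ewas(delta, pheno, None).set_index("probe_id")
        assert res.loc["a", "n_used"] == 35
        assert np.isnan(res.loc["b", "p_value"])
        assert res.loc["c", "n_used"] == 40

    def test_zero_variance_phenotype_errors(self, rng):
        pheno = _pheno(rng, 30)
        pheno["bmi_followup"] = pheno["bmi_baseline"]
        delta = pd.DataFrame(rng.normal(size=(2, 30)) * 0.01,
                             index=["a", "b"], columns=pheno.index)
        with pytest.raises(ValidationError, match="zero variance"):
            fit_delta_ewas(delta, pheno, None)

    def test_lifestyle_covariates_keep_n_used(self, rng):
        pheno = _pheno(rng, 50)
        delta = pd.DataFrame(rng.normal(0, 0.02, size=(4, 50)),
                             index=list("abcd"), columns=pheno.index)
        base = fit_delta_ewas(delta, pheno, None)
        sec = fit_delta_ewas(delta, pheno, None, adjust_lifestyle=True)
        assert (base["n_used"] == sec["n_used"]).all()
        assert set(sec["model_tag"]) == {"delta_secondary"}

    def test_moderated_variance_shrinks_se_spread(self, rng):
        pheno = _pheno(rng, 50)
        delta = pd.DataFrame(rng.normal(0, 0.02, size=(200, 50)),
                             index=[f"cg{i}" for i in range(200)], columns=pheno.index)
        plain = fit_delta_ewas(delta, pheno, None)
        mod = fit_delta_ewas(delta, pheno, None, moderate_variance=True)
        assert mod["se"].std() < plain["se"].std()
        assert mod["p_value"].notna().sum() == plain["p_value"].notna().sum()


class TestCrossSectional:
    def test_visit_bookkeeping(self, rng):
        pheno = _pheno(rng, 80)
        betas = rng.uniform(0.2, 0.8, size=(5, 80))
        m = MethylationMatrix(betas=pd.DataFrame(
            betas, index=[f"cg{i}" for i in range(5)], columns=pheno.index))
        res_b = fit_cross_sectional_ewas(m, pheno, None, visit="baseline")
        res_f = fit_cross_sectional_ewas(m, pheno, None, visit="followup")
        assert not np.allclose(res_b["effect"], res_f["effect"])
        assert set(res_b["model_tag"]) == {"cross_sectional"}

    def test_constant_probe_gets_missing_result(self, rng):
        pheno = _pheno(rng, 40)
        betas = np.vstack([np.full(40, 0.5), rng.uniform(0.2, 0.8, 40)])
        m = MethylationMatrix(betas=pd.DataFrame(betas, index=["const", "ok"],
                                                 columns=pheno.index))
        res = fit_cross_sectional_ewas(m, pheno, None).set_index("probe_id")
        assert np.isnan(res.loc["const", "p_value"])
        assert np.isfinite(res.loc["ok", "p_value"])


class TestBhFdr:
    def test_all_permutations_of_six_match_brute_force(self):
        base = np.array([0.001, 0.008, 0.039, 0.041, 0.27, 0.9])
        for perm in itertools.permutations(base):
            np.testing.assert_allclose(bh_fdr(list(perm)), brute_force_bh(list(perm)),
                                       atol=1e-12)

    def test_hand_examples(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12)
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_rank_one_inversion_at_published_scale(self):
        # smallest p among m = 713068 tests: q = m * p at rank 1
        m = 713_068
        p = np.concatenate([[3.52e-9], np.linspace(0.5, 1.0, m - 1)])
        q = bh_fdr(p)
        assert q[0] == pytest.approx(2.51e-3, rel=1e-3)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_oracle_on_random_vectors(self, p):
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_nan_aware(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and np.isfinite(q[0])
        with pytest.raises(ValidationError):
            bh_fdr([1.5])


class TestStratified:
    def test_single_sex_data_equals_sexless_pooled_fit(self, rng):
        pheno = _pheno(rng, 60)
        pheno["sex"] = "male"
        delta = pd.DataFrame(rng.normal(0, 0.02, size=(10, 60)),
                             index=[f"cg{i}" for i in range(10)], columns=pheno.index)
        strat = stratified_ewas(delta, pheno, None, "male")
        pooled = fit_delta_ewas(delta, pheno, None, _include_sex=False, model_tag="male")
        pd.testing.assert_frame_equal(strat, pooled)

    def test_empty_stratum_errors(self, rng):
        pheno = _pheno(rng, 30)
        pheno["sex"] = "male"
        delta = pd.DataFrame(rng.normal(size=(2, 30)), index=["a", "b"], columns=pheno.index)
        with pytest.raises(ValidationError, match="female"):
            stratified_ewas(delta, pheno, None, "female")

    def test_sex_specific_effect_detected_only_in_that_stratum(self, rng):
        n = 600
        pheno = _pheno(rng, n)
        x = ((pheno["bmi_followup"] - pheno["bmi_baseline"]) / pheno["bmi_baseline"]).to_numpy()
        male = (pheno["sex"] == "male").to_numpy(dtype=float)
        y = 0.5 * x * male + rng.normal(0, 0.02, n)
        delta = pd.DataFrame([y], index=["cg_male_only"], columns=pheno.index)
        res_m = stratified_ewas(delta, pheno, None, "male")
        res_f = stratified_ewas(delta, pheno, None, "female")
        assert res_m["p_value"].iloc[0] < 1e-6
        assert res_f["p_value"].iloc[0] > 1e-3


class TestConcordanceAndComparison:
    def _results(self, effects, probes=None):
        probes = probes or [f"cg{i}" for i in range(len(effects))]
        return pd.DataFrame({"probe_id": probes, "effect": effects,
                             "se": 1.0, "t_stat": effects, "p_value": 0.5,
                             "fdr": 0.5, "n_used": 10, "model_tag": "delta"})

    def test_self_concordance_is_one(self, rng):
        res = self._results(rng.normal(size=50))
        r, n = effect_concordance(res, res)
        assert r == pytest.approx(1.0) and n == 50

    def test_independent_nulls_are_uncorrelated(self, rng):
        a = self._results(rng.normal(size=2000))
        b = self._results(rng.normal(size=2000))
        r, _ = effect_concordance(a, b)
        assert abs(r) < 0.1

    def test_constant_effects_error(self):
        res = self._results([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="constant"):
            effect_concordance(res, res)

    def test_cpg_list_null_p_is_uniform_over_replicates(self, rng):
        probes = [f"cg{i:05d}" for i in range(2000)]
        pvals = rng.random(2000)
        res = pd.DataFrame({"probe_id": probes, "p_value": pvals})
        reps = []
        for seed in range(200):
            pick = np.random.default_rng(10_000 + seed).choice(probes, 50, replace=False)
            _, p = compare_cpg_list_significance(res, list(pick), n_random=200, seed=seed)
            reps.append(p)
        assert stats.kstest(reps, "uniform").pvalue > 0.01

    def test_causal_list_is_more_significant_than_random(self):
        cfg = SimulationConfig(n_samples=200, n_probes=800, n_causal=5, seed=9)
        m0, m1, pheno, truth = simulate_cohort(cfg)
        res = fit_delta_ewas(compute_delta_matrix(m0, m1), pheno, truth.true_cell_fractions)
        t, p = compare_cpg_list_significance(res, truth.causal_probe_ids,
                                             n_random=200, seed=1)
        assert p < 1e-3 and t > 0

    def test_empty_list_errors(self):
        res = self._results([0.1, 0.2, 0.3])
        with pytest.raises(ValidationError, match="empty"):
            compare_cpg_list_significance(res, [])


class TestTopCpgSelection:
    def _results(self, pvals, probes):
        return pd.DataFrame({"probe_id": probes, "p_value": pvals})

    def test_truncates_to_k_smallest(self, rng):
        p = np.concatenate([rng.uniform(1e-9, 9e-6, 25), rng.uniform(0.1, 1, 75)])
        probes = [f"cg{i:03d}" for i in range(100)]
        top = select_top_cpgs(self._results(p, probes))
        assert len(top) == 20
        assert set(top) == set(np.array(probes)[np.argsort(p)[:20]])

    def test_returns_all_when_fewer_pass(self):
        top = select_top_cpgs(self._results([1e-7, 2e-6, 0.5, 0.9, 1e-4], list("abcde")))
        assert top == ["a", "b"]

    def test_tie_broken_lexicographically(self):
        top = select_top_cpgs(self._results([1e-7, 1e-7, 1e-7], ["cgB", "cgA", "cgC"]), k=2)
        assert top == ["cgA", "cgB"]


def test_inverse_normal_transform_is_rank_preserving_and_gaussian(rng):
    x = pd.Series(rng.exponential(size=500) ** 2)
    z = inverse_normal_transform(x)
    assert (z.rank() == x.rank()).all()
    assert abs(z.mean()) < 0.05 and abs(z.std() - 1) < 0.05
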