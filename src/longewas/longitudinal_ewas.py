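"""Per-CpG regression engines for the longitudinal and cross-sectional EWAS.

The longitudinal model regresses each probe's methylation change on the BMI
change degree with baseline covariates:

    delta_M_i = b0 + b_S * dBMI_i + b_age * age_i + b_ageing * interval_i
                + b_sex * sex_i + gamma . cellfractions_i  (+ smoking, drinking)

fitted by ordinary least squares probe by probe (complete cases), with
two-sided p-values from the t distribution on n - p degrees of freedom and
Benjamini-Hochberg FDR across probes. One cell type (neutrophils, the
majority type, by default) is dropped from the design to avoid collinearity
with the intercept since fractions sum to one.

An optional moderated-variance mode shrinks per-probe residual variances
toward a pooled inverse-chi-square prior fitted by moment matching on the
log variances (empirical-Bayes moderated t with augmented degrees of
freedom), for users who want limma-style behaviour; plain OLS is the
reference engine.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.linalg import solve_triangular
from statsmodels.stats.multitest import multipletests

from .core_io import CellFractions, MethylationMatrix, ValidationError, sex_to_numeric
from .qc_preprocess import compute_bmi_change_degree

log = logging.getLogger(__name__)

DEFAULT_DROP_CELL_TYPE = "Neutro"


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, missing-aware.

    Missing p-values are excluded from the number of tests and get missing
    q-values; all others map back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(np.isfinite(p) & ((p < 0) | (p > 1))):
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def inverse_normal_transform(x: pd.Series) -> pd.Series:
    """Rank-based inverse normal transform (offset 0.5, average ranks for ties)."""
    ranks = x.rank(method="average")
    return pd.Series(stats.norm.ppf((ranks - 0.5) / x.notna().sum()), index=x.index, name=x.name)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for trigamma^{-1}, after the standard moderated-t recipe
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _squeeze_variances(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit the scale (s0^2) and prior df (d0) of the pooled variance prior.

    Moment matching on log residual variances; returns (d0, s0^2) with
    d0 = inf when the observed log-variances are underdispersed relative to
    pure chi-square sampling noise.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def _fit_per_probe(
    Y: np.ndarray, X: np.ndarray, coef_idx: int, min_extra: int = 2,
    moderate_variance: bool = False,
) -> pd.DataFrame:
    """Batched OLS of each row of ``Y`` (probes x samples) on the design ``X``.

    Probes are grouped by their missingness pattern so each distinct pattern
    costs one QR factorisation. Probes with fewer complete cases than design
    columns + ``min_extra``, or with constant response, get missing results.
    """
    n_probes, n_samples = Y.shape
    p = X.shape[1]
    eff = np.full(n_probes, np.nan)
    se = np.full(n_probes, np.nan)
    s2_arr = np.full(n_probes, np.nan)
    cjj_arr = np.full(n_probes, np.nan)
    dof_arr = np.full(n_probes, np.nan)
    n_used = np.zeros(n_probes, dtype=int)

    mask = np.isfinite(Y)
    patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
    for g in range(patterns.shape[0]):
        cols = patterns[g]
        rows = np.flatnonzero(inverse == g)
        n = int(cols.sum())
        if n < p + min_extra:
            continue
        Xs = X[cols]
        Q, R = np.linalg.qr(Xs)
        diag = np.abs(np.diag(R))
        if diag.min() <= 1e-10 * max(diag.max(), 1.0):
            continue  # rank-deficient for this pattern
        Ys = Y[np.ix_(rows, cols)].T  # n x k
        const = (Ys.max(axis=0) - Ys.min(axis=0)) == 0.0
        B = solve_triangular(R, Q.T @ Ys)
        resid = Ys - Xs @ B
        dof = n - p
        s2 = (resid**2).sum(axis=0) / dof
        Rinv = solve_triangular(R, np.eye(p))
        cjj = float((Rinv[coef_idx] ** 2).sum())
        keep = ~const
        idx = rows[keep]
        eff[idx] = B[coef_idx, keep]
        s2_arr[idx] = s2[keep]
        cjj_arr[idx] = cjj
        dof_arr[idx] = dof
        n_used[idx] = n

    if moderate_variance:
        d0, s02 = _squeeze_variances(s2_arr, dof_arr)
        if np.isinf(d0):
            s2_post = np.full_like(s2_arr, s02)
            dof_total = np.full_like(dof_arr, np.inf)
        else:
            s2_post = (d0 * s02 + dof_arr * s2_arr) / (d0 + dof_arr)
            dof_total = dof_arr + d0
    else:
        s2_post, dof_total = s2_arr, dof_arr

    se = np.sqrt(s2_post * cjj_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / se
    pvals = np.full(n_probes, np.nan)
    ok = np.isfinite(t) & np.isfinite(dof_total)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), dof_total[ok])
    inf_t = np.isfinite(eff) & np.isfinite(dof_total) & ~np.isfinite(t) & (se == 0.0)
    pvals[inf_t] = 0.0  # zero residual variance with a nonzero effect
    norm_ok = np.isfinite(t) & np.isinf(dof_total)
    pvals[norm_ok] = 2.0 * stats.norm.sf(np.abs(t[norm_ok]))
    return pd.DataFrame({
        "effect": eff, "se": se, "t_stat": t, "p_value": pvals, "n_used": n_used,
    })


def _assemble(
    y_frame: pd.DataFrame,
    design: pd.DataFrame,
    coef: str,
    *,
    model_tag: str,
    moderate_variance: bool = False,
) -> pd.DataFrame:
    samples = [s for s in y_frame.columns if s in design.index]
    if not samples:
        raise ValidationError("no samples shared between methylation data and covariates")
    design = design.loc[samples]
    complete = design.notna().all(axis=1)
    design = design.loc[complete]
    samples = list(design.index)
    X = design.to_numpy(dtype=float)
    x = design[coef].to_numpy()
    if np.ptp(x[np.isfinite(x)]) == 0:
        raise ValidationError(f"phenotype {coef!r} has zero variance")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank-deficient; check covariates")
    Y = y_frame[samples].to_numpy(dtype=float)
    fit = _fit_per_probe(Y, X, coef_idx=design.columns.get_loc(coef),
                         moderate_variance=moderate_variance)
    fit.insert(0, "probe_id", y_frame.index.to_numpy())
    fit["fdr"] = bh_fdr(fit["p_value"].to_numpy())
    fit["model_tag"] = model_tag
    from .core_io import EWAS_RESULT_COLUMNS
    return fit[EWAS_RESULT_COLUMNS]


def _cell_columns(fracs: CellFractions | pd.DataFrame | None,
                  drop_cell_type: str | None) -> pd.DataFrame | None:
    if fracs is None:
        return None
    frame = fracs.fractions if isinstance(fracs, CellFractions) else fracs
    cols = list(frame.columns)
    if drop_cell_type is None:
        drop = cols[-1]
    elif drop_cell_type in cols:
        drop = drop_cell_type
    else:
        drop = cols[-1]
    return frame.drop(columns=drop)


# ---------------------------------------------------------------------------
# Public model fits
# ---------------------------------------------------------------------------

def fit_delta_ewas(
    delta_m: pd.DataFrame,
    pheno: pd.DataFrame,
    fracs: CellFractions | pd.DataFrame | None,
    *,
    adjust_lifestyle: bool = False,
    moderate_variance: bool = False,
    inverse_normal: bool = False,
    annualize: bool = False,
    drop_cell_type: str | None = DEFAULT_DROP_CELL_TYPE,
    _include_sex: bool = True,
    model_tag: str | None = None,
) -> pd.DataFrame:
    """Fit the per-CpG longitudinal change model and return an EWAS result table.

    ``delta_m`` is the probes x samples methylation-change matrix; ``fracs``
    may be None to fit without cell-composition adjustment (used to
    demonstrate confounding inflation). ``adjust_lifestyle`` adds smoking and
    drinking covariates (the secondary model); ``inverse_normal`` applies a
    rank-based inverse normal transform to the BMI change degree.
    """
    degree = compute_bmi_change_degree(pheno, annualize=annualize)
    if inverse_normal:
        degree = inverse_normal_transform(degree)
    design = pd.DataFrame({"intercept": 1.0, "dbmi_degree": degree,
                           "age": pheno["age"].astype(float),
                           "interval_years": pheno["interval_years"].astype(float)},
                          index=pheno.index)
    if _include_sex:
        design["sex"] = sex_to_numeric(pheno["sex"])
    cells = _cell_columns(fracs, drop_cell_type)
    if cells is not None:
        design = design.join(cells, how="inner")
    if adjust_lifestyle:
        design["smoking"] = pheno["smoking"].astype(float)
        design["drinking"] = pheno["drinking"].astype(float)
    tag = model_tag or ("delta_secondary" if adjust_lifestyle else "delta")
    return _assemble(delta_m, design, "dbmi_degree", model_tag=tag,
                     moderate_variance=moderate_variance)


def fit_cross_sectional_ewas(
    m: MethylationMatrix,
    pheno: pd.DataFrame,
    fracs: CellFractions | pd.DataFrame | None,
    visit: str = "baseline",
    *,
    moderate_variance: bool = False,
    drop_cell_type: str | None = DEFAULT_DROP_CELL_TYPE,
) -> pd.DataFrame:
    """Per-CpG regression of beta on BMI at one visit, adjusting sex, age, cells.

    At follow-up the age covariate is baseline age plus the interval years.
    """
    if visit not in ("baseline", "followup"):
        raise ValidationError("visit must be 'baseline' or 'followup'")
    bmi = pheno[f"bmi_{visit}"].astype(float)
    age = pheno["age"].astype(float)
    if visit == "followup":
        age = age + pheno["interval_years"].astype(float)
    design = pd.DataFrame({"intercept": 1.0, "bmi": bmi, "age": age,
                           "sex": sex_to_numeric(pheno["sex"])}, index=pheno.index)
    cells = _cell_columns(fracs, drop_cell_type)
    if cells is not None:
        design = design.join(cells, how="inner")
    return _assemble(m.betas, design, "bmi", model_tag="cross_sectional",
                     moderate_variance=moderate_variance)


def stratified_ewas(
    delta_m: pd.DataFrame,
    pheno: pd.DataFrame,
    fracs: CellFractions | pd.DataFrame | None,
    stratum: str,
    **kwargs,
) -> pd.DataFrame:
    """Longitudinal model within one sex stratum, with the sex column removed."""
    if stratum not in ("male", "female"):
        raise ValidationError("stratum must be 'male' or 'female'")
    sub = pheno[pheno["sex"] == stratum]
    if sub.empty:
        raise ValidationError(f"no samples in stratum {stratum!r}")
    if isinstance(fracs, CellFractions):
        fracs = fracs.fractions
    if fracs is not None:
        fracs = fracs.loc[fracs.index.intersection(sub.index)]
    cols = [s for s in delta_m.columns if s in sub.index]
    return fit_delta_ewas(delta_m[cols], sub, fracs, _include_sex=False,
                          model_tag=stratum, **kwargs)


def effect_concordance(res_a: pd.DataFrame, res_b: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation of effect estimates over shared probes with finite effects."""
    a = res_a.set_index("probe_id")["effect"]
    b = res_b.set_index("probe_id")["effect"]
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValidationError("need at least 3 shared probes with finite effects")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("effect estimates are constant; correlation undefined")
    r, _ = stats.pearsonr(a, b)
    return float(r), int(len(a))


def compare_cpg_list_significance(
    results: pd.DataFrame,
    cpg_list: Sequence[str],
    n_random: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample t-test of -log10(p) for listed CpGs vs randomly drawn CpGs.

    The random CpGs are sampled uniformly without replacement from the probes
    not on the list. Returns (t statistic, two-sided p); reproducible from
    ``seed``. Used to ask whether a published CpG list is collectively more
    significant in these results than chance.
    """
    if len(cpg_list) == 0:
        raise ValidationError("cpg_list is empty")
    tab = results.set_index("probe_id")["p_value"]
    listed = tab.reindex(pd.Index(cpg_list).unique()).dropna()
    if listed.empty:
        raise ValidationError("none of the listed CpGs are present with finite p-values")
    pool = tab.drop(index=listed.index, errors="ignore").dropna()
    if len(pool) < n_random:
        raise ValidationError(
            f"only {len(pool)} probes remain outside the list; cannot sample {n_random}")
    rng = np.random.default_rng(seed)
    sampled = pool.iloc[rng.choice(len(pool), size=n_random, replace=False)]
    eps = np.finfo(float).tiny
    t, p = stats.ttest_ind(-np.log10(listed + eps), -np.log10(sampled + eps), equal_var=False)
    return float(t), float(p)


def select_top_cpgs(
    results: pd.DataFrame, p_threshold: float = 1e-5, k: int = 20
) -> list[str]:
    """Probes with p below the loosened threshold, best-k by p (ties by probe id)."""
    if results.empty:
        raise ValidationError("results table is empty")
    sub = results[results["p_value"] < p_threshold]
    sub = sub.sort_values(["p_value", "probe_id"], kind="mergesort")
    return sub["probe_id"].head(k).tolist()
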