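"""Sample-size-weighted z-score meta-analysis with heterogeneity statistics.

Per study, a signed z-statistic is derived from the two-sided p-value and the
effect direction: z_k = sign_k * Phi^{-1}(1 - p_k / 2). Studies combine as

    eta = sum_k w_k z_k,     Var(eta) = sum_k w_k^2 V_k,

with w_k proportional to sqrt(n_k) and chosen so the squared weights sum to
one; V_k = 1 for unit-variance z-scores (unequal V_k may be supplied). The
combined two-sided p is 2 * Phi(-|eta| / sqrt(Var)). Heterogeneity across
studies is Cochran's Q on the per-study z-scale effects with the combination
weights, and I^2 = (Q - df) / Q clipped to [0, 1].

When a per-study p-value underflows double precision, the z-score is taken
from the study's regression t-statistic directly (normal approximation).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import META_RESULT_COLUMNS, ValidationError

log = logging.getLogger(__name__)

_P_UNDERFLOW = 5e-324  # smallest subnormal double; below this isf returns inf


def per_study_z(p_value: float, effect_sign: int) -> float:
    """Signed z from a two-sided p: z = sign * Phi^{-1}(1 - p/2).

    ``p_value`` must lie in (0, 1]; a p of exactly zero underflows the normal
    quantile and must instead be converted from the study's t-statistic.
    """
    if not 0.0 < p_value <= 1.0:
        raise ValidationError(f"p-value must be in (0, 1], got {p_value!r}")
    if effect_sign not in (1, -1, +1.0, -1.0):
        raise ValidationError("effect_sign must be +1 or -1")
    return float(effect_sign) * float(stats.norm.isf(p_value / 2.0))


def meta_weights(n_per_study: Sequence[float]) -> np.ndarray:
    """Weights proportional to sqrt(n), normalised so the squared weights sum to 1."""
    n = np.asarray(n_per_study, dtype=float)
    if n.size == 0:
        raise ValidationError("need at least one study")
    if np.any(n <= 0):
        raise ValidationError("study sizes must be positive")
    return np.sqrt(n / n.sum())


def combine_z(
    z_per_study: Sequence[float],
    n_per_study: Sequence[float],
    v_per_study: Sequence[float] | None = None,
) -> dict:
    """Combine per-study signed z-statistics into one weighted z and p.

    Returns a dict with eta (combined z), var, the two-sided p, the weights,
    and the direction string built from the per-study signs in input order
    ('+', '-', or '?' for a missing z).
    """
    z = np.asarray(z_per_study, dtype=float)
    w = meta_weights(n_per_study)
    if z.shape != w.shape:
        raise ValidationError("z_per_study and n_per_study must have equal length")
    v = np.ones_like(z) if v_per_study is None else np.asarray(v_per_study, dtype=float)
    eta = float(np.sum(w * np.where(np.isfinite(z), z, 0.0)))
    var = float(np.sum(w**2 * v))
    p = float(2.0 * stats.norm.sf(abs(eta) / np.sqrt(var)))
    direction = "".join("?" if not np.isfinite(zi) else ("+" if zi > 0 else "-" if zi < 0 else "?")
                        for zi in z)
    return {"z_combined": eta, "var_combined": var, "p_value": p,
            "weights": w, "direction": direction}


def heterogeneity(
    y_per_study: Sequence[float], w_per_study: Sequence[float]
) -> tuple[float, int, float]:
    """Cochran's Q and I-squared over per-study effects with positive weights.

    ybar is the weighted mean effect, Q = sum_k w_k (y_k - ybar)^2,
    df = K - 1, and I^2 = (Q - df)/Q clipped into [0, 1].
    """
    y = np.asarray(y_per_study, dtype=float)
    w = np.asarray(w_per_study, dtype=float)
    if y.size < 2:
        raise ValidationError("heterogeneity needs at least 2 studies")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    df = int(y.size - 1)
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q)
    return q, df, min(i2, 1.0)


def _study_z_vector(res: pd.DataFrame, probes: pd.Index) -> np.ndarray:
    """Signed z per probe, from p and effect sign; t-statistic fallback on underflow."""
    sub = res.set_index("probe_id").reindex(probes)
    p = sub["p_value"].to_numpy(dtype=float)
    sign = np.sign(sub["effect"].to_numpy(dtype=float))
    t = sub["t_stat"].to_numpy(dtype=float) if "t_stat" in sub.columns else np.full(len(sub), np.nan)
    z = np.full(len(sub), np.nan)
    ok = np.isfinite(p) & (p > _P_UNDERFLOW) & np.isfinite(sign) & (sign != 0)
    z[ok] = sign[ok] * stats.norm.isf(p[ok] / 2.0)
    under = np.isfinite(p) & (p <= _P_UNDERFLOW) & np.isfinite(t)
    if under.any():
        log.info("%d probes with underflowing p; z taken from the t-statistic", int(under.sum()))
        z[under] = t[under]
    return z


def run_meta(
    results_by_cohort: Mapping[str, pd.DataFrame],
    n_by_cohort: Mapping[str, float],
) -> pd.DataFrame:
    """Meta-analyse per-cohort EWAS result tables over the union of probes.

    Probes present in only one cohort get a '?' in the direction string and a
    single-study combination (flagged via ``n_studies``); weights are
    renormalised over the studies actually present so the squared weights
    always sum to one.
    """
    cohorts = list(results_by_cohort)
    if not cohorts:
        raise ValidationError("no cohorts supplied")
    missing_n = [c for c in cohorts if c not in n_by_cohort]
    if missing_n:
        raise ValidationError(f"missing sample sizes for cohorts: {missing_n}")
    probe_sets = [pd.Index(results_by_cohort[c]["probe_id"]) for c in cohorts]
    shared = probe_sets[0]
    for s in probe_sets[1:]:
        shared = shared.intersection(s)
    if len(shared) == 0:
        raise ValidationError("no probes shared across cohorts")
    union = probe_sets[0]
    for s in probe_sets[1:]:
        union = union.union(s)
    union = pd.Index(sorted(union))

    K = len(cohorts)
    Z = np.column_stack([_study_z_vector(results_by_cohort[c], union) for c in cohorts])
    n = np.array([float(n_by_cohort[c]) for c in cohorts])
    if np.any(n <= 0):
        raise ValidationError("cohort sample sizes must be positive")
    present = np.isfinite(Z)
    n_eff = present * n[None, :]
    denom = n_eff.sum(axis=1)
    valid = denom > 0
    W = np.zeros_like(Z)
    W[valid] = np.sqrt(n_eff[valid] / denom[valid, None])
    Z0 = np.where(present, Z, 0.0)
    eta = (W * Z0).sum(axis=1)
    var = (W**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(eta) / np.sqrt(var))
    p[~valid] = np.nan
    eta[~valid] = np.nan

    k_present = present.sum(axis=1)
    q = np.full(len(union), np.nan)
    i2 = np.full(len(union), np.nan)
    df = np.where(k_present >= 1, k_present - 1, 0)
    multi = k_present >= 2
    if multi.any():
        wsum = W.sum(axis=1)
        ybar = np.where(multi, (W * Z0).sum(axis=1) / np.where(wsum > 0, wsum, 1.0), np.nan)
        qv = (W * (np.where(present, Z0 - ybar[:, None], 0.0)) ** 2).sum(axis=1)
        q[multi] = qv[multi]
        with np.errstate(invalid="ignore", divide="ignore"):
            i2_raw = (qv - df) / qv
        i2[multi] = np.clip(np.where(qv[multi] > 0, i2_raw[multi], 0.0), 0.0, 1.0)

    direction = ["".join("?" if not present[i, k] else
                         ("+" if Z[i, k] > 0 else "-" if Z[i, k] < 0 else "?")
                         for k in range(K)) for i in range(len(union))]
    out = pd.DataFrame({
        "probe_id": union,
        "z_combined": eta,
        "var_combined": np.where(valid, var, np.nan),
        "p_value": p,
        "direction": direction,
        "q_stat": q,
        "df": df,
        "i_squared": i2,
        "n_studies": k_present,
    })
    for k, c in enumerate(cohorts):
        out[f"z_{c}"] = Z[:, k]
        out[f"w_{c}"] = W[:, k]
    return out[META_RESULT_COLUMNS + [f"z_{c}" for c in cohorts] + [f"w_{c}" for c in cohorts]]


def call_significant(
    meta: pd.DataFrame,
    discovery: pd.DataFrame,
    discovery_threshold: float = 1e-6,
) -> pd.DataFrame:
    """Discovery-significant probes with replication direction consistency and meta p.

    Lists probes whose discovery p falls below the threshold, ordered by meta
    p-value; ``direction_consistent`` is True when every non-missing study
    direction agrees.
    """
    disc = discovery.set_index("probe_id")
    hits = disc.index[disc["p_value"] < discovery_threshold]
    sub = meta.set_index("probe_id").reindex(hits.intersection(meta["probe_id"]))
    consistent = [len({ch for ch in d if ch != "?"}) <= 1 if isinstance(d, str) else False
                  for d in sub["direction"]]
    out = pd.DataFrame({
        "probe_id": sub.index,
        "discovery_p": disc.loc[sub.index, "p_value"].to_numpy(),
        "discovery_effect": disc.loc[sub.index, "effect"].to_numpy(),
        "direction": sub["direction"].to_numpy(),
        "direction_consistent": consistent,
        "meta_p": sub["p_value"].to_numpy(),
        "i_squared": sub["i_squared"].to_numpy(),
    }).sort_values("meta_p", kind="mergesort").reset_index(drop=True)
    return out
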