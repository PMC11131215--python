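"""Reference-based blood cell-type deconvolution by simplex-constrained least squares.

Each sample's beta values over a panel of cell-type-discriminating probes are
regressed on the reference mean-beta profiles, subject to non-negative
fractions that sum to one. The solver is non-negative least squares on a
penalty-augmented system (the sum constraint appended as a heavily weighted
row) followed by an exact Euclidean projection onto the unit simplex, so the
returned fractions satisfy the simplex constraints exactly rather than by
post-hoc rescaling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import CellFractions, MethylationMatrix, ValidationError

_SUM_PENALTY = 1000.0
_COND_WARN = 1e8


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of ``v`` onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def estimate_cell_fractions(m: MethylationMatrix, ref: pd.DataFrame) -> CellFractions:
    """Estimate leukocyte fractions for every sample of ``m`` against ``ref``.

    ``ref`` is a probes x cell-types table of mean beta profiles in [0, 1].
    Requires at least as many shared, non-missing probes as cell types per
    sample; samples falling below that get missing fractions (with a warning)
    rather than an error. Returns fractions plus per-sample residual RMSE.
    """
    if ref.shape[1] < 2:
        raise ValidationError("reference must contain at least 2 cell types")
    vals = ref.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValidationError("reference profiles must lie in [0, 1]")
    shared = ref.index.intersection(m.betas.index)
    n_types = ref.shape[1]
    if len(shared) < n_types:
        raise ValidationError(
            f"only {len(shared)} probes shared between matrix and reference; "
            f"need at least {n_types} for identifiability"
        )
    A_full = ref.loc[shared].to_numpy(dtype=float)
    cond = np.linalg.cond(A_full)
    if not np.isfinite(cond) or cond > _COND_WARN:
        warnings.warn(
            f"reference profile condition number {cond:.3g} exceeds {_COND_WARN:.0e}; "
            "collinear cell types — the solution is tie-broken by the active-set order",
            stacklevel=2,
        )
    Y = m.betas.loc[shared].to_numpy(dtype=float)
    sum_row = _SUM_PENALTY * np.ones((1, n_types))
    out = np.full((m.n_samples, n_types), np.nan)
    rmse = np.full(m.n_samples, np.nan)
    for j in range(m.n_samples):
        y = Y[:, j]
        ok = np.isfinite(y)
        if ok.sum() < n_types:
            warnings.warn(f"sample {m.sample_ids[j]!r}: fewer usable probes than cell types; "
                          "fractions set to missing", stacklevel=2)
            continue
        A = np.vstack([A_full[ok], sum_row])
        b = np.concatenate([y[ok], [_SUM_PENALTY]])
        f, _ = nnls(A, b)
        f = project_simplex(f)
        out[j] = f
        resid = A_full[ok] @ f - y[ok]
        rmse[j] = float(np.sqrt(np.mean(resid**2)))
    fractions = pd.DataFrame(out, index=pd.Index(m.sample_ids, name="sample_id"),
                             columns=list(ref.columns))
    return CellFractions(fractions=fractions,
                         residual_rmse=pd.Series(rmse, index=fractions.index, name="residual_rmse"))


def apply_fraction_delta(
    baseline: CellFractions, followup: CellFractions, mode: str = "baseline"
) -> pd.DataFrame:
    """Choose the cell-fraction covariate representation for the change model.

    ``baseline`` passes baseline fractions through (the default), ``average``
    is the per-sample visit mean, ``delta`` is follow-up minus baseline.
    """
    if list(baseline.fractions.index) != list(followup.fractions.index):
        raise ValidationError("baseline and follow-up fractions cover different samples")
    if mode == "baseline":
        return baseline.fractions.copy()
    if mode == "average":
        return (baseline.fractions + followup.fractions) / 2.0
    if mode == "delta":
        return followup.fractions - baseline.fractions
    raise ValidationError(f"unknown fraction mode {mode!r}; expected baseline/average/delta")
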