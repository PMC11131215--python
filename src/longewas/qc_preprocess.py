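"""Probe-level quality filters and the longitudinal change matrices.

The filter pipeline applies, in order: detection-p masking (beta becomes
missing where its detection p exceeds 0.01, strictly), the bead filter
(drop probes with fewer than 3 beads in at least 5% of samples), and removal
of chrX/chrY and SNP-related probes. Each filter is idempotent and reports
what it changed. Normalisation (BMIQ) and batch correction (ComBat) are
published methods outside this package's scope; `normalize_hook` is an
explicit no-op that says so.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MethylationMatrix, SEX_PROBE_CHROMOSOMES, ValidationError

log = logging.getLogger(__name__)


def mask_low_quality_betas(
    m: MethylationMatrix, p_threshold: float = 0.01
) -> tuple[MethylationMatrix, int]:
    """Set betas with detection p strictly above ``p_threshold`` to missing.

    Returns the filtered matrix and the number of newly masked betas. A beta
    whose detection p equals the threshold exactly is retained.
    """
    if m.detection_p is None:
        raise ValidationError("mask_low_quality_betas requires a detection_p companion")
    dp = m.detection_p.to_numpy(dtype=float)
    betas = m.betas.to_numpy(dtype=float).copy()
    to_mask = (dp > p_threshold) & np.isfinite(betas)
    betas[to_mask] = np.nan
    n_masked = int(to_mask.sum())
    log.info("detection-p mask (> %g): %d betas set to missing", p_threshold, n_masked)
    masked = m.replace(betas=pd.DataFrame(betas, index=m.betas.index, columns=m.betas.columns))
    return masked, n_masked


def filter_low_bead_probes(
    m: MethylationMatrix, min_beads: int = 3, sample_fraction: float = 0.05
) -> tuple[MethylationMatrix, list[str]]:
    """Drop probes with < ``min_beads`` beads in at least ``sample_fraction`` of samples.

    The boundary is inclusive: a probe failing in exactly 5% of samples is
    dropped. Returns the filtered matrix and the dropped probe ids.
    """
    if m.bead_counts is None:
        raise ValidationError("filter_low_bead_probes requires a bead_counts companion")
    low = (m.bead_counts.to_numpy(dtype=float) < min_beads).mean(axis=1)
    dropped = [p for p, frac in zip(m.probe_ids, low) if frac >= sample_fraction]
    keep = [p for p in m.probe_ids if p not in set(dropped)]
    log.info("bead filter (<%d beads in >=%g of samples): dropped %d/%d probes",
             min_beads, sample_fraction, len(dropped), m.n_probes)
    return m.subset_probes(keep), dropped


def drop_sex_and_snp_probes(
    m: MethylationMatrix, manifest: pd.DataFrame
) -> tuple[MethylationMatrix, list[str]]:
    """Remove probes on chromosome X or Y and SNP-related probes."""
    missing = [p for p in m.probe_ids if p not in manifest.index]
    if missing:
        raise ValidationError(f"probes absent from manifest: {missing[:5]}")
    sub = manifest.loc[m.probe_ids]
    bad = sub["chromosome"].astype(str).isin(SEX_PROBE_CHROMOSOMES) | sub["is_snp_probe"].astype(bool)
    dropped = sub.index[bad].tolist()
    keep = sub.index[~bad].tolist()
    log.info("sex/SNP probe filter: dropped %d/%d probes", len(dropped), m.n_probes)
    return m.subset_probes(keep), dropped


def run_qc(
    m: MethylationMatrix,
    manifest: pd.DataFrame,
    *,
    p_threshold: float = 0.01,
    min_beads: int = 3,
    sample_fraction: float = 0.05,
) -> tuple[MethylationMatrix, dict]:
    """Full QC in the stated order: mask -> bead filter -> sex/SNP drop.

    Returns the filtered matrix and a report dict with counts per step.
    """
    n0 = m.n_probes
    m, n_masked = mask_low_quality_betas(m, p_threshold)
    m, bead_dropped = filter_low_bead_probes(m, min_beads, sample_fraction)
    m, sexsnp_dropped = drop_sex_and_snp_probes(m, manifest)
    report = {
        "probes_in": n0,
        "betas_masked": n_masked,
        "bead_filter_dropped": len(bead_dropped),
        "sex_snp_dropped": len(sexsnp_dropped),
        "probes_out": m.n_probes,
    }
    return m, report


def compute_delta_matrix(
    baseline: MethylationMatrix, followup: MethylationMatrix
) -> pd.DataFrame:
    """Longitudinal methylation change: follow-up beta minus baseline beta.

    Probes and samples are intersected (with a warning when anything is lost);
    a change is missing wherever either visit is missing.
    """
    probes = baseline.betas.index.intersection(followup.betas.index)
    samples = baseline.betas.columns.intersection(followup.betas.columns)
    if len(probes) == 0 or len(samples) == 0:
        raise ValidationError("baseline and follow-up matrices share no probes or no samples")
    lost_p = max(baseline.n_probes, followup.n_probes) - len(probes)
    lost_s = max(baseline.n_samples, followup.n_samples) - len(samples)
    if lost_p or lost_s:
        warnings.warn(
            f"delta matrix restricted to intersection: lost up to {lost_p} probes, {lost_s} samples",
            stacklevel=2,
        )
    return followup.betas.loc[probes, samples] - baseline.betas.loc[probes, samples]


def compute_bmi_change_degree(pheno: pd.DataFrame, annualize: bool = False) -> pd.Series:
    """BMI change degree per sample: (follow-up BMI - baseline BMI) / baseline BMI.

    Dimensionless. With ``annualize=True`` the degree is additionally divided
    by the follow-up interval in years (not the default: the headline cohort
    summaries are consistent with the un-annualised definition).
    """
    b0 = pheno["bmi_baseline"].astype(float)
    if (b0 <= 0).any():
        raise ValidationError("non-positive baseline BMI")
    degree = (pheno["bmi_followup"].astype(float) - b0) / b0
    if annualize:
        degree = degree / pheno["interval_years"].astype(float)
    return degree.rename("bmi_change_degree")


def normalize_hook(m: MethylationMatrix, method: str = "none") -> MethylationMatrix:
    """Placeholder for beta normalisation / batch correction.

    BMIQ and ComBat are published algorithms this package deliberately does
    not re-implement; requesting them warns and returns the input unchanged.
    """
    if method != "none":
        warnings.warn(f"normalisation method {method!r} is out of scope; returning input unchanged",
                      stacklevel=2)
    return m
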