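"""Two-visit, two-cohort methylation cohort simulator with known ground truth.

The generator emulates the statistical structure a longitudinal blood-methylation
EWAS of BMI change assumes: paired beta-value matrices roughly four years apart,
per-sample leukocyte composition drawn from a Dirichlet and expressed through
cell-type reference profiles, a small set of causal CpGs whose methylation
change tracks the BMI change degree (follow-up BMI minus baseline BMI, over
baseline BMI), small age/sex/interval contributions, and detection-p /
bead-count contamination at configurable rates.

Betas are formed on the logit scale and mapped through the logistic function,
so they live strictly inside (0, 1) without hard clipping. The causal signal
is injected on the beta-change scale: for causal probe p and subject i,

    delta_M[p, i] = beta_S[p] * dBMI_degree[i] + covariate terms + N(0, noise_sd)

and the follow-up beta is expit(logit(baseline) + delta / (b * (1 - b))),
which realises that change to first order while keeping the value bounded.

Randomness is a single global seed feeding per-cohort, per-stage substreams
(numpy SeedSequence spawn keys), so each stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_io import (
    AUTOSOMES,
    DEFAULT_CELL_TYPES,
    ISLAND_RELATIONS,
    MethylationMatrix,
    ValidationError,
    validate_phenotypes,
)

# stage -> substream key; fixed so adding stages never reshuffles existing draws
_STAGES = {
    "causal": 0, "phenotype": 1, "fractions": 2, "reference": 3,
    "baseline": 4, "delta": 5, "detection": 6, "beads": 7, "manifest": 8,
}

# typical blood leukocyte composition, order matches DEFAULT_CELL_TYPES
_DEFAULT_MEAN_FRACTIONS = (0.08, 0.16, 0.10, 0.06, 0.06, 0.54)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Phenotype defaults follow the discovery cohort of the emulated study design:
    n = 407, baseline age 61.7 +- 7.5 y, 44% male, baseline BMI 23.9 +- 3.0
    kg/m^2, follow-up interval 4.1 y, BMI change degree 0.03 +- 0.07,
    smoking 19%, drinking 18%. ``cohort2_config`` provides the replication
    cohort's conditions (n = 126, interval 4.4 y, change degree 0.02 +- 0.08).
    """

    n_samples: int = 407
    n_probes: int = 5000
    n_causal: int = 8
    effect_mean: float = 0.5     # true beta_S, beta-change per unit change degree
    effect_sd: float = 0.1
    noise_sd: float = 0.02       # residual sd of delta-M on the beta-change scale
    baseline_logit_sd: float = 0.3
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    cell_mean_fractions: tuple[float, ...] = _DEFAULT_MEAN_FRACTIONS
    dirichlet_concentration: float = 60.0
    n_reference_probes: int = 60
    cell_reference: pd.DataFrame | None = None  # probes x cell types; generated if None
    cell_confounding: float = 0.0  # logistic tilt of fractions along BMI change degree
    cell_effect_sd: float = 0.0    # per-probe sensitivity of delta-M to cell fractions
    bmi_change_degree_mean: float = 0.03
    bmi_change_degree_sd: float = 0.07
    bmi_baseline_mean: float = 23.9
    bmi_baseline_sd: float = 3.0
    age_mean: float = 61.7
    age_sd: float = 7.5
    male_fraction: float = 0.44
    interval_years_mean: float = 4.1
    interval_years_sd: float = 0.3
    smoking_rate: float = 0.19
    drinking_rate: float = 0.18
    age_effect_sd: float = 2e-4
    sex_effect_sd: float = 2e-3
    interval_effect_sd: float = 5e-4
    detection_fail_rate: float = 0.002
    low_bead_rate: float = 0.005
    cohort: str = "cohort1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.n_probes:
            raise ValidationError("n_causal must not exceed n_probes")
        for name in ("detection_fail_rate", "low_bead_rate", "smoking_rate",
                     "drinking_rate", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("effect_sd", "noise_sd", "baseline_logit_sd", "bmi_change_degree_sd",
                     "age_sd", "interval_years_sd", "cell_effect_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if len(self.cell_mean_fractions) != len(self.cell_types):
            raise ValidationError("cell_mean_fractions length must match cell_types")


def cohort2_config(**overrides) -> SimulationConfig:
    """Replication-cohort conditions (see :class:`SimulationConfig`)."""
    base = dict(
        n_samples=126, age_mean=62.4, age_sd=8.6, male_fraction=0.52,
        bmi_baseline_mean=24.1, bmi_baseline_sd=2.5,
        bmi_change_degree_mean=0.02, bmi_change_degree_sd=0.08,
        interval_years_mean=4.4, smoking_rate=0.23, drinking_rate=0.09,
        cohort="cohort2", seed=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class GroundTruth:
    """What the simulator knows and an analysis should recover."""

    causal_probe_ids: list[str]
    true_effects: pd.Series            # beta_S per causal probe
    true_cell_fractions: pd.DataFrame  # samples x cell types (stable across visits)
    cell_reference: pd.DataFrame       # reference probes x cell types


def _rng(config: SimulationConfig, stage: str, cohort_offset: int = 0) -> np.random.Generator:
    key = (_STAGES[stage], cohort_offset)
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=key))


def probe_universe(n_probes: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n_probes)]


def _draw_causal(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    rng = _rng(config, "causal")
    probes = probe_universe(config.n_probes)
    candidates = probes[config.n_reference_probes:]  # causal probes never overlap the reference panel
    ids = sorted(rng.choice(candidates, size=config.n_causal, replace=False).tolist())
    effects = rng.normal(config.effect_mean, config.effect_sd, size=config.n_causal)
    return ids, effects


def _draw_reference(config: SimulationConfig) -> pd.DataFrame:
    if config.cell_reference is not None:
        ref = config.cell_reference
        if not set(ref.index).issubset(probe_universe(config.n_probes)):
            raise ValidationError("cell_reference probes are not a subset of the probe universe")
        return ref
    rng = _rng(config, "reference")
    probes = probe_universe(config.n_probes)[: config.n_reference_probes]
    n_types = len(config.cell_types)
    # each reference probe discriminates one cell type: high there, low elsewhere
    marker_of = rng.integers(0, n_types, size=len(probes))
    prof = np.full((len(probes), n_types), 0.15) + rng.uniform(-0.05, 0.05, size=(len(probes), n_types))
    prof[np.arange(len(probes)), marker_of] = 0.85 + rng.uniform(-0.05, 0.05, size=len(probes))
    return pd.DataFrame(np.clip(prof, 0.05, 0.95), index=probes, columns=list(config.cell_types))


def _draw_phenotypes(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config, "phenotype")
    n = config.n_samples
    sample_ids = [f"{config.cohort}_S{i:04d}" for i in range(n)]
    age = np.maximum(45.0, rng.normal(config.age_mean, config.age_sd, n))
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    interval = np.maximum(0.5, rng.normal(config.interval_years_mean, config.interval_years_sd, n))
    bmi0 = np.maximum(15.0, rng.normal(config.bmi_baseline_mean, config.bmi_baseline_sd, n))
    degree = rng.normal(config.bmi_change_degree_mean, config.bmi_change_degree_sd, n)
    pheno = pd.DataFrame({
        "cohort": config.cohort,
        "sex": sex,
        "age": age,
        "interval_years": interval,
        "bmi_baseline": bmi0,
        "bmi_followup": bmi0 * (1.0 + degree),
        "smoking": (rng.random(n) < config.smoking_rate).astype(int),
        "drinking": (rng.random(n) < config.drinking_rate).astype(int),
    }, index=pd.Index(sample_ids, name="sample_id"))
    return validate_phenotypes(pheno)


def _draw_fractions(config: SimulationConfig, degree: np.ndarray) -> pd.DataFrame:
    rng = _rng(config, "fractions")
    alpha = config.dirichlet_concentration * np.asarray(config.cell_mean_fractions)
    fracs = rng.dirichlet(alpha, size=config.n_samples)
    if config.cell_confounding != 0.0:
        # tilt composition along the phenotype: granulocytes up, lymphoid down
        n_types = len(config.cell_types)
        contrast = np.full(n_types, -1.0 / (n_types - 1))
        contrast[-1] = 1.0
        logw = np.log(fracs) + config.cell_confounding * np.outer(degree, contrast)
        fracs = np.exp(logw)
        fracs /= fracs.sum(axis=1, keepdims=True)
    return pd.DataFrame(fracs, columns=list(config.cell_types))


def simulate_cohort(
    config: SimulationConfig,
    *,
    causal: tuple[Sequence[str], np.ndarray] | None = None,
    reference: pd.DataFrame | None = None,
) -> tuple[MethylationMatrix, MethylationMatrix, pd.DataFrame, GroundTruth]:
    """Generate one cohort: (baseline, followup, phenotypes, ground truth).

    ``causal`` and ``reference`` override the seed-derived draws so two cohorts
    can share the same causal probes, true effects and cell reference.
    """
    probes = probe_universe(config.n_probes)
    ref = _draw_reference(config) if reference is None else reference
    if not set(ref.index).issubset(probes):
        raise ValidationError("reference probe set is not a subset of the probe universe")
    if causal is None:
        causal_ids, effects = _draw_causal(config)
    else:
        causal_ids, effects = list(causal[0]), np.asarray(causal[1], dtype=float)
        missing = set(causal_ids) - set(probes)
        if missing:
            raise ValidationError(f"causal probes outside the probe universe: {sorted(missing)[:5]}")

    pheno = _draw_phenotypes(config)
    degree = ((pheno["bmi_followup"] - pheno["bmi_baseline"]) / pheno["bmi_baseline"]).to_numpy()
    fracs = _draw_fractions(config, degree)
    fracs.index = pheno.index

    n_p, n_s = config.n_probes, config.n_samples
    rng_base = _rng(config, "baseline")
    # mixture means: reference probes reflect composition, others a probe-level mean
    mu = np.empty((n_p, n_s))
    probe_pos = {p: i for i, p in enumerate(probes)}
    base_means = rng_base.uniform(0.1, 0.9, size=n_p)
    causal_rows = np.array([probe_pos[p] for p in causal_ids], dtype=int)
    # intermediate methylation at causal probes keeps the beta-scale effect faithful
    base_means[causal_rows] = rng_base.uniform(0.35, 0.65, size=len(causal_rows))
    mu[:] = base_means[:, None]
    ref_rows = np.array([probe_pos[p] for p in ref.index], dtype=int)
    mu[ref_rows] = ref.to_numpy() @ fracs.to_numpy().T
    baseline = expit(logit(mu) + rng_base.normal(0.0, config.baseline_logit_sd, size=(n_p, n_s)))

    rng_delta = _rng(config, "delta")
    delta = rng_delta.normal(0.0, config.noise_sd, size=(n_p, n_s))
    sex01 = (pheno["sex"] == "male").to_numpy(dtype=float)
    age_c = pheno["age"].to_numpy() - pheno["age"].mean()
    itv_c = pheno["interval_years"].to_numpy() - pheno["interval_years"].mean()
    delta += np.outer(rng_delta.normal(0.0, config.age_effect_sd, n_p), age_c)
    delta += np.outer(rng_delta.normal(0.0, config.sex_effect_sd, n_p), sex01 - sex01.mean())
    delta += np.outer(rng_delta.normal(0.0, config.interval_effect_sd, n_p), itv_c)
    if config.cell_effect_sd > 0:
        sens = rng_delta.normal(0.0, config.cell_effect_sd, size=(n_p, len(config.cell_types)))
        delta += sens @ (fracs.to_numpy() - fracs.to_numpy().mean(axis=0)).T
    if len(causal_rows):
        delta[causal_rows] += np.outer(effects, degree)
    followup = expit(logit(baseline) + delta / (baseline * (1.0 - baseline)))

    def _qc_layers(offset: int) -> tuple[pd.DataFrame, pd.DataFrame]:
        rng_d = _rng(config, "detection", offset)
        dp = rng_d.uniform(0.0, 0.005, size=(n_p, n_s))
        fail = rng_d.random((n_p, n_s)) < config.detection_fail_rate
        dp[fail] = rng_d.uniform(0.011, 1.0, size=int(fail.sum()))
        rng_b = _rng(config, "beads", offset)
        beads = rng_b.poisson(14.0, size=(n_p, n_s)) + 3
        low = rng_b.random((n_p, n_s)) < config.low_bead_rate
        beads[low] = rng_b.integers(1, 3, size=int(low.sum()))
        idx = pd.Index(probes, name="probe_id")
        return (pd.DataFrame(dp, index=idx, columns=pheno.index),
                pd.DataFrame(beads, index=idx, columns=pheno.index))

    idx = pd.Index(probes, name="probe_id")
    dp0, bc0 = _qc_layers(0)
    dp1, bc1 = _qc_layers(1)
    m0 = MethylationMatrix(pd.DataFrame(baseline, index=idx, columns=pheno.index),
                           detection_p=dp0, bead_counts=bc0, visit="baseline")
    m1 = MethylationMatrix(pd.DataFrame(followup, index=idx, columns=pheno.index),
                           detection_p=dp1, bead_counts=bc1, visit="followup")
    truth = GroundTruth(
        causal_probe_ids=list(causal_ids),
        true_effects=pd.Series(effects, index=pd.Index(causal_ids, name="probe_id"), name="beta_s"),
        true_cell_fractions=fracs,
        cell_reference=ref,
    )
    return m0, m1, pheno, truth


def simulate_two_cohorts(
    config_pair: tuple[SimulationConfig, SimulationConfig],
) -> dict[str, tuple[MethylationMatrix, MethylationMatrix, pd.DataFrame, GroundTruth]]:
    """Paired discovery/replication datasets sharing causal probes, effects and reference.

    Noise, samples and phenotypes are independent between cohorts.
    """
    c1, c2 = config_pair
    if c1.n_probes != c2.n_probes:
        raise ValidationError("both cohorts must share the same probe universe (n_probes)")
    if c1.cohort == c2.cohort:
        raise ValidationError("cohort labels must differ")
    causal = _draw_causal(c1)
    reference = _draw_reference(c1)
    return {
        c1.cohort: simulate_cohort(c1, causal=causal, reference=reference),
        c2.cohort: simulate_cohort(c2, causal=causal, reference=reference),
    }


def simulate_manifest(
    config: SimulationConfig,
    protected: Sequence[str] = (),
) -> pd.DataFrame:
    """Draw an EPIC-style probe manifest for the simulated probe universe.

    ``protected`` probes (typically the causal set and the reference panel) are
    forced onto autosomes and never SNP-flagged, so the stated QC filters
    cannot remove the planted signal.
    """
    rng = _rng(config, "manifest")
    probes = probe_universe(config.n_probes)
    n = len(probes)
    chrom_pool = list(AUTOSOMES) + ["X", "Y"]
    chrom_p = np.array([0.96 / 22] * 22 + [0.03, 0.01])
    chrom = rng.choice(chrom_pool, size=n, p=chrom_p)
    snp = rng.random(n) < 0.03
    prot = np.isin(probes, list(protected))
    chrom[prot] = rng.choice(list(AUTOSOMES), size=int(prot.sum()))
    snp[prot] = False
    rel_p = np.array([0.31, 0.13, 0.11, 0.05, 0.05, 0.35])
    relation = rng.choice(list(ISLAND_RELATIONS), size=n, p=rel_p / rel_p.sum())
    gene_pool = [f"GENE{i:04d}" for i in range(max(10, n // 8))]
    has_gene = rng.random(n) < 0.6
    gene = np.where(has_gene, rng.choice(gene_pool, size=n), "")
    multi = has_gene & (rng.random(n) < 0.02)
    if multi.any():
        extra = rng.choice(gene_pool, size=int(multi.sum()))
        gene[multi] = [f"{g}; {e}" for g, e in zip(gene[multi], extra)]
    manifest = pd.DataFrame({
        "chromosome": chrom,
        "position": rng.integers(1, 240_000_000, size=n),
        "gene": gene,
        "island_relation": relation,
        "is_snp_probe": snp,
    }, index=pd.Index(probes, name="probe_id"))
    return manifest
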