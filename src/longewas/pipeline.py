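"""End-to-end orchestration: simulate -> qc -> deconvolve -> ewas -> meta -> enrich -> compare.

A run is driven by one YAML config and writes a fixed artifact layout under
the run directory:

    simulated/   per-cohort beta/detection-p/bead matrices, phenotypes,
                 ground truth, cell reference, probe manifest
    qc/          filtered matrices and the per-sample change matrix
    fractions/   estimated cell fractions per cohort
    ewas/        per-cohort result tables (delta, cross-sectional, strata)
    meta/        meta-analysis table and the significant-probe report
    enrichment/  top-CpG gene list and per-set enrichment table
    report/      human-readable summary

plus ``manifest.json`` (a machine-readable run manifest: versions, seed,
thresholds, row counts at every filter). All outputs are pure functions of
(config, seed); a rerun with the same config reproduces every numeric
artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .core_io import (
    MethylationMatrix, read_beta_matrix, read_cell_fractions, read_manifest,
    read_phenotypes, read_results, write_beta_matrix, write_cell_fractions,
    write_manifest, write_phenotypes, write_results, ValidationError,
)
from .cell_deconvolution import apply_fraction_delta, estimate_cell_fractions
from .enrichment import GeneSetCollection, annotate_cpgs_to_genes, enrich_gene_list, read_gmt
from .longitudinal_ewas import (
    compare_cpg_list_significance, fit_cross_sectional_ewas, fit_delta_ewas,
    select_top_cpgs, stratified_ewas,
)
from .meta_analysis import call_significant, run_meta
from .qc_preprocess import compute_delta_matrix, run_qc
from .synthetic_cohort import (
    SimulationConfig, cohort2_config, simulate_cohort, simulate_manifest,
    simulate_two_cohorts,
)

log = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "qc", "deconvolve", "ewas", "meta", "enrich", "compare", "report"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulation": {"n_probes": 5000, "n_causal": 8},
    "cohorts": {"cohort1": {}, "cohort2": {"preset": "cohort2"}},
    "qc": {"detection_p_threshold": 0.01, "min_beads": 3, "max_low_bead_fraction": 0.05},
    "ewas": {"adjust_lifestyle": False, "fraction_mode": "baseline",
             "moderate_variance": False, "stratified": True, "cross_sectional": True},
    "meta": {"discovery_cohort": "cohort1", "discovery_threshold": 1e-6},
    "selection": {"p_threshold": 1e-5, "top_k": 20},
    "enrichment": {"gmt": None, "n_synthetic_sets": 10},
    "comparison": {"cpg_list": None, "n_random": 200},
    "stages": list(ALL_STAGES),
}


def load_config(path_or_dict: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Load a YAML pipeline config and merge it over the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    if not isinstance(user, dict):
        raise ValidationError("pipeline config must be a mapping")
    config: dict[str, Any] = {}
    for key, default in DEFAULT_CONFIG.items():
        if isinstance(default, dict):
            merged = dict(default)
            merged.update(user.get(key) or {})
            config[key] = merged
        else:
            config[key] = user.get(key, default)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    bad_stages = set(config["stages"]) - set(ALL_STAGES)
    if bad_stages:
        raise ValidationError(f"unknown stages: {sorted(bad_stages)}")
    return config


def _cohort_configs(config: Mapping[str, Any], seed: int) -> list[SimulationConfig]:
    shared = dict(config["simulation"])
    configs = []
    for i, (name, overrides) in enumerate(config["cohorts"].items()):
        overrides = dict(overrides or {})
        preset = overrides.pop("preset", None)
        params = {**shared, **overrides, "cohort": name, "seed": seed + 1000 * i}
        if preset == "cohort2":
            configs.append(cohort2_config(**params))
        elif preset in (None, "cohort1"):
            configs.append(SimulationConfig(**params))
        else:
            raise ValidationError(f"unknown cohort preset {preset!r}")
    return configs


def _frame(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=False, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    return frame


class PipelineRun:
    """Mutable state for one pipeline run; stages read/write through it."""

    def __init__(self, config: dict[str, Any], out_dir: str | Path, seed: int | None = None):
        self.config = config
        self.seed = int(config["seed"] if seed is None else seed)
        self.out = Path(out_dir)
        self.counts: dict[str, Any] = {}
        self.cohorts = list(config["cohorts"])
        for sub in ("simulated", "qc", "fractions", "ewas", "meta", "enrichment", "report"):
            (self.out / sub).mkdir(parents=True, exist_ok=True)

    # -- simulate ----------------------------------------------------------
    def simulate(self) -> None:
        configs = _cohort_configs(self.config, self.seed)
        if len(configs) == 2:
            datasets = simulate_two_cohorts(tuple(configs))
        else:
            datasets = {cfg.cohort: simulate_cohort(cfg) for cfg in configs}
        truth0 = next(iter(datasets.values()))[3]
        protected = list(truth0.causal_probe_ids) + list(truth0.cell_reference.index)
        manifest = simulate_manifest(configs[0], protected=protected)
        write_manifest(manifest, self.out / "simulated" / "probe_manifest.tsv")
        truth0.cell_reference.to_csv(self.out / "simulated" / "cell_reference.tsv",
                                     sep="\t", index_label="probe_id")
        truth0.true_effects.to_frame().to_csv(self.out / "simulated" / "ground_truth_effects.tsv",
                                              sep="\t")
        for name, (m0, m1, pheno, truth) in datasets.items():
            d = self.out / "simulated" / name
            d.mkdir(exist_ok=True)
            for m, visit in ((m0, "baseline"), (m1, "followup")):
                write_beta_matrix(m, d / f"betas_{visit}.tsv")
                write_beta_matrix(m, d / f"detection_p_{visit}.tsv", which="detection_p")
                write_beta_matrix(m, d / f"bead_counts_{visit}.tsv", which="bead_counts")
            write_phenotypes(pheno, d / "phenotypes.tsv")
            truth.true_cell_fractions.to_csv(d / "true_cell_fractions.tsv", sep="\t",
                                             index_label="sample_id")
            self.counts[f"{name}_n_samples"] = pheno.shape[0]
            self.counts[f"{name}_n_probes_simulated"] = m0.n_probes

    def _load_cohort(self, name: str, visit: str, stage_dir: str = "simulated") -> MethylationMatrix:
        d = self.out / stage_dir / name
        if stage_dir == "simulated":
            return read_beta_matrix(d / f"betas_{visit}.tsv",
                                    detection_p=d / f"detection_p_{visit}.tsv",
                                    bead_counts=d / f"bead_counts_{visit}.tsv", visit=visit)
        return MethylationMatrix(betas=_frame(d / f"betas_{visit}.tsv"), visit=visit)

    # -- qc ----------------------------------------------------------------
    def qc(self) -> None:
        qc_cfg = self.config["qc"]
        manifest = read_manifest(self.out / "simulated" / "probe_manifest.tsv")
        for name in self.cohorts:
            d = self.out / "qc" / name
            d.mkdir(exist_ok=True)
            filtered = {}
            for visit in ("baseline", "followup"):
                m = self._load_cohort(name, visit)
                m2, report = run_qc(
                    m, manifest,
                    p_threshold=qc_cfg["detection_p_threshold"],
                    min_beads=qc_cfg["min_beads"],
                    sample_fraction=qc_cfg["max_low_bead_fraction"],
                )
                filtered[visit] = m2
                self.counts[f"{name}_{visit}_qc"] = report
                write_beta_matrix(m2, d / f"betas_{visit}.tsv")
            delta = compute_delta_matrix(filtered["baseline"], filtered["followup"])
            delta.to_csv(d / "delta_m.tsv", sep="\t", na_rep="NA", index_label="probe_id")
            self.counts[f"{name}_delta_probes"] = int(delta.shape[0])

    # -- deconvolve --------------------------------------------------------
    def deconvolve(self) -> None:
        ref = _frame(self.out / "simulated" / "cell_reference.tsv").astype(float)
        mode = self.config["ewas"]["fraction_mode"]
        visits = ("baseline",) if mode == "baseline" else ("baseline", "followup")
        for name in self.cohorts:
            per_visit = {}
            for visit in visits:
                m = self._load_cohort(name, visit, stage_dir="qc")
                per_visit[visit] = estimate_cell_fractions(m, ref)
                write_cell_fractions(per_visit[visit],
                                     self.out / "fractions" / f"{name}_{visit}.tsv")
            if mode != "baseline":
                covars = apply_fraction_delta(per_visit["baseline"], per_visit["followup"], mode)
                covars.to_csv(self.out / "fractions" / f"{name}_covariates.tsv", sep="\t",
                              index_label="sample_id", na_rep="NA")

    def _fraction_covariates(self, name: str) -> pd.DataFrame:
        mode = self.config["ewas"]["fraction_mode"]
        if mode == "baseline":
            return read_cell_fractions(self.out / "fractions" / f"{name}_baseline.tsv").fractions
        return _frame(self.out / "fractions" / f"{name}_covariates.tsv").astype(float)

    # -- ewas --------------------------------------------------------------
    def ewas(self) -> None:
        cfg = self.config["ewas"]
        disc = self.config["meta"]["discovery_cohort"]
        for name in self.cohorts:
            delta = _frame(self.out / "qc" / name / "delta_m.tsv")
            pheno = read_phenotypes(self.out / "simulated" / name / "phenotypes.tsv")
            fracs = self._fraction_covariates(name)
            res = fit_delta_ewas(delta, pheno, fracs,
                                 adjust_lifestyle=cfg["adjust_lifestyle"],
                                 moderate_variance=cfg["moderate_variance"])
            write_results(res, self.out / "ewas" / f"delta_{name}.tsv")
            self.counts[f"{name}_ewas_probes"] = int(res["p_value"].notna().sum())
            if name == disc:
                if cfg["cross_sectional"]:
                    for visit in ("baseline", "followup"):
                        m = self._load_cohort(name, visit, stage_dir="qc")
                        cs = fit_cross_sectional_ewas(m, pheno, fracs, visit=visit,
                                                      moderate_variance=cfg["moderate_variance"])
                        write_results(cs, self.out / "ewas" / f"cross_sectional_{visit}_{name}.tsv")
                if cfg["stratified"]:
                    for stratum in ("male", "female"):
                        sr = stratified_ewas(delta, pheno, fracs, stratum,
                                             moderate_variance=cfg["moderate_variance"])
                        write_results(sr, self.out / "ewas" / f"stratified_{stratum}_{name}.tsv")

    # -- meta --------------------------------------------------------------
    def meta(self) -> None:
        if len(self.cohorts) < 2:
            log.warning("meta stage needs >=2 cohorts; skipping")
            return
        results = {name: read_results(self.out / "ewas" / f"delta_{name}.tsv")
                   for name in self.cohorts}
        n_by = {name: read_phenotypes(self.out / "simulated" / name / "phenotypes.tsv").shape[0]
                for name in self.cohorts}
        meta = run_meta(results, n_by)
        write_results(meta, self.out / "meta" / "meta.tsv")
        disc = self.config["meta"]["discovery_cohort"]
        sig = call_significant(meta, results[disc],
                               discovery_threshold=self.config["meta"]["discovery_threshold"])
        sig.to_csv(self.out / "meta" / "significant.tsv", sep="\t", index=False, na_rep="NA")
        self.counts["discovery_significant"] = int(sig.shape[0])

    # -- enrich ------------------------------------------------------------
    def enrich(self) -> None:
        sel = self.config["selection"]
        meta_path = self.out / "meta" / "meta.tsv"
        source = read_results(meta_path) if meta_path.exists() else read_results(
            self.out / "ewas" / f"delta_{self.config['meta']['discovery_cohort']}.tsv")
        top = select_top_cpgs(source, p_threshold=sel["p_threshold"], k=sel["top_k"])
        manifest = read_manifest(self.out / "simulated" / "probe_manifest.tsv")
        genes = annotate_cpgs_to_genes(top, manifest)
        (self.out / "enrichment" / "top_cpgs.txt").write_text("\n".join(top) + "\n" if top else "")
        (self.out / "enrichment" / "top_genes.txt").write_text("\n".join(genes) + "\n" if genes else "")
        self.counts["top_cpgs"] = len(top)
        self.counts["top_genes"] = len(genes)
        if not genes:
            log.warning("no annotated genes among the top CpGs; enrichment skipped")
            return
        universe = sorted(set(annotate_cpgs_to_genes(list(manifest.index), manifest)))
        gmt = self.config["enrichment"]["gmt"]
        if gmt:
            collection = read_gmt(gmt, universe=universe)
        else:
            collection = synthetic_collection(universe, self.config["enrichment"]["n_synthetic_sets"],
                                              seed=self.seed)
        table = enrich_gene_list(genes, collection)
        table.to_csv(self.out / "enrichment" / "enrichment.tsv", sep="\t", index=False, na_rep="NA")

    # -- compare -----------------------------------------------------------
    def compare(self) -> None:
        cmp_cfg = self.config["comparison"]
        disc = self.config["meta"]["discovery_cohort"]
        if cmp_cfg["cpg_list"]:
            cpgs = [line.strip() for line in Path(cmp_cfg["cpg_list"]).read_text().splitlines()
                    if line.strip()]
        else:
            truth = pd.read_csv(self.out / "simulated" / "ground_truth_effects.tsv", sep="\t")
            cpgs = truth["probe_id"].astype(str).tolist()
        rows = []
        tables = {"delta": self.out / "ewas" / f"delta_{disc}.tsv"}
        for visit in ("baseline", "followup"):
            p = self.out / "ewas" / f"cross_sectional_{visit}_{disc}.tsv"
            if p.exists():
                tables[f"cross_sectional_{visit}"] = p
        for label, path in tables.items():
            res = read_results(path)
            present = [c for c in cpgs if c in set(res["probe_id"])]
            if not present:
                continue
            t, p = compare_cpg_list_significance(res, present,
                                                 n_random=cmp_cfg["n_random"], seed=self.seed)
            rows.append({"model": label, "n_listed": len(present), "t_stat": t, "p_value": p})
        pd.DataFrame(rows).to_csv(self.out / "report" / "cpg_list_comparison.tsv",
                                  sep="\t", index=False, na_rep="NA")

    # -- manifest / report -------------------------------------------------
    def write_manifest(self, stages_run: list[str]) -> None:
        manifest = {
            "package": "longewas",
            "version": __version__,
            "library_versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                                 "pandas": pd.__version__},
            "seed": self.seed,
            "config": self.config,
            "stages_run": stages_run,
            "counts": self.counts,
        }
        (self.out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def synthetic_collection(universe: list[str], n_sets: int, seed: int) -> GeneSetCollection:
    """Seeded random gene-set collection over a gene universe (synthetic stand-in
    for a curated pathway database, used when no GMT file is supplied)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(5, max(6, len(universe) // 4)))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        sets[f"SET{i:03d}"] = (f"synthetic gene set {i}", frozenset(members.tolist()))
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def run_pipeline(
    config_path: str | Path | Mapping[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Run the configured stages in order and return the run directory.

    Stage errors propagate annotated with the stage name; the run manifest is
    written even when later stages are disabled.
    """
    config = load_config(config_path)
    run = PipelineRun(config, out_dir, seed=seed)
    handler = logging.FileHandler(run.out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("longewas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stages_run = []
    try:
        for stage in ALL_STAGES:
            if stage not in config["stages"]:
                log.info("stage %s disabled; skipped", stage)
                continue
            log.info("stage %s starting", stage)
            try:
                if stage == "report":
                    run.write_manifest(stages_run + [stage])
                    report_summary(run.out)
                else:
                    getattr(run, stage)()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
            stages_run.append(stage)
        run.write_manifest(stages_run)
    finally:
        root.removeHandler(handler)
        handler.close()
    return run.out


def _inflation_lambda(p: np.ndarray) -> float:
    """Median-chi-square genomic inflation factor of a p-value vector."""
    from scipy.stats import chi2
    p = p[np.isfinite(p)]
    if p.size == 0:
        return float("nan")
    return float(np.median(chi2.isf(p, df=1)) / chi2.isf(0.5, df=1))


def report_summary(run_dir: str | Path) -> str:
    """Assemble the human-readable run report; never modifies other artifacts."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"{run_dir} is not a completed run (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"longewas {manifest['version']} run report", f"seed: {manifest['seed']}", ""]
    lines.append("QC counts:")
    for key, val in sorted(manifest["counts"].items()):
        lines.append(f"  {key}: {val}")
    lines.append("")
    for path in sorted((run_dir / "ewas").glob("*.tsv")):
        res = read_results(path)
        lam = _inflation_lambda(res["p_value"].to_numpy(dtype=float))
        lines.append(f"inflation lambda [{path.stem}]: {lam:.4f}")
    sig_path = run_dir / "meta" / "significant.tsv"
    if sig_path.exists():
        sig = pd.read_csv(sig_path, sep="\t")
        lines.append("")
        lines.append(f"discovery-significant probes: {len(sig)}")
        if len(sig):
            lines.append(sig.to_string(index=False))
    else:
        lines.append("")
        lines.append("meta stage skipped: no significant-probe report")
    text = "\n".join(lines) + "\n"
    (run_dir / "report" / "report.txt").write_text(text)
    return text
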