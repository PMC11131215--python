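"""Domain containers and readers/writers for the tabular artifacts of the pipeline.

Every on-disk table is tab-delimited UTF-8 text with a header row (CSV is
accepted where noted). Methylation matrices are probes x samples with the
first column holding probe identifiers. The missing-value token on disk is
``NA``; empty cells are also accepted on read. Genomic coordinates are
1-based positions (strandless points); BED export converts to 0-based
half-open intervals. Sex is encoded 0 = female, 1 = male wherever it enters
a design matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X", "Y")
SEX_PROBE_CHROMOSOMES = frozenset({"X", "Y"})
DEFAULT_CELL_TYPES = ("B", "CD4T", "CD8T", "NK", "Mono", "Neutro")

PHENOTYPE_COLUMNS = [
    "sample_id", "cohort", "sex", "age", "interval_years",
    "bmi_baseline", "bmi_followup", "smoking", "drinking",
]
MANIFEST_COLUMNS = ["probe_id", "chromosome", "position", "gene", "island_relation", "is_snp_probe"]
EWAS_RESULT_COLUMNS = ["probe_id", "effect", "se", "t_stat", "p_value", "fdr", "n_used", "model_tag"]
META_RESULT_COLUMNS = [
    "probe_id", "z_combined", "var_combined", "p_value", "direction",
    "q_stat", "df", "i_squared", "n_studies",
]

_SEPARATORS = {"tsv": "\t", "csv": ","}


class ValidationError(ValueError):
    """An input table violates a documented invariant; the message names the offender."""


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {sorted(_SEPARATORS)}")


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].tolist()
        raise ValidationError(f"duplicate {what}: {dup[:5]}")


def _first_offender(frame: pd.DataFrame, bad: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(bad)[0]
    return str(frame.index[i]), str(frame.columns[j])


@dataclass
class MethylationMatrix:
    """Probes x samples beta values with optional detection-p and bead-count companions.

    Betas are methylated-signal fractions in [0, 1]; NaN marks a missing
    measurement. Companion matrices, when present, share the exact probe and
    sample order of ``betas``.
    """

    betas: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_counts: pd.DataFrame | None = None
    visit: str = "baseline"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def probe_ids(self) -> list[str]:
        return list(self.betas.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.betas.columns)

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def validate(self) -> None:
        if self.visit not in ("baseline", "followup"):
            raise ValidationError(f"visit must be 'baseline' or 'followup', got {self.visit!r}")
        _check_unique(self.betas.index, "probe ids")
        _check_unique(self.betas.columns, "sample ids")
        vals = self.betas.to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals < 0.0) | (vals > 1.0))
        if bad.any():
            probe, sample = _first_offender(self.betas, bad)
            raise ValidationError(
                f"beta outside [0, 1] at probe {probe!r}, sample {sample!r}: "
                f"{vals[np.argwhere(bad)[0][0], np.argwhere(bad)[0][1]]!r}"
            )
        for name, comp in (("detection_p", self.detection_p), ("bead_counts", self.bead_counts)):
            if comp is None:
                continue
            if not comp.index.equals(self.betas.index) or not comp.columns.equals(self.betas.columns):
                raise ValidationError(f"{name} companion does not share probe/sample order with betas")
            if name == "detection_p":
                pv = comp.to_numpy(dtype=float)
                if np.any(np.isfinite(pv) & ((pv < 0.0) | (pv > 1.0))):
                    probe, sample = _first_offender(comp, np.isfinite(pv) & ((pv < 0) | (pv > 1)))
                    raise ValidationError(f"detection p outside [0, 1] at probe {probe!r}, sample {sample!r}")
            else:
                bc = comp.to_numpy()
                if np.any(np.isfinite(bc.astype(float)) & (bc.astype(float) < 0)):
                    probe, sample = _first_offender(comp, bc.astype(float) < 0)
                    raise ValidationError(f"negative bead count at probe {probe!r}, sample {sample!r}")

    def replace(self, **kwargs) -> "MethylationMatrix":
        fields = dict(betas=self.betas, detection_p=self.detection_p,
                      bead_counts=self.bead_counts, visit=self.visit)
        fields.update(kwargs)
        return MethylationMatrix(**fields)

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationMatrix":
        keep = pd.Index(probe_ids)
        return MethylationMatrix(
            betas=self.betas.loc[keep],
            detection_p=None if self.detection_p is None else self.detection_p.loc[keep],
            bead_counts=None if self.bead_counts is None else self.bead_counts.loc[keep],
            visit=self.visit,
        )


@dataclass
class CellFractions:
    """Per-sample leukocyte fractions (samples x cell types), rows on the unit simplex."""

    fractions: pd.DataFrame
    residual_rmse: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)

    def validate(self, tol: float = 1e-8) -> None:
        _check_unique(self.fractions.index, "sample ids")
        vals = self.fractions.to_numpy(dtype=float)
        finite_rows = np.all(np.isfinite(vals), axis=1)
        if np.any(vals[finite_rows] < -tol) or np.any(vals[finite_rows] > 1.0 + tol):
            raise ValidationError("cell fraction outside [0, 1]")
        sums = vals[finite_rows].sum(axis=1)
        if finite_rows.any() and np.max(np.abs(sums - 1.0)) > tol:
            i = int(np.argmax(np.abs(sums - 1.0)))
            sample = self.fractions.index[np.flatnonzero(finite_rows)[i]]
            raise ValidationError(f"fractions for sample {sample!r} sum to {sums[i]!r}, not 1")


@dataclass(frozen=True)
class EnrichmentQuery:
    """Hypergeometric over-representation query: universe N, set M, markers R, overlap k."""

    universe_size: int
    set_size: int
    marker_size: int
    overlap: int

    def __post_init__(self) -> None:
        n, m, r, k = self.universe_size, self.set_size, self.marker_size, self.overlap
        if not (0 <= m <= n and 0 <= r <= n):
            raise ValidationError(f"require M <= N and R <= N; got N={n}, M={m}, R={r}")
        if not (0 <= k <= min(m, r)):
            raise ValidationError(f"overlap k={k} outside [0, min(M, R)={min(m, r)}]")


# ---------------------------------------------------------------------------
# Methylation matrices
# ---------------------------------------------------------------------------

def _read_matrix_frame(path: str | Path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_sep(dialect), index_col=0,
                        na_values=[MISSING_TOKEN, ""], keep_default_na=False, float_precision="round_trip")
    if frame.index.name is None or frame.shape[1] == 0:
        raise ValidationError(f"{path}: malformed header (need probe-id column plus >=1 sample)")
    for col in frame.columns:
        if frame[col].dtype == object:
            try:
                frame[col] = frame[col].astype(float)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{path}: non-numeric cell in sample column {col!r}: {exc}")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_beta_matrix(
    path: str | Path,
    dialect: str = "tsv",
    *,
    detection_p: str | Path | None = None,
    bead_counts: str | Path | None = None,
    visit: str = "baseline",
) -> MethylationMatrix:
    """Read a probes-x-samples beta matrix (plus optional companion matrices).

    Out-of-range betas raise :class:`ValidationError` naming the probe and
    sample; they are never clamped.
    """
    betas = _read_matrix_frame(path, dialect)
    dp = None if detection_p is None else _read_matrix_frame(detection_p, dialect)
    bc = None if bead_counts is None else _read_matrix_frame(bead_counts, dialect)
    if bc is not None:
        bc = bc.astype("Int64").astype(object).astype(float) if bc.isna().any().any() else bc.astype(int)
    return MethylationMatrix(betas=betas, detection_p=dp, bead_counts=bc, visit=visit)


def write_beta_matrix(m: MethylationMatrix, path: str | Path, dialect: str = "tsv",
                      which: str = "betas") -> None:
    """Write one layer of a methylation matrix in the canonical dialect.

    The canonical writer round-trips: ``write(read(f))`` reproduces ``f``
    byte-identically for files produced by this writer.
    """
    frame = {"betas": m.betas, "detection_p": m.detection_p, "bead_counts": m.bead_counts}[which]
    if frame is None:
        raise ValidationError(f"matrix has no {which} layer")
    frame.to_csv(Path(path), sep=_sep(dialect), na_rep=MISSING_TOKEN, index_label="probe_id")


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table (indexed by sample_id) and return it.

    Requires positive BMI at both visits, positive interval years, sex in
    {male, female}, and one row per (sample_id, cohort).
    """
    missing = [c for c in PHENOTYPE_COLUMNS[1:] if c not in pheno.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    _check_unique(zip(pheno.index, pheno["cohort"]), "(sample_id, cohort) pairs")
    bad_sex = ~pheno["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValidationError(f"sample {pheno.index[bad_sex][0]!r}: sex must be 'male' or 'female'")
    for col in ("bmi_baseline", "bmi_followup"):
        bad = ~(pheno[col].astype(float) > 0)
        if bad.any():
            raise ValidationError(f"sample {pheno.index[bad][0]!r}: non-positive {col}")
    bad = ~(pheno["interval_years"].astype(float) > 0)
    if bad.any():
        raise ValidationError(f"sample {pheno.index[bad][0]!r}: non-positive interval_years")
    return pheno


def read_phenotypes(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    pheno = pd.read_csv(path, sep=_sep(dialect), na_values=[MISSING_TOKEN, ""], keep_default_na=False, float_precision="round_trip")
    if "sample_id" not in pheno.columns:
        raise ValidationError(f"{path}: missing sample_id column")
    pheno = pheno.set_index("sample_id")
    pheno.index = pheno.index.astype(str)
    for col in ("smoking", "drinking"):
        if col in pheno.columns:
            pheno[col] = pheno[col].astype(int)
    return validate_phenotypes(pheno)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    out = pheno.reset_index().rename(columns={"index": "sample_id"})
    if "sample_id" not in out.columns:
        out = out.rename(columns={out.columns[0]: "sample_id"})
    out[PHENOTYPE_COLUMNS].to_csv(Path(path), sep=_sep(dialect), index=False, na_rep=MISSING_TOKEN)


def sex_to_numeric(sex: pd.Series) -> pd.Series:
    """Encode sex for design matrices: 0 = female, 1 = male."""
    return sex.map({"female": 0.0, "male": 1.0})


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS[1:] if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    _check_unique(manifest.index, "probe ids")
    bad = ~manifest["chromosome"].astype(str).isin(CHROMOSOMES)
    if bad.any():
        raise ValidationError(
            f"probe {manifest.index[bad][0]!r}: chromosome {manifest['chromosome'][bad].iloc[0]!r} "
            f"not in 1-22/X/Y"
        )
    bad = ~manifest["island_relation"].isin(ISLAND_RELATIONS)
    if bad.any():
        raise ValidationError(
            f"probe {manifest.index[bad][0]!r}: island_relation "
            f"{manifest['island_relation'][bad].iloc[0]!r} not in {ISLAND_RELATIONS}"
        )
    bad = ~(manifest["position"].astype(float) >= 1)
    if bad.any():
        raise ValidationError(f"probe {manifest.index[bad][0]!r}: position < 1")
    return manifest


def read_manifest(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    manifest = pd.read_csv(path, sep=_sep(dialect), na_values=[MISSING_TOKEN], keep_default_na=False, float_precision="round_trip")
    if "probe_id" not in manifest.columns:
        raise ValidationError(f"{path}: missing probe_id column")
    manifest = manifest.set_index("probe_id")
    manifest.index = manifest.index.astype(str)
    manifest["chromosome"] = manifest["chromosome"].astype(str)
    manifest["position"] = manifest["position"].astype(int)
    manifest["gene"] = manifest["gene"].fillna("").astype(str)
    manifest["is_snp_probe"] = (
        manifest["is_snp_probe"].replace({"True": 1, "False": 0, "true": 1, "false": 0}).astype(int).astype(bool)
    )
    return validate_manifest(manifest)


def write_manifest(manifest: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    out = manifest.copy()
    out["is_snp_probe"] = out["is_snp_probe"].astype(int)
    out.reset_index(names="probe_id")[MANIFEST_COLUMNS].to_csv(
        Path(path), sep=_sep(dialect), index=False, na_rep=MISSING_TOKEN
    )


# ---------------------------------------------------------------------------
# Cell fractions and references
# ---------------------------------------------------------------------------

def read_cell_fractions(path: str | Path, dialect: str = "tsv") -> CellFractions:
    frame = pd.read_csv(path, sep=_sep(dialect), index_col=0,
                        na_values=[MISSING_TOKEN, ""], keep_default_na=False, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    rmse = None
    if "residual_rmse" in frame.columns:
        rmse = frame.pop("residual_rmse")
    return CellFractions(fractions=frame.astype(float), residual_rmse=rmse)


def write_cell_fractions(fracs: CellFractions, path: str | Path, dialect: str = "tsv") -> None:
    out = fracs.fractions.copy()
    if fracs.residual_rmse is not None:
        out["residual_rmse"] = fracs.residual_rmse
    out.to_csv(Path(path), sep=_sep(dialect), index_label="sample_id", na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def validate_ewas_results(results: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EWAS_RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"EWAS result table missing columns: {missing}")
    for col in ("p_value", "fdr"):
        v = results[col].to_numpy(dtype=float)
        if np.any(np.isfinite(v) & ((v < 0) | (v > 1))):
            raise ValidationError(f"{col} outside [0, 1]")
    return results


def write_results(results: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    """Write an EWAS/meta/enrichment result table with fixed column order.

    Column order follows the table kind (detected from the columns present);
    p-values keep full double precision (pandas' shortest round-trip repr,
    scientific for small values).
    """
    for schema in (EWAS_RESULT_COLUMNS, META_RESULT_COLUMNS):
        if all(c in results.columns for c in schema):
            extras = [c for c in results.columns if c not in schema]
            results = results[schema + extras]
            break
    results.to_csv(Path(path), sep=_sep(dialect), index=False, na_rep=MISSING_TOKEN)


def read_results(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    results = pd.read_csv(path, sep=_sep(dialect), na_values=[MISSING_TOKEN, ""], keep_default_na=False, float_precision="round_trip")
    if "probe_id" in results.columns:
        results["probe_id"] = results["probe_id"].astype(str)
    return results


def probes_to_bed(probes: Sequence[str], manifest: pd.DataFrame, path: str | Path) -> None:
    """Export probes as BED (0-based half-open: start = position - 1, end = position)."""
    missing = [p for p in probes if p not in manifest.index]
    if missing:
        raise ValidationError(f"probes absent from manifest: {missing[:5]}")
    sub = manifest.loc[list(probes)]
    bed = pd.DataFrame({
        "chrom": "chr" + sub["chromosome"].astype(str),
        "start": sub["position"].astype(int) - 1,
        "end": sub["position"].astype(int),
        "name": sub.index,
    })
    bed.to_csv(Path(path), sep="\t", header=False, index=False)
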