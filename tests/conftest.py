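import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from longewas.synthetic_cohort import SimulationConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_manifest() -> pd.DataFrame:
    """Hand-built probe manifest exercising every annotation case."""
    rows = [
        # probe_id, chromosome, position, gene, island_relation, is_snp_probe
        ("cg14671384", "12", 47_219_920, "SLC38A4", "OpenSea", False),
        ("cg10848724", "12", 123_380_878, "VPS37B", "Island", False),
        ("cg25540824", "6", 30_139_686, "TRIM15", "N_Shore", False),
        ("cg02539153", "5", 140_614_765, "PCDHB18; CH17-40K24.2", "N_Shore", False),
        ("cgAUTOSOMAL", "1", 100, "", "S_Shelf", False),
        ("cgSAMEGENE1", "2", 200, "SLC38A4", "OpenSea", False),
        ("cgCHRX", "X", 300, "XGENE", "Island", False),
        ("cgCHRY", "Y", 400, "", "OpenSea", False),
        ("cgSNP", "3", 500, "SNPGENE", "N_Shelf", True),
    ]
    manifest = pd.DataFrame(rows, columns=[
        "probe_id", "chromosome", "position", "gene", "island_relation", "is_snp_probe",
    ]).set_index("probe_id")
    return manifest


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort with planted effects, shared across tests."""
    cfg = SimulationConfig(n_samples=150, n_probes=400, n_causal=3, seed=5)
    baseline, followup, pheno, truth = simulate_cohort(cfg)
    return cfg, baseline, followup, pheno, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
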