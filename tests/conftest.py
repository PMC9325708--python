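"""Shared fixtures: small synthetic studies generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pleioscan.io import GenotypePanel
from pleioscan.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=7, n_blocks=40, snps_per_block=50, n_genes=40,
        n_panel=400, n_cohort=400, ppi_universe_extra=1000,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """A 2000-SNP, 40-gene, 5-trait study with the default planted truth."""
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def tiny_study():
    cfg = SimulationConfig(
        seed=3, n_blocks=6, snps_per_block=30, n_genes=6,
        n_panel=150, n_cohort=120, ppi_universe_extra=300,
    )
    return simulate_study(cfg)


def exact_ld_panel(r: np.ndarray, n: int = 64, spacing_bp: int = 10, seed: int = 0) -> GenotypePanel:
    """A panel whose *sample* correlation matrix equals ``r`` exactly.

    Columns are built from an orthonormal, mean-zero basis rotated by a
    square root of r; useful for closed-form LD arithmetic tests.
    """
    m = r.shape[0]
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, m))
    a -= a.mean(axis=0)
    q, _ = np.linalg.qr(a)
    w, v = np.linalg.eigh(r)
    root = v * np.sqrt(np.clip(w, 0, None))
    x = np.sqrt(n) * q @ root.T
    snps = pd.DataFrame(
        {"SNP": [f"m{k}" for k in range(m)], "CHR": "1",
         "BP": 1 + np.arange(m) * spacing_bp, "A1": "A", "A2": "G"}
    )

    panel = GenotypePanel(snps=snps, dosages=np.zeros((n, m), np.int8))
    # bypass the 0/1/2 coding: tests need the exact continuous correlations
    object.__setattr__(panel, "_std_cache", x)
    return panel


@pytest.fixture
def ar1_exact_panel():
    lag = np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
    return exact_ld_panel(0.9 ** lag)
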