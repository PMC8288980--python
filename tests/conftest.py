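"""Shared fixtures: small hand-built panels and tiny simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from convergescan.panel import SitePanel
from convergescan.simulate import SimulationConfig, SweepConfig, simulate_pair


def build_panel(hap_high: np.ndarray, hap_low: np.ndarray,
                positions: np.ndarray | None = None,
                polarized: np.ndarray | None = None,
                derived_is_alt: np.ndarray | None = None,
                chrom: str = "1") -> SitePanel:
    """Construct a SitePanel from raw haplotype matrices (ALT coding)."""
    hap_high = np.asarray(hap_high, dtype=np.uint8)
    hap_low = np.asarray(hap_low, dtype=np.uint8)
    n = hap_high.shape[1]
    if positions is None:
        positions = (np.arange(n, dtype=np.int64) + 1) * 100
    if polarized is None:
        polarized = np.ones(n, dtype=bool)
    if derived_is_alt is None:
        derived_is_alt = np.ones(n, dtype=bool)
    return SitePanel(
        species="test",
        chrom=np.full(n, chrom, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        snp_id=np.array([f"{chrom}_{p}" for p in positions], dtype=object),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        polarized=np.asarray(polarized, dtype=bool),
        derived_is_alt=np.asarray(derived_is_alt, dtype=bool),
        hap_high=hap_high,
        hap_low=hap_low,
        samples_high=[f"hi{i}" for i in range(hap_high.shape[0] // 2)],
        samples_low=[f"lo{i}" for i in range(hap_low.shape[0] // 2)],
    )


@pytest.fixture
def random_panel():
    """20-site random panel, 8+8 haplotypes, all pooled-polymorphic."""
    rng = np.random.default_rng(42)
    while True:
        hh = rng.integers(0, 2, (8, 20)).astype(np.uint8)
        hl = rng.integers(0, 2, (8, 20)).astype(np.uint8)
        pooled = hh.sum(0) + hl.sum(0)
        if ((pooled > 0) & (pooled < 16)).all():
            return build_panel(hh, hl)


@pytest.fixture(scope="session")
def small_sweep_panel():
    """Tiny fast sweep run shared by several tests (s=0.5, near fixation)."""
    cfg = SimulationConfig(
        n_dip_high=40, n_dip_low=40, L_bp=60_000, n_sites_target=600,
        n_generations_split=40, migration_rate=0.001, r=1e-4, seed=11,
        sweep=SweepConfig(on=True, s=0.5, pos_bp=30_000, min_final_daf=0.95,
                          max_extra_generations=100),
    )
    panel, truth = simulate_pair(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def small_neutral_panel():
    cfg = SimulationConfig(
        n_dip_high=40, n_dip_low=40, L_bp=60_000, n_sites_target=600,
        n_generations_split=30, migration_rate=0.002, r=1e-4, seed=12,
    )
    panel, _ = simulate_pair(cfg)
    return panel
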