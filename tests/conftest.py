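"""Shared synthetic fixtures.

Everything is generated at run time from the package's own simulator;
session scope keeps the larger panels shared across test modules.
"""

import numpy as np
import pytest

import podpop as pp


@pytest.fixture(scope="session")
def qc_bundle():
    """Wild + two cultivated panels with sweeps, missingness and hets."""
    cfg = pp.SimulationConfig(
        n_wild=150, panel_sizes=(150, 150), snps_per_chrom=25,
        sweep_fraction=0.05, sweep_shift=0.8, missing_rate=0.02,
        het_rate=0.01, seed=11)
    panels, truth = pp.simulate_panels(cfg)
    return cfg, panels, truth


@pytest.fixture(scope="session")
def assoc_bundle():
    """One clean (no missing / no het) cultivated panel, n=500, m=2000,
    with a 10-QTL h2=0.8 trait — the association/selection workhorse."""
    cfg = pp.SimulationConfig(
        n_wild=50, panel_sizes=(500,), snps_per_chrom=100, n_qtl=10,
        heritability=0.8, missing_rate=0.0, het_rate=0.0, seed=101)
    panels, truth = pp.simulate_panels(cfg)
    panel = panels[1]
    records = pp.simulate_trait(panel, truth, cfg)
    return cfg, panel, truth, records


@pytest.fixture(scope="session")
def assoc_kinship(assoc_bundle):
    _, panel, _, _ = assoc_bundle
    return pp.kinship(pp.maf_filter(panel), "marker-vanraden")


def plant_qtl(panel, snp_index: int, variance_explained: float,
              rng: np.random.Generator) -> np.ndarray:
    """Trait controlled by one SNP explaining a set fraction of variance."""
    dose = panel.dose_major()[:, snp_index]
    g = (dose - dose.mean())
    sg = g.std()
    if sg == 0:
        raise ValueError("planted SNP is monomorphic")
    g = g / sg * np.sqrt(variance_explained)
    e = rng.standard_normal(panel.n_accessions) * np.sqrt(1 - variance_explained)
    return g + e
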