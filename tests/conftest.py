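"""Shared fixtures: scaled synthetic experiments reused across test modules.

Session-scoped so the read-level pipeline (the expensive part) runs once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from duoqtl.config import PipelineConfig
from duoqtl.pipeline import genotype_parent, sim_config
from duoqtl.simulate import (SimConfig, simulate_experiment,
                             simulate_marker_population, simulate_parents)


@pytest.fixture(scope="session")
def tiny_parents():
    return simulate_parents(n_chrom=2, chrom_len=500_000, het_density=5e-4,
                            seed=11)


@pytest.fixture(scope="session")
def small_experiment():
    """A fast experiment for structural tests (not for power claims)."""
    cfg = SimConfig(n_chrom=2, chrom_len=1_000_000, n_lines=60, deep_n=30,
                    indel_size_range=(250_000, 600_000))
    return simulate_experiment(cfg, seed=7)


@pytest.fixture(scope="session")
def default_stages():
    """Default-scale experiment with both parents phased and genotyped.

    This is the read-level recovery workhorse: 5 chromosomes x 2 Mb,
    343 lines at 0.5x with a 122-line deep subset at 30x.
    """
    cfg = PipelineConfig()
    exp = simulate_experiment(sim_config(cfg), seed=101)
    parents = {p: genotype_parent(exp, p, cfg) for p in ("Pd", "Pn")}
    return cfg, exp, parents


@pytest.fixture(scope="session")
def marker_population():
    """Marker-level population: 343 lines, 5 chromosomes x 20 markers."""
    return simulate_marker_population(seed=23)
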