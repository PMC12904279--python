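"""Shared fixtures: hand-built panels and a small synthetic experiment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolsel.datatypes import PooledCounts, StrainGenotypeMatrix
from poolsel.simulate import SimulationConfig, simulate_experiment


def make_panel(calls: np.ndarray, replicon: str = "chromosome",
               ld_groups=None, strain_ids=None) -> StrainGenotypeMatrix:
    """Small panel builder: calls is strains x variants (0/1/NaN)."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    strains = strain_ids or [f"S{i+1:02d}" for i in range(n)]
    vids = [f"{replicon}:{(j+1)*100}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "replicon": replicon,
            "pos": [(j + 1) * 100 for j in range(m)],
            "ld_group": ld_groups or [f"{replicon}_g{j+1}" for j in range(m)],
        },
        index=pd.Index(vids, name="variant_id"),
    )
    return StrainGenotypeMatrix(pd.DataFrame(calls, index=strains, columns=vids),
                                variants)


def make_counts(panel: StrainGenotypeMatrix, alt, ref, sample_id="s1") -> PooledCounts:
    return PooledCounts(
        sample_id,
        pd.DataFrame(
            {"ref_count": ref, "alt_count": alt},
            index=panel.variant_ids.rename("variant_id"),
        ),
    )


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """A small but complete experiment: 24 strains, 6 hosts, 2 replicates."""
    return SimulationConfig(
        n_strains=24,
        variants_per_replicon={"chromosome": 60, "pSymA": 60, "pSymB": 60},
        ld_block_size=2.0,
        n_hosts=6,
        replicates_per_host=2,
        n_inoculum_aliquots=3,
        n_pervasive=1,
        pervasive_hosts=3,
        n_limited=2,
        limited_hosts_max=2,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_experiment(tiny_config):
    return simulate_experiment(tiny_config)


@pytest.fixture(scope="session")
def panel3():
    """3 strains x 4 variants with one missing call (hand-checked fixture)."""
    calls = np.array(
        [
            [1.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, np.nan],
        ]
    )
    return make_panel(calls, replicon="pSymA")
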