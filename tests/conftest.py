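from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the bruteforce oracle module

from gpmap import synthetic
from gpmap.pbm_io import EScoreTable
from gpmap.space import build_omega


@pytest.fixture(scope="session")
def omega4():
    return build_omega(4)


@pytest.fixture(scope="session")
def omega8():
    return build_omega(8)


@pytest.fixture(scope="session")
def toy_table4(omega4):
    """Three overlapping phenotypes on the k=4 space, plus a truth record."""
    spec = synthetic.SyntheticSpec(
        n_tfs=3,
        k=4,
        seed=11,
        consensus_sites=["ACGG", "ACGT", "TTTT"],
        decay=[0.06, 0.06, 0.08],
        noise_sd=0.0,
    )
    table, truth = synthetic.generate_escore_table(spec, omega4)
    return table, truth


@pytest.fixture(scope="session")
def synth10(omega8):
    """Ten-TF synthetic dataset on the full space, mild noise."""
    spec = synthetic.SyntheticSpec(
        n_tfs=10,
        seed=7,
        decay=[synthetic.decay_for_radius(r) for r in (2, 3)],
        noise_sd=0.01,
    )
    table, truth = synthetic.generate_escore_table(spec, omega8)
    meta = synthetic.generate_metadata(spec)
    return table, meta, truth


def make_table(scores: dict[str, dict[str, float]], k: int = 8, fill: float = -0.4):
    """Small helper: build a complete EScoreTable from sparse scores.

    ``scores`` maps tf_id -> {site: escore}; all other sites get ``fill``.
    """
    from gpmap.space import canonical, enumerate_space

    sites = enumerate_space(k)
    frame = pd.DataFrame(fill, index=pd.Index(sites, name="8mer"), columns=list(scores))
    for tf, vals in scores.items():
        for site, v in vals.items():
            frame.loc[canonical(site), tf] = v
    return EScoreTable(frame, k=k)
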