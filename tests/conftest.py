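"""Shared fixtures: synthetic datasets at two scales.

The full-scale dataset (2,000 genes, 20 Mb, enrichment fold 5) is generated
once per session and shared by the recovery/acceptance tests; the small one
keeps module tests fast.
"""

import numpy as np
import pandas as pd
import pytest

from chromstate import analyze_bundle
from chromstate.reads import ReadLibrary
from chromstate.synthetic_data import SimulationConfig, generate_dataset

FULL_SEED = 0
SMALL_SEED = 3


@pytest.fixture(scope="session")
def full_dataset():
    cfg = SimulationConfig(seed=FULL_SEED)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def full_analysis(full_dataset):
    cfg = full_dataset["config"]
    return analyze_bundle(
        full_dataset["transcripts"], full_dataset["libraries"],
        full_dataset["rpkm"], genome_bp=cfg.genome_bp, seed=cfg.seed)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(
        seed=SMALL_SEED, n_genes=300, genome_bp=4_000_000,
        n_short_transcripts=7, n_overlapping_pairs=5,
        n_close_tss_pairs=5, n_multi_isoform=10)
    return generate_dataset(cfg)


def make_library(plus_positions, minus_positions, chrom="c",
                 read_length=25, fragment_size=160, name="test"):
    """Small hand-built library from explicit per-strand 5' positions."""
    p = np.asarray(plus_positions, dtype=int)
    m = np.asarray(minus_positions, dtype=int)
    df = pd.DataFrame({
        "chrom": chrom,
        "start": np.r_[p, m - read_length + 1],
        "end": np.r_[p + read_length, m + 1],
        "strand": ["+"] * len(p) + ["-"] * len(m),
    })
    return ReadLibrary(name, df, fragment_size=fragment_size)
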