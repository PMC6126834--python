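"""Shared fixtures: small seeded synthetic worlds used across the suite."""

import numpy as np
import pandas as pd
import pytest

from stratenrich.assoc_stats import add_chisq
from stratenrich.io_formats import AnnotationSet
from stratenrich.synthetic_data import SimConfig, simulate_gwas, simulate_variants


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(n_variants=2_000, block_size=10, block_span_bp=30_000, seed=11)


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    """2,000-variant block-LD universe with tissue eQTL and chromatin sets."""
    variants, ld_pairs, sets = simulate_variants(tiny_config)
    return variants, ld_pairs, sets


@pytest.fixture(scope="session")
def tiny_stats(tiny_world, tiny_config):
    variants, _, sets = tiny_world
    return add_chisq(simulate_gwas(variants, tiny_config, sets=sets))


@pytest.fixture()
def hand_variants():
    """Ten hand-placed variants on two chromosomes for coordinate tests."""
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(1, 11)],
            "chrom": ["chr1"] * 6 + ["chr2"] * 4,
            "pos": [50, 101, 150, 201, 500, 1000, 100, 150, 400, 900],
            "maf": np.linspace(0.05, 0.45, 10),
            "is_genic": [True, False] * 5,
            "tss_distance": [1000.0, 24_999.0, 25_000.0, 25_001.0, 40_000.0,
                             np.nan, 500.0, 60_000.0, 10.0, 30_000.0],
            "total_ld": np.ones(10),
        }
    )


def annotation(label, ids):
    return AnnotationSet(label=label, variant_ids=frozenset(ids), provenance="test")


@pytest.fixture()
def make_set():
    return annotation
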