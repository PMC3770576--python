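"""Shared fixtures: small synthetic datasets and the haplogroup rule table."""

from pathlib import Path

import numpy as np
import pytest

from mtscan import SimConfig, simulate_dataset
from mtscan.genotype_io import Haplotype

RULES_PATH = (
    Path(__file__).parent.parent
    / "src"
    / "mtscan"
    / "data"
    / "synthetic_haplogroup_rules.tsv"
)


@pytest.fixture(scope="session")
def rules_path() -> Path:
    return RULES_PATH


@pytest.fixture(scope="session")
def small_sim():
    """200 individuals on 15 haplotypes with a planted 2.5-SD clade shift."""
    cfg = SimConfig(
        n_individuals=200,
        n_haplotypes=15,
        n_sites=40,
        delta=2.5,
        clade_target_size=25,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """150 individuals, no planted effect."""
    cfg = SimConfig(
        n_individuals=150, n_haplotypes=12, n_sites=30, delta=0.0, seed=7
    )
    return simulate_dataset(cfg)


def make_haplotypes(vectors, counts=None, prefix="H"):
    """Hand-built haplotype list from binary strings."""
    counts = counts or [1] * len(vectors)
    haps = []
    k = 0
    for i, (vec, cnt) in enumerate(zip(vectors, counts)):
        members = frozenset(f"S{j:03d}" for j in range(k, k + cnt))
        k += cnt
        haps.append(
            Haplotype(
                haplotype_id=f"{prefix}{i + 1:03d}",
                alleles=tuple(int(c) for c in vec),
                members=members,
            )
        )
    return haps


@pytest.fixture
def rng():
    return np.random.default_rng(123)
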