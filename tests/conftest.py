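"""Shared fixtures: small synthetic objects built fresh per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cortmapgen.synthetic_data import (
    PhantomConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_phantom,
)
from cortmapgen.types import GenotypeMatrix


def make_snp_meta(n: int, chrom: str = "1", spacing: int = 1000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(n)],
            "chrom": chrom,
            "pos": 10_000 + spacing * np.arange(n),
            "ref_allele": "A",
            "has_ref_id": True,
            "ref_allele_valid": True,
        }
    )


def make_genotypes(calls: np.ndarray, **meta_kwargs) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(calls=calls, snp_meta=make_snp_meta(calls.shape[1], **meta_kwargs))


def make_covariates(n: int, seed: int = 0, n_sites: int = 2) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age_years": rng.uniform(45, 83, n),
            "sex": rng.integers(0, 2, n),
            **{f"pc{k}": rng.normal(0, 1, n) for k in range(1, 6)},
            "site_id": rng.integers(0, n_sites, n),
        },
        index=pd.Index([f"P{i:06d}" for i in range(n)], name="participant_id"),
    )


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A fast cohort: strong effects so planted signal is unambiguous."""
    from cortmapgen.synthetic_data import LDBlockSpec

    return SimulationConfig(
        n_participants=400,
        n_snps=200,
        n_locations=162,
        ld_block_spec=LDBlockSpec(n_blocks=2, block_size=3, target_dprime=0.9),
        n_monomorphic=10,
        n_bad_refid=5,
        n_bad_allele=5,
        archetype_count=4,
        n_causal_per_archetype=10,
        effect_size_per_archetype=25.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg, phenotype_names=("CT",))


@pytest.fixture(scope="session")
def phantom_default():
    return simulate_phantom(PhantomConfig())
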