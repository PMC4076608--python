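"""Shared fixtures: small but fully featured synthetic cross datasets."""

from __future__ import annotations

import pytest

from methcross import simulate
from methcross.simulate import TruthConfig


@pytest.fixture(scope="session")
def small_config() -> TruthConfig:
    """Compact study-condition generator config: 60x, 1% error, all effects."""
    return TruthConfig(
        n_regions=6,
        region_length=1500,
        n_strain_sites=30,
        n_sex_sites=20,
        n_imprinted_regions=2,
        n_epimutation_sites=4,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate.build_truth_model(small_config, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return simulate.simulate_dataset(small_truth, seed=12)


@pytest.fixture(scope="session")
def clean_config() -> TruthConfig:
    """Noise-free variant: no sequencing error, no replicate dispersion."""
    return TruthConfig(
        n_regions=4,
        region_length=1500,
        error_rate=0.0,
        sample_jitter_sd=0.0,
        n_strain_sites=20,
        n_sex_sites=10,
        n_imprinted_regions=1,
        n_epimutation_sites=2,
    )


@pytest.fixture(scope="session")
def clean_truth(clean_config):
    return simulate.build_truth_model(clean_config, seed=21)


@pytest.fixture(scope="session")
def clean_dataset(clean_truth):
    return simulate.simulate_dataset(clean_truth, seed=22)


@pytest.fixture(scope="session")
def small_amr_results(small_dataset):
    """Per-sample AMR scans plus cross-sample imprinted candidates."""
    from methcross.amr import amr_scan, candidate_imprinted_regions
    from methcross.io import standard_cross_samples

    metas = {m.sample_id: m for m in standard_cross_samples()}
    per_sample = {
        sample_id: amr_scan(small_dataset[sample_id].epireads, seed=i)
        for i, sample_id in enumerate(metas)
    }
    candidates = candidate_imprinted_regions(per_sample, metas)
    return per_sample, candidates


@pytest.fixture(scope="session")
def epi_null_truth():
    """Noise-free cross with every effect class planted except epimutations."""
    cfg = TruthConfig(
        n_regions=3,
        region_length=1200,
        error_rate=0.0,
        sample_jitter_sd=0.0,
        n_strain_sites=12,
        n_sex_sites=8,
        n_imprinted_regions=1,
        n_epimutation_sites=0,
    )
    return simulate.build_truth_model(cfg, seed=31)


@pytest.fixture(scope="session")
def epi_null_dataset(epi_null_truth):
    return simulate.simulate_dataset(epi_null_truth, seed=32)
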