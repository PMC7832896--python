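"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from radsexmark import SimParams, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


CLEAN = dict(error_rate=0.0, dropout_rate=0.0, lowqual_fraction=0.0)


@pytest.fixture(scope="session")
def clean_zw(tmp_path_factory):
    """Noise-free ZW dataset: every carried tag is sequenced verbatim."""
    params = SimParams(
        n_males=5, n_females=4, system="ZW",
        n_autosomal_loci=30, n_sexlimited_loci=6, n_gametolog_pairs=3,
        mean_depth=20.0, poly_fraction=0.3, seed=11, **CLEAN,
    )
    return simulate_dataset(params, tmp_path_factory.mktemp("clean_zw"))


@pytest.fixture(scope="session")
def clean_xy(tmp_path_factory):
    """Noise-free XY dataset used by the recovery tests."""
    params = SimParams(
        n_males=4, n_females=4, system="XY",
        n_autosomal_loci=25, n_sexlimited_loci=5, n_gametolog_pairs=2,
        mean_depth=20.0, poly_fraction=0.0, seed=23, **CLEAN,
    )
    return simulate_dataset(params, tmp_path_factory.mktemp("clean_xy"))


@pytest.fixture(scope="session")
def noisy_zw(tmp_path_factory):
    """ZW dataset with sequencing error and allelic dropout enabled."""
    params = SimParams(
        n_males=6, n_females=4, system="ZW",
        n_autosomal_loci=60, n_sexlimited_loci=8, n_gametolog_pairs=2,
        mean_depth=20.0, error_rate=0.001, dropout_rate=0.02, seed=5,
    )
    return simulate_dataset(params, tmp_path_factory.mktemp("noisy_zw"))
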