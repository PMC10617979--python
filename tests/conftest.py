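"""Shared fixtures: small synthetic populations and a quickly trained model."""

import numpy as np
import pytest

from ledshape.mesh import compute_template_stats
from ledshape.networks import ArchitectureConfig, MeshHierarchy
from ledshape.spectral import fit_spectral_basis
from ledshape.synthetic import SyntheticSpec, make_template, sample_population
from ledshape.training import TrainConfig, Trainer


@pytest.fixture(scope="session")
def small_spec():
    # 162-vertex sphere: big enough for 4 connected sectors, fast to train on
    return SyntheticSpec(subdivision=2, n_attributes=4, factors_per_attribute=3,
                         factor_scale=(0.05,), noise_std=0.0005, seed=11)


@pytest.fixture(scope="session")
def small_template(small_spec):
    return make_template(small_spec)


@pytest.fixture(scope="session")
def small_population(small_spec):
    pop, factors = sample_population(small_spec, 250)
    return pop, factors


@pytest.fixture(scope="session")
def small_stats(small_population):
    return compute_template_stats(small_population[0])


@pytest.fixture(scope="session")
def small_basis(small_population, small_stats):
    return fit_spectral_basis(small_population[0], small_stats, kappa=3)


@pytest.fixture(scope="session")
def tiny_arch():
    return ArchitectureConfig(channels=(8, 16), spiral_length=6)


@pytest.fixture(scope="session")
def small_hierarchy(small_population, small_stats, tiny_arch):
    pop, _ = small_population
    return MeshHierarchy(pop.topology, small_stats.mean, tiny_arch)


@pytest.fixture(scope="session")
def trained_led_vae(small_population, small_stats, small_basis, tiny_arch,
                    small_hierarchy):
    """LED-VAE trained briefly on the small population; used by editing and
    localization tests that only need a generator with locality structure."""
    pop, _ = small_population
    cfg = TrainConfig(flavour="vae", epochs=60, batch_size=16, seed=5)
    trainer = Trainer(pop, small_stats, small_basis, cfg, arch=tiny_arch,
                      hierarchy=small_hierarchy)
    trainer.fit()
    return trainer
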