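"""Shared fixtures: the default phantom, material fields and reference runs.

Simulation fixtures are session-scoped — several analysis tests reuse the
same breathing runs instead of re-integrating them.
"""

import numpy as np
import pytest

import porolung as pl


@pytest.fixture(scope="session")
def phantom_mesh():
    """Default coarse three-zone ellipsoid phantom (seed 0)."""
    return pl.build_multizone_phantom(pl.PhantomSpec(), seed=0)


@pytest.fixture(scope="session")
def tiny_mesh():
    """Very coarse phantom for fast solver checks."""
    spec = pl.PhantomSpec(target_edge_length=(0.03, 0.035, 0.04))
    return pl.build_multizone_phantom(spec, seed=0)


@pytest.fixture(scope="session")
def iso_material(phantom_mesh):
    return pl.generate_elasticity_field(
        phantom_mesh, pl.ElasticityFieldSpec(mode="isotropic")
    )


@pytest.fixture(scope="session")
def aniso_material(phantom_mesh):
    return pl.generate_elasticity_field(
        phantom_mesh, pl.ElasticityFieldSpec(mode="anisotropic_synthetic", seed=0)
    )


@pytest.fixture(scope="session")
def landmarks(phantom_mesh):
    return pl.default_landmarks(phantom_mesh)


@pytest.fixture(scope="session")
def waveform():
    return pl.Waveform()


@pytest.fixture(scope="session")
def linear_run_3cyc(phantom_mesh, iso_material, waveform):
    """Reference linear-isotropic breathing run: 3 cycles at dt = 0.02 s."""
    return pl.run_simulation(
        phantom_mesh, iso_material, waveform, pl.SolverConfig(n_cycles=3)
    )


@pytest.fixture(scope="session")
def linear_run_6cyc(phantom_mesh, iso_material, waveform):
    return pl.run_simulation(
        phantom_mesh, iso_material, waveform, pl.SolverConfig(n_cycles=6)
    )


@pytest.fixture(scope="session")
def aniso_run_3cyc(phantom_mesh, aniso_material, waveform):
    return pl.run_simulation(
        phantom_mesh, aniso_material, waveform, pl.SolverConfig(n_cycles=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
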