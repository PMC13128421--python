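"""Shared fixtures.

The heavy end-to-end pipeline results are session-scoped: one run at
the full 0.5-mm phantom resolution (used by the geometric-oracle and
classification-recovery checks) and cheaper 1-mm runs for everything
else.  All seeds are fixed.
"""

import numpy as np
import pytest
import trimesh

from colliflow import (PhantomConfig, PipelineConfig, TriangleMesh,
                       make_phantom, run_pipeline)

SEED = 7


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    return PipelineConfig(
        phantom=PhantomConfig(voxel_size_mm=1.0, rng_seed=SEED),
        rng_seed=SEED, n_boot=500, write_plots=False)


@pytest.fixture(scope="session")
def fast_result(fast_config):
    """Full pipeline on the 1-mm phantom."""
    return run_pipeline(fast_config)


@pytest.fixture(scope="session")
def noiseless_result():
    """Full pipeline on a noise- and drift-free 1-mm phantom."""
    cfg = PipelineConfig(
        phantom=PhantomConfig(voxel_size_mm=1.0, noise_sd=0.0,
                              drift_amplitude=0.0, rng_seed=SEED),
        rng_seed=SEED, n_boot=500, write_plots=False)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline at the default 0.5-mm phantom resolution."""
    cfg = PipelineConfig(phantom=PhantomConfig(rng_seed=SEED), rng_seed=SEED)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def fast_phantom():
    return make_phantom(PhantomConfig(voxel_size_mm=1.0, rng_seed=SEED))


@pytest.fixture()
def icosphere() -> TriangleMesh:
    """Analytic sphere mesh, radius 10 mm."""
    tm = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


@pytest.fixture()
def small_mesh() -> TriangleMesh:
    """Coarse closed mesh (80 faces) for brute-force distance oracles."""
    tm = trimesh.creation.icosphere(subdivisions=1, radius=5.0)
    v = np.asarray(tm.vertices).copy()
    rng = np.random.default_rng(SEED)
    v *= 1.0 + 0.1 * rng.standard_normal(len(v))[:, None]   # break symmetry
    return TriangleMesh(v, np.asarray(tm.faces))
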