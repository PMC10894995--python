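"""Shared fixtures: small phantoms and the (expensive) end-to-end study runs.

The end-to-end pipeline and FEM accuracy studies are session-scoped so the
acceptance tests can share one set of solves.
"""

import logging
import warnings

import numpy as np
import pytest

from seegvc import fem
from seegvc.phantom import (
    ConductivityProfile,
    build_sphere_phantom,
    make_stimulation_plan,
    place_shafts,
)
from seegvc.pipeline import PipelineConfig, run_pipeline

logging.getLogger("seegvc").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="voxel size .* exceeds thinnest shell")

#: nested five-shell phantom small enough for per-test meshing
SMALL_RADII = {"scalp": 9.0, "skull": 8.0, "csf": 7.0, "gray": 6.0, "white": 5.0}

STUDY_SEEDS = (1, 2)


@pytest.fixture(scope="session")
def small_phantom():
    return build_sphere_phantom(SMALL_RADII, voxel_size_mm=1.0)


@pytest.fixture(scope="session")
def study_phantom():
    """Study-size five-shell phantom (50 mm outer radius, 2 mm voxels)."""
    return build_sphere_phantom(PipelineConfig().radii_mm_by_tissue, voxel_size_mm=2.0)


@pytest.fixture(scope="session")
def brain_sphere():
    """Homogeneous 20 mm 'gray' sphere at 2 mm voxels."""
    return build_sphere_phantom({"gray": 20.0}, voxel_size_mm=2.0)


@pytest.fixture(scope="session")
def brain_sphere_mesh(brain_sphere):
    return fem.voxels_to_hex_mesh(brain_sphere, node_shift=0.0)


@pytest.fixture(scope="session")
def brain_profile():
    return ConductivityProfile("4C", {4: 0.33})


@pytest.fixture(scope="session")
def brain_system(brain_sphere_mesh, brain_profile):
    return fem.assemble_stiffness(brain_sphere_mesh, brain_profile)


@pytest.fixture(scope="session")
def reciprocity_setup(brain_sphere):
    """Small phantom with two shafts and three stimulation pairs."""
    electrodes = place_shafts(
        brain_sphere, n_shafts=2, contacts_per_shaft=5, seed=7, focus_spread_mm=3.0
    )
    plan = make_stimulation_plan(
        electrodes, n_pairs=3, n_events_per_pair=1, inter_event_samples=400, seed=8
    )
    return brain_sphere, electrodes, plan


def study_config(seed: int) -> PipelineConfig:
    return PipelineConfig(seed=seed)


@pytest.fixture(scope="session")
def study_results():
    """Full synthetic validation runs at the study conditions, two seeds."""
    return {seed: run_pipeline(study_config(seed)) for seed in STUDY_SEEDS}


def tiny_config(seed: int = 3) -> PipelineConfig:
    """Coarser, smaller configuration for smoke/determinism runs."""
    return PipelineConfig(
        seed=seed,
        voxel_size_mm=3.0,
        n_shafts=3,
        contacts_per_shaft=10,
        n_pairs=5,
        n_events_per_pair=2,
    )


@pytest.fixture(scope="session")
def tiny_run_pair(tmp_path_factory):
    """The same tiny configuration executed twice into separate directories."""
    outs = []
    for tag in ("a", "b"):
        out = tmp_path_factory.mktemp(f"tiny_{tag}")
        result = run_pipeline(tiny_config(), out_dir=out)
        outs.append((out, result))
    return outs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
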