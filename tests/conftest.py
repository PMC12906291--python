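"""Shared fixtures: small phantoms and one small end-to-end pipeline run.

All fixtures are generated programmatically; heavy ones are session-scoped
so the full suite builds each phantom exactly once.
"""

import numpy as np
import pytest

from bonereg import PhantomSpec, PipelineConfig, make_phantom, run_pipeline

SMALL = dict(shape=(64, 64, 64), vol_spacing=21.0, section_downscale=4)


@pytest.fixture(scope="session")
def bundle_plain():
    """Distortion-free, noise-free, untilted phantom: ground truth and the
    section agree exactly up to discretization."""
    spec = PhantomSpec(plane_tilt=0.0, warp_amplitude=0.0, noise_sd=0.0,
                       seed=7, **SMALL)
    return spec, make_phantom(spec)


@pytest.fixture(scope="session")
def bundle_warped():
    """Small phantom with realistic tilt, sectioning distortion and noise."""
    spec = PhantomSpec(plane_tilt=8.0, warp_amplitude=2 * 21.0 / 4, noise_sd=0.05,
                       seed=11, **SMALL)
    return spec, make_phantom(spec)


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(
        simulate=True, seed=5,
        phantom=dict(plane_tilt=6.0, warp_amplitude=2 * 21.0 / 4, **SMALL),
        orientation_step_deg=6.0, psi_step_deg=15.0, cone_deg=25.0,
        max_edge_points=2500, top_k=200, refine_candidates=3,
        refine_maxfev=250, elastic_iterations=30)


@pytest.fixture(scope="session")
def small_run(small_config, tmp_path_factory):
    """One complete pipeline run on the small phantom."""
    out = tmp_path_factory.mktemp("pipeline_run")
    return small_config, run_pipeline(small_config, out)


def rng(seed=0):
    return np.random.default_rng(seed)
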