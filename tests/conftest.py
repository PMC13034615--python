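import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_spec():
    """Compact shell phantom for geometry unit tests (spec-example radii)."""
    from lamvaso.phantom import PhantomSpec

    return PhantomSpec(domain_shape=(48, 48, 12), shell_inner_radius_mm=10.0,
                       shell_outer_radius_mm=12.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_sim():
    """Noise-free default phantom: one simulated run plus its ground truth."""
    from lamvaso.phantom import (PhantomSpec, build_ribbon, make_design,
                                 paint_digits, simulate_run)

    spec = PhantomSpec(noise_sd_bold=0.0, noise_sd_nulled=0.0, seed=3)
    seg, depth_truth = build_ribbon(spec)
    truth = paint_digits(seg, depth_truth, spec)
    design = make_design(spec, 13)
    nulled, bold, motion = simulate_run(seg, truth, design, spec, 99)
    return dict(spec=spec, seg=seg, depth_truth=depth_truth, truth=truth,
                design=design, nulled=nulled, bold=bold, motion=motion)


@pytest.fixture(scope="session")
def default_pipeline(tmp_path_factory):
    """Full pipeline on the default-noise shell phantom (3 runs, 12 trials/digit)."""
    from lamvaso.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipe_default")
    return run_pipeline(PipelineConfig(outdir=str(out), seed=2))


@pytest.fixture(scope="session")
def noiseless_pipeline(tmp_path_factory):
    """Full pipeline on the zero-noise shell phantom."""
    from lamvaso.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipe_noiseless")
    return run_pipeline(PipelineConfig(outdir=str(out), seed=2,
                                       noise_sd_bold=0.0, noise_sd_nulled=0.0))


@pytest.fixture(scope="session")
def slab_pipeline(tmp_path_factory):
    """Zero-noise flat-slab pipeline (equivolume == equidistant limit)."""
    from lamvaso.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipe_slab")
    return run_pipeline(PipelineConfig(outdir=str(out), seed=2, geometry="slab",
                                       n_runs=1, noise_sd_bold=0.0,
                                       noise_sd_nulled=0.0))
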