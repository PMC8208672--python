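import pytest
from hypothesis import HealthCheck, settings

from nestheat.pipeline import RunConfig, run_pipeline
from nestheat.simulate import (
    BreedingConfig,
    SimulationConfig,
    TeConfig,
    WashoutConfig,
    WeatherConfig,
    simulate_bundle,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def small_config() -> SimulationConfig:
    """A scaled-down study: fast to generate, every stage still exercised."""
    return SimulationConfig(
        washout=WashoutConfig(n_birds=20),
        weather=WeatherConfig(n_days=40),
        te=TeConfig(n_nests=8, days_per_nest=6),
        breeding=BreedingConfig(n_nests=40, n_obs_days=15, n_mass_birds=60),
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Small synthetic input bundle on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    bundle, truth = simulate_bundle(small_config(), seed=123, outdir=outdir)
    return outdir, bundle, truth


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    """Full pipeline output for the small bundle."""
    indir, bundle, truth = bundle_dir
    outdir = tmp_path_factory.mktemp("report")
    staged = run_pipeline(
        RunConfig(
            input_dir=str(indir),
            output_dir=str(outdir),
            seed=123,
            breakpoint_bootstrap_reps=200,
            log_level="WARNING",
        )
    )
    return outdir, staged, truth
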