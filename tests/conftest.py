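import pytest
from hypothesis import HealthCheck, settings

from nodsyn import pipeline as pl
from nodsyn import synthdata as sd

settings.register_profile(
    "repeatable",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")


def small_config(rng_seed: int = 0) -> sd.SimConfig:
    """Two-species desk config (one with a recent WGD) for fast tests."""
    return sd.SimConfig(
        species=(
            sd.SpeciesSpec("G. max", "Gm", (40_000_000,) * 4, 640, has_recent_wgd=True),
            sd.SpeciesSpec("M. truncatula", "Mt", (40_000_000,) * 3, 480),
        ),
        n_seed_groups=8,
        cluster=sd.ClusterSpec(fraction=6 / 8, span_bp=2_000_000),
        rng_seed=rng_seed,
    )


@pytest.fixture(scope="session")
def default_dataset() -> sd.SimulatedDataset:
    """The four-species default genome, simulated once per session."""
    return sd.simulate(sd.default_config(0))


@pytest.fixture(scope="session")
def small_dataset() -> sd.SimulatedDataset:
    return sd.simulate(small_config(0))


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory) -> pl.PipelineResult:
    """One full pipeline run on the small config, shared across tests."""
    cfg = pl.RunConfig(
        outdir=tmp_path_factory.mktemp("run"),
        simulate=small_config(),
        thresholds=pl.Thresholds(n_permutations=300),
        rng_seed=1,
    )
    return pl.run(cfg)
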