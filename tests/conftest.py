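import pytest
from hypothesis import settings

from festcons.fixtures import FixtureParams, generate_toy_dataset, generate_wgd_dataset
from festcons.pipeline import run_pipeline

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

WGD_CATEGORY_PLAN = {"1:2": 1, "1:1": 2, "0:2": 4, "1:0": 3, "0:1": 5}


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """Small 3-species dataset with 20 planted conserved clusters."""
    outdir = tmp_path_factory.mktemp("toy")
    manifest = generate_toy_dataset(FixtureParams(), seed=11, outdir=outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def toy_result(toy_dataset):
    outdir, _ = toy_dataset
    return run_pipeline(outdir)


@pytest.fixture(scope="session")
def wgd_dataset(tmp_path_factory):
    """Singleton:duplicate-pair sets with one planted event per category."""
    outdir = tmp_path_factory.mktemp("wgd")
    manifest = generate_wgd_dataset(
        WGD_CATEGORY_PLAN, seed=5, outdir=outdir, rescued_fraction=0.5
    )
    return outdir, manifest


@pytest.fixture(scope="session")
def wgd_result(wgd_dataset):
    outdir, _ = wgd_dataset
    return run_pipeline(outdir)
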