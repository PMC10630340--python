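import warnings

import pytest

from nestprimer.config import PipelineConfig
from nestprimer.fixtures import FixtureSpec, generate_fixture
from nestprimer.pipeline import PipelineInputs, run_pipeline

warnings.filterwarnings("ignore", category=DeprecationWarning)

SMALL_SPEC = dict(
    n_qualifying_loci=3,
    n_short_exons=1,
    n_duplicated_exons=1,
    n_hyperconserved=1,
    n_hypervariable=1,
    n_ingroup_taxa=2,
    n_outgroup_taxa=1,
    seed=7,
)


@pytest.fixture(scope="session")
def small_fixture():
    return generate_fixture(FixtureSpec(**SMALL_SPEC))


@pytest.fixture(scope="session")
def small_run(small_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_run")
    config = PipelineConfig(random_seed=7)
    manifest = run_pipeline(config, PipelineInputs.from_fixture(small_fixture), outdir)
    return manifest, outdir, small_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The full study conditions: 20 qualifying loci, 5 of each decoy class,
    6 ingroup and 2 outgroup taxa."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_run(default_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(random_seed=1)
    manifest = run_pipeline(
        config, PipelineInputs.from_fixture(default_fixture), outdir
    )
    return manifest, outdir, default_fixture
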