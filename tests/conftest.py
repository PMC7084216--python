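import random

import pytest

from mornaquant.pipeline import RunConfig, run_pipeline
from mornaquant.simulate import SimBundle, simulate_dataset, write_bundle


@pytest.fixture(scope="session")
def bundle() -> SimBundle:
    """Canonical-only synthetic dataset shared across the suite."""
    return simulate_dataset(seed=11)


@pytest.fixture(scope="session")
def sim_paths(bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return write_bundle(bundle, outdir)


def make_run_config(bundle, paths, outdir, **overrides) -> RunConfig:
    cfg = RunConfig(
        samples={"s1": str(paths["reads"])},
        genome=str(paths["genome"]),
        annotation=str(paths["annotation"]),
        fold_structures=str(paths["structures"]),
        adapter=bundle.adapter,
        outdir=str(outdir),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def run_result(bundle, sim_paths, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    cfg = make_run_config(bundle, sim_paths, outdir)
    return run_pipeline(cfg)


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(0)
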