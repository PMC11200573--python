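import numpy as np
import pytest

from fquwf import (NetConfig, PhantomParams, RunConfig, generate_phantom,
                   run_pipeline)


@pytest.fixture(scope="session")
def tiny_cfg():
    return NetConfig.tiny()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def vessel_phantom():
    """One fixed clean phantom used by sharpness/degradation tests."""
    return generate_phantom(PhantomParams(size=96, n_drusen=3), seed=5).clean


@pytest.fixture(scope="session")
def trained_pipeline(tmp_path_factory):
    """The miniature end-to-end training run shared by the pipeline tests.

    Runs the full schedule (pretrain 500 / DE 500 / SR 500 / macular FT 200
    iterations, batch 4, 64-pixel fundus patches) once per test session.
    """
    root = tmp_path_factory.mktemp("e2e") / "run"
    config = RunConfig(seed=1, output_root=str(root))
    summary = run_pipeline(config)
    return {"summary": summary, "root": root, "config": config}
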