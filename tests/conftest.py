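import numpy as np
import pytest

import hbmscore as hs


@pytest.fixture(scope="session")
def ref_config_continuous():
    """Reference-solution generator in continuous mode."""
    return hs.reference_config(response_scale="continuous", seed=20260919)


@pytest.fixture(scope="session")
def large_continuous_fit(ref_config_continuous):
    """CFA fit to n = 50,000 continuous responses from the reference solution.

    Shared session-wide: this is the canonical parameter-recovery benchmark.
    """
    cfg = hs.GeneratorConfig.from_dict(
        {**ref_config_continuous.to_dict(), "n_post": 50_000}
    )
    _, post = hs.generate_study(cfg)
    return hs.fit(post, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
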