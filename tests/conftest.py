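import numpy as np
import pytest

from ppikit import GroundTruth, PipelineConfig
from ppikit.diagnostics import subject_interaction_stats


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def null_pipeline4_stats():
    """Subject-level interaction (t, p) under the AR(1) null, Pipeline 4.

    Null world satisfying the fitted model's error assumption: no
    interaction, no physiological coupling, no target latent noise — the
    target's stochastic part is purely AR(1) measurement noise.  Shared
    across the calibration and p-uniformity tests (1,000 replicates).
    """
    truth = GroundTruth(beta_ppi=0.0, alpha=0.0, target_latent_sd=0.0, rho_noise=0.4)
    return subject_interaction_stats(
        truth, 1000, PipelineConfig.from_pipeline(4), master_seed=424242
    )
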