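import numpy as np
import pytest

from teloscreen import CohortSimConfig, DESK_QC, MotifSpec, generate_cohort, screen_cohort


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 6-sample cohort (2 targets x 3 replicates, one planted candidate)
    generated once per session; returns (directory, manifest, config)."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = CohortSimConfig(
        n_targets=2,
        replicates_per_target=3,
        background_ratio=0.01,
        tap_targets={"TAPX": 0.1},
        reads_per_sample=1000,
        read_length=50,
        seed=7,
    )
    manifest = generate_cohort(cfg, out)
    return out, manifest, cfg


@pytest.fixture(scope="session")
def small_cohort_results(small_cohort):
    out, manifest, _ = small_cohort
    return screen_cohort(manifest, MotifSpec(), qc=DESK_QC, base_dir=out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
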