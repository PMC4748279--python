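import pytest

from lincnet import SimConfig
from lincnet.pipeline import run_synthetic

# pre-declared seed list for every planted-recovery check
RECOVERY_SEEDS = (101, 102, 103)


@pytest.fixture(scope="session")
def recovery_runs():
    """Full synthetic pipeline runs on the fixed recovery seeds."""
    runs = []
    for seed in RECOVERY_SEEDS:
        cfg = SimConfig(seed=seed)
        result, truth, expr = run_synthetic(cfg)
        runs.append((cfg, result, truth, expr))
    return runs
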