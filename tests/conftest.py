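import warnings

import pytest

import seedshell as ss
from seedshell.sweep import SweepConfig, run_sweep

warnings.filterwarnings("ignore", message="overflow encountered in exp")


@pytest.fixture(scope="session")
def wt_dataset():
    """Default synthetic wild-type growth table (generator seed 42)."""
    return ss.generate_growth_dataset(ss.WT_GROWTH)


@pytest.fixture(scope="session")
def iku2_dataset():
    return ss.generate_growth_dataset(ss.IKU2_GROWTH)


@pytest.fixture(scope="session")
def wt_sweep(wt_dataset):
    """Constant-pressure sweep of 5e4 sets against the WT dataset."""
    return run_sweep(
        SweepConfig(n_sets=50_000, seed=1), 1.0, wt_dataset, genotype="Col-0"
    )


@pytest.fixture(scope="session")
def iku2_sweep(iku2_dataset):
    """Sweep of 5e4 sets under the iku2 pressure drop against iku2 data."""
    return run_sweep(
        SweepConfig(n_sets=50_000, seed=1),
        ss.DEFAULT_IKU2_DROP,
        iku2_dataset,
        genotype="iku2",
    )
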