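import numpy as np
import pandas as pd
import pytest

from cernet.diffexpr import ExpressionMatrix
from cernet.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """Noise-free, decoy-free synthetic bundle: the exact-recovery regime."""
    outdir = tmp_path_factory.mktemp("clean_bundle")
    config = SimulationConfig(rng_seed=7)
    truth = simulate_bundle(config, outdir, decoy_pairs=0, noise="none")
    return config, truth, outdir


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """Default study conditions: NB noise and decoy database pairs."""
    outdir = tmp_path_factory.mktemp("noisy_bundle")
    config = SimulationConfig(rng_seed=11)
    truth = simulate_bundle(config, outdir, decoy_pairs=15, noise="nb")
    return config, truth, outdir


def make_matrix(counts_by_sample: dict[str, list], ids=None, classes=None) -> ExpressionMatrix:
    """Small expression matrix: sample name starting with 'E' -> stage1, else stage2."""
    n = len(next(iter(counts_by_sample.values())))
    ids = ids or [f"G{i}" for i in range(n)]
    classes = classes or ["mRNA"] * n
    return ExpressionMatrix(
        counts=pd.DataFrame(counts_by_sample, index=ids, dtype=float),
        classes=pd.Series(classes, index=ids),
        stages=pd.Series(
            {s: "stage1" if s.startswith("E") else "stage2" for s in counts_by_sample}
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
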