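import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from seqsig import pipeline, synthetic_data as sd

CELL_A = sd.CELL_A
CELL_B = sd.CELL_B


@pytest.fixture(scope="session")
def default_dataset():
    """Default-parameter synthetic dataset (the study-condition analogue)."""
    return sd.generate(sd.GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    ds = default_dataset
    return pipeline.run_pipeline(
        ds.genome, ds.genes, ds.reads[CELL_A], ds.expression[CELL_A], seed=101
    )


@pytest.fixture(scope="session")
def small_dataset():
    """300 genes -> ~1e5 segments / ~1e5 state transitions."""
    return sd.generate(sd.GeneratorConfig(n_genes=300, seed=7))


@pytest.fixture(scope="session")
def small_pipeline_pair(small_dataset):
    ds = small_dataset
    res_a = pipeline.run_pipeline(
        ds.genome, ds.genes, ds.reads[CELL_A], seed=3, fit_expression=False
    )
    res_b = pipeline.run_pipeline(
        ds.genome, ds.genes, ds.reads[CELL_B], seed=3, fit_expression=False
    )
    return res_a, res_b
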