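import numpy as np
import pandas as pd
import pytest

from sgnseq.design import StudyDesign, generate_design
from sgnseq.io import CountMatrix
from sgnseq.synthetic import synthetic_dataset
from sgnseq.pipeline import run_pipeline

PANEL_SEED = 1  # fixed seed of the default synthetic study


@pytest.fixture(scope="session")
def panel():
    """Default synthetic study: counts + truth table."""
    m, truth = synthetic_dataset(seed=PANEL_SEED)
    return m, truth


@pytest.fixture(scope="session")
def pipeline_result(panel):
    m, _ = panel
    return run_pipeline(m)


@pytest.fixture()
def two_group_design():
    return StudyDesign(
        ("A", "B"),
        (("a1", "A", 1), ("a2", "A", 2), ("b1", "B", 1), ("b2", "B", 2)),
        (),
    )


def make_matrix(counts, design, lengths=None):
    """Small CountMatrix from a plain array."""
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=genes, columns=list(design.sample_ids))
    lens = pd.Series(lengths, index=genes) if lengths is not None else None
    return CountMatrix(df, design, lens)


@pytest.fixture()
def small_sgn_design():
    return generate_design(2, include_refs=False)
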