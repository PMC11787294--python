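import numpy as np
import pandas as pd
import pytest

import cltsdeconv as cd


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic single-sample dataset for fast unit tests."""
    cfg = cd.ScrnaSimConfig(
        n_genes=400,
        n_cell_types=3,
        cells_per_type_per_sample=60,
        n_samples=1,
        type_mean_transcriptome_sizes=(20_000.0, 8_000.0, 4_000.0),
        sample_amplification=(1.0,),
        sample_offset=(0.0,),
        seed=11,
    )
    matrix, annotation, lengths = cd.simulate_scrna(cfg)
    return cfg, matrix, annotation, lengths


@pytest.fixture(scope="session")
def small_signatures(small_world):
    _, matrix, annotation, _ = small_world
    return cd.find_signatures(matrix, annotation, k=40)


@pytest.fixture(scope="session")
def small_reference(small_world, small_signatures):
    _, matrix, annotation, _ = small_world
    return cd.build_reference(matrix, annotation, small_signatures)


@pytest.fixture(scope="session")
def study_world():
    """The six-type, 300-cells/type, 2000-gene single-sample study dataset
    whose type mean transcriptome sizes span 8-fold."""
    cfg = cd.ScrnaSimConfig(seed=101)
    matrix, annotation, lengths = cd.simulate_scrna(cfg)
    signatures = cd.find_signatures(matrix, annotation)
    reference = cd.build_reference(matrix, annotation, signatures)
    return cfg, matrix, annotation, lengths, signatures, reference


def tiny_matrix():
    """3 genes x 4 cells, two types, hand-enterable values."""
    values = np.array([
        [2.0, 4.0, 0.0, 1.0],
        [1.0, 1.0, 5.0, 7.0],
        [0.0, 1.0, 2.0, 2.0],
    ])
    m = cd.ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"])
    ann = cd.CellAnnotation(pd.DataFrame({
        "cell": ["c1", "c2", "c3", "c4"],
        "sample": ["s1"] * 4,
        "cell_type": ["A", "A", "B", "B"],
    }))
    return m, ann


@pytest.fixture
def tiny():
    return tiny_matrix()
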