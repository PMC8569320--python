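"""Shared fixtures: small random study matrices with known structure."""

import numpy as np
import pandas as pd
import pytest

from acnesig.io_formats import CONDITIONS, ExpressionMatrix, SampleTable


def random_matrix(rng, n_features=20, n_samples=8, low=2.0, high=12.0, prefix="F"):
    """A random log2-scale matrix with unique IDs."""
    values = rng.uniform(low, high, size=(n_features, n_samples))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i:03d}" for i in range(n_features)],
            columns=[f"smp{j:02d}" for j in range(n_samples)],
        )
    )


def paired_samples(n_subjects=9):
    """A full paired design: one sample per subject per condition."""
    rows = [
        (f"S{i:02d}_{c}", f"S{i:02d}", c)
        for i in range(n_subjects)
        for c in CONDITIONS
    ]
    return SampleTable(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "condition"])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def samples9():
    return paired_samples(9)


@pytest.fixture
def study_matrix(rng, samples9):
    """36-sample random matrix annotated by samples9."""
    values = rng.uniform(3.0, 12.0, size=(50, 36))
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i:03d}" for i in range(50)],
            columns=samples9.sample_ids,
        )
    )
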