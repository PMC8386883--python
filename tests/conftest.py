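import numpy as np
import pandas as pd
import pytest

from omsubtype.datatypes import ClinicalTable, ClinicalVariable, OmicsMatrix


def make_matrix(values, omic="omic", prefix="f", **flags) -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsMatrix(
        omic,
        [f"S{i:03d}" for i in range(n)],
        [f"{prefix}{j:03d}" for j in range(p)],
        values,
        **flags,
    )


def make_clinical(subject_ids, **columns) -> ClinicalTable:
    """columns: name=(kind, roles, values)"""
    variables = [
        ClinicalVariable(name, kind, roles, pd.Series(vals, index=subject_ids))
        for name, (kind, roles, vals) in columns.items()
    ]
    return ClinicalTable(list(subject_ids), variables)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def standardized_matrix(rng):
    X = rng.standard_normal((60, 8))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return make_matrix(X, adjusted=True, standardized=True, filtered=True)
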