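import numpy as np
import pandas as pd
import pytest

from neurocoloc.parcellation import (
    EdgeIndex,
    Parcellation,
    RegionDef,
    default_edge_index,
    load_default_parcellation,
)


@pytest.fixture(scope="session")
def parcellation():
    return load_default_parcellation()


@pytest.fixture(scope="session")
def edge_index(parcellation):
    return default_edge_index(parcellation)


@pytest.fixture(scope="session")
def toy_parcellation():
    """Six regions (three homologous pairs), enough to exercise flipping."""
    defs = [
        ("lh_hippocampus", "left", "subcortical", True),
        ("lh_thalamus", "left", "subcortical", True),
        ("lh_insula", "left", "insula", False),
        ("rh_hippocampus", "right", "subcortical", True),
        ("rh_thalamus", "right", "subcortical", True),
        ("rh_insula", "right", "insula", False),
    ]
    return Parcellation(
        [RegionDef(i, n, h, l, s) for i, (n, h, l, s) in enumerate(defs)]
    )


@pytest.fixture(scope="session")
def toy_edge_index(toy_parcellation):
    """Complete graph on the toy parcellation (mirror-symmetric)."""
    n = toy_parcellation.n_regions
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return EdgeIndex(toy_parcellation, pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_subjects(n_controls, n_patients, lateralities=None, seed=0):
    rng = np.random.default_rng(seed)
    n = n_controls + n_patients
    ids = [f"c{i}" for i in range(n_controls)] + [f"p{i}" for i in range(n_patients)]
    group = ["control"] * n_controls + ["patient"] * n_patients
    if lateralities is None:
        lateralities = ["L" if i % 2 == 0 else "R" for i in range(n_patients)]
    return pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "batch": ["b1"] * n,
            "age": rng.uniform(20, 60, n),
            "sex": rng.integers(0, 2, n),
            "icv": rng.normal(1.5e6, 1e5, n),
            "laterality": [""] * n_controls + list(lateralities),
        }
    )
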