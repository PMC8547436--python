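"""Shared fixtures: toy matrices and one session-scoped synthetic survey."""

import numpy as np
import pandas as pd
import pytest

from npdiv import preprocess, synth
from npdiv.containers import FeatureTable, IncidenceMatrix


@pytest.fixture
def toy_incidence() -> IncidenceMatrix:
    """Four isolates, five features with incidence frequencies (1,2,4,2,1).

    S_obs = 5, Q1 = 2, Q2 = 2; E[S(2)] = 5 - 8/6 = 11/3.
    """
    presence = pd.DataFrame(
        {
            "A": [1, 1, 1, 0, 0],
            "B": [0, 1, 1, 0, 0],
            "C": [0, 0, 1, 1, 0],
            "D": [0, 0, 1, 1, 1],
        },
        index=[f"f{i}" for i in range(1, 6)],
    )
    return IncidenceMatrix(presence)


@pytest.fixture
def small_table() -> tuple[FeatureTable, pd.DataFrame]:
    """Three features, two cultures of one isolate plus one blank."""
    abundances = pd.DataFrame(
        {
            "iso1_r1": [2.0, 3.0, 5.0],
            "iso1_r2": [1.0, 0.0, 4.0],
            "BLANK_1": [0.0, 0.0, 7.0],
        },
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
    )
    mz = pd.Series([100.1, 200.2, 300.3], index=abundances.index, name="mz")
    rt = pd.Series([1.0, 2.0, 3.0], index=abundances.index, name="rt")
    metadata = pd.DataFrame(
        {
            "sample_id": ["iso1_r1", "iso1_r2", "BLANK_1"],
            "isolate_id": ["iso1", "iso1", ""],
            "clade": ["U", "U", ""],
            "replicate": [1, 2, 0],
            "is_blank": [False, False, True],
        }
    ).set_index("sample_id", drop=False)
    return FeatureTable(abundances, mz, rt), metadata


@pytest.fixture(scope="session")
def default_survey():
    """One generated survey on defaults (seed 1), reused across modules."""
    config = synth.GeneratorConfig(seed=1)
    table, metadata, spectra, truth = synth.generate_dataset(config)
    return config, table, metadata, spectra, truth


@pytest.fixture(scope="session")
def default_incidence(default_survey):
    """Preprocessed isolate-level incidence of the session survey."""
    _, table, metadata, _, _ = default_survey
    normalized, incidence = preprocess.preprocess_pipeline(table, metadata)
    return normalized, incidence


def random_incidence(rng: np.random.Generator, T: int, n_items: int) -> IncidenceMatrix:
    """Random incidence matrix with no all-zero rows (helper, not a fixture)."""
    presence = (rng.random((n_items, T)) < rng.uniform(0.15, 0.7)).astype(int)
    # ensure every item occurs somewhere
    empty = presence.sum(axis=1) == 0
    cols = rng.integers(T, size=int(empty.sum()))
    presence[np.nonzero(empty)[0], cols] = 1
    return IncidenceMatrix(
        pd.DataFrame(
            presence,
            index=[f"f{i}" for i in range(n_items)],
            columns=[f"iso{j}" for j in range(T)],
        )
    )
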