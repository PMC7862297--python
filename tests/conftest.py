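"""Shared fixtures: the default synthetic cohort and derived tables.

Expensive artifacts (full 46-session cohort, its 460x35 feature table)
are built once per test session and shared.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import qeegpain as qp
from qeegpain.spectral import FEATURE_COLUMNS


@pytest.fixture(scope="session")
def default_generator_config() -> qp.GeneratorConfig:
    return qp.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_generator_config) -> qp.CohortManifest:
    return qp.generate_cohort(default_generator_config)


@pytest.fixture(scope="session")
def default_segments(default_cohort):
    return [qp.preprocess_session(s) for s in default_cohort.sessions]


@pytest.fixture(scope="session")
def default_dataset(default_segments, default_cohort) -> qp.FeatureDataset:
    return qp.build_feature_dataset(default_segments, default_cohort)


@pytest.fixture(scope="session")
def small_layout() -> dict:
    """Half-size cohort layout used by slower classifier experiments."""
    return {"none": 8, "mild": 4, "moderate": 8, "severe": 4}


@pytest.fixture(scope="session")
def fast_classifier_config() -> qp.ClassifierConfig:
    """Reduced grid/folds to keep CV experiments quick."""
    return qp.ClassifierConfig(
        cost_grid=(1.0, 10.0), gamma_grid=("scale",), n_folds=5, inner_folds=3, seed=2
    )


def make_feature_dataset(
    features: np.ndarray,
    quartiles,
    nrs=None,
    session_keys=None,
    windows_per_session: int | None = None,
) -> qp.FeatureDataset:
    """Build a FeatureDataset from a raw (n, 35) matrix for toy problems."""
    features = np.asarray(features, dtype=float)
    n = len(features)
    quartiles = list(quartiles)
    default_nrs = {"none": 0, "mild": 2, "moderate": 5, "severe": 8}
    nrs = [default_nrs[q] for q in quartiles] if nrs is None else list(nrs)
    if session_keys is None:
        if windows_per_session is None:
            session_keys = [f"T{i:03d}/pre" for i in range(n)]
        else:
            session_keys = [f"T{i // windows_per_session:03d}/pre" for i in range(n)]
    subject_ids = [k.split("/")[0] for k in session_keys]
    phases = [k.split("/")[1] for k in session_keys]
    window_index = []
    seen: dict[str, int] = {}
    for k in session_keys:
        window_index.append(seen.get(k, 0))
        seen[k] = window_index[-1] + 1
    frame = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "phase": phases,
            "window_index": window_index,
            "nrs": nrs,
            "quartile": quartiles,
            "artifact_flag": False,
        }
    )
    frame[FEATURE_COLUMNS] = features
    return qp.FeatureDataset(frame=frame)
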