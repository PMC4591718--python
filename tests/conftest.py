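"""Shared fixtures: small synthetic tables built programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from strucov.io import PHENOTYPE_COLUMNS, SUBSCALES, CohortTable, VolumeTable
from strucov.roi import load_scheme
from strucov.synthetic_data import GeneratorConfig, generate_cohort


def make_cohort(n: int, seed: int = 0, is_scores=None) -> CohortTable:
    """A valid random phenotype table with optional fixed IS scores."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "age": rng.uniform(14, 25, n),
            "iq": rng.uniform(85, 140, n),
            "icv": rng.uniform(1.2e6, 1.8e6, n),
            **{s: rng.integers(0, 12, n).astype(float) for s in SUBSCALES},
        },
        index=pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id"),
    )
    if is_scores is not None:
        data["insistence_on_sameness"] = np.asarray(is_scores, dtype=float)
    return CohortTable(data[list(PHENOTYPE_COLUMNS)])


def make_volumes(n: int, seed: int = 0, override: dict[str, np.ndarray] | None = None) -> VolumeTable:
    """A valid random 75-column bilateral volume table."""
    rng = np.random.default_rng(seed)
    scheme = load_scheme("bilateral7")
    data = pd.DataFrame(
        rng.uniform(500.0, 12000.0, (n, len(scheme.names))),
        index=pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id"),
        columns=scheme.names,
    )
    for name, values in (override or {}).items():
        data[name] = np.asarray(values, dtype=float)
    return VolumeTable(data, scheme)


@pytest.fixture(scope="session")
def scheme():
    return load_scheme("bilateral7")


@pytest.fixture(scope="session")
def lat_scheme():
    return load_scheme("lateralized14")


@pytest.fixture(scope="session")
def planted_run():
    """One default planted-coupling cohort (seed 0), shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def null_run():
    from strucov.synthetic_data import preset_config

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(preset_config("null", 0))
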