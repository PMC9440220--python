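"""Shared fixtures: hand-built tiny tables and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gnotodiff import FeatureTable, SimulationConfig, simulate_feature_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def build_table(
    values: np.ndarray | list,
    tissues: tuple[str, ...] = ("cecum",),
    n_replicates: int = 5,
    rt: float | list = 2.0,
    has_msms: bool | list = True,
    mode: str = "RP+",
) -> FeatureTable:
    """Construct a valid FeatureTable from a raw matrix.

    Columns must be laid out tissue-major with the GF block before the MPF
    block within each tissue (``n_replicates`` each).
    """
    values = np.asarray(values, dtype=float)
    n_f = values.shape[0]
    sample_ids, rows = [], []
    for tissue in tissues:
        for group in ("GF", "MPF"):
            for r in range(1, n_replicates + 1):
                sample_ids.append(f"{tissue}_{group}_{r}")
                rows.append({"tissue": tissue, "group": group, "replicate": r})
    assert values.shape[1] == len(sample_ids)
    fids = pd.Index([f"{mode}:F{i:03d}" for i in range(n_f)], name="feature_id")
    abundance = pd.DataFrame(values, index=fids, columns=sample_ids)
    feature_meta = pd.DataFrame(
        {
            "mode": mode,
            "mz": np.linspace(100, 900, n_f),
            "rt": rt if isinstance(rt, list) else [rt] * n_f,
            "has_msms": has_msms if isinstance(has_msms, list) else [has_msms] * n_f,
        },
        index=fids,
    )
    sample_meta = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    return FeatureTable(abundance, feature_meta, sample_meta)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Two-tissue, 500-feature configuration used across tests."""
    return SimulationConfig(
        tissues=("cecum", "liver"),
        n_features_per_mode={"RP+": 300, "HILIC-": 200},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_feature_table(small_config)


@pytest.fixture(scope="session")
def clean_config() -> SimulationConfig:
    """No planted effects, no dropout, no absence: every status null, no zeros."""
    return SimulationConfig(
        tissues=("cecum", "liver"),
        n_features_per_mode={"RP+": 200},
        frac_differential=0.0,
        frac_exclusive=0.0,
        frac_absent=0.0,
        dropout_midpoint=None,
        detection_floor=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_feature_table(clean_config)
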