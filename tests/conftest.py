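"""Shared fixtures: compact synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sifsalt as ss


@pytest.fixture(scope="session")
def small_cfg() -> ss.SceneConfig:
    """A compact all-sensitive scene: 2 cells, 150 sites, 21 years."""
    return ss.typical_training_scenario(seed=11, n_sites=150)


@pytest.fixture(scope="session")
def small_scene(small_cfg) -> ss.Scene:
    return ss.generate_scene(small_cfg)


@pytest.fixture(scope="session")
def small_monthly(small_scene) -> pd.DataFrame:
    return ss.aggregate_monthly(small_scene.fluor)


@pytest.fixture(scope="session")
def small_sifi(small_monthly) -> pd.DataFrame:
    return ss.compute_sifi(small_monthly, anchor_month=12)


@pytest.fixture(scope="session")
def small_table(small_sifi, small_scene) -> pd.DataFrame:
    table, _ = ss.build_feature_table(small_sifi, small_scene.samples)
    return table


def make_monthly(values: np.ndarray, sites=None, first_year: int = 2000
                 ) -> pd.DataFrame:
    """Long monthly table from a (site, year, month) array."""
    values = np.asarray(values, dtype=float)
    n_sites, n_years, _ = values.shape
    sites = np.arange(n_sites) if sites is None else np.asarray(sites)
    idx = pd.MultiIndex.from_product(
        [sites, np.arange(first_year, first_year + n_years),
         np.arange(1, 13)], names=["site_id", "year", "month"]
    )
    return (pd.Series(values.ravel(), index=idx, name="value")
            .reset_index())
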