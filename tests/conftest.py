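"""Shared fixtures: synthetic worlds and a seed-averaged recovery run.

Everything is generated programmatically; the expensive multi-seed
parameter-recovery sweep is session-scoped and shared between the module
tests and the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

from cropcwp.evaluate import build_adjacency
from cropcwp.preprocess import build_feature_table, build_feature_table_multiyear
from cropcwp.synthgrid import SimConfig, make_world
from cropcwp.yield_model import (combo_search, evaluate_on, point_validate,
                                 predict_pixels, split_train_test, train_rf)

RECOVERY_SEEDS = tuple(range(10))


def feature_table_of(world) -> pd.DataFrame:
    tables = [build_feature_table(world.truth_features[y], world.soil,
                                  world.county_map, world.crop_mask[y],
                                  world.county_yields, y)
              for y in world.years]
    return build_feature_table_multiyear(tables)


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic world (60x60 grid, 25 counties, 3 years)."""
    return make_world(SimConfig(seed=7))


@pytest.fixture(scope="session")
def deep_world():
    """A 12-year world whose counties are deep enough for a single planted
    value to trip the one-pass 3-SD screen."""
    return make_world(SimConfig(grid_rows=24, grid_cols=24, counties_rows=4,
                                counties_cols=4, n_years=12, n_point_sites=10,
                                n_towers=1, year_amplitude=0.05,
                                field_amplitude=0.2, seed=99))


@pytest.fixture(scope="session")
def default_table(default_world):
    return feature_table_of(default_world)


@pytest.fixture(scope="session")
def recovery():
    """Ten independent worlds, each with a four-indicator model, held-out
    regional metrics, pixel predictions with point validation, and the
    full indicator-combination search."""
    runs = []
    for seed in RECOVERY_SEEDS:
        world = make_world(SimConfig(seed=seed))
        table = feature_table_of(world)
        adjacency = build_adjacency(world.county_map)
        train, test = split_train_test(table, 0.8, seed=seed)
        bundle = train_rf(train, ("ET", "GPP", "Ts", "LAI"), seed=seed)
        regional = evaluate_on(bundle, test, adjacency)
        rasters = {y: predict_pixels(bundle, world.truth_features[y],
                                     world.soil, world.crop_mask[y])
                   for y in world.years}
        point = point_validate(rasters, world.point_yields,
                               m=len(bundle.feature_columns))
        combo = combo_search(table, seed=seed, adjacency=adjacency)
        runs.append({"seed": seed, "world": world, "table": table,
                     "train": train, "test": test, "bundle": bundle,
                     "regional": regional, "point": point, "combo": combo})
    return runs
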