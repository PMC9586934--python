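"""Yield-record screening, split protocol, forest training and pixel
prediction."""

import math

import numpy as np
import pandas as pd
import pytest

from cropcwp.grids import NODATA
from cropcwp.synthgrid import OutlierSpec, inject_outliers
from cropcwp.yield_model import (FilterRules, filter_yield_records,
                                 point_validate, predict_pixels,
                                 split_train_test, train_rf)


def yields_df(yields, areas=None, counties=None, years=None):
    n = len(yields)
    return pd.DataFrame({
        "county_id": counties if counties is not None else np.arange(1, n + 1),
        "year": years if years is not None else [2001] * n,
        "yield_kg_ha": yields,
        "planting_area_ha": areas if areas is not None else [5000.0] * n,
    })


# --------------------------------------------------------------------------
# screening

def test_bounds_rule_printed_thresholds():
    t = yields_df([400.0, 6000.0, 15500.0, 7000.0])
    out, audit = filter_yield_records(t, FilterRules.for_crop("maize"))
    assert out["yield_kg_ha"].tolist() == [6000.0, 7000.0]
    assert audit["below_bound"] == 1 and audit["above_bound"] == 1
    # single-record counties: SD rule skipped and flagged
    assert audit["sd"] == 0 and len(audit["sd_skipped_counties"]) == 4


def test_clean_table_untouched(default_world):
    out, audit = filter_yield_records(default_world.county_yields,
                                      FilterRules.for_crop("maize"))
    pd.testing.assert_frame_equal(out, default_world.county_yields)
    assert audit["below_bound"] == audit["above_bound"] == 0
    assert audit["sd"] == audit["area"] == 0


def test_filter_is_idempotent(default_world):
    rules = FilterRules.for_crop("maize")
    once, _ = filter_yield_records(default_world.county_yields, rules)
    twice, audit = filter_yield_records(once, rules)
    pd.testing.assert_frame_equal(once, twice)
    assert sum(audit[k] for k in ("below_bound", "above_bound", "sd", "area")) == 0


def test_area_rule_direction_is_configurable():
    t = yields_df([6000.0, 7000.0], areas=[12000.0, 5000.0])
    above, a_audit = filter_yield_records(t, FilterRules.for_crop("maize"))
    assert above["yield_kg_ha"].tolist() == [7000.0] and a_audit["area"] == 1
    below, b_audit = filter_yield_records(
        t, FilterRules.for_crop("maize", area_rule_direction="exclude_below"))
    assert below["yield_kg_ha"].tolist() == [6000.0] and b_audit["area"] == 1


def test_audit_counts_match_injected_spec(deep_world):
    """Planted outliers are recovered class-for-class by the screen."""
    spec = OutlierSpec(below_bound=3, above_bound=2, sd=2, area=3)
    seeded = inject_outliers(deep_world.county_yields, spec, "maize", seed=21)
    out, audit = filter_yield_records(seeded.drop(columns="outlier_class"),
                                      FilterRules.for_crop("maize"))
    assert audit["below_bound"] == spec.below_bound
    assert audit["above_bound"] == spec.above_bound
    assert audit["sd"] == spec.sd
    assert audit["area"] == spec.area
    assert len(out) == len(seeded) - spec.total


# --------------------------------------------------------------------------
# split protocol

def test_split_sizes_and_forced_extremes():
    rng = np.random.default_rng(0)
    t = yields_df(rng.uniform(2000, 12000, 10))
    train, test = split_train_test(t, 0.8, seed=3)
    assert len(train) == 8 and len(test) == 2
    assert t["yield_kg_ha"].min() in train["yield_kg_ha"].tolist()
    assert t["yield_kg_ha"].max() in train["yield_kg_ha"].tolist()
    # disjoint and exhaustive
    keys = pd.concat([train, test])[["county_id", "year"]]
    assert not keys.duplicated().any() and len(keys) == len(t)


@pytest.mark.parametrize("seed", range(8))
def test_forced_extremes_hold_for_all_seeds(default_world, seed):
    t = default_world.county_yields
    train, _ = split_train_test(t, 0.8, seed=seed)
    assert t["yield_kg_ha"].min() in train["yield_kg_ha"].tolist()
    assert t["yield_kg_ha"].max() in train["yield_kg_ha"].tolist()


def test_split_tied_minimum_forces_exactly_one_row():
    y = [3000.0, 3000.0, 8000.0, 5000.0, 6000.0, 7000.0]
    t = yields_df(y)
    train, test = split_train_test(t, 0.5, seed=1)
    assert len(train) == 3
    assert 3000.0 in train["yield_kg_ha"].tolist()
    assert 8000.0 in train["yield_kg_ha"].tolist()


def test_split_determinism():
    t = yields_df(np.random.default_rng(1).uniform(2000, 9000, 20))
    a = split_train_test(t, 0.8, seed=11)
    b = split_train_test(t, 0.8, seed=11)
    pd.testing.assert_frame_equal(a[0], b[0])
    pd.testing.assert_frame_equal(a[1], b[1])
    with pytest.raises(ValueError):
        split_train_test(t, 1.2, seed=0)


# --------------------------------------------------------------------------
# forest behaviour

def _tiny_features(n=30, seed=0, target=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "county_id": np.arange(n), "year": 2001,
        "cumET": rng.uniform(250, 450, n), "cumGPP": rng.uniform(600, 1200, n),
        "cumTs": rng.uniform(300, 500, n), "meanLAI": rng.uniform(1.5, 3.5, n),
        "clay": rng.uniform(15, 35, n), "sand": rng.uniform(30, 50, n),
        "silt": rng.uniform(25, 45, n),
    })
    df["yield_kg_ha"] = target if target is not None else rng.uniform(4000, 9000, n)
    return df


def test_constant_target_predicts_constant():
    t = _tiny_features(target=6500.0)
    bundle = train_rf(t, ("ET", "GPP", "Ts", "LAI"), seed=0)
    assert np.allclose(bundle.predict(_tiny_features(seed=5)), 6500.0)


def test_forest_cannot_extrapolate_beyond_training_range():
    t = _tiny_features()
    bundle = train_rf(t, ("ET", "GPP"), seed=0)
    probe = _tiny_features(seed=7)
    probe[["cumET", "cumGPP"]] *= 10  # far outside the training domain
    pred = bundle.predict(probe)
    assert pred.min() >= t["yield_kg_ha"].min() - 1e-9
    assert pred.max() <= t["yield_kg_ha"].max() + 1e-9


def test_training_is_reproducible_and_validates_input():
    t = _tiny_features()
    a = train_rf(t, ("ET", "GPP"), seed=4).predict(t)
    b = train_rf(t, ("ET", "GPP"), seed=4).predict(t)
    assert np.array_equal(a, b)
    bad = t.copy()
    bad.loc[0, "cumET"] = np.nan
    with pytest.raises(ValueError):
        train_rf(bad, ("ET", "GPP"), seed=4)
    with pytest.raises(ValueError):
        train_rf(t, (), seed=4)


# --------------------------------------------------------------------------
# pixel prediction and point validation

def test_pixel_prediction_consistent_with_tabular(recovery):
    run = recovery[0]
    bundle, row = run["bundle"], run["train"].iloc[[0]]
    shape = (3, 3)
    rasters = {c: np.full(shape, float(row[c].iloc[0]))
               for c in bundle.feature_columns}
    soil = {k: rasters.pop(k) for k in ("clay", "sand", "silt")}
    out = predict_pixels(bundle, rasters, soil, np.ones(shape, bool))
    assert np.allclose(out, bundle.predict(row)[0])


def test_pixel_prediction_propagates_nodata(recovery):
    bundle = recovery[0]["bundle"]
    shape = (4, 4)
    rasters = {c: np.full(shape, 300.0) for c in bundle.feature_columns}
    soil = {k: rasters.pop(k) for k in ("clay", "sand", "silt")}
    rasters["cumET"][1, 1] = NODATA
    mask = np.ones(shape, bool)
    mask[2, 2] = False
    out = predict_pixels(bundle, rasters, soil, mask)
    assert out[1, 1] == NODATA and out[2, 2] == NODATA
    assert out[0, 0] != NODATA
    with pytest.raises(ValueError):
        predict_pixels(bundle, {}, soil, mask)


def test_point_validation_exact_sites_give_zero_rmse():
    ras = np.arange(16.0).reshape(4, 4) * 1000 + 3000
    pts = pd.DataFrame({"site_id": ["a", "b"], "row": [0, 2], "col": [1, 3],
                        "year": [2001, 2001],
                        "yield_kg_ha": [ras[0, 1], ras[2, 3]]})
    rep = point_validate(ras, pts, m=1)
    assert rep.rmse == 0.0


def test_point_validation_single_site_and_drops():
    ras = np.full((4, 4), 5000.0)
    ras[1, 1] = NODATA
    pts = pd.DataFrame({"site_id": ["a", "off", "nod"],
                        "row": [0, 9, 1], "col": [0, 0, 1],
                        "year": [2001] * 3,
                        "yield_kg_ha": [5100.0, 5000.0, 5000.0]})
    with pytest.warns(UserWarning):
        rep = point_validate(ras, pts, m=1)
    assert rep.n == 1
    assert math.isnan(rep.r2_conventional)
    assert rep.rmse == pytest.approx(100.0)
    assert rep.mbe == pytest.approx(-100.0)
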