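"""Resampling, masking, phenology-window aggregation and zonal statistics."""

import numpy as np
import pandas as pd
import pytest

from cropcwp.grids import (COMPOSITE_DOYS, NODATA, CompositeStack,
                           GridGeometry, PhenologyMap)
from cropcwp.preprocess import (build_feature_table, mask_cropland,
                                resample_nearest, select_window_composites,
                                window_cumulate, zonal_aggregate)


# --------------------------------------------------------------------------
# oracles

def nearest_oracle(data, src, dst):
    """Exhaustive per-cell nearest-source-center search."""
    out = np.empty(dst.shape)
    sr, sc = np.meshgrid(np.arange(src.rows), np.arange(src.cols), indexing="ij")
    sx, sy = src.pixel_center(sr, sc)
    for r in range(dst.rows):
        for c in range(dst.cols):
            tx, ty = dst.pixel_center(r, c)
            d2 = (sx - tx) ** 2 + (sy - ty) ** 2
            i, j = np.unravel_index(np.argmin(d2), d2.shape)
            out[r, c] = data[i, j]
    return out


def window_oracle(stack, phen, statistic, crop_mask, max_missing=0.2):
    """Per-pixel python-loop window aggregation."""
    out = np.full(stack.geometry.shape, NODATA)
    for r in range(stack.geometry.rows):
        for c in range(stack.geometry.cols):
            if crop_mask is not None and not crop_mask[r, c]:
                continue
            sel = [k for k, d in enumerate(stack.doys)
                   if phen.start_doy[r, c] <= d <= phen.end_doy[r, c]]
            vals = [stack.data[k, r, c] for k in sel
                    if stack.data[k, r, c] != stack.nodata]
            if not sel or len(vals) < (1 - max_missing) * len(sel):
                continue
            if statistic == "sum":
                out[r, c] = sum(vals) * len(sel) / len(vals)
            else:
                out[r, c] = sum(vals) / len(vals)
    return out


def zonal_oracle(raster, county_map, crop_mask):
    acc = {}
    for r in range(raster.shape[0]):
        for c in range(raster.shape[1]):
            cid = int(county_map[r, c])
            if cid == 0 or raster[r, c] == NODATA:
                continue
            if crop_mask is not None and not crop_mask[r, c]:
                continue
            acc.setdefault(cid, []).append(raster[r, c])
    return {cid: float(np.mean(v)) for cid, v in sorted(acc.items())}


# --------------------------------------------------------------------------
# resampling

def test_resample_identity():
    g = GridGeometry(6, 7)
    data = np.random.default_rng(0).normal(size=g.shape)
    assert np.array_equal(resample_nearest(data, g, g), data)


def test_resample_constant_upsample():
    src = GridGeometry(4, 4, pixel_size=1000.0)
    dst = GridGeometry(8, 8, pixel_size=500.0)
    out = resample_nearest(np.full(src.shape, 3.0), src, dst)
    assert np.all(out == 3.0)


def test_resample_matches_bruteforce_oracle():
    rng = np.random.default_rng(4)
    # 500-m block pattern to 1-km, plus randomized offset geometries
    src = GridGeometry(8, 8, pixel_size=500.0)
    dst = GridGeometry(4, 4, pixel_size=1000.0)
    data = rng.normal(size=src.shape)
    assert np.array_equal(resample_nearest(data, src, dst),
                          nearest_oracle(data, src, dst))
    for _ in range(5):
        src = GridGeometry(7, 9, pixel_size=700.0,
                           origin_x=float(rng.uniform(-500, 500)),
                           origin_y=float(rng.uniform(-500, 500)))
        dst = GridGeometry(5, 6, pixel_size=1000.0)
        data = rng.normal(size=src.shape)
        assert np.array_equal(resample_nearest(data, src, dst),
                              nearest_oracle(data, src, dst))


def test_resample_disjoint_extents_rejected():
    src = GridGeometry(4, 4, origin_x=0.0)
    dst = GridGeometry(4, 4, origin_x=1e7)
    with pytest.raises(ValueError):
        resample_nearest(np.zeros(src.shape), src, dst)


# --------------------------------------------------------------------------
# masking

def _small_stack(value=5.0, rows=6, cols=6):
    g = GridGeometry(rows, cols)
    data = np.full((46, rows, cols), value, dtype=float)
    return CompositeStack("ET", 2001, data, g)


def test_mask_all_true_is_identity():
    s = _small_stack()
    out = mask_cropland(s, np.ones(s.geometry.shape, bool))
    assert np.array_equal(out.data, s.data)


def test_mask_all_false_is_all_nodata():
    s = _small_stack()
    out = mask_cropland(s, np.zeros(s.geometry.shape, bool))
    assert np.all(out.data == s.nodata)


def test_mask_valid_pixel_count_per_layer():
    s = _small_stack()
    mask = np.zeros(s.geometry.shape, bool)
    mask[np.unravel_index([0, 7, 13, 22], mask.shape)] = True
    out = mask_cropland(s, mask)
    assert np.all((out.data != s.nodata).sum(axis=(1, 2)) == 4)


# --------------------------------------------------------------------------
# window selection and cumulation

def test_window_selection_arithmetic():
    idx = select_window_composites(100, 260, COMPOSITE_DOYS)
    doys = np.asarray(COMPOSITE_DOYS)[idx]
    assert doys[0] == 105 and doys[-1] == 257 and len(doys) == 20
    assert len(select_window_composites(1, 365, COMPOSITE_DOYS)) == 46
    only = select_window_composites(105, 105, COMPOSITE_DOYS)
    assert np.asarray(COMPOSITE_DOYS)[only].tolist() == [105]


def test_window_shorter_than_one_composite_rejected():
    with pytest.raises(ValueError):
        select_window_composites(106, 112, COMPOSITE_DOYS)


def _phen(g, start, end, year=2001):
    return PhenologyMap(year, "maize", np.full(g.shape, start, int),
                        np.full(g.shape, end, int), g)


def test_constant_stack_cumulates_k_times_v():
    s = _small_stack(5.0)
    phen = _phen(s.geometry, 100, 260)  # 20 composites
    out = window_cumulate(s, phen, "sum")
    assert np.allclose(out, 100.0)
    lai = _small_stack(3.0)
    assert np.allclose(window_cumulate(lai, phen, "mean"), 3.0)


def test_window_sum_additive_over_split():
    rng = np.random.default_rng(9)
    s = _small_stack()
    s.data[:] = rng.uniform(0, 10, size=s.data.shape)
    g = s.geometry
    whole = window_cumulate(s, _phen(g, 100, 260), "sum")
    left = window_cumulate(s, _phen(g, 100, 150), "sum")
    right = window_cumulate(s, _phen(g, 151, 260), "sum")
    assert np.allclose(whole, left + right)


def test_pixel_varying_windows_match_loop_oracle():
    rng = np.random.default_rng(10)
    s = _small_stack(rows=8, cols=8)
    s.data[:] = rng.uniform(0, 10, size=s.data.shape)
    # sprinkle nodata
    hole = rng.random(s.data.shape) < 0.05
    s.data[hole] = s.nodata
    g = s.geometry
    phen = PhenologyMap(2001, "maize",
                        rng.integers(90, 131, size=g.shape),
                        rng.integers(230, 281, size=g.shape), g)
    mask = rng.random(g.shape) < 0.9
    for stat in ("sum", "mean"):
        got = window_cumulate(s, phen, stat, crop_mask=mask)
        want = window_oracle(s, phen, stat, mask)
        assert np.allclose(got, want)


def test_heavily_gapped_pixel_becomes_nodata():
    s = _small_stack(5.0)
    phen = _phen(s.geometry, 100, 260)
    # knock out 6 of the 20 selected composites at one pixel (30% > 20%)
    idx = select_window_composites(100, 260, s.doys)
    s.data[idx[:6], 0, 0] = s.nodata
    out = window_cumulate(s, phen, "sum")
    assert out[0, 0] == NODATA and out[1, 1] != NODATA


# --------------------------------------------------------------------------
# zonal statistics and the feature table

def test_zonal_two_pixel_mean():
    cm = np.array([[1, 1], [2, 2]])
    ras = np.array([[2.0, 4.0], [NODATA, NODATA]])
    out = zonal_aggregate(ras, cm)
    assert out[1] == pytest.approx(3.0)
    assert 2 not in out.index  # fully-nodata county omitted


def test_zonal_matches_dictionary_oracle_and_bounds():
    rng = np.random.default_rng(12)
    for _ in range(10):
        shape = (rng.integers(4, 9), rng.integers(4, 9))
        cm = rng.integers(0, 4, size=shape)
        ras = rng.normal(size=shape)
        ras[rng.random(shape) < 0.2] = NODATA
        mask = rng.random(shape) < 0.8
        got = zonal_aggregate(ras, cm, mask)
        want = zonal_oracle(ras, cm, mask)
        assert got.index.tolist() == list(want)
        for cid, v in want.items():
            assert got[cid] == pytest.approx(v, rel=1e-12)
            contrib = ras[(cm == cid) & (ras != NODATA) & mask]
            assert contrib.min() <= got[cid] <= contrib.max()


def test_masking_commutes_with_aggregation(default_world):
    w = default_world
    year = w.years[0]
    stack = w.stacks["ET"][year]
    mask = w.crop_mask[year]
    masked_first = mask_cropland(stack, mask)
    a = zonal_aggregate(masked_first.data[20], w.county_map)
    b = zonal_aggregate(stack.data[20], w.county_map, mask)
    pd.testing.assert_series_equal(a, b)


def test_feature_table_shape_and_join(default_world, default_table):
    t = default_table
    assert len(t) == 75  # 25 counties x 3 years
    assert not t[["cumET", "cumGPP", "cumTs", "meanLAI",
                  "clay", "sand", "silt", "yield_kg_ha"]].isna().any().any()
    # inner-join semantics: dropping a county from the yield table drops its rows
    w = default_world
    from cropcwp.preprocess import build_feature_table
    reduced = w.county_yields[w.county_yields["county_id"] != 1]
    t1 = build_feature_table(w.truth_features[w.years[0]], w.soil, w.county_map,
                             w.crop_mask[w.years[0]], reduced, w.years[0])
    assert 1 not in t1["county_id"].tolist()
    assert len(t1) == 24


def test_duplicate_yield_keys_rejected(default_world):
    w = default_world
    dup = pd.concat([w.county_yields, w.county_yields.iloc[[0]]])
    with pytest.raises(ValueError):
        build_feature_table(w.truth_features[w.years[0]], w.soil, w.county_map,
                            w.crop_mask[w.years[0]], dup, w.years[0])
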