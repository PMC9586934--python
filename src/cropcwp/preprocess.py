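"""Indicator preprocessing: resampling, cropland masking, phenology-window
aggregation and county-level statistics.

The modelling features are built in four steps: (1) bring every input
raster onto the common 1-km analysis grid by nearest-neighbour resampling;
(2) mask all indicators to the cropland layer; (3) per pixel, cumulate ET,
GPP and Ts and average LAI over that pixel's phenology window (an 8-day
composite belongs to the window iff its start day-of-year lies inside
[start, end], with no fractional weighting); (4) aggregate the windowed
rasters to county level (unweighted mean over crop pixels) and join with
the recorded county yields to form the feature table with columns
cumET [mm], cumGPP [g C/m²], cumTs [°C·composite], meanLAI [-],
clay/sand/silt [%], yield [kg/ha].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cropcwp.grids import NODATA, CompositeStack, GridGeometry, PhenologyMap

#: Window statistic per indicator: growing-window sums for fluxes and
#: accumulated temperature, mean for canopy state.
WINDOW_STATISTIC = {"ET": "sum", "GPP": "sum", "Ts": "sum", "LAI": "mean"}

#: Feature-table column per indicator.
FEATURE_NAME = {"ET": "cumET", "GPP": "cumGPP", "Ts": "cumTs", "LAI": "meanLAI"}

SOIL_COLUMNS = ("clay", "sand", "silt")

#: A pixel's window aggregate becomes nodata when more than this fraction
#: of its selected composites are missing; below it the sum is rescaled to
#: the full window and the mean uses valid layers only.
MAX_MISSING_FRACTION = 0.2


def resample_nearest(data: np.ndarray, src: GridGeometry, dst: GridGeometry,
                     nodata: float = NODATA) -> np.ndarray:
    """Nearest-neighbour resampling between axis-aligned grids.

    Each target cell takes the value of the source cell whose center is
    nearest to the target cell center; nodata propagates.  Raises if the
    grids do not overlap.
    """
    data = np.asarray(data)
    if data.shape[-2:] != src.shape:
        raise ValueError("data shape does not match source geometry")
    rr = np.arange(dst.rows)
    cc = np.arange(dst.cols)
    xs, _ = dst.pixel_center(np.zeros_like(cc), cc)
    _, ys = dst.pixel_center(rr, np.zeros_like(rr))
    # nearest source center along each axis (grids are axis-aligned)
    src_c = np.rint((xs - src.origin_x) / src.pixel_size - 0.5).astype(int)
    src_r = np.rint((src.origin_y - ys) / src.pixel_size - 0.5).astype(int)
    if src_c.max() < 0 or src_c.min() >= src.cols or src_r.max() < 0 or src_r.min() >= src.rows:
        raise ValueError("source and target extents are disjoint")
    src_r = np.clip(src_r, 0, src.rows - 1)
    src_c = np.clip(src_c, 0, src.cols - 1)
    return data[..., src_r[:, None], src_c[None, :]]


def mask_cropland(stack: CompositeStack, crop_mask: np.ndarray) -> CompositeStack:
    """Set non-crop pixels to nodata in every layer of the stack."""
    crop_mask = np.asarray(crop_mask).astype(bool)
    if crop_mask.shape != stack.geometry.shape:
        raise ValueError("crop mask geometry mismatch")
    out = stack.copy()
    out.data[:, ~crop_mask] = stack.nodata
    return out


def select_window_composites(start_doy: int, end_doy: int,
                             composite_doys) -> np.ndarray:
    """Indices of composites whose start DOY d satisfies start <= d <= end."""
    if start_doy > end_doy:
        raise ValueError("window requires start <= end")
    doys = np.asarray(composite_doys)
    idx = np.flatnonzero((doys >= start_doy) & (doys <= end_doy))
    if idx.size == 0:
        raise ValueError(
            f"window [{start_doy}, {end_doy}] shorter than one composite: "
            "no composite start DOY falls inside it")
    return idx


def window_cumulate(stack: CompositeStack, phenology: PhenologyMap,
                    statistic: str, crop_mask: np.ndarray | None = None,
                    max_missing_fraction: float = MAX_MISSING_FRACTION) -> np.ndarray:
    """Per-pixel phenology-window aggregate of an 8-day composite stack.

    ``statistic`` is ``'sum'`` (cumulative ET/GPP/Ts) or ``'mean'`` (LAI).
    Windows vary per pixel; a composite contributes wherever its start DOY
    lies in that pixel's [start, end].  Pixels outside the crop mask, with
    an empty window, or with more than ``max_missing_fraction`` of their
    selected composites missing become nodata; otherwise sums are rescaled
    by selected/valid and means use valid layers only.
    """
    if statistic not in ("sum", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if stack.geometry != phenology.geometry:
        raise ValueError("stack and phenology geometry mismatch")
    doys = np.asarray(stack.doys)[:, None, None]
    member = (doys >= phenology.start_doy[None]) & (doys <= phenology.end_doy[None])
    valid = member & (stack.data != stack.nodata)
    n_sel = member.sum(axis=0)
    n_val = valid.sum(axis=0)

    vals = np.where(valid, stack.data, 0.0).astype(float)
    total = vals.sum(axis=0)
    ok = (n_sel > 0) & (n_val >= (1.0 - max_missing_fraction) * n_sel)
    if crop_mask is not None:
        ok &= np.asarray(crop_mask).astype(bool)

    out = np.full(stack.geometry.shape, NODATA, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if statistic == "sum":
            res = total * (n_sel / np.maximum(n_val, 1))
        else:
            res = total / np.maximum(n_val, 1)
    out[ok] = res[ok]
    return out


def zonal_aggregate(raster: np.ndarray, county_map: np.ndarray,
                    crop_mask: np.ndarray | None = None,
                    nodata: float = NODATA, background: int = 0) -> pd.Series:
    """Unweighted county mean of a raster over valid crop pixels.

    Counties with zero contributing pixels are omitted.  Returns a Series
    indexed by county id.
    """
    raster = np.asarray(raster, dtype=float)
    cm = np.asarray(county_map)
    if raster.shape != cm.shape:
        raise ValueError("raster and county map geometry mismatch")
    sel = (cm != background) & (raster != nodata) & np.isfinite(raster)
    if crop_mask is not None:
        sel &= np.asarray(crop_mask).astype(bool)
    ids = cm[sel]
    vals = raster[sel]
    sums = np.bincount(ids, weights=vals, minlength=cm.max() + 1)
    counts = np.bincount(ids, minlength=cm.max() + 1)
    present = np.flatnonzero(counts)
    return pd.Series(sums[present] / counts[present], index=present,
                     name="mean").rename_axis("county_id")


def build_feature_table(annual_rasters: dict[str, np.ndarray],
                        soil: dict[str, np.ndarray],
                        county_map: np.ndarray, crop_mask: np.ndarray,
                        yields: pd.DataFrame, year: int,
                        background: int = 0) -> pd.DataFrame:
    """County-level feature rows for one year.

    ``annual_rasters`` maps feature names (cumET, cumGPP, cumTs, meanLAI)
    to windowed rasters; ``soil`` maps clay/sand/silt to static rasters.
    The result is the inner join of the zonal means with the yield table
    on (county_id, year); duplicate keys in the yield table are rejected.
    """
    cols = {}
    for name, ras in {**annual_rasters, **soil}.items():
        cols[name] = zonal_aggregate(ras, county_map, crop_mask, background=background)
    feats = pd.DataFrame(cols).dropna()
    feats = feats.reset_index()
    feats["year"] = year

    ytab = yields[yields["year"] == year]
    if ytab.duplicated(subset=["county_id", "year"]).any():
        raise ValueError("duplicate (county_id, year) keys in yield table")
    merged = feats.merge(ytab, on=["county_id", "year"], how="inner")
    return merged


def build_feature_table_multiyear(per_year_tables) -> pd.DataFrame:
    """Pool per-year feature tables into one modelling table."""
    out = pd.concat(list(per_year_tables), ignore_index=True)
    if out.duplicated(subset=["county_id", "year"]).any():
        raise ValueError("duplicate (county_id, year) rows after pooling")
    return out
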