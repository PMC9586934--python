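"""Crop water productivity: yield per unit of growing-window water use.

CWP [kg/m³] is the ratio of grain yield to cumulative evapotranspiration
over the same phenology window used for the yield features.  With yield
in kg/ha and cumulative ET in mm, 1 mm of water over 1 ha is 10 m³, so

    CWP = yield / (10 * cumET)

Pixels where either input is missing, or where cumulative ET falls below
a small floor (default 1 mm, guarding the division), come out as nodata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from cropcwp.grids import NODATA

#: mm of water over one hectare expressed in m³ (unit bridge kg/ha & mm -> kg/m³).
MM_HA_TO_M3 = 10.0

#: Minimum cumulative ET [mm] below which CWP is not computed.
ET_FLOOR_MM = 1.0


def compute_cwp(yield_raster: np.ndarray, cum_et_raster: np.ndarray,
                nodata: float = NODATA, et_floor_mm: float = ET_FLOOR_MM):
    """CWP raster [kg/m³] from yield [kg/ha] and window-cumulative ET [mm].

    Returns ``(cwp, n_floored)`` where ``n_floored`` counts otherwise-valid
    pixels suppressed by the ET floor.
    """
    y = np.asarray(yield_raster, dtype=float)
    et = np.asarray(cum_et_raster, dtype=float)
    if y.shape != et.shape:
        raise ValueError("yield and cumulative-ET rasters must share geometry")
    valid_in = (y != nodata) & (et != nodata) & np.isfinite(y) & np.isfinite(et)
    floored = valid_in & (et <= et_floor_mm)
    ok = valid_in & ~floored
    out = np.full(y.shape, nodata, dtype=float)
    out[ok] = y[ok] / (MM_HA_TO_M3 * et[ok])
    return out, int(np.count_nonzero(floored))


def regional_summary(raster: np.ndarray, region_map: np.ndarray,
                     nodata: float = NODATA, background: int = 0,
                     national_label: str = "ALL") -> pd.DataFrame:
    """Per-region mean ± SD of a raster, plus an all-region national row.

    The mean is the unweighted pixel mean over valid pixels; the SD uses
    the population convention (divide by n).  Regions with no valid pixels
    are omitted.  The national row pools every valid pixel, so the
    national mean equals the pixel-count-weighted mean of regional means.
    """
    r = np.asarray(raster, dtype=float)
    rm = np.asarray(region_map)
    if r.shape != rm.shape:
        raise ValueError("raster and region map must share geometry")
    valid = (rm != background) & (r != nodata) & np.isfinite(r)
    rows = []
    for region in np.unique(rm[valid]):
        vals = r[valid & (rm == region)]
        rows.append({"region": str(region), "n_pixels": int(vals.size),
                     "mean": float(vals.mean()), "sd": float(vals.std())})
    allvals = r[valid]
    if allvals.size:
        rows.append({"region": national_label, "n_pixels": int(allvals.size),
                     "mean": float(allvals.mean()), "sd": float(allvals.std())})
    return pd.DataFrame(rows, columns=["region", "n_pixels", "mean", "sd"])
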