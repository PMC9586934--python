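"""Eddy-covariance quality control and pairing with gridded ET.

Daily tower records carry the surface-energy-balance components: net
radiation Rn, soil heat flux G, sensible heat H and latent heat λET, all
as daily means in W/m².  Because the eddy-covariance method rarely closes
the energy balance, each day is screened by its closure ratio

    ECR = (H + λET) / (Rn - G)

days with ECR < 0.80 are discarded (the comparison is strict: exactly 0.80
is retained), and retained days are rescaled with the Bowen-ratio
energy-balance correction

    λET_cor = λET * (Rn - G) / (H + λET)

which forces closure while preserving the Bowen ratio H/λET.  Corrected
latent heat converts to water-equivalent ET via the latent heat of
vaporisation (2.45 MJ/kg, no temperature dependence), is cumulated to the
46 fixed 8-day composite periods, and is paired with the ET raster pixel
at the tower location for validation.

Days with Rn - G <= 0 (nocturnal- or winter-dominated energy budgets) are
flagged invalid and excluded rather than corrected: the Bowen correction
is numerically unstable there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cropcwp.grids import COMPOSITE_DOYS, CompositeStack

#: Latent heat of vaporisation [J/kg].
LAMBDA_V = 2.45e6

#: Default energy-balance closure-ratio acceptance threshold.
ECR_THRESHOLD = 0.80

#: Minimum valid days for an 8-day composite to count (gap-scaled to 8).
MIN_VALID_DAYS = 6

FLUX_COLUMNS = ("doy", "rn", "g", "h", "lam_et")


@dataclass
class FluxSeries:
    """Daily energy-balance records of one tower on the analysis grid."""

    tower_id: str
    row: int
    col: int
    days: pd.DataFrame  # columns doy, rn, g, h, lam_et (+ qc columns)

    def __post_init__(self) -> None:
        missing = set(FLUX_COLUMNS) - set(self.days.columns)
        if missing:
            raise ValueError(f"flux table missing columns {sorted(missing)}")
        doys = self.days["doy"].to_numpy()
        if np.any(np.diff(doys) <= 0):
            raise ValueError("flux days must be strictly increasing")


def compute_ecr(rn, g, h, lam_et):
    """Energy-balance closure ratio (H + λET)/(Rn - G).

    Vectorised; days with Rn - G <= 0 return NaN (invalid, to be
    excluded).
    """
    rn, g, h, lam_et = (np.asarray(v, dtype=float) for v in (rn, g, h, lam_et))
    avail = rn - g
    with np.errstate(divide="ignore", invalid="ignore"):
        ecr = np.where(avail > 0, (h + lam_et) / avail, np.nan)
    return ecr if ecr.ndim else float(ecr)


def bowen_correct(rn, g, h, lam_et):
    """Bowen-ratio energy-balance corrected latent heat λET_cor.

    Satisfies λET_cor * (H + λET) = λET * (Rn - G) exactly; days with
    H + λET <= 0 return NaN (invalid).
    """
    rn, g, h, lam_et = (np.asarray(v, dtype=float) for v in (rn, g, h, lam_et))
    turb = h + lam_et
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = np.where(turb > 0, lam_et * (rn - g) / turb, np.nan)
    return cor if cor.ndim else float(cor)


def filter_and_correct(series: FluxSeries, threshold: float = ECR_THRESHOLD) -> FluxSeries:
    """Drop low-closure / invalid days and attach corrected λET.

    A day survives iff its ECR is defined (Rn - G > 0, H + λET > 0) and
    ECR >= threshold; survivors carry ``ecr`` and ``lam_et_cor`` columns.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    d = series.days.copy()
    ecr = compute_ecr(d["rn"], d["g"], d["h"], d["lam_et"])
    cor = bowen_correct(d["rn"], d["g"], d["h"], d["lam_et"])
    keep = np.isfinite(ecr) & np.isfinite(cor) & (ecr >= threshold)
    d = d.loc[keep].copy()
    d["ecr"] = np.asarray(ecr)[keep]
    d["lam_et_cor"] = np.asarray(cor)[keep]
    if d.empty:
        warnings.warn(f"tower {series.tower_id}: no days survive ECR >= {threshold}")
    return FluxSeries(series.tower_id, series.row, series.col, d.reset_index(drop=True))


def latent_heat_to_mm(lam_et_w_m2):
    """Daily-mean latent heat [W/m²] to water-equivalent ET [mm/day]."""
    v = np.asarray(lam_et_w_m2, dtype=float) * 86400.0 / LAMBDA_V
    return v if v.ndim else float(v)


def cumulate_8day(daily: pd.DataFrame, composite_doys=COMPOSITE_DOYS,
                  min_valid_days: int = MIN_VALID_DAYS) -> pd.DataFrame:
    """Cumulate QC'd daily ET [mm/day] to 8-day composite totals [mm/8d].

    ``daily`` needs columns ``doy`` and ``et_mm``.  A composite with at
    least ``min_valid_days`` surviving days is gap-scaled by
    ``8 / valid_days`` to a full 8-day-equivalent total; fewer valid days
    mark the composite missing (NaN).  The final composite (start DOY 361)
    spans only 5-6 calendar days, so its minimum is prorated by the same
    fraction and its total is likewise scaled to the 8-day equivalent,
    matching the fixed-cadence product convention.
    """
    doy = daily["doy"].to_numpy()
    et = daily["et_mm"].to_numpy(dtype=float)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day-of-year out of range")
    out = []
    for start in composite_doys:
        stop = min(start + 8, 367)  # last composite truncated at year end
        sel = (doy >= start) & (doy < stop)
        nvalid = int(np.count_nonzero(sel))
        nominal = stop - start
        min_req = int(np.ceil(min_valid_days / 8.0 * nominal))
        if nvalid >= min_req:
            value = float(et[sel].sum()) * 8.0 / nvalid
        else:
            value = np.nan
        out.append({"doy": start, "et_mm_8d": value, "valid_days": nvalid})
    return pd.DataFrame(out)


def pair_with_raster(tower_8day: pd.DataFrame, stack: CompositeStack,
                     row: int, col: int) -> pd.DataFrame:
    """Pair tower 8-day ET with the raster pixel at the tower location.

    Returns rows (doy, tower_et, raster_et); composites missing on either
    side (tower NaN or raster nodata) are dropped from both.
    """
    if not stack.geometry.contains(row, col):
        raise ValueError(f"location ({row}, {col}) off the {stack.geometry.shape} grid")
    raster_by_doy = {d: float(stack.data[k, row, col]) for k, d in enumerate(stack.doys)}
    rows = []
    for rec in tower_8day.itertuples(index=False):
        rv = raster_by_doy.get(int(rec.doy))
        if rv is None or rv == stack.nodata or not np.isfinite(rec.et_mm_8d):
            continue
        rows.append({"doy": int(rec.doy), "tower_et": float(rec.et_mm_8d),
                     "raster_et": rv})
    paired = pd.DataFrame(rows, columns=["doy", "tower_et", "raster_et"])
    if paired.empty:
        warnings.warn("no overlapping composites between tower and raster")
    return paired


def qc_and_pair(series: FluxSeries, stack: CompositeStack,
                threshold: float = ECR_THRESHOLD,
                min_valid_days: int = MIN_VALID_DAYS) -> pd.DataFrame:
    """Full tower pipeline: QC, Bowen-correct, cumulate, pair with raster."""
    qcd = filter_and_correct(series, threshold=threshold)
    daily = pd.DataFrame({"doy": qcd.days["doy"],
                          "et_mm": latent_heat_to_mm(qcd.days["lam_et_cor"])})
    eightday = cumulate_8day(daily, stack.doys, min_valid_days=min_valid_days)
    return pair_with_raster(eightday, stack, qcd.row, qcd.col)
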