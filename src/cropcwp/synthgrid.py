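"""Self-contained synthetic worlds with known ground truth.

A world emulates, at toy scale, every input the yield/CWP pipeline needs:
8-day composite stacks of ET, GPP, land-surface temperature (Ts, °C) and
LAI with smooth spatial structure; static soil clay/sand/silt fractions on
the simplex; yearly cropland masks and phenology windows; a block
partition of the grid into counties; county yield statistics; point-scale
yield records; and daily flux-tower energy-balance series with a
prescribed closure gap.

The generative truth is a known function of exactly the features the
pipeline later reconstructs: per pixel,

    Y = b0 + b_gpp*cumGPP + b_lai*meanLAI + b_et*cumET
        - b_ts*(cumTs - t_opt)^2 + b_clay*clay + eps

where the cumulative/mean terms are taken over that pixel's phenology
window with the same composite-inclusion rule as
:func:`cropcwp.preprocess.window_cumulate` (the generator calls that very
function, so recomputing features downstream reproduces them bit-exactly).
County yields are the crop-pixel means of true yield plus configurable
county noise; point records are true pixel yields; tower series are built
so that the Bowen-corrected latent heat recovers the ET raster at the
tower pixel exactly.

Everything is reproducible bit-for-bit from the configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from cropcwp.flux_qc import LAMBDA_V, FluxSeries
from cropcwp.grids import COMPOSITE_DOYS, NODATA, CompositeStack, GridGeometry, PhenologyMap
from cropcwp.preprocess import FEATURE_NAME, WINDOW_STATISTIC, window_cumulate, zonal_aggregate
from cropcwp.yield_model import CROP_BOUNDS

INDICATOR_UNITS = {"ET": "mm/8d", "GPP": "g C/m2/8d", "Ts": "degC", "LAI": "-"}

#: Fraction of crop pixel-years allowed outside the biophysical yield
#: bounds before the configuration is rejected as systematically invalid.
MAX_OUT_OF_BOUNDS_FRACTION = 0.01


@dataclass(frozen=True)
class YieldCoefficients:
    """Weights of the generative yield function [kg/ha per feature unit].

    Defaults are scaled so that realistic windowed indicator values
    (cumGPP ~ 600-1200 g C/m², meanLAI ~ 1.5-3.5, cumET ~ 250-450 mm,
    cumTs ~ 300-500 °C·composite, clay ~ 15-35%) put the mean yield near
    7 t/ha, comfortably inside the attainable range for both crops.
    """

    b0: float = 2000.0
    b_gpp: float = 2.8
    b_lai: float = 350.0
    b_et: float = 2.5
    b_ts: float = 0.03
    t_opt: float = 400.0
    b_clay: float = 20.0


@dataclass(frozen=True)
class OutlierSpec:
    """How many rows of each outlier class to plant in the yield table."""

    below_bound: int = 0
    above_bound: int = 0
    sd: int = 0
    area: int = 0

    @property
    def total(self) -> int:
        return self.below_bound + self.above_bound + self.sd + self.area


@dataclass(frozen=True)
class SimConfig:
    grid_rows: int = 60
    grid_cols: int = 60
    n_years: int = 3
    counties_rows: int = 5
    counties_cols: int = 5
    crop: str = "maize"
    first_year: int = 2001
    composite_doys: tuple[int, ...] = COMPOSITE_DOYS
    yield_coefficients: YieldCoefficients = field(default_factory=YieldCoefficients)
    noise_sd_pixel: float = 250.0
    noise_sd_county: float = 150.0
    closure_ratio: float = 0.85
    outlier_spec: OutlierSpec = field(default_factory=OutlierSpec)
    n_point_sites: int = 30
    n_towers: int = 3
    smooth_sigma: float = 8.0       # gaussian correlation length [pixels]
    field_amplitude: float = 0.45   # relative spatial amplitude of indicators
    year_amplitude: float = 0.18    # relative year-to-year variation
    climate_coupling: float = 0.85  # indicator correlation via shared latent
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_rows, self.grid_cols, self.n_years,
               self.counties_rows, self.counties_cols) <= 0:
            raise ValueError("dimensions must be positive")
        if self.grid_rows % self.counties_rows or self.grid_cols % self.counties_cols:
            raise ValueError("grid dimensions must be divisible by county block dims")
        if self.crop not in CROP_BOUNDS:
            raise ValueError(f"crop must be one of {sorted(CROP_BOUNDS)}")
        doys = np.asarray(self.composite_doys)
        if len(doys) != 46 or doys[0] != 1 or np.any(np.diff(doys) != 8):
            raise ValueError("composite_doys must be the 46-step ladder 1, 9, ..., 361")
        if not (0 < self.closure_ratio <= 1.2):
            raise ValueError("closure_ratio must be in (0, 1.2]")
        if self.noise_sd_pixel < 0 or self.noise_sd_county < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0.0 <= self.climate_coupling <= 1.0):
            raise ValueError("climate_coupling must be in [0, 1]")

    @property
    def years(self) -> list[int]:
        return [self.first_year + k for k in range(self.n_years)]

    @property
    def n_counties(self) -> int:
        return self.counties_rows * self.counties_cols


@dataclass
class SyntheticWorld:
    config: SimConfig
    geometry: GridGeometry
    stacks: dict            # indicator -> {year -> CompositeStack}
    soil: dict              # clay/sand/silt -> raster [%]
    crop_mask: dict         # year -> bool raster
    phenology: dict         # year -> PhenologyMap
    county_map: np.ndarray  # int32, labels 1..n_counties
    county_yields: pd.DataFrame
    point_yields: pd.DataFrame
    flux: list              # FluxSeries
    flux_year: int
    truth_yield: dict       # year -> raster [kg/ha], NODATA off-crop
    truth_features: dict    # year -> {feature -> raster}

    @property
    def years(self) -> list[int]:
        return self.config.years


# --------------------------------------------------------------------------
# field helpers

def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-SD spatially correlated Gaussian field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _trend_field(rng: np.random.Generator, shape) -> np.ndarray:
    """Random low-order (planar + saddle) trend, standardized."""
    rr, cc = np.meshgrid(np.linspace(-1, 1, shape[0]),
                         np.linspace(-1, 1, shape[1]), indexing="ij")
    a, b, c = rng.uniform(-1, 1, size=3)
    t = a * rr + b * cc + c * rr * cc
    sd = t.std()
    return t / sd if sd > 0 else t


def _structured_field(rng, shape, sigma):
    """Equal mix of large-scale trend and correlated noise, unit SD."""
    f = 0.6 * _trend_field(rng, shape) + 0.4 * _smooth_field(rng, shape, sigma)
    return f / f.std()


# seasonal mean curves (value at mid-composite day-of-year)
def _seasonal_et(doy):
    return 2.0 + 26.0 * np.exp(-((doy - 200.0) / 70.0) ** 2)


def _seasonal_gpp(doy):
    return 3.0 + 60.0 * np.exp(-((doy - 200.0) / 60.0) ** 2)


def _seasonal_lai(doy):
    return 0.2 + 4.0 * np.exp(-((doy - 195.0) / 55.0) ** 2)


def _seasonal_ts(doy):
    return 2.0 + 24.0 * np.exp(-((doy - 200.0) / 95.0) ** 2)


_SEASONAL = {"ET": _seasonal_et, "GPP": _seasonal_gpp, "LAI": _seasonal_lai,
             "Ts": _seasonal_ts}


# --------------------------------------------------------------------------
# world construction

def make_world(config: SimConfig) -> SyntheticWorld:
    """Generate a complete synthetic world from the configuration.

    Raises if the implied true yields fall systematically outside the
    crop's biophysically attainable range (no silent clipping).
    """
    geom = GridGeometry(config.grid_rows, config.grid_cols)
    shape = geom.shape
    ss = np.random.SeedSequence(config.seed)
    (soil_ss, phen_ss, mask_ss, ind_ss, noise_ss, county_ss,
     area_ss, point_ss, flux_ss) = ss.spawn(9)

    county_map = _block_counties(config)
    soil = _make_soil(np.random.default_rng(soil_ss), shape, config.smooth_sigma)
    crop_mask = {}
    phenology = {}
    mask_rng = np.random.default_rng(mask_ss)
    phen_rng = np.random.default_rng(phen_ss)
    for year in config.years:
        crop_mask[year] = _make_mask(mask_rng, config, county_map)
        phenology[year] = _make_phenology(phen_rng, geom, year, config)

    # Indicators co-vary along a shared per-year "climate" field plus a
    # shared year anomaly, as real indicator products do along regional
    # climate gradients; each keeps an independent component on top.
    stacks = {ind: {} for ind in _SEASONAL}
    ind_rng = np.random.default_rng(ind_ss)
    for year in config.years:
        latent = _structured_field(ind_rng, shape, config.smooth_sigma)
        year_anom = ind_rng.standard_normal()
        for ind in ("ET", "GPP", "Ts", "LAI"):
            stacks[ind][year] = _make_stack(ind_rng, geom, ind, year, config,
                                            latent, year_anom)

    # truth: features via the production window aggregator, then the
    # generative yield function plus pixel noise
    noise_rng = np.random.default_rng(noise_ss)
    truth_features = {}
    truth_yield = {}
    for year in config.years:
        feats = {}
        for ind in ("ET", "GPP", "Ts", "LAI"):
            feats[FEATURE_NAME[ind]] = window_cumulate(
                stacks[ind][year], phenology[year], WINDOW_STATISTIC[ind],
                crop_mask=crop_mask[year])
        truth_features[year] = feats
        truth_yield[year] = _truth_yield(feats, soil, crop_mask[year],
                                         config, noise_rng)
    _check_bounds(truth_yield, crop_mask, config)

    county_yields = _county_yields(truth_yield, county_map, crop_mask, config,
                                   np.random.default_rng(county_ss),
                                   np.random.default_rng(area_ss))
    point_yields = _point_yields(truth_yield, crop_mask, config,
                                 np.random.default_rng(point_ss))
    flux_year = config.years[0]
    flux = _make_flux(stacks["ET"][flux_year], crop_mask[flux_year], config,
                      np.random.default_rng(flux_ss))

    return SyntheticWorld(config=config, geometry=geom, stacks=stacks,
                          soil=soil, crop_mask=crop_mask, phenology=phenology,
                          county_map=county_map, county_yields=county_yields,
                          point_yields=point_yields, flux=flux,
                          flux_year=flux_year, truth_yield=truth_yield,
                          truth_features=truth_features)


def _block_counties(config: SimConfig) -> np.ndarray:
    br = config.grid_rows // config.counties_rows
    bc = config.grid_cols // config.counties_cols
    rr = np.arange(config.grid_rows) // br
    cc = np.arange(config.grid_cols) // bc
    return (rr[:, None] * config.counties_cols + cc[None, :] + 1).astype(np.int32)


def _make_soil(rng, shape, sigma) -> dict:
    logits = {"clay": np.log(0.25), "sand": np.log(0.40), "silt": np.log(0.35)}
    raw = {k: np.exp(v + 0.30 * _smooth_field(rng, shape, sigma))
           for k, v in logits.items()}
    total = sum(raw.values())
    return {k: np.asarray(100.0 * v / total, dtype=np.float32) for k, v in raw.items()}


def _make_mask(rng, config: SimConfig, county_map) -> np.ndarray:
    shape = (config.grid_rows, config.grid_cols)
    # short correlation length: non-crop gaps stay dispersed so every
    # county keeps a usable crop-pixel sample
    f = _smooth_field(rng, shape, 2.0)
    mask = f > np.quantile(f, 0.08)  # ~92% cropland
    for cid in range(1, config.n_counties + 1):
        if np.count_nonzero(mask[county_map == cid]) < 5:
            raise ValueError(f"county {cid} has fewer than 5 crop pixels; "
                             "enlarge the grid or the cropland fraction")
    return mask


def _make_phenology(rng, geom, year, config: SimConfig) -> PhenologyMap:
    shape = geom.shape
    start = np.rint(110.0 + 7.0 * _structured_field(rng, shape, config.smooth_sigma))
    end = np.rint(255.0 + 8.0 * _structured_field(rng, shape, config.smooth_sigma))
    start = np.clip(start, 90, 130).astype(np.int16)
    end = np.clip(end, 230, 280).astype(np.int16)
    return PhenologyMap(year=year, crop=config.crop, start_doy=start,
                        end_doy=end, geometry=geom)


def _make_stack(rng, geom, indicator, year, config: SimConfig,
                latent: np.ndarray, year_anom: float) -> CompositeStack:
    doys = np.asarray(config.composite_doys, dtype=float) + 3.5  # mid-composite
    seasonal = _SEASONAL[indicator](doys)
    shape = geom.shape
    # each indicator's variation correlates with the shared climate latent;
    # the remainder is indicator-specific
    rho = config.climate_coupling
    own = _structured_field(rng, shape, config.smooth_sigma)
    spatial = rho * latent + np.sqrt(1.0 - rho ** 2) * own
    anom = rho * year_anom + np.sqrt(1.0 - rho ** 2) * rng.standard_normal()
    data = np.empty((len(doys),) + shape)
    if indicator == "Ts":
        for k in range(len(doys)):
            layer_noise = 0.4 * _smooth_field(rng, shape, config.smooth_sigma)
            data[k] = seasonal[k] + 3.0 * spatial + 1.5 * anom + layer_noise
    else:
        mult = np.clip(1.0 + config.field_amplitude * spatial, 0.2, None)
        year_fac = np.clip(1.0 + config.year_amplitude * anom, 0.5, None)
        for k in range(len(doys)):
            layer_noise = np.clip(
                1.0 + 0.03 * _smooth_field(rng, shape, config.smooth_sigma), 0.2, None)
            data[k] = seasonal[k] * mult * year_fac * layer_noise
        data = np.clip(data, 0.0, None)
    return CompositeStack(indicator=indicator, year=year,
                          data=data.astype(np.float32), geometry=geom,
                          doys=tuple(config.composite_doys),
                          units=INDICATOR_UNITS[indicator])


def _truth_yield(feats, soil, mask, config: SimConfig, rng) -> np.ndarray:
    b = config.yield_coefficients
    valid = mask & np.all([feats[f] != NODATA for f in feats], axis=0)
    cum_gpp, mean_lai = feats["cumGPP"], feats["meanLAI"]
    cum_et, cum_ts = feats["cumET"], feats["cumTs"]
    y = (b.b0 + b.b_gpp * cum_gpp + b.b_lai * mean_lai + b.b_et * cum_et
         - b.b_ts * (cum_ts - b.t_opt) ** 2
         + b.b_clay * soil["clay"].astype(float))
    y += rng.normal(0.0, config.noise_sd_pixel, size=y.shape) if config.noise_sd_pixel > 0 \
        else 0.0
    out = np.full(y.shape, NODATA)
    out[valid] = y[valid]
    return out


def _check_bounds(truth_yield, crop_mask, config: SimConfig) -> None:
    lo, hi = CROP_BOUNDS[config.crop]
    n_out = n_tot = 0
    for year, ras in truth_yield.items():
        vals = ras[crop_mask[year] & (ras != NODATA)]
        n_tot += vals.size
        n_out += int(np.count_nonzero((vals < lo) | (vals > hi)))
    if n_tot == 0:
        raise ValueError("no valid crop pixels in the world")
    if n_out > MAX_OUT_OF_BOUNDS_FRACTION * n_tot:
        raise ValueError(
            f"{n_out}/{n_tot} true yields fall outside the attainable range "
            f"[{lo}, {hi}] kg/ha for {config.crop}; the configuration implies "
            "systematically unphysical yields and is rejected")


def _county_yields(truth_yield, county_map, crop_mask, config: SimConfig,
                   rng, area_rng) -> pd.DataFrame:
    rows = []
    pixel_area_ha = 100.0  # 1 km² pixel
    for year in config.years:
        means = zonal_aggregate(truth_yield[year], county_map, crop_mask[year])
        counts = pd.Series(np.bincount(
            county_map[crop_mask[year]].ravel(), minlength=config.n_counties + 1))
        for cid, mean in means.items():
            obs = mean + (rng.normal(0.0, config.noise_sd_county)
                          if config.noise_sd_county > 0 else 0.0)
            area = counts[cid] * pixel_area_ha * area_rng.uniform(0.3, 0.6)
            rows.append({"county_id": int(cid), "year": int(year),
                         "yield_kg_ha": float(obs),
                         "planting_area_ha": float(area)})
    return pd.DataFrame(rows)


def _point_yields(truth_yield, crop_mask, config: SimConfig, rng) -> pd.DataFrame:
    rows = []
    for site in range(config.n_point_sites):
        year = int(rng.choice(config.years))
        ras = truth_yield[year]
        ok = crop_mask[year] & (ras != NODATA)
        flat = np.flatnonzero(ok)
        pix = int(rng.choice(flat))
        r, c = divmod(pix, config.grid_cols)
        rows.append({"site_id": f"S{site:03d}", "row": r, "col": c,
                     "year": year, "yield_kg_ha": float(ras[r, c])})
    return pd.DataFrame(rows)


def _make_flux(et_stack: CompositeStack, mask, config: SimConfig, rng) -> list:
    """Daily tower series whose Bowen-corrected λET reproduces the ET
    raster at the tower pixel; measured fluxes carry the configured
    closure gap (per-day jitter SD 0.06 around closure_ratio)."""
    towers = []
    flat = np.flatnonzero(mask)
    pix = rng.choice(flat, size=config.n_towers, replace=False)
    doys = np.arange(1, 366)
    comp_idx = np.minimum((doys - 1) // 8, len(et_stack.doys) - 1)
    for t, p in enumerate(pix):
        r, c = divmod(int(p), config.grid_cols)
        daily_et = et_stack.data[comp_idx, r, c].astype(float) / 8.0  # mm/day
        lam_true = daily_et * LAMBDA_V / 86400.0  # W/m² daily mean
        beta = np.clip(0.45 + 0.10 * rng.standard_normal(365), 0.1, None)
        h_true = beta * lam_true
        avail = h_true + lam_true  # Rn - G by construction
        rn = avail / 0.9
        g = rn - avail
        closure = np.clip(config.closure_ratio
                          + 0.06 * rng.standard_normal(365), 0.05, 1.5)
        days = pd.DataFrame({"doy": doys, "rn": rn, "g": g,
                             "h": closure * h_true,
                             "lam_et": closure * lam_true})
        towers.append(FluxSeries(tower_id=f"T{t:02d}", row=r, col=c, days=days))
    return towers


# --------------------------------------------------------------------------
# outlier injection

def inject_outliers(table: pd.DataFrame, spec: OutlierSpec, crop: str,
                    seed: int = 0, sd_multiplier: float = 3.0,
                    area_threshold_ha: float = 10000.0,
                    area_rule_direction: str = "exclude_above") -> pd.DataFrame:
    """Plant outliers that each violate exactly one screening rule.

    Returns a copy of the table with modified rows and an
    ``outlier_class`` audit column (empty string for untouched rows);
    callers drop the column outside test fixtures.  The sd class needs a
    county deep enough that a single within-bounds value can exceed
    ``sd_multiplier`` standard deviations of its own county (the maximum
    standardized deviation among n values is (n-1)/sqrt(n)); infeasible
    requests raise.
    """
    if spec.total > len(table):
        raise ValueError("outlier spec larger than table")
    lo, hi = CROP_BOUNDS[crop]
    out = table.copy().reset_index(drop=True)
    out["outlier_class"] = ""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(out))
    taken: set[int] = set()

    def _grab(k: int) -> list[int]:
        if k == 0:
            return []
        picked = []
        for i in order:
            if int(i) not in taken:
                picked.append(int(i))
                taken.add(int(i))
            if len(picked) == k:
                return picked
        raise ValueError("outlier spec larger than table")

    for i in _grab(spec.below_bound):
        out.loc[i, "yield_kg_ha"] = float(rng.uniform(50.0, 0.8 * lo))
        out.loc[i, "outlier_class"] = "below_bound"
    for i in _grab(spec.above_bound):
        out.loc[i, "yield_kg_ha"] = float(hi * 1.05 + rng.uniform(0.0, 1000.0))
        out.loc[i, "outlier_class"] = "above_bound"
    if area_rule_direction == "exclude_above":
        for i in _grab(spec.area):
            out.loc[i, "planting_area_ha"] = float(
                area_threshold_ha * 1.2 + rng.uniform(0.0, 2000.0))
            out.loc[i, "outlier_class"] = "area"
    else:
        for i in _grab(spec.area):
            out.loc[i, "planting_area_ha"] = float(
                area_threshold_ha * rng.uniform(0.2, 0.8))
            out.loc[i, "outlier_class"] = "area"

    # sd class: pick rows from the deepest counties and solve for a value
    # that trips the one-pass SD rule while staying inside the bounds
    if spec.sd:
        depth = out.groupby("county_id")["county_id"].transform("size")
        candidates = [int(i) for i in order
                      if int(i) not in taken and depth.iloc[int(i)] >= 3]
        candidates.sort(key=lambda i: -int(depth.iloc[i]))
        planted = 0
        for i in candidates:
            if planted == spec.sd:
                break
            cid = out.loc[i, "county_id"]
            same = out.index[(out["county_id"] == cid) & (out.index != i)]
            others = out.loc[same, "yield_kg_ha"].to_numpy(dtype=float)
            x = _sd_violating_value(others, lo, hi, sd_multiplier)
            if x is None:
                continue
            out.loc[i, "yield_kg_ha"] = x
            out.loc[i, "outlier_class"] = "sd"
            taken.add(i)
            planted += 1
        if planted < spec.sd:
            raise ValueError(
                "sd-class injection infeasible: no county is deep enough for a "
                "within-bounds value to exceed the SD rule computed on its own rows")
    return out


def _sd_violating_value(others: np.ndarray, lo: float, hi: float,
                        mult: float) -> float | None:
    for x in (hi - 1.0, lo + 1.0):
        arr = np.append(others, x)
        sd = arr.std(ddof=1)
        if sd > 0 and abs(x - arr.mean()) > mult * sd:
            # the other county rows must stay clean under the shifted stats
            if np.all(np.abs(others - arr.mean()) <= mult * sd):
                return float(x)
    return None


# --------------------------------------------------------------------------
# persistence

def write_world(world: SyntheticWorld, directory) -> dict:
    """Write a world to disk (banded TIFF rasters, CSV tables, JSON
    manifest); read-back via :func:`read_world` is bit-exact."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = []

    def _tif(name, arr, role):
        tifffile.imwrite(d / name, arr)
        files.append({"file": name, "role": role})

    for ind, by_year in world.stacks.items():
        for year, stack in by_year.items():
            _tif(f"{ind}_{year}.tif", stack.data, f"stack:{ind}:{year}")
    for k, ras in world.soil.items():
        _tif(f"soil_{k}.tif", ras, f"soil:{k}")
    for year in world.years:
        _tif(f"crop_mask_{year}.tif", world.crop_mask[year].astype(np.uint8),
             f"crop_mask:{year}")
        _tif(f"phenology_start_{year}.tif", world.phenology[year].start_doy,
             f"phenology_start:{year}")
        _tif(f"phenology_end_{year}.tif", world.phenology[year].end_doy,
             f"phenology_end:{year}")
        _tif(f"truth_yield_{year}.tif", world.truth_yield[year],
             f"truth_yield:{year}")
    _tif("county_map.tif", world.county_map, "county_map")

    world.county_yields.to_csv(d / "county_yields.csv", index=False)
    files.append({"file": "county_yields.csv", "role": "county_yields"})
    world.point_yields.to_csv(d / "point_yields.csv", index=False)
    files.append({"file": "point_yields.csv", "role": "point_yields"})
    for fs in world.flux:
        name = f"flux_{fs.tower_id}.csv"
        fs.days.to_csv(d / name, index=False)
        files.append({"file": name, "role": f"flux:{fs.tower_id}",
                      "row": fs.row, "col": fs.col})

    manifest = {
        "geometry": world.geometry.to_dict(),
        "nodata": NODATA,
        "crop": world.config.crop,
        "years": world.years,
        "flux_year": world.flux_year,
        "composite_doys": list(world.config.composite_doys),
        "seed": world.config.seed,
        "config": _config_dict(world.config),
        "indicator_units": INDICATOR_UNITS,
        "coordinate_convention": "(row, col), 0-based, pixel-center registration",
        "files": files,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_dict(config: SimConfig) -> dict:
    c = asdict(config)
    c["composite_doys"] = list(c["composite_doys"])
    return c


def read_world(directory) -> SyntheticWorld:
    """Reconstruct a world written by :func:`write_world`.

    Truth features are recomputed from the (bit-exact) stacks and
    phenology with the same window aggregator used at generation time,
    so they equal the originals exactly.
    """
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = manifest["config"]
    cfg["composite_doys"] = tuple(cfg["composite_doys"])
    cfg["yield_coefficients"] = YieldCoefficients(**cfg["yield_coefficients"])
    cfg["outlier_spec"] = OutlierSpec(**cfg["outlier_spec"])
    config = SimConfig(**cfg)
    geom = GridGeometry.from_dict(manifest["geometry"])

    stacks = {ind: {} for ind in _SEASONAL}
    for ind in _SEASONAL:
        for year in config.years:
            data = tifffile.imread(d / f"{ind}_{year}.tif")
            stacks[ind][year] = CompositeStack(
                indicator=ind, year=year, data=data, geometry=geom,
                doys=tuple(config.composite_doys), units=INDICATOR_UNITS[ind])
    soil = {k: tifffile.imread(d / f"soil_{k}.tif") for k in ("clay", "sand", "silt")}
    crop_mask, phenology, truth_yield, truth_features = {}, {}, {}, {}
    for year in config.years:
        crop_mask[year] = tifffile.imread(d / f"crop_mask_{year}.tif").astype(bool)
        phenology[year] = PhenologyMap(
            year=year, crop=config.crop,
            start_doy=tifffile.imread(d / f"phenology_start_{year}.tif"),
            end_doy=tifffile.imread(d / f"phenology_end_{year}.tif"),
            geometry=geom)
        truth_yield[year] = tifffile.imread(d / f"truth_yield_{year}.tif")
        truth_features[year] = {
            FEATURE_NAME[ind]: window_cumulate(
                stacks[ind][year], phenology[year], WINDOW_STATISTIC[ind],
                crop_mask=crop_mask[year])
            for ind in ("ET", "GPP", "Ts", "LAI")}
    county_map = tifffile.imread(d / "county_map.tif")
    county_yields = pd.read_csv(d / "county_yields.csv")
    point_yields = pd.read_csv(d / "point_yields.csv")
    flux = []
    for entry in manifest["files"]:
        if entry["role"].startswith("flux:"):
            tower_id = entry["role"].split(":", 1)[1]
            days = pd.read_csv(d / entry["file"])
            flux.append(FluxSeries(tower_id=tower_id, row=entry["row"],
                                   col=entry["col"], days=days))
    return SyntheticWorld(config=config, geometry=geom, stacks=stacks,
                          soil=soil, crop_mask=crop_mask, phenology=phenology,
                          county_map=county_map, county_yields=county_yields,
                          point_yields=point_yields, flux=flux,
                          flux_year=manifest["flux_year"],
                          truth_yield=truth_yield, truth_features=truth_features)
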