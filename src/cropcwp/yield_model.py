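"""County-yield filtering, random-forest yield estimation, the
indicator-combination search, and pixel-level prediction.

Recorded county yields are screened in a single pass against three rules:
(a) biophysically attainable bounds (maize 500-15,000 kg/ha, wheat
500-13,000 kg/ha); (b) departure from the county's study-period mean by
more than 3 study-period standard deviations; (c) a planting-area rule on
the county's planted area (direction configurable, see
:class:`FilterRules`).  Statistics are computed once on the table as given
and never re-estimated after removals.

The yield model is a random forest of 100 regression trees with 4
candidate variables per split (capped at the available feature count),
trained on 80% of the county-year rows with the rows holding the global
minimum and maximum yield forced into the training split so the forest
never has to extrapolate beyond the observed range.  The combination
search refits the forest on every non-empty subset of the four
remote-sensing indicators {ET, GPP, Ts, LAI} — the three soil-texture
features are always included — using one fixed split, and scores each
subset on the held-out rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from itertools import combinations
from sklearn.ensemble import RandomForestRegressor

from cropcwp.evaluate import AdjacencyMatrix, MetricsReport, metrics, morans_i
from cropcwp.grids import NODATA
from cropcwp.preprocess import FEATURE_NAME, SOIL_COLUMNS

INDICATORS = ("ET", "GPP", "Ts", "LAI")

#: Biophysically attainable yield range [kg/ha] per crop.
CROP_BOUNDS = {"maize": (500.0, 15000.0), "wheat": (500.0, 13000.0)}

N_TREES = 100
VARS_PER_SPLIT = 4


@dataclass(frozen=True)
class FilterRules:
    """Outlier-screening rules for recorded county yields.

    ``area_rule_direction`` selects which side of ``area_threshold_ha`` is
    excluded.  The default ``exclude_above`` follows the source-data
    screening as printed (records from counties with more than 10,000 ha
    planted are dropped); the audit log makes the consequence visible and
    ``exclude_below`` is available where the opposite reading is wanted.
    """

    crop: str
    lower_bound: float
    upper_bound: float
    sd_multiplier: float = 3.0
    area_threshold_ha: float = 10000.0
    area_rule_direction: str = "exclude_above"

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be below upper_bound")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        if self.area_rule_direction not in ("exclude_above", "exclude_below"):
            raise ValueError("area_rule_direction must be exclude_above|exclude_below")

    @classmethod
    def for_crop(cls, crop: str, **kw) -> "FilterRules":
        lo, hi = CROP_BOUNDS[crop]
        return cls(crop=crop, lower_bound=lo, upper_bound=hi, **kw)


def filter_yield_records(table: pd.DataFrame, rules: FilterRules):
    """Screen a county yield table; returns (filtered table, audit dict).

    All three rules are evaluated on the original table in one pass; a
    removed row is attributed to the first rule it violates, in the order
    below-bound, above-bound, >k·SD, planting-area.  Counties with a
    single record skip the SD rule and are flagged in the audit.
    """
    for col in ("county_id", "year", "yield_kg_ha", "planting_area_ha"):
        if col not in table.columns:
            raise ValueError(f"yield table missing column {col!r}")
    y = table["yield_kg_ha"].to_numpy(dtype=float)
    area = table["planting_area_ha"].to_numpy(dtype=float)

    below = y < rules.lower_bound
    above = y > rules.upper_bound

    grp = table.groupby("county_id")["yield_kg_ha"]
    cmean = grp.transform("mean").to_numpy()
    csd = grp.transform("std").to_numpy()  # sample SD; NaN for single-record counties
    csize = grp.transform("size").to_numpy()
    sd_applicable = csize > 1
    sd_viol = np.zeros(len(table), bool)
    sd_viol[sd_applicable] = (np.abs(y - cmean) > rules.sd_multiplier * csd)[sd_applicable]

    if rules.area_rule_direction == "exclude_above":
        area_viol = area > rules.area_threshold_ha
    else:
        area_viol = area < rules.area_threshold_ha

    reason = np.full(len(table), "", dtype=object)
    reason[area_viol] = "area"
    reason[sd_viol] = "sd"
    reason[above] = "above_bound"
    reason[below] = "below_bound"

    audit = {
        "below_bound": int(np.sum(reason == "below_bound")),
        "above_bound": int(np.sum(reason == "above_bound")),
        "sd": int(np.sum(reason == "sd")),
        "area": int(np.sum(reason == "area")),
        "sd_skipped_counties": sorted(
            table.loc[~sd_applicable, "county_id"].unique().tolist()),
    }
    filtered = table.loc[reason == ""].reset_index(drop=True)
    return filtered, audit


def split_train_test(table: pd.DataFrame, fraction: float = 0.8, seed: int = 0):
    """Random train/test split with the extreme-yield rows forced to train.

    ``ceil(fraction * n)`` rows go to training; the first rows (in the
    table's stable order) holding the global minimum and maximum yield are
    always among them so the training data spans the observed yield range.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    y = table["yield_kg_ha"].to_numpy(dtype=float)
    n_train = math.ceil(fraction * n)
    forced = {int(np.argmin(y)), int(np.argmax(y))}
    pool = np.array([i for i in range(n) if i not in forced])
    rng = np.random.default_rng(seed)
    extra = rng.choice(pool, size=n_train - len(forced), replace=False)
    train_idx = np.sort(np.concatenate([np.fromiter(forced, int), extra]))
    test_idx = np.setdiff1d(np.arange(n), train_idx)
    return (table.iloc[train_idx].reset_index(drop=True),
            table.iloc[test_idx].reset_index(drop=True))


@dataclass
class ModelBundle:
    """A fitted forest plus everything needed to reapply it."""

    forest: RandomForestRegressor
    indicators: tuple[str, ...]
    feature_columns: tuple[str, ...]
    seed: int
    manifest: dict

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[list(self.feature_columns)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        return self.forest.predict(X)


def train_rf(train: pd.DataFrame, indicators, seed: int = 0) -> ModelBundle:
    """Fit the 100-tree random forest on county-year feature rows.

    ``indicators`` is a subset of {ET, GPP, Ts, LAI}; the soil columns
    clay/sand/silt always enter.  Candidate variables per split are
    min(4, number of features); each tree is fit on a bootstrap resample;
    the forest prediction is the mean over trees.
    """
    indicators = tuple(indicators)
    if not indicators:
        raise ValueError("need at least one indicator")
    unknown = set(indicators) - set(INDICATORS)
    if unknown:
        raise ValueError(f"unknown indicators {unknown}")
    cols = tuple(FEATURE_NAME[i] for i in indicators) + SOIL_COLUMNS
    X = train[list(cols)].to_numpy(dtype=float)
    y = train["yield_kg_ha"].to_numpy(dtype=float)
    if len(train) == 0:
        raise ValueError("empty training table")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    rf_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    forest = RandomForestRegressor(
        n_estimators=N_TREES, max_features=min(VARS_PER_SPLIT, len(cols)),
        bootstrap=True, random_state=rf_seed)
    forest.fit(X, y)
    manifest = {"n_train": len(train), "indicators": list(indicators),
                "feature_columns": list(cols), "seed": seed,
                "n_trees": N_TREES, "vars_per_split": min(VARS_PER_SPLIT, len(cols)),
                "train_keys": train[["county_id", "year"]].to_dict("records")}
    return ModelBundle(forest=forest, indicators=indicators,
                       feature_columns=cols, seed=seed, manifest=manifest)


def evaluate_on(bundle: ModelBundle, test: pd.DataFrame,
                adjacency: AdjacencyMatrix | None = None) -> dict:
    """Held-out metrics (and Moran's I of county-mean errors if adjacency
    is given) for a fitted bundle."""
    pred = bundle.predict(test)
    obs = test["yield_kg_ha"].to_numpy(dtype=float)
    rep = metrics(pred, obs, m=len(bundle.feature_columns))
    out = rep.to_dict()
    out["morans_i"] = math.nan
    if adjacency is not None:
        err = pd.Series(pred - obs, index=test["county_id"].to_numpy())
        county_err = err.groupby(level=0).mean()
        if len(county_err) >= 3 and county_err.std() > 0:
            sub = adjacency.subset(county_err.index.to_numpy())
            if sub.S > 0:
                out["morans_i"] = morans_i(county_err.to_numpy(), sub)
    return out


def combo_search(table: pd.DataFrame, seed: int = 0,
                 adjacency: AdjacencyMatrix | None = None,
                 fraction: float = 0.8) -> pd.DataFrame:
    """Score every non-empty indicator subset on one fixed held-out split.

    Returns a 15-row frame (2^4 - 1 subsets) with the held-out metrics per
    combination, reproducible from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    split_seed, *model_seeds = [int(s % (2 ** 31)) for s in ss.generate_state(16)]
    train, test = split_train_test(table, fraction=fraction, seed=split_seed)
    rows = []
    k = 0
    for size in range(1, len(INDICATORS) + 1):
        for combo in combinations(INDICATORS, size):
            bundle = train_rf(train, combo, seed=model_seeds[k])
            k += 1
            res = evaluate_on(bundle, test, adjacency)
            res["indicators"] = "+".join(combo)
            res["n_indicators"] = size
            rows.append(res)
    cols = ["indicators", "n_indicators", "n", "m", "r2_paper", "r2_conventional",
            "rmse", "rrmse_pct", "mbe", "morans_i"]
    return pd.DataFrame(rows)[cols]


def predict_pixels(bundle: ModelBundle, annual_rasters: dict[str, np.ndarray],
                   soil: dict[str, np.ndarray], crop_mask: np.ndarray) -> np.ndarray:
    """Apply a trained bundle per pixel to produce a yield raster [kg/ha].

    Pixels outside the crop mask or with nodata in any feature raster come
    out as nodata; the feature column order is exactly the training order.
    """
    grids = {**annual_rasters, **soil}
    missing = [c for c in bundle.feature_columns if c not in grids]
    if missing:
        raise ValueError(f"missing feature rasters {missing}")
    shape = np.asarray(crop_mask).shape
    valid = np.asarray(crop_mask).astype(bool).copy()
    layers = []
    for c in bundle.feature_columns:
        g = np.asarray(grids[c], dtype=float)
        if g.shape != shape:
            raise ValueError("feature raster geometry mismatch")
        valid &= (g != NODATA) & np.isfinite(g)
        layers.append(g)
    out = np.full(shape, NODATA, dtype=float)
    if valid.any():
        X = np.column_stack([g[valid] for g in layers])
        out[valid] = bundle.forest.predict(X)
    return out


def point_validate(yield_rasters, points: pd.DataFrame, m: int) -> MetricsReport:
    """Compare predicted yield pixels with point-scale yield records.

    ``yield_rasters`` is either a single raster applied to every record or
    a dict keyed by year.  Sites off the grid or on nodata pixels are
    dropped with a warning.
    """
    single = isinstance(yield_rasters, np.ndarray)
    est, obs, dropped = [], [], 0
    for rec in points.itertuples(index=False):
        ras = yield_rasters if single else yield_rasters.get(int(rec.year))
        if ras is None:
            dropped += 1
            continue
        r, c = int(rec.row), int(rec.col)
        if not (0 <= r < ras.shape[0] and 0 <= c < ras.shape[1]) or ras[r, c] == NODATA:
            dropped += 1
            continue
        est.append(float(ras[r, c]))
        obs.append(float(rec.yield_kg_ha))
    if dropped:
        warnings.warn(f"{dropped} point records off-grid or on nodata; dropped")
    if not est:
        raise ValueError("no usable point records")
    return metrics(est, obs, m=m)
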