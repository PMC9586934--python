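"""Validation suite: accuracy metrics, spatial autocorrelation of county
residuals, and input-perturbation sensitivity analysis.

Metrics
-------
For estimates M and observations O (n samples, m model variables):

* ``RMSE  = sqrt(mean((M - O)^2))``
* ``rRMSE = RMSE / mean(O) * 100%``
* ``MBE   = mean(M - O)``
* two adjusted coefficients of determination are reported side by side:
  ``r2_paper`` follows the variance-ratio convention sometimes printed in
  the agronomy literature, ``1 - (1 - SS_M/SS_O) * (n-1)/(n-m-1)`` with
  ``SS_M = sum((M - mean(M))^2)`` and ``SS_O = sum((O - mean(O))^2)``;
  ``r2_conventional`` is the adjusted squared Pearson correlation,
  ``1 - (1 - r^2) * (n-1)/(n-m-1)``.  The variance-ratio form rewards any
  estimator whose spread matches the observations regardless of pairing,
  so all recovery checks in this package rely on ``r2_conventional``.

Spatial autocorrelation
-----------------------
Global Moran's I over county-level residuals x with a binary queen
contiguity matrix w::

    I = n * sum_ij w_ij (x_i - xbar)(x_j - xbar)
        / (S * sum_i (x_i - xbar)^2),   S = sum_ij w_ij

Residuals clustered in space push I towards +1; a value near the
permutation null -1/(n-1) indicates spatially random model errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# accuracy metrics

@dataclass(frozen=True)
class MetricsReport:
    n: int
    m: int
    r2_paper: float
    r2_conventional: float
    rmse: float
    rrmse_pct: float
    mbe: float

    def to_dict(self) -> dict:
        return {"n": self.n, "m": self.m, "r2_paper": self.r2_paper,
                "r2_conventional": self.r2_conventional, "rmse": self.rmse,
                "rrmse_pct": self.rrmse_pct, "mbe": self.mbe}


def metrics(estimates, observations, m: int) -> MetricsReport:
    """Accuracy metrics of estimates against observations.

    Parameters
    ----------
    estimates, observations : array-like, equal length
    m : number of model variables entering the adjusted-R² correction.

    Adjusted R² values require ``n > m + 1`` and non-degenerate variance;
    otherwise they are reported as NaN.  ``n == 1`` still yields RMSE and
    MBE (R² undefined).
    """
    M = np.asarray(estimates, dtype=float)
    O = np.asarray(observations, dtype=float)
    if M.shape != O.shape or M.ndim != 1:
        raise ValueError("estimates and observations must be equal-length 1-D")
    n = M.size
    if n < 1:
        raise ValueError("need at least one sample")
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(O))):
        raise ValueError("non-finite values in metrics input")

    diff = M - O
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    mbe = float(np.mean(diff))
    obar = float(np.mean(O))
    if obar == 0:
        raise ValueError("mean of observations is zero; rRMSE undefined")
    rrmse = rmse / obar * 100.0

    r2_paper = math.nan
    r2_conv = math.nan
    if n > m + 1:
        adj = (n - 1) / (n - m - 1)
        ss_o = float(np.sum((O - O.mean()) ** 2))
        ss_m = float(np.sum((M - M.mean()) ** 2))
        if ss_o > 0:
            r2_paper = 1.0 - (1.0 - ss_m / ss_o) * adj
            if ss_m > 0:
                r = float(np.corrcoef(M, O)[0, 1])
                r2_conv = 1.0 - (1.0 - r * r) * adj
    return MetricsReport(n=n, m=m, r2_paper=r2_paper, r2_conventional=r2_conv,
                         rmse=rmse, rrmse_pct=rrmse, mbe=mbe)


# --------------------------------------------------------------------------
# adjacency and Moran's I

@dataclass
class AdjacencyMatrix:
    """Symmetric binary contiguity weights over labelled counties."""

    county_ids: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.county_ids = np.asarray(self.county_ids)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.county_ids.size, self.county_ids.size):
            raise ValueError("weights must be square over county_ids")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(w, w.T):
            raise ValueError("adjacency must be symmetric")
        self.weights = w

    @property
    def S(self) -> float:
        return float(self.weights.sum())

    def subset(self, ids) -> "AdjacencyMatrix":
        """Restrict to the given county ids (order preserved as given)."""
        ids = np.asarray(ids)
        pos = {cid: k for k, cid in enumerate(self.county_ids.tolist())}
        idx = np.array([pos[c] for c in ids.tolist()])
        return AdjacencyMatrix(ids, self.weights[np.ix_(idx, idx)])


def build_adjacency(county_map: np.ndarray, background: int = 0) -> AdjacencyMatrix:
    """Queen-contiguity adjacency from a labelled county raster.

    Two counties are adjacent iff any pair of their pixels touch along an
    edge or a corner.  Pixels labelled ``background`` separate counties.
    """
    cm = np.asarray(county_map)
    ids = np.unique(cm[cm != background])
    if ids.size < 2:
        raise ValueError("adjacency needs at least two counties (S would be 0)")
    pos = {int(c): k for k, c in enumerate(ids.tolist())}
    w = np.zeros((ids.size, ids.size))
    # compare each pixel with its E, S, SE, SW neighbour; symmetry fills the rest
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for dr, dc in shifts:
        r0, r1 = max(0, -dr), cm.shape[0] - max(0, dr)
        c0, c1 = max(0, -dc), cm.shape[1] - max(0, dc)
        a = cm[r0:r1, c0:c1]
        b = cm[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        touch = (a != b) & (a != background) & (b != background)
        for x, y in zip(a[touch].ravel().tolist(), b[touch].ravel().tolist()):
            w[pos[int(x)], pos[int(y)]] = 1.0
            w[pos[int(y)], pos[int(x)]] = 1.0
    return AdjacencyMatrix(ids, w)


def morans_i(x, W: AdjacencyMatrix) -> float:
    """Global Moran's I of zone values x under binary weights W.

    Requires n >= 3 zones and non-zero variance of x; the result lies in
    [-1, 1] up to floating-point tolerance for binary contiguity weights.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != W.county_ids.size:
        raise ValueError("x must align with W.county_ids")
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 zones")
    d = x - x.mean()
    denom = float(np.sum(d ** 2))
    if denom == 0:
        raise ValueError("Moran's I undefined for constant x")
    S = W.S
    if S <= 0:
        raise ValueError("sum of weights must be positive")
    num = float(d @ W.weights @ d)
    return n * num / (S * denom)


# --------------------------------------------------------------------------
# sensitivity analysis

@dataclass(frozen=True)
class Scenario:
    """Multiplicative input-perturbation scenario.

    Each feature in ``features`` is scaled by (1 + u), u ~ Uniform(low,
    high), drawn independently per row and feature.  ``low``/``high`` are
    relative errors, e.g. (0.0, 0.4) for 0 to +40%.
    """

    name: str
    features: tuple[str, ...]
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.low <= self.high <= 1.0):
            raise ValueError("perturbation range must satisfy -1 <= low <= high <= 1")


@dataclass
class SensitivityReport:
    baseline: MetricsReport
    table: pd.DataFrame
    reps: int
    seed: int


def sensitivity(model, test_features: pd.DataFrame, observations, scenarios,
                reps: int = 30, seed: int = 0) -> SensitivityReport:
    """Recompute test metrics of a *fixed* trained model under multiplicative
    input errors.

    The model is never retrained: per scenario and replicate the targeted
    feature columns are perturbed, the model re-predicts, and metrics are
    recomputed; the report carries per-scenario means over replicates and
    deltas against the unperturbed baseline.
    """
    from cropcwp.yield_model import ModelBundle  # local import, avoids cycle

    if not isinstance(model, ModelBundle):
        raise TypeError("model must be a trained ModelBundle")
    obs = np.asarray(observations, dtype=float)
    X = test_features[list(model.feature_columns)]
    base_pred = model.predict(X)
    m = len(model.feature_columns)
    baseline = metrics(base_pred, obs, m=m)

    rng = np.random.default_rng(seed)
    rows = []
    for sc in scenarios:
        missing = set(sc.features) - set(model.feature_columns)
        if missing:
            raise ValueError(f"scenario {sc.name!r} targets unknown features {missing}")
        r2s, rrmses = [], []
        for _ in range(reps):
            Xp = X.copy()
            for f in sc.features:
                u = rng.uniform(sc.low, sc.high, size=len(Xp))
                Xp[f] = Xp[f].to_numpy() * (1.0 + u)
            rep = metrics(model.predict(Xp), obs, m=m)
            r2s.append(rep.r2_conventional)
            rrmses.append(rep.rrmse_pct)
        rows.append({
            "scenario": sc.name, "features": ",".join(sc.features),
            "low": sc.low, "high": sc.high,
            "r2": float(np.mean(r2s)), "rrmse_pct": float(np.mean(rrmses)),
            "delta_r2": float(np.mean(r2s)) - baseline.r2_conventional,
            "delta_rrmse_pct": float(np.mean(rrmses)) - baseline.rrmse_pct,
        })
    return SensitivityReport(baseline=baseline, table=pd.DataFrame(rows),
                             reps=reps, seed=seed)
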