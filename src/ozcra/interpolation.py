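"""Spatial interpolation of the station network onto a grid.

Two estimators of the concentration surface are provided:

* **Inverse distance weighting (IDW)** — the deterministic estimator
  Z_j = sum_i w_i Z_i / sum_i w_i with weights w_i = d_ij**(-p).  The
  power p defaults to 2 and, by default, every station participates
  (no search neighbourhood).

* **Ordinary kriging** — the best linear unbiased predictor under a
  fitted semivariogram, solving the (n+1)x(n+1) system with a Lagrange
  multiplier so the weights sum to one.  The semivariogram is estimated
  by the classical Matheron estimator and fitted by weighted least
  squares over a multi-start search.

Distances are great-circle kilometres throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geo_io import (
    ExposureGrid,
    GridSpec,
    StationRecord,
    haversine_km,
    haversine_matrix,
)

COINCIDENT_TOL_KM = 1e-9

VARIOGRAM_FAMILIES = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class IDWParams:
    """IDW weighting exponent and neighbourhood size ("all" = every station)."""

    power: float = 2.0
    max_neighbors: int | str = "all"

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("IDW power must be > 0")
        if self.max_neighbors != "all" and int(self.max_neighbors) < 1:
            raise ValueError("max_neighbors must be >= 1 or 'all'")


@dataclass(frozen=True)
class EmpiricalVariogram:
    bin_centers: np.ndarray  # km
    semivariance: np.ndarray  # ppb^2
    pair_counts: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bin_centers", "semivariance", "pair_counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.semivariance < 0):
            raise ValueError("semivariance must be >= 0")
        if np.any(self.pair_counts < 1):
            raise ValueError("retained bins must have >= 1 pair")


@dataclass(frozen=True)
class VariogramModel:
    """Bounded semivariogram model gamma(h) = nugget + partial_sill * g(h/range)."""

    family: str
    nugget: float
    partial_sill: float
    range_km: float

    def __post_init__(self) -> None:
        if self.family not in VARIOGRAM_FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill <= 0 or self.range_km <= 0:
            raise ValueError("require nugget >= 0, partial_sill > 0, range_km > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def gamma(self, h) -> np.ndarray:
        """Semivariance at lag h (km); gamma(0) = 0, jumping to nugget for h > 0."""
        h = np.asarray(h, dtype=float)
        r = self.range_km
        if self.family == "spherical":
            x = np.minimum(h / r, 1.0)
            structure = 1.5 * x - 0.5 * x**3
        elif self.family == "exponential":
            structure = 1.0 - np.exp(-3.0 * h / r)
        else:  # gaussian
            structure = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        out = self.nugget + self.partial_sill * structure
        return np.where(h <= 0, 0.0, out)

    def covariance(self, h) -> np.ndarray:
        """C(h) = sill - gamma(h); equals the full sill (nugget included) at h = 0."""
        return self.sill - self.gamma(h)


def _station_arrays(stations: list[StationRecord]):
    lons = np.array([s.lon for s in stations])
    lats = np.array([s.lat for s in stations])
    vals = np.array([s.conc for s in stations])
    return lons, lats, vals


# ---------------------------------------------------------------------------
# IDW


def idw_predict(
    stations: list[StationRecord],
    target: tuple[float, float],
    params: IDWParams = IDWParams(),
) -> float:
    """Inverse-distance-weighted estimate at a (lon, lat) target."""
    if not stations:
        raise ValueError("IDW requires at least one station")
    d = np.array([haversine_km((s.lon, s.lat), target) for s in stations])
    vals = np.array([s.conc for s in stations])
    hit = d <= COINCIDENT_TOL_KM
    if hit.any():
        return float(vals[np.argmax(hit)])
    if params.max_neighbors != "all" and int(params.max_neighbors) < len(stations):
        keep = np.argsort(d)[: int(params.max_neighbors)]
        d, vals = d[keep], vals[keep]
    w = d ** (-params.power)
    return float(np.sum(w * vals) / np.sum(w))


# ---------------------------------------------------------------------------
# variogram estimation & fitting


def empirical_variogram(
    stations: list[StationRecord],
    n_bins: int = 12,
    max_lag_km: float | None = None,
) -> EmpiricalVariogram:
    """Matheron estimator gamma(h) = (1/2N(h)) sum (Z_i - Z_k)^2, distance-binned.

    The default lag cutoff is half the maximum pairwise distance; empty bins
    are dropped.
    """
    n = len(stations)
    if n < 2:
        raise ValueError("empirical variogram needs >= 2 stations")
    lons, lats, vals = _station_arrays(stations)
    dmat = haversine_matrix(lons, lats, lons, lats)
    iu = np.triu_indices(n, k=1)
    d = dmat[iu]
    sq = (vals[iu[0]] - vals[iu[1]]) ** 2
    if max_lag_km is None:
        max_lag_km = float(d.max()) / 2.0
    if max_lag_km <= 0 or np.allclose(d, d[0]):
        # all pairs at one lag: single-bin result
        return EmpiricalVariogram(
            bin_centers=[float(d.mean())],
            semivariance=[float(sq.mean() / 2.0)],
            pair_counts=[len(d)],
        )
    keep = d <= max_lag_km
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0.0, max_lag_km, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        centers.append(float(d[sel].mean()))
        gammas.append(float(sq[sel].mean() / 2.0))
        counts.append(int(sel.sum()))
    return EmpiricalVariogram(centers, gammas, counts)


#: multi-start grid for the WLS fit: (nugget frac of var, range frac of max lag)
_FIT_STARTS = [(0.0, 0.3), (0.0, 0.8), (0.2, 0.5), (0.5, 1.0)]


def fit_variogram(emp: EmpiricalVariogram, family: str = "spherical") -> VariogramModel:
    """Weighted least-squares variogram fit (Cressie weights N(h)/gamma_model^2).

    Runs a small multi-start search and returns the best local optimum;
    nugget is constrained >= 0.
    """
    if family not in VARIOGRAM_FAMILIES:
        raise ValueError(f"unknown variogram family {family!r}")
    h = emp.bin_centers
    g = emp.semivariance
    ncounts = emp.pair_counts
    if len(h) < 3:
        raise ValueError(
            "fewer than 3 variogram bins: cannot fit a model, fall back to IDW"
        )
    if np.all(g <= 0):
        raise ValueError("all-zero semivariance: pure-nugget field, not fittable")

    gmax = float(g.max())
    hmax = float(h.max())

    def residuals(theta):
        nugget, psill, rng = theta
        model = VariogramModel(family, max(nugget, 0.0), max(psill, 1e-12), max(rng, 1e-9))
        gm = model.gamma(h)
        w = np.sqrt(ncounts) / np.maximum(gm, 1e-12)
        return w * (g - gm)

    best = None
    best_cost = np.inf
    for nug_frac, rng_frac in _FIT_STARTS:
        x0 = [nug_frac * gmax, max(gmax * (1 - nug_frac), 1e-6), rng_frac * hmax]
        try:
            res = least_squares(
                residuals,
                x0,
                bounds=([0.0, 1e-12, 1e-9], [np.inf, np.inf, np.inf]),
                method="trf",
                max_nfev=2000,
            )
        except Exception:
            continue
        if res.cost < best_cost:
            best_cost = res.cost
            best = res.x
    if best is None:
        raise RuntimeError("variogram fit failed from every start")
    nugget, psill, rng = best
    return VariogramModel(family, float(max(nugget, 0.0)), float(psill), float(rng))


def weighted_sse(emp: EmpiricalVariogram, model: VariogramModel) -> float:
    """The WLS objective used by :func:`fit_variogram`, for model comparison."""
    gm = model.gamma(emp.bin_centers)
    w = emp.pair_counts / np.maximum(gm, 1e-12) ** 2
    return float(np.sum(w * (emp.semivariance - gm) ** 2))


# ---------------------------------------------------------------------------
# ordinary kriging


def _check_duplicates(stations: list[StationRecord], dmat: np.ndarray) -> None:
    n = len(stations)
    iu = np.triu_indices(n, k=1)
    coincident = dmat[iu] <= COINCIDENT_TOL_KM
    if coincident.any():
        k = int(np.argmax(coincident))
        i, j = iu[0][k], iu[1][k]
        raise ValueError(
            "duplicate station locations: "
            f"{stations[i].station_id!r} and {stations[j].station_id!r}"
        )


def _kriging_system(dmat: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = dmat.shape[0]
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = model.gamma(dmat)
    a[n, :] = 1.0
    a[:, n] = 1.0
    a[n, n] = 0.0
    return a


def kriging_weights(
    stations: list[StationRecord],
    target: tuple[float, float],
    model: VariogramModel,
) -> tuple[np.ndarray, float]:
    """Ordinary-kriging weights and Lagrange multiplier for one target."""
    if len(stations) < 2:
        raise ValueError("ordinary kriging requires >= 2 stations")
    lons, lats, _ = _station_arrays(stations)
    dmat = haversine_matrix(lons, lats, lons, lats)
    _check_duplicates(stations, dmat)
    a = _kriging_system(dmat, model)
    d0 = haversine_matrix(lons, lats, [target[0]], [target[1]])[:, 0]
    b = np.append(model.gamma(d0), 1.0)
    sol = np.linalg.solve(a, b)
    return sol[:-1], float(sol[-1])


def kriging_predict(
    stations: list[StationRecord],
    target: tuple[float, float],
    model: VariogramModel,
) -> tuple[float, float]:
    """Ordinary-kriging prediction and kriging variance (ppb, ppb^2).

    With a zero nugget the predictor is exact at station locations.  A
    numerically negative variance is clamped to 0 with a warning.
    """
    lons, lats, vals = _station_arrays(stations)
    d0 = np.array([haversine_km((lo, la), target) for lo, la in zip(lons, lats)])
    hit = d0 <= COINCIDENT_TOL_KM
    if hit.any() and model.nugget == 0:
        return float(vals[np.argmax(hit)]), 0.0
    w, mu = kriging_weights(stations, target, model)
    pred = float(w @ vals)
    var = float(w @ model.gamma(d0) + mu)
    if var < 0:
        if var < -1e-8:
            warnings.warn(f"negative kriging variance {var:.3g} clamped to 0")
        var = 0.0
    return pred, var


# ---------------------------------------------------------------------------
# grid prediction


def predict_grid(
    stations: list[StationRecord],
    spec: GridSpec,
    mask: np.ndarray | None = None,
    method: str = "kriging",
    idw_params: IDWParams = IDWParams(),
    variogram: VariogramModel | None = None,
    variogram_family: str = "spherical",
) -> tuple[ExposureGrid, dict]:
    """Predict the surface on every unmasked cell; returns (grid, summary stats).

    For kriging, a variogram is fitted from the stations when not supplied,
    and the station-side system is factorised once for the whole grid.
    Summary statistics (mean, 95% CI of the mean, median, sd, min, max) are
    computed over unmasked cells.
    """
    if mask is None:
        mask = np.ones(spec.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    lons_g, lats_g = spec.cell_centers()
    tlon = lons_g[mask]
    tlat = lats_g[mask]
    lons, lats, vals = _station_arrays(stations)

    out = np.full(spec.shape, np.nan)
    if method == "idw":
        if not stations:
            raise ValueError("IDW requires at least one station")
        d = haversine_matrix(tlon, tlat, lons, lats)  # (cells, stations)
        preds = np.empty(len(tlon))
        coincident = d <= COINCIDENT_TOL_KM
        any_hit = coincident.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(d > 0, d, np.inf) ** (-idw_params.power)
            preds = (w @ vals) / w.sum(axis=1)
        if any_hit.any():
            hit_idx = coincident[any_hit].argmax(axis=1)
            preds[any_hit] = vals[hit_idx]
    elif method == "kriging":
        if variogram is None:
            emp = empirical_variogram(stations)
            variogram = fit_variogram(emp, variogram_family)
        dmat = haversine_matrix(lons, lats, lons, lats)
        _check_duplicates(stations, dmat)
        a = _kriging_system(dmat, variogram)
        d0 = haversine_matrix(lons, lats, tlon, tlat)  # (stations, cells)
        b = np.vstack([variogram.gamma(d0), np.ones(len(tlon))])
        sol = np.linalg.solve(a, b)  # (n+1, cells)
        preds = sol[:-1].T @ vals
        # exactness at coincident cells with zero nugget is inherent in the system
    else:
        raise ValueError(f"unknown method {method!r}")

    out[mask] = preds
    grid = ExposureGrid(spec=spec, values=out, mask=mask)
    grid_summary = summarize_surface(grid)
    return grid, grid_summary


def summarize_surface(grid: ExposureGrid) -> dict:
    """Mean, 95% CI of the mean, median, sd, min, max over unmasked cells."""
    v = grid.values[grid.mask]
    n = v.size
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n > 1 else 0.0
    half = 1.959963984540054 * sd / np.sqrt(n) if n > 1 else 0.0
    return {
        "n_cells": int(n),
        "mean": mean,
        "ci95_lo": mean - half,
        "ci95_hi": mean + half,
        "median": float(np.median(v)),
        "sd": sd,
        "min": float(v.min()),
        "max": float(v.max()),
    }
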