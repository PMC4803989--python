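"""Leave-one-out cross-validation of the interpolators and its scoring.

Each station is withheld in turn and predicted from the remaining n-1;
the (measured, predicted) pairs are scored by MAE, RMSE and Pearson r.
For kriging the variogram is refitted on every fold by default — the
honest LOOCV — with a flag to reuse a single pre-fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geo_io import StationRecord
from .interpolation import (
    IDWParams,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    idw_predict,
    kriging_predict,
)


def mae(pairs) -> float:
    """Mean absolute error over (measured, estimated) pairs."""
    p = np.asarray(pairs, dtype=float)
    return float(np.mean(np.abs(p[:, 0] - p[:, 1])))


def rmse(pairs) -> float:
    """Root mean squared error over (measured, estimated) pairs."""
    p = np.asarray(pairs, dtype=float)
    return float(np.sqrt(np.mean((p[:, 0] - p[:, 1]) ** 2)))


def pearson(pairs) -> tuple[float, float]:
    """Pearson r and two-tailed p between measured and estimated values.

    Returns (nan, nan) when either vector has zero variance (r undefined).
    """
    p = np.asarray(pairs, dtype=float)
    if len(p) < 3:
        raise ValueError("Pearson p-value needs >= 3 pairs")
    if np.std(p[:, 0]) == 0 or np.std(p[:, 1]) == 0:
        return (float("nan"), float("nan"))
    r, pval = stats.pearsonr(p[:, 0], p[:, 1])
    return float(r), float(pval)


@dataclass
class CrossValidationReport:
    method: str
    station_ids: list[str]
    measured: np.ndarray
    predicted: np.ndarray
    mae: float
    rmse: float
    pearson_r: float
    pearson_p: float
    failed_stations: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_ids,
                "measured": self.measured,
                "predicted": self.predicted,
            }
        )


def loocv(
    stations: list[StationRecord],
    method: str = "kriging",
    idw_params: IDWParams = IDWParams(),
    variogram_family: str = "spherical",
    refit_variogram: bool = True,
    fixed_variogram: VariogramModel | None = None,
) -> CrossValidationReport:
    """Leave-one-out cross-validation over the station network.

    A fold that fails (e.g. unfittable variogram) is recorded and excluded
    from the metrics rather than aborting the run.
    """
    if len(stations) < 3:
        raise ValueError("LOOCV needs >= 3 stations")
    if not refit_variogram and method == "kriging" and fixed_variogram is None:
        fixed_variogram = fit_variogram(empirical_variogram(stations), variogram_family)

    ids, meas, pred, failed = [], [], [], []
    for i, held_out in enumerate(stations):
        rest = stations[:i] + stations[i + 1 :]
        target = (held_out.lon, held_out.lat)
        try:
            if method == "idw":
                est = idw_predict(rest, target, idw_params)
            elif method == "kriging":
                model = fixed_variogram
                if model is None:
                    model = fit_variogram(empirical_variogram(rest), variogram_family)
                est, _ = kriging_predict(rest, target, model)
            else:
                raise ValueError(f"unknown method {method!r}")
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            failed.append(held_out.station_id)
            continue
        ids.append(held_out.station_id)
        meas.append(held_out.conc)
        pred.append(est)

    pairs = np.column_stack([meas, pred])
    r, p = pearson(pairs) if len(pairs) >= 3 else (float("nan"), float("nan"))
    return CrossValidationReport(
        method=method,
        station_ids=ids,
        measured=np.array(meas),
        predicted=np.array(pred),
        mae=mae(pairs),
        rmse=rmse(pairs),
        pearson_r=r,
        pearson_p=p,
        failed_stations=failed,
    )


def compare_models(reports: dict[str, CrossValidationReport]) -> pd.DataFrame:
    """Rank interpolators by RMSE (then MAE) and report the accuracy gap.

    The percent difference is expressed relative to the worse model:
    100 * (metric_worse - metric_better) / metric_worse.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 reports to compare")
    sets = [frozenset(r.station_ids) for r in reports.values()]
    if len(set(sets)) != 1:
        raise ValueError("reports cover different station sets; cannot compare")
    rows = sorted(
        (
            {"method": m, "rmse": r.rmse, "mae": r.mae, "pearson_r": r.pearson_r}
            for m, r in reports.items()
        ),
        key=lambda d: (d["rmse"], d["mae"]),
    )
    worst_rmse = rows[-1]["rmse"]
    worst_mae = max(r["mae"] for r in rows)
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
        row["rmse_pct_better_than_worst"] = (
            100.0 * (worst_rmse - row["rmse"]) / worst_rmse if worst_rmse > 0 else 0.0
        )
        row["mae_pct_better_than_worst"] = (
            100.0 * (worst_mae - row["mae"]) / worst_mae if worst_mae > 0 else 0.0
        )
    return pd.DataFrame(rows).set_index("method")
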