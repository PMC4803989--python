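from __future__ import annotations

import numpy as np
import pytest

from ozcra.geo_io import GridSpec, StationRecord
from ozcra.health_impact import build_paf_grid, regional_paf_table
from ozcra.interpolation import predict_grid
from ozcra.synthetic import make_scenario
from ozcra.validation import loocv

RECOVERY_SEEDS = list(range(20))


@pytest.fixture
def five_stations() -> list[StationRecord]:
    """Small irregular network with distinct values, for oracle checks."""
    rng = np.random.default_rng(42)
    return [
        StationRecord(
            station_id=f"S{i}",
            lon=float(100.0 + rng.uniform(-2, 2)),
            lat=float(15.0 + rng.uniform(-2, 2)),
            conc=float(rng.uniform(60, 140)),
        )
        for i in range(5)
    ]


@pytest.fixture
def small_spec() -> GridSpec:
    return GridSpec(lon0=99.0, lat0=14.0, cell_size=0.5, n_lon=5, n_lat=4)


@pytest.fixture(scope="session")
def recovery_study():
    """20-seed synthetic study: LOOCV metrics, grid RMSE, and regional PAF
    recovery for both interpolators; computed once per session."""
    out = {
        "loocv_rmse": {"idw": [], "kriging": []},
        "grid_rmse": {"idw": [], "kriging": []},
        "paf_rel_err": [],  # kriging pipeline vs truth, one entry per region-seed
    }
    for seed in RECOVERY_SEEDS:
        s = make_scenario(seed=seed)
        for method in ("idw", "kriging"):
            out["loocv_rmse"][method].append(loocv(s.stations, method=method).rmse)
            grid, _ = predict_grid(s.stations, s.field.spec, method=method)
            out["grid_rmse"][method].append(
                float(np.sqrt(np.mean((grid.values - s.field.values) ** 2)))
            )
            if method == "kriging":
                pg = build_paf_grid(grid, s.pop, s.params)
                table = regional_paf_table(pg, s.regions).set_index("region")
                for name, truth in s.truth.regional_pafs.items():
                    est = float(table.loc[name, "paf"])
                    out["paf_rel_err"].append(abs(est - truth) / truth)
    return out
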