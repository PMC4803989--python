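"""Exposure -> relative risk -> population attributable fraction.

The health impact function is log-linear: RR = exp(beta * dx), where dx
is the concentration excess over the theoretical-minimum-risk exposure
distribution (TMRED) and beta is the concentration-response slope per
ppb.  The default beta corresponds to a cohort relative risk of 1.040
per 10 ppb of long-term ozone, i.e. beta = ln(1.040)/10.

The TMRED is a band (default 33.3-41.9 ppb); its collapse to a working
counterfactual is a policy choice: the deterministic midpoint (default)
or an average of PAFs over K evenly spaced counterfactuals in the band.

The multi-category PAF over grid cells i is

    PAF = S / (S + 1),   S = sum_i Pe_i * (RR_i - 1),

with Pe_i the share of the national exposed (age >= 25) population in
cell i.  Pe is normalised nationally so regional PAFs are fractions of
the *national* burden; restricted to one cell this reduces to the
single-category form pe*(rr-1)/(pe*(rr-1)+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo_io import ExposureGrid, GridSpec, RegionMap

#: cohort RR per 10 ppb used to calibrate the default slope
RR_PER_10PPB = 1.040
DEFAULT_BETA = float(np.log(RR_PER_10PPB) / 10.0)

TMRED_LO_PPB = 33.3
TMRED_HI_PPB = 41.9


@dataclass(frozen=True)
class HealthImpactParams:
    beta: float = DEFAULT_BETA
    tmred_lo: float = TMRED_LO_PPB
    tmred_hi: float = TMRED_HI_PPB
    tmred_policy: str = "midpoint"
    tmred_samples: int = 100

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not 0 <= self.tmred_lo <= self.tmred_hi:
            raise ValueError("require 0 <= tmred_lo <= tmred_hi")
        if self.tmred_policy not in ("midpoint", "uniform_average"):
            raise ValueError(f"unknown TMRED policy {self.tmred_policy!r}")


def resolve_tmred(params: HealthImpactParams) -> np.ndarray:
    """Counterfactual concentration(s) implied by the TMRED policy.

    ``midpoint`` -> one value, (lo+hi)/2; ``uniform_average`` -> K evenly
    spaced values across the band whose downstream PAFs are averaged.
    """
    if params.tmred_policy == "midpoint":
        return np.array([(params.tmred_lo + params.tmred_hi) / 2.0])
    return np.linspace(params.tmred_lo, params.tmred_hi, params.tmred_samples)


def delta_x(conc, x0: float):
    """Concentration excess max(conc - x0, 0); no negative excess risk."""
    return np.maximum(np.asarray(conc, dtype=float) - x0, 0.0)


def rr_from_delta(dx, beta: float = DEFAULT_BETA):
    """Log-linear relative risk exp(beta * dx); 1 at dx = 0."""
    return np.exp(beta * np.asarray(dx, dtype=float))


def pe_grid(pop: np.ndarray, age_fraction: float = 1.0, mask=None) -> np.ndarray:
    """Share of the national exposed population per cell (sums to 1)."""
    pop = np.asarray(pop, dtype=float)
    if not 0 <= age_fraction <= 1:
        raise ValueError("age_fraction must be in [0, 1]")
    if np.any(pop < 0):
        raise ValueError("population must be >= 0 everywhere")
    exposed = pop * age_fraction
    if mask is not None:
        exposed = np.where(np.asarray(mask, bool), exposed, 0.0)
    total = exposed.sum()
    if total <= 0:
        raise ValueError("zero national exposed population")
    return exposed / total


def paf_single(pe: float, rr: float) -> float:
    """Single-category PAF = pe(rr-1) / (pe(rr-1) + 1)."""
    if not 0 <= pe <= 1:
        raise ValueError("pe must be in [0, 1]")
    if rr < 1:
        raise ValueError("rr must be >= 1")
    s = pe * (rr - 1.0)
    return s / (s + 1.0)


@dataclass
class PAFGrid:
    """Per-cell excess, relative risk, population share and PAF contribution."""

    spec: GridSpec
    delta_x: np.ndarray
    rr: np.ndarray
    pe: np.ndarray
    paf_contrib: np.ndarray  # Pe_i * (RR_i - 1)
    mask: np.ndarray

    def national_paf(self) -> float:
        s = float(self.paf_contrib[self.mask].sum())
        return s / (s + 1.0)


def build_paf_grid(
    exposure: ExposureGrid,
    pop: np.ndarray,
    params: HealthImpactParams = HealthImpactParams(),
    age_fraction: float = 1.0,
) -> PAFGrid:
    """Per-cell PAF machinery from an exposure surface and population raster.

    Under the ``uniform_average`` TMRED policy the per-cell contributions
    Pe_i(RR_i - 1) are averaged over the sampled counterfactuals; dx and rr
    are reported at the band midpoint for the map outputs.
    """
    mask = exposure.mask
    pe = pe_grid(pop, age_fraction, mask=mask)
    x0s = resolve_tmred(params)
    conc = np.where(mask, exposure.values, 0.0)

    contribs = np.zeros_like(pe)
    for x0 in x0s:
        dx = delta_x(conc, x0)
        rr = rr_from_delta(dx, params.beta)
        contribs += pe * (rr - 1.0)
    contribs /= len(x0s)
    contribs = np.where(mask, contribs, 0.0)

    x0_mid = (params.tmred_lo + params.tmred_hi) / 2.0
    dx_mid = np.where(mask, delta_x(conc, x0_mid), 0.0)
    rr_mid = np.where(mask, rr_from_delta(dx_mid, params.beta), 1.0)
    return PAFGrid(
        spec=exposure.spec,
        delta_x=dx_mid,
        rr=rr_mid,
        pe=pe,
        paf_contrib=contribs,
        mask=mask,
    )


def paf_region(paf_grid: PAFGrid, regions: RegionMap, region: str) -> float:
    """Multi-category PAF restricted to one region's cells.

    PAF_region = S / (S + 1) with S summed over the region's cells only;
    Pe stays nationally normalised, so the result reads as a fraction of
    the national burden.
    """
    if regions.spec != paf_grid.spec:
        raise ValueError("region map and PAF grid have different grid specs")
    sel = regions.cells_of(region) & paf_grid.mask
    s = float(paf_grid.paf_contrib[sel].sum())
    return s / (s + 1.0)


def regional_paf_table(paf_grid: PAFGrid, regions: RegionMap) -> pd.DataFrame:
    """Per-region mean excess, mean RR and PAF, plus the national row."""
    rows = []
    for name in regions.region_names:
        sel = regions.cells_of(name) & paf_grid.mask
        if not sel.any():
            rows.append({"region": name, "mean_dx": 0.0, "mean_rr": 1.0, "paf": 0.0})
            continue
        rows.append(
            {
                "region": name,
                "mean_dx": float(paf_grid.delta_x[sel].mean()),
                "mean_rr": float(paf_grid.rr[sel].mean()),
                "paf": paf_region(paf_grid, regions, name),
            }
        )
    rows.append(
        {
            "region": "National",
            "mean_dx": float(paf_grid.delta_x[paf_grid.mask].mean()),
            "mean_rr": float(paf_grid.rr[paf_grid.mask].mean()),
            "paf": paf_grid.national_paf(),
        }
    )
    return pd.DataFrame(rows)
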