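"""Published summary inputs for the Thai national ozone assessment setting.

These are the printed inputs of the national study this package
emulates: per-region mean concentration excesses over the TMRED band,
the regional attributable-burden (AB) figures, and the national
burden-of-disease totals.  They feed the worked examples and the
reproduction checks; the monitoring-station, population and regional
rasters behind them are not redistributable, which is what the
synthetic generator stands in for.
"""

from __future__ import annotations

from .geo_io import RegionBurden

REGIONS = ("Northern", "Northeastern", "Central", "Eastern", "Western", "Southern")

#: regional mean concentration excess over the TMRED midpoint (ppb)
DELTA_X_MEAN_PPB = {
    "Northern": 64.7,
    "Northeastern": 60.8,
    "Central": 84.9,
    "Eastern": 80.5,
    "Western": 83.97,
    "Southern": 43.5,
}

#: population aged >= 25 by region (millions)
POP25_MILLIONS = {
    "Northern": 3.9,
    "Northeastern": 13.7,
    "Central": 12.7,
    "Eastern": 2.4,
    "Western": 1.9,
    "Southern": 5.2,
}

#: national COPD burden (DALYs) and its published sex decomposition
NATIONAL_COPD_DALYS = 259_512.0
NATIONAL_COPD_MALE = 204_312.0
NATIONAL_COPD_FEMALE = 55_199.0
NATIONAL_TOTAL_DALYS = 10.2e6

#: regional total burden of disease, all causes (DALYs)
REGIONAL_TOTAL_DALYS = {
    "Northern": 1.4e6,
    "Northeastern": 3.3e6,
    "Central": 3.0e6,
    "Eastern": 0.7e6,
    "Western": 0.5e6,
    "Southern": 1.3e6,
}

#: published regional ozone-attributable COPD burden (DALYs, both sexes)
REGIONAL_AB_DALYS = {
    "Northern": 5_490.0,
    "Northeastern": 18_430.0,
    "Central": 24_813.0,
    "Eastern": 4_531.0,
    "Western": 3_804.0,
    "Southern": 4_510.0,
}

#: published leave-one-out cross-validation metrics of the two interpolators
CV_METRICS = {
    "idw": {"mae": 20.25, "rmse": 25.13, "pearson_r": 0.272},
    "kriging": {"mae": 17.9, "rmse": 22.58, "pearson_r": 0.50},
}


def regional_pafs_from_ab() -> dict[str, float]:
    """Regional PAFs implied by the published ABs against the national COPD total."""
    return {r: ab / NATIONAL_COPD_DALYS for r, ab in REGIONAL_AB_DALYS.items()}


def burden_table() -> list[RegionBurden]:
    """Six-region burden table consistent with the published national totals.

    Regional COPD DALYs (not published separately) are apportioned in
    proportion to each region's total DALYs; the male share is the
    national one.  All national sums reproduce the published totals.
    """
    male_share = NATIONAL_COPD_MALE / NATIONAL_COPD_DALYS
    rows = []
    for region in REGIONS:
        share = REGIONAL_TOTAL_DALYS[region] / NATIONAL_TOTAL_DALYS
        copd = NATIONAL_COPD_DALYS * share
        rows.append(
            RegionBurden(
                region=region,
                pop25=0.0,
                total_dalys=REGIONAL_TOTAL_DALYS[region],
                copd_dalys=copd,
                copd_male=copd * male_share,
                copd_female=copd * (1.0 - male_share),
            )
        )
    return rows
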