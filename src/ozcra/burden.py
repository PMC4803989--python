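"""Attribute COPD DALYs to ozone: AB = PAF x TB, with a national sex split.

Regional PAFs arrive nationally normalised (fractions of the national
COPD burden), so by default each region's attributable burden is its PAF
times the *national* COPD DALY total; the alternative convention
(regional PAF x regional COPD total) sits behind ``against_national=False``.
The male/female split applies one national ratio taken from the burden
table's national COPD male share.  All arithmetic is carried in full
precision; DALYs are rounded half-up to integers only at the report
boundary.
"""

from __future__ import annotations

import math

import pandas as pd

from .geo_io import RegionBurden


def attributable_burden(paf: float, tb: float) -> float:
    """AB = PAF x TB (DALYs, unrounded)."""
    if not 0 <= paf < 1:
        raise ValueError("paf must be in [0, 1)")
    if tb < 0:
        raise ValueError("tb must be >= 0")
    return paf * tb


def sex_split(ab_total: float, male_dalys: float, total_dalys: float) -> tuple[float, float]:
    """Split an attributable burden by the national male share of COPD DALYs."""
    if total_dalys <= 0:
        raise ValueError("total_dalys must be > 0")
    if not 0 <= male_dalys <= total_dalys:
        raise ValueError("male_dalys must be in [0, total_dalys]")
    male = ab_total * male_dalys / total_dalys
    return male, ab_total - male


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def build_report(
    regional_pafs: dict[str, float],
    burden_table: list[RegionBurden],
    against_national: bool = True,
) -> pd.DataFrame:
    """Regional attributable-burden table with sex split and a Total row.

    Columns: paf, ab_total, ab_male, ab_female (integer DALYs),
    pct_of_region_dalys; the Total row carries pct_of_national_dalys in
    the same column.  Deterministic; permutation of region order leaves
    the totals unchanged.
    """
    regions = {b.region: b for b in burden_table}
    if set(regional_pafs) != set(regions):
        only_paf = sorted(set(regional_pafs) - set(regions))
        only_tab = sorted(set(regions) - set(regional_pafs))
        raise ValueError(
            f"region label mismatch: PAF-only {only_paf}, table-only {only_tab}"
        )

    nat_copd = sum(b.copd_dalys for b in burden_table)
    nat_male = sum(b.copd_male for b in burden_table)
    nat_total = sum(b.total_dalys for b in burden_table)

    rows = []
    ab_sum = 0.0
    for b in burden_table:
        paf = regional_pafs[b.region]
        tb = nat_copd if against_national else b.copd_dalys
        ab = attributable_burden(paf, tb)
        male, female = sex_split(ab, nat_male, nat_copd)
        ab_sum += ab
        rows.append(
            {
                "region": b.region,
                "paf": paf,
                "ab_total": _round_half_up(ab),
                "ab_male": _round_half_up(male),
                "ab_female": _round_half_up(female),
                "region_total_dalys": b.total_dalys,
                "pct_of_region_dalys": 100.0 * ab / b.total_dalys
                if b.total_dalys > 0
                else 0.0,
            }
        )

    male_sum, female_sum = sex_split(ab_sum, nat_male, nat_copd)
    rows.append(
        {
            "region": "Total",
            "paf": ab_sum / nat_copd if nat_copd > 0 else 0.0,
            "ab_total": _round_half_up(ab_sum),
            "ab_male": _round_half_up(male_sum),
            "ab_female": _round_half_up(female_sum),
            "region_total_dalys": nat_total,
            "pct_of_region_dalys": 100.0 * ab_sum / nat_total if nat_total > 0 else 0.0,
        }
    )
    return pd.DataFrame(rows).set_index("region")
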