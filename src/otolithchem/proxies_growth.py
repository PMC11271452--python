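"""Annual chemical proxies and back-calculated growth.

Turns per-zone otolith chemistry into the analysis proxies — Mn:Mg
(hypoxia exposure), Mg:Ca (metabolic status), Sr:Ca (salinity habitat) —
assigns salinity groups, predicts salinity from otolith Sr, and
back-calculates length at age with the biological-intercept method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Columns of the fish-year proxy table.
PROXY_COLUMNS = (
    "fish_id",
    "age",
    "calendar_year",
    "mn_mg",
    "mg_ca",
    "sr_ca",
    "p_ca",
    "predicted_salinity_psu",
    "salinity_group",
    "back_calc_length_mm",
    "sd_region",
    "period",
    "decade",
    "n_points",
    "flagged",
)


@dataclass(frozen=True)
class SalinityCalibration:
    """Otolith-Sr salinity calibration and Sr:Ca habitat grouping.

    ``intercept``/``slope`` parametrise the natural log-log Sr(ppm) to
    salinity relation, predicted salinity = exp((ln Sr - intercept)/slope).
    ``group_thresholds_srca_mmolmol`` split annual mean Sr:Ca into 4 habitat
    salinity groups (half-open upward: [0,3.0) -> 1, ..., [4.6,inf) -> 4).
    """

    intercept: float = 6.241
    slope: float = 0.442
    group_thresholds_srca_mmolmol: tuple = (3.0, 4.0, 4.6)
    group_salinity_labels: tuple = ("<6", "6-12", "12-16", ">16")

    def __post_init__(self):
        t = self.group_thresholds_srca_mmolmol
        if not all(a < b for a, b in zip(t, t[1:])):
            raise ValueError("group thresholds must be strictly increasing")
        if self.slope == 0:
            raise ValueError("slope must be nonzero")


@dataclass(frozen=True)
class GrowthCalibration:
    """Total-length regression on dorsal otolith radius, and the biological
    intercept anchoring back-calculation.

    TL(mm) = tl_slope * dorsal radius (um) + tl_intercept.  L_i is the
    length of a newly hatched larva (4 mm) at otolith radius O_i (10 um).
    """

    tl_slope: float = 0.1323  # mm per um
    tl_intercept: float = -31.033  # mm
    L_i: float = 4.0  # mm
    O_i: float = 10.0  # um

    def __post_init__(self):
        if self.tl_slope <= 0 or self.O_i <= 0 or self.L_i <= 0:
            raise ValueError("tl_slope, O_i and L_i must be > 0")


def predict_salinity(sr_ppm, cal: SalinityCalibration | None = None):
    """Predicted salinity (PSU) from otolith Sr concentration (ppm)."""
    cal = cal or SalinityCalibration()
    sr = np.asarray(sr_ppm, dtype=float)
    if np.any(sr <= 0):
        raise ValueError("sr_ppm must be > 0")
    out = np.exp((np.log(sr) - cal.intercept) / cal.slope)
    return out if out.ndim else float(out)


def assign_salinity_group(sr_ca_mmolmol, cal: SalinityCalibration | None = None):
    """Map annual mean Sr:Ca (mmol/mol) to salinity group 1..4.

    Half-open upward intervals; missing input yields missing output (pandas
    NA), never a default group.
    """
    cal = cal or SalinityCalibration()
    sr = np.asarray(sr_ca_mmolmol, dtype=float)
    if np.any(sr[np.isfinite(sr)] < 0):
        raise ValueError("sr_ca must be >= 0")
    t = cal.group_thresholds_srca_mmolmol
    grp = np.searchsorted(t, sr, side="right") + 1
    grp = np.where(np.isfinite(sr), grp, -1)
    if grp.ndim == 0:
        return int(grp) if grp != -1 else None
    return pd.array(np.where(grp == -1, np.nan, grp), dtype="Int64")


def tl_from_dorsal_radius(dorsal_radius_um: float, cal: GrowthCalibration | None = None) -> float:
    """Total length (mm) predicted from the dorsal otolith radius (um).

    Used for fish lacking a measured length (archaeological samples).
    Raises if the prediction falls at or below the hatch length L_i.
    """
    cal = cal or GrowthCalibration()
    tl = cal.tl_slope * dorsal_radius_um + cal.tl_intercept
    if tl <= cal.L_i:
        raise ValueError(
            f"radius {dorsal_radius_um} um predicts TL {tl:.1f} mm <= L_i; "
            "implausibly small otolith"
        )
    return tl


def dorsal_radius_from_tl(tl_mm: float, cal: GrowthCalibration | None = None) -> float:
    """Inverse of the TL regression: dorsal radius (um) from length (mm)."""
    cal = cal or GrowthCalibration()
    return (tl_mm - cal.tl_intercept) / cal.tl_slope


def back_calculate_length(
    TL: float, O_a, O_c: float, cal: GrowthCalibration | None = None
):
    """Biological-intercept back-calculated length (mm) at annulus O_a.

    L_a = TL + (O_a - O_c) * (TL - L_i) / (O_c - O_i): the linear
    interpolation between hatch (O_i, L_i) and capture (O_c, TL).
    """
    cal = cal or GrowthCalibration()
    if O_c <= cal.O_i:
        raise ValueError("O_c must exceed the hatch radius O_i")
    if TL <= cal.L_i:
        raise ValueError("TL must exceed the hatch length L_i")
    oa = np.asarray(O_a, dtype=float)
    if np.any(oa > O_c + 1e-9):
        raise ValueError("annulus radius beyond the otolith edge")
    if np.any(oa < cal.O_i):
        raise ValueError("annulus radius below the hatch radius O_i")
    out = TL + (oa - O_c) * (TL - cal.L_i) / (O_c - cal.O_i)
    return out if out.ndim else float(out)


def split_age_groups(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition fish-year rows into Age-0 (inshore juvenile habitat) and
    Age >= 1 (offshore habitat) groups."""
    if (rows["age"] < 0).any():
        raise ValueError("negative age in proxy rows")
    is0 = rows["age"] == 0
    return rows.loc[is0].copy(), rows.loc[~is0].copy()


def decade_of(year: int) -> str:
    return f"{int(year) // 10 * 10}s"


def build_proxy_table(
    zone_means: pd.DataFrame,
    fish_meta: pd.Series | dict,
    sal_cal: SalinityCalibration | None = None,
    growth_cal: GrowthCalibration | None = None,
) -> pd.DataFrame:
    """Assemble the fish-year proxy table for one fish.

    ``zone_means`` is the per-zone output of chemical ageing (one row per
    growth zone with mean ratios, zone age, calendar year and outer boundary
    position).  ``fish_meta`` needs fish_id, total_length_mm (may be NaN for
    archaeological fish), dorsal_radius_um, sd_region, period.

    O_a for a zone is its outer boundary; the edge (catch-year) zone ends at
    the otolith edge, so its back-calculated length equals TL at capture.
    """
    sal_cal = sal_cal or SalinityCalibration()
    growth_cal = growth_cal or GrowthCalibration()
    meta = dict(fish_meta)
    O_c = float(meta["dorsal_radius_um"])
    tl = meta.get("total_length_mm")
    if tl is None or (isinstance(tl, float) and math.isnan(tl)):
        tl = tl_from_dorsal_radius(O_c, growth_cal)
    tl = float(tl)

    out = zone_means.copy()
    out["fish_id"] = meta["fish_id"]
    out["sd_region"] = meta.get("sd_region", "")
    out["period"] = meta.get("period", "modern")
    out["decade"] = [
        decade_of(y) if meta.get("period", "modern") != "neolithic" else "neolithic"
        for y in out["calendar_year"]
    ]
    out["salinity_group"] = assign_salinity_group(
        out["sr_ca"].to_numpy(), sal_cal
    )
    sr_ppm = out.get("sr_ppm")
    if sr_ppm is not None:
        valid = sr_ppm > 0
        pred = np.full(len(out), np.nan)
        pred[valid.to_numpy()] = predict_salinity(sr_ppm[valid].to_numpy(), sal_cal)
        out["predicted_salinity_psu"] = pred
    else:
        out["predicted_salinity_psu"] = np.nan
    oa = out["outer_boundary_um"].to_numpy(dtype=float)
    oa = np.minimum(oa, O_c)  # edge zone ends at the otolith edge
    out["back_calc_length_mm"] = back_calculate_length(tl, oa, O_c, growth_cal)
    cols = [c for c in PROXY_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]
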