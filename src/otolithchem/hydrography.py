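"""Environmental covariate preparation.

Holds the annual hydrographic record (dissolved oxygen, temperature,
salinity at the 30-90 m habitat depth window; basin-wide anoxic and hypoxic
water volumes), converts DO concentration to percent saturation via an
equilibrium-solubility formula, computes 3-year moving averages, and joins
the covariates onto fish-year proxy rows for model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HYDRO_COLUMNS = (
    "year",
    "do_ml_l",
    "do_pct_sat",
    "temp_c",
    "salinity_psu",
    "anoxic_km3",
    "hypoxic_km3",
)

# Garcia & Gordon (1992) combined fit to the Benson & Krause equilibrium
# oxygen solubility data, in ml/l.  Ts is the scaled temperature
# ln((298.15 - T)/(273.15 + T)); S is practical salinity.
_A = (2.00907, 3.22014, 4.05010, 4.94457, -0.256847, 3.88767)
_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_C0 = -4.88682e-7


def oxygen_solubility_ml_l(temp_c, salinity_psu):
    """Equilibrium O2 solubility (ml/l) at one atmosphere moist air.

    Benson-Krause-type fit; valid for temp in [-2, 35] degC and salinity in
    [0, 40] PSU.
    """
    t = np.asarray(temp_c, dtype=float)
    s = np.asarray(salinity_psu, dtype=float)
    if np.any(t < -2.0) or np.any(t > 35.0):
        raise ValueError("temperature outside [-2, 35] degC")
    if np.any(s < 0.0) or np.any(s > 40.0):
        raise ValueError("salinity outside [0, 40] PSU")
    ts = np.log((298.15 - t) / (273.15 + t))
    poly_a = sum(a * ts**i for i, a in enumerate(_A))
    poly_b = sum(b * ts**i for i, b in enumerate(_B))
    out = np.exp(poly_a + s * poly_b + _C0 * s**2)
    return out if out.ndim else float(out)


def do_percent_saturation(do_ml_l, temp_c, salinity_psu):
    """Dissolved oxygen as percent of equilibrium solubility at (T, S)."""
    do = np.asarray(do_ml_l, dtype=float)
    if np.any(do < 0):
        raise ValueError("dissolved oxygen must be >= 0")
    sat = 100.0 * do / oxygen_solubility_ml_l(temp_c, salinity_psu)
    return sat if sat.ndim else float(sat)


@dataclass
class HydroSeries:
    """Annual environmental record, one row per year, years unique/sorted."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table
        for col in HYDRO_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"hydro table missing column {col!r}")
        years = df["year"].to_numpy()
        if len(np.unique(years)) != len(years):
            raise ValueError("duplicated years in hydro series")
        if not np.all(np.diff(years) > 0):
            self.table = df.sort_values("year").reset_index(drop=True)
        bad = self.table["anoxic_km3"] > self.table["hypoxic_km3"] + 1e-9
        if bad.any():
            raise ValueError("anoxic volume exceeds hypoxic volume")
        if (self.table["do_pct_sat"] < 0).any():
            raise ValueError("negative DO percent saturation")

    @property
    def years(self) -> np.ndarray:
        return self.table["year"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HydroSeries":
        return cls(pd.read_csv(path))


def moving_average_3yr(series: pd.Series, edges: str = "partial") -> pd.Series:
    """Centered 3-year moving average of a year-indexed series.

    ``edges='partial'`` averages the available 2-year window at the first
    and last year; ``edges='na'`` leaves the edges missing.  A missing
    interior year propagates missing into windows that cover it.
    """
    if len(series) < 2:
        import warnings

        warnings.warn("moving_average_3yr: fewer than 2 years, returning input")
        return series.copy()
    years = series.index.to_numpy()
    full = np.arange(years.min(), years.max() + 1)
    s = series.reindex(full)
    out = s.rolling(3, center=True, min_periods=3).mean()
    if edges == "partial":
        out.iloc[0] = s.iloc[:2].mean() if s.iloc[:2].notna().all() else np.nan
        out.iloc[-1] = s.iloc[-2:].mean() if s.iloc[-2:].notna().all() else np.nan
    return out.loc[years]


def align_covariates(
    rows: pd.DataFrame,
    env: HydroSeries,
    fit_window: tuple[int, int] = (1960, 2019),
) -> pd.DataFrame:
    """Join each fish-year proxy row with its calendar year's covariates.

    Rows outside the fit window, or before the environmental record starts,
    are retained but flagged ``in_model=False``; no row is ever dropped.
    """
    cov = env.table[["year", "anoxic_km3", "salinity_psu", "do_pct_sat", "temp_c"]]
    if cov["year"].duplicated().any():
        raise ValueError("duplicated env years")
    out = rows.merge(
        cov.rename(columns={"year": "calendar_year"}),
        on="calendar_year",
        how="left",
        suffixes=("", "_env"),
    )
    lo, hi = fit_window
    covered = out["calendar_year"].isin(cov["year"])
    out["in_model"] = (
        (out["calendar_year"] >= lo) & (out["calendar_year"] <= hi) & covered
    )
    if len(out) != len(rows):
        raise AssertionError("covariate join changed row count")
    return out
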