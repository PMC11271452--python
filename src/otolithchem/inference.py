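"""The three repeated-measures models and the nonparametric comparisons.

Hypoxia:    log annual mean Mn:Mg ~ anoxic volume + salinity + age
            + (age | fish) + (1 | year)
Metabolic:  log annual mean Mg:Ca ~ DO percent saturation + temperature
            + age + (age | fish) + (1 | year)
Growth:     back-calculated length ~ age (categorical), random intercept by
            fish, fitted separately per decade (or the prehistoric period)
            to predict mean length at age.

Plus the VIF multicollinearity screen (flag > 5) and Kruskal-Wallis /
pairwise Wilcoxon rank-sum comparisons of decades within salinity groups,
with Bonferroni-adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import MixedModelResult, fit_crossed_lmm, vif_screen

__all__ = [
    "MixedModelSpec",
    "GroupComparisonResult",
    "fit_hypoxia_model",
    "fit_metabolic_model",
    "fit_length_at_age",
    "vif_screen",
    "decade_group_comparisons",
]

HYPOXIA_TERMS = ["anoxic_km3", "salinity_psu", "age"]
METABOLIC_TERMS = ["do_pct_sat", "temp_c", "age"]


@dataclass(frozen=True)
class MixedModelSpec:
    """What to fit: response, fixed terms, window, df method."""

    response: str
    fixed_terms: tuple
    fit_window: tuple = (1960, 2019)
    reml: bool = True
    log_response: bool = True
    df_method: str = "satterthwaite"
    min_age: int = 1


def hypoxia_spec(**kw) -> MixedModelSpec:
    return MixedModelSpec(response="mn_mg", fixed_terms=tuple(HYPOXIA_TERMS), **kw)


def metabolic_spec(**kw) -> MixedModelSpec:
    return MixedModelSpec(response="mg_ca", fixed_terms=tuple(METABOLIC_TERMS), **kw)


def _fit_proxy_model(table: pd.DataFrame, spec: MixedModelSpec) -> MixedModelResult:
    df = table.copy()
    df = df[df["age"] >= spec.min_age]
    if "in_model" in df.columns:
        df = df[df["in_model"]]
    else:
        lo, hi = spec.fit_window
        df = df[(df["calendar_year"] >= lo) & (df["calendar_year"] <= hi)]
    return fit_crossed_lmm(
        df,
        response=spec.response,
        fixed=list(spec.fixed_terms),
        log_response=spec.log_response,
        df_method=spec.df_method,
    )


def fit_hypoxia_model(
    table: pd.DataFrame, spec: MixedModelSpec | None = None
) -> MixedModelResult:
    """Fit the hypoxia-exposure model on Age >= 1 rows within the window."""
    return _fit_proxy_model(table, spec or hypoxia_spec())


def fit_metabolic_model(
    table: pd.DataFrame, spec: MixedModelSpec | None = None
) -> MixedModelResult:
    """Fit the metabolic-status model on Age >= 1 rows within the window."""
    return _fit_proxy_model(table, spec or metabolic_spec())


@dataclass
class LengthAtAgeResult:
    """Per-group predicted mean length at each age with SE."""

    group: str
    predictions: pd.DataFrame  # age, mean_length_mm, se_mm
    n_fish: int
    flagged: bool = False  # single fish: random intercept unidentifiable


def fit_length_at_age(
    rows: pd.DataFrame,
    group_col: str = "decade",
    length_col: str = "back_calc_length_mm",
    categorical_age: bool = True,
) -> dict[str, LengthAtAgeResult]:
    """length ~ age with a random intercept per fish, per group.

    Age enters as a categorical level (default) so each group yields a
    predicted mean length at each observed age; the continuous-age variant
    is available via ``categorical_age=False``.
    """
    import statsmodels.formula.api as smf

    out: dict[str, LengthAtAgeResult] = {}
    for grp, sub in rows.dropna(subset=[length_col]).groupby(group_col):
        sub = sub[sub["age"] >= 1].copy()
        if sub.empty:
            continue
        nf = sub["fish_id"].nunique()
        ages = np.sort(sub["age"].unique())
        n_fe = len(ages) if categorical_age else 2

        def _fallback():
            pred = (
                sub.groupby("age")[length_col]
                .agg(mean_length_mm="mean", se_mm="sem")
                .reset_index()
            )
            out[str(grp)] = LengthAtAgeResult(str(grp), pred, nf, flagged=True)

        # saturated or single-fish groups: plain per-age means, flagged
        if nf < 2 or len(ages) < 2 or len(sub) <= n_fe + 1:
            _fallback()
            continue
        formula = (
            f"{length_col} ~ C(age)" if categorical_age else f"{length_col} ~ age"
        )
        try:
            md = smf.mixedlm(formula, sub, groups=sub["fish_id"])
            with np.errstate(all="ignore"):
                fit = md.fit(reml=True, method="lbfgs")
        except (np.linalg.LinAlgError, ValueError):
            _fallback()
            continue
        rows_pred = []
        params = fit.params
        cov = fit.cov_params()
        fe_names = [n for n in fit.model.exog_names]
        for a in ages:
            vec = np.zeros(len(fe_names))
            for i, name in enumerate(fe_names):
                if name == "Intercept":
                    vec[i] = 1.0
                elif categorical_age and name == f"C(age)[T.{a}]":
                    vec[i] = 1.0
                elif not categorical_age and name == "age":
                    vec[i] = float(a)
            mean = float(vec @ params[: len(fe_names)])
            se = float(np.sqrt(vec @ cov.iloc[: len(fe_names), : len(fe_names)].to_numpy() @ vec))
            rows_pred.append({"age": int(a), "mean_length_mm": mean, "se_mm": se})
        out[str(grp)] = LengthAtAgeResult(
            str(grp), pd.DataFrame(rows_pred), nf, flagged=False
        )
    return out


@dataclass
class GroupComparisonResult:
    """Kruskal-Wallis across decades within each salinity group, with
    Bonferroni-adjusted pairwise Wilcoxon rank-sum follow-ups."""

    kw_table: pd.DataFrame  # salinity_group, kw_statistic, kw_p, n_decades
    pairwise: pd.DataFrame  # salinity_group, decade_a, decade_b, p_raw, p_bonferroni
    excluded: pd.DataFrame  # salinity_group, decade, n, reason


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, p * n_comparisons)


def decade_group_comparisons(
    rows: pd.DataFrame,
    value_col: str = "mn_mg",
    min_n: int = 5,
    alpha: float = 0.05,
    group_col: str = "salinity_group",
    decade_col: str = "decade",
) -> GroupComparisonResult:
    """Compare decades within each salinity group nonparametrically.

    Decades with fewer than ``min_n`` fish-year values are excluded (and
    reported); with at least two retained decades a Kruskal-Wallis test is
    run, followed — only when KW rejects at ``alpha`` — by all pairwise
    two-sided Wilcoxon rank-sum tests with Bonferroni multiplier equal to
    the number of pairs tested within that salinity group.
    """
    kw_rows, pair_rows, excl_rows = [], [], []
    data = rows.dropna(subset=[value_col, group_col])
    for grp, sub in data.groupby(group_col):
        samples = {}
        for dec, vals in sub.groupby(decade_col)[value_col]:
            v = vals.to_numpy(float)
            if v.size < min_n:
                excl_rows.append(
                    {group_col: grp, "decade": dec, "n": v.size,
                     "reason": f"n < {min_n}"}
                )
            else:
                samples[dec] = v
        if len(samples) < 2:
            excl_rows.append(
                {group_col: grp, "decade": "(all)", "n": len(samples),
                 "reason": "fewer than 2 retained decades"}
            )
            continue
        ks, kp = stats.kruskal(*samples.values())
        kw_rows.append(
            {group_col: grp, "kw_statistic": float(ks), "kw_p": float(kp),
             "n_decades": len(samples)}
        )
        if kp < alpha:
            decs = sorted(samples)
            pairs = [(a, b) for i, a in enumerate(decs) for b in decs[i + 1 :]]
            m = len(pairs)
            for a, b in pairs:
                p = stats.mannwhitneyu(
                    samples[a], samples[b], alternative="two-sided"
                ).pvalue
                pair_rows.append(
                    {group_col: grp, "decade_a": a, "decade_b": b,
                     "p_raw": float(p), "p_bonferroni": bonferroni(float(p), m)}
                )
    return GroupComparisonResult(
        kw_table=pd.DataFrame(kw_rows),
        pairwise=pd.DataFrame(pair_rows),
        excluded=pd.DataFrame(excl_rows),
    )
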