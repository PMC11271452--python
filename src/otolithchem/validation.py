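"""Self-validation studies: formula oracles, ageing recovery rates and
statistical calibration of the repeated-measures machinery.

These routines re-run the whole stack on synthetic data with known truth
and summarise how well each stage performs: exact formula fixed points,
age-recovery rates at zero and realistic measurement noise, type-I error
and confidence-interval coverage of the mixed-model Wald tests, the null
rejection rate of the Kruskal-Wallis comparisons, and pipeline
row-conservation/determinism.  Everything is driven by one integer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import synthetic_data as syn
from .hydrography import align_covariates
from .inference import decade_group_comparisons, fit_hypoxia_model, fit_metabolic_model
from .pipeline import PipelineConfig, run_pipeline
from .proxies_growth import (
    assign_salinity_group,
    back_calculate_length,
    predict_salinity,
    tl_from_dorsal_radius,
)
from .transect_processing import (
    CorrectionConfig,
    apply_mg_interference_correction,
    compute_ratios,
)
from .chemical_ageing import detect_annuli


def formula_oracles() -> dict:
    """Closed-form fixed points of the calibration formulas."""
    import otolithchem as oc

    # 100 ppm Mg from the interference-affected instrument batch
    t = oc.ElementTransect(
        fish_id="o", distance_um=[0.0, 1.0],
        concentrations_ppm={
            "Mg": [100.0, 100.0], "P": [1.0, 1.0], "Mn": [1.0, 1.0],
            "Sr": [1.0, 1.0], "Ca": [4e5, 4e5],
        },
        lab_tag="SUNY-ESF",
    )
    corrected = apply_mg_interference_correction(t, CorrectionConfig())
    return {
        "back_calc_identity_at_capture_mm": back_calculate_length(500.0, 2000.0, 2000.0),
        "back_calc_at_hatch_radius_mm": back_calculate_length(500.0, 10.0, 2000.0),
        "back_calc_midpoint_mm": back_calculate_length(500.0, 1005.0, 2000.0),
        "salinity_at_exp_intercept_psu": predict_salinity(math.exp(6.241)),
        "salinity_one_log_step_psu": predict_salinity(math.exp(6.241 + 0.442)),
        "tl_at_10000um_mm": tl_from_dorsal_radius(10_000.0),
        "mg_100ppm_corrected_ppm": float(corrected.concentrations_ppm["Mg"][0]),
        "salinity_group_at_2p5": int(assign_salinity_group(2.5)),
        "salinity_group_at_3p0": int(assign_salinity_group(3.0)),
        "salinity_group_at_4p0": int(assign_salinity_group(4.0)),
        "salinity_group_at_4p6": int(assign_salinity_group(4.6)),
    }


def _age_errors(scenario, env=None):
    env = env or syn.generate_environment(scenario)
    fish, truth = syn.generate_cohort(scenario, env)
    true_age = truth.fish.set_index("fish_id")["true_age"]
    errs = []
    for f in fish:
        r = compute_ratios(syn.generate_transect(f, truth, env, scenario))
        a = detect_annuli(r)
        errs.append(a.age_years - int(true_age[f.fish_id]))
    return np.array(errs)


def ageing_recovery(seed: int, n_noiseless: int = 24, n_noisy: int = 200) -> dict:
    """Age-recovery rates on noiseless and sigma-0.15 transects."""
    noiseless = syn.SyntheticScenario(
        n_fish=n_noiseless,
        seed=seed,
        noise=syn.NoiseParams(0, 0, 0, 0, 0, tl_sigma=0, radius_sigma=0),
        age_probs={a: 1 / 8 for a in range(1, 9)},
    )
    e0 = _age_errors(noiseless)
    noisy = syn.SyntheticScenario(n_fish=n_noisy, seed=seed + 1)
    e1 = _age_errors(noisy)
    return {
        "ageing_noiseless_exact_pct": 100.0 * float((e0 == 0).mean()),
        "ageing_sigma015_within1yr_pct": 100.0 * float((np.abs(e1) <= 1).mean()),
        "ageing_sigma015_exact_pct": 100.0 * float((e1 == 0).mean()),
    }


#: Null-simulation scenario: all generating fixed effects zero, random
#: effects and residual noise retained; deliberately small ("reduced n").
def _null_scenario(seed: int) -> syn.SyntheticScenario:
    link = syn.ProxyLink(
        mnmg_anoxic_per_km3=0.0, mnmg_salinity_per_psu=0.0, mnmg_age_per_yr=0.0,
        mgca_do_per_pct=0.0, mgca_temp_per_c=0.0, mgca_age_per_yr=0.0,
    )
    return syn.SyntheticScenario(
        n_fish=60,
        years_span=(2000, 2011),
        decade_mix={"2000s": 0.6, "2010s": 0.4},
        proxy_link=link,
        seed=seed,
    )


def _signed_scenario(seed: int, n_fish: int = 60) -> syn.SyntheticScenario:
    return syn.SyntheticScenario(
        n_fish=n_fish,
        years_span=(1990, 2019),
        decade_mix={"1990s": 0.34, "2000s": 0.33, "2010s": 0.33},
        age_probs={1: 0.2, 2: 0.25, 3: 0.25, 4: 0.15, 5: 0.15},
        seed=seed,
    )


_FITTERS = {"hypoxia": fit_hypoxia_model, "metabolic": fit_metabolic_model}


def type1_error(seed: int, model: str, reps: int = 500, alpha: float = 0.05) -> dict:
    """Rejection rate of each fixed-effect Wald test under the null."""
    fit = _FITTERS[model]
    rej = []
    base = _null_scenario(0)
    for rep in range(reps):
        sc = dataclasses.replace(base, seed=(seed + 7919 * rep) % 2**31)
        env = syn.generate_environment(sc)
        joined = align_covariates(syn.generate_annual_table(sc, env), env)
        res = fit(joined)
        rej.append(res.pvals[1:] < alpha)
    rates = np.mean(rej, axis=0)
    terms = res.terms[1:]
    return {f"{model}_{t}": 100.0 * float(r) for t, r in zip(terms, rates)}


def ci_coverage(seed: int, reps: int = 100, n_fish: int = 60) -> dict:
    """95% Wald-interval coverage of the generating coefficients."""
    base = _signed_scenario(0, n_fish=n_fish)
    link = base.proxy_link
    truths = {
        "hypoxia": np.array(
            [link.mnmg_anoxic_per_km3, link.mnmg_salinity_per_psu, link.mnmg_age_per_yr]
        ),
        "metabolic": np.array(
            [link.mgca_do_per_pct, link.mgca_temp_per_c, link.mgca_age_per_yr]
        ),
    }
    cover = {m: [] for m in _FITTERS}
    for rep in range(reps):
        sc = dataclasses.replace(base, seed=(seed + 104729 * rep) % 2**31)
        env = syn.generate_environment(sc)
        joined = align_covariates(syn.generate_annual_table(sc, env), env)
        for m, fit in _FITTERS.items():
            res = fit(joined)
            ci = res.wald_ci(0.95)
            lo, hi = ci["lo"].to_numpy()[1:], ci["hi"].to_numpy()[1:]
            cover[m].append((lo <= truths[m]) & (truths[m] <= hi))
    out = {}
    for m in _FITTERS:
        rates = np.mean(cover[m], axis=0)
        out[f"{m}_ci95_coverage_min_pct"] = 100.0 * float(rates.min())
        out[f"{m}_ci95_coverage_mean_pct"] = 100.0 * float(rates.mean())
    return out


def sign_recovery(seed: int, n_fish: int = 300) -> dict:
    """Do the study-scale fits recover every generating sign?"""
    sc = syn.SyntheticScenario(n_fish=n_fish, seed=seed)
    env = syn.generate_environment(sc)
    joined = align_covariates(syn.generate_annual_table(sc, env), env)
    link = sc.proxy_link
    truths = {
        "hypoxia": [link.mnmg_anoxic_per_km3, link.mnmg_salinity_per_psu,
                    link.mnmg_age_per_yr],
        "metabolic": [link.mgca_do_per_pct, link.mgca_temp_per_c,
                      link.mgca_age_per_yr],
    }
    out = {}
    for m, fit in _FITTERS.items():
        res = fit(joined)
        ok = np.all(np.sign(res.beta[1:]) == np.sign(truths[m]))
        out[f"{m}_signs_recovered"] = float(ok)
        out[f"{m}_marginal_r2"] = float(res.marginal_r2)
        out[f"{m}_conditional_r2"] = float(res.conditional_r2)
    return out


def kw_null_rejection(seed: int, reps: int = 500, n_per_decade: int = 50) -> dict:
    """Kruskal-Wallis rejection rate when all decades share a distribution."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(reps):
        rows = pd.DataFrame(
            {
                "salinity_group": 2,
                "decade": np.repeat(["1980s", "1990s", "2000s", "2010s"], n_per_decade),
                "mn_mg": rng.lognormal(-2.5, 0.5, 4 * n_per_decade),
            }
        )
        res = decade_group_comparisons(rows)
        rej += int((res.kw_table["kw_p"] < 0.05).any())
    return {"kw_null_rejection_pct": 100.0 * rej / reps}


def pipeline_checks(seed: int, n_fish: int = 25, workdir=None) -> dict:
    """Row conservation (one proxy row per fish-zone) and rerun determinism."""
    def digest(path: Path) -> str:
        return hashlib.sha256(path.read_bytes()).hexdigest()

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        runs = []
        for name in ("a", "b"):
            cfg = PipelineConfig(
                mode="synthetic", outdir=str(tmp / name), seed=seed,
                scenario=syn.SyntheticScenario(n_fish=n_fish),
            )
            runs.append(run_pipeline(cfg))
        proxy = pd.read_csv(runs[0] / "proxy_table.csv")
        annuli = pd.read_csv(runs[0] / "annuli.csv")
        per_zone = float(len(proxy)) / float(len(annuli))
        identical = all(
            digest(runs[0] / f) == digest(runs[1] / f)
            for f in ("proxy_table.csv", "annuli.csv", "analysis_table.csv")
        )
    return {
        "proxy_rows_per_fish_zone": per_zone,
        "rerun_bit_identical": float(identical),
    }
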