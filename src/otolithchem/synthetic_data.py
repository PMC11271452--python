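"""Synthetic otoliths, cohorts and hydrography with known ground truth.

The generator emulates the study system end to end: an annual Baltic-like
environmental record (anoxic/hypoxic volumes with a post-1999 ramp,
declining deep-water oxygen, quarter-4 temperature and salinity); a cohort
of cod growing by von Bertalanffy; and per-fish LA-ICP-MS-like element
transects in which Mg:Ca and P:Ca cycle once per year of life (winter
minima = annulus boundaries), annual increments shrink with age, Mn tracks
that year's anoxic volume and salinity through a log-linear link, Sr tracks
habitat salinity, and Mg:Ca declines ontogenetically.  Everything is
reproducible from a single integer seed, and a truth table records ages,
annulus radii, lengths and noiseless annual mean ratios so every
downstream stage can be scored against ground truth.

Time convention: hatch is idealised at the start of the birth calendar
year, so winter minima fall at integer ages and growth zone ``a`` spans
calendar year ``birth_year + a`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .hydrography import HydroSeries, do_percent_saturation
from .proxies_growth import GrowthCalibration, dorsal_radius_from_tl
from .transect_processing import ElementTransect

CA_PPM = 400780.0  # aragonite matrix; Ca/40.078 = 10 mmol/g exactly
_M = {"Mg": 24.305, "P": 30.974, "Mn": 54.938, "Sr": 87.62, "Ca": 40.078}


@dataclass(frozen=True)
class EnvParams:
    """Trend/level parameters of the synthetic environmental record.

    Anoxic volume ramps linearly after ``ramp_start_year``; DO, temperature
    and salinity follow linear trends from the series start; multiplicative
    (anoxic) or additive (others) interannual noise on top.
    """

    anoxic_base_km3: float = 150.0
    anoxic_ramp_km3_per_yr: float = 55.0
    ramp_start_year: int = 1999
    hypoxic_factor: float = 2.0
    hypoxic_offset_km3: float = 600.0
    do_base_ml_l: float = 5.5
    do_trend_ml_l_per_yr: float = -0.025
    temp_base_c: float = 5.0
    temp_trend_c_per_yr: float = 0.01
    salinity_base_psu: float = 8.5
    salinity_trend_psu_per_yr: float = -0.005
    anoxic_sigma: float = 0.15  # lognormal
    do_sigma_ml_l: float = 0.35
    temp_sigma_c: float = 0.5
    salinity_sigma_psu: float = 0.45


@dataclass(frozen=True)
class GrowthParams:
    """Von Bertalanffy growth: L(t) = L_inf * (1 - exp(-k (t - t0)))."""

    L_inf_mm: float = 1150.0
    k_per_yr: float = 0.18
    t0_yr: float = -0.3

    def __post_init__(self):
        if self.k_per_yr <= 0 or self.L_inf_mm <= 0:
            raise ValueError("von Bertalanffy k and L_inf must be > 0")

    def length_at(self, t):
        return self.L_inf_mm * (1.0 - np.exp(-self.k_per_yr * (np.asarray(t, float) - self.t0_yr)))


@dataclass(frozen=True)
class ProxyLink:
    """Log-linear links from drivers to annual mean otolith chemistry.

    ln Mn:Mg  = intercept + a_anox*anoxic + a_sal*salinity + a_age*age (+ RE)
    ln Mg:Ca  = intercept + b_do*DO%% + b_temp*temp + b_age*age (+ RE)
    Sr:Ca     = intercept + c_sal * habitat salinity  (linear, clipped > 0)

    Random effects: correlated per-fish intercept and age slope, a per-year
    intercept, and an independent fish-year residual (``annual_sigma``),
    all on the log scale — mirroring the repeated-measures models fitted
    downstream so parameter recovery is well-posed.
    """

    mnmg_intercept: float = -2.526  # ln(0.08)
    mnmg_anoxic_per_km3: float = 8.0e-4
    mnmg_salinity_per_psu: float = -0.10
    mnmg_age_per_yr: float = -0.12
    mgca_intercept: float = -2.91
    mgca_do_per_pct: float = 0.006
    mgca_temp_per_c: float = 0.04
    mgca_age_per_yr: float = -0.10
    srca_intercept_mmolmol: float = 1.2
    srca_salinity_per_psu: float = 0.28
    pca_base_mmolmol: float = 0.6
    fish_habitat_salinity_sd: float = 2.5
    age0_salinity_shift_psu: float = -2.0
    fish_intercept_sd: float = 0.25
    fish_age_slope_sd: float = 0.06
    fish_corr: float = -0.3
    year_sd: float = 0.12
    annual_sigma: float = 0.10


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative lognormal measurement noise, sigma per element, plus
    lognormal scatter on catch length and otolith radius."""

    mg: float = 0.15
    p: float = 0.15
    mn: float = 0.15
    sr: float = 0.15
    ca: float = 0.01
    tl_sigma: float = 0.08
    radius_sigma: float = 0.03

    def __post_init__(self):
        if any(v < 0 for v in asdict(self).values()):
            raise ValueError("noise sigmas must be >= 0")

    def scaled(self, factor: float) -> "NoiseParams":
        return NoiseParams(
            mg=self.mg * factor, p=self.p * factor, mn=self.mn * factor,
            sr=self.sr * factor, ca=self.ca * factor,
            tl_sigma=self.tl_sigma, radius_sigma=self.radius_sigma,
        )


_DEFAULT_DECADES = tuple(f"{d}s" for d in range(1930, 2020, 10))


@dataclass(frozen=True)
class SyntheticScenario:
    """Full specification of a synthetic study."""

    years_span: tuple = (1920, 2019)
    n_fish: int = 200
    decade_mix: dict = field(
        default_factory=lambda: {d: 1.0 / len(_DEFAULT_DECADES) for d in _DEFAULT_DECADES}
    )
    env_params: EnvParams = field(default_factory=EnvParams)
    growth_params: GrowthParams = field(default_factory=GrowthParams)
    proxy_link: ProxyLink = field(default_factory=ProxyLink)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    # age-at-catch distribution over ages 1..8 (age 0 allowed if weighted)
    age_probs: dict = field(
        default_factory=lambda: {1: 0.10, 2: 0.20, 3: 0.20, 4: 0.20,
                                 5: 0.12, 6: 0.08, 7: 0.06, 8: 0.04}
    )
    catch_quarter_probs: tuple = (0.0, 0.0, 0.0, 1.0)
    sampling_step_um: float = 10.0
    seasonal_amp_mg: float = 0.30
    seasonal_amp_p: float = 0.40
    # phase of the P:Ca cycle relative to Mg:Ca (years); 0 = in phase
    pca_phase_offset_yr: float = 0.0
    diagenesis_n_spikes: int = 0
    diagenesis_spike_factor: float = 50.0
    period: str = "modern"

    def __post_init__(self):
        lo, hi = self.years_span
        if hi < lo:
            raise ValueError(f"invalid years_span: end {hi} < start {lo}")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if abs(sum(self.decade_mix.values()) - 1.0) > 1e-9:
            raise ValueError("decade_mix must sum to 1")
        if abs(sum(self.age_probs.values()) - 1.0) > 1e-9:
            raise ValueError("age_probs must sum to 1")


def neolithic_scenario(**overrides) -> SyntheticScenario:
    """A pre-industrial baseline scenario: no anthropogenic ramps or trends,
    high Mg:Ca baseline, diagenetic Mn spikes switched on."""
    env = EnvParams(
        anoxic_base_km3=20.0, anoxic_ramp_km3_per_yr=0.0,
        do_base_ml_l=6.5, do_trend_ml_l_per_yr=0.0,
        temp_trend_c_per_yr=0.0, salinity_trend_psu_per_yr=0.0,
    )
    link = ProxyLink(mgca_intercept=-2.6)
    kw = dict(
        years_span=(-4500, -4450), n_fish=46, env_params=env, proxy_link=link,
        decade_mix={"neolithic": 1.0}, diagenesis_n_spikes=3, period="neolithic",
    )
    kw.update(overrides)
    return SyntheticScenario(**kw)


@dataclass
class FishRecord:
    """Catch metadata for one simulated fish (what a sampling programme
    would know; true age lives only in the truth table)."""

    fish_id: str
    index: int
    catch_year: int
    catch_quarter: int
    sd_region: str
    period: str
    total_length_mm: float
    dorsal_radius_um: float
    lab_tag: str = "Lund"


@dataclass
class SyntheticTruth:
    """Ground truth: per-fish scalars and one row per fish-year."""

    fish: pd.DataFrame  # fish_id, true_age, birth_year, catch frac, O_c, TL
    rows: pd.DataFrame  # one row per fish-year (see generate_cohort)
    spike_positions: dict = field(default_factory=dict)  # fish_id -> positions um

    def annulus_radii(self, fish_id: str) -> np.ndarray:
        """Interior annulus radii (winter boundaries), increasing."""
        sub = self.rows[self.rows.fish_id == fish_id].sort_values("age")
        return sub["annulus_radius_um"].to_numpy()[:-1]  # last is the edge


def _rng(scenario: SyntheticScenario, *key: int) -> np.random.Generator:
    return np.random.default_rng([scenario.seed & 0x7FFFFFFF, *key])


def generate_environment(scenario: SyntheticScenario) -> HydroSeries:
    """Annual hydrographic record for the scenario's year span."""
    p = scenario.env_params
    rng = _rng(scenario, 0)
    lo, hi = scenario.years_span
    years = np.arange(lo, hi + 1)
    t = years - lo
    ramp = np.maximum(0, years - p.ramp_start_year)
    anoxic = (p.anoxic_base_km3 + p.anoxic_ramp_km3_per_yr * ramp) * np.exp(
        rng.normal(0.0, p.anoxic_sigma, years.size) if p.anoxic_sigma > 0 else np.zeros(years.size)
    )
    hypoxic = anoxic * max(1.0, p.hypoxic_factor) + p.hypoxic_offset_km3
    do = p.do_base_ml_l + p.do_trend_ml_l_per_yr * t + rng.normal(0, p.do_sigma_ml_l, years.size)
    do = np.clip(do, 0.2, None)
    temp = p.temp_base_c + p.temp_trend_c_per_yr * t + rng.normal(0, p.temp_sigma_c, years.size)
    temp = np.clip(temp, -1.5, 30.0)
    sal = p.salinity_base_psu + p.salinity_trend_psu_per_yr * t + rng.normal(
        0, p.salinity_sigma_psu, years.size
    )
    sal = np.clip(sal, 0.5, 39.0)
    do_pct = do_percent_saturation(do, temp, sal)
    return HydroSeries(
        pd.DataFrame(
            {
                "year": years,
                "do_ml_l": do,
                "do_pct_sat": np.clip(do_pct, 0.0, 120.0),
                "temp_c": temp,
                "salinity_psu": sal,
                "anoxic_km3": anoxic,
                "hypoxic_km3": hypoxic,
            }
        )
    )


def _catch_fraction(quarter: int) -> float:
    """Within-year age fraction at a mid-quarter catch date."""
    return (2 * quarter - 1) / 8.0


def generate_cohort(
    scenario: SyntheticScenario, env: HydroSeries
) -> tuple[list[FishRecord], SyntheticTruth]:
    """Draw a cohort of fish and build the fish-year truth table.

    Catch years follow ``decade_mix``; ages at catch follow ``age_probs``;
    total length is von Bertalanffy at catch age times lognormal noise; the
    dorsal radius comes from inverting the length regression (plus noise);
    interior annulus radii follow the biological-intercept line so
    back-calculation is exactly self-consistent.
    """
    rng = _rng(scenario, 1)
    gp, link, noise = scenario.growth_params, scenario.proxy_link, scenario.noise
    cal = GrowthCalibration()
    env_t = env.table.set_index("year")
    lo_env = int(env.years.min())

    decades = list(scenario.decade_mix)
    probs = np.array([scenario.decade_mix[d] for d in decades])
    ages = np.array(list(scenario.age_probs))
    age_p = np.array([scenario.age_probs[a] for a in ages])
    lo, hi = scenario.years_span

    fish_records: list[FishRecord] = []
    fish_truth = []
    year_rows = []
    # shared year effects (per response) across the cohort
    all_years = env.years
    u_mnmg = dict(zip(all_years, rng.normal(0, link.year_sd, all_years.size)))
    u_mgca = dict(zip(all_years, rng.normal(0, link.year_sd, all_years.size)))

    cov = np.array(
        [
            [link.fish_intercept_sd**2,
             link.fish_corr * link.fish_intercept_sd * link.fish_age_slope_sd],
            [link.fish_corr * link.fish_intercept_sd * link.fish_age_slope_sd,
             link.fish_age_slope_sd**2],
        ]
    )

    for i in range(scenario.n_fish):
        fid = f"F{i:04d}"
        decade = decades[rng.choice(len(decades), p=probs)]
        if decade == "neolithic":
            y0, y1 = lo, hi
        else:
            y0, y1 = int(decade[:4]), int(decade[:4]) + 9
        y0, y1 = max(y0, lo), min(y1, hi)
        age = int(ages[rng.choice(len(ages), p=age_p)])
        # catch late enough that the whole life is inside the env record
        y0 = max(y0, lo_env + age)
        if y0 > y1:
            raise ValueError(
                f"decade {decade}: no catch year allows age {age} within the "
                "environmental record"
            )
        catch_year = int(rng.integers(y0, y1 + 1))
        quarter = int(rng.choice(4, p=np.array(scenario.catch_quarter_probs))) + 1
        frac = _catch_fraction(quarter)
        birth_year = catch_year - age

        tl_noise = np.exp(rng.normal(0, noise.tl_sigma)) if noise.tl_sigma > 0 else 1.0
        TL = float(gp.length_at(age + frac)) * tl_noise
        O_c = dorsal_radius_from_tl(TL, cal) * (
            np.exp(rng.normal(0, noise.radius_sigma)) if noise.radius_sigma > 0 else 1.0
        )
        # lengths at completed ages, scaled onto this fish's trajectory
        t_ages = np.arange(1, age + 1)
        L_at = gp.length_at(t_ages) / gp.length_at(age + frac) * TL
        L_all = np.append(L_at, TL)  # last entry = edge (catch)
        O_at = cal.O_i + (L_all - cal.L_i) * (O_c - cal.O_i) / (TL - cal.L_i)

        sd_region = "SD25" if rng.random() < 0.75 else "SD28"
        b0, b1 = rng.multivariate_normal([0.0, 0.0], cov)
        c0m, c1m = rng.multivariate_normal([0.0, 0.0], cov)
        habitat_offset = rng.normal(0, link.fish_habitat_salinity_sd)
        pca_level = link.pca_base_mmolmol * np.exp(rng.normal(0, 0.1))

        fish_records.append(
            FishRecord(
                fish_id=fid, index=i, catch_year=catch_year, catch_quarter=quarter,
                sd_region=sd_region, period=scenario.period,
                total_length_mm=TL, dorsal_radius_um=float(O_c),
            )
        )
        fish_truth.append(
            {
                "fish_id": fid, "true_age": age, "birth_year": birth_year,
                "catch_quarter": quarter, "catch_frac": frac,
                "TL_mm": TL, "O_c_um": float(O_c), "pca_level": pca_level,
                "habitat_offset_psu": habitat_offset,
            }
        )

        for a in range(age + 1):
            year = birth_year + a
            e = env_t.loc[year]
            sal_hab = (
                e["salinity_psu"] + habitat_offset
                + (link.age0_salinity_shift_psu if a == 0 else 0.0)
            )
            ln_mnmg = (
                link.mnmg_intercept
                + link.mnmg_anoxic_per_km3 * e["anoxic_km3"]
                + link.mnmg_salinity_per_psu * e["salinity_psu"]
                + link.mnmg_age_per_yr * a
                + b0 + b1 * a + u_mnmg[year]
                + (rng.normal(0, link.annual_sigma) if link.annual_sigma > 0 else 0.0)
            )
            ln_mgca = (
                link.mgca_intercept
                + link.mgca_do_per_pct * e["do_pct_sat"]
                + link.mgca_temp_per_c * e["temp_c"]
                + link.mgca_age_per_yr * a
                + c0m + c1m * a + u_mgca[year]
                + (rng.normal(0, link.annual_sigma) if link.annual_sigma > 0 else 0.0)
            )
            srca = max(
                0.2, link.srca_intercept_mmolmol + link.srca_salinity_per_psu * sal_hab
            )
            year_rows.append(
                {
                    "fish_id": fid, "age": a, "calendar_year": year,
                    "true_length_mm": float(L_all[a] if age > 0 else TL),
                    "annulus_radius_um": float(O_at[a] if age > 0 else O_c),
                    "anoxic_km3": float(e["anoxic_km3"]),
                    "true_mn_mg": float(np.exp(ln_mnmg)),
                    "true_mg_ca": float(np.exp(ln_mgca)),
                    "true_sr_ca": float(srca),
                    "true_p_ca": float(pca_level),
                }
            )

    truth = SyntheticTruth(fish=pd.DataFrame(fish_truth), rows=pd.DataFrame(year_rows))
    return fish_records, truth


def _ratio_profiles(scenario, fish_row, truth_rows, distances):
    """Noiseless pointwise ratio profiles along the distance grid."""
    cal = GrowthCalibration()
    age = int(fish_row["true_age"])
    frac = float(fish_row["catch_frac"])
    O_c = float(fish_row["O_c_um"])
    radii = np.concatenate(
        [[cal.O_i], truth_rows["annulus_radius_um"].to_numpy()]
    )
    t_knots = np.concatenate([[0.0], np.arange(1, age + 1), [age + frac]]) if age > 0 \
        else np.array([0.0, frac])
    t = np.interp(distances, radii, t_knots)
    zone = np.minimum(np.floor(t).astype(int), age)
    mg_level = truth_rows["true_mg_ca"].to_numpy()[zone]
    mnmg_level = truth_rows["true_mn_mg"].to_numpy()[zone]
    sr_level = truth_rows["true_sr_ca"].to_numpy()[zone]
    p_level = float(fish_row["pca_level"])
    s_mg = 1.0 - scenario.seasonal_amp_mg * np.cos(2 * np.pi * t)
    s_p = 1.0 - scenario.seasonal_amp_p * np.cos(
        2 * np.pi * (t - scenario.pca_phase_offset_yr)
    )
    mg_ca = mg_level * s_mg
    p_ca = p_level * s_p
    mn_ca = mnmg_level * mg_ca * 1000.0  # umol/mol; Mn shares Mg's seasonality
    sr_ca = np.full_like(mg_ca, np.nan)
    sr_ca[:] = sr_level
    return mg_ca, p_ca, mn_ca, sr_ca, t


def _ratios_to_ppm(mg_ca, p_ca, mn_ca, sr_ca, ca_ppm=CA_PPM):
    ca_umol_g = ca_ppm / _M["Ca"]  # ppm is ug/g, so this is umol/g
    return {
        "Mg": mg_ca * 1e-3 * ca_umol_g * _M["Mg"],
        "P": p_ca * 1e-3 * ca_umol_g * _M["P"],
        "Mn": mn_ca * 1e-6 * ca_umol_g * _M["Mn"],
        "Sr": sr_ca * 1e-3 * ca_umol_g * _M["Sr"],
    }


def generate_transect(
    fish: FishRecord,
    truth: SyntheticTruth,
    env: HydroSeries,
    scenario: SyntheticScenario,
) -> ElementTransect:
    """Element transect for one fish: core to dorsal edge.

    The seasonal cycle lives in the *time* domain and is mapped to distance
    through the radius-at-age curve, so annual increments shrink with age.
    Noiseless realised zone means are appended to the truth table the first
    time each fish is generated; with diagenesis enabled, narrow Mn spikes
    are injected and their positions recorded.
    """
    fr = truth.fish[truth.fish.fish_id == fish.fish_id]
    if fr.empty:
        raise ValueError(f"{fish.fish_id} not in truth table")
    fish_row = fr.iloc[0]
    rows = truth.rows[truth.rows.fish_id == fish.fish_id].sort_values("age")
    step = scenario.sampling_step_um
    if step <= 0:
        raise ValueError("sampling step must be > 0")
    cal = GrowthCalibration()
    O_c = float(fish_row["O_c_um"])
    if O_c - cal.O_i < 2 * step:
        raise ValueError("life span too short for the requested sampling step")
    distances = np.arange(cal.O_i + step, O_c + 1e-9, step)

    mg_ca, p_ca, mn_ca, sr_ca, t = _ratio_profiles(scenario, fish_row, rows, distances)

    # record realised (noiseless, discrete) zone means in the truth table
    if "zone_mean_mg_ca" not in truth.rows.columns or np.isnan(
        truth.rows.loc[truth.rows.fish_id == fish.fish_id].get(
            "zone_mean_mg_ca", pd.Series([np.nan])
        ).iloc[0]
    ):
        zone = np.minimum(np.floor(t).astype(int), int(fish_row["true_age"]))
        mnmg_pt = mn_ca / 1000.0 / mg_ca
        for a in range(int(fish_row["true_age"]) + 1):
            sel = zone == a
            idx = truth.rows.index[
                (truth.rows.fish_id == fish.fish_id) & (truth.rows.age == a)
            ]
            for col, series in (
                ("zone_mean_mg_ca", mg_ca), ("zone_mean_p_ca", p_ca),
                ("zone_mean_sr_ca", sr_ca), ("zone_mean_mn_mg", mnmg_pt),
            ):
                truth.rows.loc[idx, col] = float(series[sel].mean()) if sel.any() else np.nan

    ppm = _ratios_to_ppm(mg_ca, p_ca, mn_ca, sr_ca)
    ppm["Ca"] = np.full(distances.size, CA_PPM)

    rng = _rng(scenario, 2, fish.index)
    sig = {"Mg": scenario.noise.mg, "P": scenario.noise.p, "Mn": scenario.noise.mn,
           "Sr": scenario.noise.sr, "Ca": scenario.noise.ca}
    for el in ppm:
        if sig[el] > 0:
            ppm[el] = ppm[el] * np.exp(rng.normal(0, sig[el], distances.size))

    if scenario.diagenesis_n_spikes > 0:
        k = min(scenario.diagenesis_n_spikes, distances.size)
        idx = np.sort(rng.choice(distances.size, size=k, replace=False))
        ppm["Mn"] = ppm["Mn"].copy()
        ppm["Mn"][idx] *= scenario.diagenesis_spike_factor
        truth.spike_positions[fish.fish_id] = distances[idx].copy()

    return ElementTransect(
        fish_id=fish.fish_id,
        distance_um=distances,
        concentrations_ppm=ppm,
        axis="dorsal",
        lab_tag=fish.lab_tag,
    )


def generate_annual_table(
    scenario: SyntheticScenario, env: HydroSeries
) -> pd.DataFrame:
    """Fish-year proxy rows straight from the link model (no transects).

    Fast path for statistical calibration work: the returned table has the
    same random-effect structure the repeated-measures models assume, with
    residual sd ``annual_sigma``.  Columns match what align_covariates +
    model fitting need.
    """
    _, truth = generate_cohort(scenario, env)
    df = truth.rows.rename(
        columns={"true_mn_mg": "mn_mg", "true_mg_ca": "mg_ca",
                 "true_sr_ca": "sr_ca", "true_p_ca": "p_ca"}
    )
    return df[["fish_id", "age", "calendar_year", "mn_mg", "mg_ca", "sr_ca", "p_ca"]]


def write_dataset(
    outdir,
    scenario: SyntheticScenario,
    env: HydroSeries,
    fish: list[FishRecord],
    truth: SyntheticTruth,
    transects: dict | None = None,
) -> None:
    """Write the synthetic dataset as plain CSV files.

    One transect CSV per fish (distance_um, Mg_ppm, ..., Ca_ppm), a fish
    metadata CSV, the hydro CSV and the truth CSV.
    """
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "transects").mkdir(parents=True, exist_ok=True)
    env.to_csv(outdir / "hydro.csv")
    pd.DataFrame([asdict(f) for f in fish]).to_csv(outdir / "fish.csv", index=False)
    truth.rows.to_csv(outdir / "truth.csv", index=False)
    if transects:
        for fid, tr in transects.items():
            tr.to_frame().to_csv(outdir / "transects" / f"{fid}.csv", index=False)
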