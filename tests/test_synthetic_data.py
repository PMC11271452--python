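import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import otolithchem as oc

from conftest import NOISELESS


FLAT_ENV = oc.EnvParams(
    anoxic_ramp_km3_per_yr=0.0,
    do_trend_ml_l_per_yr=0.0,
    temp_trend_c_per_yr=0.0,
    salinity_trend_psu_per_yr=0.0,
    anoxic_sigma=0.0,
    do_sigma_ml_l=0.0,
    temp_sigma_c=0.0,
    salinity_sigma_psu=0.0,
)


class TestEnvironment:
    def test_flat_scenario_constant_series(self):
        sc = oc.SyntheticScenario(seed=1, env_params=FLAT_ENV)
        env = oc.generate_environment(sc)
        for col in ("anoxic_km3", "do_ml_l", "temp_c", "salinity_psu"):
            assert env.table[col].nunique() == 1

    def test_determinism_bit_identical(self):
        sc = oc.SyntheticScenario(seed=77)
        e1, e2 = oc.generate_environment(sc), oc.generate_environment(sc)
        pd.testing.assert_frame_equal(e1.table, e2.table)

    def test_post1999_ramp_monotone_association(self):
        sc = oc.SyntheticScenario(seed=5)
        env = oc.generate_environment(sc)
        sub = env.table[(env.table.year >= 1999) & (env.table.year <= 2019)]
        rho = stats.spearmanr(sub["year"], sub["anoxic_km3"]).statistic
        assert rho > 0.9

    def test_anoxic_never_exceeds_hypoxic(self):
        env = oc.generate_environment(oc.SyntheticScenario(seed=9))
        assert (env.table["anoxic_km3"] <= env.table["hypoxic_km3"]).all()

    def test_do_saturation_in_range(self):
        env = oc.generate_environment(oc.SyntheticScenario(seed=9))
        assert env.table["do_pct_sat"].between(0, 120).all()

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError, match="years_span"):
            oc.SyntheticScenario(years_span=(2000, 1990))


class TestCohort:
    def test_single_age0_fish_one_truth_row(self):
        sc = oc.SyntheticScenario(
            n_fish=1, seed=3, age_probs={0: 1.0}, noise=NOISELESS
        )
        env = oc.generate_environment(sc)
        fish, truth = oc.generate_cohort(sc, env)
        assert len(truth.rows) == 1
        assert truth.rows["age"].iloc[0] == 0

    def test_noiseless_tl_equals_von_bertalanffy(self):
        sc = oc.SyntheticScenario(n_fish=20, seed=3, noise=NOISELESS)
        env = oc.generate_environment(sc)
        fish, truth = oc.generate_cohort(sc, env)
        for f, (_, tr) in zip(fish, truth.fish.iterrows()):
            t = tr["true_age"] + tr["catch_frac"]
            assert f.total_length_mm == pytest.approx(
                sc.growth_params.length_at(t)
            )

    def test_monte_carlo_mean_tl_matches_closed_form(self):
        sc = oc.SyntheticScenario(n_fish=200, seed=13, age_probs={3: 1.0})
        env = oc.generate_environment(sc)
        fish, truth = oc.generate_cohort(sc, env)
        tl = np.array([f.total_length_mm for f in fish])
        frac = truth.fish["catch_frac"].iloc[0]
        expected = sc.growth_params.length_at(3 + frac)
        se = tl.std(ddof=1) / np.sqrt(tl.size)
        assert abs(tl.mean() - expected) < 3 * se

    def test_truth_invariants(self, noisy_cohort):
        _, _, fish, truth = noisy_cohort
        for f in fish:
            sub = truth.rows[truth.rows.fish_id == f.fish_id].sort_values("age")
            radii = sub["annulus_radius_um"].to_numpy()
            lengths = sub["true_length_mm"].to_numpy()
            assert np.all(np.diff(radii) > 0)
            assert np.all(np.diff(lengths) > 0)

    def test_one_row_per_fish_year(self, noisy_cohort):
        _, _, fish, truth = noisy_cohort
        counts = truth.rows.groupby("fish_id").size()
        ages = truth.fish.set_index("fish_id")["true_age"]
        for fid, n in counts.items():
            assert n == ages[fid] + 1

    def test_life_before_env_start_rejected(self):
        sc = oc.SyntheticScenario(
            n_fish=5, seed=3, years_span=(1930, 1934),
            decade_mix={"1930s": 1.0}, age_probs={8: 1.0},
        )
        env = oc.generate_environment(sc)
        with pytest.raises(ValueError):
            oc.generate_cohort(sc, env)


class TestTransect:
    def test_age5_noiseless_has_five_pca_maxima(self):
        from scipy.signal import find_peaks

        sc = oc.SyntheticScenario(
            n_fish=1, seed=4, noise=NOISELESS, age_probs={5: 1.0},
            catch_quarter_probs=(0.0, 1.0, 0.0, 0.0),  # Q2: partial year < 0.5
        )
        env = oc.generate_environment(sc)
        fish, truth = oc.generate_cohort(sc, env)
        tr = oc.generate_transect(fish[0], truth, env, sc)
        r = oc.compute_ratios(tr)
        s = oc.smooth_profile(r, "p_ca")
        peaks, _ = find_peaks(s, prominence=0.05 * s.mean())
        assert len(peaks) == 5

    def test_distances_increasing_increments_shrinking(self, noiseless_cohort):
        sc, env, fish, truth = noiseless_cohort
        f = next(
            f for f in fish
            if truth.fish.set_index("fish_id").loc[f.fish_id, "true_age"] >= 4
        )
        tr = oc.generate_transect(f, truth, env, sc)
        assert np.all(np.diff(tr.distance_um) > 0)
        bounds = truth.annulus_radii(f.fish_id)
        widths = np.diff(np.concatenate([[0.0], bounds]))
        assert np.all(np.diff(widths) < 0)

    def test_ca_is_constant_aragonite_level(self, noiseless_cohort):
        sc, env, fish, truth = noiseless_cohort
        tr = oc.generate_transect(fish[0], truth, env, sc)
        assert np.allclose(tr.concentrations_ppm["Ca"], 400780.0)

    def test_no_hypoxia_link_means_flat_mn_mg(self):
        link = oc.ProxyLink(
            mnmg_anoxic_per_km3=0.0, mnmg_salinity_per_psu=0.0,
            mnmg_age_per_yr=0.0, fish_intercept_sd=0.0,
            fish_age_slope_sd=0.0, year_sd=0.0, annual_sigma=0.0,
        )
        sc = oc.SyntheticScenario(
            n_fish=5, seed=6, noise=NOISELESS, proxy_link=link,
            env_params=FLAT_ENV,
        )
        env = oc.generate_environment(sc)
        fish, truth = oc.generate_cohort(sc, env)
        spread = truth.rows.groupby("fish_id")["true_mn_mg"].agg(
            lambda v: v.max() / v.min()
        )
        assert np.allclose(spread, 1.0)

    def test_transect_determinism(self, noisy_cohort):
        sc, env, fish, truth = noisy_cohort
        t1 = oc.generate_transect(fish[0], truth, env, sc)
        t2 = oc.generate_transect(fish[0], truth, env, sc)
        for el in t1.concentrations_ppm:
            assert np.array_equal(
                t1.concentrations_ppm[el], t2.concentrations_ppm[el]
            )

    def test_diagenetic_spikes_recorded_and_censorable(self):
        sc = oc.neolithic_scenario(n_fish=1, seed=8, diagenesis_n_spikes=3)
        env = oc.generate_environment(sc)
        fish, truth = oc.generate_cohort(sc, env)
        tr = oc.generate_transect(fish[0], truth, env, sc)
        spikes = truth.spike_positions[fish[0].fish_id]
        assert len(spikes) == 3
        r = oc.compute_ratios(tr)
        out = oc.censor_diagenetic_spikes(r, "mn_ca")
        masked = out.distance_um[out.censored_mask]
        assert out.censored_mask.sum() >= 3
        for s in spikes:
            assert np.any(np.abs(masked - s) <= sc.sampling_step_um + 1e-9)


class TestWriteDataset:
    def test_round_trip_through_csv(self, tmp_path, noisy_cohort):
        sc, env, fish, truth = noisy_cohort
        tr = {f.fish_id: oc.generate_transect(f, truth, env, sc) for f in fish[:3]}
        from otolithchem.synthetic_data import write_dataset

        write_dataset(tmp_path, sc, env, fish[:3], truth, tr)
        back = oc.read_transect(tmp_path / "transects" / f"{fish[0].fish_id}.csv")
        assert len(back) == len(tr[fish[0].fish_id])
        env_back = oc.HydroSeries.from_csv(tmp_path / "hydro.csv")
        assert len(env_back) == len(env)
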