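import dataclasses

import numpy as np
import pandas as pd
import pytest

import otolithchem as oc
from otolithchem.chemical_ageing import AgeingConfig, AnnulusSet

from conftest import NOISELESS


def _ratio_from(values, distances=None, p_values=None):
    n = len(values)
    x = np.asarray(distances, float) if distances is not None else np.linspace(
        10, 2000, n
    )
    return oc.RatioTransect(
        fish_id="r",
        distance_um=x,
        mg_ca=np.asarray(values, float),
        p_ca=np.asarray(p_values if p_values is not None else values, float),
        sr_ca=np.ones(n),
        mn_ca=np.ones(n),
        mn_mg=np.full(n, 0.05),
    )


def _truth_annuli(truth, fish_id, catch_year):
    """AnnulusSet built from ground-truth boundaries."""
    sub = truth.rows[truth.rows.fish_id == fish_id].sort_values("age")
    radii = sub["annulus_radius_um"].to_numpy()
    bounds = radii[:-1]
    spans = []
    lo = 0.0
    for b in bounds:
        spans.append((lo, float(b)))
        lo = float(b)
    spans.append((lo, float(radii[-1])))
    a = AnnulusSet(
        fish_id=fish_id,
        boundary_positions_um=bounds,
        age_years=len(bounds),
        zone_spans=spans,
    )
    return oc.assign_calendar_years(a, catch_year)


class TestSmoothProfile:
    def test_constant_series_unchanged(self):
        r = _ratio_from(np.full(200, 2.0))
        assert np.allclose(oc.smooth_profile(r, "mg_ca"), 2.0)

    def test_sinusoid_extrema_preserved(self):
        x = np.arange(0, 4000, 10.0)
        period = 800.0
        y = 1.0 + 0.5 * np.cos(2 * np.pi * x / period)
        r = _ratio_from(y, distances=x)
        s = oc.smooth_profile(r, "mg_ca", AgeingConfig(smoothing_bandwidth_um=40))
        # analytic minima at odd multiples of period/2
        from scipy.signal import find_peaks

        idx, _ = find_peaks(-s, prominence=0.2)
        expected = np.arange(400.0, 4000.0, period)
        found = x[idx]
        assert len(found) == len(expected)
        assert np.all(np.abs(found - expected) <= 10.0)

    def test_mean_preserved_under_smoothing(self):
        rng = np.random.default_rng(2)
        y = np.ones(300)
        y[150] = 10.0  # delta spike on constant background
        r = _ratio_from(y)
        s = oc.smooth_profile(r, "mg_ca")
        assert s[150] < 10.0
        assert s.mean() == pytest.approx(y.mean(), rel=0.01)

    def test_narrow_bandwidth_falls_back(self):
        r = _ratio_from(np.ones(20), distances=np.arange(20) * 50.0)
        with pytest.warns(UserWarning):
            oc.smooth_profile(r, "mg_ca", AgeingConfig(smoothing_bandwidth_um=1.0))

    def test_too_few_points_rejected(self):
        r = _ratio_from(np.ones(4), distances=np.arange(4.0) + 1)
        with pytest.raises(ValueError):
            oc.smooth_profile(r, "mg_ca")


class TestDetectAnnuli:
    def test_monotone_profile_is_age_zero(self):
        x = np.linspace(10, 2000, 100)
        r = _ratio_from(np.linspace(1.0, 0.2, 100), distances=x)
        a = oc.detect_annuli(r)
        assert a.age_years == 0 and len(a.zone_spans) == 1

    def test_noiseless_age5_boundaries_near_truth(self):
        sc = oc.SyntheticScenario(
            n_fish=1, seed=2, noise=NOISELESS, age_probs={5: 1.0}
        )
        env = oc.generate_environment(sc)
        fish, truth = oc.generate_cohort(sc, env)
        r = oc.compute_ratios(oc.generate_transect(fish[0], truth, env, sc))
        a = oc.detect_annuli(r)
        true_bounds = truth.annulus_radii(fish[0].fish_id)
        assert a.age_years == 5
        increments = np.diff(np.concatenate([[0.0], true_bounds]))
        for est, tru, inc in zip(a.boundary_positions_um, true_bounds, increments):
            assert abs(est - tru) < inc / 2

    def test_noiseless_cohort_recovers_age_exactly(self, noiseless_cohort):
        sc, env, fish, truth = noiseless_cohort
        for f in fish:
            r = oc.compute_ratios(oc.generate_transect(f, truth, env, sc))
            a = oc.detect_annuli(r)
            true_age = int(truth.fish[truth.fish.fish_id == f.fish_id].true_age.iloc[0])
            assert a.age_years == true_age, f.fish_id

    def test_age_invariant_to_ratio_rescaling(self, noisy_cohort):
        sc, env, fish, truth = noisy_cohort
        r = oc.compute_ratios(oc.generate_transect(fish[0], truth, env, sc))
        a1 = oc.detect_annuli(r)
        r.mg_ca = r.mg_ca * 7.3
        r.p_ca = r.p_ca * 0.11
        a2 = oc.detect_annuli(r)
        assert a1.age_years == a2.age_years
        assert np.allclose(a1.boundary_positions_um, a2.boundary_positions_um)

    def test_determinism(self, noisy_cohort):
        sc, env, fish, truth = noisy_cohort
        r = oc.compute_ratios(oc.generate_transect(fish[3], truth, env, sc))
        a1, a2 = oc.detect_annuli(r), oc.detect_annuli(r)
        assert a1.age_years == a2.age_years
        assert np.array_equal(a1.boundary_positions_um, a2.boundary_positions_um)

    def test_age_error_monotone_in_noise(self):
        """Mean absolute age error does not decrease as measurement noise
        grows over sigma in {0, 0.1, 0.2, 0.3}."""
        errors = []
        for k, sigma in enumerate((0.0, 0.1, 0.2, 0.3)):
            noise = oc.NoiseParams(sigma, sigma, sigma, sigma, 0.01)
            sc = oc.SyntheticScenario(n_fish=100, seed=31, noise=noise)
            env = oc.generate_environment(sc)
            fish, truth = oc.generate_cohort(sc, env)
            errs = []
            for f in fish:
                r = oc.compute_ratios(oc.generate_transect(f, truth, env, sc))
                a = oc.detect_annuli(r)
                ta = int(truth.fish[truth.fish.fish_id == f.fish_id].true_age.iloc[0])
                errs.append(abs(a.age_years - ta))
            errors.append(np.mean(errs))
        assert all(b >= a - 1e-12 for a, b in zip(errors, errors[1:])), errors


class TestCalendarYears:
    def test_age3_catch_2019(self):
        a = AnnulusSet(
            "f", np.array([100.0, 200.0, 300.0]), 3,
            [(0, 100.0), (100.0, 200.0), (200.0, 300.0), (300.0, 400.0)],
        )
        oc.assign_calendar_years(a, 2019)
        assert a.zone_calendar_years == [2016, 2017, 2018, 2019]

    def test_age0_catch_1935(self):
        a = AnnulusSet("f", np.array([]), 0, [(0, 500.0)])
        oc.assign_calendar_years(a, 1935)
        assert a.zone_calendar_years == [1935]

    def test_missing_catch_year_rejected(self):
        a = AnnulusSet("f", np.array([]), 0, [(0, 500.0)])
        with pytest.raises(ValueError):
            oc.assign_calendar_years(a, None)

    def test_round_trip_with_truth(self, noiseless_cohort):
        """When the age is recovered correctly, every zone-year label
        matches the generator's calendar years."""
        sc, env, fish, truth = noiseless_cohort
        for f in fish[:50]:
            r = oc.compute_ratios(oc.generate_transect(f, truth, env, sc))
            a = oc.detect_annuli(r)
            oc.assign_calendar_years(a, f.catch_year, f.catch_quarter)
            sub = truth.rows[truth.rows.fish_id == f.fish_id].sort_values("age")
            assert a.zone_calendar_years == list(sub["calendar_year"])


class TestAnnualMeans:
    def test_constant_single_zone(self):
        r = _ratio_from(np.full(30, 0.7))
        a = AnnulusSet("r", np.array([]), 0, [(0.0, 2000.0)])
        oc.assign_calendar_years(a, 2001)
        out = oc.annual_means(r, a)
        assert len(out) == 1
        assert out["mg_ca"].iloc[0] == pytest.approx(0.7)

    def test_two_zones_distinct_means(self):
        x = np.linspace(10, 2000, 40)
        r = _ratio_from(np.ones(40), distances=x)
        r.mn_mg = np.where(x < 1000.0, 0.1, 0.3)
        a = AnnulusSet("r", np.array([1000.0]), 1, [(0.0, 1000.0), (1000.0, 2000.0)])
        oc.assign_calendar_years(a, 2001)
        out = oc.annual_means(r, a)
        assert out["mn_mg"].tolist() == pytest.approx([0.1, 0.3])

    def test_sparse_zone_flagged_not_dropped(self):
        x = np.linspace(10, 2000, 40)
        r = _ratio_from(np.ones(40), distances=x)
        a = AnnulusSet("r", np.array([1990.0]), 1, [(0.0, 1990.0), (1990.0, 2000.0)])
        oc.assign_calendar_years(a, 2001)
        out = oc.annual_means(r, a)
        assert len(out) == 2
        assert bool(out["flagged"].iloc[1])

    def test_noiseless_zone_means_match_truth(self, noiseless_cohort):
        """With the true boundaries, zone means equal the truth table's
        realised annual means to 1e-6 relative."""
        sc, env, fish, truth = noiseless_cohort
        for f in fish[:12]:
            r = oc.compute_ratios(oc.generate_transect(f, truth, env, sc))
            a = _truth_annuli(truth, f.fish_id, f.catch_year)
            out = oc.annual_means(r, a)
            sub = truth.rows[truth.rows.fish_id == f.fish_id].sort_values("age")
            for col_est, col_true in (
                ("mg_ca", "zone_mean_mg_ca"),
                ("p_ca", "zone_mean_p_ca"),
                ("mn_mg", "zone_mean_mn_mg"),
                ("sr_ca", "zone_mean_sr_ca"),
            ):
                np.testing.assert_allclose(
                    out[col_est].to_numpy(),
                    sub[col_true].to_numpy(),
                    rtol=1e-6,
                )
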