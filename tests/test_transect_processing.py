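import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import otolithchem as oc
from otolithchem.transect_processing import (
    TransectSchemaError,
    TransectValidationError,
)

from conftest import transect_csv


class TestReadTransect:
    def test_well_formed_csv(self, tmp_path):
        t = oc.read_transect(transect_csv(tmp_path, n=5))
        assert len(t) == 5

    def test_missing_column_names_it(self, tmp_path):
        with pytest.raises(TransectSchemaError, match="Ca_ppm"):
            oc.read_transect(transect_csv(tmp_path, drop="Ca_ppm"))

    def test_nan_row_dropped(self, tmp_path):
        t = oc.read_transect(transect_csv(tmp_path, nan_row=2, n=6))
        assert len(t) == 5

    def test_non_monotone_distances_rejected(self):
        with pytest.raises(TransectValidationError):
            oc.ElementTransect(
                fish_id="x",
                distance_um=[10.0, 5.0, 20.0],
                concentrations_ppm={
                    el: np.ones(3) for el in ("Mg", "P", "Mn", "Sr", "Ca")
                },
            )


class TestMgInterferenceCorrection:
    def test_affected_lab_scales_by_0p6(self, simple_transect):
        simple_transect.lab_tag = "SUNY-ESF"
        out = oc.apply_mg_interference_correction(simple_transect, oc.CorrectionConfig())
        assert np.allclose(out.concentrations_ppm["Mg"], 243.05 * 0.6)
        # other elements untouched
        assert np.allclose(out.concentrations_ppm["Sr"], 2000.0)

    def test_unaffected_lab_unchanged(self, simple_transect):
        out = oc.apply_mg_interference_correction(simple_transect, oc.CorrectionConfig())
        assert np.allclose(out.concentrations_ppm["Mg"], 243.05)

    def test_double_application_rejected(self, simple_transect):
        out = oc.apply_mg_interference_correction(simple_transect, oc.CorrectionConfig())
        with pytest.raises(ValueError):
            oc.apply_mg_interference_correction(out, oc.CorrectionConfig())


class TestComputeRatios:
    def test_hand_arithmetic_mg_ca(self, simple_transect):
        # 243.05 ppm Mg over 400780 ppm Ca: 10 umol/g over 10 mmol/g
        r = oc.compute_ratios(simple_transect)
        assert np.allclose(r.mg_ca, 1.0, atol=1e-12)

    def test_zero_mn_and_mg_flags_mn_mg(self, simple_transect):
        simple_transect.concentrations_ppm["Mn"][:] = 0.0
        simple_transect.concentrations_ppm["Mg"][:] = 0.0
        r = oc.compute_ratios(simple_transect)
        assert np.allclose(r.mn_ca, 0.0)
        assert r.mn_mg_undefined.all() or np.isnan(r.mn_mg).all()

    def test_uniform_rescaling_invariance(self, simple_transect):
        r1 = oc.compute_ratios(simple_transect)
        for el in simple_transect.concentrations_ppm:
            simple_transect.concentrations_ppm[el] = (
                simple_transect.concentrations_ppm[el] * 2.0
            )
        r2 = oc.compute_ratios(simple_transect)
        for name in ("mg_ca", "p_ca", "sr_ca", "mn_ca", "mn_mg"):
            assert np.allclose(r1.series(name), r2.series(name))

    def test_correction_commutes_with_ratios(self, simple_transect):
        """Applying the 0.6 factor scales Mg:Ca by 0.6 and Mn:Mg by 1/0.6."""
        simple_transect.lab_tag = "SUNY-ESF"
        r_raw = oc.compute_ratios(simple_transect)
        corrected = oc.apply_mg_interference_correction(
            simple_transect, oc.CorrectionConfig()
        )
        r_cor = oc.compute_ratios(corrected)
        assert np.allclose(r_cor.mg_ca, 0.6 * r_raw.mg_ca)
        assert np.allclose(r_cor.mn_mg, r_raw.mn_mg / 0.6)
        assert np.allclose(r_cor.sr_ca, r_raw.sr_ca)


class TestCensorSpikes:
    def _ratio(self, values):
        n = len(values)
        return oc.RatioTransect(
            fish_id="r",
            distance_um=np.arange(n, dtype=float),
            mg_ca=np.ones(n),
            p_ca=np.ones(n),
            sr_ca=np.ones(n),
            mn_ca=np.asarray(values, float),
            mn_mg=np.ones(n),
        )

    def test_single_100x_spike_masked(self):
        vals = np.ones(50)
        vals[17] = 100.0
        out = oc.censor_diagenetic_spikes(self._ratio(vals), "mn_ca")
        assert out.censored_mask.sum() == 1 and out.censored_mask[17]

    def test_quiet_series_untouched(self):
        rng = np.random.default_rng(0)
        vals = 1.0 + 0.01 * rng.standard_normal(100)
        out = oc.censor_diagenetic_spikes(self._ratio(vals), "mn_ca")
        assert out.censored_mask.sum() == 0

    def test_injected_spikes_recovered(self):
        """Spikes injected by the generator are found near their true
        positions, with few false positives at the default noise level."""
        sc = oc.neolithic_scenario(n_fish=6, seed=3, diagenesis_n_spikes=3)
        env = oc.generate_environment(sc)
        fish, truth = oc.generate_cohort(sc, env)
        total_false = 0
        total_points = 0
        for f in fish:
            tr = oc.generate_transect(f, truth, env, sc)
            r = oc.compute_ratios(tr)
            out = oc.censor_diagenetic_spikes(r, "mn_ca")
            spikes = truth.spike_positions[f.fish_id]
            step = sc.sampling_step_um
            hit = [
                np.any(np.abs(out.distance_um[out.censored_mask] - s) <= step + 1e-9)
                for s in spikes
            ]
            assert all(hit), f"missed injected spike for {f.fish_id}"
            masked = out.distance_um[out.censored_mask]
            false = sum(
                1 for m in masked if np.all(np.abs(spikes - m) > step + 1e-9)
            )
            total_false += false
            total_points += len(r)
        assert total_false / total_points <= 1 / 500

    def test_censoring_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        vals = np.exp(rng.normal(0, 0.5, 300))
        counts = []
        for thr in (2.0, 3.0, 4.0, 6.0):
            out = oc.censor_diagenetic_spikes(
                self._ratio(vals), "mn_ca", oc.CorrectionConfig(spike_sd_threshold=thr)
            )
            counts.append(int(out.censored_mask.sum()))
        assert counts == sorted(counts, reverse=True)

    def test_values_never_altered(self):
        vals = np.ones(30)
        vals[5] = 50.0
        r = self._ratio(vals)
        out = oc.censor_diagenetic_spikes(r, "mn_ca")
        assert np.array_equal(out.mn_ca, vals)


class TestProximalNormalization:
    def _prox(self):
        n = 10
        return oc.RatioTransect(
            fish_id="p",
            distance_um=np.linspace(100, 1000, n),
            mg_ca=np.ones(n), p_ca=np.ones(n), sr_ca=np.ones(n),
            mn_ca=np.ones(n), mn_mg=np.ones(n),
            axis="proximal",
        )

    def test_equal_radii_identity(self):
        r = self._prox()
        out = oc.normalize_proximal_axis(r, 1500.0, 1500.0)
        assert np.allclose(out.distance_um, r.distance_um)
        assert out.axis == "dorsal-equivalent"

    def test_linear_scaling(self):
        r = self._prox()
        r.distance_um = np.array([250.0, 500.0, 1000.0])
        r.mg_ca = r.p_ca = r.sr_ca = r.mn_ca = r.mn_mg = np.ones(3)
        r.censored_mask = np.zeros(3, bool)
        r.mn_mg_undefined = np.zeros(3, bool)
        out = oc.normalize_proximal_axis(r, 2000.0, 1000.0)
        assert np.allclose(out.distance_um, [500.0, 1000.0, 2000.0])

    def test_round_trip(self):
        r = self._prox()
        out = oc.normalize_proximal_axis(r, 2345.0, 876.0)
        out.axis = "proximal"
        back = oc.normalize_proximal_axis(out, 876.0, 2345.0)
        assert np.allclose(back.distance_um, r.distance_um, atol=1e-9)

    @pytest.mark.parametrize("radii", [(0.0, 100.0), (100.0, -5.0)])
    def test_nonpositive_radius_rejected(self, radii):
        with pytest.raises(ValueError):
            oc.normalize_proximal_axis(self._prox(), *radii)


@given(scale=st.floats(0.1, 10.0))
@settings(max_examples=25, deadline=None)
def test_ratio_scale_invariance_property(scale):
    n = 8
    t = oc.ElementTransect(
        fish_id="h",
        distance_um=np.linspace(10, 500, n),
        concentrations_ppm={
            "Mg": np.full(n, 25.0 * scale),
            "P": np.full(n, 150.0 * scale),
            "Mn": np.full(n, 3.0 * scale),
            "Sr": np.full(n, 1800.0 * scale),
            "Ca": np.full(n, 4.0e5 * scale),
        },
    )
    r = oc.compute_ratios(t)
    base = oc.compute_ratios(
        oc.ElementTransect(
            fish_id="h",
            distance_um=np.linspace(10, 500, n),
            concentrations_ppm={
                "Mg": np.full(n, 25.0), "P": np.full(n, 150.0),
                "Mn": np.full(n, 3.0), "Sr": np.full(n, 1800.0),
                "Ca": np.full(n, 4.0e5),
            },
        )
    )
    assert np.allclose(r.mg_ca, base.mg_ca)
    assert np.allclose(r.mn_mg, base.mn_mg)
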