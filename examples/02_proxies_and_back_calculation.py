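"""From one transect to the fish-year proxy table.

Processes a single synthetic fish end to end: interference correction,
molar ratios, spike censoring, ageing, per-zone means, salinity grouping
and biological-intercept length back-calculation.  Each printed row is one
year of the fish's life.
"""

import otolithchem as oc

scenario = oc.SyntheticScenario(n_fish=1, seed=7, age_probs={5: 1.0})
env = oc.generate_environment(scenario)
fish, truth = oc.generate_cohort(scenario, env)
f = fish[0]

transect = oc.generate_transect(f, truth, env, scenario)
corrected = oc.apply_mg_interference_correction(transect, oc.CorrectionConfig())
ratios = oc.compute_ratios(corrected)
ratios = oc.censor_diagenetic_spikes(ratios, "mn_ca")
annuli = oc.detect_annuli(ratios)
annuli = oc.assign_calendar_years(annuli, f.catch_year, f.catch_quarter)
zones = oc.annual_means(ratios, annuli, element_transect=corrected)
proxy = oc.build_proxy_table(
    zones,
    {
        "fish_id": f.fish_id,
        "total_length_mm": f.total_length_mm,
        "dorsal_radius_um": f.dorsal_radius_um,
        "sd_region": f.sd_region,
        "period": f.period,
        "catch_year": f.catch_year,
        "catch_quarter": f.catch_quarter,
    },
)

cols = ["age", "calendar_year", "mn_mg", "mg_ca", "sr_ca",
        "salinity_group", "back_calc_length_mm"]
print(proxy[cols].round(4).to_string(index=False))
print(
    f"\ncatch length {f.total_length_mm:.0f} mm at radius "
    f"{f.dorsal_radius_um:.0f} um; the last row's back-calculated length "
    "equals the catch length by construction.\n"
    "mn_mg is the hypoxia-exposure proxy (higher = more exposure), mg_ca the\n"
    "metabolic proxy, and salinity_group bins Sr:Ca into 4 habitat classes."
)
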