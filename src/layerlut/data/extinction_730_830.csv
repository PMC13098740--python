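# Molar extinction coefficients of oxy-/deoxy-hemoglobin (base-10, 1/(cm M))
# from the standard compiled in-vitro spectra, and absorption coefficients of
# pure water and pure lipid (mm^-1) from published transmission measurements.
# These are swappable data, not code: pass an alternative table to
# mua_to_chromophores to use different literature values.
wavelength_nm,eps_hbo2_percm_perM,eps_hb_percm_perM,mua_water_permm,mua_lipid_permm
730,390.0,1102.2,0.00196,0.00035
830,974.0,693.0,0.00292,0.00065
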