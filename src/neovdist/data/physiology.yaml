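# Body-composition configuration for the neovdist virtual populations.
#
# Everything in this file is a transparent, literature-informed
# approximation assembled by the package authors:
#   * adult tissue compositions follow the tabulations that accompany the
#     tissue-composition Kp methods (fractional tissue water split into
#     extra-/intracellular, neutral lipid and neutral phospholipid volume
#     fractions, acidic phospholipid in mg/g, and tissue:plasma albumin /
#     lipoprotein concentration ratios);
#   * neonatal and preterm values combine published body-composition
#     ontogeny (total body water ~75% of weight at term and ~85% at
#     GA 30 weeks vs ~60% in adults; fat mass ~13% at term and ~3% at
#     GA 30 weeks vs ~20% in adults) with per-tissue scaling factors;
#   * plasma-protein ontogeny scalars are neonate:adult concentration
#     ratios for albumin and alpha-1-acid glycoprotein.
#
# Units: volume fractions are L per L of tissue (composition tables) or
# L per kg body weight (volume_fractions); acidic_phospholipid is mg/g;
# body weights are kg; gestational age (ga) weeks; postnatal age (pna)
# days; adult age years.

ph:
  plasma: 7.4
  intracellular: 7.0
  erythrocyte: 7.22

plasma_composition:
  f_water: 0.945
  f_neutral_lipid: 0.0035
  f_neutral_phospholipid: 0.00225

erythrocyte_composition:
  f_water_intracellular: 0.603
  f_neutral_lipid: 0.0017
  f_neutral_phospholipid: 0.0029
  acidic_phospholipid: 0.5

# Adult reference composition per tissue:
# [f_water_extracellular, f_water_intracellular, f_neutral_lipid,
#  f_neutral_phospholipid, acidic_phospholipid_mg_g,
#  albumin_ratio, lipoprotein_ratio]
adult_tissue_composition:
  adipose:  [0.135, 0.017, 0.8530, 0.0016, 0.40, 0.049, 0.068]
  bone:     [0.100, 0.346, 0.0170, 0.0017, 0.67, 0.100, 0.050]
  brain:    [0.162, 0.620, 0.0390, 0.0015, 0.40, 0.048, 0.041]
  gut:      [0.282, 0.475, 0.0380, 0.0125, 2.41, 0.158, 0.0141]
  heart:    [0.320, 0.456, 0.0140, 0.0111, 2.25, 0.157, 0.0160]
  kidney:   [0.273, 0.483, 0.0120, 0.0242, 5.03, 0.130, 0.137]
  liver:    [0.161, 0.573, 0.0140, 0.0240, 4.56, 0.086, 0.161]
  lung:     [0.336, 0.446, 0.0220, 0.0128, 3.91, 0.212, 0.168]
  muscle:   [0.118, 0.630, 0.0100, 0.0072, 1.53, 0.064, 0.059]
  pancreas: [0.120, 0.664, 0.0410, 0.0093, 1.67, 0.060, 0.060]
  skin:     [0.382, 0.291, 0.0600, 0.0044, 1.32, 0.277, 0.096]
  spleen:   [0.207, 0.579, 0.0077, 0.0113, 3.18, 0.097, 0.207]

populations:
  adult:
    age_range_years: [20.0, 25.0]
    hematocrit: 0.45
    albumin_relative: 1.0
    agp_relative: 1.0
    water_scale: {extracellular: 1.0, intracellular: 1.0}
    lipid_scale: {neutral_lipid: 1.0, phospholipid: 1.0}
    # body weight by age (years)
    growth:
      breakpoints: [20.0, 25.0]
      bw_kg: [70.0, 70.0]
    # tissue volume fractions of body weight, constant over the age range
    volume_fractions:
      breakpoints: [20.0, 25.0]
      adipose:     [0.190, 0.190]
      bone:        [0.100, 0.100]
      brain:       [0.020, 0.020]
      gut:         [0.017, 0.017]
      heart:       [0.0047, 0.0047]
      kidney:      [0.0044, 0.0044]
      liver:       [0.026, 0.026]
      lung:        [0.0076, 0.0076]
      muscle:      [0.420, 0.420]
      pancreas:    [0.0014, 0.0014]
      skin:        [0.040, 0.040]
      spleen:      [0.0026, 0.0026]
      plasma:      [0.0436, 0.0436]
      erythrocyte: [0.0357, 0.0357]

  term:
    ga_range_weeks: [37.0, 42.0]
    pna_range_days: [0.0, 60.0]
    hematocrit: 0.50
    albumin_relative: 0.75
    agp_relative: 0.45
    # term-neonate tissues carry more extracellular water and less
    # neutral lipid than adult tissue of the same type
    water_scale: {extracellular: 1.35, intracellular: 1.00}
    lipid_scale: {neutral_lipid: 0.55, phospholipid: 1.00}
    # body weight by postnatal age (days)
    growth:
      breakpoints: [0.0, 7.0, 30.0, 60.0]
      bw_kg: [3.5, 3.6, 4.2, 5.0]
    volume_fractions:
      breakpoints: [0.0, 7.0, 30.0, 60.0]
      adipose:     [0.120, 0.135, 0.155, 0.175]
      bone:        [0.060, 0.060, 0.060, 0.060]
      brain:       [0.100, 0.100, 0.095, 0.090]
      gut:         [0.030, 0.030, 0.030, 0.030]
      heart:       [0.006, 0.006, 0.006, 0.006]
      kidney:      [0.009, 0.009, 0.009, 0.009]
      liver:       [0.045, 0.045, 0.045, 0.045]
      lung:        [0.012, 0.012, 0.012, 0.012]
      muscle:      [0.215, 0.220, 0.225, 0.235]
      pancreas:    [0.001, 0.001, 0.001, 0.001]
      skin:        [0.130, 0.130, 0.126, 0.122]
      spleen:      [0.003, 0.003, 0.003, 0.003]
      plasma:      [0.043, 0.043, 0.043, 0.043]
      erythrocyte: [0.042, 0.042, 0.041, 0.040]

  preterm:
    ga_range_weeks: [22.0, 36.999]
    pna_range_days: [0.0, 60.0]
    hematocrit: 0.47
    albumin_relative: 0.65
    agp_relative: 0.35
    water_scale: {extracellular: 1.60, intracellular: 1.00}
    lipid_scale: {neutral_lipid: 0.35, phospholipid: 1.00}
    # body weight by gestational age at birth (weeks); postnatal growth
    # is applied on top in code (fractional gain per day after day 7)
    growth:
      breakpoints: [24.0, 28.0, 30.0, 34.0, 36.0]
      bw_kg: [0.65, 1.10, 1.40, 2.20, 2.80]
    volume_fractions:
      breakpoints: [24.0, 28.0, 30.0, 34.0, 36.0]
      adipose:     [0.015, 0.025, 0.030, 0.060, 0.090]
      bone:        [0.045, 0.045, 0.045, 0.045, 0.045]
      brain:       [0.130, 0.115, 0.110, 0.105, 0.100]
      gut:         [0.030, 0.030, 0.030, 0.030, 0.030]
      heart:       [0.006, 0.006, 0.006, 0.006, 0.006]
      kidney:      [0.009, 0.009, 0.009, 0.009, 0.009]
      liver:       [0.048, 0.048, 0.048, 0.045, 0.043]
      lung:        [0.013, 0.013, 0.013, 0.013, 0.012]
      muscle:      [0.120, 0.135, 0.150, 0.165, 0.180]
      pancreas:    [0.001, 0.001, 0.001, 0.001, 0.001]
      skin:        [0.165, 0.160, 0.158, 0.150, 0.145]
      spleen:      [0.003, 0.003, 0.003, 0.003, 0.003]
      plasma:      [0.050, 0.050, 0.050, 0.048, 0.046]
      erythrocyte: [0.043, 0.043, 0.042, 0.042, 0.041]

# Inter-individual variability: lognormal coefficient of variation applied
# to body weight and tissue volume fractions when sampling virtual subjects.
variability:
  cv_bw: 0.15
  cv_tissue: 0.15

# Fractional body-weight gain per day beyond postnatal day 7, applied to
# the preterm birth weight from the growth table.
postnatal_growth_per_day: 0.015
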