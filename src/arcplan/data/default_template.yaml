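# Initial plan template: prostate single-arc VMAT.
# Prescription: 78 Gy / 72 Gy to PTV1 / PTV2 in 39 fractions.
# The zRectum serial function's isoconstraint (800 cGy, exponent 20) is
# deliberately unattainable: the first planning step probes its isoeffect
# and replaces it with a per-case achievable value.
prescription:
  PTV1: 7800.0
  PTV2: 7200.0
  fractions: 39
settings:
  arc_increment_deg: 36
  beamlet_width_mm: 4.0
  grid_spacing_mm: 4.0
cost_functions:
- structure: urethra
  cost_function: target_eud
  weight_adjust: manual
  weight: 15.0
  isoconstraint: 7840.0
  extras:
    cell_sensitivity: 0.90
- structure: urethra
  cost_function: maximum_dose
  weight_adjust: manual
  weight: 30.0
  isoconstraint: 8050.0
- structure: CTV
  cost_function: underdose_dvh
  weight_adjust: manual
  weight: 100.0
  threshold_cgy: 7810.0
  isoconstraint: 99.0
  extras:
    optimize_all_voxels: true
- structure: CTV
  cost_function: target_penalty
  weight_adjust: manual
  weight: 100.0
  isoconstraint: 7800.0
  extras:
    minimum_volume_pct: 99.0
    optimize_all_voxels: true
- structure: PTV1
  cost_function: underdose_dvh
  weight_adjust: manual
  weight: 100.0
  threshold_cgy: 7800.0
  isoconstraint: 99.0
- structure: PTV1
  cost_function: target_penalty
  weight_adjust: manual
  weight: 100.0
  isoconstraint: 7800.0
  extras:
    minimum_volume_pct: 96.0
- structure: PTV2
  cost_function: underdose_dvh
  weight_adjust: manual
  weight: 100.0
  threshold_cgy: 7200.0
  isoconstraint: 95.0
- structure: PTV2
  cost_function: target_penalty
  weight_adjust: manual
  weight: 100.0
  isoconstraint: 7200.0
  extras:
    minimum_volume_pct: 96.0
- structure: PTV2
  cost_function: quadratic_overdose
  weight_adjust: auto
  threshold_cgy: 7810.0
  isoconstraint: 9.0
- structure: PTV2
  cost_function: overdose_dvh
  weight_adjust: auto
  threshold_cgy: 7400.0
  isoconstraint: 60.0
- structure: zRectum
  cost_function: serial
  weight_adjust: auto
  isoconstraint: 800.0
  extras:
    power_law_exponent: 20.0
    first_step_probe: true
- structure: zRectum
  cost_function: quadratic_overdose
  weight_adjust: auto
  threshold_cgy: 7000.0
  isoconstraint: 9.0
- structure: zRectum
  cost_function: quadratic_overdose
  weight_adjust: auto
  threshold_cgy: 2340.0
  isoconstraint: 20.0
- structure: bladder
  cost_function: serial
  weight_adjust: manual
  weight: 20.0
  isoconstraint: 5000.0
  extras:
    power_law_exponent: 1.0
    shrink_margin_mm: 10.0
- structure: bladder
  cost_function: serial
  weight_adjust: manual
  weight: 20.0
  isoconstraint: 5000.0
  extras:
    power_law_exponent: 15.0
    shrink_margin_mm: 20.0
- structure: femoral_head_L
  cost_function: maximum_dose
  weight_adjust: manual
  weight: 20.0
  isoconstraint: 5000.0
- structure: femoral_head_R
  cost_function: maximum_dose
  weight_adjust: manual
  weight: 20.0
  isoconstraint: 5000.0
- structure: patient
  cost_function: maximum_dose
  weight_adjust: manual
  weight: 4.0
  isoconstraint: 7980.0
  extras:
    optimize_all_voxels: true
- structure: patient
  cost_function: quadratic_overdose
  weight_adjust: auto
  threshold_cgy: 7800.0
  isoconstraint: 2.0
  extras:
    shrink_margin_mm: 1.0
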