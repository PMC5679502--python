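# Calibrated kinetic parameter set.
# provenance: "literature" = taken from published transport/enzyme
# measurements; "fitted" = fitted to batch-fermentation time-series.
# Units: rates mmol/gDW/h, Michaelis & inhibition constants mM, unless noted.
parameters:
  v_Pe_max: 0.08          # fitted; external phosphate maximum input rate
  K_Pe: 0.0333            # fitted; external phosphate Michaelis constant
  v_P_max: 0.0008         # fitted; stored (internal) phosphate maximum input rate
  K_P: 0.0833             # fitted; stored phosphate Michaelis constant
  v_G1: 0.00031419        # fitted; passive glucose uptake rate per mM glucose
  v_G2_max: 0.186         # literature; glucose high-affinity transport Vmax
  K_G2: 0.26              # literature; glucose high-affinity Michaelis constant
  K_i2: 933.0             # literature; citrate inhibition constant (high affinity)
  v_G3_max: 2.706         # literature; glucose low-affinity transport Vmax
  K_G3: 3.67              # literature; glucose low-affinity Michaelis constant
  K_i3: 233.21            # literature; citrate inhibition constant (low affinity)
  v_X1: 0.00033           # fitted; passive xylose uptake rate per mM xylose
  v_X2_max: 0.2           # fitted; xylose high-affinity transport Vmax
  K_X2: 3.33              # fitted; xylose high-affinity Michaelis constant
  v_X3_max: 2.5           # fitted; xylose low-affinity transport Vmax
  K_X3: 3.33              # fitted; xylose low-affinity Michaelis constant
  GOX_conc: 0.1           # fitted; glucose oxidase enzyme, mg per gDW
  v_GOX_per_mg: 27.48     # literature; GOX Vmax per mg enzyme
  K_GOX: 33.0             # literature; GOX Michaelis constant
  v_CIT: 0.12             # fitted; citrate output cap (initial pH <= 2)
  v_OXAL: 0.01            # fitted; oxalate output cap (zero below pH 2)
  pie_after_8h_pH2: 0.015 # fitted; phosphate input rate from t >= 8 h, pH-2 start
  pie_after_8h_pH7: 0.004 # fitted; phosphate input rate from t >= 8 h, pH-7 start
  v_CIT_high_pH: 0.016    # fitted; citrate output cap when initial pH above 2
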