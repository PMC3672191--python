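"""Full titration pipeline: simulate a pH series, fit, select, shape.

Generates correlation curves whose diffusion coefficient follows a
pH-unfolding profile (compact at neutral pH, slowed and aggregation-prone
at the extremes), then runs calibrate -> fit -> model selection ->
Stokes-Einstein -> equal-volume Perrin inversion per pH.
"""

import fcs_hydroshape as fh

scenario = fh.titration_scenario([2.0, 4.0, 5.5, 7.0, 8.5, 10.0], seed=3)
config = fh.RunConfig(omega0_um=0.4, z0_um=2.0, photon_mode="two-photon", seed=3)
report = fh.run_titration(config, scenario.curves)

cols = ["pH", "selected", "D1", "R_sph_A", "a_A", "b_A", "p", "slow_fraction"]
print(report.table[cols].round(3).to_string(index=False))
print(f"\nreference volume: {report.provenance['reference_volume_A3']:,.0f} ų "
      "(sphere of the fastest, most compact state)")
# D1 peaks at neutral pH; at acidic/basic pH the smaller D maps to an
# elongated prolate of the same volume, and the slow fraction (aggregates)
# grows toward the extremes.
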