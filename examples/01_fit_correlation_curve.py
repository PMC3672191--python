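"""Fit one- and two-species diffusion models to a noisy correlation curve.

Simulates a two-photon FCS curve for a 43 kDa-sized protein mixed with a
small aggregate fraction, fits both models, and applies the parsimony rule.
"""

import fcs_hydroshape as fh

beam = fh.BeamGeometry(omega0_um=0.4, z0_um=2.0, photon_mode="two-photon")
truth = fh.FcsModel(
    species=(fh.Species(D_um2_s=43.0, fraction=0.97), fh.Species(D_um2_s=14.0, fraction=0.03)),
    occupancy=10.7,
)
curve = fh.simulate_curve(truth, beam, noise_cv=0.02, lag_grid=fh.default_lag_grid(1024), seed=7)

fit1 = fh.fit_correlation(curve, 1, beam)
fit2 = fh.fit_correlation(curve, 2, beam)
choice = fh.compare_models(fit1, fit2)

print(f"one-species fit:  D = {fit1.model.species[0].D_um2_s:6.1f} µm²/s, chi2_red = {fit1.chi2_red:.2f}")
d1, d2 = fit2.model.species
print(f"two-species fit:  D1 = {d1.D_um2_s:5.1f} µm²/s (F1 = {d1.fraction:.1%}), "
      f"D2 = {d2.D_um2_s:5.1f} µm²/s, chi2_red = {fit2.chi2_red:.2f}")
print(f"selected model:   {choice.n_species} species ({choice.reason})")
# The fast component is the monomer diffusion coefficient; the few-percent
# slow component is the aggregate the two-species model is there to catch.
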