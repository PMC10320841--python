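"""Recovering intrinsic cooperativity from a noisy dilution series.

Generates a synthetic %C_bound curve (12-point dilution series, Gaussian
noise on the bound fraction), then refits alpha by least squares against the
equilibrium model.
"""

from ternaq import GridSpec, TernarySystem, fit_alpha_from_curve, generate_noisy_curve

truth = TernarySystem(k_c1=100, k_t1=1e5, alpha=200, c_tot=5, t_tot=1000)
grid = GridSpec(min=1, max=1e5, points=12)

curve = generate_noisy_curve(truth, grid, sigma=0.02, seed=42, monitor="c_bound")
print("l_tot (nM)   true fraction   observed")
for l, t, o in zip(curve.grid, curve.true_fraction, curve.observed_fraction):
    print(f"{l:>10.3g}   {t:13.3f}   {o:8.3f}")

fit = fit_alpha_from_curve(truth.k_c1, truth.k_t1, truth.c_tot, truth.t_tot,
                           curve.observed(), monitor="c_bound")
print(f"\ntrue alpha = {truth.alpha:.0f}; fitted alpha_hat = {fit.alpha_hat:.1f} "
      f"(residual norm {fit.residual_norm:.3f})")
print("With 2% noise on the bound fraction a single 12-point curve already\n"
      "constrains alpha to within a few tens of percent.")
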