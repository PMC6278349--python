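"""Linear-response-theory fit on synthetic electrostatic energy pairs.

LRT predicts that the electrostatic hydration free-energy component is a
fixed fraction of the mean solute-water electrostatic interaction energy:
dA_ES = alpha * <U_ES>, with alpha = 0.5 in theory and about 0.41 in
global empirical fits.  Here we generate 200 noisy pairs with a known
slope and recover it with the origin-constrained least-squares fit.
"""

from hydrodecomp import fit_through_origin, make_lrt_pairs

pairs = make_lrt_pairs(n=200, slope=0.41, noise_sd=0.2, seed=42)
fit = fit_through_origin(pairs)

print(f"generated 200 pairs with true slope 0.41, noise sd 0.2 kcal/mol")
print(f"recovered slope {fit.slope:.4f} (intercept fixed at 0), R^2 = {fit.r2:.4f}")
print("The fitted slope sits within sampling error of the generating 0.41,")
print("mirroring how an empirical LRT coefficient is read off component data.")
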