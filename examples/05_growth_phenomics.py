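"""Growth-curve phenomics: mu, carrying capacity, permutation tests.

Simulates two-strain plate-reader curves (20-min sampling, 24 h) with
the default physiology — reference mu 0.402 1/h reaching OD 0.265 at
24 h, mutant 0.450 1/h reaching 0.338 — estimates the parameters per
replicate, and compares the strains with a difference-in-medians
permutation test.
"""

from gemscout import curves_from_frame, simulate_growth_curves, strain_comparison

frame = simulate_growth_curves(replicates=16, noise_sd=0.02, seed=11)
curves = curves_from_frame(frame)
out = strain_comparison(curves, n=10_000, seed=0)

for key in ("mu", "od_max", "od_24h"):
    test = out["tests"][key]
    print(f"{key:7s} median diff (mutant - reference) = "
          f"{out['median_diff'][key]:+.3f}   permutation p = {test.p:.4f}")

# With noise-free curves the estimated growth-rate difference is 0.048 1/h
# and the 24-h OD difference is 0.073; multiplicative measurement noise
# blurs the per-replicate estimates but the strain separation in OD stays
# detectable at the permutation floor p = 1/n.
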