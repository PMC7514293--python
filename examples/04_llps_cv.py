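"""Quantify cell-content homogeneity by the footprint intensity CV.

Renders fluorescence-like cell images whose droplet/dilute intensity ratio
(partition ratio) emulates increasing liquid-liquid phase separation, at
fixed total intensity, and measures the coefficient of variation of the
footprint pixels. Higher partitioning -> higher CV -> lower homogeneity.
A Monte-Carlo check shows realistic imaging noise barely inflates the CV.
"""

from diffent import llps, synth

print("partition ratio -> footprint CV (total intensity conserved):")
for ratio in (1.0, 1.5, 2.0, 3.0, 4.0):
    image, mask = synth.render_llps_image(
        synth.LLPSImageSpec(partition_ratio=ratio, noise_sd=0.0, seed=5))
    res = llps.compute_cv(image, mask)
    print(f"  ratio {ratio:.1f}: cv = {res.cv:.4f} "
          f"(sum = {image.sum():.1f}, {res.n_pixels} px)")

image, mask = synth.render_llps_image(
    synth.LLPSImageSpec(partition_ratio=2.0, noise_sd=0.0, seed=5))
base = llps.compute_cv(image, mask)
impact = llps.noise_cv_impact(image, noise_sd=0.05 * base.mean_intensity,
                              n_reps=200, seed=0, mask=mask)
print(f"\nwith 5% additive noise: cv {base.cv:.4f} -> {impact.cv_observed:.4f} "
      f"(inflation {impact.inflation:.4f}; "
      f"quadrature predicts {impact.quadrature_prediction:.4f})")
print("Imaging noise adds in quadrature and is negligible next to the "
      "droplet-driven CV.")
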