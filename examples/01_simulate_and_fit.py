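"""Simulate anomalous-diffusion trajectories and recover (K_alpha, alpha).

Generates 200 fractional-Brownian-motion trajectories with a known
generalized diffusion coefficient and diffusion power, computes the
ensemble MSD over the standard 0.3–3 s lag window, and fits the power law
MSD = 2nK_alpha dt^alpha. The printed estimates should straddle the ground
truth within a few percent.
"""

import numpy as np

from diffent import synth, tracking

K_TRUE, ALPHA_TRUE = 0.02, 0.8

spec = synth.TrajectorySpec(k_alpha=K_TRUE, alpha=ALPHA_TRUE, n_steps=100,
                            dt_frame=0.3, seed=1)
pos = synth.simulate_fbm_ensemble(spec, n_reps=200)
t = np.arange(spec.n_steps) * spec.dt_frame
trajs = [tracking.Trajectory(i, t, pos[i]) for i in range(200)]

curve = tracking.compute_msd(trajs, k_max=10)
fit = tracking.fit_power_law(curve, n_dims=2)

print(f"ground truth : K_alpha = {K_TRUE}, alpha = {ALPHA_TRUE}")
print(f"fitted       : K_alpha = {fit.k_alpha:.5f} +/- {fit.k_alpha_stderr:.5f}, "
      f"alpha = {fit.alpha:.4f} +/- {fit.alpha_stderr:.4f}")
print("K_alpha is the MSD prefactor in um^2/s^alpha; alpha < 1 means the "
      "motion is sub-diffusive (hindered by the viscoelastic medium).")
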