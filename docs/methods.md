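# Methods

## Model

A tracked intracellular object (vesicle/organelle scale, 0.1–1 µm) in a
viscoelastic, actively driven medium performs anomalous diffusion:

    MSD(Δt) = 2 n K_α Δt^α,

n spatial dimensions (2 for image-plane tracking), K_α in µm²/s^α, α
dimensionless. Three assumptions connect this to thermodynamic state
functions. (1) Steady state: diffusion (sub-second) is much faster than
global cell remodeling, so equilibrium state functions extend to a
generalized entropy. (2) Gaussian translocations: each measured Δx over a
long-enough lag composes many microscopic steps, so the translocation PDF is
approximately normal with variance 2K_αΔt^α per dimension, even when the
microscopic process is anomalous. (3) Elasticity dominance: at low Reynolds
number with a dominant elastic modulus, energy changes are potential
(E ∝ Δx² under F = −KΔx), so translocations track the square root of the
total energy.

Under these, the differential entropy of the (half-)Gaussian of
translocations approximates the particle's generalized entropy and the
Gaussian normalization integral its total energy:

    S(K_α, α, Δt) = ¼ ln(4πe K_α Δt^α)        [nats]
    E(K_α, α, Δt) = 4π K_α Δt^α               [arbitrary units]

All proportionality constants are set to 1 and units are fixed to µm and s:
differential entropy is not unit-invariant, so only like-for-like
comparisons within this one unit system are meaningful. Entropy values can
be negative (ordinary for differential entropies) — only differences and
orderings carry meaning. Two exact consequences are used as internal
conservation checks: S = ¼ + ¼ ln E everywhere, and the equilibrium
(constant-energy) level sets K_α = E/(4π)·Δt^−α are exact preimages of
`total_energy`.

**Work decomposition.** At equilibrium, α is set by the elastic medium; a
power-law regression α_e = a·K_α^b fitted on equilibrium (ATP-depleted)
cells summarizes that dependence (a reference coefficient pair for such a
regression is a = 0.53, b = −0.46; the coefficients are bound to the unit
convention of the data they were fitted on, so the package always refits
them on its own depleted arm). For an active cell, the elastic share is the
law evaluated at the cell's current K_α, and the remainder is attributed to
ATP-dependent mechanical work:

    α = α_e(K_α) + α_work,     α_e(K_α) = a·K_α^b.

α_work may come out negative on noisy cells; it is flagged, never clipped.
The corresponding entropy split is defined as

    elastic = ¼ ln(2πe K_α Δt^α_e),   work = ¼ ln(2 Δt^α_work),

chosen so the two terms sum *exactly* to S(K_α, α_e+α_work, Δt) (offset 0);
the work term has a Δt-independent baseline ¼ ln 2 at α_work = 0.  The
intermediate prefactors inside the two logarithms admit more than one
algebraically consistent split; this one keeps the total entropy (the
primary definition) exact and the elastic term in the same 2πe form as a
one-dimensional Gaussian entropy.

**Homogeneity.** The liquid–liquid phase separation (LLPS) state of a
fluorescently labeled cell is proxied by CV = SD/mean of pixel intensities
in the cell footprint (population SD; at >10³ footprint pixels the
sample/population difference is negligible and the population form is
deterministic). Whole-footprint CV is used; a nuclear/other mask can be
supplied instead. Additive imaging noise inflates CV in quadrature,
CV_obs ≈ sqrt(CV² + (σ/mean)²), which is negligible at realistic noise —
`noise_cv_impact` verifies this per image by Monte Carlo.

## Measurement chain

Stacks are min–max rescaled to 8-bit (round-half-even; a constant stack maps
to zeros). Segmentation uses an inclusive gray-level *band* — DIC objects
carry dark cores and bright fringes, so an interval, not a single cut — with
Otsu on the pooled 8-bit histogram as the automatic default (foreground =
the sparser side of the cut). Components are 8-connected; components under
`min_area` = 4 px are dropped (too-narrow bands fragment objects into
isolated pixels; the floor suppresses those). Centroids are
intensity-unweighted, pixel centers at integer coordinates, origin top-left,
x = column·pixel_size; all downstream math is in µm. Over-wide bands
(>50% of pixels) are warned about, since they thicken and merge contours.
Because per-cell band choices are inherently manual, `threshold_sensitivity`
reruns the whole chain across a set of bands and reports the SD of K_α and α
as the segmentation-induced uncertainty.

Linking is greedy in global distance order (all candidate pairs within
`max_disp`, ascending distance, ties to the smaller particle id) — the
deterministic, MultiTracker-class choice; no gap closing, trajectories
under `min_len` dropped. The MSD is time-averaged over all overlapping index
pairs per trajectory, then averaged unweighted across trajectories
(weighting by trajectory length is a flagged open choice; unweighted
maximizes comparability across cells at 100-frame acquisitions). The default
lag grid is k·0.3 s, k = 1..10 — a 3 s window, long enough for the entropy
estimate to be in its logarithmic saturation regime and short enough that a
~10 µm cell does not confine the motion. Fits are nonlinear least squares of
MSD = A·Δt^α (unweighted over lags; inverse-variance weighting available),
initialized from the log-log linear regression, K_α = A/(2n); on
non-convergence the log-log estimate is returned flagged.

Paired statistics use the two-sided paired Student's t-test at p ≤ 0.05 with
no multiple-testing correction by default (matching the single-panel
practice the analysis mirrors; Benjamini–Hochberg is available behind a
flag). Regressions between positive quantities are log-log least squares
(power-law form). Couplings *to entropy* use an exponential (semi-log)
regression ln y = ln a + b·S instead, because the differential entropy can
be negative; via S = ¼ + ¼ ln E this is exactly a power law in energy with
an identical slope p-value. In the log-log CV~α_work regression, cells with
α_work ≤ 0 are excluded and counted.

## Synthetic data

The generators replace unavailable live-cell microscopy; their defaults are
the study conditions of the analyses and tests.

**Trajectories.** Anomalous diffusion with exponent α is fractional Brownian
motion with Hurst H = α/2. Increments are exact fractional Gaussian noise
from circulant embedding of the fGn covariance (Davies–Harte): the 2n-point
embedding eigenvalues are computed once per (H, n) and cached; if an
eigenvalue were materially negative the generator falls back to exact
Cholesky sampling (with tiny jitter); H = 1 (ballistic) is the degenerate
fully-correlated case, handled directly. Increments are scaled so the
per-dimension ensemble MSD at lag Δt is exactly 2K_αΔt^α — no Euler
approximation error. All randomness flows from a master seed through
`numpy.random.SeedSequence` spawning (one stream per object), so outputs are
bit-reproducible.

**Stacks.** Dark disks (radius 0.05–1.0 µm, the vesicle/organelle range) on
a light background with a 1-pixel soft edge approximating partial pixel
coverage, plus additive Gaussian noise; initial positions non-overlapping;
trajectories reflected at the frame borders so boundaries stay out of the
MSD regime. Not emulated: DIC shear/interference optics, defocus, 3-D
motion, confinement or hop diffusion. Passing tracking tests therefore
demonstrate the chain's correctness on idealized contrast, not robustness to
DIC artifacts.

**LLPS images.** A circular cell footprint containing non-overlapping bright
droplets; `partition_ratio` (≥1) is the droplet/dilute intensity ratio and
the summed footprint intensity is held at `total_intensity` regardless of
droplet count or partitioning (mass conservation under phase separation;
ratio 1 is perfectly homogeneous). Droplet centers sit on integer pixels so
the droplet pixel fraction — hence the noise-free CV — is a deterministic,
strictly increasing function of the partition ratio. Not emulated: droplet
size spectra, nucleolar substructure, out-of-focus light.

**Paired cohorts.** Defaults: 12 cells, each in both arms; 40 trajectories
per cell-condition, 100 frames at 0.3 s; evaluation lag dt_eval = 3 s;
96×96 px LLPS image per cell-condition with 1% intensity noise. A
cohort-level elastic law α_e = a₀·K^b₀ (b₀ = −0.46, anchored so
α_e(0.01) = 0.6) represents the equilibrium medium. Depleted-arm cells draw
a per-cell energy (ln-spread 0.18) and sit at the intersection of their
constant-energy curve with the elastic law, plus a residual α scatter of
0.04·ᾱ — so with zero residual the refitted regression recovers b₀
exactly, and with defaults the refit is reliably significantly negative at
n = 12. Active-arm cells draw an LLPS partition ratio pr ~ N(2.5, 0.6)
(truncated ≥1.05) and gain mechanical work
α_work = w̄ − 0.35·(pr − 2.5) + N(0, 0.03) — the programmed negative
work–LLPS coupling — with w̄ fixed by the arm means
(w̄ = ᾱ_active − α_e(K̄_active); defaults ᾱ_active = 1.0,
K̄_active = 0.03 vs depleted 0.6 and 0.01). ln K_active is centered on the
active mean with gain 2.0·(α_work − w̄) and noise 0.1 — the work-driven K
boost that creates the positive α_work–K and negative CV–K couplings —
and α_active = α_e(K_active) + α_work: elasticity evaluated at the cell's
current diffusion coefficient, which is exactly how the decomposition is
applied downstream. Depleted-arm partition ratios are independent draws, so
that arm has no CV–diffusion coupling by construction. Effect sizes were
fixed once by an a-priori power analysis at n = 12 so that each programmed
qualitative effect is recovered with high per-seed probability; a
zero-effect cohort (equal arm means, zero slope) leaves only independent
noise between arms, giving a valid null for calibration. These spreads and
couplings emulate the effect *structure* of paired active/ATP-depleted
measurements, not any particular cell line's numbers; real cohorts have
heavier tails, partial pairing and threshold-choice variability that the
generator does not reproduce.

## Numerical choices and problem sizes

- Embedding eigenvalues clipped at 0 only within −1e-8 relative tolerance;
  beyond that the Cholesky route is used.
- The depleted-arm intersection (constant-energy × elastic law) is solved by
  vectorized Newton iteration on ln K; the objective's derivative
  1 + b₀·α·lnΔt stays positive throughout the sub-diffusive regime, so the
  root is unique.
- Degenerate inputs are contracts, not crashes: constant stack → zeros;
  empty detection table → empty histogram; dt = 1 s constant-energy curve →
  flat with warning; identical paired samples → degenerate-flagged t-test;
  non-positive pairs excluded (and counted) from log-log regressions;
  <3 depleted cells → no elastic regression, α_work reported as NaN.
- Validation problem sizes (chosen to keep the default suite fast while
  leaving Monte-Carlo error well below the tested margins): fBM oracle
  grids at 4 000–8 000 replicates; parameter recovery at 200 trajectories ×
  100 frames × 20 seeds per (K, α); t-test calibration over 500 null
  cohorts; direction recovery over 100 paper-scale cohorts.

## Known limitations

- The entropy/energy scale is conventional (constants = 1): values are
  comparable only within the µm/s unit system, and the elastic-regression
  coefficients are likewise unit-bound.
- Greedy linking is near-optimal only for sparse scenes; it is exact when
  object spacing exceeds twice the search radius, and dense scenes would
  need assignment-based tracking (out of scope).
- Centroid (not PSF-fitting) localization limits K_α accuracy at very small
  displacements; the threshold-sensitivity SD is the honest error envelope.
- The active-arm generative process is a modeling choice: work enters as an
  additive exponent shift on fBM at the combined (K_α, α). Whether real
  active motion is fBM-like at the combined exponent or has a crossover
  timescale is not settled; no crossover is simulated.
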