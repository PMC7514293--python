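"""Synthetic generators for every input the pipeline consumes.

Four generators with known ground truth:

* fractional-Brownian-motion trajectories with prescribed (K_α, α),
* image stacks of segmentable dark moving disks (DIC-like fixtures),
* fluorescence images of a cell footprint with bright droplets whose
  contrast emulates a liquid–liquid phase-separated (LLPS) state,
* paired active / ATP-depleted cohorts whose ground-truth diffusion
  parameters follow the constant-energy relation in the depleted arm and
  carry added mechanical work, coupled to the LLPS state, in the active arm.

Anomalous diffusion is simulated as fractional Brownian motion with Hurst
exponent H = α/2, scaled so the per-dimension ensemble MSD at lag Δt is
exactly 2·K_α·Δt^α.  Increments are exact fractional Gaussian noise drawn by
circulant embedding of the fGn covariance (Davies–Harte), with a Cholesky
fallback when an embedding eigenvalue is materially negative; α = 2 (H = 1,
ballistic) is handled as a degenerate special case.  All randomness derives
from a master seed through ``numpy.random.SeedSequence`` spawning, so equal
seeds reproduce outputs bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from diffent.tracking import Trajectory

logger = logging.getLogger(__name__)

FOUR_PI_ = 4.0 * np.pi

_EMBED_CACHE: dict[tuple[float, int], np.ndarray] = {}
_CHOL_CACHE: dict[tuple[float, int], np.ndarray] = {}


# ---------------------------------------------------------------------------
# fractional Gaussian noise

def _fgn_covariance(hurst: float, n_lags: int) -> np.ndarray:
    k = np.arange(n_lags + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def _embedding_eigenvalues(hurst: float, n: int) -> np.ndarray | None:
    """Eigenvalues of the 2n-circulant embedding of the fGn covariance.

    Returns None when the embedding is not (numerically) nonnegative
    definite, in which case the caller falls back to Cholesky sampling.
    """
    key = (hurst, n)
    if key not in _EMBED_CACHE:
        gamma = _fgn_covariance(hurst, n)
        row = np.concatenate([gamma[:n], [gamma[n]], gamma[n - 1:0:-1]])
        lam = np.fft.fft(row).real
        if lam.min() < -1e-8 * lam.max():
            _EMBED_CACHE[key] = None  # type: ignore[assignment]
        else:
            _EMBED_CACHE[key] = np.sqrt(np.clip(lam, 0.0, None) / (2 * n))
    return _EMBED_CACHE[key]


def _cholesky_factor(hurst: float, n: int) -> np.ndarray:
    key = (hurst, n)
    if key not in _CHOL_CACHE:
        gamma = _fgn_covariance(hurst, n)[:n]
        idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        cov = gamma[idx]
        # jitter guards against borderline indefiniteness at H near 1
        _CHOL_CACHE[key] = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return _CHOL_CACHE[key]


def sample_fgn(hurst: float, n: int, size: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` series of length ``n`` of unit-variance fGn.

    The returned increments have exactly Cov(X_i, X_{i+k}) =
    ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); their cumulative sums B satisfy
    E[(B_{j+m} − B_j)²] = m^{2H}.
    """
    if not 0 < hurst <= 1:
        raise ValueError("hurst must be in (0, 1]")
    if hurst == 1.0:
        # fully correlated increments: straight-line motion
        return np.repeat(rng.standard_normal((size, 1)), n, axis=1)
    scale = _embedding_eigenvalues(hurst, n)
    if scale is not None:
        m = 2 * n
        z = rng.standard_normal((size, m)) + 1j * rng.standard_normal((size, m))
        return np.fft.fft(z * scale, axis=-1).real[:, :n]
    chol = _cholesky_factor(hurst, n)
    return rng.standard_normal((size, n)) @ chol.T


@dataclass(frozen=True)
class TrajectorySpec:
    """Ground-truth anomalous-diffusion parameters for one simulated object.

    ``k_alpha`` (µm²/s^α) and ``alpha`` ∈ (0, 2] parameterize the MSD law
    2·n_dims·K_α·Δt^α; ``n_steps`` positions are produced on a grid of
    ``dt_frame`` seconds.
    """

    k_alpha: float
    alpha: float
    n_steps: int = 100
    dt_frame: float = 0.3
    n_dims: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 2:
            raise ValueError("alpha must be in (0, 2]")
        if self.k_alpha <= 0:
            raise ValueError("k_alpha must be positive")
        if self.dt_frame <= 0:
            raise ValueError("dt_frame must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")


def _fbm_increments(spec: TrajectorySpec, size: int,
                    rng: np.random.Generator) -> np.ndarray:
    """(size, n_steps-1, n_dims) increments scaled to the target MSD law."""
    n_inc = spec.n_steps - 1
    hurst = spec.alpha / 2.0
    sigma = np.sqrt(2.0 * spec.k_alpha * spec.dt_frame ** spec.alpha)
    fgn = sample_fgn(hurst, n_inc, size * spec.n_dims, rng)
    return sigma * fgn.reshape(size, spec.n_dims, n_inc).transpose(0, 2, 1)


def simulate_fbm_trajectory(spec: TrajectorySpec,
                            rng: np.random.Generator | None = None) -> Trajectory:
    """Simulate one fBM trajectory with per-dimension MSD(Δt) = 2·K_α·Δt^α."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    inc = _fbm_increments(spec, 1, rng)[0]
    xy = np.vstack([np.zeros((1, spec.n_dims)), np.cumsum(inc, axis=0)])
    return Trajectory(particle_id=0,
                      t=np.arange(spec.n_steps) * spec.dt_frame, xy=xy)


def simulate_fbm_ensemble(spec: TrajectorySpec, n_reps: int,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Vectorized batch of ``n_reps`` trajectories, shape (n_reps, n_steps, n_dims)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    inc = _fbm_increments(spec, n_reps, rng)
    pos = np.zeros((n_reps, spec.n_steps, spec.n_dims))
    np.cumsum(inc, axis=1, out=pos[:, 1:, :])
    return pos


# ---------------------------------------------------------------------------
# trackable image stacks

@dataclass(frozen=True)
class StackSpec:
    """Geometry and noise model of a DIC-like stack of dark moving disks.

    ``objects`` pairs each :class:`TrajectorySpec` with a physical radius in
    µm (0.05–1.0, the vesicle/organelle size range) and a contrast (intensity
    dip below ``background_level``).  Trajectories are reflected at the frame
    borders so boundaries never enter the MSD regime.
    """

    height: int = 128
    width: int = 128
    pixel_size: float = 0.1
    n_frames: int = 100
    dt_frame: float = 0.3
    objects: tuple = ()          # ((TrajectorySpec, radius_um, contrast), ...)
    background_level: float = 200.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for _, radius, _ in self.objects:
            if not 0.05 <= radius <= 1.0:
                raise ValueError("object radii must lie in [0.05, 1.0] um")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by reflection at the boundaries."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def render_stack(spec: StackSpec):
    """Render a stack of dark disks on a light background.

    Returns ``(frames, trajectories)`` where ``frames`` is a float array of
    shape (n_frames, height, width) and ``trajectories`` are the ground-truth
    (possibly boundary-reflected) trajectories in µm.  Initial positions are
    drawn non-overlapping; each object's diffusion stream is spawned from the
    stack seed.
    """
    rng_streams = np.random.SeedSequence(spec.seed).spawn(len(spec.objects) + 2)
    place_rng = np.random.default_rng(rng_streams[0])
    noise_rng = np.random.default_rng(rng_streams[1])
    h_um, w_um = spec.height * spec.pixel_size, spec.width * spec.pixel_size

    # non-overlapping initial positions
    centers: list[np.ndarray] = []
    radii = [obj[1] for obj in spec.objects]
    for i, r in enumerate(radii):
        for _ in range(2000):
            c = place_rng.uniform([r, r], [w_um - r, h_um - r])
            if all(np.linalg.norm(c - c2) > r + r2
                   for c2, r2 in zip(centers, radii[:i])):
                centers.append(c)
                break
        else:
            raise RuntimeError("could not place objects without overlap")

    frames = np.full((spec.n_frames, spec.height, spec.width),
                     spec.background_level, dtype=float)
    cols_um = np.arange(spec.width) * spec.pixel_size
    rows_um = np.arange(spec.height) * spec.pixel_size
    trajectories = []
    for i, (tspec, radius, contrast) in enumerate(spec.objects):
        tspec = replace(tspec, n_steps=spec.n_frames, dt_frame=spec.dt_frame,
                        n_dims=2)
        rng = np.random.default_rng(rng_streams[2 + i])
        inc = _fbm_increments(tspec, 1, rng)[0]
        pos = centers[i] + np.vstack([np.zeros(2), np.cumsum(inc, axis=0)])
        pos[:, 0] = _reflect(pos[:, 0], radius, w_um - radius)
        pos[:, 1] = _reflect(pos[:, 1], radius, h_um - radius)
        trajectories.append(Trajectory(
            particle_id=i, t=np.arange(spec.n_frames) * spec.dt_frame, xy=pos))
        for f in range(spec.n_frames):
            dx = cols_um[None, :] - pos[f, 0]
            dy = rows_um[:, None] - pos[f, 1]
            # 1-pixel soft edge approximates partial pixel coverage
            dist = np.sqrt(dx * dx + dy * dy)
            cover = np.clip((radius + 0.5 * spec.pixel_size - dist)
                            / spec.pixel_size, 0.0, 1.0)
            frames[f] -= contrast * cover
    if spec.noise_sd > 0:
        frames += noise_rng.normal(0.0, spec.noise_sd, frames.shape)
    return frames, trajectories


# ---------------------------------------------------------------------------
# LLPS images

@dataclass(frozen=True)
class LLPSImageSpec:
    """A cell footprint with bright droplets emulating a phase-separated state.

    ``partition_ratio`` is the droplet/dilute intensity ratio (≥ 1; 1 means a
    homogeneous footprint).  The summed footprint intensity equals
    ``total_intensity`` regardless of droplet count or partitioning — mass is
    conserved under phase separation.
    """

    height: int = 96
    width: int = 96
    n_droplets: int = 6
    droplet_radius: int = 7
    partition_ratio: float = 2.0
    total_intensity: float = 1e6
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition_ratio < 1:
            raise ValueError("partition_ratio must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")


def render_llps_image(spec: LLPSImageSpec):
    """Render the footprint image and its mask.

    Returns ``(image, mask)``.  Droplet centers sit on integer pixels so the
    droplet pixel count — hence the CV — depends only on the spec geometry,
    not on placement randomness.  Placement failures after bounded retries
    raise ``RuntimeError``.
    """
    rng = np.random.default_rng(spec.seed)
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    foot_r = 0.45 * min(spec.height, spec.width)
    yy, xx = np.mgrid[0:spec.height, 0:spec.width]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= foot_r ** 2

    r = spec.droplet_radius
    centers: list[tuple[int, int]] = []
    for _ in range(spec.n_droplets):
        for _ in range(5000):
            ang = rng.uniform(0, 2 * np.pi)
            rad = (foot_r - r - 1) * np.sqrt(rng.uniform())
            py, px = int(round(cy + rad * np.sin(ang))), int(round(cx + rad * np.cos(ang)))
            if all((py - qy) ** 2 + (px - qx) ** 2 > (2 * r) ** 2
                   for qy, qx in centers):
                centers.append((py, px))
                break
        else:
            raise RuntimeError("could not place droplets without overlap")

    droplet = np.zeros_like(mask)
    for py, px in centers:
        droplet |= (yy - py) ** 2 + (xx - px) ** 2 <= r ** 2
    droplet &= mask

    n_drop = int(droplet.sum())
    n_dilute = int(mask.sum()) - n_drop
    # dilute-phase level solving I0*(n_dilute + ratio*n_drop) = total
    dilute = spec.total_intensity / (n_dilute + spec.partition_ratio * n_drop)
    image = np.zeros((spec.height, spec.width), dtype=float)
    image[mask] = dilute
    image[droplet] = dilute * spec.partition_ratio
    if spec.noise_sd > 0:
        image[mask] += rng.normal(0.0, spec.noise_sd, n_drop + n_dilute)
    return image, mask


# ---------------------------------------------------------------------------
# paired cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth effect structure of a paired active/ATP-depleted cohort.

    A cohort-level elastic law α_e(K) = a₀·K^b₀ (exponent
    ``elastic_exponent``; a₀ anchored so α_e(depleted_k_mean) =
    depleted_alpha_mean) describes the equilibrium medium.  Depleted-arm
    cells draw a per-cell energy E_i (relative ln-spread
    ``depleted_energy_sd``) and sit at the intersection of their
    constant-energy curve K = E_i/(4π)·Δt^−α with the elastic law, plus a
    small residual α scatter ``cell_noise_cv``·mean.  Active-arm cells add
    mechanical work: α_work,i = w̄ + work_cv_slope·(pr_i − p̄r) + noise,
    coupled negatively to the cell's LLPS partition ratio pr_i; ln K is
    boosted by ``k_work_gain``·(α_work − w̄) around the active mean, and
    α_active = α_e(K_active) + α_work (elasticity evaluated at the current
    diffusion coefficient).  The mean work w̄ is fixed by the arm means:
    w̄ = active_alpha_mean − α_e(active_k_mean).  A zero-effect (null)
    cohort is obtained with equal arm means and zero slope.
    """

    n_cells: int = 12
    active_k_mean: float = 0.03      # µm²/s^α
    active_alpha_mean: float = 1.0
    depleted_k_mean: float = 0.01
    depleted_alpha_mean: float = 0.6
    elastic_exponent: float = -0.46    # b0 of the cohort elastic law
    depleted_energy_sd: float = 0.18   # relative spread of ln E
    work_cv_slope: float = -0.35       # d alpha_work / d partition_ratio
    cell_noise_cv: float = 0.04        # residual alpha scatter / mean
    k_work_gain: float = 2.0           # d ln K_active / d alpha_work
    k_noise_sd: float = 0.1            # ln K_active noise
    work_noise_sd: float = 0.03
    partition_mean: float = 2.5
    partition_sd: float = 0.6
    n_traj_per_cell: int = 40
    n_frames: int = 100
    dt_frame: float = 0.3
    dt_eval: float = 3.0
    image_noise_frac: float = 0.01     # noise_sd as fraction of mean intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("need at least 3 cells")
        if (self.active_k_mean < self.depleted_k_mean
                or self.active_alpha_mean < self.depleted_alpha_mean):
            raise ValueError("active means must be >= depleted means "
                             "(paired effect direction)")
        for v in (self.active_k_mean, self.depleted_k_mean,
                  self.active_alpha_mean, self.depleted_alpha_mean):
            if v <= 0:
                raise ValueError("diffusion means must be positive")


@dataclass
class SyntheticCell:
    """One cell in one condition: trajectories, LLPS image, and ground truth."""

    cell_id: str
    condition: str               # "active" | "depleted"
    trajectories: list[Trajectory]
    image: np.ndarray | None
    mask: np.ndarray | None
    truth: dict


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    cells: list[SyntheticCell]

    def ground_truth(self) -> pd.DataFrame:
        return pd.DataFrame([{"cell_id": c.cell_id, "condition": c.condition,
                              **c.truth} for c in self.cells])


def _truncated_normal(rng, mean, sd, lo, size):
    x = rng.normal(mean, sd, size)
    while np.any(x < lo):
        bad = x < lo
        x[bad] = rng.normal(mean, sd, bad.sum())
    return x


def _elastic_a0(spec: CohortSpec) -> float:
    """Prefactor anchoring the elastic law at the depleted arm mean."""
    return spec.depleted_alpha_mean * spec.depleted_k_mean ** (-spec.elastic_exponent)


def _constant_energy_elastic_intersection(log_e: np.ndarray, a0: float,
                                          b0: float, dt: float) -> np.ndarray:
    """ln K at the crossing of K = E/(4π)·Δt^−α with α = a0·K^b0.

    Solves lnK + a0·exp(b0·lnK)·lnΔt − lnE + ln4π = 0 by Newton iteration;
    the left side is monotone in lnK whenever α < 1/(|b0|·lnΔt), which
    holds throughout the sub-diffusive regime of interest.
    """
    ln_dt = np.log(dt)
    x = log_e - np.log(FOUR_PI_)  # starting guess: alpha = 0
    for _ in range(60):
        alpha = a0 * np.exp(b0 * x)
        f = x + alpha * ln_dt - log_e + np.log(FOUR_PI_)
        fp = 1.0 + b0 * alpha * ln_dt
        step = f / fp
        x = x - step
        if np.max(np.abs(step)) < 1e-13:
            break
    return x


def generate_cohort(spec: CohortSpec, with_images: bool = True) -> SyntheticCohort:
    """Generate a paired cohort with programmed ground truth.

    Every cell appears in both arms.  Depleted-arm cells sit (up to a small
    residual α scatter) at the intersection of a per-cell constant-energy
    curve K = E_i/(4π)·Δt^−α with the cohort elastic law α_e = a₀·K^b₀, so
    refitting the law on noise-free parameters recovers b₀ exactly.
    Active-arm cells add work α_work,i coupled negatively to their LLPS
    partition ratio pr_i; ln K_active is centered on the active arm mean and
    boosted by k_work_gain·(α_work,i − w̄); α_active = α_e(K_active) +
    α_work.  Active-arm pr_i drive both α_work and the rendered image CV;
    depleted-arm partition ratios are independent draws, so no
    CV–diffusion coupling exists in that arm.
    """
    master = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(master.spawn(1)[0])
    cell_seeds = master.spawn(spec.n_cells)

    n = spec.n_cells
    dt = spec.dt_eval
    a0, b0 = _elastic_a0(spec), spec.elastic_exponent
    w_mean = spec.active_alpha_mean - a0 * spec.active_k_mean ** b0

    log_e = (np.log(FOUR_PI_ * spec.depleted_k_mean
                    * dt ** spec.depleted_alpha_mean)
             + param_rng.normal(0.0, spec.depleted_energy_sd, n))
    k_dep = np.exp(_constant_energy_elastic_intersection(log_e, a0, b0, dt))
    alpha_dep = (a0 * k_dep ** b0
                 + param_rng.normal(0.0, spec.cell_noise_cv
                                    * spec.depleted_alpha_mean, n))

    pr_act = _truncated_normal(param_rng, spec.partition_mean,
                               spec.partition_sd, 1.05, n)
    pr_dep = _truncated_normal(param_rng, spec.partition_mean,
                               spec.partition_sd, 1.05, n)
    alpha_work = (w_mean + spec.work_cv_slope * (pr_act - spec.partition_mean)
                  + param_rng.normal(0.0, spec.work_noise_sd, n))
    if w_mean > 0:
        alpha_work = np.maximum(alpha_work, 0.05)
    k_act = (spec.active_k_mean
             * np.exp(spec.k_work_gain * (alpha_work - w_mean))
             * np.exp(param_rng.normal(0.0, spec.k_noise_sd, n)))
    alpha_act = (a0 * k_act ** b0 + alpha_work
                 + param_rng.normal(0.0, spec.cell_noise_cv
                                    * spec.depleted_alpha_mean, n))

    cells: list[SyntheticCell] = []
    for i in range(n):
        streams = cell_seeds[i].spawn(4)
        for cond, k, a, aw, pr, s_traj, s_img in (
                ("active", k_act[i], alpha_act[i], alpha_work[i], pr_act[i],
                 streams[0], streams[1]),
                ("depleted", k_dep[i], alpha_dep[i], 0.0, pr_dep[i],
                 streams[2], streams[3])):
            a = float(np.clip(a, 0.05, 2.0))
            tspec = TrajectorySpec(k_alpha=float(k), alpha=a,
                                   n_steps=spec.n_frames,
                                   dt_frame=spec.dt_frame)
            pos = simulate_fbm_ensemble(tspec, spec.n_traj_per_cell,
                                        np.random.default_rng(s_traj))
            t = np.arange(spec.n_frames) * spec.dt_frame
            trajs = [Trajectory(j, t, pos[j]) for j in range(spec.n_traj_per_cell)]
            image = mask = None
            if with_images:
                img_seed = int(np.random.default_rng(s_img).integers(2 ** 31))
                ispec = LLPSImageSpec(partition_ratio=float(pr), seed=img_seed)
                mean_level = ispec.total_intensity / (np.pi * (0.45 * 96) ** 2)
                ispec = replace(ispec,
                                noise_sd=spec.image_noise_frac * mean_level)
                image, mask = render_llps_image(ispec)
            cells.append(SyntheticCell(
                cell_id=f"cell{i:02d}", condition=cond, trajectories=trajs,
                image=image, mask=mask,
                truth={"k_alpha": float(k), "alpha": a,
                       "alpha_work": float(aw), "partition_ratio": float(pr),
                       "energy": float(4 * np.pi * k * dt ** a)}))
    return SyntheticCohort(spec=spec, cells=cells)
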