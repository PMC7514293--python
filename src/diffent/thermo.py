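"""Generalized entropy and total energy of a diffusing intracellular particle.

Repeated translocations Δx of a particle over a time lag Δt distribute
approximately normally with variance 2·K_α·Δt^α.  In an elasticity-dominated
medium Δx tracks the square root of the particle's total energy, so the
Gaussian differential entropy of the translocations approximates the
particle's generalized entropy and the Gaussian normalization integral its
total energy:

    S(K_α, α, Δt)  =  ¼ ln(4πe · K_α · Δt^α)           (nats)
    E(K_α, α, Δt)  =  4π · K_α · Δt^α                  (arbitrary units)

with all proportionality constants fixed at 1 and units fixed to µm and s
(differential entropy is not unit-invariant, so only like-for-like
comparisons in this one unit system are meaningful).  These conventions make
the identity S = ¼ + ¼ ln E exact, and the equilibrium (constant-energy)
level sets K_α = E/(4π)·Δt^−α trace the negative K_α–α relation expected of
ATP-depleted cells.  The diffusion exponent of an active cell decomposes as
α = α_e + α_work, where the elastic component α_e is predicted from K_α by a
power-law regression fitted on ATP-depleted cells (reference coefficients
α_e = 0.53·K_α^−0.46) and α_work is the remainder attributable to
ATP-dependent mechanical work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from diffent.tracking import DiffusionFit

logger = logging.getLogger(__name__)

FOUR_PI = 4.0 * np.pi


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise ValueError(f"{name} must be positive")


def gaussian_entropy(sigma2):
    """Differential entropy ½·ln(2πe·σ²) of a Gaussian with variance σ², in nats."""
    _check_positive(sigma2=sigma2)
    return 0.5 * np.log(2.0 * np.pi * np.e * np.asarray(sigma2, float))


def particle_entropy(k_alpha, alpha, dt):
    """Generalized particle entropy ¼·ln(4πe·K_α·Δt^α), in nats.

    Logarithmic (increasing, saturating) in Δt, so a finite experimental
    window already approximates the long-lag entropy well.
    """
    _check_positive(k_alpha=k_alpha, dt=dt)
    k_alpha, alpha, dt = (np.asarray(v, float) for v in (k_alpha, alpha, dt))
    return 0.25 * np.log(FOUR_PI * np.e * k_alpha * dt ** alpha)


def total_energy(k_alpha, alpha, dt):
    """Average total energy 4π·K_α·Δt^α in arbitrary units (constant = 1)."""
    _check_positive(k_alpha=k_alpha, dt=dt)
    k_alpha, alpha, dt = (np.asarray(v, float) for v in (k_alpha, alpha, dt))
    return FOUR_PI * k_alpha * dt ** alpha


def constant_energy_curve(energy, dt, alphas):
    """K_α along the constant-energy level set: K_α = E/(4π)·Δt^−α.

    Strictly decreasing in α for Δt > 1; its slope is
    ∂K_α/∂α = −E·Δt^−α·ln(Δt)/(4π).  At Δt = 1 the curve is constant in α
    (Δt^−α ≡ 1), which is reported with a warning.
    """
    _check_positive(energy=energy, dt=dt)
    if dt == 1:
        logger.warning("dt = 1 s: constant-energy curve is flat in alpha")
    alphas = np.asarray(alphas, float)
    return energy / FOUR_PI * dt ** (-alphas)


@dataclass
class ElasticRegression:
    """Power-law model α_e = a·K_α^b fitted on ATP-depleted cells.

    ``b`` is expected negative for equilibrium (constant-energy) data; this
    is reported, not enforced.  The coefficients are bound to the unit
    system of the K_α values they were fitted on.
    """

    a: float
    b: float
    p_value: float = float("nan")
    n: int = 0
    stderr_b: float = float("nan")

    def predict(self, k_alpha):
        """Elastic diffusion exponent α_e at the given K_α."""
        return self.a * np.asarray(k_alpha, float) ** self.b


def fit_elastic_regression(k_alpha, alpha) -> ElasticRegression:
    """Least-squares fit of ln α = ln a + b·ln K_α on depleted-arm cells.

    Requires at least 3 strictly positive (K_α, α) pairs; returns the
    coefficients with the two-sided p-value for the slope b.
    """
    k_alpha = np.asarray(k_alpha, float)
    alpha = np.asarray(alpha, float)
    if k_alpha.size != alpha.size:
        raise ValueError("k_alpha and alpha must have equal length")
    if k_alpha.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(k_alpha <= 0) or np.any(alpha <= 0):
        raise ValueError("all values must be positive")
    res = stats.linregress(np.log(k_alpha), np.log(alpha))
    return ElasticRegression(a=float(np.exp(res.intercept)),
                             b=float(res.slope),
                             p_value=float(res.pvalue), n=int(k_alpha.size),
                             stderr_b=float(res.stderr))


def decompose_alpha(fit: DiffusionFit | tuple[float, float],
                    reg: ElasticRegression) -> tuple[float, float]:
    """Split a fitted α into (α_e, α_work) using the elastic regression.

    α_e = a·K_α^b is the exponent the cell would show at equilibrium given
    its K_α; α_work = α − α_e is the excess attributed to mechanical work.
    A negative α_work is flagged in the log but returned unclipped.
    """
    if isinstance(fit, DiffusionFit):
        k_alpha, alpha = fit.k_alpha, fit.alpha
    else:
        k_alpha, alpha = fit
    _check_positive(k_alpha=k_alpha)
    alpha_e = float(reg.predict(k_alpha))
    alpha_work = float(alpha - alpha_e)
    if alpha_work < 0:
        logger.info("negative alpha_work (%.3g) at k_alpha=%.3g", alpha_work,
                    k_alpha)
    return alpha_e, alpha_work


def entropy_decomposition(k_alpha, alpha_e, alpha_work, dt):
    """Elastic and work contributions to the particle entropy.

        elastic = ¼ ln(2πe · K_α · Δt^α_e)
        work    = ¼ ln(2 · Δt^α_work)

    The two terms sum exactly to ``particle_entropy(K_α, α_e + α_work, Δt)``
    (offset 0 by construction).  With no work the work term reduces to its
    Δt-independent baseline ¼·ln 2; for Δt > 1 the work term is strictly
    increasing in α_work.
    """
    _check_positive(k_alpha=k_alpha, dt=dt)
    k_alpha, dt = np.asarray(k_alpha, float), np.asarray(dt, float)
    alpha_e = np.asarray(alpha_e, float)
    alpha_work = np.asarray(alpha_work, float)
    elastic = 0.25 * np.log(2.0 * np.pi * np.e * k_alpha * dt ** alpha_e)
    work = 0.25 * np.log(2.0 * dt ** alpha_work)
    return elastic, work


@dataclass
class ThermoState:
    """Entropy/energy state of one cell at the evaluation lag ``dt_eval``.

    Satisfies entropy = ¼ + ¼·ln(energy) exactly, and
    alpha_e + alpha_work equals the fitted α when a decomposition was
    supplied (alpha_work is NaN otherwise).
    """

    entropy: float               # nats (µm/s unit system)
    energy: float                # arbitrary units
    alpha_e: float
    alpha_work: float
    dt_eval: float

    def to_dict(self) -> dict:
        return {"entropy_nats": self.entropy, "energy_au": self.energy,
                "alpha_e": self.alpha_e, "alpha_work": self.alpha_work,
                "dt_eval_s": self.dt_eval}


def thermo_state(k_alpha: float, alpha: float, dt: float = 3.0,
                 reg: ElasticRegression | None = None) -> ThermoState:
    """Map fitted (K_α, α) to a :class:`ThermoState` at lag ``dt``.

    The default evaluation lag is the maximal measured lag of the standard
    acquisition window (3 s): the lag must be long enough to cover the
    particle's accessible translocations, and entropy grows only
    logarithmically beyond it.
    """
    s = float(particle_entropy(k_alpha, alpha, dt))
    e = float(total_energy(k_alpha, alpha, dt))
    if reg is not None:
        alpha_e, alpha_work = decompose_alpha((k_alpha, alpha), reg)
    else:
        alpha_e, alpha_work = float(alpha), float("nan")
    return ThermoState(entropy=s, energy=e, alpha_e=alpha_e,
                       alpha_work=alpha_work, dt_eval=float(dt))
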