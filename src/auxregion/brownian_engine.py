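"""Individual-based (Brownian dynamics) regime.

Particles carry explicit positions inside the Brownian subdomain and are
updated with the Euler-Maruyama rule x += sqrt(2*D*dt)*xi, xi ~ N(0,1) per
coordinate, with mirror reflection at every boundary.  Reactions enacted
here are the ones that live naturally at the microscopic scale:

* first-order decay, removed per particle with exact probability
  1 - exp(-mu*dt) per step;
* zeroth-order birth, one particle placed uniformly in the subdomain with
  probability kappa2*dt*V_B per step (which must be < 1);
* second-order annihilation by the lambda-rho scheme: an unordered pair
  closer than the reaction radius rho reacts with probability P_lambda per
  step.  Pairs lying entirely inside an exclusion interval (the Brownian
  auxiliary region of the hybrid method) are skipped here -- the coupling
  handles them as mesoscopic events.

``compute_P_lambda`` calibrates P_lambda against the macroscopic rate
constant by direct stochastic simulation of the two-particle (relative
coordinate) problem, so the calibration is valid even when the per-step RMS
displacement is comparable to rho, where closed-form Smoluchowski-type
inversions lose accuracy.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "ParticleEnsemble",
    "diffuse",
    "count_in",
    "first_order_decay",
    "zeroth_order_birth",
    "lambda_rho_step",
    "compute_P_lambda",
    "reflect",
]

logger = logging.getLogger(__name__)


@dataclass
class ParticleEnsemble:
    """Explicit particle positions in the Brownian subdomain.

    ``positions`` has shape (n,) in 1-D or (n, 3) in 3-D.  ``lo`` and ``hi``
    are the per-axis closed bounds of the subdomain.
    """

    positions: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.lo = np.atleast_1d(np.asarray(self.lo, dtype=float))
        self.hi = np.atleast_1d(np.asarray(self.hi, dtype=float))
        if np.any(self.hi <= self.lo):
            raise ValueError("domain bounds must satisfy lo < hi per axis")

    @classmethod
    def _raw(cls, positions: np.ndarray, lo: np.ndarray,
             hi: np.ndarray) -> "ParticleEnsemble":
        """Internal constructor skipping validation (hot-loop path).

        Callers guarantee ``positions`` is a float array and the bounds
        are the already-validated arrays of an existing ensemble.
        """
        obj = object.__new__(cls)
        obj.positions, obj.lo, obj.hi = positions, lo, hi
        return obj

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return 1 if self.positions.ndim == 1 else self.positions.shape[1]

    @property
    def x(self) -> np.ndarray:
        """First (interface-normal) coordinate of every particle."""
        return self.positions if self.positions.ndim == 1 \
            else self.positions[:, 0]

    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble._raw(self.positions.copy(), self.lo,
                                     self.hi)


def reflect(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Mirror positions back into [lo, hi] per axis (repeatedly if needed).

    Uses the triangular-wave folding identity, which applies arbitrarily
    many reflections in one vectorised pass and always terminates.
    """
    width = hi - lo
    z = np.mod(pos - lo, 2.0 * width)
    return lo + width - np.abs(width - z)


def diffuse(ensemble: ParticleEnsemble, dt: float, D: float,
            rng: np.random.Generator) -> ParticleEnsemble:
    """Brownian update with reflective boundaries; returns a new ensemble."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if D < 0:
        raise ValueError("D must be non-negative")
    if ensemble.n == 0 or D == 0.0:
        return ensemble.copy()
    sigma = math.sqrt(2.0 * D * dt)
    if sigma > float(np.min(ensemble.hi - ensemble.lo)):
        logger.warning("RMS step %.3g exceeds domain width; dt is "
                       "physically too large", sigma)
    pos = ensemble.positions + sigma * rng.standard_normal(
        ensemble.positions.shape)
    if ensemble.positions.ndim == 1:
        pos = reflect(pos, ensemble.lo[0], ensemble.hi[0])
    else:
        pos = reflect(pos, ensemble.lo, ensemble.hi)
    return ParticleEnsemble._raw(pos, ensemble.lo, ensemble.hi)


def count_in(ensemble: ParticleEnsemble,
             region: "tuple[float, float]") -> int:
    """Number of particles with first coordinate in [lo, hi).

    The half-open convention means a particle sitting exactly on the
    interface belongs to the Brownian auxiliary region.
    """
    lo, hi = region
    x = ensemble.x
    return int(np.count_nonzero((x >= lo) & (x < hi)))


def first_order_decay(ensemble: ParticleEnsemble, mu: float, dt: float,
                      rng: np.random.Generator) -> ParticleEnsemble:
    """Remove each particle independently with probability 1 - exp(-mu*dt)."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if mu == 0.0 or ensemble.n == 0:
        return ensemble.copy()
    p = -math.expm1(-mu * dt)
    keep = rng.random(ensemble.n) >= p
    return ParticleEnsemble._raw(ensemble.positions[keep], ensemble.lo,
                                 ensemble.hi)


def zeroth_order_birth(ensemble: ParticleEnsemble, kappa2: float, dt: float,
                       rng: np.random.Generator) -> ParticleEnsemble:
    """With probability kappa2*dt*V_B add one particle uniformly in the domain."""
    if kappa2 < 0:
        raise ValueError("kappa2 must be non-negative")
    if kappa2 == 0.0:
        return ensemble.copy()
    p = kappa2 * dt * ensemble.volume()
    if p >= 1.0:
        raise ValueError(
            f"kappa2*dt*V_B = {p:.3g} >= 1; decrease dt so the per-step "
            "birth probability is a valid Bernoulli parameter")
    if rng.random() >= p:
        return ensemble.copy()
    if ensemble.positions.ndim == 1:
        new = rng.uniform(ensemble.lo[0], ensemble.hi[0])
        pos = np.append(ensemble.positions, new)
    else:
        new = rng.uniform(ensemble.lo, ensemble.hi)
        pos = np.vstack([ensemble.positions, new])
    return ParticleEnsemble._raw(pos, ensemble.lo, ensemble.hi)


def lambda_rho_step(ensemble: ParticleEnsemble, rho: float, P_lambda: float,
                    rng: np.random.Generator,
                    exclusion: "tuple[float, float] | None" = None,
                    ) -> ParticleEnsemble:
    """One lambda-rho reaction sweep for 2A -> 0.

    Every unordered pair closer than ``rho`` with at least one member
    outside the exclusion interval reacts (both particles removed) with
    probability ``P_lambda``.  Pairs entirely inside the exclusion interval
    are left for the compartment-based coupling.  Pairs are visited in
    randomised order and a particle reacts at most once per step.
    """
    n = ensemble.n
    if n < 2 or P_lambda <= 0.0:
        return ensemble.copy()
    if exclusion is not None and rho >= (exclusion[1] - exclusion[0]):
        logger.warning("reaction radius rho=%.3g is not smaller than the "
                       "auxiliary width %.3g", rho,
                       exclusion[1] - exclusion[0])
    pos = ensemble.positions
    pts = pos[:, None] if pos.ndim == 1 else pos
    close = pdist(pts) < rho          # condensed upper-triangle distances
    if not close.any():
        return ensemble.copy()
    ii, jj = np.triu_indices(n, k=1)
    ii, jj = ii[close], jj[close]
    order = rng.permutation(ii.size)
    ii, jj = ii[order], jj[order]
    if exclusion is not None:
        x = ensemble.x
        inside = (x >= exclusion[0]) & (x < exclusion[1])
    removed = np.zeros(n, dtype=bool)
    for a, b in zip(ii, jj):
        if removed[a] or removed[b]:
            continue
        if exclusion is not None and inside[a] and inside[b]:
            continue
        if rng.random() < P_lambda:
            removed[a] = removed[b] = True
    if not removed.any():
        return ensemble.copy()
    return ParticleEnsemble._raw(pos[~removed], ensemble.lo, ensemble.hi)


def _measure_pair_rate(P: float, rho: float, D: float, dt: float,
                       n_walkers: int, n_steps: int,
                       seed: int) -> float:
    """Empirical well-mixed rate constant of the lambda-rho scheme.

    Simulates the relative coordinate of a reactant pair (diffusivity 2*D)
    in a periodic unit-free cube, killing in-range walkers with probability
    ``P`` per step and resurrecting them uniformly so the ensemble stays
    stationary.  The long-run event rate per walker times the box volume is
    the effective bimolecular rate constant.
    """
    rng = np.random.default_rng(seed)
    side = max(10.0 * rho, 6.0 * math.sqrt(4.0 * D * dt))
    half = side / 2.0
    y = rng.uniform(-half, half, size=(n_walkers, 3))
    sigma = math.sqrt(2.0 * (2.0 * D) * dt)
    events = 0
    burn = n_steps // 10
    counted_steps = 0
    for step in range(n_steps):
        y += sigma * rng.standard_normal((n_walkers, 3))
        y = (y + half) % side - half          # periodic minimum image
        in_range = np.einsum("ij,ij->i", y, y) < rho * rho
        hits = np.nonzero(in_range)[0]
        if hits.size:
            fire = hits[rng.random(hits.size) < P]
            if fire.size:
                if step >= burn:
                    events += fire.size
                y[fire] = rng.uniform(-half, half, size=(fire.size, 3))
        if step >= burn:
            counted_steps += 1
    return events * side**3 / (n_walkers * counted_steps * dt)


@functools.lru_cache(maxsize=32)
def compute_P_lambda(kappa1: float, rho: float, D: float, dt: float,
                     rel_tol: float = 0.01, n_walkers: int = 4000,
                     n_steps: int = 22000) -> float:
    """Per-step pair-reaction probability matching the macroscopic rate.

    Calibrated so that a well-mixed 2A -> 0 system stepped with the
    lambda-rho scheme decays with rate constant ``kappa1`` (per-pair
    propensity kappa1/V).  The starting point is the ballistic estimate
    P = kappa1*dt / (4/3 pi rho^3); a fixed-point iteration against the
    simulated rate (common random numbers, deterministic internal seeding)
    corrects for rebinding and finite-step effects to ``rel_tol`` relative
    accuracy.  The result is cached per parameter set so the hybrid and the
    fully microscopic reference share the identical calibration.
    """
    for name, v in [("kappa1", kappa1), ("rho", rho), ("D", D), ("dt", dt)]:
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if kappa1 == 0.0:
        return 0.0
    if rho <= 0 or D <= 0 or dt <= 0:
        raise ValueError("rho, D and dt must be positive when kappa1 > 0")
    v_rho = 4.0 / 3.0 * math.pi * rho**3
    P = min(0.9, kappa1 * dt / v_rho)
    for it in range(8):
        rate = _measure_pair_rate(P, rho, D, dt, n_walkers, n_steps,
                                  seed=987_654_321 + it)
        if abs(rate - kappa1) <= rel_tol * kappa1:
            return float(P)
        P = min(0.999, P * kappa1 / rate)
        if P >= 0.999:
            raise ValueError(
                "lambda-rho calibration failed: kappa1 too large for the "
                "given rho, D, dt (reaction probability saturates)")
    # final check with an independent stream
    rate = _measure_pair_rate(P, rho, D, dt, n_walkers, n_steps, seed=13)
    if abs(rate - kappa1) > 3.0 * rel_tol * kappa1:
        raise ValueError("lambda-rho calibration did not converge")
    return float(P)
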