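"""Ground-truth references the hybrid method is validated against.

For reaction networks of order <= 1 the mean-field PDE equals the expected
density of the individual-based model exactly, so:

* pure diffusion on an interval with zero-flux walls has a cosine-series
  solution (``meanfield_diffusion``), truncated adaptively so the
  neglected tail is below 1e-10;
* the morphogen-gradient problem (boundary influx D*lambda, uniform decay
  mu) is solved on a fine reference grid with a banded theta-method march
  (``meanfield_morphogen``) -- a numerically independent path from the
  hybrid's dense propagator.

For the second-order system the mean-field PDE requires a moment closure
(Poisson: Var(A) = E[A]), which introduces its own bias, so the reference
is instead the fully individual-based simulation of the whole cuboid
(``full_microscopic_tp4``), sharing the identical lambda-rho calibration
with the hybrid so that only the coupling is under test.

``two_box_mean`` is the closed-form mean occupancy of the isolated
two-compartment jump process, M_P(t) = (nu0 - (nu0 - 2 mu_P) e^(-2dt))/2,
used to check the ARM's degenerate limit when the synchronous updates are
disabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_banded

from .brownian_engine import (ParticleEnsemble, compute_P_lambda, diffuse,
                              lambda_rho_step, zeroth_order_birth)
from .config import SimulationConfig

__all__ = [
    "meanfield_diffusion",
    "meanfield_region_mass",
    "meanfield_binned",
    "meanfield_morphogen",
    "morphogen_binned",
    "moment_closure_reduce",
    "ReducedKinetics",
    "full_microscopic_tp4",
    "MicroTrajectory",
    "two_box_mean",
]

_TAIL_TOL = 1e-10


def _series_terms(p0_spec: str, N: float, domain, split, D: float,
                  t: float):
    """Cosine-series coefficients b_m and decay rates for the diffusion IC.

    The series is p(x,t) = N/L + sum_m b_m cos(m pi (x-lo)/L) exp(-lam_m t)
    with lam_m = D (m pi / L)^2.  The truncation order is chosen from the
    Gaussian tail bound so the neglected remainder is below ``_TAIL_TOL``
    in absolute density units.
    """
    lo, hi = domain
    L = hi - lo
    if t <= 0:
        raise ValueError("series evaluation requires t > 0")
    arg = max((N + 1.0) / _TAIL_TOL, math.e)
    m_max = int(math.ceil(L / math.pi * math.sqrt(math.log(arg) / (D * t))))
    m = np.arange(1, max(m_max, 8) + 1, dtype=float)
    if p0_spec == "uniform":
        b = np.zeros_like(m)
    elif p0_spec == "left_step":
        w = (split if split is not None else (lo + hi) / 2.0) - lo
        b = (2.0 * N / (w * L)) * (L / (m * np.pi)) * np.sin(
            m * np.pi * w / L)
    elif p0_spec == "linear_ramp":
        a = 2.0 * N / L**2
        b = 2.0 * a * L * (1.0 - (-1.0) ** m) / (m**2 * np.pi**2)
    else:
        raise ValueError(f"unknown initial profile {p0_spec!r}")
    lam = D * (m * np.pi / L) ** 2
    return m, b * np.exp(-lam * t), L, lo


def _ic_density(p0_spec: str, N: float, domain, split,
                x: np.ndarray) -> np.ndarray:
    lo, hi = domain
    L = hi - lo
    if p0_spec == "uniform":
        return np.full_like(x, N / L, dtype=float)
    if p0_spec == "left_step":
        s = split if split is not None else (lo + hi) / 2.0
        return np.where(x < s, N / (s - lo), 0.0)
    if p0_spec == "linear_ramp":
        a = 2.0 * N / L**2
        return a * (hi - np.asarray(x, dtype=float))
    raise ValueError(f"unknown initial profile {p0_spec!r}")


def meanfield_diffusion(p0_spec: str, N: float, D: float, t: float,
                        x_grid: np.ndarray, domain=(-1.0, 1.0),
                        split: Optional[float] = None) -> np.ndarray:
    """Mean-field diffusion density on a zero-flux interval.

    ``p0_spec`` selects the initial profile: ``uniform`` (N/L everywhere,
    the stationary solution), ``left_step`` (all mass uniform left of
    ``split``) or ``linear_ramp`` (density proportional to hi - x).
    """
    x = np.asarray(x_grid, dtype=float)
    if t == 0.0:
        return _ic_density(p0_spec, N, domain, split, x)
    m, bt, L, lo = _series_terms(p0_spec, N, domain, split, D, t)
    if not np.any(bt):
        return np.full_like(x, N / L)
    phases = np.cos(np.outer(x - lo, m) * (np.pi / L))
    return N / L + phases @ bt


def meanfield_region_mass(p0_spec: str, N: float, D: float, t: float,
                          interval, domain=(-1.0, 1.0),
                          split: Optional[float] = None) -> float:
    """Exact integral of the mean-field density over ``interval``."""
    a, b = interval
    lo, hi = domain
    L = hi - lo
    if t == 0.0:
        # integrate the piecewise-linear IC exactly on a fine grid
        xs = np.linspace(a, b, 4001)
        vals = _ic_density(p0_spec, N, domain, split, xs)
        return float(np.trapezoid(vals, xs))
    m, bt, L, lo = _series_terms(p0_spec, N, domain, split, D, t)
    base = N * (b - a) / L
    if not np.any(bt):
        return base
    k = m * np.pi / L
    contrib = bt / k * (np.sin(k * (b - lo)) - np.sin(k * (a - lo)))
    return float(base + contrib.sum())


def meanfield_binned(p0_spec: str, N: float, D: float, t: float,
                     edges: np.ndarray, domain=(-1.0, 1.0),
                     split: Optional[float] = None) -> np.ndarray:
    """Mean-field mass in each bin of the common comparison mesh."""
    return np.array([
        meanfield_region_mass(p0_spec, N, D, t, (edges[i], edges[i + 1]),
                              domain, split)
        for i in range(len(edges) - 1)])


# ----------------------------------------------------------------------
# morphogen gradient reference (fine-grid banded theta march)


def _march_theta_banded(c0: np.ndarray, h: float, dt: float, n_steps: int,
                        D: float, mu: float, flux_lambda: float,
                        theta: float) -> np.ndarray:
    """theta-method march with a banded solve; boundary influx D*lambda.

    Independent of the dense pre-factorised propagator used by the hybrid
    engine, which makes it a genuine cross-check at shared parameters.
    """
    n = c0.size
    r = D * dt / h**2
    main = np.full(n, 2.0 * r)
    main[0] = main[-1] = r
    upper = np.full(n, -r)
    lower = np.full(n, -r)
    ab = np.zeros((3, n))
    ab[0, 1:] = theta * upper[:-1]
    ab[1] = 1.0 + theta * (main + mu * dt)
    ab[2, :-1] = theta * lower[1:]
    influx = np.zeros(n)
    influx[0] = D * flux_lambda * dt / h
    c = c0.astype(float).copy()
    one_minus = 1.0 - theta
    for _ in range(n_steps):
        rhs = c - one_minus * (main * c + mu * dt * c)
        rhs[:-1] -= one_minus * upper[:-1] * c[1:]
        rhs[1:] -= one_minus * lower[1:] * c[:-1]
        rhs += influx
        c = solve_banded((1, 1), ab, rhs)
    return c


def meanfield_morphogen(lambda_: float, mu: float, D: float, t: float,
                        x_grid: Optional[np.ndarray] = None,
                        domain=(-1.0, 1.0), N: float = 500.0,
                        h: float = 1e-3, dt: Optional[float] = None,
                        theta: Optional[float] = None):
    """Whole-domain mean-field morphogen profile at time ``t``.

    Solves dp/dt = D p'' - mu p with gradient -lambda at the left wall
    (influx rate D*lambda) and zero flux at the right wall from a uniform
    initial condition, on a cell-centred grid of spacing ``h``.  Returns
    ``(x_centers, density)`` when ``x_grid`` is None, else the density
    interpolated onto ``x_grid``.
    """
    lo, hi = domain
    L = hi - lo
    n = round(L / h)
    centers = lo + (np.arange(n) + 0.5) * h
    c = np.full(n, N / L)
    if t > 0:
        if dt is None:
            dt = 0.02 if t <= 400 else t / 20000
        if theta is None:
            # Crank-Nicolson for smooth short runs; damped theta when the
            # step is large relative to the stiff modes
            theta = 0.5 if D * dt / h**2 < 50 else 0.51
        n_steps = max(1, round(t / dt))
        c = _march_theta_banded(c, h, t / n_steps, n_steps, D, mu,
                                lambda_, theta)
    if x_grid is None:
        return centers, c
    return np.interp(np.asarray(x_grid, dtype=float), centers, c)


def morphogen_profiles(lambda_: float, mu: float, D: float,
                       times: np.ndarray, domain=(-1.0, 1.0),
                       N: float = 500.0, h: float = 1e-3,
                       dt: float = 0.02, theta: float = 0.5):
    """March the morphogen reference once, capturing several times.

    ``times`` must be (near-)multiples of ``dt``.  Returns
    ``(centers, profiles)`` with ``profiles[i]`` the density at
    ``times[i]``; far cheaper than one march per requested time.
    """
    lo, hi = domain
    L = hi - lo
    n = round(L / h)
    centers = lo + (np.arange(n) + 0.5) * h
    times = np.asarray(times, dtype=float)
    steps = np.round(times / dt).astype(int)
    if not np.allclose(steps * dt, times, atol=1e-9):
        raise ValueError("capture times must be multiples of dt")
    c = np.full(n, N / L)
    profiles = np.empty((times.size, n))
    order = np.argsort(steps)
    done = 0
    for idx in order:
        target = steps[idx]
        if target > done:
            c = _march_theta_banded(c, h, dt, target - done, D, mu,
                                    lambda_, theta)
            done = target
        profiles[idx] = c
    return centers, profiles


def morphogen_binned(lambda_: float, mu: float, D: float, t: float,
                     edges: np.ndarray, domain=(-1.0, 1.0),
                     N: float = 500.0, h: float = 1e-3) -> np.ndarray:
    """Morphogen reference mass per bin (fine cells summed into bins)."""
    centers, c = meanfield_morphogen(lambda_, mu, D, t, domain=domain,
                                     N=N, h=h)
    idx = np.clip(np.searchsorted(edges, centers, side="right") - 1,
                  0, len(edges) - 2)
    out = np.zeros(len(edges) - 1)
    np.add.at(out, idx, c * h)
    return out


# ----------------------------------------------------------------------
# second-order system: moment-closure reduction and microscopic reference


@dataclass(frozen=True)
class ReducedKinetics:
    """Reduced 1-D reaction operator for 2A->0 / 0->A kinetics.

    After Poisson moment closure the 3-D mean equation becomes
    dc/dt = D lap c - kappa1 c^2 + kappa2; folding a translationally
    invariant cross-section Ly x Lz gives the operator on the reduced
    density C(x) = Ly*Lz*c:  f(C) = kappa2*Ly*Lz - kappa1*C^2/(Ly*Lz).
    """

    kappa1: float
    kappa2: float
    Ly: float
    Lz: float

    @property
    def area(self) -> float:
        return self.Ly * self.Lz

    def f(self, c_bar: np.ndarray) -> np.ndarray:
        return self.kappa2 * self.area - self.kappa1 * c_bar**2 / self.area

    @property
    def fixed_point(self) -> float:
        """Well-mixed reduced density where production balances decay."""
        if self.kappa1 <= 0:
            raise ValueError("fixed point requires kappa1 > 0")
        return self.area * math.sqrt(self.kappa2 / self.kappa1)


def moment_closure_reduce(kappa1: float, kappa2: float, Ly: float,
                          Lz: float) -> ReducedKinetics:
    """Coefficients of the closed 1-D PDE for the second-order system."""
    if Ly <= 0 or Lz <= 0:
        raise ValueError("cross-section dimensions must be positive")
    return ReducedKinetics(kappa1, kappa2, Ly, Lz)


@dataclass
class MicroTrajectory:
    """Summaries of one fully individual-based realization."""

    t: np.ndarray
    n_particles: np.ndarray
    bin_edges: np.ndarray
    binned: np.ndarray
    seed: int


def full_microscopic_tp4(cfg: SimulationConfig, seed: int = 0,
                         p_lambda: Optional[float] = None) -> MicroTrajectory:
    """Simulate the whole cuboid with Brownian dynamics only.

    No interface and no auxiliary exclusion: lambda-rho pair reactions act
    everywhere and zeroth-order births fire with probability
    kappa2*dt*V.  Shares ``compute_P_lambda`` with the hybrid, so the two
    arms differ only in the coupling.
    """
    cfg = cfg.validate()
    rng = np.random.default_rng(seed)
    if cfg.cross_section is None:
        lo = np.array([cfg.x_lo])
        hi = np.array([cfg.x_hi])
    else:
        lo = np.array([cfg.x_lo, 0.0, 0.0])
        hi = np.array([cfg.x_hi, cfg.Ly, cfg.Lz])
    L = cfg.domain_length
    # initial particles from the configured profile
    u = rng.random(cfg.N)
    if cfg.ic == "ramp":
        xs = cfg.x_hi - L * np.sqrt(1.0 - u)
    elif cfg.ic == "uniform":
        xs = cfg.x_lo + L * u
    elif cfg.ic == "all_pde":
        xs = cfg.x_lo + (cfg.interface - cfg.x_lo) * u
    else:
        raise ValueError(f"unsupported microscopic IC {cfg.ic!r}")
    if lo.size == 1:
        pos = xs
    else:
        pos = np.column_stack([xs, rng.uniform(0, cfg.Ly, cfg.N),
                               rng.uniform(0, cfg.Lz, cfg.N)])
    ens = ParticleEnsemble(pos, lo, hi)

    if p_lambda is None:
        p_lambda = (compute_P_lambda(cfg.kappa1, cfg.rho, cfg.D, cfg.dt)
                    if cfg.kappa1 > 0 else 0.0)
    kappa2_cap = cfg.kappa2 * cfg.dt * ens.volume()
    if kappa2_cap >= 1.0:
        raise ValueError("kappa2*dt*V >= 1 in the microscopic reference")

    n_bins = round(L / cfg.h_a)
    edges = cfg.x_lo + np.arange(n_bins + 1) * cfg.h_a
    n_steps = round(cfg.t_end / cfg.dt)
    rec_every = max(1, round(cfg.record_dt / cfg.dt))
    ts, totals, rows = [0.0], [ens.n], [np.histogram(ens.x, edges)[0]]
    for step in range(n_steps):
        ens = diffuse(ens, cfg.dt, cfg.D, rng)
        if cfg.kappa1 > 0 and p_lambda > 0 and ens.n > 1:
            ens = lambda_rho_step(ens, cfg.rho, p_lambda, rng)
        if cfg.kappa2 > 0:
            ens = zeroth_order_birth(ens, cfg.kappa2, cfg.dt, rng)
        if (step + 1) % rec_every == 0 or step + 1 == n_steps:
            ts.append((step + 1) * cfg.dt)
            totals.append(ens.n)
            rows.append(np.histogram(ens.x, edges)[0])
    return MicroTrajectory(np.array(ts), np.array(totals, dtype=float),
                           edges, np.array(rows, dtype=float), seed)


def two_box_mean(nu0: float, mu_P: float, d: float, t) -> np.ndarray:
    """Mean PDE-box occupancy of the isolated two-compartment jump process.

    M_P(t) = (nu0 - (nu0 - 2 mu_P) exp(-2 d t)) / 2; M_B = nu0 - M_P.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    if not 0 <= mu_P <= nu0:
        raise ValueError("need 0 <= mu_P <= nu0")
    t = np.asarray(t, dtype=float)
    out = 0.5 * (nu0 - (nu0 - 2.0 * mu_P) * np.exp(-2.0 * d * t))
    return out if out.ndim else float(out)
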