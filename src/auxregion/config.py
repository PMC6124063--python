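"""Simulation configuration containers.

A :class:`SimulationConfig` fully specifies one hybrid experiment: geometry
(1-D interval, or 3-D cuboid reduced to a 1-D slab problem through a
translationally invariant cross-section), the synchronous time step shared
by the PDE and Brownian updates, the auxiliary-region width, the reaction
network parameters and the initial condition.  All experiment definitions
(`experiments_cli.make_test_problem`) produce one of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = ["AdaptiveConfig", "SimulationConfig"]


@dataclass(frozen=True)
class AdaptiveConfig:
    """Thresholds for adaptive interface motion.

    The interface moves one auxiliary width toward the PDE subdomain when
    the PDE auxiliary occupancy drops below ``beta_l`` and toward the
    Brownian subdomain when the Brownian auxiliary occupancy exceeds
    ``beta_u``.  Requiring ``beta_u > beta_l`` provides hysteresis that
    prevents the interface from oscillating between two positions.
    """

    beta_u: float
    beta_l: float

    def __post_init__(self) -> None:
        if not self.beta_u > self.beta_l:
            raise ValueError("beta_u must exceed beta_l (hysteresis)")


@dataclass
class SimulationConfig:
    """Full specification of one hybrid (or reference) simulation."""

    # geometry: whole domain (x_lo, x_hi); PDE on the left of the interface
    x_lo: float = -1.0
    x_hi: float = 1.0
    interface: float = 0.0
    #: (Ly, Lz) cross-section for 3-D slab problems; None means 1-D
    cross_section: Optional[tuple] = None

    # discretisation
    dt: float = 0.02
    t_end: float = 100.0
    h_a: float = 0.05
    h_p: float = 0.01
    theta: float = 0.51

    # physics
    D: float = 0.0025
    N: int = 500
    ic: str = "uniform"          # uniform | all_pde | ramp | custom
    ic_pde_values: Optional[np.ndarray] = None
    ic_particles: Optional[np.ndarray] = None
    #: uniform IC only: draw the particle count as Binomial(N, |Omega_B|/L)
    #: instead of the deterministic expected split
    ic_binomial_split: bool = False

    # reactions
    mu: float = 0.0              # first-order decay A -> 0
    flux_lambda: float = 0.0     # left-boundary influx gradient (rate D*lambda)
    kappa1: float = 0.0          # 2A -> 0
    kappa2: float = 0.0          # 0 -> A (per volume per time)
    rho: float = 0.0             # lambda-rho reaction radius
    P_lambda: Optional[float] = None   # override; None -> calibrate

    # interface motion
    adaptive: Optional[AdaptiveConfig] = None

    # bookkeeping
    record_dt: float = 1.0
    record_bins: bool = True
    snapshot_times: tuple = ()
    #: disable the synchronous PDE / Brownian updates (degenerate two-box mode)
    pde_update: bool = True
    brownian_update: bool = True

    # repeats
    S: int = 1
    base_seed: int = 0

    # ------------------------------------------------------------------
    @property
    def Ly(self) -> float:
        return 1.0 if self.cross_section is None else self.cross_section[0]

    @property
    def Lz(self) -> float:
        return 1.0 if self.cross_section is None else self.cross_section[1]

    @property
    def cross_area(self) -> float:
        return self.Ly * self.Lz

    @property
    def aux_volume(self) -> float:
        """Physical volume of one auxiliary compartment."""
        return self.h_a * self.cross_area

    @property
    def domain_length(self) -> float:
        return self.x_hi - self.x_lo

    def brownian_volume(self, interface: Optional[float] = None) -> float:
        i = self.interface if interface is None else interface
        return (self.x_hi - i) * self.cross_area

    def validate(self) -> "SimulationConfig":
        if not self.x_lo < self.interface < self.x_hi:
            raise ValueError("interface must lie strictly inside the domain")
        if self.dt <= 0 or self.t_end < self.dt:
            raise ValueError("need dt > 0 and t_end >= dt")
        if self.h_a <= 0 or self.h_p <= 0:
            raise ValueError("h_a and h_p must be positive")
        m = self.h_a / self.h_p
        if abs(m - round(m)) > 1e-9 * max(1.0, m):
            raise ValueError("h_a must be an integer multiple of h_p")
        w = (self.interface - self.x_lo) / self.h_p
        if abs(w - round(w)) > 1e-6 * max(1.0, w):
            raise ValueError("the PDE subdomain width must be a whole "
                             "number of grid cells")
        if self.interface - self.x_lo < self.h_a - 1e-12 or \
                self.x_hi - self.interface < self.h_a - 1e-12:
            raise ValueError("each subdomain must be at least h_a wide")
        if self.kappa2 > 0:
            p = self.kappa2 * self.dt * self.brownian_volume()
            if p >= 1.0:
                raise ValueError(
                    f"kappa2*dt*V_B = {p:.3g} >= 1 at t=0; reduce dt")
        if self.kappa1 > 0 and self.rho <= 0:
            raise ValueError("second-order kinetics need a reaction radius")
        return self

    def with_overrides(self, **kw) -> "SimulationConfig":
        if "adaptive" in kw and isinstance(kw["adaptive"], dict):
            kw["adaptive"] = AdaptiveConfig(**kw["adaptive"])
        return replace(self, **kw).validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d
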