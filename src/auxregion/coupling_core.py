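"""The auxiliary region method (ARM) coupling core.

A point interface I splits the domain into a PDE subdomain (left) and a
Brownian subdomain (right).  Two compartments of width h_a flank the
interface: the PDE auxiliary region Omega_PA = [I - h_a, I) and the
Brownian auxiliary region Omega_BA = [I, I + h_a).  Inside them, mass is
simultaneously represented in its native form (continuum density or
particles) and as well-mixed compartment counts:

* N_PA = integral of the density over Omega_PA ("pseudo-particles",
  real-valued),
* N_BA = number of Brownian particles in Omega_BA (integer).

The two compartments form a two-box reaction-diffusion master equation
whose events -- diffusive jumps across the interface at rate d = D / h_a^2
per particle, and any bimolecular reactions confined to Omega_BA -- are
sampled exactly with the Gillespie SSA.  Jump enactment converts mass
between representations: a P->B jump withdraws one particle's worth of
mass uniformly from Omega_PA and creates a particle uniformly in Omega_BA;
a B->P jump deletes a uniformly chosen particle from Omega_BA and deposits
its mass uniformly over Omega_PA.  Both directions conserve mass exactly.

``run_hybrid`` interleaves this event-driven process with the fixed-step
synchronous updates of the two regimes: SSA events are enacted (with
propensities refreshed after every event) until the putative next-event
time passes the next synchronous update, at which point the PDE is
theta-stepped, the particles are diffused and reacted microscopically,
the adaptive interface (if enabled) is checked, and the stale putative
event is discarded -- the exponential clock is memoryless, so redrawing
it after the update is statistically consistent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

from .brownian_engine import (ParticleEnsemble, count_in, diffuse,
                              first_order_decay, lambda_rho_step,
                              zeroth_order_birth, compute_P_lambda)
from .config import SimulationConfig
from .pde_engine import PDEField, ThetaStepper, deposit_uniform, region_mass

__all__ = [
    "InterfaceState",
    "ReactionChannel",
    "ReactionNetwork",
    "PropensitySet",
    "HybridTrajectory",
    "jump_rate",
    "propensities",
    "sample_waiting_time",
    "select_event",
    "enact_jump_P_to_B",
    "enact_jump_B_to_P",
    "enact_aux_reaction",
    "build_initial_state",
    "run_hybrid",
]

logger = logging.getLogger(__name__)

#: pseudo-particle clamp threshold: alpha_P is zeroed when N_PA < 1 so a
#: jump can never withdraw more mass than the auxiliary region holds.  The
#: tolerance keeps accumulated rounding in N_PA (integer-valued up to float
#: error in jump-only runs) from spuriously triggering the clamp.
_CLAMP_TOL = 1e-9


def jump_rate(D_k: float, h_a: float) -> float:
    """Per-particle interfacial jump rate d = D / h_a^2."""
    if h_a <= 0:
        raise ValueError("h_a must be positive")
    return D_k / h_a**2


@dataclass
class InterfaceState:
    """Interface position, auxiliary intervals and compartment counts."""

    I: float
    h_a: float
    d: float                      # jump rate per particle, D / h_a^2
    N_PA: float = 0.0
    N_BA: int = 0
    clamp_activations: int = 0

    @property
    def omega_PA(self) -> "tuple[float, float]":
        return (self.I - self.h_a, self.I)

    @property
    def omega_BA(self) -> "tuple[float, float]":
        return (self.I, self.I + self.h_a)

    def refresh(self, field: PDEField, ensemble: ParticleEnsemble) -> None:
        """Recompute both auxiliary counts from the live state.

        Counts are never carried across mutations: every propensity
        evaluation sees freshly integrated / counted occupancies.  When
        the PDE grid ends exactly at the interface (always true inside
        ``run_hybrid``) the integral is a direct tail-cell sum; otherwise
        it goes through the general aligned-interval primitive.
        """
        h_p = field.h_p
        vals = field.values
        if abs(field.x_lo + vals.size * h_p - self.I) < 1e-9 * max(
                1.0, abs(self.I)):
            m_a = int(self.h_a / h_p + 0.5)
            self.N_PA = float(vals[vals.size - m_a:].sum()) * h_p
        else:
            self.N_PA = region_mass(field, self.omega_PA)
        x = ensemble.positions
        if x.ndim != 1:
            x = x[:, 0]
        self.N_BA = int(np.count_nonzero((x >= self.I)
                                         & (x < self.I + self.h_a)))
        if self.N_PA < -1e-9:
            raise RuntimeError("negative auxiliary occupancy: "
                               f"N_PA={self.N_PA}")


@dataclass(frozen=True)
class ReactionChannel:
    """One reaction pathway of the network (single chemical species).

    ``n_reactants`` / ``n_products`` count the A molecules consumed and
    produced; ``order`` is the kinetic order nu; ``mesoscopic`` marks the
    channel as enacted compartment-wise inside Omega_BA by the SSA (true
    for bimolecular channels, whose cross-interface pairs would otherwise
    be ambiguous).  Zeroth- and first-order channels are enacted per-step
    in the Brownian regime and through the mean-field operator in the PDE
    regime, where the two descriptions agree exactly.
    """

    name: str
    order: int
    rate: float
    n_reactants: int
    n_products: int
    mesoscopic: bool

    def g(self, n_ba: int) -> int:
        """Combinatorial count of reactant sets among N_BA particles."""
        return math.comb(int(n_ba), self.n_reactants)


@dataclass
class ReactionNetwork:
    """Reaction channels plus the microscopic and mean-field parameters."""

    channels: "tuple[ReactionChannel, ...]" = ()
    aux_volume: float = 1.0       # h_a in 1-D, h_a * Ly * Lz in 3-D
    rho: float = 0.0
    P_lambda: float = 0.0
    f: Optional[Callable[[np.ndarray], np.ndarray]] = None

    @property
    def meso_channels(self) -> "tuple[ReactionChannel, ...]":
        return tuple(ch for ch in self.channels if ch.mesoscopic)

    @classmethod
    def from_config(cls, cfg: SimulationConfig,
                    calibrate: bool = True) -> "ReactionNetwork":
        channels = []
        if cfg.mu > 0:
            channels.append(ReactionChannel("A->0", 1, cfg.mu, 1, 0, False))
        if cfg.kappa2 > 0:
            channels.append(ReactionChannel("0->A", 0, cfg.kappa2, 0, 1,
                                            False))
        if cfg.kappa1 > 0:
            channels.append(ReactionChannel("2A->0", 2, cfg.kappa1, 2, 0,
                                            True))
        p_lam = 0.0
        if cfg.kappa1 > 0:
            if cfg.P_lambda is not None:
                p_lam = cfg.P_lambda
            elif calibrate:
                p_lam = compute_P_lambda(cfg.kappa1, cfg.rho, cfg.D, cfg.dt)
        f = None
        if cfg.kappa1 > 0 or cfg.kappa2 > 0:
            area = cfg.cross_area
            k1, k2 = cfg.kappa1, cfg.kappa2

            def f(c, _a=area, _k1=k1, _k2=k2):
                # reduced 1-D operator: birth kappa2 per volume folds to
                # kappa2*Ly*Lz per length; annihilation -kappa1*c^2/(Ly*Lz)
                return _k2 * _a - _k1 * c * c / _a

        return cls(tuple(channels), cfg.aux_volume, cfg.rho, p_lam, f)


class PropensitySet(NamedTuple):
    """Propensities of every possible SSA event, in enumeration order.

    Enumeration order is fixed (P->B jumps by species, then B->P jumps by
    species, then mesoscopic reaction channels in network order) so that
    trajectories are bit-reproducible under a fixed seed.
    """

    alpha_P: "tuple[float, ...]"
    alpha_B: "tuple[float, ...]"
    alpha_r: "tuple[float, ...]"

    @property
    def alpha_P0(self) -> float:
        return sum(self.alpha_P)

    @property
    def alpha_B0(self) -> float:
        return sum(self.alpha_B)

    @property
    def total(self) -> float:
        return sum(self.alpha_P) + sum(self.alpha_B) + sum(self.alpha_r)


def propensities(interface: InterfaceState,
                 net: ReactionNetwork) -> PropensitySet:
    """Jump and reaction propensities from fresh auxiliary counts.

    alpha_P = d * N_PA, clamped to zero when N_PA < 1 (withdrawing a whole
    particle would drive the density negative); alpha_B = d * N_BA;
    alpha_r = g_r(N_BA) * kappa_r * V_aux^(1 - nu) for the mesoscopic
    channels.
    """
    n_pa, n_ba = interface.N_PA, interface.N_BA
    if n_ba < 0:
        raise RuntimeError("negative particle count")
    if n_pa < 1.0 - _CLAMP_TOL:
        a_p = 0.0
        if interface.d > 0.0 and n_pa > _CLAMP_TOL:
            interface.clamp_activations += 1
    else:
        a_p = interface.d * n_pa
    a_b = interface.d * n_ba
    a_r = tuple(ch.g(n_ba) * ch.rate * net.aux_volume ** (1 - ch.order)
                for ch in net.meso_channels)
    return PropensitySet((a_p,), (a_b,), a_r)


def sample_waiting_time(alpha0: float, u: float) -> float:
    """Exponential waiting time tau = ln(1/u) / alpha0, u ~ Unif(0, 1)."""
    if alpha0 < 0:
        raise ValueError("alpha0 must be non-negative")
    if alpha0 == 0.0:
        return math.inf
    return math.log(1.0 / u) / alpha0 if u > 0.0 else math.inf


def select_event(props: PropensitySet, u2: float):
    """Choose an event by cumulative-sum inversion over the fixed order.

    Returns ``("P2B", k)``, ``("B2P", k)`` or ``("RXN", r)``.
    """
    total = props.total
    if total <= 0:
        raise ValueError("select_event requires a positive total propensity")
    target = u2 * total
    acc = 0.0
    for k, a in enumerate(props.alpha_P):
        acc += a
        if target < acc:
            return ("P2B", k)
    for k, a in enumerate(props.alpha_B):
        acc += a
        if target < acc:
            return ("B2P", k)
    for r, a in enumerate(props.alpha_r):
        acc += a
        if target < acc:
            return ("RXN", r)
    # u2 == 1.0 edge: last event with nonzero propensity
    for r in range(len(props.alpha_r) - 1, -1, -1):
        if props.alpha_r[r] > 0:
            return ("RXN", r)
    return ("B2P", 0) if props.alpha_B[0] > 0 else ("P2B", 0)


def _new_particle_in(interval: "tuple[float, float]",
                     ensemble: ParticleEnsemble,
                     rng: np.random.Generator) -> np.ndarray:
    """Uniform position in the auxiliary slab (full cross-section in 3-D)."""
    if ensemble.positions.ndim == 1:
        return np.array([rng.uniform(interval[0], interval[1])])
    lo = ensemble.lo.copy()
    hi = ensemble.hi.copy()
    lo[0], hi[0] = interval
    return rng.uniform(lo, hi)[None, :]


def enact_jump_P_to_B(field: PDEField, ensemble: ParticleEnsemble,
                      interface: InterfaceState, rng: np.random.Generator):
    """PDE -> Brownian jump: withdraw one particle's worth of mass
    uniformly from Omega_PA and place a new particle uniformly in Omega_BA.
    """
    new_field = deposit_uniform(field, interface.omega_PA, -1.0)
    new = _new_particle_in(interface.omega_BA, ensemble, rng)
    if ensemble.positions.ndim == 1:
        pos = np.append(ensemble.positions, new)
    else:
        pos = np.vstack([ensemble.positions, new])
    return new_field, ParticleEnsemble(pos, ensemble.lo, ensemble.hi)


def enact_jump_B_to_P(field: PDEField, ensemble: ParticleEnsemble,
                      interface: InterfaceState, rng: np.random.Generator):
    """Brownian -> PDE jump: delete a uniformly chosen particle from
    Omega_BA and add its mass uniformly over Omega_PA."""
    lo, hi = interface.omega_BA
    x = ensemble.x
    idx = np.nonzero((x >= lo) & (x < hi))[0]
    if idx.size == 0:
        raise RuntimeError("B->P jump selected with empty Omega_BA "
                           "(propensity/state desync)")
    victim = idx[rng.integers(idx.size)]
    pos = np.delete(ensemble.positions, victim, axis=0)
    new_field = deposit_uniform(field, interface.omega_PA, +1.0)
    return new_field, ParticleEnsemble(pos, ensemble.lo, ensemble.hi)


def enact_aux_reaction(ensemble: ParticleEnsemble,
                       interface: InterfaceState, channel: ReactionChannel,
                       rng: np.random.Generator) -> ParticleEnsemble:
    """Compartment-based reaction inside Omega_BA: reactants are removed
    uniformly at random among eligible particles; products are placed
    uniformly throughout the Brownian auxiliary region."""
    lo, hi = interface.omega_BA
    x = ensemble.x
    idx = np.nonzero((x >= lo) & (x < hi))[0]
    if idx.size < channel.n_reactants:
        raise RuntimeError(
            f"channel {channel.name} fired with {idx.size} particles in "
            f"Omega_BA but needs {channel.n_reactants}")
    pos = ensemble.positions
    if channel.n_reactants:
        chosen = rng.choice(idx, size=channel.n_reactants, replace=False)
        pos = np.delete(pos, chosen, axis=0)
    for _ in range(channel.n_products):
        new = _new_particle_in((lo, hi), ensemble, rng)
        pos = np.append(pos, new) if pos.ndim == 1 else np.vstack([pos, new])
    return ParticleEnsemble(pos, ensemble.lo, ensemble.hi)


# ----------------------------------------------------------------------
# initial state and trajectory containers


def build_initial_state(cfg: SimulationConfig, rng: np.random.Generator):
    """Construct (PDEField, ParticleEnsemble, InterfaceState) from a config."""
    cfg.validate()
    n_cells = round((cfg.interface - cfg.x_lo) / cfg.h_p)
    centers = cfg.x_lo + (np.arange(n_cells) + 0.5) * cfg.h_p
    length = cfg.domain_length
    if cfg.cross_section is None:
        lo = np.array([cfg.interface])
        hi = np.array([cfg.x_hi])
        dim = 1
    else:
        lo = np.array([cfg.interface, 0.0, 0.0])
        hi = np.array([cfg.x_hi, cfg.Ly, cfg.Lz])
        dim = 3

    def _uniform_particles(n):
        if dim == 1:
            return rng.uniform(lo[0], hi[0], size=n)
        return rng.uniform(lo, hi, size=(n, 3))

    if cfg.ic == "uniform":
        values = np.full(n_cells, cfg.N / length)
        q = (cfg.x_hi - cfg.interface) / length
        n_b = (int(rng.binomial(cfg.N, q)) if cfg.ic_binomial_split
               else round(cfg.N * q))
        particles = _uniform_particles(n_b)
    elif cfg.ic == "all_pde":
        values = np.full(n_cells, cfg.N / (cfg.interface - cfg.x_lo))
        particles = _uniform_particles(0)
    elif cfg.ic == "ramp":
        # reduced linear density a*(x_hi - x), vanishing at the far end
        a = 2.0 * cfg.N / length**2
        values = a * (cfg.x_hi - centers)
        pde_mass = float(values.sum() * cfg.h_p)
        n_float = cfg.N - pde_mass
        n_b = int(n_float) + int(rng.random() < (n_float % 1.0))
        # inverse-CDF sample of the ramp restricted to the Brownian side
        u = rng.random(n_b)
        w = cfg.x_hi - cfg.interface
        xs = cfg.x_hi - w * np.sqrt(1.0 - u)
        if dim == 1:
            particles = xs
        else:
            particles = np.column_stack([
                xs, rng.uniform(0.0, cfg.Ly, n_b),
                rng.uniform(0.0, cfg.Lz, n_b)])
    elif cfg.ic == "custom":
        if cfg.ic_pde_values is None or len(cfg.ic_pde_values) != n_cells:
            raise ValueError("custom IC needs ic_pde_values of length "
                             f"{n_cells}")
        values = np.asarray(cfg.ic_pde_values, dtype=float).copy()
        particles = (np.asarray(cfg.ic_particles, dtype=float).copy()
                     if cfg.ic_particles is not None
                     else _uniform_particles(0))
    else:
        raise ValueError(f"unknown IC spec {cfg.ic!r}")

    fld = PDEField(cfg.x_lo, cfg.h_p, values, cfg.theta, cfg.flux_lambda)
    ens = ParticleEnsemble(particles, lo, hi)
    iface = InterfaceState(cfg.interface, cfg.h_a,
                           jump_rate(cfg.D, cfg.h_a))
    iface.refresh(fld, ens)
    return fld, ens, iface


@dataclass
class HybridTrajectory:
    """Time-stamped summaries of one hybrid realization plus a mass ledger.

    ``binned`` holds the hybrid mass per h_a-wide bin on the common
    comparison mesh (PDE integral on the PDE side, particle counts on the
    Brownian side); its last column is the far-end slab occupancy used by
    the relative-error metric.
    """

    t: np.ndarray
    pde_mass: np.ndarray
    n_particles: np.ndarray
    N_PA: np.ndarray
    N_BA: np.ndarray
    interface: np.ndarray
    bin_edges: Optional[np.ndarray]
    binned: Optional[np.ndarray]
    ledger: dict
    clamp_activations: int
    snapshots: list
    config: SimulationConfig
    seed: int

    @property
    def total_mass(self) -> np.ndarray:
        return self.pde_mass + self.n_particles

    def ledger_balance(self) -> float:
        """Net recorded mass change (creation positive) over the run."""
        led = self.ledger
        return (led.get("pde_influx", 0.0)
                + led.get("particle_birth", 0.0)
                + led.get("pde_reaction", 0.0)
                - led.get("particle_decay", 0.0)
                - led.get("micro_reaction_removed", 0.0)
                - led.get("aux_reaction_removed", 0.0)
                + led.get("move_mass_error", 0.0))


def _bin_hybrid(field: PDEField, ensemble: ParticleEnsemble,
                edges: np.ndarray, h_a: float) -> np.ndarray:
    """Hybrid mass per h_a bin: PDE cell-sum integrals plus particle counts."""
    out = np.zeros(edges.size - 1)
    m_per_bin = round(h_a / field.h_p)
    n_pde_bins = field.n_cells // m_per_bin
    if n_pde_bins:
        out[:n_pde_bins] = (field.values[:n_pde_bins * m_per_bin]
                            .reshape(n_pde_bins, m_per_bin).sum(axis=1)
                            * field.h_p)
    if ensemble.n:
        counts, _ = np.histogram(ensemble.x, bins=edges)
        out += counts
    return out


def run_hybrid(config: SimulationConfig, seed: int = 0) -> HybridTrajectory:
    """Simulate one realization of the auxiliary region method.

    Repeats the cycle: (i) refresh counts and propensities and draw the
    next SSA event; (ii) while the event lands before the next synchronous
    update, enact it and redraw; (iii) at the update time, theta-step the
    PDE, diffuse and react the particles, check the adaptive interface,
    and discard the stale putative event.
    """
    cfg = config.validate()
    rng = np.random.default_rng(seed)
    fld, ens, iface = build_initial_state(cfg, rng)
    net = ReactionNetwork.from_config(
        cfg, calibrate=cfg.brownian_update and cfg.kappa1 > 0)

    from .adaptive_interface import check_and_move  # deferred: avoids cycle

    dt, h_p, h_a = cfg.dt, cfg.h_p, cfg.h_a
    n_steps = round(cfg.t_end / dt)
    rec_every = max(1, round(cfg.record_dt / dt))
    edges = None
    if cfg.record_bins:
        n_bins = round(cfg.domain_length / h_a)
        edges = cfg.x_lo + np.arange(n_bins + 1) * h_a

    # nonlinear reaction operator for the theta step; linear decay is
    # folded into the propagator itself
    f_nonlin = net.f
    steppers: dict = {}

    def get_stepper(n: int) -> ThetaStepper:
        if n not in steppers:
            steppers[n] = ThetaStepper(n, h_p, dt, cfg.D, cfg.theta,
                                       cfg.flux_lambda, cfg.mu)
        return steppers[n]

    ledger: dict = {}

    def led(key, amount=1.0):
        ledger[key] = ledger.get(key, 0.0) + amount

    snap_times = set(round(ts / dt) for ts in cfg.snapshot_times)
    records = {k: [] for k in
               ("t", "pde_mass", "n_particles", "N_PA", "N_BA", "interface")}
    binned_rows = []
    snapshots = []

    def record(t_now):
        iface.refresh(fld, ens)
        records["t"].append(t_now)
        records["pde_mass"].append(fld.total_mass())
        records["n_particles"].append(float(ens.n))
        records["N_PA"].append(iface.N_PA)
        records["N_BA"].append(float(iface.N_BA))
        records["interface"].append(iface.I)
        if edges is not None:
            binned_rows.append(_bin_hybrid(fld, ens, edges, h_a))

    record(0.0)
    if 0 in snap_times:
        snapshots.append((0.0, fld.copy(), ens.copy(), iface.I))

    influx_per_step = cfg.D * cfg.flux_lambda * dt
    exclusion = None

    for step in range(n_steps):
        t_cur = step * dt
        t_next = (step + 1) * dt
        # --- event-driven interfacial jumps / auxiliary reactions -------
        t_ssa = t_cur
        while True:
            iface.refresh(fld, ens)
            props = propensities(iface, net)
            a0 = props.total
            if a0 <= 0.0:
                break
            tau = sample_waiting_time(a0, 1.0 - rng.random())
            if t_ssa + tau > t_next:
                break           # stale putative event discarded at update
            t_ssa += tau
            tag, k = select_event(props, rng.random())
            if logger.isEnabledFor(logging.DEBUG):
                logger.debug("ssa %s t=%.6f N_PA=%.3f N_BA=%d",
                             tag, t_ssa, iface.N_PA, iface.N_BA)
            if tag == "P2B":
                fld, ens = enact_jump_P_to_B(fld, ens, iface, rng)
                led("jump_P2B")
            elif tag == "B2P":
                fld, ens = enact_jump_B_to_P(fld, ens, iface, rng)
                led("jump_B2P")
            else:
                ch = net.meso_channels[k]
                ens = enact_aux_reaction(ens, iface, ch, rng)
                led("aux_reaction_removed",
                    float(ch.n_reactants - ch.n_products))

        # --- synchronous PDE / Brownian updates --------------------------
        if cfg.pde_update:
            before = fld.total_mass()
            fld.values = get_stepper(fld.n_cells).step(fld.values, f_nonlin)
            after = fld.total_mass()
            if influx_per_step:
                led("pde_influx", influx_per_step)
            led("pde_reaction", after - before - influx_per_step)
        if cfg.brownian_update:
            ens = diffuse(ens, dt, cfg.D, rng)
            if cfg.kappa1 > 0 and net.P_lambda > 0 and ens.n > 1:
                exclusion = iface.omega_BA
                n_before = ens.n
                ens = lambda_rho_step(ens, cfg.rho, net.P_lambda, rng,
                                      exclusion=exclusion)
                led("micro_reaction_removed", float(n_before - ens.n))
            if cfg.mu > 0:
                n_before = ens.n
                ens = first_order_decay(ens, cfg.mu, dt, rng)
                led("particle_decay", float(n_before - ens.n))
            if cfg.kappa2 > 0:
                n_before = ens.n
                ens = zeroth_order_birth(ens, cfg.kappa2, dt, rng)
                led("particle_birth", float(ens.n - n_before))
        if cfg.adaptive is not None:
            fld, ens, iface, moved = check_and_move(
                fld, ens, iface, cfg.adaptive, rng,
                x_lo=cfg.x_lo, x_hi=cfg.x_hi, ledger=ledger)
            if moved:
                led("adaptive_moves")

        if (step + 1) % rec_every == 0 or step + 1 == n_steps:
            record(t_next)
        if (step + 1) in snap_times:
            snapshots.append((t_next, fld.copy(), ens.copy(), iface.I))
            logger.info("snapshot t=%.3f pde_mass=%.3f particles=%d I=%.3f",
                        t_next, fld.total_mass(), ens.n, iface.I)

    return HybridTrajectory(
        t=np.array(records["t"]),
        pde_mass=np.array(records["pde_mass"]),
        n_particles=np.array(records["n_particles"]),
        N_PA=np.array(records["N_PA"]),
        N_BA=np.array(records["N_BA"]),
        interface=np.array(records["interface"]),
        bin_edges=edges,
        binned=np.array(binned_rows) if binned_rows else None,
        ledger=ledger,
        clamp_activations=iface.clamp_activations,
        snapshots=snapshots,
        config=cfg,
        seed=seed,
    )
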