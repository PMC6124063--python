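"""Threshold-driven adaptive interface motion.

When particle numbers change dynamically there is no position for a static
interface that keeps the PDE valid (dense side) and the particle regime
affordable (dilute side) for all time.  The adaptive rule monitors the two
auxiliary occupancies at every synchronous update and moves the interface
one auxiliary width at a time:

* ``N_PA < beta_l``  -> move toward the PDE subdomain (interface shifts
  left by h_a): the PDE auxiliary region is converted into particles;
* ``N_BA > beta_u``  -> move toward the Brownian subdomain (interface
  shifts right by h_a): the Brownian auxiliary particles are converted
  into a uniform slab of PDE density.

``beta_u > beta_l`` gives the rule hysteresis, preventing rapid
oscillation between two positions.  Both conversions conserve total mass
exactly for every realization: particle counts are integers, so the
fractional part of N_PA initializes one extra particle with matching
probability and the residual is folded back into the remaining PDE
density by a multiplicative rescale (unbiased in the particle number).
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .brownian_engine import ParticleEnsemble
from .config import AdaptiveConfig
from .coupling_core import InterfaceState
from .pde_engine import PDEField, region_mass

__all__ = ["AdaptiveConfig", "check_and_move", "pde_to_particles",
           "particles_to_pde"]

logger = logging.getLogger(__name__)


def pde_to_particles(field: PDEField, interface: InterfaceState,
                     rng: np.random.Generator):
    """Convert the PDE auxiliary region into discrete particles.

    Returns ``(trimmed_field, new_particle_x, mass_error)``.  The region's
    pseudo-particle mass N_PA becomes ``floor(N_PA)`` particles plus one
    extra with probability ``N_PA mod 1``; the realized surplus or deficit
    ``N_PA - n`` is folded into the remaining PDE cells by a multiplicative
    rescale so each realization conserves mass exactly.  ``mass_error`` is
    nonzero only in the degenerate case of an empty remaining subdomain.
    """
    m_a = round(interface.h_a / field.h_p)
    n_pa = region_mass(field, interface.omega_PA)
    n_new = int(math.floor(n_pa))
    frac = n_pa - n_new
    if rng.random() < frac:
        n_new += 1
    rest = field.values[:-m_a]
    m_rest = float(rest.sum() * field.h_p)
    mass_error = 0.0
    residual = n_pa - n_new
    if m_rest > 0.0:
        factor = (m_rest + residual) / m_rest
        if abs(factor - 1.0) > 0.1:
            logger.warning("adaptive rescale factor %.3f deviates strongly "
                           "from 1 (N_PA=%.3f, n=%d)", factor, n_pa, n_new)
        new_values = rest * factor
    else:
        new_values = rest.copy()
        mass_error = residual
        logger.warning("PDE subdomain empty during conversion; mass "
                       "discrepancy %.3g absorbed into ledger", residual)
    trimmed = PDEField(field.x_lo, field.h_p, new_values, field.theta,
                       field.flux_lambda)
    lo, hi = interface.omega_PA
    xs = rng.uniform(lo, hi, size=n_new)
    return trimmed, xs, mass_error


def particles_to_pde(field: PDEField, ensemble: ParticleEnsemble,
                     interface: InterfaceState):
    """Convert the Brownian auxiliary region into PDE mass.

    All particles in Omega_BA are deleted and the slab becomes PDE cells
    holding the uniform reduced density N_BA / h_a (particles per unit
    interface-normal length), which conserves mass exactly.
    """
    lo, hi = interface.omega_BA
    x = ensemble.x
    inside = (x >= lo) & (x < hi)
    n_ba = int(np.count_nonzero(inside))
    m_a = round(interface.h_a / field.h_p)
    new_cells = np.full(m_a, n_ba / interface.h_a)
    extended = PDEField(field.x_lo, field.h_p,
                        np.concatenate([field.values, new_cells]),
                        field.theta, field.flux_lambda)
    kept = ParticleEnsemble(ensemble.positions[~inside], ensemble.lo,
                            ensemble.hi)
    return extended, kept


def check_and_move(field: PDEField, ensemble: ParticleEnsemble,
                   interface: InterfaceState, cfg: AdaptiveConfig,
                   rng: np.random.Generator, x_lo: float, x_hi: float,
                   ledger: "dict | None" = None):
    """Apply the threshold rule; at most one h_a move per call.

    Returns ``(field, ensemble, interface, moved)`` with ``moved`` in
    {-1, 0, +1} (direction of interface displacement).  A move that would
    shrink either subdomain below one auxiliary width is suppressed with a
    warning.
    """
    interface.refresh(field, ensemble)
    h_a = interface.h_a
    if interface.N_PA < cfg.beta_l:
        new_i = interface.I - h_a
        if new_i - x_lo < h_a - 1e-12:
            logger.warning("interface move left suppressed: PDE subdomain "
                           "would shrink below h_a")
            if ledger is not None:
                ledger["moves_suppressed"] = \
                    ledger.get("moves_suppressed", 0.0) + 1.0
            return field, ensemble, interface, 0
        trimmed, xs, mass_err = pde_to_particles(field, interface, rng)
        lo = ensemble.lo.copy()
        lo[0] = new_i
        if ensemble.positions.ndim == 1:
            new_pos = np.concatenate([ensemble.positions, xs])
        else:
            extra = np.column_stack(
                [xs] + [rng.uniform(ensemble.lo[j], ensemble.hi[j],
                                    xs.size) for j in (1, 2)])
            new_pos = np.vstack([ensemble.positions, extra]) \
                if xs.size else ensemble.positions.copy()
        new_ens = ParticleEnsemble(new_pos, lo, ensemble.hi)
        new_iface = InterfaceState(new_i, h_a, interface.d,
                                   clamp_activations=
                                   interface.clamp_activations)
        if ledger is not None and mass_err:
            ledger["move_mass_error"] = \
                ledger.get("move_mass_error", 0.0) + mass_err
        new_iface.refresh(trimmed, new_ens)
        return trimmed, new_ens, new_iface, -1
    if interface.N_BA > cfg.beta_u:
        new_i = interface.I + h_a
        if x_hi - new_i < h_a - 1e-12:
            logger.warning("interface move right suppressed: Brownian "
                           "subdomain would shrink below h_a")
            if ledger is not None:
                ledger["moves_suppressed"] = \
                    ledger.get("moves_suppressed", 0.0) + 1.0
            return field, ensemble, interface, 0
        extended, kept = particles_to_pde(field, ensemble, interface)
        lo = kept.lo.copy()
        lo[0] = new_i
        new_ens = ParticleEnsemble(kept.positions, lo, kept.hi)
        new_iface = InterfaceState(new_i, h_a, interface.d,
                                   clamp_activations=
                                   interface.clamp_activations)
        new_iface.refresh(extended, new_ens)
        return extended, new_ens, new_iface, +1
    return field, ensemble, interface, 0
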