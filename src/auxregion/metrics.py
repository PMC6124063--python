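"""Error instrumentation for hybrid-versus-reference comparisons.

All comparisons live on a common mesh of bins one auxiliary width wide:
the hybrid's contribution to a bin is the PDE integral on the continuum
side and the particle count on the Brownian side, which is how continuum
and particle mass are overlaid throughout this package.

* ``hde`` -- histogram distance error: half the L1 distance between two
  normalised histograms; 0 means identical profiles, 1 disjoint supports.
* ``region_relative_errors`` -- repeat-averaged particle numbers in the
  PDE and Brownian regions against the mean-field expectation, reported
  as relative errors (an unbiased coupling shows no sign preference).
* ``last_slab_error`` -- relative error of the far-end slab occupancy
  between two simulation arms (hybrid vs fully microscopic).
* ``binned_variance`` -- across-repeat variance of the binned density,
  with the fully-Brownian binomial variance as the reference line.
* ``robustness_sweep`` -- HDE over a (dt, h_a) grid, with the diagnostic
  ratio D*dt/h_a^2 that governs auxiliary-region equilibration.

Every metric is a pure function of stored trajectory summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .coupling_core import HybridTrajectory, run_hybrid
from .reference_models import meanfield_binned

__all__ = [
    "hde",
    "ErrorReport",
    "region_relative_errors",
    "sign_test_pvalue",
    "last_slab_error",
    "binned_variance",
    "binomial_variance_reference",
    "robustness_sweep",
    "mean_binned",
]


def hde(hist_H: np.ndarray, hist_P: np.ndarray) -> float:
    """Histogram distance error between two nonnegative histograms.

    Each histogram is normalised to unit total; the HDE is half the L1
    distance, so it is symmetric, invariant under common rescaling of
    either argument, and lies in [0, 1].
    """
    h = np.asarray(hist_H, dtype=float)
    p = np.asarray(hist_P, dtype=float)
    if h.shape != p.shape:
        raise ValueError("histograms must share the comparison mesh")
    if np.any(h < 0) or np.any(p < 0):
        raise ValueError("histograms must be nonnegative")
    sh, sp = h.sum(), p.sum()
    if sh <= 0 or sp <= 0:
        raise ValueError("histograms must have positive total mass")
    return float(0.5 * np.abs(h / sh - p / sp).sum())


@dataclass
class ErrorReport:
    """Region-count comparison between hybrid repeats and a reference."""

    t: np.ndarray
    N_HP: np.ndarray        # repeat-averaged PDE-region mass
    N_HB: np.ndarray        # repeat-averaged Brownian-region count
    N_MP: np.ndarray        # reference PDE-region mass
    N_MB: np.ndarray        # reference Brownian-region mass
    rel_P: np.ndarray       # (N_HP - N_MP) / N_MP, nan where N_MP == 0
    rel_B: np.ndarray
    se_HP: np.ndarray       # standard errors of the repeat means
    se_HB: np.ndarray
    S: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("N_HP", "N_HB", "N_MP", "N_MB", "rel_P", "rel_B",
                     "se_HP", "se_HB"):
            vals = getattr(self, name)
            rows.append(pd.DataFrame(
                {"metric": name, "t": self.t, "value": vals}))
        return pd.concat(rows, ignore_index=True)


def region_relative_errors(trajectories: Sequence[HybridTrajectory],
                           ref_P, ref_B) -> ErrorReport:
    """Relative region-count errors of S hybrid repeats.

    ``ref_P`` / ``ref_B`` give the mean-field mass in the PDE and Brownian
    regions: either arrays on the trajectories' record grid or callables
    of time.  Ratios where the reference mass vanishes are reported as
    nan (undefined), never as infinities.
    """
    if len(trajectories) < 1:
        raise ValueError("need at least one repeat")
    t = trajectories[0].t
    for tr in trajectories[1:]:
        if tr.t.shape != t.shape or not np.allclose(tr.t, t):
            raise ValueError("repeats must share the record grid")
    hp = np.stack([tr.pde_mass for tr in trajectories])
    hb = np.stack([tr.n_particles for tr in trajectories])
    n_mp = np.asarray(ref_P(t) if callable(ref_P) else ref_P, dtype=float)
    n_mb = np.asarray(ref_B(t) if callable(ref_B) else ref_B, dtype=float)
    s = hp.shape[0]
    n_hp = hp.mean(axis=0)
    n_hb = hb.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_p = np.where(n_mp != 0.0, (n_hp - n_mp) / n_mp, np.nan)
        rel_b = np.where(n_mb != 0.0, (n_hb - n_mb) / n_mb, np.nan)
    se_hp = hp.std(axis=0, ddof=1) / np.sqrt(s) if s > 1 else \
        np.zeros_like(n_hp)
    se_hb = hb.std(axis=0, ddof=1) / np.sqrt(s) if s > 1 else \
        np.zeros_like(n_hb)
    return ErrorReport(t, n_hp, n_hb, n_mp, n_mb, rel_p, rel_b,
                       se_hp, se_hb, s)


def sign_test_pvalue(values: np.ndarray) -> float:
    """Two-sided sign test for zero median (exact binomial, zeros dropped)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v) & (v != 0.0)]
    if v.size == 0:
        return 1.0
    return float(stats.binomtest(int(np.sum(v > 0)), v.size, 0.5).pvalue)


def last_slab_error(hybrid_slabs: np.ndarray, micro_slabs: np.ndarray,
                    t: Optional[np.ndarray] = None) -> np.ndarray:
    """E_Rel(t) = (N_M - N_H) / N_M from two repeat sets of slab counts.

    Inputs are (S, T)-shaped occupancies of the far-end slab for each arm;
    repeats are averaged first.  Undefined time points (reference slab
    empty) come back as nan.
    """
    h = np.atleast_2d(np.asarray(hybrid_slabs, dtype=float)).mean(axis=0)
    m = np.atleast_2d(np.asarray(micro_slabs, dtype=float)).mean(axis=0)
    if h.shape != m.shape:
        raise ValueError("the two arms must share the time grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(m != 0.0, (m - h) / m, np.nan)


def mean_binned(trajectories: Sequence[HybridTrajectory],
                t_index: int) -> np.ndarray:
    """Repeat-averaged hybrid mass per bin at one record index."""
    return np.stack([tr.binned[t_index] for tr in trajectories]).mean(axis=0)


def binned_variance(trajectories: Sequence[HybridTrajectory],
                    t_index: int) -> np.ndarray:
    """Across-repeat variance of the binned density at one record time.

    Bin mass (PDE integral or particle count) is divided by the bin width
    h_a, matching the density units of the profile plots.
    """
    if len(trajectories) < 2:
        raise ValueError("variance needs at least two repeats")
    h_a = trajectories[0].config.h_a
    dens = np.stack([tr.binned[t_index] for tr in trajectories]) / h_a
    return dens.var(axis=0, ddof=1)


def binomial_variance_reference(N: int, h_a: float,
                                domain_length: float) -> float:
    """Per-bin density variance of a fully Brownian uniform steady state.

    N particles fall in a bin of width h_a with probability
    q = h_a / L, so the count variance is N q (1-q) and the density
    variance N q (1-q) / h_a^2.
    """
    q = h_a / domain_length
    return N * q * (1.0 - q) / h_a**2


def robustness_sweep(dt_list: Sequence[float], ha_list: Sequence[float],
                     D: float, T: float, S: int, N: int = 500,
                     h_p: float = 0.01, base_seed: int = 0,
                     domain=(-1.0, 1.0), interface: float = 0.0,
                     ) -> pd.DataFrame:
    """HDE over a (dt, h_a) grid for the all-mass-in-the-PDE stress test.

    For each parameter pair, S hybrid repeats run to time T from an
    initial condition with every particle's worth of mass uniform in the
    PDE subdomain; the repeat-averaged profile is compared to the
    diffusion series oracle on that cell's own h_a mesh.  The returned
    frame carries the stability diagnostic D*dt/h_a^2 per cell.
    """
    rows = []
    lo, hi = domain
    for h_a in ha_list:
        for dt in dt_list:
            cfg = SimulationConfig(
                x_lo=lo, x_hi=hi, interface=interface, dt=dt, t_end=T,
                h_a=h_a, h_p=h_p, D=D, N=N, ic="all_pde",
                record_dt=T, record_bins=True, S=S,
            ).validate()
            trajs = [run_hybrid(cfg, seed=base_seed + 1000 * len(rows) + s)
                     for s in range(S)]
            edges = trajs[0].bin_edges
            ref = meanfield_binned("left_step", N, D, T, edges,
                                   domain=domain, split=interface)
            per_rep = np.array([hde(tr.binned[-1], ref) for tr in trajs])
            avg = mean_binned(trajs, -1)
            rows.append({
                "dt": dt, "ha": h_a,
                "D_dt_over_ha2": D * dt / h_a**2,
                "hde_mean": hde(avg, ref),
                "hde_sd": float(per_rep.std(ddof=1)) if S > 1 else 0.0,
            })
    return pd.DataFrame(rows)
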