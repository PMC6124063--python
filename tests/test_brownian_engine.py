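"""Brownian regime: displacement moments, reflection, reaction enactment
and the lambda-rho calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from auxregion import (ParticleEnsemble, compute_P_lambda, count_in,
                       diffuse, first_order_decay, lambda_rho_step,
                       zeroth_order_birth)
from auxregion.brownian_engine import reflect


def _ens(positions, lo=0.0, hi=1.0):
    return ParticleEnsemble(np.asarray(positions, dtype=float),
                            np.atleast_1d(lo), np.atleast_1d(hi))


# ---------------------------------------------------------------- diffusion

def test_zero_diffusivity_is_identity(unit_ensemble, rng):
    out = diffuse(unit_ensemble, dt=0.02, D=0.0, rng=rng)
    assert np.array_equal(out.positions, unit_ensemble.positions)


def test_displacement_variance_matches_generator():
    """Free displacements carry variance 2*D*dt (checked to 3 SE on 1e5
    steps with the canonical D = 0.0025, dt = 0.02)."""
    rng = np.random.default_rng(11)
    D, dt, n = 0.0025, 0.02, 100_000
    # huge domain so no reflections interfere
    ens = _ens(np.zeros(n), lo=-1e6, hi=1e6)
    disp = diffuse(ens, dt, D, rng).positions
    var = disp.var(ddof=1)
    target = 2.0 * D * dt
    se = target * math.sqrt(2.0 / (n - 1))
    assert abs(var - target) < 3.0 * se
    assert abs(disp.mean()) < 3.0 * math.sqrt(target / n)


def test_reflection_mirrors_at_boundary():
    assert reflect(np.array([1.05]), 0.0, 1.0)[0] == pytest.approx(0.95)
    assert reflect(np.array([-0.3]), 0.0, 1.0)[0] == pytest.approx(0.3)
    # multiple folds terminate and land inside
    far = reflect(np.array([7.3, -5.1]), 0.0, 1.0)
    assert np.all((far >= 0.0) & (far <= 1.0))


@given(x=st.floats(-50.0, 50.0), lo=st.floats(-2.0, 0.0),
       width=st.floats(0.5, 3.0))
@settings(derandomize=True, max_examples=200, deadline=None)
def test_reflection_always_lands_inside(x, lo, width):
    out = reflect(np.array([x]), lo, lo + width)[0]
    assert lo - 1e-12 <= out <= lo + width + 1e-12


def test_reflection_preserves_uniform_stationarity():
    """Uniform positions stay uniform under many reflected steps
    (chi-squared on 20 bins after 1e3 steps)."""
    rng = np.random.default_rng(5)
    ens = _ens(rng.uniform(0, 1, 500))
    for _ in range(1000):
        ens = diffuse(ens, 0.02, 0.0025, rng)
    counts, _ = np.histogram(ens.positions, bins=20, range=(0, 1))
    p = stats.chisquare(counts).pvalue
    assert p > 0.01


def test_diffuse_preserves_exchangeability():
    """Permuting particle labels commutes with the update in distribution:
    the updated position cloud of a relabelled ensemble is statistically
    indistinguishable from the relabelled update (two-sample KS)."""
    pos = np.linspace(0.05, 0.95, 5000)
    perm = np.random.default_rng(3).permutation(pos.size)
    out_a = diffuse(_ens(pos[perm]), 0.02, 0.0025,
                    np.random.default_rng(41)).positions
    out_b = diffuse(_ens(pos), 0.02, 0.0025,
                    np.random.default_rng(42)).positions[perm]
    assert stats.ks_2samp(out_a, out_b).pvalue > 0.01


# ---------------------------------------------------------------- counting

@pytest.mark.parametrize("positions,region,expected", [
    ([], (0.0, 0.05), 0),
    ([0.01, 0.04, 0.06], (0.0, 0.05), 2),
    ([0.01, 0.04, 0.06], (0.0, 1.0), 3),
    ([0.05], (0.0, 0.05), 0),          # half-open: right edge excluded
    ([0.0], (0.0, 0.05), 1),           # left edge included
])
def test_count_in_half_open_convention(positions, region, expected):
    assert count_in(_ens(positions), region) == expected


# ---------------------------------------------------------------- reactions

def test_decay_zero_rate_removes_nothing(unit_ensemble, rng):
    out = first_order_decay(unit_ensemble, 0.0, 0.02, rng)
    assert out.n == unit_ensemble.n


def test_decay_fraction_matches_exact_probability():
    """One step over 1e6 particle-steps at mu=0.001, dt=0.02: removal
    fraction within 3 SE of 1 - exp(-2e-5)."""
    rng = np.random.default_rng(17)
    n = 1_000_000
    ens = _ens(np.full(n, 0.5))
    out = first_order_decay(ens, 0.001, 0.02, rng)
    p = -math.expm1(-0.001 * 0.02)
    removed = n - out.n
    se = math.sqrt(n * p * (1 - p))
    assert abs(removed - n * p) < 3.0 * se


def test_decay_infinite_rate_limit(rng):
    ens = _ens(np.linspace(0.1, 0.9, 200))
    out = first_order_decay(ens, mu=2500.0, dt=0.02, rng=rng)  # mu*dt = 50
    assert out.n == 0


def test_birth_zero_rate_never_adds(unit_ensemble, rng):
    assert zeroth_order_birth(unit_ensemble, 0.0, 0.01, rng).n == \
        unit_ensemble.n


def test_birth_probability_and_uniform_placement():
    """Per-step birth probability kappa2*dt*V_B = 0.19 at the canonical
    second-order parameters (kappa2=0.5, dt=0.01, V_B=38), with uniform
    placement along every axis (KS at 1%)."""
    rng = np.random.default_rng(23)
    lo = np.array([0.5, 0.0, 0.0])
    hi = np.array([10.0, 2.0, 2.0])
    base = ParticleEnsemble(np.empty((0, 3)), lo, hi)
    assert base.volume() == pytest.approx(38.0)
    births = []
    trials = 10_000
    for _ in range(trials):
        out = zeroth_order_birth(base, 0.5, 0.01, rng)
        if out.n:
            births.append(out.positions[0])
    frac = len(births) / trials
    se = math.sqrt(0.19 * 0.81 / trials)
    assert abs(frac - 0.19) < 3.0 * se
    pts = np.array(births)
    for axis, (a, b) in enumerate(zip(lo, hi)):
        u = (pts[:, axis] - a) / (b - a)
        assert stats.kstest(u, "uniform").pvalue > 0.01


def test_birth_probability_above_one_is_config_error(rng):
    ens = ParticleEnsemble(np.empty((0, 3)), np.zeros(3),
                           np.array([10.0, 2.0, 2.0]))
    with pytest.raises(ValueError, match="kappa2"):
        zeroth_order_birth(ens, kappa2=0.5, dt=0.1, rng=rng)


def test_lambda_rho_no_pairs_in_range(rng):
    ens = _ens([0.1, 0.5, 0.9])
    out = lambda_rho_step(ens, rho=0.05, P_lambda=1.0, rng=rng)
    assert out.n == 3


def test_lambda_rho_certain_reaction_removes_pair(rng):
    ens = _ens([0.30, 0.32])
    out = lambda_rho_step(ens, rho=0.05, P_lambda=1.0, rng=rng)
    assert out.n == 0


def test_lambda_rho_skips_pairs_inside_exclusion(rng):
    """A pair entirely inside the auxiliary region is the coupling's job."""
    ens = _ens([0.01, 0.02])
    out = lambda_rho_step(ens, rho=0.05, P_lambda=1.0, rng=rng,
                          exclusion=(0.0, 0.05))
    assert out.n == 2
    # one partner outside the exclusion interval: pair reacts
    ens2 = _ens([0.04, 0.06])
    out2 = lambda_rho_step(ens2, rho=0.05, P_lambda=1.0, rng=rng,
                           exclusion=(0.0, 0.05))
    assert out2.n == 0


def test_lambda_rho_at_most_one_reaction_per_particle(rng):
    # three mutually close particles: exactly one pair fires
    ens = _ens([0.50, 0.51, 0.52])
    out = lambda_rho_step(ens, rho=0.05, P_lambda=1.0, rng=rng)
    assert out.n == 1


def test_p_lambda_zero_rate():
    assert compute_P_lambda(0.0, 0.1, 0.2, 0.01) == 0.0


def test_p_lambda_calibration_monotonicity():
    """P_lambda grows with the target rate and shrinks with the radius
    (checked with a reduced calibration sample)."""
    kw = dict(n_walkers=1500, n_steps=8000, rel_tol=0.02)
    base = compute_P_lambda(0.01, 0.1, 0.2, 0.01, **kw)
    assert compute_P_lambda(0.02, 0.1, 0.2, 0.01, **kw) > base
    assert compute_P_lambda(0.01, 0.15, 0.2, 0.01, **kw) < base


def test_well_mixed_decay_matches_rate_law():
    """Closed-box 2A->0 with the calibrated P_lambda follows the mass-
    action decay at the canonical rates (kappa1=0.01, volume 40, 200
    particles, t in [0,5], S=200 repeats, 3 SE).

    The mean-field oracle carries the reflective-wall correction: near a
    wall part of the interaction sphere lies outside the box, reducing
    the pair-encounter probability by 3*S_box*rho/(16*V) for uniform
    positions -- a real feature of distance-based pair reactions in
    bounded geometry, shared by hybrid and microscopic arms alike.
    """
    kappa1, rho, D, dt, V = 0.01, 0.1, 0.2, 0.01, 40.0
    P = compute_P_lambda(kappa1, rho, D, dt)
    lo = np.zeros(3)
    hi = np.array([10.0, 2.0, 2.0])
    s_box = 2 * (10 * 2 + 10 * 2 + 2 * 2)
    kappa_eff = kappa1 * (1.0 - 3.0 * s_box * rho / (16.0 * V))

    def oracle(n0, t):
        # dn/dt = -kappa_eff n(n-1)/V
        c = (n0 - 1.0) / n0
        return 1.0 / (1.0 - c * math.exp(-kappa_eff * t / V))

    S, n0, steps = 200, 200, 500
    checks = {100: [], 250: [], 500: []}
    for s in range(S):
        rng = np.random.default_rng(40_000 + s)
        ens = ParticleEnsemble(rng.uniform(lo, hi, size=(n0, 3)), lo, hi)
        for step in range(1, steps + 1):
            ens = diffuse(ens, dt, D, rng)
            ens = lambda_rho_step(ens, rho, P, rng)
            if step in checks:
                checks[step].append(ens.n)
    for step, vals in checks.items():
        vals = np.asarray(vals, dtype=float)
        se = vals.std(ddof=1) / math.sqrt(S)
        assert abs(vals.mean() - oracle(n0, step * dt)) < 3.0 * se, \
            f"t={step * dt}"
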