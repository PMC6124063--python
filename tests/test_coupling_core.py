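"""Coupling core: jump rates, propensities, SSA primitives, enactments
and the interleaved hybrid loop."""

import math

import numpy as np
import pytest
from scipy import stats

from auxregion import (InterfaceState, ParticleEnsemble, PDEField,
                       PropensitySet, ReactionChannel, ReactionNetwork,
                       enact_aux_reaction, enact_jump_B_to_P,
                       enact_jump_P_to_B, jump_rate, make_test_problem,
                       make_two_box, propensities, region_mass, run_hybrid,
                       sample_waiting_time, select_event)


def _state(n_pa=12.5, n_ba=13, d=1.0, h_a=0.05, I=0.0):
    iface = InterfaceState(I, h_a, d)
    iface.N_PA = n_pa
    iface.N_BA = n_ba
    return iface


def _flat_system(density=250.0, n_particles=3, h_a=0.05):
    field = PDEField(-1.0, 0.01, np.full(100, density))
    rng = np.random.default_rng(0)
    ens = ParticleEnsemble(rng.uniform(0.0, h_a, n_particles),
                           np.array([0.0]), np.array([1.0]))
    iface = InterfaceState(0.0, h_a, jump_rate(0.0025, h_a))
    iface.refresh(field, ens)
    return field, ens, iface


# ------------------------------------------------------------- primitives

@pytest.mark.parametrize("D,h_a,expected", [
    (0.0025, 0.05, 1.0),
    (0.025, 0.05, 10.0),
    (0.0, 0.05, 0.0),       # sealed interface
])
def test_jump_rate_values(D, h_a, expected):
    assert jump_rate(D, h_a) == pytest.approx(expected)


def test_jump_rate_invalid_width():
    with pytest.raises(ValueError):
        jump_rate(0.0025, 0.0)


def test_propensity_clamp_below_one_pseudo_particle():
    iface = _state(n_pa=0.7, n_ba=0, d=5.0)
    props = propensities(iface, ReactionNetwork())
    assert props.alpha_P[0] == 0.0
    assert iface.clamp_activations == 1


def test_propensity_sums():
    props = propensities(_state(12.5, 13, d=1.0), ReactionNetwork())
    assert props.alpha_P[0] == pytest.approx(12.5)
    assert props.alpha_B[0] == pytest.approx(13.0)
    assert props.total == pytest.approx(25.5)


def test_reaction_propensity_combinatorics():
    """2A->0 with N_BA=5 in a 1-D compartment of size h_a: alpha_r =
    (5*4/2) * kappa1 / h_a."""
    kappa1, h_a = 0.01, 0.05
    net = ReactionNetwork(
        channels=(ReactionChannel("2A->0", 2, kappa1, 2, 0, True),),
        aux_volume=h_a)
    props = propensities(_state(0.0, 5, d=0.0, h_a=h_a), net)
    assert props.alpha_r[0] == pytest.approx(10.0 * kappa1 / h_a)
    # below the stoichiometric requirement the combinatorial count is zero
    props1 = propensities(_state(0.0, 1, d=0.0, h_a=h_a), net)
    assert props1.alpha_r[0] == 0.0


@pytest.mark.parametrize("alpha0,u,expected", [
    (2.0, math.exp(-1.0), 0.5),
    (5.0, 1.0, 0.0),
])
def test_waiting_time_transform(alpha0, u, expected):
    assert sample_waiting_time(alpha0, u) == pytest.approx(expected)


def test_waiting_time_zero_propensity_sentinel():
    assert sample_waiting_time(0.0, 0.5) == math.inf


def test_waiting_time_exponential_moment():
    rng = np.random.default_rng(31)
    draws = np.array([sample_waiting_time(1.0, u)
                      for u in 1.0 - rng.random(100_000)])
    assert abs(draws.mean() - 1.0) < 3.0 / math.sqrt(draws.size)


def test_select_event_certain_and_invalid():
    props = PropensitySet((0.0,), (3.0,), ())
    assert select_event(props, 0.99) == ("B2P", 0)
    with pytest.raises(ValueError):
        select_event(PropensitySet((0.0,), (0.0,), ()), 0.5)


def test_select_event_multinomial_fraction():
    """alpha_P=1, alpha_B=3: the P->B fraction over 1e5 draws sits within
    3 SE of 1/4."""
    rng = np.random.default_rng(37)
    props = PropensitySet((1.0,), (3.0,), ())
    n = 100_000
    hits = sum(select_event(props, u)[0] == "P2B" for u in rng.random(n))
    se = math.sqrt(0.25 * 0.75 / n)
    assert abs(hits / n - 0.25) < 3.0 * se


# ------------------------------------------------------------- enactments

def test_jump_p_to_b_conserves_and_transfers():
    field, ens, iface = _flat_system()
    total0 = field.total_mass() + ens.n
    rng = np.random.default_rng(2)
    f2, e2 = enact_jump_P_to_B(field, ens, iface, rng)
    assert f2.total_mass() + e2.n == pytest.approx(total0, abs=1e-12)
    n_pa0, n_ba0 = iface.N_PA, iface.N_BA
    iface.refresh(f2, e2)
    assert iface.N_PA == pytest.approx(n_pa0 - 1.0, abs=1e-12)
    assert iface.N_BA == n_ba0 + 1


def test_jump_p_to_b_uniform_placement():
    field, ens, iface = _flat_system(n_particles=0)
    rng = np.random.default_rng(3)
    xs = []
    for _ in range(10_000):
        _, e2 = enact_jump_P_to_B(field, ens, iface, rng)
        xs.append(e2.positions[-1])
    u = np.array(xs) / iface.h_a
    assert stats.kstest(u, "uniform").pvalue > 0.01


def test_jump_b_to_p_conserves_and_raises_density():
    field, ens, iface = _flat_system()
    rng = np.random.default_rng(4)
    f2, e2 = enact_jump_B_to_P(field, ens, iface, rng)
    assert f2.total_mass() + e2.n == pytest.approx(
        field.total_mass() + ens.n, abs=1e-12)
    # density over Omega_PA rises by exactly 1/h_a
    assert np.max(f2.values - field.values) == pytest.approx(
        1.0 / iface.h_a)
    assert e2.n == ens.n - 1


def test_jump_b_to_p_uniform_victim_choice():
    field, ens, iface = _flat_system(n_particles=3)
    counts = np.zeros(3)
    rng = np.random.default_rng(5)
    trials = 10_000
    for _ in range(trials):
        _, e2 = enact_jump_B_to_P(field, ens, iface, rng)
        gone = set(ens.positions) - set(e2.positions)
        counts[list(ens.positions).index(gone.pop())] += 1
    se = math.sqrt(trials / 3 * (2 / 3))
    assert np.all(np.abs(counts - trials / 3) < 3.0 * se)


def test_jump_b_to_p_empty_region_is_fault():
    field, ens, iface = _flat_system(n_particles=0)
    with pytest.raises(RuntimeError, match="desync"):
        enact_jump_B_to_P(field, ens, iface, np.random.default_rng(0))


def test_aux_reaction_annihilation_and_locality():
    field, ens, iface = _flat_system(n_particles=2)
    outside = ParticleEnsemble(
        np.concatenate([ens.positions, [0.5, 0.7]]), ens.lo, ens.hi)
    iface.refresh(field, outside)
    ch = ReactionChannel("2A->0", 2, 0.01, 2, 0, True)
    out = enact_aux_reaction(outside, iface, ch, np.random.default_rng(6))
    iface.refresh(field, out)
    assert iface.N_BA == 0
    # particles outside Omega_BA untouched
    assert set(out.positions) == {0.5, 0.7}


def test_aux_reaction_product_placement_uniform():
    field, ens, iface = _flat_system(n_particles=0)
    ch = ReactionChannel("0->A", 0, 0.5, 0, 1, True)
    rng = np.random.default_rng(7)
    xs = [enact_aux_reaction(ens, iface, ch, rng).positions[0]
          for _ in range(5_000)]
    assert stats.kstest(np.array(xs) / iface.h_a, "uniform").pvalue > 0.01


def test_aux_reaction_insufficient_reactants_is_fault():
    field, ens, iface = _flat_system(n_particles=1)
    ch = ReactionChannel("2A->0", 2, 0.01, 2, 0, True)
    with pytest.raises(RuntimeError, match="needs"):
        enact_aux_reaction(ens, iface, ch, np.random.default_rng(0))


def test_enactment_count_coherence():
    """After a chain of enactments the recomputed occupancies equal the
    ledger-predicted values exactly."""
    field, ens, iface = _flat_system(n_particles=5)
    rng = np.random.default_rng(8)
    expected_pa, expected_ba = iface.N_PA, iface.N_BA
    for k in range(60):
        if k % 3 == 0 and expected_ba >= 1:
            field, ens = enact_jump_B_to_P(field, ens, iface, rng)
            expected_pa += 1
            expected_ba -= 1
        elif expected_pa >= 1:
            field, ens = enact_jump_P_to_B(field, ens, iface, rng)
            expected_pa -= 1
            expected_ba += 1
        iface.refresh(field, ens)
        assert iface.N_PA == pytest.approx(expected_pa, abs=1e-9)
        assert iface.N_BA == expected_ba


# ------------------------------------------------------------- run_hybrid

def test_hybrid_mass_conservation_short():
    cfg = make_test_problem("tp1", t_end=20.0, S=1)
    tr = run_hybrid(cfg, seed=12)
    drift = np.max(np.abs(tr.total_mass - 500.0)) / 500.0
    assert drift <= 1e-9
    # per-event zero-sum transfers: jumps appear in the ledger, mass does not
    assert abs(tr.ledger_balance()
               - (tr.total_mass[-1] - tr.total_mass[0])) < 1e-9


def test_sealed_interface_keeps_totals_separately():
    cfg = make_test_problem("tp1", t_end=10.0, S=1, D=0.0)
    tr = run_hybrid(cfg, seed=13)
    assert np.all(tr.pde_mass == tr.pde_mass[0])
    assert np.all(tr.n_particles == tr.n_particles[0])
    assert "jump_P2B" not in tr.ledger and "jump_B2P" not in tr.ledger


def test_hybrid_reproducible_and_seed_sensitive():
    cfg = make_test_problem("tp1", t_end=5.0, S=1)
    a = run_hybrid(cfg, seed=99)
    b = run_hybrid(cfg, seed=99)
    c = run_hybrid(cfg, seed=100)
    assert np.array_equal(a.binned, b.binned)
    assert np.array_equal(a.n_particles, b.n_particles)
    assert not np.array_equal(a.binned, c.binned)


def test_two_box_degenerate_counts_are_integers():
    """With updates disabled the hybrid is a pure two-box jump process:
    occupancies stay integer (to rounding) and conserved."""
    cfg = make_two_box(10, 8.0, 1.0)
    tr = run_hybrid(cfg, seed=21)
    total = tr.N_PA + tr.N_BA
    np.testing.assert_allclose(total, 10.0, atol=1e-9)
    np.testing.assert_allclose(tr.N_PA, np.round(tr.N_PA), atol=1e-9)


def test_two_box_mean_occupancy_small_sample():
    """200 realizations of the degenerate two-box process sit within 4 SE
    of the closed-form mean at t=0.5 (the full-strength check lives in
    the acceptance suite)."""
    from auxregion import two_box_mean
    cfg = make_two_box(10, 8.0, 1.0, t_end=0.5, record_dt=0.25)
    vals = np.array([run_hybrid(cfg, seed=500 + s).N_PA[-1]
                     for s in range(200)])
    target = two_box_mean(10, 8.0, 1.0, 0.5)
    se = vals.std(ddof=1) / math.sqrt(vals.size)
    assert abs(vals.mean() - target) < 4.0 * se


def test_snapshot_times_recorded():
    cfg = make_test_problem("tp1", t_end=2.0, S=1, record_dt=1.0,
                            snapshot_times=(0.0, 1.0, 2.0))
    tr = run_hybrid(cfg, seed=1)
    assert [s[0] for s in tr.snapshots] == [0.0, 1.0, 2.0]
    fld = tr.snapshots[1][1]
    assert region_mass(fld, (-1.0, 0.0)) == pytest.approx(
        tr.pde_mass[tr.t == 1.0][0])
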