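import numpy as np
import pytest

from glygolgi.glycans import parse_glycan
from glygolgi.golgi import (EnzymeProfile, GolgiConfig, GolgiSolver,
                            beta_compartment_fractions, load_default_config,
                            reaction_rate)
from glygolgi.network import Reaction, ReactionNetwork
from glygolgi.rules import KineticParameters, load_default_ruleset

TABLE5 = [
    (0.346, (0.340, 0.453, 0.188, 0.019)),   # ManI
    (0.479, (0.126, 0.419, 0.371, 0.085)),   # medial group
    (0.618, (0.029, 0.237, 0.465, 0.269)),   # GnTIII
    (0.812, (0.002, 0.041, 0.244, 0.713)),   # trans group
]


@pytest.mark.parametrize("mean,expected", TABLE5)
def test_beta_quartile_fractions_match_published_rows(mean, expected):
    # compare at the three printed decimals, within one unit in the last place
    # (the trans-group row prints 0.713 where the exact integral is 0.71412)
    f = beta_compartment_fractions(mean, 6.0, 4)
    assert f.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.abs(np.round(f, 3) - np.asarray(expected)) <= 0.001 + 1e-12)


def test_beta_fractions_symmetric_at_half():
    f = beta_compartment_fractions(0.5, 6.0, 4)
    assert f[0] == pytest.approx(f[3])
    assert f[1] == pytest.approx(f[2])


@pytest.mark.parametrize("mean", [0.0, 1.0, -0.2, 1.4])
def test_beta_fractions_reject_degenerate_means(mean):
    with pytest.raises(ValueError):
        beta_compartment_fractions(mean, 6.0, 4)


def test_rate_reduces_to_classical_michaelis_menten():
    # single substrate, donor-saturated, competition = S/Km
    kf, km, s, et = 7.0, 120.0, 55.0, 2.0
    r = reaction_rate(kf, km, 0.0, et, s, 1e9, competition_sum=s / km)
    assert r == pytest.approx(kf * et * s / (km + s))


def test_rate_independent_of_donor_when_saturated():
    r1 = reaction_rate(1.0, 100.0, 0.0, 1.0, 10.0, 5.0, 0.3)
    r2 = reaction_rate(1.0, 100.0, 0.0, 1.0, 10.0, 5000.0, 0.3)
    assert r1 == r2
    # Kmd > 0 with no donor present: rate is zero, not an error
    assert reaction_rate(1.0, 100.0, 50.0, 1.0, 10.0, 0.0, 0.3) == 0.0


def test_rate_half_maximal_at_km():
    assert reaction_rate(1.0, 1.0, 0.0, 1.0, 1.0, 1e9, 1.0) == pytest.approx(0.5)


def _toy_network(texts, reactions):
    structures = [parse_glycan(t) for t in texts]
    return ReactionNetwork(structures=structures, reactions=reactions, seeds=[0])


def _chain_config(inlet_text, competition="substrates"):
    return GolgiConfig(
        n_compartments=1, residence_times=(5.0,),
        enzyme_fractions={"GnTI": np.array([1.0]), "GnTII": np.array([1.0])},
        donor_concentrations={"UDP-GlcNAc": np.array([1e4])},
        total_glycan_concentration=500.0,
        inlet_composition={inlet_text: 1.0},
        competition=competition)


A_TEXT = "Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN"
B_TEXT = "GNb2Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN"
C_TEXT = "GNb2Ma3(GNb2Ma6)Mb4GNb4GN"


def test_cstr_two_species_chain_matches_closed_form(ruleset):
    # A -> B with competition only from A: the outlet solves a scalar quadratic
    kp = KineticParameters(kf=1.0, Km=200.0, Kmd=0.0)
    net = _toy_network([A_TEXT, B_TEXT],
                       [Reaction(8, "GnTI", 0, 1, kp, "UDP-GlcNAc", "UDP", kp)])
    cfg = _chain_config(A_TEXT)
    solver = GolgiSolver(net, ruleset, cfg)
    out = solver.solve(EnzymeProfile({"GnTI": 2.0}))
    a = out.concentrations[0, 0]
    # balance: a = a_in - tau * k * a / (1 + a/Km), with per-rule scale k = 2.0
    tau, k, km, a_in = 5.0, 2.0, 200.0, 500.0
    disc = (km + tau * k * km - a_in) ** 2 + 4 * km * a_in
    a_closed = (a_in - km - tau * k * km + np.sqrt(disc)) / 2.0
    assert a == pytest.approx(a_closed, rel=1e-10)
    assert out.concentrations[0].sum() == pytest.approx(500.0, rel=1e-12)


def test_symmetric_fork_splits_evenly(ruleset):
    kp = KineticParameters(kf=1.0, Km=150.0, Kmd=0.0)
    net = _toy_network(
        [A_TEXT, B_TEXT, C_TEXT],
        [Reaction(8, "GnTI", 0, 1, kp, "UDP-GlcNAc", "UDP", kp),
         Reaction(8, "GnTI", 0, 2, kp, "UDP-GlcNAc", "UDP", kp)])
    solver = GolgiSolver(net, ruleset, _chain_config(A_TEXT))
    out = solver.solve(EnzymeProfile({"GnTI": 1.0}))
    assert out.concentrations[0, 1] == pytest.approx(out.concentrations[0, 2])


def test_no_enzymes_outlet_equals_inlet(small_solver, profiles):
    zero = EnzymeProfile({e: 0.0 for e in profiles["Pro-5"].activities})
    out = small_solver.solve(zero)
    inlet = small_solver.inlet_vector()
    assert np.allclose(out.concentrations[-1], inlet)
    assert out.outlet_percent[small_solver.net.seeds[0]] == pytest.approx(100.0)


def test_conservation_and_nonnegativity(small_solver, profiles):
    out = small_solver.solve(profiles["Pro-5"])
    for k in range(4):
        assert out.concentrations[k].sum() == pytest.approx(500.0, rel=1e-8)
    assert np.all(out.concentrations >= 0.0)
    assert out.outlet_percent.sum() == pytest.approx(100.0, rel=1e-9)


def test_rate_time_scaling_invariance(ruleset, profiles, tiny_net):
    cfg1 = load_default_config()
    out1 = GolgiSolver(tiny_net, ruleset, cfg1).solve(profiles["Pro-5"])
    cfg2 = load_default_config()
    cfg2.residence_times = tuple(t / 2 for t in cfg1.residence_times)
    doubled = EnzymeProfile({e: 2 * a for e, a
                             in profiles["Pro-5"].activities.items()})
    out2 = GolgiSolver(tiny_net, ruleset, cfg2).solve(doubled)
    assert np.allclose(out1.outlet_percent, out2.outlet_percent, atol=1e-8)


def test_monotone_dose_response_on_direct_product(ruleset, profiles, tiny_net):
    cfg = load_default_config()
    solver = GolgiSolver(tiny_net, ruleset, cfg)
    gn_man5 = tiny_net.index[B_TEXT]
    base = profiles["Lec1"]  # low GnTI: the product responds strongly
    lo = solver.solve(base).outlet_percent[gn_man5]
    acts = dict(base.activities)
    acts["GnTI"] *= 2
    hi = solver.solve(EnzymeProfile(acts)).outlet_percent[gn_man5]
    assert hi >= lo


def test_dense_newton_equivalence(ruleset, profiles, tiny_net):
    """The sparse fixed-point solver agrees with a dense Newton solve."""
    from scipy.optimize import fsolve

    cfg = load_default_config()
    solver = GolgiSolver(tiny_net, ruleset, cfg)
    profile = profiles["Pro-5"]
    totals = {e: profile.activities.get(e, 0.0) for e in solver.enzyme_names}
    c_in = solver.inlet_vector()
    n = tiny_net.n_structures
    for k in range(2):  # two compartments are enough to exercise the path
        et = np.array([totals[e] * cfg.enzyme_fractions[e][k]
                       for e in solver.enzyme_names])
        pref = solver.rx_unit_rate * et[solver.rx_enz] * solver._donor_factor[k]
        tau = cfg.residence_times[k]

        def residual(c):
            comp = solver.comp_matrix @ c
            kappa = pref / (1.0 + comp[solver.rx_enz])
            rate = kappa * c[solver.rx_sub]
            net_prod = np.zeros(n)
            np.add.at(net_prod, solver.rx_prod, rate)
            np.add.at(net_prod, solver.rx_sub, -rate)
            return c - c_in - tau * net_prod

        c_sparse = solver.solve_compartment(c_in, {e: totals[e] *
                                                   cfg.enzyme_fractions[e][k]
                                                   for e in solver.enzyme_names},
                                            k)
        c_dense = fsolve(residual, c_in, xtol=1e-12)
        assert np.allclose(c_sparse, c_dense, rtol=1e-8, atol=1e-8)
        c_in = c_sparse


def test_config_validation():
    cfg = GolgiConfig(enzyme_fractions={"GnTI": np.array([0.5, 0.6])})
    with pytest.raises(ValueError):
        cfg.validate()
    cfg2 = GolgiConfig(residence_times=(0.0, 1.0))
    with pytest.raises(ValueError):
        cfg2.validate()
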