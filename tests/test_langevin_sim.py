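"""Ensemble simulations: pushed/diffusive/pulled width laws, phenotype
ordering, consumption-coupled bands, trail following."""

import numpy as np
import pytest
import scipy.stats

from bandwave import langevin_sim as ls
from bandwave import ou_model as ou
from bandwave.ou_model import Phenotype

EPS = 0.124
GRAD = dict(g0=1.636, g1=-0.4545, v_g=0.18)


def single_pop(chi=0.11, n=4000, z0=None):
    z_star = (GRAD["v_g"] - chi * GRAD["g0"]) / (chi * GRAD["g1"])
    return ls.PopulationSpec(
        n_particles=n,
        phenotypes=[(Phenotype(chi=chi, epsilon=EPS), 1.0)],
        initial_mean=z_star if z0 is None else z0, initial_sd=0.2)


def test_particles_conserved_and_tags_immutable():
    pop = ls.PopulationSpec(
        n_particles=500,
        phenotypes=[(Phenotype(chi=0.08, epsilon=EPS), 0.5),
                    (Phenotype(chi=0.14, epsilon=EPS), 0.5)])
    grad = ls.MovingGradientSpec(**GRAD)
    res = ls.simulate_population(pop, grad, dt=0.01, T=2.0, seed=0)
    assert res.z.shape[1] == 500
    assert len(res.chi) == 500
    assert set(np.unique(res.tags)) <= {0, 1}


def test_stability_guard_suggests_dt():
    pop = single_pop(chi=5.0)
    grad = ls.MovingGradientSpec(**GRAD)
    with pytest.raises(ValueError, match="dt"):
        ls.simulate_population(pop, grad, dt=0.1, T=1.0, seed=0)


def test_pushed_single_phenotype_reaches_ou_stationary_sd():
    chi = 0.11
    pop = single_pop(chi=chi)
    grad = ls.MovingGradientSpec(**GRAD)
    res = ls.simulate_population(pop, grad, dt=0.005, T=80.0, seed=1)
    sigma_pred = ou.stationary_sd(Phenotype(chi=chi, epsilon=EPS), GRAD["g1"])
    widths = ls.group_width_timeseries(res)
    late = widths[widths.t_min > 50.0]["sigma_mm"]
    assert abs(late.mean() - sigma_pred) < 0.05 * sigma_pred
    # bounded for all t after burn-in (pushed wave keeps the band compact)
    assert widths[widths.t_min > 20.0]["sigma_mm"].max() < 1.2 * sigma_pred


def test_diffusive_width_law_and_phenotype_separation():
    """Constant perceived gradient: sigma^2 grows like 2 D t, and two
    phenotypes separate at rate |chi1 - chi2| g0 — no compact diverse
    group without a decreasing gradient."""
    chi1, chi2 = 0.09, 0.13
    g0 = GRAD["g0"]
    pop = ls.PopulationSpec(
        n_particles=6000,
        phenotypes=[(Phenotype(chi=chi1, epsilon=EPS), 0.5),
                    (Phenotype(chi=chi2, epsilon=EPS), 0.5)],
        initial_mean=0.0, initial_sd=0.01)
    grad = ls.MovingGradientSpec(form="constant", g0=g0, g1=0.0,
                                 v_g=0.11 * g0)
    res = ls.simulate_population(pop, grad, dt=0.005, T=30.0, seed=2)
    # single-phenotype subensemble spreads diffusively: d sigma^2/dt = eps^2
    t = res.times
    for tag in (0, 1):
        var = res.z[:, res.tags == tag].var(axis=1, ddof=1)
        slope = np.polyfit(t, var, 1)[0]
        assert abs(slope - EPS**2) < 0.15 * EPS**2
    sep = (res.z[:, res.tags == 1].mean(axis=1)
           - res.z[:, res.tags == 0].mean(axis=1))
    rate = np.polyfit(t, sep, 1)[0]
    assert np.isclose(rate, (chi2 - chi1) * g0, rtol=0.1)


def test_pulled_width_diverges():
    pop = single_pop(chi=0.11, z0=0.0)
    pushed = ls.MovingGradientSpec(**GRAD)
    pulled = ls.MovingGradientSpec(g0=GRAD["g0"], g1=+0.4545,
                                   v_g=GRAD["v_g"])
    res_pull = ls.simulate_population(pop, pulled, dt=0.005, T=25.0, seed=3)
    widths = ls.group_width_timeseries(res_pull)
    sig = widths["sigma_mm"].to_numpy()
    t = widths["t_min"].to_numpy()
    # increasing beyond the diffusive envelope sigma0^2 + eps^2 t
    envelope = np.sqrt(sig[0] ** 2 + EPS**2 * t + 1e-12)
    assert sig[-1] > 2 * envelope[-1]
    assert np.all(np.diff(sig[t > 5.0]) > -0.01)


def test_gaussian_population_plateau_and_ordering():
    """A Gaussian chi population (0.11 +/- 0.02 mm^2/min) under a
    decreasing gradient converges to a finite total width with
    phenotype means perfectly ordered by chi."""
    pop = ls.PopulationSpec(n_particles=4000, chi_mean=0.11, chi_sd=0.02,
                            epsilon=EPS, initial_mean=0.0, initial_sd=0.3)
    grad = ls.MovingGradientSpec(**GRAD)
    res = ls.simulate_population(pop, grad, dt=0.005, T=120.0, seed=4,
                                 record_every=400)
    widths = ls.group_width_timeseries(res)
    late = widths[widths.t_min >= 60.0]["sigma_mm"]
    # width converges: no trend in the second half
    first, second = late.iloc[:len(late) // 2], late.iloc[len(late) // 2:]
    assert abs(second.mean() - first.mean()) < 0.05 * first.mean()
    # chi-quintile means are strictly ordered
    q = np.quantile(res.chi, [0.2, 0.4, 0.6, 0.8])
    groups = np.digitize(res.chi, q)
    final = res.z[-1]
    means = [final[groups == g].mean() for g in range(5)]
    assert np.all(np.diff(means) > 0)
    rho = scipy.stats.spearmanr(np.arange(5), means).statistic
    assert rho > 1.0 - 1e-9


def test_subpopulation_summary_matches_closed_form():
    chis = (0.08, 0.11, 0.155)
    pop = ls.PopulationSpec(
        n_particles=6000,
        phenotypes=[(Phenotype(chi=c, epsilon=EPS), 1 / 3) for c in chis],
        initial_mean=0.0, initial_sd=0.3)
    grad = ls.MovingGradientSpec(**GRAD)
    # the slowest phenotype relaxes with 1/r ~ 27 min: simulate well past it
    res = ls.simulate_population(pop, grad, dt=0.005, T=250.0, seed=5,
                                 record_every=1000)
    summary = ls.subpopulation_summary(res, burn_in=150.0)
    table = ou.phenotype_order([Phenotype(chi=c, epsilon=EPS) for c in chis],
                               **GRAD)
    for (_, sim), (_, pred) in zip(summary.iterrows(), table.iterrows()):
        assert abs(sim.mean_z_mm - pred.z_star_mm) < max(4 * sim.mean_z_sem,
                                                         0.05)
        assert abs(sim.sigma_mm - pred.sigma_mm) < 0.1 * pred.sigma_mm
    rho = scipy.stats.spearmanr(summary.chi, summary.mean_z_mm).statistic
    assert rho > 1.0 - 1e-9


def test_comoving_deterministic_particles_keep_width():
    pop = ls.PopulationSpec(
        n_particles=100,
        phenotypes=[(Phenotype(chi=0.11, epsilon=1e-9), 1.0)],
        initial_mean=(GRAD["v_g"] - 0.11 * GRAD["g0"]) / (0.11 * GRAD["g1"]),
        initial_sd=0.0)
    grad = ls.MovingGradientSpec(**GRAD)
    res = ls.simulate_population(pop, grad, dt=0.005, T=5.0, seed=6)
    widths = ls.group_width_timeseries(res)
    assert widths["sigma_mm"].max() < 1e-6


# --- consumption-coupled ----------------------------------------------------


def test_no_consumption_no_band():
    pop = ls.PopulationSpec(
        n_particles=1500,
        phenotypes=[(Phenotype(chi=0.11, epsilon=EPS), 1.0)],
        initial_mean=3.0, initial_sd=0.3)
    res = ls.simulate_with_consumption(pop, s0=200.0, k=0.0, domain=(0, 14),
                                       dt=0.01, T=30.0, seed=7)
    # uniform attractant -> no gradient forms -> diffusive spreading
    np.testing.assert_allclose(res.S_snapshots[-1], 200.0, rtol=1e-6)
    widths = ls.group_width_timeseries(res)
    var = widths["sigma_mm"] ** 2
    slope = np.polyfit(widths["t_min"], var, 1)[0]
    assert abs(slope - EPS**2) < 0.25 * EPS**2


def test_consumption_travelling_band():
    """Consumption generates a gradient the band then chases: the density
    peak advances linearly (R^2 > 0.99) after a formation transient."""
    pop = ls.PopulationSpec(
        n_particles=2000,
        phenotypes=[(Phenotype(chi=0.11, epsilon=EPS), 1.0)],
        initial_mean=3.0, initial_sd=0.3)
    res = ls.simulate_with_consumption(pop, s0=200.0, k=0.02, domain=(0, 14),
                                       dt=0.01, T=40.0, seed=2)
    v, r2, peaks = ls.measure_group_velocity(res, burn_in=15.0)
    assert v > 0.05
    assert r2 > 0.99
    assert res.meta["n_leaked"] < 0.5 * pop.n_particles


def test_consumption_orders_two_phenotypes():
    pop = ls.PopulationSpec(
        n_particles=2000,
        phenotypes=[(Phenotype(chi=0.09, epsilon=EPS, label="lo"), 0.5),
                    (Phenotype(chi=0.14, epsilon=EPS, label="hi"), 0.5)],
        initial_mean=1.5, initial_sd=0.3)
    res = ls.simulate_with_consumption(pop, s0=200.0, k=0.015, domain=(0, 12),
                                       dt=0.01, T=50.0, seed=3)
    for i in range(len(res.times) - 3, len(res.times)):
        act = res.active_at(i)
        lo = res.z[i, act & (res.tags == 0)].mean()
        hi = res.z[i, act & (res.tags == 1)].mean()
        assert hi > lo + 0.3     # stable ordering in the emergent band


# --- trail following --------------------------------------------------------


def test_trail_zero_secretion_is_diffusion():
    pop = ls.PopulationSpec(
        n_particles=3000,
        phenotypes=[(Phenotype(chi=0.11, epsilon=EPS), 1.0)],
        initial_mean=6.0, initial_sd=0.01)
    res = ls.simulate_trail_following(pop, beta=0.0, domain=(0, 12),
                                      dt=0.01, T=20.0, seed=8)
    assert res.S_snapshots[-1].max() == 0.0
    widths = ls.group_width_timeseries(res)
    slope = np.polyfit(widths["t_min"], widths["sigma_mm"] ** 2, 1)[0]
    assert abs(slope - EPS**2) < 0.2 * EPS**2


def test_trail_linear_response_in_beta():
    """With decay and negligible chemotaxis the quasi-steady secreted field
    is linear in the secretion rate: doubling beta doubles S."""
    def run(beta):
        pop = ls.PopulationSpec(
            n_particles=2000,
            phenotypes=[(Phenotype(chi=1e-6, epsilon=EPS), 1.0)],
            initial_mean=6.0, initial_sd=0.5)
        return ls.simulate_trail_following(
            pop, beta=beta, decay=0.5, domain=(0, 12), dt=0.01, T=15.0,
            seed=9)
    s1 = run(0.01).S_snapshots[-1]
    s2 = run(0.02).S_snapshots[-1]
    mask = s1 > 0.1 * s1.max()
    np.testing.assert_allclose(s2[mask] / s1[mask], 2.0, rtol=0.05)


def test_trail_group_advances_with_ordered_phenotypes():
    """A secreting group started at a wall surfs the leading edge of its
    own saturated trail: the group advances and the phenotype means stay
    strictly ordered, with high-chi cells held closest to the accumulated
    signal (the mirror of the consumption ordering)."""
    pop = ls.PopulationSpec(
        n_particles=1500,
        phenotypes=[(Phenotype(chi=0.06, epsilon=EPS, label="lo"), 1 / 3),
                    (Phenotype(chi=0.11, epsilon=EPS, label="mid"), 1 / 3),
                    (Phenotype(chi=0.18, epsilon=EPS, label="hi"), 1 / 3)],
        initial_mean=0.5, initial_sd=0.2)
    res = ls.simulate_trail_following(pop, beta=0.05, domain=(0, 15),
                                      dt=0.01, T=90.0, seed=1)
    i30 = int(np.argmin(np.abs(res.times - 30.0)))
    assert res.z[-1].mean() > res.z[i30].mean() + 0.1   # group advances
    means = [res.z[-1, res.tags == tg].mean() for tg in (0, 1, 2)]
    rho = scipy.stats.spearmanr([0.06, 0.11, 0.18], means).statistic
    assert rho == -1.0
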