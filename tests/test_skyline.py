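import math

import numpy as np
import pytest

from paleodemo import (Genealogy, McmcConfig, SkylineSampler,
                       coalescent_log_density, effective_sample_size,
                       paper_scale_config, run_mcmc, sequence_log_likelihood,
                       simulate_dataset, simulate_genealogy,
                       suggest_prior_bounds)
from paleodemo.scenario import DemographicScenario
from paleodemo.substitution import HKYModel, jc_model, jc_p_different

from conftest import random_clean_alignment


def pair_genealogy(t: float, deme: int = 0) -> Genealogy:
    return Genealogy(2, np.array([2, 2, -1]), np.array([0.0, 0.0, t]),
                     np.array([deme, deme, deme]))


def naive_coalescent_density(gen: Genealogy, scen: DemographicScenario) -> float:
    """Independent interval-walk oracle on a fine time grid."""
    events = []
    for v in range(gen.n_tips, gen.n_nodes):
        events.append((float(gen.time[v]), "coal", int(gen.node_deme[v])))
    for (t, v, a, b) in gen.migration_events():
        events.append((float(t), "mig", (a, b)))
    events.sort(key=lambda e: e[0])
    k = [0] * scen.D
    for d in gen.node_deme[:gen.n_tips]:
        k[d] += 1
    logp = 0.0
    t_prev = 0.0
    for (t, kind, data) in events:
        # Riemann integration of the waiting-time exponent
        steps = 2000
        dt = (t - t_prev) / steps
        for s in range(steps):
            mid = t_prev + (s + 0.5) * dt
            e = scen.epoch_at(mid)
            lam = sum(k[d] * (k[d] - 1) / scen.theta[d, e] for d in range(scen.D))
            lam += sum(k[d] * scen.mig[:, d, e].sum() for d in range(scen.D))
            logp -= lam * dt
        e = scen.epoch_at(t)
        if kind == "coal":
            logp += math.log(2.0 / scen.theta[data, e])
            k[data] -= 1
        else:
            a, b = data
            logp += math.log(scen.mig[b, a, e])
            k[a] -= 1
            k[b] += 1
        t_prev = t
    return logp


class TestCoalescentLogDensity:
    def test_pair_closed_form(self):
        scen = DemographicScenario.constant(0.01)
        t = 0.004
        expected = math.log(2 / 0.01) - 2 * t / 0.01
        assert coalescent_log_density(pair_genealogy(t), scen) == pytest.approx(expected)

    def test_theta_doubling_changes_by_analytic_amount(self):
        t = 0.006
        gen = pair_genealogy(t)
        ld1 = coalescent_log_density(gen, DemographicScenario.constant(0.01))
        ld2 = coalescent_log_density(gen, DemographicScenario.constant(0.02))
        # log(2/theta) - 2t/theta: difference = -log 2 + 2t/0.02
        assert ld2 - ld1 == pytest.approx(-math.log(2) + 2 * t * (1 / 0.01 - 1 / 0.02))

    def test_matches_naive_interval_walk(self):
        scen = DemographicScenario.piecewise(
            [0.0, 0.01], [[0.01, 0.03], [0.02, 0.02]],
            mig=np.stack([np.array([[0, 2.0], [3.0, 0]]),
                          np.array([[0, 1.0], [4.0, 0]])], axis=2))
        rng = np.random.default_rng(0)
        for _ in range(5):
            gen = simulate_genealogy(scen, [3, 3], rng)
            fast = coalescent_log_density(gen, scen)
            slow = naive_coalescent_density(gen, scen)
            assert fast == pytest.approx(slow, abs=1e-3)

    def test_inconsistent_event_is_minus_inf(self):
        scen = DemographicScenario.constant([0.01, 0.01], mig=0.0)
        gen = simulate_genealogy(DemographicScenario.constant([0.01, 0.01], mig=2.0),
                                 [2, 2], seed=1)
        # migration events present but M = 0 under the evaluated scenario
        if gen.migration_events():
            assert coalescent_log_density(gen, scen) == -math.inf


class TestSequenceLogLikelihood:
    def test_identical_sequences_zero_height_tree(self):
        sim = simulate_dataset(DemographicScenario.constant(0.01), [4], 30, 0)
        gen = sim.genealogy
        gen.time[gen.n_tips:] = 0.0
        aln = sim.alignment
        aln.seqs[:] = aln.seqs[0]
        model = HKYModel(kappa=2.0, freqs=(0.4, 0.3, 0.2, 0.1))
        expected = sum(math.log(model.stationary[c]) for c in aln.seqs[0])
        assert sequence_log_likelihood(aln, gen, model) == pytest.approx(expected)

    def test_two_taxa_jc_closed_form(self):
        sim = simulate_dataset(DemographicScenario.constant(0.01), [2], 200, 1)
        gen, aln = sim.genealogy, sim.alignment
        d = 2 * gen.tmrca
        p = jc_p_different(d)
        diffs = int((aln.seqs[0] != aln.seqs[1]).sum())
        expected = (diffs * math.log(p / 3) + (aln.L - diffs) * math.log(1 - p)
                    + aln.L * math.log(0.25))
        assert sequence_log_likelihood(aln, gen, jc_model()) == pytest.approx(expected)

    def test_matches_uncompressed_naive_pruning(self):
        rng = np.random.default_rng(3)
        sim = simulate_dataset(DemographicScenario.constant(0.02), [4], 25, 7)
        gen = sim.genealogy
        aln = random_clean_alignment(rng, 4, 25)
        model = HKYModel(kappa=2.5, freqs=(0.3, 0.2, 0.3, 0.2))

        def naive(aln, gen, model):
            kids = gen.children_map()
            total = 0.0
            for site in range(aln.L):
                def partial(v):
                    if v < gen.n_tips:
                        vec = np.zeros(4)
                        vec[aln.seqs[v, site]] = 1.0
                        return vec
                    a, b = kids[v]
                    Pa = model.transition_matrix(gen.branch_length(a))
                    Pb = model.transition_matrix(gen.branch_length(b))
                    return (Pa @ partial(a)) * (Pb @ partial(b))
                total += math.log(float(model.stationary @ partial(gen.root)))
            return total

        fast = sequence_log_likelihood(aln, gen, model)
        assert fast == pytest.approx(naive(aln, gen, model), abs=1e-10)

    def test_rejects_unfiltered_alignment(self):
        from paleodemo import SequenceAlignment
        aln = SequenceAlignment.from_strings(["a", "b"], ["AC-T", "ACGT"])
        gen = pair_genealogy(0.01)
        with pytest.raises(ValueError, match="gap"):
            sequence_log_likelihood(aln, gen)


class TestEffectiveSampleSize:
    def test_iid_draws_near_n(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        assert effective_sample_size(x) == pytest.approx(4000, rel=0.15)

    def test_ar1_analytic_reduction(self):
        rng = np.random.default_rng(1)
        phi = 0.9
        n = 40_000
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_constant_series_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            assert effective_sample_size(np.ones(100)) == 100.0


class TestMcmcConfig:
    def test_burn_in_bound(self):
        with pytest.raises(ValueError, match="burn_in"):
            McmcConfig(steps=100, burn_in=100)

    def test_heating_scheme_validation(self):
        with pytest.raises(ValueError, match="temperatures"):
            McmcConfig(heat_temperatures=(1.5, 3.0))
        with pytest.raises(ValueError, match="temperatures"):
            McmcConfig(heat_temperatures=(1.0, 3.0, 1.5))

    def test_paper_scale_preset(self):
        cfg = paper_scale_config()
        assert cfg.steps == 16_000_000
        assert cfg.burn_in == 8_000_000
        assert cfg.thin == 200
        assert cfg.heat_temperatures == (1.0, 1.5, 3.0, 1_000_000.0)
        assert cfg.ess_threshold == 10_000.0


@pytest.fixture(scope="module")
def small_result():
    sim = simulate_dataset(DemographicScenario.constant(0.01), [8], 300, 42)
    cfg = McmcConfig(steps=4000, burn_in=1000, thin=5,
                     theta_bounds=(1e-3, 0.1), n_time_bins=8,
                     time_horizon=0.03, seed=3, kappa=1.0)
    return run_mcmc(sim.alignment, cfg), sim


class TestRunMcmc:
    def test_seed_determinism(self, small_result):
        res, sim = small_result
        cfg = McmcConfig(steps=4000, burn_in=1000, thin=5,
                         theta_bounds=(1e-3, 0.1), n_time_bins=8,
                         time_horizon=0.03, seed=3, kappa=1.0)
        res2 = run_mcmc(sim.alignment, cfg)
        assert np.array_equal(res.trace["theta_1_e0"], res2.trace["theta_1_e0"])

    def test_posterior_in_prior_bounds(self, small_result):
        res, _ = small_result
        th = res.trace["theta_1_e0"]
        assert th.between(1e-3, 0.1).all()

    def test_skyline_contract(self, small_result):
        res, _ = small_result
        sky = res.skyline.table
        t1 = sky[sky["parameter"] == "theta_1"]
        assert len(t1) == 8
        assert (t1["n"] >= 0).all()
        assert (np.diff(t1["bin_start"]) > 0).all()
        usable = t1[t1["n"] > 0]
        assert usable["median"].between(1e-3, 0.1).all()
        # recent bins always overlap the genealogy
        assert t1.iloc[0]["n"] > 0

    def test_heated_chains_swap(self):
        sim = simulate_dataset(DemographicScenario.constant(0.01), [6], 200, 9)
        cfg = McmcConfig(steps=2000, burn_in=500, thin=5,
                         heat_temperatures=(1.0, 1.5, 3.0),
                         theta_bounds=(1e-3, 0.1), n_time_bins=5,
                         time_horizon=0.03, seed=4, kappa=1.0)
        res = run_mcmc(sim.alignment, cfg)
        assert not math.isnan(res.acceptance["swap"])

    def test_prior_only_mean_matches_uniform_prior(self):
        sim = simulate_dataset(DemographicScenario.constant(0.01), [5], 100, 11)
        lo, hi = 0.004, 0.04
        cfg = McmcConfig(steps=20_000, burn_in=2000, thin=10,
                         theta_bounds=(lo, hi), n_time_bins=5,
                         time_horizon=0.03, seed=5, sample_prior_only=True)
        res = run_mcmc(sim.alignment, cfg)
        th = res.trace["theta_1_e0"].to_numpy()
        mc_se = th.std() / math.sqrt(max(res.ess["theta_1_e0"], 1.0))
        assert abs(th.mean() - (lo + hi) / 2) < 3.5 * mc_se


class TestSuggestPriorBounds:
    def test_theta_bracket_around_watterson(self):
        from paleodemo.diversity import watterson_theta
        sim = simulate_dataset(DemographicScenario.constant(0.01), [10], 400, 2)
        (lo, hi), (mlo, mhi) = suggest_prior_bounds(sim.alignment)
        tw = watterson_theta(sim.alignment)
        assert lo == pytest.approx(tw / 10) and hi == pytest.approx(tw * 10)
        assert mlo == 0.0 and mhi > 0

    def test_two_deme_m_bounds_positive(self):
        sim = simulate_dataset(
            DemographicScenario.constant([0.01, 0.01], mig=2.0), [6, 6], 400, 3)
        _, (mlo, mhi) = suggest_prior_bounds(sim.alignment)
        assert mlo == 0.0 and mhi > 0


class TestSkylineSampler:
    def test_sklearn_surface_and_fit(self):
        sim = simulate_dataset(DemographicScenario.constant(0.01), [6], 200, 5)
        est = SkylineSampler(steps=1500, burn_in=500, thin=5,
                             theta_bounds=(1e-3, 0.1), n_time_bins=5,
                             time_horizon=0.03, seed=1)
        assert est.get_params()["steps"] == 1500
        est.set_params(steps=1200, burn_in=400)
        est.fit(sim.alignment)
        assert hasattr(est, "trace_") and hasattr(est, "skyline_")
        assert est.acceptance_["param"] > 0

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        est = SkylineSampler(steps=1000, burn_in=100, seed=2)
        assert clone(est).get_params() == est.get_params()
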