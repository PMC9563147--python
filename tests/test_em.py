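import numpy as np
import pandas as pd
import pytest

from tcistate import (DriverActivationModel, SimulationConfig, generate_cohort,
                      truth_catalog)
from tcistate.catalog import DriverCatalog


def _manual_catalog(edges):
    drivers = sorted({d for d, _ in edges})
    targets = sorted({g for _, g in edges})
    return DriverCatalog(
        drivers=pd.DataFrame({"n_hosting": 0, "n_called": 0, "call_rate": 1.0},
                             index=pd.Index(drivers, name="gene")),
        target_degs=pd.DataFrame({"n_deg": 0, "n_targeted": 0, "call_rate": 1.0},
                                 index=pd.Index(targets, name="gene")),
        retained_edges=pd.DataFrame(sorted(edges), columns=["driver", "target"])
        .assign(support=0),
    )


def _toy_model(n=100, n_alt=30, mu_shift=2.0, seed=0, **kw):
    """One driver, one target; expression shifted where the SGA is present."""
    rng = np.random.default_rng(seed)
    tumors = [f"T{i}" for i in range(n)]
    sga = pd.DataFrame({"D": [1] * n_alt + [0] * (n - n_alt)}, index=tumors)
    x = rng.normal(0, 1.0, n) + mu_shift * sga["D"].to_numpy()
    expr = pd.DataFrame({"G": x}, index=tumors)
    cat = _manual_catalog({("D", "G")})
    return DriverActivationModel(expr, cat, sga, **kw), sga, expr


class TestInitialize:
    def test_prior_is_alteration_fraction(self):
        model, _, _ = _toy_model(n=100, n_alt=30)
        model.initialize()
        assert model.priors_[0] == pytest.approx(0.3)

    def test_emissions_are_partition_moments(self):
        model, sga, expr = _toy_model(n=200, n_alt=80, mu_shift=2.0)
        model.initialize()
        on = expr["G"][sga["D"] == 1]
        off = expr["G"][sga["D"] == 0]
        assert model._mu1[0][0] == pytest.approx(on.mean())
        assert model._mu0[0][0] == pytest.approx(off.mean())
        assert model._sd1[0][0] == pytest.approx(on.std(ddof=0))

    def test_all_tumors_altered_falls_back_to_pooled(self):
        model, _, expr = _toy_model(n=50, n_alt=50)
        model.initialize()
        assert model.priors_[0] == pytest.approx(1.0)
        # inactive side has no members: pooled moments, floored SD
        assert model._mu0[0][0] == pytest.approx(expr["G"].mean())
        assert model._sd0[0][0] >= model.sigma_min

    def test_driver_without_expressed_targets_rejected(self):
        rng = np.random.default_rng(0)
        sga = pd.DataFrame({"D": [1, 0]}, index=["T1", "T2"])
        expr = pd.DataFrame({"OTHER": rng.normal(size=2)}, index=["T1", "T2"])
        cat = _manual_catalog({("D", "MISSING")})
        with pytest.raises(ValueError, match="D"):
            DriverActivationModel(expr, cat, sga)


class TestESteps:
    def test_equal_emissions_give_posterior_half_and_active_state(self):
        model, _, _ = _toy_model(n=40, n_alt=20, mu_shift=0.0)
        model.initialize()
        model._mu1[0][:] = 0.0
        model._mu0[0][:] = 0.0
        model._sd1[0][:] = 1.0
        model._sd0[0][:] = 1.0
        model.priors_[:] = 0.5
        post = model.e_step()
        assert np.allclose(post, 0.5)
        assert (model.states_ == 1).all()  # the >= 0.5 rule maps ties to active

    def test_posterior_arithmetic_with_known_density_ratio(self):
        # prior 0.3, one target with active:inactive density ratio 7
        model, sga, expr = _toy_model(n=10, n_alt=3)
        model.initialize()
        model.priors_[:] = 0.3
        model._sd1[0][:] = 1.0
        model._sd0[0][:] = 1.0
        model._mu1[0][:] = 1.0
        model._mu0[0][:] = 0.0
        x = np.log(7.0) + 0.5  # density ratio exp(x*d - d^2/2) = 7 at d = 1
        model._X[0] = np.full((10, 1), x)
        post = model.e_step()
        assert np.allclose(post, 0.3 * 7 / (0.3 * 7 + 0.7))

    def test_separated_emissions_recover_generating_state(self):
        cfg = SimulationConfig(n_tumors=200, n_drivers=3, n_passenger_sgas=2,
                               n_target_degs_per_driver=4, n_noise_genes=5,
                               crosstalk_rate=0.2, effect_size=10.0,
                               n_subtypes=1, subtype_assoc_strength=0.0,
                               survival_scale_per_subtype=(400.0,), seed=3)
        c = generate_cohort(cfg)
        model = DriverActivationModel(c.expression, truth_catalog(c.truth, c.sga),
                                      c.sga)
        model.initialize()
        post = model.e_step()
        truth = c.truth.true_protein_states.values
        assert np.allclose(np.round(post), truth)
        # once EM refines the emissions the posteriors saturate
        res = model.fit()
        final = res.states_prob.values
        assert np.minimum(final, 1 - final).max() < 1e-6
        assert (res.states.values == truth).all()


class TestMStep:
    def test_unchanged_states_are_a_fixed_point(self):
        model, _, _ = _toy_model(n=120, n_alt=40, mu_shift=3.0)
        model.initialize()
        before = (model.priors_.copy(), model._mu1[0].copy(), model._sd0[0].copy())
        model.m_step()  # states still equal initialization
        assert model.priors_[0] == pytest.approx(before[0][0])
        assert model._mu1[0][0] == pytest.approx(before[1][0])
        assert model._sd0[0][0] == pytest.approx(before[2][0])

    def test_moment_recovery_from_balanced_split(self):
        n = 200
        tumors = [f"T{i}" for i in range(n)]
        sga = pd.DataFrame({"D": [1] * 100 + [0] * 100}, index=tumors)
        expr = pd.DataFrame({"G": [2.0] * 100 + [0.0] * 100}, index=tumors)
        model = DriverActivationModel(expr, _manual_catalog({("D", "G")}), sga)
        model.initialize()
        assert model._mu1[0][0] == pytest.approx(2.0)
        assert model._mu0[0][0] == pytest.approx(0.0)

    def test_soft_weights_reduce_to_hard_at_binary_posteriors(self):
        hard, sga, expr = _toy_model(n=80, n_alt=30, mu_shift=3.0, mode="hard")
        soft, _, _ = _toy_model(n=80, n_alt=30, mu_shift=3.0, mode="soft")
        for m in (hard, soft):
            m.initialize()
            m.posteriors_ = m._sga.copy()  # degenerate {0,1} posteriors
            m.states_ = m._sga.copy()
            m.m_step()
        assert hard._mu1[0][0] == pytest.approx(soft._mu1[0][0])
        assert hard._sd0[0][0] == pytest.approx(soft._sd0[0][0])
        assert hard.priors_[0] == pytest.approx(soft.priors_[0])


class TestFit:
    def test_zero_crosstalk_large_effect_returns_sga(self):
        cfg = SimulationConfig(n_tumors=300, n_drivers=5, n_passenger_sgas=5,
                               n_target_degs_per_driver=8, n_noise_genes=10,
                               crosstalk_rate=0.0, effect_size=5.0,
                               n_subtypes=1, subtype_assoc_strength=0.0,
                               survival_scale_per_subtype=(400.0,), seed=11)
        c = generate_cohort(cfg)
        res = DriverActivationModel(c.expression, truth_catalog(c.truth, c.sga),
                                    c.sga).fit()
        assert res.converged
        assert (res.states.values == c.sga[res.states.columns].values).all()

    def test_infinite_tolerance_stops_after_one_iteration(self):
        model, _, _ = _toy_model(n=60, n_alt=20, tol=np.inf)
        res = model.fit()
        assert res.n_iterations == 1
        assert res.converged

    def test_soft_mode_loglik_non_decreasing(self, small_cohort):
        c = small_cohort
        res = DriverActivationModel(c.expression, truth_catalog(c.truth, c.sga),
                                    c.sga, mode="soft").fit()
        ll = np.asarray(res.loglik_path)
        assert (np.diff(ll) >= -1e-8).all()

    def test_state_recovery_with_crosstalk(self, small_cohort):
        from sklearn.metrics import balanced_accuracy_score

        c = small_cohort
        res = DriverActivationModel(c.expression, truth_catalog(c.truth, c.sga),
                                    c.sga).fit()
        truth = c.truth.true_protein_states
        ba = balanced_accuracy_score(truth.values.ravel(), res.states.values.ravel())
        assert ba >= 0.9

    def test_posteriors_invariant_to_target_order(self, small_cohort):
        c = small_cohort
        cat = truth_catalog(c.truth, c.sga)
        flipped = DriverCatalog(
            drivers=cat.drivers,
            target_degs=cat.target_degs.iloc[::-1],
            retained_edges=cat.retained_edges.iloc[::-1].reset_index(drop=True),
        )
        a = DriverActivationModel(c.expression, cat, c.sga).fit()
        b = DriverActivationModel(c.expression, flipped, c.sga).fit()
        assert np.allclose(a.states_prob.values, b.states_prob.values)

    def test_non_convergence_is_reported_not_fatal(self, small_cohort):
        c = small_cohort
        res = DriverActivationModel(c.expression, truth_catalog(c.truth, c.sga),
                                    c.sga, max_iter=1, tol=1e-12).fit()
        assert not res.converged
        assert res.n_iterations == 1
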