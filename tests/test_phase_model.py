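import numpy as np
import pytest

import paleochron as pc
from paleochron.phase_model import (
    InitializationError,
    ModelBuildError,
    PhaseSpec,
    SequenceSpec,
    convergence_diagnostics,
    infer_order,
    log_posterior_density,
    sample_posterior,
)

from oracles import autocorr_ess, batch_median_mcse, ks_distance, phase_grid_oracle


def _gauss_density(curve, age, err):
    return pc.calibrate_radiocarbon(pc.GeochronDate.symmetric(age, err), curve)


def one_phase_model(curve, specs):
    densities = [_gauss_density(curve, a, e) for a, e in specs]
    return SequenceSpec(phases=[PhaseSpec("au1", densities)], ordered=False)


class TestInferOrder:
    def test_depths_define_order(self):
        cu = pc.CollectionUnit(id="c", analysis_units=[
            pc.AnalysisUnit(id="a", depth=1.5, dates=[pc.GeochronDate.symmetric(5000, 50)]),
            pc.AnalysisUnit(id="b", depth=1.0, dates=[pc.GeochronDate.symmetric(4000, 50)]),
            pc.AnalysisUnit(id="c", depth=0.5, dates=[pc.GeochronDate.symmetric(3000, 50)]),
        ])
        ordered, ids = infer_order(cu)
        assert ordered and ids == ["a", "b", "c"]  # deepest first

    def test_no_metadata_unordered(self):
        cu = pc.CollectionUnit(id="c", analysis_units=[
            pc.AnalysisUnit(id="a", dates=[pc.GeochronDate.symmetric(5000, 50)]),
            pc.AnalysisUnit(id="b", dates=[pc.GeochronDate.symmetric(4000, 50)]),
        ])
        ordered, _ = infer_order(cu)
        assert not ordered

    def test_duplicate_depths_unordered_with_warning(self):
        cu = pc.CollectionUnit(id="c", analysis_units=[
            pc.AnalysisUnit(id="a", depth=1.0, dates=[pc.GeochronDate.symmetric(5000, 50)]),
            pc.AnalysisUnit(id="b", depth=1.0, dates=[pc.GeochronDate.symmetric(4000, 50)]),
        ])
        with pytest.warns(UserWarning):
            ordered, _ = infer_order(cu)
        assert not ordered

    def test_declared_order_wins(self):
        cu = pc.CollectionUnit(id="c", declared_order=["b", "a"], analysis_units=[
            pc.AnalysisUnit(id="a", dates=[pc.GeochronDate.symmetric(5000, 50)]),
            pc.AnalysisUnit(id="b", dates=[pc.GeochronDate.symmetric(4000, 50)]),
        ])
        ordered, ids = infer_order(cu)
        assert ordered and ids == ["b", "a"]


class TestBuildCollectionModel:
    def test_selby_shape(self, selby_cu, intcal20):
        model = pc.build_collection_model(selby_cu, intcal20)
        assert not model.ordered
        assert len(model.phases) == 2
        assert all(ph.n_events == 2 for ph in model.phases)

    def test_undated_unit_excluded(self, identity_curve):
        cu = pc.CollectionUnit(id="c", analysis_units=[
            pc.AnalysisUnit(id="dated", dates=[pc.GeochronDate.symmetric(5000, 50)]),
            pc.AnalysisUnit(id="undated"),
        ])
        model = pc.build_collection_model(cu, identity_curve)
        assert [ph.analysis_unit_ref for ph in model.phases] == ["dated"]

    def test_no_dated_units_raises(self, identity_curve):
        cu = pc.CollectionUnit(id="c", analysis_units=[pc.AnalysisUnit(id="u")])
        with pytest.raises(ModelBuildError):
            pc.build_collection_model(cu, identity_curve)

    def test_mixed_radiocarbon_and_tl(self, identity_curve):
        cu = pc.CollectionUnit(id="c", analysis_units=[
            pc.AnalysisUnit(id="m", dates=[
                pc.GeochronDate.symmetric(5000, 50),
                pc.GeochronDate.symmetric(5200, 300, kind="calendar"),
            ]),
        ])
        model = pc.build_collection_model(cu, identity_curve)
        assert model.phases[0].n_events == 2


class TestLogPosterior:
    def test_event_outside_boundaries(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50)])
        assert log_posterior_density(model, [(np.array([5000.0]), 4990.0, 4800.0)]) == -np.inf

    def test_flat_exponent_power_law(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50)])
        lp1 = log_posterior_density(model, [(np.array([5000.0]), 5100.0, 4900.0)], span_prior_exponent="flat")
        lp2 = log_posterior_density(model, [(np.array([5000.0]), 5200.0, 4800.0)], span_prior_exponent="flat")
        # density proportional to (alpha - beta)^(-1) on the feasible wedge
        assert lp1 - lp2 == pytest.approx(np.log(400.0 / 200.0))

    def test_hand_computed_two_event_sum(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50), (5200, 50)])
        t = np.array([5020.0, 5180.0])
        alpha, beta = 5300.0, 4950.0
        lp = log_posterior_density(model, [(t, alpha, beta)], span_prior_exponent=1.0)
        d1, d2 = model.phases[0].event_densities
        expected = (
            np.log(np.interp(5020.0, d1.grid, d1.p))
            + np.log(np.interp(5180.0, d2.grid, d2.p))
            + (1.0 - 2.0) * np.log(alpha - beta)
        )
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_ordered_constraint(self, identity_curve):
        d_old = [_gauss_density(identity_curve, 6000, 50)]
        d_new = [_gauss_density(identity_curve, 4000, 50)]
        model = SequenceSpec(
            phases=[PhaseSpec("old", d_old), PhaseSpec("new", d_new)],
            ordered=True, order=[0, 1],
        )
        good = [(np.array([6000.0]), 6100.0, 5900.0), (np.array([4000.0]), 4100.0, 3900.0)]
        bad = [(np.array([6000.0]), 6100.0, 4050.0), (np.array([4000.0]), 4100.0, 3900.0)]
        assert np.isfinite(log_posterior_density(model, good))
        assert log_posterior_density(model, bad) == -np.inf

    def test_improper_exponent_rejected(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50)])
        with pytest.raises(ValueError):
            log_posterior_density(model, [(np.array([5000.0]), 5100.0, 4900.0)], span_prior_exponent=-1.5)


class TestSamplePosterior:
    def test_single_date_limit_matches_calibrated_density(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50)])
        s = sample_posterior(model, n_iter=30_000, burn_in=5_000, thin=5, chains=2, seed=7)
        dens = model.phases[0].event_densities[0]
        ks = ks_distance(s.event_draws(0, 0), dens.grid.astype(float), dens.p)
        assert ks < 0.05

    def test_containment_every_draw(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50), (5400, 60)])
        s = sample_posterior(model, n_iter=4_000, burn_in=1_000, thin=2, chains=2, seed=3)
        t = s.events[0]
        assert (s.beta[0][None, :, :] <= t).all()
        assert (t <= s.alpha[0][None, :, :]).all()

    def test_stochastic_dominance_of_quantiles(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50), (5400, 60)])
        s = sample_posterior(model, n_iter=6_000, burn_in=1_000, thin=2, chains=2, seed=9)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            qa = np.quantile(s.alpha_draws(0), q)
            qb = np.quantile(s.beta_draws(0), q)
            for i in range(2):
                qt = np.quantile(s.event_draws(0, i), q)
                assert qb <= qt <= qa

    def test_seed_determinism(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50), (5200, 50)])
        a = sample_posterior(model, n_iter=2_000, burn_in=500, thin=2, chains=2, seed=11)
        b = sample_posterior(model, n_iter=2_000, burn_in=500, thin=2, chains=2, seed=11)
        np.testing.assert_array_equal(a.alpha[0], b.alpha[0])
        np.testing.assert_array_equal(a.events[0], b.events[0])
        np.testing.assert_array_equal(a.predictive[0], b.predictive[0])

    def test_different_seed_differs(self, identity_curve):
        model = one_phase_model(identity_curve, [(5000, 50)])
        a = sample_posterior(model, n_iter=2_000, burn_in=500, thin=2, chains=2, seed=1)
        b = sample_posterior(model, n_iter=2_000, burn_in=500, thin=2, chains=2, seed=2)
        assert not np.array_equal(a.alpha[0], b.alpha[0])

    def test_ordered_two_phase_constraint_every_draw(self, identity_curve):
        d_old = [_gauss_density(identity_curve, 6000, 60)]
        d_new = [_gauss_density(identity_curve, 4000, 60)]
        model = SequenceSpec(
            phases=[PhaseSpec("old", d_old), PhaseSpec("new", d_new)],
            ordered=True, order=[0, 1],
        )
        s = sample_posterior(model, n_iter=4_000, burn_in=1_000, thin=2, chains=2, seed=5)
        assert (s.beta[0] >= s.alpha[1]).all()

    def test_infeasible_declared_order_raises(self, identity_curve):
        # dated unit declared older has support strictly younger than the other
        d_old = [_gauss_density(identity_curve, 3000, 20)]
        d_new = [_gauss_density(identity_curve, 8000, 20)]
        model = SequenceSpec(
            phases=[PhaseSpec("a", d_old), PhaseSpec("b", d_new)],
            ordered=True, order=[0, 1],
        )
        with pytest.raises(InitializationError):
            sample_posterior(model, n_iter=1_000, burn_in=100, thin=1, chains=2, seed=1)

    def test_oracle_equivalence_one_date(self):
        curve = pc.make_curve("identity", age_max=10_000, resolution=5)
        model = one_phase_model(curve, [(5000, 60)])
        s = sample_posterior(model, n_iter=20_000, burn_in=4_000, thin=4, chains=2, seed=13)
        dens = model.phases[0].event_densities[0]
        oracle = phase_grid_oracle([(dens.grid.astype(float), dens.p)])
        a = np.median(s.alpha_draws(0))
        b = np.median(s.beta_draws(0))
        mcse_a = batch_median_mcse(s.alpha_draws(0))
        mcse_b = batch_median_mcse(s.beta_draws(0))
        assert abs(a - oracle["alpha_median"]) <= max(10.0, 2.5 * mcse_a)
        assert abs(b - oracle["beta_median"]) <= max(10.0, 2.5 * mcse_b)

    def test_oracle_equivalence_two_dates(self):
        curve = pc.make_curve("identity", age_max=10_000, resolution=5)
        model = one_phase_model(curve, [(5000, 50), (5200, 50)])
        s = sample_posterior(model, n_iter=20_000, burn_in=4_000, thin=4, chains=2, seed=17)
        ds = [(d.grid.astype(float), d.p) for d in model.phases[0].event_densities]
        oracle = phase_grid_oracle(ds)
        for key, draws in [
            ("alpha_median", s.alpha_draws(0)),
            ("beta_median", s.beta_draws(0)),
            ("event0_median", s.event_draws(0, 0)),
            ("event1_median", s.event_draws(0, 1)),
        ]:
            mcse = batch_median_mcse(draws)
            assert abs(np.median(draws) - oracle[key]) <= max(10.0, 2.5 * mcse), key


class TestConvergenceDiagnostics:
    def _samples(self, alpha):
        return pc.PosteriorSamples(
            unit_ids=["u"],
            events=[np.zeros((1, 2, alpha.shape[1]))],
            predictive=[alpha.copy()],
            alpha=[alpha],
            beta=[alpha - 10.0],
            chains=2, seed=0, n_kept=alpha.shape[1],
        )

    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        rep = convergence_diagnostics(self._samples(np.vstack([chain, chain])))
        assert rep.rhat["alpha[u]"] == pytest.approx(1.0, abs=2e-3)

    def test_constant_distinct_chains_flagged(self):
        alpha = np.vstack([np.full(200, 10.0), np.full(200, 20.0)])
        rep = convergence_diagnostics(self._samples(alpha))
        assert np.isinf(rep.rhat["alpha[u]"]) or rep.rhat["alpha[u]"] > 1.1
        assert rep.flagged

    def test_iid_gaussian_ess_near_n(self):
        rng = np.random.default_rng(42)
        alpha = rng.normal(size=(2, 2_000))
        rep = convergence_diagnostics(self._samples(alpha))
        assert rep.ess["alpha[u]"] == pytest.approx(4_000, rel=0.2)

    def test_ess_agrees_with_direct_autocorrelation(self):
        rng = np.random.default_rng(7)
        # AR(1) chain with known strong autocorrelation
        n = 4_000
        x = np.empty(n)
        x[0] = 0.0
        for i in range(1, n):
            x[i] = 0.8 * x[i - 1] + rng.normal()
        alpha = np.vstack([x, x[::-1].copy()])
        rep = convergence_diagnostics(self._samples(alpha))
        direct = 2 * autocorr_ess(x)
        assert rep.ess["alpha[u]"] == pytest.approx(direct, rel=0.5)

    def test_requires_two_chains(self):
        s = self._samples(np.zeros((2, 100)))
        s.chains = 1
        with pytest.raises(ValueError):
            convergence_diagnostics(s)
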