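import numpy as np
import pandas as pd
import pytest

import herdhmm as hh
from herdhmm.fit import FitOptions, draw_init


def _series_from_model(model, n, seed):
    states = hh.simulate_states(model, n, seed=seed)
    lat, lon = hh.simulate_track(model, states, (14.5, -16.5), seed=seed + 1)
    return hh.compute_steps(pd.DataFrame({"lat": lat, "lon": lon})), states


class TestSingleFit:
    def test_one_state_mle_matches_sample_moments(self):
        # a state far from zero, so truncation is negligible and the normal
        # MLE coincides with the sample moments
        truth = hh.HmmModel(
            n_states=1,
            emissions=[hh.EmissionParams(600, 100, 0.0, 0.3, 2.0)],
            transitions=hh.TransitionStructure(n_states=1, beta=np.zeros((0, 1))),
            pi0=[1.0],
        )
        series, _ = _series_from_model(truth, 3000, seed=21)
        init = hh.HmmModel(
            n_states=1,
            emissions=[hh.EmissionParams(400, 200, 1e-6, 0.0, 1.0)],
            transitions=hh.TransitionStructure(n_states=1, beta=np.zeros((0, 1))),
            pi0=[1.0],
        )
        res = hh.fit(series, init)
        nz = series.steps[series.steps > 0]
        assert res.model.emissions[0].mu == pytest.approx(nz.mean(), rel=0.01)
        assert res.model.emissions[0].sigma == pytest.approx(nz.std(), rel=0.01)

    def test_descent_contract(self, ref_model, sim_series):
        series, _ = sim_series
        rng = np.random.default_rng(77)
        init = draw_init(rng, hh.table1_bounds(series.p0))
        ll_init = hh.log_likelihood(init, series)
        res = hh.fit(series, init, FitOptions(maxiter=30))
        assert res.loglik >= ll_init - 1e-6

    def test_recovery_from_near_truth_init(self, ref_model):
        series, states = _series_from_model(ref_model, 8000, seed=31)
        rng = np.random.default_rng(1)
        init = hh.HmmModel(
            n_states=3,
            emissions=[
                hh.EmissionParams(e.mu * rng.uniform(0.7, 1.3),
                                  e.sigma * rng.uniform(0.7, 1.3),
                                  max(e.zeta, 1e-6), e.mu_angle,
                                  e.kappa * rng.uniform(0.7, 1.3))
                for e in ref_model.emissions
            ],
            transitions=hh.TransitionStructure.from_matrix(np.full((3, 3), 1 / 3)),
            pi0=np.full(3, 1 / 3),
        )
        res = hh.fit(series, init)
        fitted, _ = hh.canonicalize(res.model)
        # at this reduced n the truncated-normal mean has SE ~ 6-7 m for the
        # foraging state, so a 10% band is the right scale here
        for est, true in zip(fitted.emissions, ref_model.emissions):
            assert est.mu == pytest.approx(true.mu, rel=0.10)
        (path,) = hh.viterbi(fitted, [series])
        assert np.mean(path == states) >= 0.90


class TestAnalyticGradient:
    @pytest.mark.parametrize("family", ["truncnorm", "gamma"])
    @pytest.mark.parametrize("covariates", [(), ("temperature_c",)])
    def test_matches_finite_differences(self, ref_model, family, covariates):
        from scipy.optimize import approx_fprime

        from herdhmm.fit import _Objective

        states = hh.simulate_states(ref_model, 300, seed=1)
        lat, lon = hh.simulate_track(ref_model, states, (14.5, -16.5), seed=2)
        df = pd.DataFrame({"lat": lat, "lon": lon,
                           "temperature_c": np.linspace(25, 45, len(lat))})
        df.iloc[50] = df.iloc[49]  # force a zero step
        series = hh.compute_steps(df, covariate_columns=covariates)
        obj = _Objective(series, covariates, family, 3)
        rng = np.random.default_rng(7)
        init = draw_init(rng, hh.table1_bounds(series.p0),
                         covariates=covariates, step_family=family)
        th = obj.packed.pack(init) + rng.normal(0, 0.05, obj.packed.size)
        v, g = obj.nll_and_grad(th)
        assert v == obj.nll(th)
        fd = approx_fprime(th, obj.nll, 1e-6)
        rel = np.abs(g - fd) / np.maximum(1.0, np.abs(fd))
        assert rel.max() < 1e-3


class TestMultistart:
    def test_identical_seed_identical_best_model(self, ref_model):
        series, _ = _series_from_model(ref_model, 1200, seed=41)
        kw = dict(bounds=hh.table1_bounds(series.p0), n_restarts=2, seed=9,
                  opts=FitOptions(maxiter=150))
        a, _ = hh.multistart_fit(series, 3, **kw)
        b, _ = hh.multistart_fit(series, 3, **kw)
        assert a.model.to_dict() == b.model.to_dict()
        assert a.loglik == b.loglik

    def test_degenerate_bounds_single_path(self, ref_model):
        series, _ = _series_from_model(ref_model, 800, seed=51)
        b = hh.SamplingBounds(
            mu=[(13.53, 13.53), (180.1, 180.1), (685.4, 685.4)],
            sigma=[(11.99, 11.99), (149.2, 149.2), (439.8, 439.8)],
            mu_angle=[(-3.05, -3.05), (0.0, 0.0), (-0.0146, -0.0146)],
            kappa=[(0.29, 0.29), (0.19, 0.19), (1.95, 1.95)],
            zeta_init=[4.2e-4, 1e-8, 1e-8],
        )
        best, summary = hh.multistart_fit(series, 3, bounds=b, n_restarts=3,
                                          seed=1, opts=FitOptions(maxiter=60))
        # identical inits => identical optimisation paths => full consensus
        assert summary.consensus == 1.0
        assert np.allclose(summary.logliks, summary.logliks[0])

    def test_easy_data_full_consensus(self, ref_model):
        series, _ = _series_from_model(ref_model, 2500, seed=61)
        best, summary = hh.multistart_fit(
            series, 3, bounds=hh.table1_bounds(series.p0), n_restarts=3, seed=3
        )
        assert summary.consensus == 1.0
        assert best.canonical
        mus = [e.mu for e in best.model.emissions]
        assert mus == sorted(mus)

    def test_ill_ordered_bounds_rejected(self):
        with pytest.raises(ValueError):
            hh.SamplingBounds(mu=[(10, 5)], sigma=[(1, 2)], mu_angle=[(0, 0)],
                              kappa=[(1, 2)], zeta_init=[0.1])
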