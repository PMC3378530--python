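import numpy as np
import pytest
from scipy.optimize import least_squares
from sklearn.base import clone

from lipact import (
    ActivityObservation,
    AmphiphileTotals,
    ExchangeParams,
    FitOptions,
    FretObservation,
    FretParams,
    LogisticStageParams,
    MicellarComposition,
    MinimalActivityModel,
    MinimalParams,
    TwoStageGlobalModel,
    TwoStageParams,
    default_initialization,
    fit_global,
    fit_minimal,
    minimal_activity,
    residual_diagnostics,
    weighted_objective,
)
from lipact.activity import activity_from_composition
from lipact.fitting import (
    GLOBAL_PARAM_NAMES,
    UnderdeterminedDesignError,
    _activity_raw,
    _efficiency_raw,
    runs_test,
)
from lipact.fret import predicted_efficiency
from lipact.optimize import levenberg_least_squares

TRUTH_DICT = {
    "a0": 1.1,
    "a1": 12.8,
    "theta05": 0.16,
    "c_theta": 15.0,
    "k_ex": 1.4,
    "xi": 51.0,
}


def _obs_arrays(act, fret):
    xa = np.array(
        [o.totals.lipid_conc / (o.totals.lipid_conc + o.totals.detergent_conc) for o in act]
    )
    ya = np.array([o.activity for o in act])
    xl = np.array([o.composition.x_lipid for o in fret])
    xp = np.array([o.composition.x_probe for o in fret])
    yf = np.array([o.e_app for o in fret])
    return xa, ya, xl, xp, yf


class TestWeightedObjective:
    def test_truth_on_exact_data_is_zero(self, truth, fret_truth, noise_free_data):
        act, fret = noise_free_data
        obj = weighted_objective((truth, fret_truth), act, fret)
        assert obj == pytest.approx(0.0, abs=1e-18)

    def test_single_residual_squared(self, truth, fret_truth):
        x = 0.2
        mean = activity_from_composition(x, truth)
        act = [ActivityObservation(AmphiphileTotals(0.2, 0.8), mean + 2.0)]
        comp = MicellarComposition(0.34, 0.02)
        fret = [FretObservation(comp, predicted_efficiency(comp, fret_truth))]
        obj = weighted_objective((truth, fret_truth), act, fret, (1.0, 1.0))
        assert obj == pytest.approx(4.0)

    def test_empty_data_rejected(self, truth, fret_truth):
        with pytest.raises(ValueError):
            weighted_objective((truth, fret_truth), [], [])

    def test_minimizer_invariant_under_weight_rescaling(
        self, noisy_data
    ):
        """Rescaling both weights jointly moves the objective, not its argmin."""
        act, fret = noisy_data
        kgrid = np.linspace(0.8, 2.2, 29)
        tgrid = np.linspace(0.10, 0.24, 29)

        def argmin(scale):
            best, arg = np.inf, None
            for k in kgrid:
                for t in tgrid:
                    ts = TwoStageParams(
                        LogisticStageParams(1.1, 12.8, t, 15.0),
                        ExchangeParams(k, 2),
                    )
                    obj = weighted_objective(
                        (ts, FretParams(51.0, ts.stage1)),
                        act,
                        fret,
                        (scale * 1.0, scale * 100.0),
                    )
                    if obj < best:
                        best, arg = obj, (k, t)
            return arg

        assert argmin(1.0) == argmin(7.3)


class TestGlobalFit:
    def test_noise_free_recovery(self, noise_free_data):
        act, fret = noise_free_data
        res = fit_global(act, fret)
        assert res.converged
        for name, val in TRUTH_DICT.items():
            assert res.estimates[name] == pytest.approx(val, rel=1e-4)

    def test_matches_independent_optimizer(self, noisy_data):
        """The in-package engine lands on the same minimizer as scipy."""
        act, fret = noisy_data
        res = fit_global(act, fret)
        xa, ya, xl, xp, yf = _obs_arrays(act, fret)
        sw_a = np.sqrt(res.weights["activity"])
        sw_f = np.sqrt(res.weights["fret"])

        def resid(p):
            return np.concatenate(
                [
                    sw_a * (ya - _activity_raw(xa, p, 2, "single")),
                    sw_f * (yf - _efficiency_raw(xl, xp, p[4], p[5], 2, "single")),
                ]
            )

        ref = least_squares(
            resid,
            [1.0, 13.0, 0.15, 15.0, 1.4, 50.0],
            bounds=(
                [0, 1e-6, 1e-3, 1e-6, 1e-3, 1e-3],
                [1e6, 1e6, 0.999, 1e6, 1e3, 1e4],
            ),
        )
        assert res.objective == pytest.approx(2 * ref.cost, rel=1e-6)
        for name, val in zip(GLOBAL_PARAM_NAMES, ref.x):
            assert res.estimates[name] == pytest.approx(val, rel=1e-3)

    def test_residuals_tagged_and_counted(self, noisy_data):
        act, fret = noisy_data
        res = fit_global(act, fret)
        assert len(res.residuals) == len(act) + len(fret)
        assert (res.residuals["dataset"] == "activity").sum() == len(act)
        assert res.covariance.shape == (6, 6)
        assert np.allclose(res.covariance, res.covariance.T)
        assert all(v >= 0 or np.isnan(v) for v in res.standard_errors.values())

    def test_zero_lipid_design_rejected(self, fret_truth, noise_free_data):
        _, fret = noise_free_data
        act = [
            ActivityObservation(AmphiphileTotals(0.0, 1.2), 2.1) for _ in range(10)
        ]
        with pytest.raises(UnderdeterminedDesignError):
            fit_global(act, fret)

    def test_too_few_observations_rejected(self, noise_free_data):
        act, fret = noise_free_data
        with pytest.raises(UnderdeterminedDesignError):
            fit_global(act[:5], fret)
        with pytest.raises(UnderdeterminedDesignError):
            fit_global(act, fret[:3])

    def test_stderr_shrinks_with_replication(self, truth, fret_truth):
        from lipact import NoiseSpec, paper_activity_design, paper_fret_design
        from lipact import simulate_activity, simulate_fret

        def se(reps, seed=5):
            rng = np.random.default_rng(seed)
            act = simulate_activity(
                truth,
                paper_activity_design(replicates=2 * reps),
                NoiseSpec(0.5, 0.02, seed),
                rng=rng,
            )
            fret = simulate_fret(
                fret_truth,
                paper_fret_design(replicates=reps),
                NoiseSpec(0.5, 0.02, seed),
                rng=rng,
            )
            return fit_global(act, fret).standard_errors

        se1, se4 = se(1), se(4)
        for name in ("a1", "theta05", "k_ex"):
            ratio = se1[name] / se4[name]
            assert 1.3 < ratio < 3.0  # ~2 expected for 4x replication

    def test_grid_oracle_equivalence(self, noisy_data):
        """On a (K_ex, theta05) slice the engine matches exhaustive search."""
        act, fret = noisy_data
        xa, ya, xl, xp, yf = _obs_arrays(act, fret)
        sw_a, sw_f = 1.0, np.sqrt(625.0)  # fixed known weights

        def resid2(q):
            p = np.array([1.1, 12.8, q[1], 15.0, q[0], 51.0])
            return np.concatenate(
                [
                    sw_a * (ya - _activity_raw(xa, p, 2, "single")),
                    sw_f * (yf - _efficiency_raw(xl, xp, p[4], p[5], 2, "single")),
                ]
            )

        kgrid = np.linspace(0.8, 2.2, 41)
        tgrid = np.linspace(0.10, 0.24, 41)
        objs = np.array(
            [[float(resid2([k, t]) @ resid2([k, t])) for t in tgrid] for k in kgrid]
        )
        ik, it = np.unravel_index(np.argmin(objs), objs.shape)
        res = levenberg_least_squares(
            resid2, [1.0, 0.15], [1e-3, 1e-3], [1e3, 0.999]
        )
        assert res.converged
        assert abs(res.params[0] - kgrid[ik]) <= (kgrid[1] - kgrid[0])
        assert abs(res.params[1] - tgrid[it]) <= (tgrid[1] - tgrid[0])

    def test_objective_monotone_over_accepted_steps(self, noisy_data):
        act, fret = noisy_data
        xa, ya, _, _, _ = _obs_arrays(act, fret)

        def resid(p5):
            return ya - _activity_raw(xa, np.append(p5, 51.0), 2, "single")

        trace = []
        levenberg_least_squares(
            resid,
            [2.0, 10.0, 0.3, 5.0, 1.0],
            [0, 1e-6, 1e-3, 1e-6, 1e-3],
            [1e6, 1e6, 0.999, 1e6, 1e3],
            callback=lambda p, obj: trace.append(obj),
        )
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-12)

    def test_pure_gauss_newton_option(self, noise_free_data):
        # classical Gauss-Newton is only locally convergent: start nearby
        act, fret = noise_free_data
        res = fit_global(
            act,
            fret,
            init=dict(TRUTH_DICT, theta05=0.18, k_ex=1.2),
            options=FitOptions(pure_gauss_newton=True, weights="unit"),
        )
        assert res.converged
        assert res.estimates["k_ex"] == pytest.approx(1.4, rel=1e-4)

    def test_estimator_is_cloneable(self):
        est = TwoStageGlobalModel(beta=2, multi_start=2, random_state=7)
        params = est.get_params()
        assert params["multi_start"] == 2
        assert clone(est).get_params() == params


class TestMinimalFit:
    def test_exact_self_recovery(self):
        p = MinimalParams(1.6, 13.0, 0.12, 26.0)
        x = np.linspace(0.0, 0.6, 40)
        res = MinimalActivityModel().fit(x, minimal_activity(x, p))
        assert res.converged_
        assert res.a0_ == pytest.approx(1.6, rel=1e-6)
        assert res.a1_ == pytest.approx(13.0, rel=1e-6)
        assert res.x05_ == pytest.approx(0.12, rel=1e-6)
        assert res.c_x_ == pytest.approx(26.0, rel=1e-6)

    def test_two_stage_curve_maps_to_published_minimal_params(self, truth):
        """Dense exact two-stage data fit by the minimal model reproduces
        the published half-activation fraction and cooperativity."""
        x = np.linspace(0, 1, 101)
        est = MinimalActivityModel().fit(x, activity_from_composition(x, truth))
        assert est.converged_
        assert 0.11 <= round(est.x05_, 2) <= 0.13
        assert 20.0 <= est.c_x_ <= 32.0

    def test_decreasing_activities_flagged(self):
        x = np.linspace(0.05, 0.6, 12)
        y = np.maximum(10 - 12 * x, 0.1)
        est = MinimalActivityModel().fit(x, y)
        assert (not est.converged_) or ("c_x" in est.at_bound_)

    def test_too_few_points_rejected(self):
        with pytest.raises(UnderdeterminedDesignError):
            MinimalActivityModel().fit([0.1, 0.2, 0.3], [1, 2, 3])

    def test_wrapper_matches_estimator(self, noise_free_data):
        act, _ = noise_free_data
        res = fit_minimal(act)
        assert res.converged
        assert set(res.estimates) == {"a0", "a1", "x05", "c_x"}


class TestInitialization:
    def test_within_factor_three_of_truth(self, noisy_data):
        act, fret = noisy_data
        init = default_initialization(act, fret)
        for name, val in TRUTH_DICT.items():
            assert val / 3 < init[name] < val * 3

    def test_deterministic(self, noisy_data):
        act, fret = noisy_data
        assert default_initialization(act, fret) == default_initialization(act, fret)

    def test_constant_activities_rejected(self):
        obs = [
            ActivityObservation(AmphiphileTotals(x, 1.0), 5.0)
            for x in (0.1, 0.2, 0.3, 0.4)
        ]
        with pytest.raises(ValueError):
            default_initialization(obs)

    def test_too_few_abscissae_rejected(self):
        obs = [
            ActivityObservation(AmphiphileTotals(0.1, 1.0), 1.0),
            ActivityObservation(AmphiphileTotals(0.5, 1.0), 9.0),
        ]
        with pytest.raises(ValueError):
            default_initialization(obs)


class TestDiagnostics:
    def test_noise_free_residuals_vanish(self, noise_free_data):
        act, fret = noise_free_data
        diag = residual_diagnostics(fit_global(act, fret))
        for d in diag.values():
            assert abs(d["mean"]) < 1e-8
            assert d["sd"] < 1e-8
            assert not d["unreliable"]

    def test_alternating_signs_not_rejected(self):
        z, p = runs_test(np.array([1.0, -1.0] * 12))
        assert p > 0.05  # many runs: no evidence of clustering

    def test_structured_residuals_flagged(self, fret_truth):
        """A minimal fit to strongly two-stage data leaves sign clusters."""
        strong = TwoStageParams(
            LogisticStageParams(1.1, 12.8, 0.16, 15.0), ExchangeParams(5.0, 2)
        )
        x = np.linspace(0, 1, 201)
        est = MinimalActivityModel().fit(x, activity_from_composition(x, strong))
        from lipact.fitting import MinimalFitResult

        result = MinimalFitResult(
            estimates=est.params_,
            standard_errors=est.stderr_,
            covariance=est.covariance_,
            residuals=est.residuals_,
            objective=est.objective_,
            converged=est.converged_,
            n_iterations=est.n_iter_,
        )
        diag = residual_diagnostics(result)["activity"]
        assert diag["runs_p"] < 0.01

    def test_few_residuals_marked_unreliable(self):
        import pandas as pd

        from lipact.fitting import MinimalFitResult

        result = MinimalFitResult(
            estimates={},
            standard_errors={},
            covariance=None,
            residuals=pd.DataFrame(
                {
                    "dataset": ["activity"] * 3,
                    "fitted": [1.0, 2.0, 3.0],
                    "residual": [0.1, -0.1, 0.2],
                }
            ),
            objective=0.0,
            converged=True,
            n_iterations=1,
        )
        assert residual_diagnostics(result)["activity"]["unreliable"]


class TestFitOptions:
    def test_validation(self):
        with pytest.raises(ValueError):
            FitOptions(convergence_tol=0)
        with pytest.raises(ValueError):
            FitOptions(max_iterations=0)
        with pytest.raises(ValueError):
            FitOptions(weights="fancy")
        with pytest.raises(ValueError):
            FitOptions(bounds={"k_ex": (2.0, 1.0)})
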