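"""Solver correctness: KKT optimality, limits, path, CV and stability."""

import warnings

import numpy as np
import pytest

import hmotriad as ht
from hmotriad.grouplasso import lambda_max

from conftest import random_group_problem


def subgradient_oracle(X, y, structure, lam, iters=200_000, step0=0.5):
    """Independent projected-subgradient minimizer of the same objective."""
    Xt = structure.expand(X)
    n = y.size
    v = np.zeros(Xt.shape[1])
    best = np.inf
    for k in range(1, iters + 1):
        r = Xt @ v - y
        g = Xt.T @ r / n
        pen_g = np.zeros_like(v)
        norms = structure.group_norms(v)
        for j, (off, size, w) in enumerate(zip(structure.offsets,
                                               structure.sizes,
                                               structure.weights)):
            sl = slice(int(off), int(off) + int(size))
            if norms[j] > 0:
                pen_g[sl] = lam * w * v[sl] / norms[j]
        v = v - (step0 / np.sqrt(k)) * (g + pen_g)
        if k % 50 == 0 or k == iters:
            obj = (0.5 * float((y - Xt @ v) @ (y - Xt @ v)) / n
                   + lam * float(structure.weights @ structure.group_norms(v)))
            best = min(best, obj)
    return best


def smoothed_oracle(X, y, structure, lam, eps=1e-10):
    """Tight independent oracle: quasi-Newton on the eps-smoothed objective."""
    from scipy.optimize import minimize
    Xt = structure.expand(X)
    n = y.size

    def fg(v):
        r = y - Xt @ v
        f = 0.5 * float(r @ r) / n
        grad = -(Xt.T @ r) / n
        for off, size, w in zip(structure.offsets, structure.sizes,
                                structure.weights):
            sl = slice(int(off), int(off) + int(size))
            nv = np.sqrt(float(v[sl] @ v[sl]) + eps ** 2)
            f += lam * w * (nv - eps)
            grad[sl] += lam * w * v[sl] / nv
        return f, grad

    res = minimize(fg, np.zeros(Xt.shape[1]), jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-18, "gtol": 1e-14})
    return res.fun


class TestSolverLimits:
    def test_lambda_max_gives_null_model(self):
        rng = np.random.default_rng(10)
        X, y, st = random_group_problem(rng, n=80, n_groups=6)
        lmax = lambda_max(X, y, st)
        for lam in (lmax, 1.5 * lmax):
            fit = ht.fit_group_lasso(X, y, st, lam)
            assert fit.selected_groups == []
            assert np.all(fit.beta[1:] == 0.0)

    def test_lambda_zero_matches_least_squares(self):
        rng = np.random.default_rng(11)
        n, p = 60, 8
        X = rng.normal(size=(n, p))
        X[:, 0] = 1.0
        y = rng.normal(size=n)
        st = ht.GroupStructure(n_columns=p, unpenalized_columns=np.array([0]),
                               group_columns=[np.array([j])
                                              for j in range(1, p)])
        fit = ht.fit_group_lasso(X, y, st, 0.0)
        beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ls, atol=1e-6)

    def test_objective_matches_independent_oracles(self):
        rng = np.random.default_rng(12)
        n, p = 30, 10
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        st = ht.GroupStructure(n_columns=p,
                               unpenalized_columns=np.array([], dtype=int),
                               group_columns=[np.arange(0, 3),
                                              np.arange(3, 7),
                                              np.arange(7, 10)])
        lam = 0.5 * lambda_max(X, y, st)
        fit = ht.fit_group_lasso(X, y, st, lam)
        tight = smoothed_oracle(X, y, st, lam)
        assert fit.objective == pytest.approx(tight, rel=1e-6)
        rough = subgradient_oracle(X, y, st, lam, iters=60_000)
        assert fit.objective == pytest.approx(rough, rel=1e-3)
        assert fit.objective <= rough + 1e-12


class TestKKT:
    def test_converged_fits_satisfy_kkt(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            X, y, st = random_group_problem(rng)
            lam = 0.3 * lambda_max(X, y, st)
            fit = ht.fit_group_lasso(X, y, st, lam)
            assert fit.converged
            assert ht.kkt_residuals(fit, X, y, st).max() <= 1e-6

    def test_perturbation_breaks_optimality(self):
        rng = np.random.default_rng(14)
        X, y, st = random_group_problem(rng, n=100, n_groups=5)
        lam = 0.1 * lambda_max(X, y, st)
        fit = ht.fit_group_lasso(X, y, st, lam)
        assert fit.selected_groups
        g = fit.selected_groups[0]
        fit.v[int(st.offsets[g])] += 0.1
        assert ht.kkt_residuals(fit, X, y, st)[g] > 1e-4

    def test_null_fit_at_lambda_max_has_zero_gaps(self):
        rng = np.random.default_rng(15)
        X, y, st = random_group_problem(rng, n=70, n_groups=4)
        lam = lambda_max(X, y, st)
        fit = ht.fit_group_lasso(X, y, st, lam)
        np.testing.assert_allclose(ht.kkt_residuals(fit, X, y, st), 0.0,
                                   atol=1e-9)


class TestPath:
    def test_grid_shape_and_monotonicity(self):
        rng = np.random.default_rng(16)
        X, y, st = random_group_problem(rng, n=50, n_groups=4)
        path = ht.lambda_path(X, y, st, n_lambdas=25, ratio=0.01)
        assert path.size == 25
        assert np.all(np.diff(path) < 0)
        fit = ht.fit_group_lasso(X, y, st, path[0])
        assert fit.selected_groups == []

    def test_lambda_max_orthonormal_closed_form(self):
        # 4x2 orthonormal design, singleton groups, no unpenalized block
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]]) / 2
        y = np.array([1.0, 2.0, 3.0, 4.0])
        st = ht.GroupStructure(n_columns=2,
                               unpenalized_columns=np.array([], dtype=int),
                               group_columns=[np.array([0]), np.array([1])])
        expected = np.max(np.abs(X.T @ y)) / 4
        assert lambda_max(X, y, st) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_design_errors(self):
        X = np.column_stack([np.ones(10), np.zeros(10)])
        y = np.ones(10)
        st = ht.GroupStructure(n_columns=2, unpenalized_columns=np.array([0]),
                               group_columns=[np.array([1])])
        with pytest.raises(ValueError, match="degenerate"):
            ht.lambda_path(X, y, st)

    def test_warm_start_matches_cold_start(self):
        rng = np.random.default_rng(17)
        X, y, st = random_group_problem(rng, n=60, n_groups=5)
        path = ht.lambda_path(X, y, st, n_lambdas=8, ratio=0.05)
        v = None
        for lam in path:
            warm = ht.fit_group_lasso(X, y, st, lam, v0=v)
            cold = ht.fit_group_lasso(X, y, st, lam)
            assert warm.objective == pytest.approx(cold.objective, rel=1e-6,
                                                   abs=1e-9)
            v = warm.v

    def test_objective_monotone_non_increasing(self):
        rng = np.random.default_rng(18)
        X, y, st = random_group_problem(rng, n=80, n_groups=8)
        hist = []
        ht.fit_group_lasso(X, y, st, 0.2 * lambda_max(X, y, st), history=hist)
        assert len(hist) > 3
        assert np.all(np.diff(hist) <= 1e-12)


def _grouped_cohort(rng, n_subjects=30, visits=2, p_noise=6, strong=2.0):
    rows, sid = [], []
    for i in range(n_subjects):
        for _ in range(visits):
            rows.append(rng.normal(size=1 + 2 + p_noise))
            sid.append(i)
    X = np.array(rows)
    X[:, 0] = 1.0
    y = X[:, 1] * strong + X[:, 2] * strong
    st = ht.GroupStructure(
        n_columns=X.shape[1], unpenalized_columns=np.array([0]),
        group_columns=[np.array([1, 2])] + [np.array([j])
                                            for j in range(3, X.shape[1])])
    return X, y, st, np.array(sid)


class TestCV:
    def test_noiseless_strong_group_selected(self):
        rng = np.random.default_rng(19)
        X, y, st, sid = _grouped_cohort(rng)
        lam, selected, info = ht.cv_select(X, y, st, sid, k=5,
                                           rng=np.random.default_rng(0),
                                           n_lambdas=25, lambda_min_ratio=1e-4)
        assert 0 in selected
        # the chosen penalty must beat the null end of the path on CV error
        assert info["cv_mse"].argmin() > 0

    def test_leave_one_subject_out_boundary(self):
        rng = np.random.default_rng(20)
        X, y, st, sid = _grouped_cohort(rng, n_subjects=12)
        lam, selected, _ = ht.cv_select(X, y, st, sid, k=12,
                                        rng=np.random.default_rng(1),
                                        n_lambdas=10, lambda_min_ratio=0.01)
        assert 0 in selected

    def test_more_folds_than_subjects_errors(self):
        rng = np.random.default_rng(21)
        X, y, st, sid = _grouped_cohort(rng, n_subjects=5)
        with pytest.raises(ValueError, match="folds"):
            ht.cv_select(X, y, st, sid, k=10, rng=np.random.default_rng(0))

    def test_duplicated_subjects_keep_selection_stable(self):
        """Doubling every subject shifts lambda* only modestly (duplicate
        subjects leak twins across folds, favouring slightly less penalty)
        and never changes which strong group is selected."""
        rng = np.random.default_rng(22)
        X, y, st, sid = _grouped_cohort(rng, n_subjects=25, p_noise=10,
                                        strong=1.0)
        y = y + rng.normal(scale=1.0, size=y.size)
        grid = ht.lambda_path(X, y, st, 20, 0.01)
        lam1, sel1, _ = ht.cv_select(X, y, st, sid, k=5,
                                     rng=np.random.default_rng(3),
                                     lambdas=grid)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        sid2 = np.concatenate([sid, sid + 1000])
        lam2, sel2, _ = ht.cv_select(X2, y2, st, sid2, k=5,
                                     rng=np.random.default_rng(4),
                                     lambdas=grid)
        i1 = int(np.argmin(np.abs(grid - lam1)))
        i2 = int(np.argmin(np.abs(grid - lam2)))
        assert abs(i1 - i2) <= 4  # under one order of magnitude on this grid
        assert 0 in sel1 and 0 in sel2


class TestStability:
    def test_single_repetition_frequencies_binary(self):
        rng = np.random.default_rng(23)
        X, y, st, sid = _grouped_cohort(rng)
        res = ht.stability_select(X, y, st, sid, reps=1, k=5,
                                  rng=np.random.default_rng(5),
                                  n_lambdas=15, lambda_min_ratio=0.01)
        assert set(np.unique(res.frequencies)) <= {0.0, 1.0}

    def test_pure_noise_triggers_fallback(self, design105):
        d, g = design105
        rng_noise = np.random.default_rng(99)
        y = rng_noise.normal(size=d.n_obs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = ht.stability_select(d.X, y, g, d.subject_ids, reps=5, k=10,
                                      rng=np.random.default_rng(6),
                                      n_lambdas=20, lambda_min_ratio=0.02)
        assert res.fallback_used
        kinds = [res.group_kinds[i] for i in res.final_groups]
        assert set(kinds) == {"hmo", "mb"}
        assert len(res.final_groups) == sum(
            k in ("hmo", "mb") for k in res.group_kinds)

    def test_strong_planted_interaction_dominates(self):
        """A paper-magnitude planted interaction is stably selected."""
        models = ht.synthdata._default_outcome_models()
        models["composite"] = ht.OutcomeModel(
            intercept=108.0, beta_cov=(0, 0, 0, 0, -3.0, -5.0),
            gamma=(ht.GammaSpec("3sl", "bif_longum", 2.5),),
            sigma_subject=5.0, sigma_resid=7.0)
        cfg = ht.default_config(n_subjects=120, seed=31,
                                outcome_models=models)
        prep = ht.prepare(ht.dataset_from_samples(ht.generate_cohort(cfg)),
                          ht.PreprocessConfig(outlier_policy="keep"))
        spec = ht.ModelSpec(outcome="composite",
                            species_names=tuple(prep.retained_species))
        d = ht.build_design(prep.frame, spec)
        g = ht.build_groups(d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = ht.stability_select(d.X, d.y, g, d.subject_ids, reps=8,
                                      k=10, rng=np.random.default_rng(7),
                                      n_lambdas=25, lambda_min_ratio=0.02)
        j = res.group_names.index("3sl:bif_longum")
        assert res.frequencies[j] >= 0.75
        assert not res.fallback_used
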