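"""Overlapping group LASSO with CV penalty choice and stability selection.

Variable selection for the interaction models uses the latent overlapping
group LASSO: each original penalized column may appear in several groups
(an interaction's triple group carries copies of its two parent main
effects), the duplicated "latent" columns make the groups disjoint, and the
fitted original coefficients are the sums of their latent copies.  Because an
interaction column exists only inside a triple that also carries its parents,
any selected support is automatically hierarchical: interaction present =>
both mains present.

The solver is a monotone accelerated proximal-gradient method (MFISTA) with
backtracking line search on the squared-error objective

    F(v) = ||y - Xt v||^2 / (2n) + lambda * sum_g w_g ||v_g||_2,

where ``Xt`` is the latent-expanded design, ``w_g = sqrt(|g|)``, and
unpenalized columns (intercept, covariates, stratum indicator) are carried in
the same coefficient vector with no penalty.  Convergence requires both a
relative-objective stall and Karush-Kuhn-Tucker residuals below tolerance.

The penalty is chosen by k-fold cross-validation with folds partitioning
SUBJECTS (all visits of an infant share a fold, so repeated measures never
leak across the split), repeated with fresh fold randomizations; per-group
selection frequencies over the repetitions give a stability-selection style
final model, with a fallback to the all-main-effects model when no
interaction group is stably selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _sciopt

__all__ = ["GroupStructure", "LassoFit", "StabilityResult",
           "fit_group_lasso", "kkt_residuals", "lambda_path",
           "cv_select", "stability_select"]


# ---------------------------------------------------------------------------
# group structure
# ---------------------------------------------------------------------------


@dataclass
class GroupStructure:
    """Penalized groups over original design columns, with latent expansion.

    ``group_columns[g]`` lists the original column indices belonging to group
    ``g``; groups may overlap.  The latent space lays out the unpenalized
    columns first, then each group's private copies contiguously, so disjoint
    slices of the latent coefficient vector correspond to groups.
    """

    n_columns: int
    unpenalized_columns: np.ndarray
    group_columns: list[np.ndarray]
    group_names: list[str] = field(default_factory=list)
    group_kinds: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.group_names:
            self.group_names = [f"g{j}" for j in range(len(self.group_columns))]
        if not self.group_kinds:
            self.group_kinds = ["group"] * len(self.group_columns)
        covered = set(int(c) for g in self.group_columns for c in g)
        penalized = set(range(self.n_columns)) - set(map(int, self.unpenalized_columns))
        missing = penalized - covered
        if missing:
            raise ValueError(f"penalized columns {sorted(missing)} belong to no group")
        self.sizes = np.array([len(g) for g in self.group_columns], dtype=int)
        self.weights = np.sqrt(self.sizes.astype(float))
        self.n_unpen = len(self.unpenalized_columns)
        self.latent_map = np.concatenate(
            [np.asarray(self.unpenalized_columns, dtype=int)]
            + [np.asarray(g, dtype=int) for g in self.group_columns]
        ) if self.group_columns else np.asarray(self.unpenalized_columns, dtype=int)
        self.offsets = self.n_unpen + np.concatenate([[0], np.cumsum(self.sizes)[:-1]]) \
            if len(self.sizes) else np.array([], dtype=int)
        self.n_latent = self.latent_map.size

    @property
    def n_groups(self) -> int:
        return len(self.group_columns)

    def expand(self, X: np.ndarray) -> np.ndarray:
        """Latent-expanded design (duplicated columns)."""
        return X[:, self.latent_map]

    def collapse(self, v: np.ndarray) -> np.ndarray:
        """Original-space coefficients: sum of latent copies per column."""
        beta = np.zeros(self.n_columns)
        np.add.at(beta, self.latent_map, v)
        return beta

    def group_norms(self, v: np.ndarray) -> np.ndarray:
        if self.n_groups == 0:
            return np.array([])
        pen = v[self.n_unpen:] ** 2
        return np.sqrt(np.add.reduceat(pen, self.offsets - self.n_unpen))


@dataclass
class LassoFit:
    lam: float
    v: np.ndarray                  # latent coefficients
    beta: np.ndarray               # collapsed original coefficients
    selected_groups: list[int]
    objective: float
    iterations: int
    converged: bool
    kkt_gap: float

    def support(self, structure: GroupStructure) -> set[int]:
        """Original columns carried by the selected groups."""
        cols = set(map(int, structure.unpenalized_columns))
        for g in self.selected_groups:
            cols.update(map(int, structure.group_columns[g]))
        return cols


@dataclass
class StabilityResult:
    frequencies: np.ndarray        # per group, in [0, 1]
    lambdas: np.ndarray            # chosen lambda per repetition
    final_groups: list[int]
    fallback_used: bool
    freq_cutoff: float
    group_names: list[str]
    group_kinds: list[str]


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


class _Quad:
    """Quadratic loss oracle ||y - Xt v||^2/(2n) in Gram form.

    Precomputing ``G = Xt'Xt`` and ``b = Xt'y`` makes every solver iteration
    two m x m matvecs instead of three n x m products and gives the KKT
    correlation vector ``(b - G v)/n`` for free from the gradient.
    """

    def __init__(self, Xt=None, y=None, G=None, b=None, yty=None, n=None):
        if G is None:
            Xt = np.asarray(Xt, dtype=float)
            y = np.asarray(y, dtype=float)
            G = Xt.T @ Xt
            b = Xt.T @ y
            yty = float(y @ y)
            n = y.size
        self.G, self.b, self.yty, self.n = G, b, float(yty), int(n)
        self.m = b.size

    def f_and_Gv(self, v):
        Gv = self.G @ v
        f = 0.5 * (float(v @ Gv) - 2.0 * float(self.b @ v) + self.yty) / self.n
        return f, Gv

    def f(self, v):
        return self.f_and_Gv(v)[0]

    def corr(self, v, Gv=None):
        if Gv is None:
            Gv = self.G @ v
        return (self.b - Gv) / self.n

    def lipschitz(self, iters: int = 12) -> float:
        z = np.random.default_rng(0).normal(size=self.m)
        for _ in range(iters):
            z = self.G @ z
            nz = np.linalg.norm(z)
            if nz == 0:
                return 1e-12
            z /= nz
        return max(float(np.linalg.norm(self.G @ z)) / self.n, 1e-12)


def _penalty(v, lam, structure):
    if structure.n_groups == 0:
        return 0.0
    return lam * float(structure.weights @ structure.group_norms(v))


def _objective_q(quad, v, lam, structure):
    return quad.f(v) + _penalty(v, lam, structure)


def _prox(v, step_lam, structure):
    """Group soft-thresholding of the penalized latent blocks."""
    out = v.copy()
    if structure.n_groups == 0 or step_lam == 0.0:
        return out
    norms = structure.group_norms(v)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = 1.0 - step_lam * structure.weights / norms
    scale[~np.isfinite(scale)] = 0.0
    np.maximum(scale, 0.0, out=scale)
    out[structure.n_unpen:] *= np.repeat(scale, structure.sizes)
    return out


def _group_gaps(c, v, lam, structure):
    """Vectorized per-group KKT gaps given the correlation vector c."""
    nu = structure.n_unpen
    off = structure.offsets - nu
    norms = structure.group_norms(v)
    cpen = c[nu:]
    vpen = v[nu:]
    cnorm = np.sqrt(np.add.reduceat(cpen ** 2, off))
    gaps = np.maximum(0.0, cnorm - lam * structure.weights)
    active = norms > 0
    if active.any():
        scale = np.zeros_like(norms)
        scale[active] = lam * structure.weights[active] / norms[active]
        d = cpen - np.repeat(scale, structure.sizes) * vpen
        dnorm = np.sqrt(np.add.reduceat(d ** 2, off))
        gaps[active] = dnorm[active]
    return gaps


def _kkt_gap_q(quad, v, lam, structure, c=None):
    """Max optimality gap over unpenalized coordinates and groups."""
    if c is None:
        c = quad.corr(v)
    gap = float(np.max(np.abs(c[:structure.n_unpen]))) if structure.n_unpen else 0.0
    if structure.n_groups == 0:
        return gap
    return max(gap, float(np.max(_group_gaps(c, v, lam, structure))))


def _polish_active(quad, v, lam, structure):
    """Refine the coefficients on the current active set.

    On the support (unpenalized coordinates plus groups with nonzero norm)
    the objective is smooth, so a quasi-Newton solve reaches much higher
    precision than first-order proximal steps; the polished point is
    accepted only when it does not increase the objective.
    """
    norms = structure.group_norms(v)
    active = np.flatnonzero(norms > 0)
    idx = list(range(structure.n_unpen))
    starts, sizes, wgts = [], [], []
    for g in active:
        start = int(structure.offsets[g])
        size = int(structure.sizes[g])
        starts.append(len(idx))
        sizes.append(size)
        wgts.append(structure.weights[g])
        idx.extend(range(start, start + size))
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        return v
    Ga = quad.G[np.ix_(idx, idx)]
    ba = quad.b[idx]
    n = quad.n
    starts = np.asarray(starts, dtype=int)
    sizes_a = np.asarray(sizes, dtype=int)
    wgts = np.asarray(wgts)
    nu = structure.n_unpen

    def fg(w):
        Gw = Ga @ w
        f = 0.5 * (float(w @ Gw) - 2.0 * float(ba @ w) + quad.yty) / n
        grad = (Gw - ba) / n
        if starts.size:
            pen = w[nu:]
            nrm = np.sqrt(np.add.reduceat(pen ** 2, starts - nu))
            f += lam * float(wgts @ nrm)
            with np.errstate(divide="ignore", invalid="ignore"):
                scl = lam * wgts / nrm
            scl[~np.isfinite(scl)] = 0.0
            grad[nu:] += np.repeat(scl, sizes_a) * pen
        return f, grad

    res = _sciopt.minimize(fg, v[idx], jac=True, method="L-BFGS-B",
                           options={"maxiter": 300, "ftol": 1e-18,
                                    "gtol": 1e-12})
    out = v.copy()
    out[idx] = res.x
    # groups driven to numerical zero are set exactly to zero
    nrm = structure.group_norms(out)
    scale = max(1.0, float(np.max(nrm))) if nrm.size else 1.0
    for g in np.flatnonzero((nrm > 0) & (nrm < 1e-12 * scale)):
        start = int(structure.offsets[g])
        out[start:start + int(structure.sizes[g])] = 0.0
    f_new = _objective_q(quad, out, lam, structure)
    f_old = _objective_q(quad, v, lam, structure)
    return out if f_new <= f_old else v


def fit_group_lasso(X: np.ndarray, y: np.ndarray, structure: GroupStructure,
                    lam: float, tol: float = 1e-10, max_iter: int = 50_000,
                    kkt_tol: float = 1e-6, v0: np.ndarray | None = None,
                    Xt: np.ndarray | None = None, quad: _Quad | None = None,
                    lip: float | None = None, polish: bool = True,
                    warn: bool = True,
                    history: list | None = None) -> LassoFit:
    """Solve the latent overlapping group LASSO at one penalty value.

    Monotone FISTA with backtracking; a relative objective change below
    ``tol`` or a periodic check triggers a KKT test, and the fit stops once
    the KKT residual is below ``kkt_tol`` (or at ``max_iter``, with
    ``converged=False`` and a warning).  On an objective stall short of
    optimality the active set is polished by a quasi-Newton solve.  ``v0``
    warm starts the latent coefficients; ``Xt`` or ``quad`` may supply the
    precomputed latent expansion / Gram form.
    """
    if quad is None:
        if Xt is None:
            Xt = structure.expand(np.asarray(X, dtype=float))
        quad = _Quad(Xt, np.asarray(y, dtype=float))
    m = quad.m
    if v0 is None:
        v = np.zeros(m)
        if structure.n_unpen:  # solve the unpenalized block exactly up front
            nu = structure.n_unpen
            Gu = quad.G[:nu, :nu]
            try:
                v[:nu] = np.linalg.solve(Gu, quad.b[:nu])
            except np.linalg.LinAlgError:
                v[:nu] = np.linalg.lstsq(Gu, quad.b[:nu], rcond=None)[0]
    else:
        v = v0.copy()

    # step size from a cheap spectral-norm estimate, refined by backtracking
    if lip is None:
        lip = quad.lipschitz()
    step = 1.0 / lip

    x = v.copy()
    yk = v.copy()
    t_prev = 1.0
    F_x = _objective_q(quad, x, lam, structure)
    c_x = None  # KKT correlation vector at x, when known
    converged = False
    it = 0
    stalls = 0
    check_every = 10
    for it in range(1, max_iter + 1):
        f_y, Gy = quad.f_and_Gv(yk)
        grad = (Gy - quad.b) / quad.n
        # backtracking line search
        while True:
            z = _prox(yk - step * grad, step * lam, structure)
            d = z - yk
            f_z, Gz = quad.f_and_Gv(z)
            if f_z <= f_y + float(grad @ d) + 0.5 * float(d @ d) / step + 1e-15:
                break
            step *= 0.5
            if step < 1e-18:
                break
        F_z = f_z + _penalty(z, lam, structure)
        if F_z > F_x:
            # monotone safeguard: reject the proximal point, restart momentum
            # (the next step is plain proximal gradient from x, which cannot
            # increase the objective)
            yk = x.copy()
            t_prev = 1.0
            if it % check_every == 0:
                if _kkt_gap_q(quad, x, lam, structure, c=c_x) <= kkt_tol:
                    converged = True
                    break
            continue
        rel = (F_x - F_z) / max(1.0, abs(F_z))
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_prev ** 2))
        yk = z + ((t_prev - 1.0) / t_new) * (z - x)
        x, F_x, t_prev = z, F_z, t_new
        c_x = (quad.b - Gz) / quad.n
        if history is not None:
            history.append(F_x)
        stalled = rel < tol
        if stalled or it % check_every == 0:
            if _kkt_gap_q(quad, x, lam, structure, c=c_x) <= kkt_tol:
                converged = True
                break
        if stalled:
            # objective stalled short of optimality: polish the active set,
            # then restart momentum
            if polish:
                x = _polish_active(quad, x, lam, structure)
                F_x = _objective_q(quad, x, lam, structure)
                c_x = None
                if _kkt_gap_q(quad, x, lam, structure) <= kkt_tol:
                    converged = True
                    break
            stalls += 1
            if stalls >= 50:
                break
            yk = x.copy()
            t_prev = 1.0
    if not converged and polish:
        x2 = _polish_active(quad, x, lam, structure)
        F2 = _objective_q(quad, x2, lam, structure)
        if F2 <= F_x:
            x, F_x = x2, F2
    # remove numerically-null groups (no objective change at this scale)
    if structure.n_groups:
        nrm = structure.group_norms(x)
        ref = max(1.0, float(np.max(nrm)))
        for g in np.flatnonzero((nrm > 0) & (nrm < 1e-11 * ref)):
            start = int(structure.offsets[g])
            x[start:start + int(structure.sizes[g])] = 0.0
    gap = _kkt_gap_q(quad, x, lam, structure)
    if not converged and gap <= kkt_tol:
        converged = True
    if not converged and warn:
        warnings.warn(
            f"group LASSO did not converge in {max_iter} iterations "
            f"(KKT gap {gap:.2e})", RuntimeWarning)
    norms = structure.group_norms(x)
    selected = [g for g in range(structure.n_groups) if norms[g] > 0]
    return LassoFit(lam=float(lam), v=x, beta=structure.collapse(x),
                    selected_groups=selected, objective=F_x,
                    iterations=it, converged=converged, kkt_gap=gap)


def kkt_residuals(fit: LassoFit, X: np.ndarray, y: np.ndarray,
                  structure: GroupStructure) -> np.ndarray:
    """Per-group KKT optimality gaps at the fitted coefficients."""
    Xt = structure.expand(np.asarray(X, dtype=float))
    n = y.size
    c = Xt.T @ (y - Xt @ fit.v) / n
    return _group_gaps(c, fit.v, fit.lam, structure)


# ---------------------------------------------------------------------------
# penalty path and cross-validation
# ---------------------------------------------------------------------------


def lambda_max(X: np.ndarray, y: np.ndarray, structure: GroupStructure) -> float:
    """Smallest penalty at which every penalized group is zero."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if structure.n_unpen:
        Xu = X[:, structure.unpenalized_columns]
        coef, *_ = np.linalg.lstsq(Xu, y, rcond=None)
        r0 = y - Xu @ coef
    else:
        r0 = y
    lam = 0.0
    for g in range(structure.n_groups):
        cg = X[:, structure.group_columns[g]].T @ r0 / n
        lam = max(lam, float(np.linalg.norm(cg)) / structure.weights[g])
    return lam


def lambda_path(X: np.ndarray, y: np.ndarray, structure: GroupStructure,
                n_lambdas: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max to ratio*lambda_max."""
    lmax = lambda_max(X, y, structure)
    if lmax <= 0:
        raise ValueError("degenerate design: lambda_max is 0")
    return np.geomspace(lmax, ratio * lmax, n_lambdas)


def _subject_folds(subject_ids: np.ndarray, k: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of subjects into k folds; returns row-index arrays."""
    subjects = np.unique(subject_ids)
    if subjects.size < k:
        raise ValueError(f"{subjects.size} subjects < {k} folds")
    perm = rng.permutation(subjects)
    folds = np.array_split(perm, k)
    return [np.flatnonzero(np.isin(subject_ids, f)) for f in folds]


def cv_select(X: np.ndarray, y: np.ndarray, structure: GroupStructure,
              subject_ids: np.ndarray, k: int = 10,
              rng: np.random.Generator | None = None,
              n_lambdas: int = 100, lambda_min_ratio: float = 1e-3,
              tol: float = 1e-8, max_iter: int = 20_000,
              fold_kkt_tol: float = 1e-3,
              lambdas: np.ndarray | None = None):
    """Choose the penalty by subject-level k-fold CV prediction error.

    Returns ``(lam_star, selected_group_ids, info)`` where ``info`` carries
    the grid, pooled held-out MSE per grid point, and the full-data fit at
    the chosen penalty.  Warm starts run down the path within each fold.
    """
    rng = np.random.default_rng() if rng is None else rng
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = lambda_path(X, y, structure, n_lambdas, lambda_min_ratio)
    Xt = structure.expand(X)
    quad_full = _Quad(Xt, y)
    folds = _subject_folds(np.asarray(subject_ids), k, rng)
    # fold fits are effort-capped: their precision only affects held-out
    # prediction error, so they run without polishing at a loose KKT
    # tolerance and a reduced iteration cap
    fold_iter = min(max_iter, 2000)
    sse = np.zeros(lambdas.size)
    for test_idx in folds:
        Xt_te, y_te = Xt[test_idx], y[test_idx]
        quad_tr = _Quad(G=quad_full.G - Xt_te.T @ Xt_te,
                        b=quad_full.b - Xt_te.T @ y_te,
                        yty=quad_full.yty - float(y_te @ y_te),
                        n=quad_full.n - y_te.size)
        lip = quad_tr.lipschitz()
        v = None
        for j, lam in enumerate(lambdas):
            fit = fit_group_lasso(None, None, structure, lam,
                                  tol=max(tol, 1e-8), max_iter=fold_iter,
                                  kkt_tol=fold_kkt_tol, v0=v, quad=quad_tr,
                                  lip=lip, polish=False, warn=False)
            v = fit.v
            resid = y_te - Xt_te @ v
            sse[j] += float(resid @ resid)
    mse = sse / y.size
    j_star = int(np.argmin(mse))
    lam_star = float(lambdas[j_star])
    # full-data fit, warm-started down the path to the chosen penalty;
    # only the final fit needs full precision
    lip = quad_full.lipschitz()
    v = None
    for lam in lambdas[:j_star]:
        warm = fit_group_lasso(None, None, structure, lam, tol=max(tol, 1e-8),
                               max_iter=fold_iter, kkt_tol=fold_kkt_tol,
                               v0=v, quad=quad_full, lip=lip, polish=False,
                               warn=False)
        v = warm.v
    full_fit = fit_group_lasso(None, None, structure, lam_star, tol=tol,
                               max_iter=max_iter, v0=v, quad=quad_full,
                               lip=lip)
    info = {"lambdas": lambdas, "cv_mse": mse, "fit": full_fit}
    return lam_star, full_fit.selected_groups, info


def stability_select(X: np.ndarray, y: np.ndarray, structure: GroupStructure,
                     subject_ids: np.ndarray, reps: int = 200, k: int = 10,
                     rng: np.random.Generator | None = None,
                     freq_cutoff: float = 0.5, **cv_kwargs) -> StabilityResult:
    """Aggregate repeated randomized-CV selections into a final model.

    The per-group selection frequency is the fraction of repetitions whose
    CV-chosen fit included the group; the final set keeps groups with
    frequency >= ``freq_cutoff``.  If that set contains no interaction group
    the fallback model is used: all HMO and all species main-effect groups.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    counts = np.zeros(structure.n_groups)
    lams = np.zeros(reps)
    for r in range(reps):
        lam, selected, _ = cv_select(X, y, structure, subject_ids, k=k,
                                     rng=rng, **cv_kwargs)
        lams[r] = lam
        counts[selected] += 1
    freqs = counts / reps
    final = [g for g in range(structure.n_groups) if freqs[g] >= freq_cutoff]
    has_interaction = any(structure.group_kinds[g] == "interaction" for g in final)
    fallback = not has_interaction
    if fallback:
        final = [g for g in range(structure.n_groups)
                 if structure.group_kinds[g] in ("hmo", "mb")]
    return StabilityResult(frequencies=freqs, lambdas=lams, final_groups=final,
                           fallback_used=fallback, freq_cutoff=freq_cutoff,
                           group_names=list(structure.group_names),
                           group_kinds=list(structure.group_kinds))
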