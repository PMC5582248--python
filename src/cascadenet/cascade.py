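"""Time-dependent regulatory network inference by Lasso cascades.

Genes are partitioned into K time-clusters; regulation is only allowed
from strictly earlier clusters to later ones, which makes the network a
DAG by construction.  For each target gene n the trajectory over
timepoints 2..T (stacked across subjects) is regressed on the
time-actions of candidate regulators' trajectories over 1..T-1:

    x~_n = sum_{n'} F_{m(n') m(n)} w_{n'n} x^_{n'} + eps,

where w_{n'n} is the signed connection strength and F_{ab} a causal
(lower-triangular Toeplitz) operator shared by all regulator/target
pairs of cluster pair (a, b).  Estimation alternates an L1-penalized
(Lasso) regression for w — the penalty level chosen by cross-validation
over subjects with a one-standard-error rule — with least squares for
the F operators, and monitors a penalized objective that is
non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import Lasso

from .synthetic import ExpressionCube

__all__ = [
    "TimeClusterAssignment",
    "LaggedViews",
    "CascadeModel",
    "assign_time_clusters",
    "lagged_views",
    "fit",
    "predict",
]


@dataclass(frozen=True)
class TimeClusterAssignment:
    """Map m(n) from gene to time-cluster index in 1..K."""

    m: Mapping[str, int]
    K: int
    flagged: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.m.items() if not 1 <= c <= self.K}
        if bad:
            raise ValueError(f"cluster indices outside 1..{self.K}: {bad}")


@dataclass(frozen=True)
class LaggedViews:
    """Response/predictor views of a cube, stacked subject-major.

    ``xtilde`` (response side) holds timepoints 2..T and ``xhat``
    (predictor side) timepoints 1..T-1; both are (n_genes, P*(T-1)),
    shifted views of the same centered cube.
    """

    xtilde: np.ndarray
    xhat: np.ndarray
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.xtilde.shape != self.xhat.shape:
            raise ValueError("response and predictor views must align")


@dataclass
class CascadeModel:
    """Fitted cascade network.

    ``w[i, j]`` is the connection strength of genes[i] -> genes[j] (zero
    unless m(i) < m(j)); ``F[(a, b)]`` the (T-1)x(T-1) lower-triangular
    time-action for cluster pair a -> b; ``lambda_n`` the per-target
    penalty level actually used; ``sigma2`` the residual variance of the
    regulated genes.  ``center`` holds the training cube's per-(gene,
    timepoint) means so predictions for new cubes live on the same
    centered scale; ``scale`` the per-gene predictor scaling still to be
    applied at prediction time (all ones when, as after ``fit``, the
    standardization has been folded into w).
    """

    genes: tuple[str, ...]
    w: np.ndarray
    F: dict[tuple[int, int], np.ndarray]
    lambda_n: dict[str, float]
    sigma2: float
    clusters: TimeClusterAssignment
    timepoints: tuple[float, ...]
    center: np.ndarray
    scale: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        order = {g: self.clusters.m[g] for g in self.genes}
        gi = {g: i for i, g in enumerate(self.genes)}
        for g_reg in self.genes:
            for g_tgt in self.genes:
                if order[g_reg] >= order[g_tgt] and self.w[gi[g_reg], gi[g_tgt]] != 0:
                    raise ValueError(
                        f"nonzero weight on non-forward pair {g_reg}->{g_tgt}"
                    )
        for (a, b), f in self.F.items():
            if not np.allclose(f, np.tril(f)):
                raise ValueError(f"F[{a},{b}] is not lower-triangular")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")

    def edges(self, cutoff: float = 0.0) -> list[tuple[str, str, float]]:
        """Directed edges with |weight| strictly above ``cutoff``."""
        out = []
        for i, reg in enumerate(self.genes):
            for j, tgt in enumerate(self.genes):
                if abs(self.w[i, j]) > cutoff:
                    out.append((reg, tgt, float(self.w[i, j])))
        return out


def assign_time_clusters(cube: ExpressionCube, K: int) -> TimeClusterAssignment:
    """Assign genes to K time-clusters by peak time of activity.

    Timepoints 2..T are partitioned into K contiguous bins; a gene's
    cluster is the bin containing the timepoint where its
    subject-averaged, per-gene-centered absolute expression peaks.
    Constant genes have no peak: they go to cluster K and are flagged.
    """
    T = cube.n_timepoints
    if not 1 <= K <= T - 1:
        raise ValueError(f"K must be in 1..{T - 1}")
    prof = cube.values.mean(axis=1)  # genes x timepoints
    centered = prof - prof.mean(axis=1, keepdims=True)
    bins = np.array_split(np.arange(1, T), K)
    bin_of = {int(t): k + 1 for k, idxs in enumerate(bins) for t in idxs}
    m: dict[str, int] = {}
    flagged: set[str] = set()
    late = np.abs(centered[:, 1:])
    for i, g in enumerate(cube.genes):
        if np.max(np.abs(centered[i])) < 1e-12:
            m[g] = K
            flagged.add(g)
        else:
            m[g] = bin_of[int(np.argmax(late[i])) + 1]
    return TimeClusterAssignment(m, K, frozenset(flagged))


def _center(cube: ExpressionCube) -> tuple[np.ndarray, np.ndarray]:
    """Per-(gene, timepoint) centering across subjects."""
    center = cube.values.mean(axis=1)  # (G, T)
    return cube.values - center[:, None, :], center


def lagged_views(cube: ExpressionCube, *, center: np.ndarray | None = None) -> LaggedViews:
    """Build the stacked response/predictor views of a cube.

    Values are centered per gene and timepoint across subjects (with the
    cube's own means unless ``center`` is supplied), then split into the
    response window 2..T and the predictor window 1..T-1 and stacked
    subject-major into (genes, P*(T-1)) matrices.
    """
    if center is None:
        c, _ = _center(cube)
    else:
        c = cube.values - center[:, None, :]
    G, P, T = c.shape
    xtilde = c[:, :, 1:].reshape(G, P * (T - 1))
    xhat = c[:, :, :-1].reshape(G, P * (T - 1))
    return LaggedViews(xtilde, xhat, cube.genes)


def _toeplitz_apply(f: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Apply the causal Toeplitz operator with subdiagonals f to x.

    x has shape (..., L) holding per-subject windows; entry k of f
    weights the signal delayed by k steps.
    """
    L = x.shape[-1]
    out = np.zeros_like(x)
    for k in range(L):
        if f[k] != 0.0:
            if k == 0:
                out += f[k] * x
            else:
                out[..., k:] += f[k] * x[..., :-k]
    return out


def _toeplitz_matrix(f: np.ndarray) -> np.ndarray:
    L = f.shape[0]
    F = np.zeros((L, L))
    for k in range(L):
        idx = np.arange(k, L)
        F[idx, idx - k] = f[k]
    return F


def _subdiagonals(F: np.ndarray) -> np.ndarray:
    L = F.shape[0]
    return np.array([F[k, 0] for k in range(L)])


class _Problem:
    """Internal fitting state on the centered, scaled, stacked data."""

    def __init__(
        self,
        cube: ExpressionCube,
        clusters: TimeClusterAssignment,
        standardize: bool,
        subjects_mask: np.ndarray | None = None,
        center: np.ndarray | None = None,
        scale: np.ndarray | None = None,
    ) -> None:
        vals = cube.values if subjects_mask is None else cube.values[:, subjects_mask, :]
        G, P, T = vals.shape
        if center is None:
            center = vals.mean(axis=1)
        c = vals - center[:, None, :]
        self.G, self.P, self.T = G, P, T
        self.L = T - 1
        self.genes = cube.genes
        self.clusters = clusters
        self.center = center
        self.y = c[:, :, 1:]  # (G, P, L) response windows
        xh = c[:, :, :-1]
        if scale is None:
            if standardize:
                sd = xh.reshape(G, -1).std(axis=1)
                sd[sd == 0] = 1.0
            else:
                sd = np.ones(G)
        else:
            sd = scale
        self.scale = sd
        self.xhat = xh / sd[:, None, None]
        gi = {g: i for i, g in enumerate(cube.genes)}
        self.candidates = {
            gi[g]: [gi[h] for h in cube.genes if clusters.m[h] < clusters.m[g]]
            for g in cube.genes
        }
        self.pairs_of = {
            (clusters.m[reg], clusters.m[tgt])
            for tgt in cube.genes
            for reg in cube.genes
            if clusters.m[reg] < clusters.m[tgt]
        }

    def design(self, j: int, F: dict) -> np.ndarray:
        """Predictor matrix for target j: one column per candidate."""
        cands = self.candidates[j]
        X = np.empty((self.P * self.L, len(cands)))
        b = self.clusters.m[self.genes[j]]
        for col, i in enumerate(cands):
            a = self.clusters.m[self.genes[i]]
            X[:, col] = (self.xhat[i] @ F[(a, b)].T).reshape(-1)
        return X

    def predictions(self, w: np.ndarray, F: dict) -> np.ndarray:
        """Model predictions for all genes, shape (G, P, L)."""
        out = np.zeros((self.G, self.P, self.L))
        for j in range(self.G):
            b = self.clusters.m[self.genes[j]]
            for i in self.candidates[j]:
                if w[i, j] != 0.0:
                    a = self.clusters.m[self.genes[i]]
                    out[j] += w[i, j] * (self.xhat[i] @ F[(a, b)].T)
        return out

    def objective(self, w: np.ndarray, F: dict, alpha: np.ndarray) -> float:
        """Penalized objective on sklearn's scale, summed over targets."""
        pred = self.predictions(w, F)
        n = self.P * self.L
        rss = ((self.y - pred) ** 2).reshape(self.G, -1).sum(axis=1)
        pen = alpha * np.abs(w).sum(axis=0)
        return float(np.sum(rss / (2 * n) + pen))


def _identity_F(pairs, L) -> dict[tuple[int, int], np.ndarray]:
    return {p: np.eye(L) for p in pairs}


def _w_step(prob: _Problem, F: dict, alpha: np.ndarray) -> np.ndarray:
    w = np.zeros((prob.G, prob.G))
    for j in range(prob.G):
        cands = prob.candidates[j]
        if not cands:
            continue
        X = prob.design(j, F)
        y = prob.y[j].reshape(-1)
        if alpha[j] <= 0:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        else:
            model = Lasso(
                alpha=float(alpha[j]), fit_intercept=False, max_iter=100000, tol=1e-10
            )
            model.fit(X, y)
            coef = model.coef_
        for c, i in enumerate(cands):
            w[i, j] = coef[c]
    return w


def _f_step(prob: _Problem, w: np.ndarray, F: dict) -> dict:
    """Least-squares update of each Toeplitz time-action, Gauss-Seidel."""
    F = {k: v.copy() for k, v in F.items()}
    pred = prob.predictions(w, F)
    resid = prob.y - pred
    for (a, b) in sorted(prob.pairs_of):
        f_old = _subdiagonals(F[(a, b)])
        targets = [
            j
            for j in range(prob.G)
            if prob.clusters.m[prob.genes[j]] == b
            and any(
                w[i, j] != 0.0 and prob.clusters.m[prob.genes[i]] == a
                for i in prob.candidates[j]
            )
        ]
        if not targets:
            continue
        rows_y, rows_X = [], []
        for j in targets:
            u = np.zeros((prob.P, prob.L))
            for i in prob.candidates[j]:
                if w[i, j] != 0.0 and prob.clusters.m[prob.genes[i]] == a:
                    u += w[i, j] * prob.xhat[i]
            # response: residual with this pair's old contribution restored
            part = _toeplitz_apply(f_old, u)
            rows_y.append((resid[j] + part).reshape(-1))
            cols = np.stack(
                [np.roll(u, k, axis=1) * (np.arange(prob.L) >= k) for k in range(prob.L)],
                axis=-1,
            )
            rows_X.append(cols.reshape(-1, prob.L))
        yv = np.concatenate(rows_y)
        Xv = np.vstack(rows_X)
        f_new, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
        F[(a, b)] = _toeplitz_matrix(f_new)
        # keep the running residual consistent with the updated operator
        for j in targets:
            u = np.zeros((prob.P, prob.L))
            for i in prob.candidates[j]:
                if w[i, j] != 0.0 and prob.clusters.m[prob.genes[i]] == a:
                    u += w[i, j] * prob.xhat[i]
            resid[j] += _toeplitz_apply(f_old, u) - _toeplitz_apply(f_new, u)
    return F


def _alpha_max(prob: _Problem, F: dict) -> np.ndarray:
    """Smallest penalty that zeroes every coefficient, per target."""
    n = prob.P * prob.L
    out = np.zeros(prob.G)
    for j in range(prob.G):
        if not prob.candidates[j]:
            continue
        X = prob.design(j, F)
        y = prob.y[j].reshape(-1)
        out[j] = np.max(np.abs(X.T @ y)) / n if X.size else 0.0
    return out


def _make_folds(P: int, cv: str, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(P)
    if cv == "auto":
        cv = "loo" if P <= 8 else "5fold"
    if cv == "loo":
        return [np.array([p]) for p in perm]
    if cv == "5fold":
        return [f for f in np.array_split(perm, 5) if f.size]
    raise ValueError("cv must be 'auto', 'loo' or '5fold'")


def _cv_relative_penalty(
    cube: ExpressionCube,
    clusters: TimeClusterAssignment,
    *,
    standardize: bool,
    folds: Sequence[np.ndarray],
    grid: np.ndarray,
    cv_iterations: int,
    one_se: bool,
) -> float:
    """Pick the relative penalty r (alpha_n = r * alpha_max_n) by CV.

    Within each training fold the fit alternates w and F updates
    ``cv_iterations`` times so the operators are re-estimated during
    cross-validation; validation error is the mean squared prediction
    error on the held-out subjects, over the regulated genes only (the
    penalty has no influence on candidate-free genes, whose variance
    would otherwise swamp the criterion).  The one-standard-error rule
    moves the choice toward the heaviest penalty within one SE of the
    minimum.
    """
    P = cube.n_subjects
    errors = np.zeros((len(grid), len(folds)))
    for fi, hold in enumerate(folds):
        train = np.setdiff1d(np.arange(P), hold)
        prob_tr = _Problem(cube, clusters, standardize, subjects_mask=train)
        prob_va = _Problem(
            cube,
            clusters,
            standardize,
            subjects_mask=hold,
            center=prob_tr.center,
            scale=prob_tr.scale,
        )
        amax = _alpha_max(prob_tr, _identity_F(prob_tr.pairs_of, prob_tr.L))
        regulated = [j for j in range(prob_tr.G) if prob_tr.candidates[j]]
        for gi_, r in enumerate(grid):
            F = _identity_F(prob_tr.pairs_of, prob_tr.L)
            alpha = r * amax
            w = np.zeros((prob_tr.G, prob_tr.G))
            for _ in range(cv_iterations):
                w = _w_step(prob_tr, F, alpha)
                F = _f_step(prob_tr, w, F)
            pred = prob_va.predictions(w, F)
            errors[gi_, fi] = float(
                np.mean((prob_va.y[regulated] - pred[regulated]) ** 2)
            )
    mean_err = errors.mean(axis=1)
    best = int(np.argmin(mean_err))
    if not one_se or len(folds) < 2:
        return float(grid[best])
    se = errors[best].std(ddof=1) / np.sqrt(len(folds))
    heavy = np.where(mean_err <= mean_err[best] + se)[0]
    return float(grid[int(heavy.max())])  # grid sorted ascending in r


def fit(
    cube: ExpressionCube,
    clusters: TimeClusterAssignment,
    *,
    cv: str = "auto",
    alpha: float | None = None,
    relative_penalty: float | None = None,
    standardize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 50,
    cv_iterations: int = 2,
    grid_size: int = 15,
    grid_min_ratio: float = 1e-3,
    one_se: bool = True,
    update_f: bool = True,
    seed: int = 0,
) -> CascadeModel:
    """Fit the cascade model by alternating Lasso and operator updates.

    The per-target penalty is ``alpha`` if given (absolute, on the
    sklearn scale), else ``relative_penalty * alpha_max_n``, else chosen
    by cross-validation over subjects.  The penalty is fixed before the
    alternating loop starts, so the penalized objective decreases at
    every half-step; a non-decreasing objective aborts with a
    diagnostic.  After convergence each time-action is rescaled to a
    unit-norm impulse response with the scale folded into w, which
    leaves all predictions unchanged.
    """
    if cube.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if cube.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    for g in cube.genes:
        if g not in clusters.m:
            raise ValueError(f"gene {g} missing from cluster assignment")

    prob = _Problem(cube, clusters, standardize)
    F = _identity_F(prob.pairs_of, prob.L)
    if alpha is not None:
        alpha_n = np.full(prob.G, float(alpha))
    else:
        if relative_penalty is None:
            grid = np.geomspace(grid_min_ratio, 1.0, grid_size)
            folds = _make_folds(prob.P, cv, seed)
            relative_penalty = _cv_relative_penalty(
                cube,
                clusters,
                standardize=standardize,
                folds=folds,
                grid=grid,
                cv_iterations=cv_iterations,
                one_se=one_se,
            )
        alpha_n = relative_penalty * _alpha_max(prob, F)

    w = np.zeros((prob.G, prob.G))
    trace = [prob.objective(w, F, alpha_n)]
    converged = False
    for it in range(max_iter):
        w = _w_step(prob, F, alpha_n)
        if update_f:
            F = _f_step(prob, w, F)
        obj = prob.objective(w, F, alpha_n)
        if obj > trace[-1] * (1 + 1e-9) + 1e-12:
            raise RuntimeError(
                f"objective increased at iteration {it + 1}: "
                f"{trace[-1]:.6g} -> {obj:.6g}"
            )
        rel = abs(trace[-1] - obj) / max(abs(trace[-1]), 1e-30)
        trace.append(obj)
        if rel < tol:
            converged = True
            break

    # unit-norm impulse responses; fold the scale into w
    for (a, b), Fab in F.items():
        f = _subdiagonals(Fab)
        c = float(np.linalg.norm(f))
        if c > 0:
            F[(a, b)] = _toeplitz_matrix(f / c)
            for j in range(prob.G):
                if clusters.m[prob.genes[j]] != b:
                    continue
                for i in prob.candidates[j]:
                    if clusters.m[prob.genes[i]] == a:
                        w[i, j] *= c

    # report w on the original (unstandardized) predictor scale
    w = w / prob.scale[:, None]

    pred_prob = _Problem(cube, clusters, standardize=False, center=prob.center)
    pred = pred_prob.predictions(w, F)
    regulated = [j for j in range(prob.G) if prob.candidates[j]]
    if regulated:
        sigma2 = float(np.mean((prob.y[regulated] - pred[regulated]) ** 2))
    else:
        sigma2 = 0.0

    return CascadeModel(
        genes=cube.genes,
        w=w,
        F=F,
        lambda_n={g: float(alpha_n[i]) for i, g in enumerate(cube.genes)},
        sigma2=sigma2,
        clusters=clusters,
        timepoints=cube.timepoints,
        center=prob.center,
        scale=np.ones(prob.G),  # w already on the original predictor scale
        objective_trace=trace,
        n_iter=len(trace) - 1,
        converged=converged,
    )


def predict(model: CascadeModel, cube: ExpressionCube) -> np.ndarray:
    """Fitted response values for timepoints 2..T given observed x^.

    The cube is centered with the model's stored per-(gene, timepoint)
    means and the predictor side scaled with the stored scales, so the
    output (genes, subjects, T-1) lives on the model's centered response
    scale; genes without candidate regulators predict 0 there.
    """
    if cube.genes != model.genes:
        raise ValueError("gene set mismatch between model and cube")
    if cube.timepoints != model.timepoints:
        raise ValueError("timepoint mismatch between model and cube")
    c = cube.values - model.center[:, None, :]
    xhat = c[:, :, :-1] / model.scale[:, None, None]
    G, P, L = xhat.shape
    gi = {g: i for i, g in enumerate(model.genes)}
    out = np.zeros((G, P, L))
    for j, tgt in enumerate(model.genes):
        b = model.clusters.m[tgt]
        for i, reg in enumerate(model.genes):
            if model.w[i, j] != 0.0:
                a = model.clusters.m[reg]
                out[j] += model.w[i, j] * (xhat[i] @ model.F[(a, b)].T)
    return out
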