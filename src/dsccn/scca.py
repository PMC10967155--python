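"""Sparse canonical correlation analysis with fused and graph-guided penalties.

The model couples two preprocessed (column-centered, unit-norm) matrices
X (s x m) and Y (s x n) through

    min_{u,v}  -u' X' Y v + phi_FGL(u) + phi_GGL(v)
    s.t.       ||X u||^2 <= 1,  ||Y v||^2 <= 1,

where phi_FGL(u) = gamma1 * sum_k w_{k,k+1} sqrt(u_k^2 + u_{k+1}^2) smooths
adjacent mRNA features and phi_GGL(v) = gamma2 * sum_{(p,q) in E} w_{p,q}
sqrt(v_p^2 + v_q^2) smooths graph-connected methylation features.

Solver
------
Alternating block minimization with iterative reweighting.  Holding one block
and the current penalty weights fixed, the subproblem is a convex quadratic
objective under a single quadratic norm constraint; its KKT system is a linear
solve parametrised by the constraint multiplier, which we root-find by Brent's
method — an exact solution of the "standard quadratic programming" step.  In
the default ``reweighted`` mode the weights w = 1 / (2 sqrt(.^2 + .^2 + eps))
majorize the (eps-smoothed) penalty, so the recorded objective history is
non-increasing.  A ``paper`` mode using w_{k,k+1} = u_k^2 verbatim is kept for
fidelity experiments; it carries no monotonicity guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "preprocess",
    "build_edge_set",
    "fgl_penalty",
    "ggl_penalty",
    "objective",
    "update_weights",
    "canonical_correlation",
    "select_top_features",
    "grid_search_gamma",
    "solve_fgl_scca",
    "FGLSCCA",
    "FeatureSelection",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _preprocess_fit(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    centered = X - means
    norms = np.linalg.norm(centered, axis=0)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"constant column at feature index {bad[0]}")
    return centered / norms, means, norms


def preprocess(X_raw) -> np.ndarray:
    """Center each column to mean zero and scale it to unit Euclidean norm."""
    Xp, _, _ = _preprocess_fit(X_raw)
    return Xp


def build_edge_set(n: int, graph=None) -> list[tuple[int, int]]:
    """Unordered edge set over ``n`` features.

    Without a graph the complete graph is used (every unordered pair once,
    matching an incidence construction with n*(n-1) ordered rows).  ``graph``
    may be an n x n adjacency matrix or an iterable of index pairs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if graph is None:
        return [(p, q) for p in range(n) for q in range(p + 1, n)]
    graph = np.asarray(graph)
    if graph.ndim == 2 and graph.shape == (n, n):
        pairs = zip(*np.nonzero(graph))
    else:
        pairs = (tuple(e) for e in graph)
    edges = set()
    for p, q in pairs:
        p, q = int(p), int(q)
        if not (0 <= p < n and 0 <= q < n):
            raise ValueError(f"edge ({p}, {q}) out of range for n={n}")
        if p != q:
            edges.add((min(p, q), max(p, q)))
    return sorted(edges)


# ---------------------------------------------------------------------------
# penalties and objective
# ---------------------------------------------------------------------------

def fgl_penalty(u, omega_u, gamma1: float) -> float:
    """gamma1 * sum_k omega_k * sqrt(u_k^2 + u_{k+1}^2) over adjacent pairs."""
    u = np.asarray(u, dtype=float)
    omega_u = np.asarray(omega_u, dtype=float)
    if omega_u.shape != (max(u.size - 1, 0),):
        raise ValueError("omega_u must have length len(u) - 1")
    if u.size < 2:
        return 0.0
    return float(gamma1 * np.sum(omega_u * np.sqrt(u[:-1] ** 2 + u[1:] ** 2)))


def _edge_arrays(edge_set) -> tuple[np.ndarray, np.ndarray]:
    edges = np.asarray(list(edge_set), dtype=int)
    if edges.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return edges[:, 0], edges[:, 1]


def ggl_penalty(v, omega_v, gamma2: float, edge_set) -> float:
    """gamma2 * sum_{(p,q) in E} omega_pq * sqrt(v_p^2 + v_q^2)."""
    v = np.asarray(v, dtype=float)
    omega_v = np.asarray(omega_v, dtype=float)
    p, q = _edge_arrays(edge_set)
    if omega_v.shape != p.shape:
        raise ValueError("omega_v must have one entry per edge")
    if p.size == 0:
        return 0.0
    if p.max(initial=-1) >= v.size or q.max(initial=-1) >= v.size:
        raise ValueError("edge index out of range")
    return float(gamma2 * np.sum(omega_v * np.sqrt(v[p] ** 2 + v[q] ** 2)))


def objective(X, Y, u, v, omega_u, omega_v, gamma1, gamma2, edge_set) -> float:
    """Evaluate -u' X' Y v + phi_FGL(u) + phi_GGL(v) (no feasibility check)."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    u, v = np.asarray(u, float), np.asarray(v, float)
    if X.shape[1] != u.size or Y.shape[1] != v.size or X.shape[0] != Y.shape[0]:
        raise ValueError("dimension mismatch between matrices and weight vectors")
    bilinear = float(u @ (X.T @ (Y @ v)))
    return -bilinear + fgl_penalty(u, omega_u, gamma1) + ggl_penalty(
        v, omega_v, gamma2, edge_set
    )


def update_weights(
    u_prev,
    v_prev,
    edge_set,
    eps: float = 1e-6,
    mode: str = "reweighted",
) -> tuple[np.ndarray, np.ndarray]:
    """Penalty weights from the previous iterate.

    ``reweighted`` (default): w = 1 / (2 sqrt(a^2 + b^2 + eps)), the standard
    half-inverse-norm rule that majorizes the smoothed group penalty.
    ``paper``: w_{k,k+1} = u_k^2 (and w_{p,q} = v_p^2) taken verbatim.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    u_prev = np.asarray(u_prev, dtype=float)
    v_prev = np.asarray(v_prev, dtype=float)
    p, q = _edge_arrays(edge_set)
    if mode == "reweighted":
        omega_u = 1.0 / (2.0 * np.sqrt(u_prev[:-1] ** 2 + u_prev[1:] ** 2 + eps))
        omega_v = 1.0 / (2.0 * np.sqrt(v_prev[p] ** 2 + v_prev[q] ** 2 + eps))
    elif mode == "paper":
        omega_u = u_prev[:-1] ** 2
        omega_v = v_prev[p] ** 2
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    return omega_u, omega_v


def _smoothed_objective(XtY, u, v, gamma1, gamma2, p, q, eps) -> float:
    """Objective with eps-smoothed penalties (the quantity MM decreases)."""
    pen_u = gamma1 * np.sum(np.sqrt(u[:-1] ** 2 + u[1:] ** 2 + eps)) if u.size > 1 else 0.0
    pen_v = gamma2 * np.sum(np.sqrt(v[p] ** 2 + v[q] ** 2 + eps)) if p.size else 0.0
    return float(-(u @ (XtY @ v)) + pen_u + pen_v)


def canonical_correlation(X, u, Y, v) -> float:
    """Pearson correlation of the canonical scores X u and Y v."""
    a = np.asarray(X, float) @ np.asarray(u, float)
    b = np.asarray(Y, float) @ np.asarray(v, float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant canonical score vector; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# constrained quadratic subproblem
# ---------------------------------------------------------------------------

def _solve_subproblem(b: np.ndarray, A: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Minimize -b'u + u' diag(d) u subject to u' A u <= 1 (A PSD, d >= 0).

    KKT: (2 diag(d) + 2 lam A) u = b with lam >= 0 and complementary
    slackness; the constraint residual is strictly decreasing in lam, so the
    active-constraint multiplier is found by Brent root-finding.
    """
    m = b.size
    if not np.any(b):
        return np.zeros(m)

    def u_of(lam: float) -> np.ndarray:
        M = 2.0 * lam * A
        M[np.diag_indices_from(M)] += 2.0 * d
        try:
            return np.linalg.solve(M, b)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(M, b, rcond=None)[0]

    def resid(lam: float) -> float:
        u = u_of(lam)
        return float(u @ (A @ u) - 1.0)

    if np.all(d > 0):
        u0 = b / (2.0 * d)
        if u0 @ (A @ u0) <= 1.0:
            return u0
        lam_lo = 0.0
    elif not np.any(d):
        # Pure linear objective: boundary solution in closed form.
        t = np.linalg.lstsq(A, b, rcond=None)[0]
        scale = t @ (A @ t)
        if scale <= 0:
            return np.zeros(m)
        return t / np.sqrt(scale)
    else:
        lam_lo = 1e-12
        if resid(lam_lo) <= 0:
            return u_of(lam_lo)

    lam_hi = 1.0
    for _ in range(200):
        if resid(lam_hi) < 0:
            break
        lam_hi *= 4.0
    lam = optimize.brentq(resid, lam_lo, lam_hi, xtol=1e-14, rtol=1e-14)
    return u_of(lam)


def _fgl_diag(omega_u: np.ndarray, gamma1: float, m: int) -> np.ndarray:
    d = np.zeros(m)
    if m > 1:
        d[:-1] += gamma1 * omega_u
        d[1:] += gamma1 * omega_u
    return d


def _ggl_diag(
    omega_v: np.ndarray, gamma2: float, p: np.ndarray, q: np.ndarray, n: int
) -> np.ndarray:
    d = np.zeros(n)
    if p.size:
        np.add.at(d, p, gamma2 * omega_v)
        np.add.at(d, q, gamma2 * omega_v)
    return d


# ---------------------------------------------------------------------------
# fitted-result containers
# ---------------------------------------------------------------------------

@dataclass
class SCCAFit:
    """Solution of the penalized CCA problem."""

    u: np.ndarray
    v: np.ndarray
    omega_u: np.ndarray
    omega_v: np.ndarray
    objective_history: list[float] = field(default_factory=list)
    corr_train: float = np.nan
    n_iter: int = 0
    converged: bool = False
    degenerate: bool = False


@dataclass
class FeatureSelection:
    """Top-|weight| cross-omics feature selection."""

    m1: int
    n1: int
    idx_u: np.ndarray
    idx_v: np.ndarray
    X_corr: np.ndarray
    Y_corr: np.ndarray


def _top_indices(w: np.ndarray, k: int) -> np.ndarray:
    # stable sort on -|w|: ties at the cut keep the lower index
    order = np.argsort(-np.abs(w), kind="stable")[:k]
    return np.sort(order)


def select_top_features(u, v, m1: int, n1: int, X, Y) -> FeatureSelection:
    """Indices (ascending) of the m1 / n1 largest-|weight| features per omics."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if not (1 <= m1 <= u.size) or not (1 <= n1 <= v.size):
        raise ValueError("m1 and n1 must lie in [1, feature count]")
    idx_u = _top_indices(u, m1)
    idx_v = _top_indices(v, n1)
    return FeatureSelection(
        m1=m1, n1=n1, idx_u=idx_u, idx_v=idx_v,
        X_corr=X[:, idx_u], Y_corr=Y[:, idx_v],
    )


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class FGLSCCA(BaseEstimator):
    """Sparse CCA with a fused penalty on X-weights and a graph-guided penalty
    on Y-weights.

    Parameters
    ----------
    gamma1, gamma2 : float
        Penalty strengths for the fused (adjacent-pair) and graph-guided
        penalties.  Zero recovers classical CCA's first pair.
    edges : list of (int, int), optional
        Unordered feature-index pairs over Y's columns.  Default: the complete
        graph.
    weight_mode : {"reweighted", "paper"}
        Penalty-weight update rule (see :func:`update_weights`).
    eps : float
        Smoothing constant inside the reweighting.
    tol : float
        Relative objective-change convergence threshold.
    max_iter : int
        Maximum alternating rounds.

    Attributes
    ----------
    u_, v_ : ndarray
        Canonical weight vectors.
    objective_history_ : list of float
        Smoothed objective per round (non-increasing in ``reweighted`` mode).
    corr_train_ : float
        Pearson correlation of the training canonical scores.
    converged_, degenerate_ : bool
    """

    def __init__(
        self,
        gamma1: float = 0.0,
        gamma2: float = 0.0,
        edges=None,
        weight_mode: str = "reweighted",
        eps: float = 1e-6,
        tol: float = 1e-5,
        max_iter: int = 100,
    ):
        self.gamma1 = gamma1
        self.gamma2 = gamma2
        self.edges = edges
        self.weight_mode = weight_mode
        self.eps = eps
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("penalty strengths must be non-negative")
        m, n = X.shape[1], Y.shape[1]
        edges = self.edges if self.edges is not None else build_edge_set(n)
        p, q = _edge_arrays(edges)

        A_x, A_y = X.T @ X, Y.T @ Y
        XtY = X.T @ Y

        def init(mat, A, size):
            w = np.ones(size)
            nrm = np.sqrt(w @ (A @ w))
            return w / nrm if nrm > 0 else w / np.sqrt(size)

        u, v = init(X, A_x, m), init(Y, A_y, n)
        history = [_smoothed_objective(XtY, u, v, self.gamma1, self.gamma2, p, q, self.eps)]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            omega_u, omega_v = update_weights(u, v, edges, self.eps, self.weight_mode)
            u = _solve_subproblem(XtY @ v, A_x, _fgl_diag(omega_u, self.gamma1, m))
            v = _solve_subproblem(XtY.T @ u, A_y, _ggl_diag(omega_v, self.gamma2, p, q, n))
            obj = _smoothed_objective(XtY, u, v, self.gamma1, self.gamma2, p, q, self.eps)
            history.append(obj)
            if abs(history[-2] - obj) <= self.tol * max(1.0, abs(history[-2])):
                converged = True
                break

        degenerate = bool(
            np.max(np.abs(u), initial=0) < 1e-10 or np.max(np.abs(v), initial=0) < 1e-10
        )
        try:
            corr = np.nan if degenerate else canonical_correlation(X, u, Y, v)
        except ValueError:
            corr = np.nan
        self.edges_ = list(edges)
        self.u_, self.v_ = u, v
        self.omega_u_, self.omega_v_ = update_weights(
            u, v, edges, self.eps, self.weight_mode
        )
        self.objective_history_ = history
        self.corr_train_ = corr
        self.n_iter_ = it
        self.converged_ = converged
        self.degenerate_ = degenerate
        return self

    def transform(self, X, Y) -> tuple[np.ndarray, np.ndarray]:
        """Canonical score vectors (X u, Y v)."""
        check_is_fitted(self, "u_")
        return np.asarray(X, float) @ self.u_, np.asarray(Y, float) @ self.v_

    def fit_result(self) -> SCCAFit:
        check_is_fitted(self, "u_")
        return SCCAFit(
            u=self.u_,
            v=self.v_,
            omega_u=self.omega_u_,
            omega_v=self.omega_v_,
            objective_history=self.objective_history_,
            corr_train=self.corr_train_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            degenerate=self.degenerate_,
        )


def solve_fgl_scca(
    X,
    Y,
    gamma1: float = 0.0,
    gamma2: float = 0.0,
    edges=None,
    weight_mode: str = "reweighted",
    eps: float = 1e-6,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> SCCAFit:
    """Functional wrapper around :class:`FGLSCCA`; returns an :class:`SCCAFit`."""
    est = FGLSCCA(
        gamma1=gamma1, gamma2=gamma2, edges=edges, weight_mode=weight_mode,
        eps=eps, tol=tol, max_iter=max_iter,
    ).fit(X, Y)
    return est.fit_result()


def grid_search_gamma(
    X_raw,
    Y_raw,
    gamma1_grid,
    gamma2_grid,
    train_idx,
    test_idx,
    edges=None,
    **solver_kwargs,
) -> tuple[float, float, FGLSCCA, dict]:
    """Select (gamma1, gamma2) by held-out canonical correlation.

    Fits on the training rows for every grid pair (columns re-centered and
    re-normalized on the training rows; the same affine map is applied to the
    held-out rows) and picks the pair maximizing |corr| on the held-out scores.
    Ties break by larger training correlation, then by smaller gamma1 + gamma2.
    """
    g1s, g2s = list(gamma1_grid), list(gamma2_grid)
    if not g1s or not g2s:
        raise ValueError("gamma grids must be non-empty")
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test index sets must be disjoint")
    X_raw = np.asarray(X_raw, dtype=float)
    Y_raw = np.asarray(Y_raw, dtype=float)
    Xtr, mx, sx = _preprocess_fit(X_raw[train_idx])
    Ytr, my, sy = _preprocess_fit(Y_raw[train_idx])
    Xte = (X_raw[test_idx] - mx) / sx
    Yte = (Y_raw[test_idx] - my) / sy

    best = None
    results = {}
    for g1 in g1s:
        for g2 in g2s:
            est = FGLSCCA(gamma1=g1, gamma2=g2, edges=edges, **solver_kwargs)
            est.fit(Xtr, Ytr)
            try:
                corr_test = (
                    np.nan
                    if est.degenerate_
                    else canonical_correlation(Xte, est.u_, Yte, est.v_)
                )
            except ValueError:
                corr_test = np.nan
            results[(g1, g2)] = {
                "corr_train": est.corr_train_,
                "corr_test": corr_test,
            }
            score = (
                -np.inf if np.isnan(corr_test) else abs(corr_test),
                -np.inf if np.isnan(est.corr_train_) else abs(est.corr_train_),
                -(g1 + g2),
            )
            if best is None or score > best[0]:
                best = (score, g1, g2, est)
    _, g1_best, g2_best, est_best = best
    return g1_best, g2_best, est_best, results
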