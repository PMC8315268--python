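"""A compact REML linear mixed-model engine.

The model is ``y = X beta + Z b + e`` with independent Gaussian random
effects ``b`` organised in *terms*:

- :class:`VarComp` — a single variance component: every column of its
  ``Z`` block shares one variance (random intercepts, uncorrelated random
  slopes, or any custom block such as a per-group extra-variance design);
- :class:`CorrPair` — a correlated (intercept, slope) pair per level of a
  grouping factor: a full 2x2 covariance block repeated over levels.

Estimation maximizes the REML criterion on the *profiled* deviance scale:
the residual variance is profiled out and the remaining parameters are the
relative Cholesky factors of each term's covariance (the lme4
parameterization), optimized by L-BFGS-B with box constraints keeping
diagonal entries non-negative. All per-iteration algebra runs on cached
cross-products ``[Z X y]'[Z X y]`` through a Woodbury/Cholesky identity,
so a fit costs O(q^3) per objective evaluation in the total number of
random-effect columns q, independent of n.

Convergence is the optimizer's success plus a projected-gradient check;
*singularity* means a fitted variance component below ``1e-8 * var(y)`` or
a pair correlation within ``1e-6`` of +/-1 — both reported honestly on the
fit, never silently accepted.

Satterthwaite denominator degrees of freedom for a contrast ``c`` use the
moment-matching formula ``df = 2 (c' C c)^2 / Var(c' C c)`` where ``C`` is
the fixed-effects covariance as a function of the variance parameters
``phi`` (component variances/covariances plus the residual variance):
the gradient of ``c' C(phi) c`` is obtained by central differences and
``Var(phi_hat)`` from the numerically differentiated Hessian of the
(unprofiled) −2 REML log-likelihood. With no random effects the formula
collapses exactly to the OLS residual df ``n − p``; when the variance of
the variance estimate is degenerate, the residual df is reported with a
warning flag instead of a spurious value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from prespeech.errors import ConvergenceError, DesignError

_SING_VAR_REL = 1e-8  # variance below this fraction of var(y) is singular
_SING_CORR = 1.0 - 1e-6


@dataclass
class VarComp:
    """One variance component: G block = theta * I over Z's columns."""

    name: str
    Z: np.ndarray

    @property
    def n_params(self) -> int:
        return 1

    @property
    def n_cols(self) -> int:
        return self.Z.shape[1]

    def lambda_block(self, th: np.ndarray) -> np.ndarray:
        return th[0] * np.eye(self.n_cols)

    def gamma_block(self, phi: np.ndarray, sigma2: float) -> np.ndarray:
        return (phi[0] / sigma2) * np.eye(self.n_cols)

    def start(self) -> np.ndarray:
        return np.array([1.0])

    def bounds(self) -> list[tuple]:
        return [(0.0, None)]

    def variances(self, th: np.ndarray, sigma2: float) -> dict[str, float]:
        return {f"var({self.name})": sigma2 * th[0] ** 2}

    def phi(self, th: np.ndarray, sigma2: float) -> np.ndarray:
        return np.array([sigma2 * th[0] ** 2])


@dataclass
class CorrPair:
    """Correlated (intercept, slope) pair; Z columns interleaved per level."""

    name: str
    Z: np.ndarray  # (n, 2m)

    @property
    def n_params(self) -> int:
        return 3  # l11, l21, l22 of the relative Cholesky factor

    @property
    def n_cols(self) -> int:
        return self.Z.shape[1]

    def _l2(self, th: np.ndarray) -> np.ndarray:
        return np.array([[th[0], 0.0], [th[1], th[2]]])

    def lambda_block(self, th: np.ndarray) -> np.ndarray:
        m = self.n_cols // 2
        return np.kron(np.eye(m), self._l2(th))

    def gamma_block(self, phi: np.ndarray, sigma2: float) -> np.ndarray:
        m = self.n_cols // 2
        g2 = np.array([[phi[0], phi[1]], [phi[1], phi[2]]]) / sigma2
        return np.kron(np.eye(m), g2)

    def start(self) -> np.ndarray:
        return np.array([1.0, 0.0, 1.0])

    def bounds(self) -> list[tuple]:
        return [(0.0, None), (None, None), (0.0, None)]

    def variances(self, th: np.ndarray, sigma2: float) -> dict[str, float]:
        g = self._l2(th) @ self._l2(th).T * sigma2
        v1, c, v2 = g[0, 0], g[0, 1], g[1, 1]
        corr = c / np.sqrt(v1 * v2) if v1 > 0 and v2 > 0 else np.nan
        return {
            f"var({self.name}|intercept)": v1,
            f"var({self.name}|slope)": v2,
            f"corr({self.name})": corr,
        }

    def phi(self, th: np.ndarray, sigma2: float) -> np.ndarray:
        g = self._l2(th) @ self._l2(th).T * sigma2
        return np.array([g[0, 0], g[0, 1], g[1, 1]])


def intercept_design(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Indicator matrix for a random intercept over a coded factor."""
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def slope_design(codes: np.ndarray, n_levels: int, x: np.ndarray) -> np.ndarray:
    return intercept_design(codes, n_levels) * np.asarray(x, float)[:, None]


def pair_design(codes: np.ndarray, n_levels: int, x: np.ndarray) -> np.ndarray:
    """Interleaved (intercept, slope) columns per level, for CorrPair."""
    n = codes.size
    Z = np.zeros((n, 2 * n_levels))
    rows = np.arange(n)
    Z[rows, 2 * codes] = 1.0
    Z[rows, 2 * codes + 1] = np.asarray(x, float)
    return Z


class _Workspace:
    """Cached cross-products for one (X, y, terms) problem."""

    def __init__(self, X, y, terms):
        self.X = np.asarray(X, float)
        self.y = np.asarray(y, float)
        self.terms = list(terms)
        n, p = self.X.shape
        if n <= p:
            raise DesignError(f"n = {n} <= p = {p}")
        if np.linalg.matrix_rank(self.X) < p:
            raise DesignError("rank-deficient fixed-effects design")
        self.n, self.p = n, p
        blocks = [np.asarray(t.Z, float) for t in self.terms]
        self.q = sum(b.shape[1] for b in blocks)
        Z = np.hstack(blocks) if blocks else np.empty((n, 0))
        W = np.hstack([Z, self.X, self.y[:, None]])
        M = W.T @ W
        q = self.q
        self.ZtZ = M[:q, :q]
        self.ZtX = M[:q, q : q + p]
        self.Zty = M[:q, -1]
        self.XtX = M[q : q + p, q : q + p]
        self.Xty = M[q : q + p, -1]
        self.yty = M[-1, -1]
        self.var_y = float(np.var(self.y))

    # -- theta (relative Cholesky) scale, residual variance profiled out --

    def _lambda(self, theta: np.ndarray) -> np.ndarray:
        lam = np.zeros((self.q, self.q))
        i_p, i_c = 0, 0
        for t in self.terms:
            k, c = t.n_params, t.n_cols
            lam[i_c : i_c + c, i_c : i_c + c] = t.lambda_block(theta[i_p : i_p + k])
            i_p += k
            i_c += c
        return lam

    def profiled(self, theta: np.ndarray):
        """Profiled −2 REML criterion and the quantities at its optimum."""
        lam = self._lambda(theta)
        A = lam.T @ self.ZtZ @ lam + np.eye(self.q)
        try:
            L = linalg.cholesky(A, lower=True)
        except linalg.LinAlgError:
            return np.inf, None
        logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
        B = linalg.solve_triangular(L, lam.T @ self.ZtX, lower=True)
        b = linalg.solve_triangular(L, lam.T @ self.Zty, lower=True)
        XtVX = self.XtX - B.T @ B
        XtVy = self.Xty - B.T @ b
        ytVy = self.yty - b @ b
        try:
            Lx = linalg.cholesky(XtVX, lower=True)
        except linalg.LinAlgError:
            return np.inf, None
        beta = linalg.cho_solve((Lx, True), XtVy)
        rss = max(ytVy - beta @ XtVy, 1e-300)
        sigma2 = rss / (self.n - self.p)
        logdet_x = 2.0 * np.sum(np.log(np.diag(Lx)))
        crit = (
            (self.n - self.p) * (1.0 + np.log(2.0 * np.pi * sigma2))
            + logdet_v
            + logdet_x
        )
        return crit, (beta, sigma2, XtVX)

    def objective(self, theta: np.ndarray) -> float:
        return self.profiled(theta)[0]

    # -- phi (variance) scale, unprofiled, for Satterthwaite machinery --

    def _gamma(self, phi: np.ndarray, sigma2: float) -> np.ndarray:
        g = np.zeros((self.q, self.q))
        i_p, i_c = 0, 0
        for t in self.terms:
            k, c = t.n_params, t.n_cols
            g[i_c : i_c + c, i_c : i_c + c] = t.gamma_block(phi[i_p : i_p + k], sigma2)
            i_p += k
            i_c += c
        return g

    def phi_quantities(self, phi: np.ndarray):
        """(−2 REML loglik, cov(beta)) at an arbitrary variance vector.

        ``phi`` stacks each term's variance parameters followed by the
        residual variance. Uses V^{-1} = I − Z G (I + Z'Z G)^{-1} Z', which
        stays valid for the slightly indefinite G perturbations that
        finite differencing at a boundary produces.
        """
        sigma2 = phi[-1]
        if sigma2 <= 0:
            return np.inf, None
        if self.q:
            gamma = self._gamma(phi[:-1], sigma2)
            A2 = np.eye(self.q) + self.ZtZ @ gamma
            lu, piv = linalg.lu_factor(A2)
            logdet_v_rel = float(np.sum(np.log(np.abs(np.diag(lu)))))
            K = gamma @ linalg.lu_solve((lu, piv), np.hstack([self.ZtX, self.Zty[:, None]]))
            XtVX = self.XtX - self.ZtX.T @ K[:, :-1]
            XtVX = 0.5 * (XtVX + XtVX.T)
            XtVy = self.Xty - self.ZtX.T @ K[:, -1]
            ytVy = self.yty - self.Zty @ K[:, -1]
        else:
            logdet_v_rel = 0.0
            XtVX, XtVy, ytVy = self.XtX, self.Xty, self.yty
        try:
            Lx = linalg.cholesky(XtVX, lower=True)
        except linalg.LinAlgError:
            return np.inf, None
        beta = linalg.cho_solve((Lx, True), XtVy)
        rss = ytVy - beta @ XtVy
        logdet_x = 2.0 * np.sum(np.log(np.diag(Lx)))
        m2l = (
            (self.n - self.p) * np.log(2.0 * np.pi * sigma2)
            + logdet_v_rel
            + logdet_x
            + rss / sigma2
        )
        cov_beta = sigma2 * linalg.cho_solve((Lx, True), np.eye(self.p))
        return float(m2l), cov_beta


@dataclass
class LMMFit:
    """A fitted mixed model (or the OLS limit when no terms are given)."""

    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    sigma2: float
    cov_beta: np.ndarray
    minus2reml: float
    converged: bool
    singular: bool
    variance_components: dict[str, float]
    n: int
    p: int
    theta: np.ndarray = field(repr=False)
    _ws: _Workspace = field(repr=False)
    df_warning: bool = False
    _phi_cov: np.ndarray | None = field(default=None, repr=False)
    _pert_cache: list | None = field(default=None, repr=False)
    _df: np.ndarray | None = field(default=None, repr=False)

    @property
    def df(self) -> np.ndarray:
        """Per-coefficient Satterthwaite df (computed lazily and cached)."""
        if self._df is None:
            self._df = np.array(
                [self.satterthwaite_df(_unit(self.p, j)) for j in range(self.p)]
            )
        return self._df

    @property
    def t_stats(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.t_stats), self.df)

    @property
    def has_random(self) -> bool:
        return bool(self._ws.terms)

    @property
    def phi(self) -> np.ndarray:
        parts = [
            t.phi(th, self.sigma2)
            for t, th in zip(self._ws.terms, _split_theta(self._ws.terms, self.theta))
        ]
        return np.concatenate(parts + [[self.sigma2]]) if parts else np.array([self.sigma2])

    # -- Satterthwaite --

    def _phi_covariance(self) -> np.ndarray:
        """Asymptotic covariance of the variance-parameter estimates."""
        if self._phi_cov is None:
            phi = self.phi
            H = _num_hessian(lambda v: self._ws.phi_quantities(v)[0], phi, _phi_steps(phi))
            # Var(phi) = 2 H^{-1} for H the Hessian of −2 loglik; pinv
            # tolerates boundary estimates.
            self._phi_cov = 2.0 * np.linalg.pinv(H)
        return self._phi_cov

    def contrast_variance(self, c: np.ndarray) -> float:
        c = np.asarray(c, float)
        return float(c @ self.cov_beta @ c)

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Denominator df for the single contrast ``c' beta``."""
        c = np.asarray(c, float)
        resid_df = float(self.n - self.p)
        if not self.has_random:
            return resid_df
        phi = self.phi
        f0 = self.contrast_variance(c)

        def f(v):
            cb = self._ws.phi_quantities(v)[1]
            return np.inf if cb is None else float(c @ cb @ c)

        g = _num_grad(f, phi, _phi_steps(phi))
        denom = float(g @ self._phi_covariance() @ g)
        if not np.isfinite(denom) or denom <= 0 or f0 <= 0:
            warnings.warn(
                "degenerate variance of the variance estimate; reporting "
                "residual df",
                stacklevel=2,
            )
            self.df_warning = True
            return resid_df
        return float(np.clip(2.0 * f0**2 / denom, 1e-2, 1e7))

    def _perturbed_covs(self):
        """cov(beta) at central-difference perturbations of each variance
        parameter (cached): the workhorse for df along contrast families."""
        if getattr(self, "_pert_cache", None) is None:
            phi = self.phi
            h = _phi_steps(phi)
            covs = []
            for j in range(phi.size):
                e = np.zeros_like(phi)
                e[j] = h[j]
                cp = self._ws.phi_quantities(phi + e)[1]
                cm = self._ws.phi_quantities(phi - e)[1]
                covs.append((h[j], cp, cm))
            self._pert_cache = covs
        return self._pert_cache

    def satterthwaite_df_path(
        self, c0: np.ndarray, c1: np.ndarray, ws: np.ndarray
    ) -> np.ndarray:
        """Satterthwaite df for the contrast family ``c(w) = c0 + w c1``.

        ``c' C c`` is quadratic in ``w`` for any fixed covariance, so one
        set of perturbed covariances serves every ``w`` — the closed form
        behind the Johnson-Neyman boundary search.
        """
        ws = np.asarray(ws, float)
        resid_df = float(self.n - self.p)
        if not self.has_random:
            return np.full(ws.shape, resid_df)

        def quad(cov):
            if cov is None:
                return None
            return (
                float(c0 @ cov @ c0),
                float(c0 @ cov @ c1),
                float(c1 @ cov @ c1),
            )

        a0, b0, d0 = quad(self.cov_beta)
        f0 = a0 + 2 * b0 * ws + d0 * ws**2
        G = []
        for h, cp, cm in self._perturbed_covs():
            qp, qm = quad(cp), quad(cm)
            if qp is None or qm is None:
                return np.full(ws.shape, resid_df)
            G.append(
                (
                    (qp[0] - qm[0]) / (2 * h)
                    + 2 * ws * (qp[1] - qm[1]) / (2 * h)
                    + ws**2 * (qp[2] - qm[2]) / (2 * h)
                )
            )
        G = np.stack(G, axis=0)  # (k, n_w)
        V = self._phi_covariance()
        denom = np.einsum("iw,ij,jw->w", G, V, G)
        df = np.where(
            (denom > 0) & (f0 > 0), 2.0 * f0**2 / np.maximum(denom, 1e-300), resid_df
        )
        return np.clip(df, 1e-2, 1e7)

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (for the
        parametric bootstrap)."""
        ws = self._ws
        y = ws.X @ self.beta + rng.normal(0.0, np.sqrt(self.sigma2), ws.n)
        for t, th in zip(ws.terms, _split_theta(ws.terms, self.theta)):
            lam = t.lambda_block(th) * np.sqrt(self.sigma2)
            b = lam @ rng.standard_normal(t.n_cols)
            y += t.Z @ b
        return y

    def refit(self, y: np.ndarray) -> "LMMFit":
        """Fit the same design and random structure to a new response."""
        return fit_mixed(self._ws.X, y, self._ws.terms, self.names)


def _split_theta(terms, theta):
    out, i = [], 0
    for t in terms:
        out.append(np.asarray(theta[i : i + t.n_params]))
        i += t.n_params
    return out


def _phi_steps(phi: np.ndarray) -> np.ndarray:
    scale = max(abs(phi[-1]), 1e-12)  # residual variance sets the scale
    return 1e-4 * (np.abs(phi) + 1e-2 * scale)


def _num_grad(f, x, h):
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * h[i])
    return g


def _num_hessian(f, x, h):
    k = x.size
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros_like(x)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros_like(x)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_mixed(X, y, terms, names: list[str] | None = None) -> LMMFit:
    """REML-fit a mixed model; ``terms=[]`` gives the exact OLS limit."""
    ws = _Workspace(X, y, terms)
    names = names or [f"x{i}" for i in range(ws.p)]
    if not ws.terms:
        crit, payload = ws.profiled(np.empty(0))
        beta, sigma2, XtVX = payload
        cov = sigma2 * np.linalg.inv(XtVX)
        return LMMFit(
            beta=beta,
            se=np.sqrt(np.diag(cov)),
            _df=np.full(ws.p, float(ws.n - ws.p)),
            names=list(names),
            sigma2=sigma2,
            cov_beta=cov,
            minus2reml=crit,
            converged=True,
            singular=False,
            variance_components={},
            n=ws.n,
            p=ws.p,
            theta=np.empty(0),
            _ws=ws,
        )

    x0 = np.concatenate([t.start() for t in ws.terms])
    bounds = [b for t in ws.terms for b in t.bounds()]
    best = None
    for start in (x0, 0.3 * x0):
        res = optimize.minimize(
            ws.objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success and best.fun <= res.fun + 1e-9:
            break
    res = best
    theta = res.x
    crit, payload = ws.profiled(theta)
    if payload is None:
        raise ConvergenceError("REML criterion undefined at the optimum")
    beta, sigma2, XtVX = payload
    cov = sigma2 * np.linalg.inv(XtVX)

    converged = bool(res.success)
    vcs: dict[str, float] = {}
    singular = False
    for t, th in zip(ws.terms, _split_theta(ws.terms, theta)):
        for key, val in t.variances(th, sigma2).items():
            vcs[key] = float(val)
            if key.startswith("var(") and val < _SING_VAR_REL * max(ws.var_y, 1e-300):
                singular = True
            if key.startswith("corr(") and np.isfinite(val) and abs(val) > _SING_CORR:
                singular = True
    vcs["var(residual)"] = float(sigma2)

    return LMMFit(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        names=list(names),
        sigma2=float(sigma2),
        cov_beta=cov,
        minus2reml=float(crit),
        converged=converged,
        singular=singular,
        variance_components=vcs,
        n=ws.n,
        p=ws.p,
        theta=theta,
        _ws=ws,
    )


def _unit(p: int, j: int) -> np.ndarray:
    e = np.zeros(p)
    e[j] = 1.0
    return e
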