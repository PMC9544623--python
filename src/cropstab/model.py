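"""Multilevel meta-analytic model with a known sampling covariance matrix.

The marginal model is

    y ~ N(X beta, V(sigma2)),   V = S + sum_l sigma2_l Z_l Z_l'

where S is the (block) sampling variance-covariance matrix of the effect
sizes (known), and each random level l (publication, experimental
comparison, effect size) contributes a variance component sigma2_l through
its grouping indicator Z_l. The effect-size level has one group per row, so
its component is the residual heterogeneity tau2 added to the diagonal.

Variance components are estimated by maximising the REML (or ML)
log-likelihood over log(sigma2) with bounded quasi-Newton iterations from
several fixed start points, then polished with a derivative-free simplex
step; fixed effects are the GLS solution at the optimum. The likelihood is
evaluated blockwise on the independent row groups implied by the random
structure and the non-zeros of S, which makes fits on hundreds of effects
essentially instant.

Cluster-robust (bias-reduced, CR2-type) covariance with Satterthwaite
degrees of freedom is provided for analyses whose sampling dependence is not
captured by S, e.g. the arm-based ln(SD) models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

SIGMA2_FLOOR = 1e-10
_LOG_FLOOR = np.log(SIGMA2_FLOOR)


@dataclass
class ModelSpec:
    """Declarative description of one meta-analytic model.

    ``fixed`` holds moderator descriptors consumed by the pipeline's design
    builder: "1" (intercept), "cat:<col>" (categorical, reference coding),
    "cellmeans:<col>" (categorical, one mean per level, no intercept),
    "cov:<col>" (continuous covariate, assumed error-free).
    """

    response_type: str = "lnCVR"
    fixed: tuple = ("1",)
    random_levels: tuple = ("publication_id", "comparison_id", "effect_id")
    method: str = "REML"

    def __post_init__(self) -> None:
        if self.method not in {"REML", "ML"}:
            raise ValueError(f"method must be REML or ML, got {self.method!r}")
        if "effect_id" not in self.random_levels:
            raise ValueError("the effect-size level (residual heterogeneity) is required")


@dataclass
class ModelFit:
    coefficients: pd.Series
    coef_vcov: pd.DataFrame
    variance_components: dict
    log_likelihood: float
    method: str
    n_effects: int
    n_params: int
    converged: bool
    optimizer_trace: list = field(default_factory=list, repr=False)
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _S: np.ndarray = field(default=None, repr=False)
    _levels: dict = field(default=None, repr=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.coef_vcov.to_numpy())),
                         index=self.coefficients.index)

    @property
    def total_sigma2(self) -> float:
        return float(sum(self.variance_components.values()))

    def fitted_values(self) -> np.ndarray:
        return self._X @ self.coefficients.to_numpy()

    def residuals(self) -> np.ndarray:
        return self._y - self.fitted_values()

    def marginal_vcov(self) -> np.ndarray:
        """Fitted marginal covariance V = S + sum sigma2_l Z_l Z_l'."""
        V = self._S.copy()
        for name, labels in self._levels.items():
            s2 = self.variance_components[name]
            if s2 <= 0:
                continue
            lab = np.asarray(labels).astype(str)
            V += s2 * (lab[:, None] == lab[None, :])
        return V

    def to_dict(self) -> dict:
        return {
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "log_likelihood": float(self.log_likelihood),
            "method": self.method,
            "n_effects": int(self.n_effects),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
        }


class _Blocks:
    """Partition rows into independent blocks and evaluate the likelihood."""

    def __init__(self, X: np.ndarray, y: np.ndarray, S: np.ndarray,
                 levels: Mapping[str, Sequence]) -> None:
        n = len(y)
        parent = np.arange(n)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        for labels in levels.values():
            lab = np.asarray(labels).astype(str)
            order = np.argsort(lab, kind="stable")
            for a, b in zip(order[:-1], order[1:]):
                if lab[a] == lab[b]:
                    union(a, b)
        ii, jj = np.nonzero(S)
        for a, b in zip(ii, jj):
            if a < b:
                union(a, b)

        roots = np.array([find(i) for i in range(n)])
        self.blocks = [np.flatnonzero(roots == r) for r in np.unique(roots)]
        self.level_names = list(levels.keys())
        self.X, self.y = X, y
        self.parts = []
        for idx in self.blocks:
            Sb = S[np.ix_(idx, idx)]
            inds = []
            for labels in levels.values():
                lab = np.asarray(labels).astype(str)[idx]
                inds.append((lab[:, None] == lab[None, :]).astype(float))
            self.parts.append((idx, Sb, inds))

    def loglik(self, sigma2: np.ndarray, method: str) -> tuple[float, np.ndarray, np.ndarray]:
        """Profiled log-likelihood; returns (ll, beta_hat, A = X'V^-1 X)."""
        p = self.X.shape[1]
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        yVy = 0.0
        logdet = 0.0
        for idx, Sb, inds in self.parts:
            Vb = Sb.copy()
            for s2, E in zip(sigma2, inds):
                if s2 > 0:
                    Vb = Vb + s2 * E
            c, low = cho_factor(Vb, check_finite=False)
            logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
            Xb, yb = self.X[idx], self.y[idx]
            ViX = cho_solve((c, low), Xb, check_finite=False)
            Viy = cho_solve((c, low), yb, check_finite=False)
            A += Xb.T @ ViX
            bvec += Xb.T @ Viy
            yVy += float(yb @ Viy)
        cA, lowA = cho_factor(A, check_finite=False)
        beta = cho_solve((cA, lowA), bvec, check_finite=False)
        q = yVy - float(beta @ bvec)
        n = len(self.y)
        if method == "ML":
            ll = -0.5 * (n * np.log(2 * np.pi) + logdet + q)
        else:
            # REML, in the convention that includes +0.5 log|X'X| (invariant
            # to linear reparameterisation of X; matches metafor's logLik)
            logdetA = 2.0 * float(np.sum(np.log(np.diag(cA))))
            _, logdetXX = np.linalg.slogdet(self.X.T @ self.X)
            ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + logdetA + q - logdetXX)
        return ll, beta, A


def fit(y, X, S, levels: Mapping[str, Sequence], method: str = "REML",
        fixed_sigma2: Optional[Mapping[str, float]] = None,
        coef_names: Optional[Sequence[str]] = None,
        tol: float = 1e-8) -> ModelFit:
    """Fit the multilevel model by REML or ML.

    Parameters
    ----------
    y, X : response vector (k,) and full-rank design matrix (k, p).
    S : known sampling variance-covariance matrix (k, k).
    levels : ordered mapping of random-level name -> length-k label array.
    fixed_sigma2 : variance components to hold fixed (not estimated),
        e.g. ``{"publication_id": 0.0}``; remaining components are estimated.
    """
    if isinstance(X, pd.DataFrame):
        coef_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    S = np.asarray(S, dtype=float)
    k, p = X.shape
    if coef_names is None:
        coef_names = [f"b{i}" for i in range(p)]
    if S.shape != (k, k):
        raise ValueError(f"VCV dimension {S.shape} does not match effect count {k}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name aliased columns for the error message
        _, R = np.linalg.qr(X)
        aliased = [coef_names[j] for j in range(p) if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {p}); "
                         f"aliased columns: {aliased or 'undetermined'}")
    if method not in {"REML", "ML"}:
        raise ValueError(f"method must be REML or ML, got {method!r}")

    blocks = _Blocks(X, y, S, levels)
    names = list(levels.keys())
    fixed_sigma2 = dict(fixed_sigma2 or {})
    unknown = set(fixed_sigma2) - set(names)
    if unknown:
        raise ValueError(f"fixed_sigma2 names not in random levels: {sorted(unknown)}")
    free = [nm for nm in names if nm not in fixed_sigma2]

    def full_sigma2(theta_free: np.ndarray) -> np.ndarray:
        s2 = np.empty(len(names))
        it = iter(theta_free)
        for i, nm in enumerate(names):
            s2[i] = fixed_sigma2[nm] if nm in fixed_sigma2 else np.exp(next(it))
        return s2

    trace: list = []

    if not free:
        sigma2 = full_sigma2(np.empty(0))
        ll, beta, A = blocks.loglik(sigma2, method)
        converged = True
    else:
        vbar = float(np.mean(np.diag(S)))
        upper = np.log(max(1e4 * vbar, 1e2 * float(np.var(y) + 1e-12), 1.0))
        bounds = [(_LOG_FLOOR, upper)] * len(free)

        def neg(theta):
            try:
                ll, _, _ = blocks.loglik(full_sigma2(theta), method)
            except np.linalg.LinAlgError:
                return 1e12
            return -ll

        best = None
        for scale in (0.1, 1.0, 10.0):
            theta0 = np.full(len(free), np.log(max(scale * vbar, SIGMA2_FLOOR)))
            res = optimize.minimize(neg, theta0, method="L-BFGS-B", bounds=bounds,
                                    options={"ftol": tol * 1e-4, "gtol": 1e-7, "maxiter": 500})
            trace.append({"start_scale": scale, "fun": float(res.fun),
                          "nit": int(res.nit), "success": bool(res.success)})
            if best is None or res.fun < best.fun:
                best = res
        polish = optimize.minimize(
            neg, best.x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": tol * 1e-2, "maxiter": 2000})
        if polish.fun <= best.fun:
            best = polish
        converged = bool(np.isfinite(best.fun)) and best.fun < 1e11
        if not converged:
            raise RuntimeError(f"variance-component optimisation failed; trace: {trace}")
        theta = np.clip(best.x, _LOG_FLOOR, None)
        sigma2 = full_sigma2(theta)
        ll, beta, A = blocks.loglik(sigma2, method)

    cov = np.linalg.inv(A)
    cov = 0.5 * (cov + cov.T)
    comp = {nm: (0.0 if s2 <= 2 * SIGMA2_FLOOR else float(s2))
            for nm, s2 in zip(names, sigma2)}
    return ModelFit(
        coefficients=pd.Series(beta, index=coef_names),
        coef_vcov=pd.DataFrame(cov, index=coef_names, columns=coef_names),
        variance_components=comp,
        log_likelihood=float(ll),
        method=method,
        n_effects=k,
        n_params=p + len(free),
        converged=converged,
        optimizer_trace=trace,
        _X=X, _y=y, _S=S,
        _levels={nm: np.asarray(lab) for nm, lab in levels.items()},
    )


def wald_summary(fit: ModelFit, level: float = 0.95) -> pd.DataFrame:
    """Per-coefficient estimate, SE, normal CI, z and two-sided p."""
    if not fit.converged:
        raise ValueError("model did not converge")
    est = fit.coefficients.to_numpy()
    se = fit.se.to_numpy()
    zcrit = stats.norm.ppf(0.5 + level / 2.0) if level > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est / se, np.inf * np.sign(est))
    pvals = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "estimate": est, "se": se,
        "ci_low": est - zcrit * se, "ci_high": est + zcrit * se,
        "z": z, "p": pvals,
    }, index=fit.coefficients.index)


def prediction_interval(fit: ModelFit, coef=None, level: float = 0.95) -> tuple[float, float]:
    """Interval for the effect expected in a new study.

    Widens the Wald CI of the selected coefficient by the summed
    random-effect variances across all levels.
    """
    name = coef if coef is not None else fit.coefficients.index[0]
    est = float(fit.coefficients[name])
    se = float(fit.se[name])
    zcrit = stats.norm.ppf(0.5 + level / 2.0) if level > 0 else 0.0
    half = zcrit * np.sqrt(se**2 + fit.total_sigma2)
    return (est - half, est + half)


def lrt(null_fit: ModelFit, alt_fit: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: (statistic, df, p)."""
    for f in (null_fit, alt_fit):
        if f.method != "ML":
            raise ValueError("likelihood-ratio moderator tests require ML fits")
    if null_fit.n_effects != alt_fit.n_effects:
        raise ValueError("fits are not on the same data (effect counts differ)")
    df = alt_fit.n_params - null_fit.n_params
    if df <= 0:
        raise ValueError("alternative model must have more parameters than the null")
    stat = max(0.0, 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood))
    return stat, df, float(stats.chi2.sf(stat, df))


def _sym_invsqrt(M: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    w, Q = np.linalg.eigh(0.5 * (M + M.T))
    cut = rtol * max(w.max(), 0.0) if w.size else 0.0
    inv = np.where(w > cut, 1.0 / np.sqrt(np.where(w > cut, w, 1.0)), 0.0)
    return (Q * inv) @ Q.T


def _sym_sqrt(M: np.ndarray) -> np.ndarray:
    w, Q = np.linalg.eigh(0.5 * (M + M.T))
    w = np.clip(w, 0.0, None)
    return (Q * np.sqrt(w)) @ Q.T


@dataclass
class RobustResult:
    coef_vcov: pd.DataFrame
    df: pd.Series

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.coef_vcov.to_numpy())),
                         index=self.coef_vcov.index)


def robust_se(fit: ModelFit, cluster: Sequence) -> RobustResult:
    """Bias-reduced (CR2-type) cluster-robust covariance of the coefficients.

    Residuals are adjusted per cluster so that, under the fitted working
    covariance, the squared adjusted residuals are unbiased for the working
    covariance; Satterthwaite degrees of freedom are computed per
    coefficient from the same working model.
    """
    cluster = np.asarray(cluster)
    if len(cluster) != fit.n_effects:
        raise ValueError("cluster labels do not match the number of rows")
    uniq = pd.unique(cluster)
    if len(uniq) < 2:
        raise ValueError("cluster-robust variance needs at least 2 clusters")

    X, y = fit._X, fit._y
    V = fit.marginal_vcov()
    W = np.linalg.inv(V)
    M = fit.coef_vcov.to_numpy()  # (X'WX)^{-1}
    H = X @ M @ (X.T @ W)
    IH = np.eye(len(y)) - H
    Omega_e = IH @ V @ IH.T
    e = fit.residuals()
    p = X.shape[1]

    meat = np.zeros((p, p))
    XtW = X.T @ W  # p x n
    adj: dict = {}
    for g in uniq:
        idx = np.flatnonzero(cluster == g)
        Vj = V[np.ix_(idx, idx)]
        Vj_half = _sym_sqrt(Vj)
        Bj = _sym_invsqrt(Vj) @ Omega_e[np.ix_(idx, idx)] @ _sym_invsqrt(Vj)
        Aj = Vj_half @ _sym_invsqrt(Bj) @ _sym_invsqrt(Vj)
        adj[g] = (idx, Aj)
        u = XtW[:, idx] @ (Aj @ e[idx])
        meat += np.outer(u, u)
    cov = M @ meat @ M
    cov = 0.5 * (cov + cov.T)

    # Satterthwaite df per coefficient: the variance estimate is a quadratic
    # form in y; df = (tr G)^2 / sum(G^2) with G_{jk} = q_j' V q_k.
    dfs = []
    for i in range(p):
        c = M[:, i]  # M e_i
        Qcols = []
        for g in uniq:
            idx, Aj = adj[g]
            u_j = Aj.T @ (XtW[:, idx].T @ c)  # n_j vector
            q = np.zeros(len(y))
            q[idx] = u_j
            Qcols.append(IH.T @ q)
        Q = np.column_stack(Qcols)
        G = Q.T @ V @ Q
        trG = float(np.trace(G))
        den = float(np.sum(G * G))
        dfs.append(trG**2 / den if den > 0 else np.nan)

    names = fit.coefficients.index
    return RobustResult(
        coef_vcov=pd.DataFrame(cov, index=names, columns=names),
        df=pd.Series(dfs, index=names),
    )


def robust_wald_summary(fit: ModelFit, cluster: Sequence,
                        level: float = 0.95) -> pd.DataFrame:
    """Wald table using CR2 SEs and t critical values with Satterthwaite df."""
    rr = robust_se(fit, cluster)
    est = fit.coefficients.to_numpy()
    se = rr.se.to_numpy()
    df = rr.df.to_numpy()
    tcrit = stats.t.ppf(0.5 + level / 2.0, df) if level > 0 else np.zeros_like(df)
    tstat = est / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    return pd.DataFrame({
        "estimate": est, "se": se, "df": df,
        "ci_low": est - tcrit * se, "ci_high": est + tcrit * se,
        "t": tstat, "p": pvals,
    }, index=fit.coefficients.index)
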