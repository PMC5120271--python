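"""Generalized linear mixed models with multi-membership random effects.

The connectivity models treat each feeder pair as belonging to *both* of
its feeders: one feeder-level variance component whose random-effect
design has two unit entries per row (the row-level random part is
``u_a + u_b``).  The count model adds an ordinary tag-identity intercept.
No established Python package fits this structure by maximum likelihood,
so the estimators here implement the Laplace-approximated marginal
likelihood directly:

* at fixed variance parameters θ = log σ, the fixed effects β and random
  modes u are found by a joint penalized Newton iteration (profiling β
  through the joint optimum, as lme4 does for its Laplace deviance);
* the profiled Laplace log-likelihood
  ``ℓ(θ) = ℓ(y|β̂,û) − ½ ûᵀD⁻¹û − ½ log|I + D ZᵀWZ|``
  is then maximized over θ (one or two dimensions) by Nelder–Mead.

Wald standard errors for β come from the β-block of the inverse joint
penalized Hessian at the optimum (conditional on θ̂), and 95% CIs are
``β̂ ± 1.96·SE``.  Supported response families are Bernoulli/binomial with
a logit link and the zero-truncated Poisson with a log link.

The estimators follow the scikit-learn protocol: ``fit(X, y,
memberships=...)``, ``predict``, ``get_params``/``set_params``, fitted
attributes with a trailing underscore.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.special import expit, gammaln
from scipy.stats import norm

from feedernet.errors import ConvergenceError, ValidationError

try:  # sklearn is optional at runtime; the protocol works without it
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:
        def get_params(self, deep=True):
            import inspect

            sig = inspect.signature(self.__init__)
            return {k: getattr(self, k) for k in sig.parameters}

        def set_params(self, **params):
            for k, v in params.items():
                setattr(self, k, v)
            return self


_ETA_MAX = 30.0


class _Binomial:
    """Bernoulli response, logit link (canonical)."""

    name = "binomial"

    @staticmethod
    def loglik(y, eta):
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def mean(eta):
        return expit(eta)

    @staticmethod
    def score(y, eta):
        return y - expit(eta)

    @staticmethod
    def weight(eta):
        p = expit(eta)
        return np.maximum(p * (1.0 - p), 1e-10)

    @staticmethod
    def check_response(y):
        if not np.isin(y, (0, 1)).all():
            raise ValidationError("binomial response must be 0/1")
        if y.min() == y.max():
            raise ConvergenceError(
                "response takes a single value: the model is degenerate "
                "(complete separation / no information)"
            )


class _Poisson:
    """Plain Poisson response, log link (for comparison fits)."""

    name = "poisson"

    @staticmethod
    def _lam(eta):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    @classmethod
    def loglik(cls, y, eta):
        lam = cls._lam(eta)
        return y * np.clip(eta, -_ETA_MAX, _ETA_MAX) - lam - gammaln(y + 1.0)

    @classmethod
    def mean(cls, eta):
        return cls._lam(eta)

    @classmethod
    def score(cls, y, eta):
        return y - cls._lam(eta)

    @classmethod
    def weight(cls, eta):
        return np.maximum(cls._lam(eta), 1e-10)

    @staticmethod
    def check_response(y):
        if (y < 0).any():
            raise ValidationError("Poisson response must be non-negative")


class _TruncatedPoisson:
    """Zero-truncated Poisson response, log link.

    Per-row log-likelihood  y·η − λ − log(1 − e^{−λ}) − log(y!)  with
    λ = exp(η); the conditional mean is m(λ) = λ / (1 − e^{−λ}) and the
    observed information equals the conditional variance
    m·(1 + λ − m).
    """

    name = "truncated_poisson"

    @staticmethod
    def _lam(eta):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    @classmethod
    def cond_mean(cls, eta):
        lam = cls._lam(eta)
        return lam / -np.expm1(-lam)

    @classmethod
    def loglik(cls, y, eta):
        lam = cls._lam(eta)
        return (
            y * np.clip(eta, -_ETA_MAX, _ETA_MAX)
            - lam
            - np.log(-np.expm1(-lam))
            - gammaln(y + 1.0)
        )

    @classmethod
    def mean(cls, eta):
        return cls.cond_mean(eta)

    @classmethod
    def score(cls, y, eta):
        return y - cls.cond_mean(eta)

    @classmethod
    def weight(cls, eta):
        lam = cls._lam(eta)
        m = lam / -np.expm1(-lam)
        return np.maximum(m * (1.0 + lam - m), 1e-10)

    @staticmethod
    def check_response(y):
        if (y < 1).any():
            raise ValidationError(
                "zero-truncated Poisson response must be >= 1 everywhere"
            )


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def _encode_memberships(memberships, n):
    """Normalize membership spec to (name, codes (n,k), levels) tuples."""
    factors = []
    for name, arr in memberships.items():
        if isinstance(arr, pd.DataFrame):
            arr = arr.to_numpy()
        arr = np.asarray(arr)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n:
            raise ValidationError(
                f"membership {name!r}: {arr.shape[0]} rows, expected {n}"
            )
        levels, codes = np.unique(arr, return_inverse=True)
        factors.append((name, codes.reshape(arr.shape), levels))
    return factors


class _LaplaceGLMM(BaseEstimator):
    """Shared machinery for the Laplace-approximated mixed models."""

    _family = None  # set by subclasses

    def __init__(
        self,
        fit_intercept: bool = True,
        vc_fixed: dict | None = None,
        refine: bool = True,
        theta_init: float = -1.0,
        theta_bounds: tuple = (-6.0, 3.0),
        inner_tol: float = 1e-8,
        max_inner: int = 100,
        max_outer: int = 400,
    ):
        self.fit_intercept = fit_intercept
        self.vc_fixed = vc_fixed
        self.refine = refine
        self.theta_init = theta_init
        self.theta_bounds = theta_bounds
        self.inner_tol = inner_tol
        self.max_inner = max_inner
        self.max_outer = max_outer

    # -- inner: penalized Newton over the columns of A at fixed D^-1 ------
    def _inner(self, A, y, dinv, z0, offset=None):
        fam = self._family
        z = z0.copy()
        off = 0.0 if offset is None else offset
        eta = off + A @ z
        pen = fam.loglik(y, eta).sum() - 0.5 * float(z @ (dinv * z))
        grad_norm = np.inf
        for _ in range(self.max_inner):
            s = fam.score(y, eta)
            w = fam.weight(eta)
            grad = A.T @ s - dinv * z
            grad_norm = np.abs(grad).max()
            if grad_norm < self.inner_tol:
                break
            Aw = A.multiply(w[:, None]) if sp.issparse(A) else A * w[:, None]
            H = (A.T @ Aw)
            if sp.issparse(H):
                H = H.toarray()
            H[np.diag_indices_from(H)] += dinv
            try:
                c = cho_factor(H, lower=True)
                step = cho_solve(c, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step halving on the penalized log-likelihood
            t = 1.0
            for _ in range(30):
                z_new = z + t * step
                eta_new = off + A @ z_new
                pen_new = fam.loglik(y, eta_new).sum() - 0.5 * float(
                    z_new @ (dinv * z_new)
                )
                if pen_new >= pen - 1e-12:
                    break
                t *= 0.5
            z, eta, pen = z_new, eta_new, pen_new
        return z, eta, pen, grad_norm

    @staticmethod
    def _logdet_term(Z, w, sigma2_per_u):
        """log|I + D Z'WZ| (the Laplace curvature correction)."""
        ZtWZ = (Z.multiply(w[:, None])).T @ Z
        ZtWZ = ZtWZ.toarray() if sp.issparse(ZtWZ) else ZtWZ
        sd = np.sqrt(sigma2_per_u)
        M = np.eye(Z.shape[1]) + (sd[:, None] * ZtWZ) * sd[None, :]
        try:
            L = cholesky(M, lower=True)
            return 2.0 * np.log(np.diag(L)).sum()
        except np.linalg.LinAlgError:
            sign, logdet = np.linalg.slogdet(M)
            return logdet if sign > 0 else np.inf

    def _laplace(self, A, y, Z, dinv_u, sigma2_per_u, z0):
        """Profiled Laplace log-likelihood at fixed variance parameters
        (β profiled through the joint penalized optimum)."""
        p = A.shape[1] - Z.shape[1] if Z is not None else A.shape[1]
        dinv = np.concatenate([np.zeros(p), dinv_u]) if Z is not None else np.zeros(p)
        z, eta, pen, gnorm = self._inner(A, y, dinv, z0)
        ll = pen
        if Z is not None and Z.shape[1]:
            w = self._family.weight(eta)
            ll = pen - 0.5 * self._logdet_term(Z, w, sigma2_per_u)
        return ll, z, eta, gnorm

    def _laplace_objective(self, Xm, Z, Zd, y, beta, per_u, u0):
        """Full Laplace objective and intermediates at fixed (β, θ)."""
        off = Xm @ beta
        u, eta, pen, _ = self._inner(Z, y, 1.0 / per_u, u0, offset=off)
        w = self._family.weight(eta)
        Hu = (Z.multiply(w[:, None])).T @ Z
        Hu = Hu.toarray() if sp.issparse(Hu) else Hu
        Hu[np.diag_indices_from(Hu)] += 1.0 / per_u
        L = cholesky(Hu, lower=True)
        # log|I + D Z'WZ| = log|Hu| + log|D|
        logdet = 2.0 * np.log(np.diag(L)).sum() + np.log(per_u).sum()
        f = -(pen - 0.5 * logdet)
        return f, u, eta, w, L

    def _refine(self, Xm, Z, y, z0, theta_free0, unpack):
        """Maximize the full Laplace objective over (β, θ) jointly.

        The profiled stage ignores the β-dependence of the curvature
        correction log|I + D Z'WZ|, which attenuates binary-response
        fits; this quasi-Newton pass over (β, log σ) with an inner
        penalized solve for u removes that bias.  The β-gradient is
        analytic (envelope theorem for the penalized part; the trace
        identity d log|Hu|/dβ = Σᵢ cᵢ w'ᵢ ∂ηᵢ/∂β with
        cᵢ = [Z Hu⁻¹ Zᵀ]ᵢᵢ and ∂η/∂β = X − Z Hu⁻¹ ZᵀWX for the
        curvature term); the 1–2 θ directions use forward differences.
        """
        from scipy.linalg import solve_triangular

        fam = self._family
        p = Xm.shape[1]
        Zd = Z.toarray() if sp.issparse(Z) else Z
        ustate = {"u": z0[p:].copy()}
        h_eta = 1e-5
        h_th = 1e-5

        def fun_and_grad(x):
            beta, th_free = x[:p], x[p:]
            _, _, per_u = unpack(th_free)
            f, u, eta, w, L = self._laplace_objective(
                Xm, Z, Zd, y, beta, per_u, ustate["u"]
            )
            ustate["u"] = u
            # analytic beta gradient
            s = fam.score(y, eta)
            wprime = (fam.weight(eta + h_eta) - fam.weight(eta - h_eta)) / (
                2.0 * h_eta
            )
            WX = Xm * w[:, None]
            B = cho_solve((L, True), Zd.T @ WX)  # Hu^{-1} Z'WX
            Xeff = Xm - Zd @ B  # d eta / d beta
            V = solve_triangular(L, Zd.T, lower=True)
            c = np.einsum("ij,ij->j", V, V)  # diag(Z Hu^{-1} Z')
            # envelope theorem: the u*-dependence of the penalized part
            # drops out, leaving X's; the curvature term keeps Xeff
            g_beta = -(Xm.T @ s) + 0.5 * (Xeff.T @ (c * wprime))
            grad = np.empty_like(x)
            grad[:p] = g_beta
            for k in range(len(th_free)):
                th2 = th_free.copy()
                th2[k] += h_th
                _, _, per_u2 = unpack(th2)
                f2, _, _, _, _ = self._laplace_objective(
                    Xm, Z, Zd, y, beta, per_u2, ustate["u"]
                )
                grad[p + k] = (f2 - f) / h_th
            return f, grad

        x0 = np.concatenate([z0[:p], theta_free0])
        bounds = [(-30.0, 30.0)] * p + [self.theta_bounds] * len(theta_free0)
        res = scipy.optimize.minimize(
            fun_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": self.max_outer, "ftol": 1e-11, "gtol": 1e-6},
        )
        beta = res.x[:p]
        theta_hat, sigma2, per_u = unpack(res.x[p:])
        u, eta, pen, gnorm = self._inner(
            Z, y, 1.0 / per_u, ustate["u"], offset=Xm @ beta
        )
        w = self._family.weight(eta)
        ll = pen - 0.5 * self._logdet_term(Z, w, per_u)
        z = np.concatenate([beta, u])
        return ll, z, eta, gnorm, theta_hat, sigma2, per_u

    def fit(self, X, y, memberships: dict | None = None):
        """Fit the model.

        Parameters
        ----------
        X : array-like or DataFrame, shape (n, p)
            Fixed-effect design (without intercept; one is added when
            ``fit_intercept``).
        y : array-like, shape (n,)
            Response.
        memberships : dict, optional
            Random-effect grouping: ``name -> array of level labels`` of
            shape (n,) for an ordinary intercept or (n, k) for a
            multi-membership term (k levels per row share one variance;
            the row's random part is the sum of the k effects).
        """
        Xm, names = _as_matrix(X)
        y = np.asarray(y, float).ravel()
        if Xm.shape[0] != y.shape[0]:
            raise ValidationError("X and y have different lengths")
        self._family.check_response(y)
        n = len(y)
        if self.fit_intercept:
            Xm = np.hstack([np.ones((n, 1)), Xm])
            names = ["intercept"] + names
        rank = np.linalg.matrix_rank(Xm)
        if rank < Xm.shape[1]:
            raise ValidationError(
                f"fixed-effect design is rank deficient ({rank} < {Xm.shape[1]})"
            )
        self.feature_names_ = names
        p = Xm.shape[1]

        vc_fixed = dict(self.vc_fixed or {})
        factors = _encode_memberships(memberships or {}, n)
        # drop factors whose variance is pinned to exactly zero
        factors = [
            (nm, codes, levels)
            for nm, codes, levels in factors
            if vc_fixed.get(nm, None) != 0.0
        ]
        self._factors_ = [
            {"name": nm, "levels": levels, "k": codes.shape[1]}
            for nm, codes, levels in factors
        ]

        if factors:
            blocks = []
            offset = 0
            rows_all, cols_all = [], []
            for nm, codes, levels in factors:
                qg = len(levels)
                for j in range(codes.shape[1]):
                    rows_all.append(np.arange(n))
                    cols_all.append(offset + codes[:, j])
                blocks.append((offset, qg))
                offset += qg
            Z = sp.csr_matrix(
                (
                    np.ones(sum(len(r) for r in rows_all)),
                    (np.concatenate(rows_all), np.concatenate(cols_all)),
                ),
                shape=(n, offset),
            )
            A = sp.hstack([sp.csr_matrix(Xm), Z], format="csr")
            q = offset
        else:
            Z, A, q = None, Xm, 0

        # free / fixed variance parameters on the log-sigma scale
        free_idx = [
            i for i, f in enumerate(self._factors_) if f["name"] not in vc_fixed
        ]
        theta_full = np.full(len(self._factors_), float(self.theta_init))
        for i, f in enumerate(self._factors_):
            if f["name"] in vc_fixed:
                theta_full[i] = 0.5 * np.log(vc_fixed[f["name"]])

        z_warm = np.zeros(p + q)

        def unpack(theta_free):
            th = theta_full.copy()
            th[free_idx] = np.clip(theta_free, *self.theta_bounds)
            sigma2 = np.exp(2.0 * th)
            per_u = np.concatenate(
                [
                    np.full(len(f["levels"]), sigma2[i])
                    for i, f in enumerate(self._factors_)
                ]
            ) if self._factors_ else np.zeros(0)
            return th, sigma2, per_u

        if q == 0:
            ll, z, eta, gnorm = self._laplace(A, y, None, None, None, z_warm)
            theta_hat = np.zeros(0)
            sigma2 = np.zeros(0)
            per_u = np.zeros(0)
        elif not free_idx:
            theta_hat, sigma2, per_u = unpack(np.zeros(0))
            ll, z, eta, gnorm = self._laplace(A, y, Z, 1.0 / per_u, per_u, z_warm)
        else:
            state = {"z": z_warm}

            def objective(theta_free):
                _, _, per_u = unpack(theta_free)
                ll, z, _, _ = self._laplace(A, y, Z, 1.0 / per_u, per_u, state["z"])
                state["z"] = z
                return -ll

            res = scipy.optimize.minimize(
                objective,
                x0=theta_full[free_idx],
                method="Nelder-Mead",
                options={
                    "xatol": 1e-4,
                    "fatol": 1e-7,
                    "maxiter": self.max_outer,
                    "maxfev": self.max_outer,
                },
            )
            theta_hat, sigma2, per_u = unpack(res.x)
            ll, z, eta, gnorm = self._laplace(A, y, Z, 1.0 / per_u, per_u, state["z"])

        if q and self.refine:
            ll, z, eta, gnorm, theta_hat, sigma2, per_u = self._refine(
                Xm, Z, y, z, theta_hat[free_idx], unpack
            )

        if gnorm > max(self.inner_tol * 1e3, 1e-3):
            raise ConvergenceError(
                f"inner Newton did not converge (gradient inf-norm {gnorm:.3g})"
            )
        beta = z[:p]
        if np.abs(beta).max() > 30.0:
            raise ConvergenceError(
                "fixed effects diverged (|beta| > 30): likely complete separation"
            )

        # Wald covariance: beta block of the inverse joint penalized Hessian
        w = self._family.weight(eta)
        Aw = A.multiply(w[:, None]) if sp.issparse(A) else A * w[:, None]
        H = A.T @ Aw
        H = H.toarray() if sp.issparse(H) else H
        if q:
            H[np.diag_indices_from(H)] += np.concatenate(
                [np.zeros(p), 1.0 / per_u]
            )
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov)[:p], 0.0))

        self.n_obs_ = n
        self.cov_ = pd.DataFrame(cov[:p, :p], index=names, columns=names)
        self.beta_ = pd.Series(beta, index=names)
        self.se_ = pd.Series(se, index=names)
        self.conf_int_ = pd.DataFrame(
            {"lower": beta - 1.96 * se, "upper": beta + 1.96 * se}, index=names
        )
        self.coef_ = beta[1:] if self.fit_intercept else beta
        self.intercept_ = beta[0] if self.fit_intercept else 0.0
        self.vc_ = {
            f["name"]: float(sigma2[i]) for i, f in enumerate(self._factors_)
        }
        self.vc_multiplicity_ = {f["name"]: f["k"] for f in self._factors_}
        self.ranef_ = {}
        off = p
        for i, f in enumerate(self._factors_):
            qg = len(f["levels"])
            self.ranef_[f["name"]] = pd.Series(z[off : off + qg], index=f["levels"])
            off += qg
        self.loglik_ = float(ll)
        self.eta_ = np.asarray(A @ z).ravel()
        self.eta_fixed_ = Xm @ beta
        self.fitted_ = self._family.mean(self.eta_)
        self.y_ = y
        self.converged_ = True
        self.grad_norm_ = float(gnorm)
        return self

    def _eta_new(self, X, memberships=None):
        Xm, _ = _as_matrix(X)
        if self.fit_intercept:
            Xm = np.hstack([np.ones((Xm.shape[0], 1)), Xm])
        eta = Xm @ self.beta_.to_numpy()
        if memberships:
            for f in self._factors_:
                nm = f["name"]
                if nm not in memberships:
                    continue
                arr = np.asarray(memberships[nm])
                if arr.ndim == 1:
                    arr = arr[:, None]
                u = self.ranef_[nm]
                for j in range(arr.shape[1]):
                    vals = pd.Series(arr[:, j]).map(u).fillna(0.0).to_numpy()
                    eta = eta + vals
        return eta

    def predict(self, X, memberships: dict | None = None):
        """Predicted mean response (population level unless memberships
        with known levels are supplied)."""
        return self._family.mean(self._eta_new(X, memberships))

    def significance(self) -> pd.DataFrame:
        """Wald z, two-sided p and conventional star codes per effect."""
        z = self.beta_ / self.se_.replace(0.0, np.nan)
        pvals = 2.0 * norm.sf(np.abs(z))
        stars = [
            "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            for p in pvals
        ]
        return pd.DataFrame(
            {"estimate": self.beta_, "se": self.se_, "z": z, "p": pvals,
             "stars": stars},
            index=self.beta_.index,
        )


class BinomialGLMM(_LaplaceGLMM):
    """Logistic mixed model for presence/absence of a connection."""

    _family = _Binomial

    def predict_proba(self, X, memberships: dict | None = None):
        p = self.predict(X, memberships)
        return np.column_stack([1.0 - p, p])


class PoissonGLMM(_LaplaceGLMM):
    """Plain-Poisson mixed model: the comparison family for the count
    part (mixed-model software often fits the frequency model as plain
    Poisson even when the data are structurally zero-truncated)."""

    _family = _Poisson

    def rate(self, X, memberships: dict | None = None):
        return np.exp(np.clip(self._eta_new(X, memberships), -_ETA_MAX, _ETA_MAX))


class TruncatedPoissonGLMM(_LaplaceGLMM):
    """Zero-truncated Poisson mixed model for connection frequency.

    ``predict`` returns the conditional mean  λ/(1 − e^{−λ}); ``rate``
    returns the untruncated λ = exp(η).
    """

    _family = _TruncatedPoisson

    def rate(self, X, memberships: dict | None = None):
        return np.exp(np.clip(self._eta_new(X, memberships), -_ETA_MAX, _ETA_MAX))


def r2_glmm(fit: _LaplaceGLMM) -> tuple[float, float]:
    """Marginal and conditional R² for a fitted GLMM.

    The variance-partition definitions: the fixed-effect variance is the
    variance of the fixed linear predictor over the fitted rows; each
    random term contributes (membership multiplicity × σ²) at the row
    level; the distribution-specific variance is π²/3 for the logit model
    and ln(1 + 1/λ̄) for the log-link count model, with λ̄ approximated on
    the untruncated scale as exp(mean fixed η + half the random variance).
    """
    sigma2_f = float(np.var(fit.eta_fixed_))
    sigma2_r = sum(
        fit.vc_multiplicity_[name] * s2 for name, s2 in fit.vc_.items()
    )
    if fit._family.name == "binomial":
        sigma2_d = np.pi**2 / 3.0
    else:
        lam_bar = float(np.exp(np.mean(fit.eta_fixed_) + 0.5 * sigma2_r))
        sigma2_d = float(np.log1p(1.0 / lam_bar))
    total = sigma2_f + sigma2_r + sigma2_d
    return sigma2_f / total, (sigma2_f + sigma2_r) / total
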