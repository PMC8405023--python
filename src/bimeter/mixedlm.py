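"""Random-intercept linear mixed model, fitted by profiled (RE)ML.

The model is

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

with one scalar random intercept per group (here: per participant).  Both
variance components are profiled onto the single ratio lambda =
sigma_u^2 / sigma_e^2: for fixed lambda the marginal covariance is
sigma_e^2 * V(lambda) with V = I + lambda Z Z', beta has a closed-form GLS
solution, and sigma_e^2 a closed-form estimate, so the (restricted)
likelihood is maximized by a one-dimensional search over log(lambda).
The random-intercept structure makes V block diagonal with
V_g^{-1} = I - lambda/(1 + lambda n_g) J, so all quantities reduce to
per-group sums and the fit costs O(N) per candidate lambda.

``RandomInterceptLM`` is the model object (built from arrays or a
DataFrame); ``fit`` returns a ``RandomInterceptLMResults`` carrying the
estimates, their standard errors, t statistics, variance components,
log-likelihood and Nakagawa-style marginal/conditional R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOG_2PI = np.log(2.0 * np.pi)


class RandomInterceptLM:
    """Linear model with fixed effects ``exog`` and a per-group random intercept.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response values.
    exog : array-like, shape (n, p)
        Fixed-effect design matrix (include the intercept column yourself,
        or use :meth:`from_dataframe`).
    groups : array-like, shape (n,)
        Group labels of the random intercept.
    exog_names : sequence of str, optional
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        codes, uniques = pd.factorize(np.asarray(groups))
        if codes.shape[0] != self.endog.shape[0]:
            raise ValueError("groups length differs from endog")
        self.group_codes = codes
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        self.nobs = self.endog.shape[0]
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        self.rank = np.linalg.matrix_rank(self.exog)
        if self.rank < self.exog.shape[1]:
            raise ValueError("fixed-effect design matrix is singular")
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups for a random intercept")

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_dataframe(cls, data, response, fixed, group, interactions=()):
        """Build the model from a tidy DataFrame.

        ``fixed`` columns enter as main effects (an intercept is prepended);
        ``interactions`` is a sequence of column-name pairs whose products
        are appended.
        """
        cols = [np.ones(len(data))]
        names = ["intercept"]
        for c in fixed:
            cols.append(data[c].to_numpy(dtype=float))
            names.append(c)
        for a, b in interactions:
            cols.append(data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float))
            names.append(f"{a}:{b}")
        return cls(
            data[response].to_numpy(dtype=float),
            np.column_stack(cols),
            data[group].to_numpy(),
            exog_names=names,
        )

    # -- likelihood machinery --------------------------------------------
    def _profile(self, lam: float):
        """GLS quantities at a fixed variance ratio lambda."""
        y, X, codes = self.endog, self.exog, self.group_codes
        sizes = np.bincount(codes, minlength=self.n_groups).astype(float)
        shrink = lam / (1.0 + lam * sizes)  # per-group J-term weight
        # group sums of y and of each column of X
        sum_y = np.bincount(codes, weights=y, minlength=self.n_groups)
        sum_X = np.column_stack(
            [np.bincount(codes, weights=X[:, j], minlength=self.n_groups)
             for j in range(X.shape[1])]
        )
        w = shrink
        xtvx = X.T @ X - (sum_X * w[:, None]).T @ sum_X
        xtvy = X.T @ y - (sum_X * w[:, None]).T @ sum_y
        ytvy = y @ y - np.sum(w * sum_y**2)
        beta = np.linalg.solve(xtvx, xtvy)
        qform = ytvy - beta @ xtvy  # (y-Xb)' V^-1 (y-Xb) at the GLS optimum
        logdet_v = float(np.sum(np.log1p(lam * sizes)))
        return beta, xtvx, qform, logdet_v

    def _neg2_criterion(self, log_lam: float, reml: bool) -> float:
        lam = np.exp(log_lam)
        n, p = self.nobs, self.rank
        try:
            _, xtvx, qform, logdet_v = self._profile(lam)
        except np.linalg.LinAlgError:
            return np.inf
        if qform <= 0:
            qform = np.finfo(float).tiny
        if reml:
            sigma2 = qform / (n - p)
            sign, logdet_x = np.linalg.slogdet(xtvx)
            return (n - p) * np.log(sigma2) + logdet_v + logdet_x
        sigma2 = qform / n
        return n * np.log(sigma2) + logdet_v

    def loglike(self, sigma_u2: float, sigma_e2: float, reml: bool = True) -> float:
        """(Restricted) log-likelihood at given variance components."""
        lam = sigma_u2 / sigma_e2
        beta, xtvx, qform, logdet_v = self._profile(lam)
        n, p = self.nobs, self.rank
        if reml:
            sign, logdet_x = np.linalg.slogdet(xtvx)
            return -0.5 * (
                (n - p) * (np.log(sigma_e2) + _LOG_2PI)
                + logdet_v
                + logdet_x
                + qform / sigma_e2
            )
        return -0.5 * (n * (np.log(sigma_e2) + _LOG_2PI) + logdet_v + qform / sigma_e2)

    # -- fitting -----------------------------------------------------------
    def fit(self, reml: bool = True) -> "RandomInterceptLMResults":
        """Profile the variance ratio, then solve the fixed effects by GLS."""
        res = optimize.minimize_scalar(
            self._neg2_criterion,
            bounds=(-12.0, 12.0),
            args=(reml,),
            method="bounded",
            options={"xatol": 1e-8},
        )
        log_lam = float(res.x)
        lam = float(np.exp(log_lam))
        at_boundary = False
        eps_crit = self._neg2_criterion(np.log(1e-10), reml)
        if eps_crit <= res.fun + 1e-9:
            lam = 0.0
            at_boundary = True
            warnings.warn(
                "random-intercept variance estimated at the zero boundary; "
                "sigma_u^2 clamped to 0",
                stacklevel=2,
            )
        beta, xtvx, qform, _ = self._profile(lam)
        n, p = self.nobs, self.rank
        sigma_e2 = qform / (n - p) if reml else qform / n
        sigma_u2 = lam * sigma_e2
        cov = sigma_e2 * np.linalg.inv(xtvx)
        df = n - p - (self.n_groups - 1)
        llf = self.loglike(sigma_u2, max(sigma_e2, np.finfo(float).tiny), reml=reml)
        return RandomInterceptLMResults(
            model=self,
            params=beta,
            cov_params=cov,
            sigma_u2=float(sigma_u2),
            sigma_e2=float(sigma_e2),
            df_resid=int(df),
            llf=float(llf),
            reml=reml,
            converged=bool(res.success),
            at_boundary=at_boundary,
        )


@dataclass(frozen=True)
class RandomInterceptLMResults:
    """Estimates, uncertainties and diagnostics of a fitted random-intercept model."""

    model: RandomInterceptLM
    params: np.ndarray
    cov_params: np.ndarray
    sigma_u2: float
    sigma_e2: float
    df_resid: int
    llf: float
    reml: bool
    converged: bool
    at_boundary: bool

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    @property
    def fittedvalues(self) -> np.ndarray:
        """Fixed-effect predictions X beta-hat."""
        return self.model.exog @ self.params

    def r2_glmm(self) -> tuple[float, float]:
        """(marginal, conditional) R^2 for the mixed model.

        Marginal: fixed-effect variance over total (fixed + intercept +
        residual) variance; conditional adds the intercept variance to the
        numerator.  The fixed-effect variance is the population variance of
        the fitted fixed-effect predictions over the observed design.
        """
        var_f = float(np.var(self.fittedvalues))
        total = var_f + self.sigma_u2 + self.sigma_e2
        if total <= 0:
            raise ValueError("total variance is zero")
        return var_f / total, (var_f + self.sigma_u2) / total

    def predicted_effect(self, name: str, span: float, ndigits: int = 2) -> float:
        """Change in the response for a `span`-unit change of one fixed effect."""
        slope = self.params[self.model.exog_names.index(name)]
        return round(float(slope * span), ndigits)

    def summary(self) -> str:
        """Human-readable coefficient table plus variance components."""
        r2m, r2c = self.r2_glmm()
        lines = [
            "Random-intercept linear mixed model "
            f"({'REML' if self.reml else 'ML'})",
            f"  observations: {self.model.nobs}   groups: {self.model.n_groups}"
            f"   df: {self.df_resid}",
            f"  sigma_u^2: {self.sigma_u2:.4g}   sigma_e^2: {self.sigma_e2:.4g}"
            f"   logLik: {self.llf:.2f}",
            f"  R2 marginal: {r2m:.3f}   conditional: {r2c:.3f}",
            "",
            f"  {'term':<22}{'slope':>12}{'SE':>12}{'df':>6}{'t':>8}{'p':>10}",
        ]
        for name, b, se, t, p in zip(
            self.model.exog_names, self.params, self.bse, self.tvalues, self.pvalues
        ):
            lines.append(
                f"  {name:<22}{b:>12.4g}{se:>12.4g}{self.df_resid:>6d}"
                f"{t:>8.2f}{p:>10.3g}"
            )
        return "\n".join(lines)
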