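"""Inferential models: Gaussian GLMs, a gamma random-intercept GLMM, VIF.

The Gaussian fits (home-range size, isotope values) go through ordinary
least squares with t tests, with optional backward elimination of
non-significant interactions.  Residence distance over time is modelled as
a gamma GLMM with log link and a random intercept per fish, fitted by
maximum likelihood with a Laplace approximation over the scalar random
effect — statsmodels offers no gamma mixed model, so the marginal
likelihood is implemented here, statsmodels-style: a Model object whose
``fit()`` returns a Results object with estimates, standard errors, Wald
tests and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats

__all__ = [
    "OLSFit",
    "fit_ols",
    "drop_insignificant_interactions",
    "GammaRandomInterceptModel",
    "GammaGLMMResults",
    "vif",
    "pearson",
    "model_table",
]


# -- Gaussian GLMs ----------------------------------------------------------


@dataclass(frozen=True)
class OLSFit:
    """Closed-form least-squares fit with two-sided t tests."""

    formula: str
    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: float
    nobs: int
    rsquared: float
    rsquared_adj: float
    llf: float
    conf_int: np.ndarray  # (p, 2) 95% bounds
    _sm: object = field(repr=False, default=None)

    def summary(self) -> str:
        return str(self._sm.summary())

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "value": self.params,
                "se": self.bse,
                "statistic": self.tvalues,
                "p": self.pvalues,
            }
        )


def fit_ols(formula: str, data: pd.DataFrame) -> OLSFit:
    """Gaussian linear model from a formula (patsy syntax, interactions OK).

    Raises on rank-deficient designs, naming the aliased columns.
    """
    model = smf.ols(formula, data=data)
    X = model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns from the QR diagonal
        _, r = np.linalg.qr(X, mode="reduced")
        names = model.exog_names
        diag = np.abs(np.diag(r))
        aliased = [names[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased or names}")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    res = model.fit()
    return OLSFit(
        formula=formula,
        names=tuple(res.model.exog_names),
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        df_resid=float(res.df_resid),
        nobs=int(res.nobs),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        llf=float(res.llf),
        conf_int=np.asarray(res.conf_int()),
        _sm=res,
    )


def _expand_formula(formula: str) -> str:
    """Rewrite ``y ~ a*b + c`` as ``y ~ a + b + a:b + c`` (explicit terms)."""
    lhs, rhs = formula.split("~")
    out: list[str] = []
    for term in (t.strip() for t in rhs.split("+")):
        if "*" in term:
            a, b = (s.strip() for s in term.split("*", 1))
            for t in (a, b, f"{a}:{b}"):
                if t not in out:
                    out.append(t)
        elif term and term not in out:
            out.append(term)
    return f"{lhs.strip()} ~ " + " + ".join(out)


def drop_insignificant_interactions(
    formula: str, data: pd.DataFrame, alpha: float = 0.05
) -> OLSFit:
    """Backward-eliminate interaction terms with p ≥ alpha, one at a time."""
    current = _expand_formula(formula)
    while True:
        fit = fit_ols(current, data)
        inter = [
            (name, p)
            for name, p in zip(fit.names, fit.pvalues)
            if ":" in name and p >= alpha
        ]
        if not inter:
            return fit
        worst = max(inter, key=lambda t: t[1])[0]
        rhs_terms = [t.strip() for t in current.split("~")[1].split("+")]
        # map the fitted column name back to the formula term
        keep = [t for t in rhs_terms if t.replace(" ", "") != worst.replace(" ", "")]
        if len(keep) == len(rhs_terms):  # name mangling (categorical codes)
            base = worst.split("[")[0].replace(" ", "")
            keep = [t for t in rhs_terms if t.replace(" ", "").split("[")[0] != base]
        if len(keep) == len(rhs_terms):
            return fit
        current = current.split("~")[0] + "~ " + " + ".join(keep)


# -- gamma random-intercept GLMM -------------------------------------------


class GammaRandomInterceptModel:
    """Gamma GLMM with log link and one random intercept per group.

    y_ij | b_i ~ Gamma(shape α, mean exp(xᵢⱼᵀβ + b_i)),  b_i ~ N(0, σ_b²).

    The marginal log-likelihood integrates b_i out with a Laplace
    approximation at the per-group conditional mode (found by a vectorized
    scalar Newton iteration), which is accurate for a single scalar random
    effect.  ``fit`` maximizes over (β, log α, log σ_b) with L-BFGS-B and
    reports Wald z tests from the numerical Hessian.
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        groups: np.ndarray,
        exog_names: list[str] | None = None,
    ) -> None:
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if np.any(y <= 0):
            raise ValueError("gamma response must be strictly positive")
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("exog must be (n, p) matching endog")
        codes, uniques = pd.factorize(np.asarray(groups))
        if len(uniques) < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        order = np.argsort(codes, kind="stable")
        self.endog = y[order]
        self.exog = X[order]
        self.group_codes = codes[order]
        self.group_labels = uniques
        self.n_groups = len(uniques)
        self.exog_names = list(exog_names or [f"x{j}" for j in range(X.shape[1])])
        # group slice bookkeeping for fast segment sums
        self._starts = np.searchsorted(
            self.group_codes, np.arange(self.n_groups)
        )
        self._counts = np.bincount(self.group_codes, minlength=self.n_groups).astype(
            float
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        terms: list[str],
        group: str,
        add_intercept: bool = True,
    ) -> "GammaRandomInterceptModel":
        """Build the design from columns; ``a:b`` denotes an interaction."""
        cols = []
        names = []
        if add_intercept:
            cols.append(np.ones(len(data)))
            names.append("Intercept")
        for term in terms:
            if ":" in term:
                a, b = (t.strip() for t in term.split(":", 1))
                cols.append(data[a].to_numpy(float) * data[b].to_numpy(float))
            else:
                cols.append(data[term.strip()].to_numpy(float))
            names.append(term.strip())
        X = np.column_stack(cols)
        return cls(
            data[response].to_numpy(float), X, data[group].to_numpy(), names
        )

    # - likelihood machinery -

    def _segment_sum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.group_codes, weights=values, minlength=self.n_groups)

    def _modes(
        self, eta: np.ndarray, alpha: float, sigma2: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-group conditional modes b̂ via Newton, vectorized over groups.

        The conditional log-density derivative in b is
        α(T_i e^{-b} − n_i) − b/σ², with T_i = Σ_j y_ij e^{-η_ij}.
        """
        T = self._segment_sum(self.endog * np.exp(-eta))
        n_i = self._counts
        b = np.log(np.maximum(T, 1e-300) / np.maximum(n_i, 1.0))  # GLM start
        b = np.clip(b, -20.0, 20.0)
        for _ in range(50):
            e = T * np.exp(-b)
            g = alpha * (e - n_i) - b / sigma2
            h = -alpha * e - 1.0 / sigma2
            step = g / h
            b_new = b - np.clip(step, -5.0, 5.0)
            if np.max(np.abs(b_new - b)) < 1e-10:
                b = b_new
                break
            b = b_new
        e = T * np.exp(-b)
        hess = -alpha * e - 1.0 / sigma2
        return b, e, hess

    def _marginal_loglik(self, params: np.ndarray) -> float:
        p = self.exog.shape[1]
        beta = params[:p]
        alpha = np.exp(params[p])
        sigma = np.exp(params[p + 1])
        sigma2 = sigma * sigma
        eta = self.exog @ beta
        b, e, hess = self._modes(eta, alpha, sigma2)
        # conditional loglik at the mode, summed within groups
        const = (
            alpha * np.log(alpha)
            - special.gammaln(alpha)
            + (alpha - 1.0) * np.log(self.endog)
        ).sum()
        ll_cond = const - alpha * (
            (eta + b[self.group_codes]).sum() + e.sum()
        )
        ll_prior = -0.5 * np.sum(b * b) / sigma2 - self.n_groups * np.log(sigma)
        ll_laplace = -0.5 * np.sum(np.log(-hess))
        return float(ll_cond + ll_prior + ll_laplace)

    def _glm_loglik(self, params: np.ndarray) -> float:
        """Plain gamma GLM log-likelihood (random effect pinned at zero)."""
        p = self.exog.shape[1]
        beta = params[:p]
        alpha = np.exp(params[p])
        eta = self.exog @ beta
        mu = np.exp(eta)
        return float(
            np.sum(
                alpha * np.log(alpha)
                - special.gammaln(alpha)
                + (alpha - 1.0) * np.log(self.endog)
                - alpha * np.log(mu)
                - alpha * self.endog / mu
            )
        )

    def fit(
        self,
        start_params: np.ndarray | None = None,
        fixed_re_sd: float | None = None,
        maxiter: int = 500,
    ) -> "GammaGLMMResults":
        """Maximize the (Laplace) marginal likelihood.

        ``fixed_re_sd=0`` pins the random effect at zero and reduces the
        model to a plain gamma GLM (useful as an oracle check).
        """
        p = self.exog.shape[1]
        if start_params is None:
            # warm start from a gamma GLM; fall back to log-scale OLS when
            # the response is (near-)constant and IRLS cannot start
            try:
                glm = sm.GLM(
                    self.endog,
                    self.exog,
                    family=sm.families.Gamma(link=sm.families.links.Log()),
                ).fit()
                beta0 = np.asarray(glm.params)
                alpha0 = float(np.clip(1.0 / max(glm.scale, 1e-8), 1e-3, 1e6))
            except (ValueError, np.linalg.LinAlgError):
                beta0, *_ = np.linalg.lstsq(
                    self.exog, np.log(self.endog), rcond=None
                )
                alpha0 = 10.0
            start = np.concatenate([beta0, [np.log(alpha0), np.log(0.3)]])
        else:
            start = np.asarray(start_params, dtype=float)

        if fixed_re_sd is not None and fixed_re_sd == 0.0:
            obj = lambda th: -self._glm_loglik(th)  # noqa: E731
            x0 = start[: p + 1]
            bounds = [(None, None)] * p + [(-10.0, 15.0)]
        else:
            obj = lambda th: -self._marginal_loglik(th)  # noqa: E731
            x0 = start
            bounds = [(None, None)] * p + [(-10.0, 15.0), (-8.0, 5.0)]
            if fixed_re_sd is not None:
                x0 = x0.copy()
                x0[p + 1] = np.log(fixed_re_sd)
                bounds[p + 1] = (np.log(fixed_re_sd), np.log(fixed_re_sd))

        res = optimize.minimize(
            obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        theta = res.x
        llf = -float(res.fun)
        hess = _numerical_hessian(obj, theta)
        # Wald SEs for the fixed effects from the observed information
        try:
            cov = np.linalg.inv(hess)
            bse = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, np.inf))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
        params = theta[:p]
        z = np.divide(params, bse, out=np.full(p, np.nan), where=bse > 0)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        alpha = float(np.exp(theta[p]))
        re_sd = (
            0.0
            if (fixed_re_sd is not None and fixed_re_sd == 0.0)
            else float(np.exp(theta[p + 1]))
        )
        return GammaGLMMResults(
            model=self,
            params=params,
            bse=bse,
            zvalues=z,
            pvalues=pvals,
            shape=alpha,
            re_sd=re_sd,
            llf=llf,
            converged=bool(res.success),
            message=str(res.message),
        )


@dataclass(frozen=True)
class GammaGLMMResults:
    """Estimates, Wald tests, and variance components of the gamma GLMM."""

    model: GammaRandomInterceptModel
    params: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    shape: float
    re_sd: float
    llf: float
    converged: bool
    message: str

    @property
    def re_var(self) -> float:
        return self.re_sd**2

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.model.exog_names,
                "value": self.params,
                "se": self.bse,
                "statistic": self.zvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            "Gamma random-intercept GLMM (log link, Laplace)",
            f"groups: {self.model.n_groups}   obs: {len(self.model.endog)}",
            f"log-likelihood: {self.llf:.3f}   converged: {self.converged}",
            f"gamma shape: {self.shape:.4f}   RE sd: {self.re_sd:.4f}",
            "",
            self.to_table().to_string(index=False, float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (small dimension, well-scaled params)."""
    n = len(x)
    H = np.empty((n, n))
    step = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = step[i]
            ej[j] = step[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step[i] * step[j])
    return H


# -- diagnostics ------------------------------------------------------------


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1 − R²_j).

    Each column is regressed (with intercept) on the others; perfect
    collinearity yields ``inf``.  Requires ≥ 2 predictors with variance.
    """
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant predictor has no VIF")
    out = {}
    for j, name in enumerate(names):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample correlation with its two-sided t test (n − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def model_table(fits: dict[str, "OLSFit | GammaGLMMResults"]) -> pd.DataFrame:
    """Stacked coefficient table (model, term, value, se, statistic, p)."""
    parts = []
    for name, fit in fits.items():
        tab = fit.to_table().copy()
        tab.insert(0, "model", name)
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)
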