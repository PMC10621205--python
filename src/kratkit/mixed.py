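"""Generalized linear mixed models for activity-budget proportions.

The modeling stage asks how the proportion of time spent in a behavior
responds to diel and environmental covariates, with random intercepts for
animal identity and calendar night (a night effect is shared by every
individual logged on that night).  Four response families are considered
(gaussian, poisson, binomial, gamma); the family is chosen by AIC among
the candidates that are feasible for the response, and fixed effects are
screened for collinearity with variance inflation factors and tested with
Wald chi-square statistics.  Model fit is summarized with the conditional
R-squared (variance explained by fixed plus random effects).

Estimation is maximum likelihood with a Laplace approximation to the
marginal likelihood for non-gaussian families (for the gaussian family
the approximation is exact, so the same engine serves all four): for
trial variance parameters the penalized joint likelihood in (beta, u) is
maximized by Newton iteration, and the profiled Laplace criterion is
optimized over the variance parameters (and the dispersion, where the
family has one).  Proportions are modeled as weighted binomial counts
(successes = behavior windows, trials = cell windows) when the binomial
family is used.

The surface follows the statsmodels idiom: ``MixedGLM`` is built from a
formula and a DataFrame, ``fit()`` returns a ``MixedGLMResults`` carrying
estimates, standard errors, AIC, Wald tests, conditional R-squared and a
``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "poisson", "binomial", "gamma")

__all__ = [
    "MixedGLM",
    "MixedGLMResults",
    "FamilySelection",
    "compute_vif",
    "select_family",
    "fit_mixed",
    "wald_tests",
    "conditional_r2",
]


# --- collinearity ----------------------------------------------------------


def compute_vif(design: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors for each predictor column.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from the OLS regression (with
    intercept) of predictor j on all other predictors.  Exactly collinear
    predictors are reported as infinite.  Categorical predictors should be
    passed already expanded to contrast columns (one VIF per contrast).
    """
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    if np.any(np.all(X == 0, axis=0)):
        raise ValueError("constant-zero predictor column")
    out = []
    n = X.shape[0]
    ones = np.ones((n, 1))
    for j in range(X.shape[1]):
        yj = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot <= 0:
            raise ValueError(f"predictor {names[j]!r} has zero variance")
        r2 = 1.0 - ss_res / ss_tot
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"predictor": names[j], "vif": vif})
    report = pd.DataFrame(out)
    exact = report.loc[~np.isfinite(report["vif"]), "predictor"].tolist()
    if exact:
        logger.warning("exact collinearity among predictors: %s", exact)
    return report


# --- family log-likelihood pieces ------------------------------------------


class _Family:
    """Log-likelihood, gradient and Fisher weights on the linear-predictor scale."""

    name: str
    link: str
    has_dispersion = False

    def mu(self, eta):
        raise NotImplementedError


class _Gaussian(_Family):
    name, link = "gaussian", "identity"
    has_dispersion = True

    def mu(self, eta):
        return eta

    def loglik(self, y, eta, m, phi):
        return -0.5 * ((y - eta) ** 2 / phi + np.log(2 * np.pi * phi))

    def grad_w(self, y, eta, m, phi):
        return (y - eta) / phi, np.full_like(eta, 1.0 / phi)


class _Poisson(_Family):
    name, link = "poisson", "log"

    def mu(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def loglik(self, y, eta, m, phi):
        mu = self.mu(eta)
        return y * np.log(mu) - mu - special.gammaln(y + 1)

    def grad_w(self, y, eta, m, phi):
        mu = self.mu(eta)
        return y - mu, mu


class _Binomial(_Family):
    """Weighted binomial: response is a proportion, m the trial count."""

    name, link = "binomial", "logit"

    def mu(self, eta):
        return special.expit(eta)

    def loglik(self, y, eta, m, phi):
        p = np.clip(self.mu(eta), 1e-12, 1 - 1e-12)
        s = y * m
        return (
            special.gammaln(m + 1)
            - special.gammaln(s + 1)
            - special.gammaln(m - s + 1)
            + s * np.log(p)
            + (m - s) * np.log1p(-p)
        )

    def grad_w(self, y, eta, m, phi):
        p = self.mu(eta)
        return m * (y - p), np.clip(m * p * (1 - p), 1e-10, None)


class _Gamma(_Family):
    name, link = "gamma", "log"
    has_dispersion = True

    def mu(self, eta):
        return np.exp(np.clip(eta, -30, 30))

    def loglik(self, y, eta, m, phi):
        nu = 1.0 / phi
        mu = self.mu(eta)
        return (
            nu * (np.log(nu) - np.log(mu))
            + (nu - 1.0) * np.log(y)
            - nu * y / mu
            - special.gammaln(nu)
        )

    def grad_w(self, y, eta, m, phi):
        nu = 1.0 / phi
        mu = self.mu(eta)
        return nu * (y - mu) / mu, np.full_like(eta, nu)


_FAMILY_MAP = {
    "gaussian": _Gaussian,
    "poisson": _Poisson,
    "binomial": _Binomial,
    "gamma": _Gamma,
}


# --- model -----------------------------------------------------------------


class ConvergenceError(RuntimeError):
    pass


class MixedGLM:
    """Mixed model with crossed random intercepts for individual and night.

    Parameters
    ----------
    endog : response vector (proportion for binomial, counts for poisson,
        positive reals for gamma).
    exog : fixed-effects design matrix (with intercept column).
    groups : mapping of random-factor name -> integer codes per row.
    family : one of gaussian, poisson, binomial, gamma.
    var_weights : binomial trial counts (ignored by other families).
    """

    def __init__(
        self,
        endog,
        exog,
        groups: dict[str, np.ndarray],
        family: str = "gaussian",
        var_weights=None,
        exog_names=None,
        design_info=None,
    ):
        if family not in _FAMILY_MAP:
            raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
        self.family_name = family
        self.family = _FAMILY_MAP[family]()
        self.y = np.asarray(endog, dtype=float)
        self.X = np.asarray(exog, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("exog must be 2-D with one row per observation")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(
                "fixed-effects design matrix is rank-deficient "
                "(exactly collinear predictors)"
            )
        self.m = (
            np.ones_like(self.y)
            if var_weights is None
            else np.asarray(var_weights, dtype=float)
        )
        self.group_names = list(groups)
        self.group_codes = []
        self.group_sizes = []
        for name in self.group_names:
            codes = np.asarray(groups[name])
            if codes.dtype.kind not in "iu":
                codes = pd.Categorical(codes).codes
            if len(np.unique(codes)) < 2:
                raise ValueError(f"random factor {name!r} needs at least 2 levels")
            self.group_codes.append(codes.astype(int))
            self.group_sizes.append(int(codes.max()) + 1)
        self.q = int(sum(self.group_sizes))
        # dense indicator matrix [Z_1 | Z_2 | ...]
        n = len(self.y)
        Z = np.zeros((n, self.q))
        offset = 0
        for codes, size in zip(self.group_codes, self.group_sizes):
            Z[np.arange(n), offset + codes] = 1.0
            offset += size
        self.Z = Z
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )
        self.design_info = design_info
        self._validate_response()

    # -- constructors --

    @classmethod
    def from_formula(
        cls,
        formula: str,
        data: pd.DataFrame,
        groups: tuple[str, ...] = ("individual", "night"),
        family: str = "gaussian",
        weights: str | None = None,
    ) -> "MixedGLM":
        """Build from a patsy formula; ``groups`` name columns of ``data``.

        ``weights`` names the binomial trials column (e.g. ``n_total``).
        """
        y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
        endog = y_dm.iloc[:, 0].to_numpy()
        var_weights = data[weights].to_numpy(float) if weights else None
        group_map = {g: data[g].to_numpy() for g in groups}
        return cls(
            endog,
            X_dm.to_numpy(),
            group_map,
            family=family,
            var_weights=var_weights,
            exog_names=list(X_dm.columns),
            design_info=X_dm.design_info,
        )

    def _validate_response(self) -> None:
        y = self.y
        fam = self.family_name
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if fam == "binomial":
            if np.any((y < 0) | (y > 1)):
                raise ValueError("binomial response must be a proportion in [0, 1]")
        elif fam == "poisson":
            if np.any(y < 0) or np.any(np.abs(y - np.round(y)) > 1e-8):
                raise ValueError("poisson response must be non-negative integers")
        elif fam == "gamma":
            if np.any(y <= 0):
                raise ValueError("gamma response must be strictly positive")

    # -- inner PIRLS ---------------------------------------------------------

    def _inner_mode(self, d_inv: np.ndarray, phi: float, beta_u0=None):
        """Joint penalized-likelihood mode over (beta, u) by Newton iteration."""
        n, p = self.X.shape
        C = np.hstack([self.X, self.Z])  # (n, p+q)
        pen = np.zeros(p + self.q)
        pen[p:] = d_inv  # diagonal penalty
        theta = np.zeros(p + self.q) if beta_u0 is None else beta_u0.copy()
        ll_prev = -np.inf
        for it in range(100):
            eta = C @ theta
            g, w = self.family.grad_w(self.y, eta, self.m, phi)
            grad = C.T @ g - pen * theta
            H = (C * w[:, None]).T @ C
            H[np.diag_indices_from(H)] += pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # damped Newton with halving on the penalized objective
            def pll(th):
                return float(
                    self.family.loglik(self.y, C @ th, self.m, phi).sum()
                    - 0.5 * np.sum(pen * th**2)
                )
            scale = 1.0
            base = pll(theta)
            for _ in range(30):
                cand = theta + scale * step
                if pll(cand) >= base - 1e-10:
                    break
                scale *= 0.5
            theta = theta + scale * step
            ll = pll(theta)
            if abs(ll - ll_prev) < 1e-10 * (1 + abs(ll)):
                break
            ll_prev = ll
        eta = C @ theta
        _, w = self.family.grad_w(self.y, eta, self.m, phi)
        return theta, w, it + 1

    def _laplace_loglik(self, log_var: np.ndarray, log_phi: float | None, state):
        sigma2 = np.exp(log_var)
        d_inv = np.concatenate(
            [np.full(size, 1.0 / s2) for size, s2 in zip(self.group_sizes, sigma2)]
        )
        phi = float(np.exp(log_phi)) if log_phi is not None else 1.0
        theta, w, _ = self._inner_mode(d_inv, phi, state.get("theta"))
        state["theta"] = theta
        p = self.X.shape[1]
        u = theta[p:]
        eta = np.hstack([self.X, self.Z]) @ theta
        ll_data = float(self.family.loglik(self.y, eta, self.m, phi).sum())
        pen = float(0.5 * np.sum(d_inv * u**2))
        ZtWZ = (self.Z * w[:, None]).T @ self.Z
        A = ZtWZ / d_inv[None, :]  # ZtWZ @ D
        A[np.diag_indices_from(A)] += 1.0
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf
        return ll_data - pen - 0.5 * logdet

    # -- public fit ----------------------------------------------------------

    def fit(self, start=None, maxiter: int = 200) -> "MixedGLMResults":
        p = self.X.shape[1]
        k = len(self.group_sizes)
        has_phi = self.family.has_dispersion
        if start is None:
            x0 = np.full(k + (1 if has_phi else 0), np.log(0.25))
            if has_phi:
                x0[-1] = np.log(max(np.var(self.y), 1e-3))
        else:
            x0 = np.asarray(start, dtype=float)
        state: dict = {}

        def objective(x):
            lv = x[:k]
            lp = x[k] if has_phi else None
            val = self._laplace_loglik(lv, lp, state)
            return -val if np.isfinite(val) else 1e10

        bounds = [(-12.0, 6.0)] * k + ([(-12.0, 8.0)] if has_phi else [])
        # quasi-Newton from two starts (the profile surface can have flat
        # ridges where a variance component collapses), then a simplex polish
        starts = [x0]
        alt = x0.copy()
        alt[:k] += 2.0
        starts.append(alt)
        res = None
        for s0 in starts:
            cand = optimize.minimize(
                objective, s0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter},
            )
            if res is None or cand.fun < res.fun:
                res = cand
        polish = optimize.minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            options={"maxiter": maxiter * (k + 1), "xatol": 1e-7, "fatol": 1e-10},
        )
        if polish.fun < res.fun:
            res = polish
        x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
        loglik = -objective(x)
        sigma2 = np.exp(x[:k])
        phi = float(np.exp(x[k])) if has_phi else 1.0

        # final mode and covariance of beta given variance parameters
        d_inv = np.concatenate(
            [np.full(size, 1.0 / s2) for size, s2 in zip(self.group_sizes, sigma2)]
        )
        theta, w, _ = self._inner_mode(d_inv, phi, state.get("theta"))
        beta, u = theta[:p], theta[p:]
        XtWX = (self.X * w[:, None]).T @ self.X
        XtWZ = (self.X * w[:, None]).T @ self.Z
        ZtWZ = (self.Z * w[:, None]).T @ self.Z
        M = ZtWZ.copy()
        M[np.diag_indices_from(M)] += d_inv
        Minv_ZtWX = np.linalg.solve(M, XtWZ.T)
        info_beta = XtWX - XtWZ @ Minv_ZtWX
        cov_beta = np.linalg.inv(info_beta)

        n_params = p + k + (1 if has_phi else 0)
        aic = -2.0 * loglik + 2.0 * n_params
        converged = bool(res.success or res.fun < 1e9)
        if not converged:
            logger.warning("MixedGLM fit did not converge: %s", res.message)
        return MixedGLMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(
                cov_beta, index=self.exog_names, columns=self.exog_names
            ),
            random_effects={
                name: u[off : off + size]
                for name, size, off in zip(
                    self.group_names,
                    self.group_sizes,
                    np.concatenate([[0], np.cumsum(self.group_sizes)[:-1]]),
                )
            },
            vc=pd.Series(sigma2, index=self.group_names),
            scale=phi,
            llf=loglik,
            aic=aic,
            converged=converged,
            n_obs=len(self.y),
        )


@dataclass
class MixedGLMResults:
    """ML estimates, uncertainties and diagnostics for a fitted MixedGLM."""

    model: MixedGLM
    params: pd.Series
    cov_params: pd.DataFrame
    random_effects: dict[str, np.ndarray]
    vc: pd.Series  # random-intercept variances
    scale: float  # dispersion (gaussian sigma^2_e; gamma 1/shape; else 1)
    llf: float
    aic: float
    converged: bool
    n_obs: int

    bse: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.bse = pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def family(self) -> str:
        return self.model.family_name

    def fittedvalues(self) -> np.ndarray:
        eta = self.model.X @ self.params.to_numpy()
        off = 0
        for name, size in zip(self.model.group_names, self.model.group_sizes):
            codes = self.model.group_codes[self.model.group_names.index(name)]
            eta = eta + self.random_effects[name][codes]
            off += size
        return self.model.family.mu(eta)

    # -- inference --

    def wald_test_terms(self, terms: list[str] | None = None) -> pd.DataFrame:
        """Joint Wald chi-square test for each model term.

        All contrast columns belonging to a term are tested jointly:
        chi2 = b' V^-1 b on the term's coefficient block, df = block size,
        p from the upper chi-square tail.  The intercept is skipped.
        """
        if not self.converged:
            raise ConvergenceError("Wald tests are undefined for a non-converged fit")
        di = self.model.design_info
        if di is not None:
            slices = {t.name(): di.term_name_slices[t.name()] for t in di.terms}
        else:
            slices = {name: slice(j, j + 1) for j, name in enumerate(self.params.index)}
        rows = []
        beta = self.params.to_numpy()
        V = self.cov_params.to_numpy()
        for name, sl in slices.items():
            if name == "Intercept":
                continue
            if terms is not None and name not in terms:
                continue
            b = beta[sl]
            Vb = V[sl, sl]
            try:
                chi2 = float(b @ np.linalg.solve(Vb, b))
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"singular covariance block for term {name!r}"
                ) from None
            df = len(b)
            rows.append(
                {
                    "term": name,
                    "chi2": chi2,
                    "df": df,
                    "p": float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0,
                }
            )
        return pd.DataFrame(rows)

    def conditional_r2(self) -> float:
        """Conditional R^2: (fixed + random variance) over total latent variance.

        The residual term is the family-appropriate variance on the link
        scale: the dispersion for gaussian; pi^2/3 for the logit-binomial;
        log(1 + 1/mean(mu)) for the log-Poisson; log(1 + dispersion) for
        the log-Gamma.
        """
        if not self.converged:
            raise ConvergenceError("conditional R^2 undefined for a non-converged fit")
        eta_fixed = self.model.X @ self.params.to_numpy()
        var_f = float(np.var(eta_fixed))
        var_r = float(self.vc.sum())
        fam = self.family
        if fam == "gaussian":
            var_e = self.scale
        elif fam == "binomial":
            var_e = np.pi**2 / 3.0
        elif fam == "poisson":
            lam = float(np.mean(self.fittedvalues()))
            var_e = float(np.log1p(1.0 / max(lam, 1e-8)))
        else:  # gamma
            var_e = float(np.log1p(self.scale))
        total = var_f + var_r + var_e
        return float(np.clip((var_f + var_r) / total, 0.0, 1.0)) if total > 0 else 0.0

    def summary(self) -> str:
        lines = [
            "Mixed GLM (Laplace ML)",
            f"  family: {self.family}   n_obs: {self.n_obs}   converged: {self.converged}",
            f"  logLik: {self.llf:.3f}   AIC: {self.aic:.3f}   "
            f"conditional R2: {self.conditional_r2():.3f}" if self.converged
            else f"  logLik: {self.llf:.3f}   AIC: {self.aic:.3f}",
            "",
            f"  {'term':<28}{'coef':>10}{'se':>10}{'z':>8}",
        ]
        for name in self.params.index:
            b, se = self.params[name], self.bse[name]
            z = b / se if se > 0 else np.nan
            lines.append(f"  {name:<28}{b:>10.4f}{se:>10.4f}{z:>8.2f}")
        lines.append("")
        for name in self.vc.index:
            lines.append(f"  random intercept {name}: var {self.vc[name]:.4f}")
        if self.model.family.has_dispersion:
            lines.append(f"  dispersion: {self.scale:.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        wald = self.wald_test_terms().set_index("term") if self.converged else None
        rows = []
        for name in self.params.index:
            rows.append(
                {
                    "term": name,
                    "estimate": self.params[name],
                    "se": self.bse[name],
                    "family": self.family,
                    "converged": self.converged,
                }
            )
        return pd.DataFrame(rows)


# --- family selection ------------------------------------------------------


@dataclass
class FamilySelection:
    best: MixedGLMResults
    aic_table: pd.DataFrame
    skipped: dict[str, str]


def _feasible(family: str, y: np.ndarray, weights_given: bool) -> str | None:
    if family == "binomial":
        if np.any((y < 0) | (y > 1)):
            return "response outside [0, 1]"
        if not weights_given:
            return "no trial counts supplied"
    if family == "poisson" and (
        np.any(y < 0) or np.any(np.abs(y - np.round(y)) > 1e-8)
    ):
        return "response is not counts"
    if family == "gamma" and np.any(y <= 0):
        return "response contains zeros or negatives"
    return None


def select_family(
    formula: str,
    data: pd.DataFrame,
    groups: tuple[str, ...] = ("individual", "night"),
    candidates: tuple[str, ...] = FAMILIES,
    weights: str | None = None,
) -> FamilySelection:
    """Fit every feasible candidate family and keep the minimum-AIC fit.

    All candidates share the identical fixed/random structure; infeasible
    candidates (zeros for gamma, non-counts for poisson, missing trial
    counts for binomial) are skipped with a recorded reason.
    """
    y = patsy.dmatrices(formula, data, return_type="dataframe")[0].iloc[:, 0].to_numpy()
    fits: dict[str, MixedGLMResults] = {}
    skipped: dict[str, str] = {}
    for fam in candidates:
        reason = _feasible(fam, y, weights is not None)
        if reason:
            skipped[fam] = reason
            logger.info("select_family: skipping %s (%s)", fam, reason)
            continue
        try:
            fit = MixedGLM.from_formula(
                formula,
                data,
                groups=groups,
                family=fam,
                weights=weights if fam == "binomial" else None,
            ).fit()
        except Exception as exc:  # noqa: BLE001 - per-family diagnostics
            skipped[fam] = f"fit failed: {exc}"
            continue
        if fit.converged:
            fits[fam] = fit
        else:
            skipped[fam] = "did not converge"
    if not fits:
        raise ConvergenceError(f"no candidate family converged: {skipped}")
    # AICs are compared on a common response scale: the binomial counts
    # likelihood is mapped to the proportion scale by the change of
    # variables density(p) = trials * pmf(successes), i.e. +sum(log trials)
    # on the log-likelihood.
    rows = []
    for fam, r in fits.items():
        adj = 0.0
        if fam == "binomial" and weights is not None:
            adj = float(np.log(data[weights].to_numpy(float)).sum())
        rows.append(
            {
                "family": fam,
                "aic": r.aic - 2.0 * adj,
                "aic_raw": r.aic,
                "loglik": r.llf,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    best = fits[table.iloc[0]["family"]]
    return FamilySelection(best=best, aic_table=table, skipped=skipped)


# --- functional wrappers ---------------------------------------------------


def fit_mixed(
    formula: str,
    data: pd.DataFrame,
    groups: tuple[str, ...] = ("individual", "night"),
    family: str = "gaussian",
    weights: str | None = None,
) -> MixedGLMResults:
    """Formula-interface convenience wrapper around MixedGLM(...).fit()."""
    return MixedGLM.from_formula(
        formula, data, groups=groups, family=family, weights=weights
    ).fit()


def wald_tests(fit: MixedGLMResults, terms: list[str] | None = None) -> pd.DataFrame:
    return fit.wald_test_terms(terms)


def conditional_r2(fit: MixedGLMResults) -> float:
    return fit.conditional_r2()
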