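"""Maximum-likelihood fitting of the linearised Ricker stock-recruit model.

The model for one population is

    log(R/S)_t = a + b * S_t + c * X_t + v_t,    v_t ~ Normal(0, sigma)

where ``a`` is the maximum per-capita log productivity, ``b`` (< 0 when
density dependence operates) is the effect of spawner abundance, ``X_t`` is an
optional driver covariate with coefficient ``c``, and ``v_t`` is Gaussian
residual error.  Because the model is linear with Gaussian errors, the ML
estimates of the regression coefficients coincide with ordinary least
squares, and the ML variance is the divide-by-n residual variance; fitting is
therefore a closed-form solve, not an iterative search.

Several populations can be fitted jointly: each gets its own intercept
``a_i``, density dependence is either shared (one ``b``) or per population
(``b_i``), a single covariate coefficient ``c`` is shared, and the residual
standard deviation is shared by default (``sigma_structure="shared"``, the
most parsimonious reading) or per population (estimated by iterated feasible
generalised least squares, which converges to the joint MLE).

Confidence intervals use the Wald construction with the finite-sample
(residual degrees-of-freedom) variance estimate and Student-t quantile, which
is exact for this model class and agrees with the inverse information matrix
asymptotically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateLikelihoodError,
    InsufficientDataError,
    SingularDesignError,
)

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-10
_DEGENERATE_SIGMA = 1e-12


@dataclass
class ModelSpec:
    """Declarative description of one candidate model.

    Parameters
    ----------
    populations
        Ordered population ids the model covers.
    density_dependence
        ``"none"`` (constant productivity), ``"shared"`` (one ``b``), or
        ``"per_population"`` (``b_i`` per population).
    covariate
        Name of the covariate column in the model frame(s), or ``None``.  At
        most one covariate per candidate; its coefficient is shared across
        populations.
    sigma_structure
        ``"shared"`` (default) or ``"per_population"``.
    """

    populations: Sequence[str]
    density_dependence: str = "none"
    covariate: str | None = None
    label: str = ""
    sigma_structure: str = "shared"

    def __post_init__(self) -> None:
        if self.density_dependence not in ("none", "shared", "per_population"):
            raise ValueError(f"unknown density dependence {self.density_dependence!r}")
        if self.sigma_structure not in ("shared", "per_population"):
            raise ValueError(f"unknown sigma structure {self.sigma_structure!r}")
        if not self.label:
            parts = [self.density_dependence]
            if self.covariate:
                parts.append(self.covariate)
            self.label = "+".join(parts)


@dataclass
class FitResult:
    """ML estimates and diagnostics for one fitted candidate model."""

    a: dict[str, float]
    b: dict[str, float] | None
    c: float | None
    sigma: float | dict[str, float]
    loglik: float
    n_obs: int
    k_params: int
    residuals: pd.Series  # MultiIndex (population, brood_year)
    fitted: pd.Series
    se: dict[str, float] = field(default_factory=dict)
    label: str = ""
    degenerate: bool = False
    df_resid: int = 0

    def estimate(self, param: str) -> float:
        """Point estimate by name: ``"a:pop"``, ``"b:pop"`` (or ``"a"``/``"b"``
        for single-population fits), or ``"c"``."""
        return self._param_value(param)

    def conf_int(self, param: str, level: float = 0.95) -> tuple[float, float]:
        """Wald interval with t quantile at ``df_resid`` degrees of freedom."""
        est = self._param_value(param)
        se = self.se[param]
        tq = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return est - tq * se, est + tq * se

    def _param_value(self, param: str) -> float:
        if param == "c":
            if self.c is None:
                raise KeyError("model has no covariate coefficient")
            return self.c
        kind, _, pop = param.partition(":")
        if kind == "a":
            return self.a[pop] if pop else next(iter(self.a.values()))
        if kind == "b":
            if self.b is None:
                raise KeyError("model has no density dependence")
            return self.b[pop] if pop else next(iter(self.b.values()))
        raise KeyError(param)


def fit_null(frame: pd.DataFrame, population: str = "pop", label: str = "null") -> FitResult:
    """Constant-productivity null model: ``log(R/S)_t = a + v_t``.

    The MLE is the sample mean with divide-by-n standard deviation;
    ``k_params = 2`` (a, sigma).
    """
    y = frame["log_rs"].to_numpy(float)
    n = len(y)
    if n < 3:
        raise InsufficientDataError(f"null fit needs >= 3 observations, got {n}")
    a = float(np.mean(y))
    resid = y - a
    sigma = float(np.sqrt(np.mean(resid**2)))
    degenerate = sigma < _DEGENERATE_SIGMA
    ll = np.nan if degenerate else _gaussian_loglik(resid, sigma)
    idx = pd.MultiIndex.from_product([[population], frame.index], names=["population", "brood_year"])
    se_a = (sigma * np.sqrt(n / max(n - 1, 1))) / np.sqrt(n)
    return FitResult(
        a={population: a}, b=None, c=None, sigma=sigma, loglik=ll,
        n_obs=n, k_params=2,
        residuals=pd.Series(resid, index=idx),
        fitted=pd.Series(a, index=idx),
        se={f"a:{population}": se_a, "a": se_a},
        label=label, degenerate=degenerate, df_resid=n - 1,
    )


def fit_ricker(frame: pd.DataFrame, spec: ModelSpec | None = None) -> FitResult:
    """Fit the (possibly covariate-augmented) Ricker model to one population.

    ``frame`` is an aligned model frame (index brood_year) with column
    ``log_rs``, optionally ``spawners``, and the covariate column named by
    ``spec.covariate``.  With Gaussian errors the MLE is the least-squares
    solution, computed here from the normal equations via a QR solve.
    """
    if spec is None:
        spec = ModelSpec(populations=["pop"], density_dependence="shared")
    pop = spec.populations[0] if spec.populations else "pop"
    frames = {pop: frame}
    return fit_multipopulation(frames, spec)


def fit_multipopulation(frames: Mapping[str, pd.DataFrame], spec: ModelSpec) -> FitResult:
    """Joint ML fit across populations with shared structure per ``spec``.

    Population-specific intercepts always; density dependence shared or per
    population; one covariate coefficient shared across populations; sigma
    shared (closed form) or per population (iterated feasible GLS).  Years
    missing in one population contribute nothing for that population only.
    """
    pops = [p for p in spec.populations if p in frames] or list(frames)
    use_b = spec.density_dependence != "none"
    per_pop_b = spec.density_dependence == "per_population"

    y_parts, X_parts, names, index_parts = [], [], [], []
    names = [f"a:{p}" for p in pops]
    if use_b:
        names += [f"b:{p}" for p in pops] if per_pop_b else ["b"]
    if spec.covariate:
        names.append("c")

    for p in pops:
        f = frames[p]
        y = f["log_rs"].to_numpy(float)
        n_i = len(y)
        cols = []
        for q in pops:  # intercept dummies
            cols.append(np.full(n_i, 1.0 if q == p else 0.0))
        if use_b:
            s = f["spawners"].to_numpy(float)
            if per_pop_b:
                for q in pops:
                    cols.append(s if q == p else np.zeros(n_i))
            else:
                cols.append(s)
        if spec.covariate:
            if spec.covariate not in f.columns:
                raise KeyError(f"frame for {p} lacks covariate column {spec.covariate!r}")
            cols.append(f[spec.covariate].to_numpy(float))
        y_parts.append(y)
        X_parts.append(np.column_stack(cols))
        index_parts.append(
            pd.MultiIndex.from_product([[p], f.index], names=["population", "brood_year"])
        )

    y = np.concatenate(y_parts)
    X = np.vstack(X_parts)
    idx = index_parts[0]
    for part in index_parts[1:]:
        idx = idx.append(part)
    n, p_reg = X.shape
    n_sigma = len(pops) if spec.sigma_structure == "per_population" else 1
    k = p_reg + n_sigma
    if n <= k:
        raise InsufficientDataError(f"{n} observations cannot support {k} parameters")
    if np.linalg.matrix_rank(X, tol=_RANK_TOL * max(1.0, np.abs(X).max())) < p_reg:
        raise SingularDesignError(
            f"design matrix rank-deficient (n={n}, columns={names}); "
            "a covariate may be collinear with spawners or an intercept"
        )

    sizes = [len(part) for part in y_parts]
    if spec.sigma_structure == "shared":
        beta, resid = _wls_solve(X, y, np.ones(n))
        sigma = float(np.sqrt(np.mean(resid**2)))
        sigmas = {p: sigma for p in pops}
    else:
        beta, resid, sigmas = _per_population_sigma_fit(X, y, pops, sizes)
        sigma = sigmas

    w = np.concatenate(
        [np.full(m, 1.0 / max(sigmas[p], _DEGENERATE_SIGMA) ** 2) for p, m in zip(pops, sizes)]
    )
    degenerate = min(sigmas.values()) < _DEGENERATE_SIGMA
    if degenerate:
        ll = np.nan
        se_vals = np.full(p_reg, np.nan)
    else:
        ll = sum(
            _gaussian_loglik(r, sigmas[p])
            for p, r in zip(pops, np.split(resid, np.cumsum(sizes)[:-1]))
        )
        # finite-sample Wald SEs: residual-dof variance, sigma^2 (X' W X)^-1
        dof = n - p_reg
        XtWX_inv = np.linalg.inv((X * w[:, None]).T @ X)
        scale = np.sum(w * resid**2) / dof
        se_vals = np.sqrt(scale * np.diag(XtWX_inv))

    a = {p: float(beta[i]) for i, p in enumerate(pops)}
    b = None
    c = None
    pos = len(pops)
    if use_b:
        if per_pop_b:
            b = {p: float(beta[pos + i]) for i, p in enumerate(pops)}
            pos += len(pops)
        else:
            b = {p: float(beta[pos]) for p in pops}
            pos += 1
    if spec.covariate:
        c = float(beta[pos])

    se = {name: float(s) for name, s in zip(names, se_vals)}
    if use_b and not per_pop_b:
        for p in pops:
            se[f"b:{p}"] = se["b"]
    if len(pops) == 1:
        se["a"] = se[f"a:{pops[0]}"]
        if use_b:
            se["b"] = se[f"b:{pops[0]}"]

    fitted = X @ beta
    result = FitResult(
        a=a, b=b, c=c,
        sigma=sigma if spec.sigma_structure == "per_population" else float(sigmas[pops[0]]),
        loglik=float(ll) if not degenerate else np.nan,
        n_obs=n, k_params=k,
        residuals=pd.Series(resid, index=idx),
        fitted=pd.Series(fitted, index=idx),
        se=se, label=spec.label, degenerate=degenerate, df_resid=n - p_reg,
    )
    if degenerate:
        logger.warning("fit %s: residual sd ~ 0; flagged degenerate", spec.label)
    return result


def loglik(result: FitResult) -> float:
    """Gaussian log-likelihood at the ML estimates.

    Sum over observations of ``log Normal(residual; 0, sigma)``.  Raises
    :class:`DegenerateLikelihoodError` when sigma is (numerically) zero.
    """
    if result.degenerate:
        raise DegenerateLikelihoodError(
            f"fit {result.label!r} has sigma ~ 0; likelihood unbounded"
        )
    if isinstance(result.sigma, dict):
        total = 0.0
        for pop, sub in result.residuals.groupby(level="population"):
            total += _gaussian_loglik(sub.to_numpy(), result.sigma[pop])
        return float(total)
    return float(_gaussian_loglik(result.residuals.to_numpy(), result.sigma))


def _gaussian_loglik(resid: np.ndarray, sigma: float) -> float:
    n = len(resid)
    return float(-0.5 * n * np.log(2 * np.pi) - n * np.log(sigma)
                 - 0.5 * np.sum(resid**2) / sigma**2)


def _wls_solve(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    return beta, resid


def _per_population_sigma_fit(X, y, pops, sizes, max_iter=200, tol=1e-12):
    """Iterated feasible GLS: alternate WLS for beta and per-block ML sigma.

    Each step increases the joint likelihood, so the iteration converges to
    the joint MLE for this block-diagonal covariance structure.
    """
    bounds = np.cumsum(sizes)[:-1]
    sigmas = {p: 1.0 for p in pops}
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        w = np.concatenate(
            [np.full(m, 1.0 / max(sigmas[p], _DEGENERATE_SIGMA) ** 2)
             for p, m in zip(pops, sizes)]
        )
        beta_new, resid = _wls_solve(X, y, w)
        new_sigmas = {
            p: float(np.sqrt(np.mean(r**2)))
            for p, r in zip(pops, np.split(resid, bounds))
        }
        delta = max(abs(new_sigmas[p] - sigmas[p]) for p in pops)
        shift = np.max(np.abs(beta_new - beta))
        sigmas, beta = new_sigmas, beta_new
        if delta < tol and shift < tol:
            break
    resid = y - X @ beta
    return beta, resid, sigmas
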