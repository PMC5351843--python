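"""Effect sizes and prediction/residual diagnostics for fitted models.

The headline effect-size summary answers: *if the driver rose by a fraction
``f`` of its mean level, what would mean log-productivity become, relative to
the status quo?*  With a coefficient ``c`` on the driver's source scale, a
source-scale mean ``M`` and baseline mean log-productivity ``P``, the shifted
mean is ``P + c * f * M`` and the reported quantity is the ratio

    ratio = (P + c * f * M) / P.

A ratio below 1 means the driver depresses productivity; it is exactly 1 when
``c = 0`` and is linear in the perturbation fraction ``f``.  When the model
was fitted on a z-scored covariate, the coefficient is first back-transformed
to the source scale by dividing by the covariate's standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .covariate_builder import CovariateSeries
from .errors import EffectError
from .ricker_engine import FitResult


@dataclass
class EffectSummary:
    covariate_name: str
    covariate_mean: float  # source-scale mean M
    perturbation_fraction: float  # f
    baseline_log_productivity: float  # P
    coefficient_source_scale: float  # c on the unstandardised scale
    ratio: float


def effect_size_ratio(
    c: float,
    covariate_mean: float,
    fraction: float,
    baseline: float,
    covariate_sd: float | None = None,
    covariate_name: str = "covariate",
) -> EffectSummary:
    """Ratio of perturbed to status-quo mean log-productivity.

    Parameters
    ----------
    c
        Fitted covariate coefficient.  If ``covariate_sd`` is given, ``c`` is
        taken to be on the standardised scale and is divided by the sd to
        recover the source-scale coefficient.
    covariate_mean
        Source-scale mean level ``M`` of the driver.
    fraction
        Perturbation fraction ``f`` (0.10 for a 10% increase in the driver).
    baseline
        Status-quo mean log-productivity ``P``; must be nonzero.
    """
    if baseline == 0:
        raise EffectError("baseline mean log-productivity is zero; ratio undefined")
    c_source = c / covariate_sd if covariate_sd is not None else c
    ratio = (baseline + c_source * fraction * covariate_mean) / baseline
    return EffectSummary(
        covariate_name=covariate_name,
        covariate_mean=covariate_mean,
        perturbation_fraction=fraction,
        baseline_log_productivity=baseline,
        coefficient_source_scale=c_source,
        ratio=ratio,
    )


def pooled_baseline(log_rs_by_population: dict[str, pd.Series], weighted: bool = False) -> float:
    """Mean log-productivity across populations.

    Default is the plain pooled mean of all usable observations; set
    ``weighted=True`` for the mean of per-population means (equal weight per
    population regardless of series length).
    """
    if weighted:
        return float(np.mean([s.mean() for s in log_rs_by_population.values()]))
    return float(pd.concat(list(log_rs_by_population.values())).mean())


def predicted_productivity(fit: FitResult, frame: pd.DataFrame | None = None):
    """Per-year predictions and the goodness of fit on the log scale.

    Returns ``(predictions, r_squared)`` where predictions are the fitted
    ``a + b S + c X`` values and ``R^2 = 1 - SS_res / SS_tot`` on the
    observed log-productivity.  For an intercept-only model this is 0 by
    construction; a zero-variance response makes it undefined.
    """
    resid = fit.residuals.to_numpy(float)
    obs = fit.fitted.to_numpy(float) + resid
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise EffectError("response has zero variance; R^2 undefined")
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 - ss_res / ss_tot
    return fit.fitted.copy(), r2


def residuals_vs_series(fit: FitResult, external: CovariateSeries):
    """Pair model residuals with an external annual series and fit a trend.

    The trend slope of residuals against a candidate driver (e.g. total pink
    hatchery returns) is the screening diagnostic for whether a driver left a
    signal the fitted model did not absorb.  Returns ``(pairs, slope,
    slope_se)`` where ``pairs`` has columns ``residual`` and the series name,
    indexed by (population, brood_year).

    Raises
    ------
    EffectError
        If fewer than 3 years overlap between residuals and the series.
    """
    resid = fit.residuals
    years = resid.index.get_level_values("brood_year")
    ext = external.data.reindex(years)
    mask = ext.notna().to_numpy()
    if mask.sum() < 3:
        raise EffectError(
            f"only {int(mask.sum())} overlapping years with {external.name}; need >= 3"
        )
    pairs = pd.DataFrame(
        {"residual": resid.to_numpy()[mask], external.name: ext.to_numpy()[mask]},
        index=resid.index[mask],
    )
    reg = stats.linregress(pairs[external.name], pairs["residual"])
    return pairs, float(reg.slope), float(reg.stderr)
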