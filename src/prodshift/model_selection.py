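"""AICc model comparison across the hypothesis suite.

Candidate models for a species are compared with the small-sample Akaike
information criterion,

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1),

reported as differences from the best candidate (delta-AICc).  IC comparisons
are only valid across identical data, so every candidate in a table must be
fitted on the same observations; the suite runner enforces this by refitting
all candidates on the intersection of years for which every candidate's
covariate exists.

Support flags follow the "within one log-likelihood unit of the best model"
convention by default (``rule="delta_loglik"``, threshold 1); the common
delta-AICc <= 2 rule is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import covariate_builder as cb
from . import ricker_engine as re_
from .errors import (
    CorrectionUndefinedError,
    IncomparableModelsError,
    SuiteError,
)
from .timeseries_io import BroodTable, align_frame, compute_productivity

logger = logging.getLogger(__name__)

HYPOTHESIS_FAMILIES = (
    "null",
    "density",
    "evos",
    "environment",
    "juvenile_competition",
    "predation_adult_competition",
)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample AIC: ``-2 logL + 2k + 2k(k+1)/(n - k - 1)``."""
    if n <= k + 1:
        raise CorrectionUndefinedError(
            f"AICc correction undefined for n={n}, k={k} (needs n > k + 1)"
        )
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aic(loglik: float, k: int) -> float:
    """Plain AIC, provided for comparison with the corrected criterion."""
    return -2.0 * loglik + 2.0 * k


@dataclass
class SelectionRow:
    label: str
    hypothesis_family: str
    loglik: float
    k_params: int
    n_obs: int
    aicc: float
    delta_aicc: float = np.nan
    supported: bool = False
    is_best: bool = False
    tied_best: bool = False


@dataclass
class SelectionTable:
    """Delta-AICc comparison of a candidate suite fitted on identical data."""

    species: str
    rows: list[SelectionRow]
    n_obs: int
    support_rule: str = "delta_loglik"
    support_threshold: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "family": r.hypothesis_family,
                    "loglik": r.loglik,
                    "k": r.k_params,
                    "n": r.n_obs,
                    "aicc": r.aicc,
                    "delta_aicc": r.delta_aicc,
                    "supported": r.supported,
                }
                for r in self.rows
            ]
        )

    @property
    def best(self) -> SelectionRow:
        return next(r for r in self.rows if r.is_best)


def build_selection_table(
    fits: Sequence[re_.FitResult],
    species: str = "species",
    families: Mapping[str, str] | None = None,
    support_rule: str = "delta_loglik",
    support_threshold: float = 1.0,
    criterion: str = "aicc",
) -> SelectionTable:
    """Rank fitted candidates by (delta-)AICc and flag well-supported ones.

    All fits must share ``n_obs``; degenerate (sigma ~ 0) fits are excluded
    with a warning rather than reported with an unbounded likelihood.  Ties
    for the minimum are broken by fewer parameters, then label order, and the
    runner-up rows are flagged ``tied_best``.
    """
    if support_rule not in ("delta_loglik", "delta_aicc"):
        raise ValueError(f"unknown support rule {support_rule!r}")
    usable = []
    for fit in fits:
        if fit.degenerate:
            logger.warning("excluding degenerate fit %r from selection table", fit.label)
            continue
        usable.append(fit)
    if not usable:
        raise IncomparableModelsError("no non-degenerate fits to compare")
    n_set = {f.n_obs for f in usable}
    if len(n_set) > 1:
        raise IncomparableModelsError(
            f"fits use different data (n_obs = {sorted(n_set)}); "
            "AICc comparisons require identical observations"
        )
    n = n_set.pop()

    rows = []
    for fit in usable:
        fam = (families or {}).get(fit.label, _infer_family(fit))
        ic = aicc(fit.loglik, fit.k_params, n) if criterion == "aicc" else aic(fit.loglik, fit.k_params)
        rows.append(
            SelectionRow(
                label=fit.label, hypothesis_family=fam,
                loglik=fit.loglik, k_params=fit.k_params, n_obs=n, aicc=ic,
            )
        )

    best_ic = min(r.aicc for r in rows)
    # tie break: smallest k, then label, among rows at the minimum
    at_min = sorted(
        (r for r in rows if r.aicc - best_ic <= 1e-9),
        key=lambda r: (r.k_params, r.label),
    )
    winner = at_min[0]
    winner.is_best = True
    for r in at_min[1:]:
        r.tied_best = True
    for r in rows:
        r.delta_aicc = r.aicc - winner.aicc
    winner.delta_aicc = 0.0

    if support_rule == "delta_loglik":
        best_ll = winner.loglik
        for r in rows:
            r.supported = (best_ll - r.loglik) <= support_threshold
    else:
        for r in rows:
            r.supported = r.delta_aicc <= support_threshold

    order = {f: i for i, f in enumerate(HYPOTHESIS_FAMILIES)}
    rows.sort(key=lambda r: (order.get(r.hypothesis_family, len(order)), r.label))
    return SelectionTable(
        species=species, rows=rows, n_obs=n,
        support_rule=support_rule, support_threshold=support_threshold,
    )


def _infer_family(fit: re_.FitResult) -> str:
    label = fit.label.lower()
    if "evos" in label:
        return "evos"
    for key in ("sst", "upwell", "discharge"):
        if key in label:
            return "environment"
    if "release" in label:
        return "juvenile_competition"
    for key in ("wild", "hatchery", "run", "whale", "return"):
        if key in label:
            return "predation_adult_competition"
    if fit.b is not None:
        return "density"
    return "null"


@dataclass
class Candidate:
    """One hypothesis-suite entry: model structure plus optional covariate."""

    label: str
    family: str
    density_dependence: str = "shared"
    covariate: str | None = None


def run_hypothesis_suite(
    candidates: Sequence[Candidate],
    brood: BroodTable,
    covariates: Mapping[str, cb.CovariateSeries],
    species: str = "species",
    populations: Sequence[str] | None = None,
    standardize_covariates: bool = True,
    sigma_structure: str = "shared",
    support_rule: str = "delta_loglik",
    support_threshold: float = 1.0,
) -> SelectionTable:
    """Fit every candidate on identical years and build the selection table.

    Each candidate names a density-dependence structure and at most one
    covariate (looked up in ``covariates``).  All candidates are refitted on
    the intersection of brood years for which the response, spawners, and
    every referenced covariate exist, so the resulting AICc values compare
    the same data.  Covariates are z-scored over exactly those years by
    default (AICc ranking is invariant to affine covariate rescaling).
    """
    pops = list(populations) if populations else brood.populations
    for cand in candidates:
        if cand.covariate is not None and cand.covariate not in covariates:
            raise SuiteError(
                f"candidate {cand.label!r} needs covariate {cand.covariate!r}, "
                "which is not in the supplied bundle"
            )

    prod = {s.population_id: s for s in compute_productivity(brood)}
    needed = sorted({c.covariate for c in candidates if c.covariate})
    common_years: dict[str, set] = {}
    for p in pops:
        yrs = set(prod[p].years)
        for name in needed:
            yrs &= set(covariates[name].years)
        if not yrs:
            raise SuiteError(f"population {p!r}: no years shared by all covariates")
        common_years[p] = yrs

    base_frames: dict[str, pd.DataFrame] = {}
    for p in pops:
        covs = [covariates[name] for name in needed]
        frame = align_frame(prod[p], covs, spawners_from=brood)
        frame = frame.loc[sorted(common_years[p])]
        if standardize_covariates:
            for name in needed:
                zc = cb.standardize(covariates[name], over_years=frame.index)
                frame[name] = zc.data.loc[frame.index]
        base_frames[p] = frame

    fits = []
    families = {}
    for cand in candidates:
        spec = re_.ModelSpec(
            populations=pops,
            density_dependence=cand.density_dependence,
            covariate=cand.covariate,
            label=cand.label,
            sigma_structure=sigma_structure,
        )
        fits.append(re_.fit_multipopulation(base_frames, spec))
        families[cand.label] = cand.family
    return build_selection_table(
        fits, species=species, families=families,
        support_rule=support_rule, support_threshold=support_threshold,
    )


# --- candidate rosters mirroring the published per-species comparison -------

_EVOS_SHAPES = ("pulse", "press", "pulse_recovery")


def table1_candidates(species: str) -> list[Candidate]:
    """The candidate roster each species was evaluated with.

    Encodes which perturbation lags, climate windows, and interaction proxies
    were considered per species — e.g. lag-1 spill impacts exist for pink
    salmon and herring (ocean entry in the year after spawning) but not for
    Chinook or sockeye (ocean entry two years after spawning), and the
    humpback-whale covariate applies to herring only.  Covariate names here
    are the keys a covariate bundle must provide.
    """
    species = species.lower()
    dd = "per_population" if species == "sockeye" else "shared"
    cands = [
        Candidate("null", "null", density_dependence="none"),
        Candidate("ricker_b", "density", density_dependence="shared"),
    ]
    if species == "sockeye":
        cands.append(Candidate("ricker_b_by_pop", "density", density_dependence="per_population"))

    evos_lags = {
        "pink": (0, 1, 2),
        "herring": (0, 1, 2),
        "chinook": (0, 2),
        "sockeye": (0, 2),
    }[species]
    for lag in evos_lags:
        for shape in _EVOS_SHAPES:
            cands.append(
                Candidate(
                    f"evos_{shape}_lag{lag}", "evos",
                    density_dependence=dd, covariate=f"evos_{shape}_lag{lag}",
                )
            )

    env = {
        "pink": ["sst_lag0", "sst_lag1", "upwelling_winter_lag1", "upwelling_winter_lag2",
                 "upwelling_spring_lag1", "upwelling_spring_lag2",
                 "discharge_lag0", "discharge_lag1"],
        "chinook": ["sst_lag0", "sst_lag1", "upwelling_winter_lag1", "upwelling_winter_lag2",
                    "upwelling_summer_lag1", "upwelling_summer_lag2",
                    "discharge_lag0", "discharge_lag1"],
        "sockeye": ["sst_lag2", "upwelling_winter_lag1", "upwelling_winter_lag2",
                    "discharge_lag0", "discharge_lag1"],
        "herring": ["sst_lag0", "sst_lag1", "upwelling_summer_lag1", "upwelling_summer_lag2",
                    "discharge_lag0", "discharge_lag1"],
    }[species]
    for name in env:
        cands.append(Candidate(name, "environment", density_dependence=dd, covariate=name))

    for name in ("hatchery_pink_releases", "hatchery_chum_releases"):
        cands.append(Candidate(name, "juvenile_competition", density_dependence=dd, covariate=name))

    pred = ["wild_chum_run", "wild_pink_run", "hatchery_chum_run", "hatchery_pink_run",
            "total_pink_run"]
    if species == "herring":
        pred.append("humpback_whales")
    for name in pred:
        cands.append(Candidate(name, "predation_adult_competition", density_dependence=dd, covariate=name))
    return cands
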