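"""Construction of driver covariates on the brood-year axis.

Three covariate families are supported:

* **Oil-spill perturbations** — pulse (one-year impact), press (permanent
  step), and pulse-recovery (one-year impact decaying linearly to zero over a
  fixed recovery span), each optionally lagged so the perturbation acts on the
  brood year whose juveniles were exposed.  A lag of ``k`` moves the affected
  brood year *back* ``k`` years: fish spawned in 1987 that entered the ocean
  as two-year-olds in 1989 carry a lag-2 spill covariate at brood year 1987.
* **Seasonal climate indices** — the mean of a monthly series (SST, upwelling)
  over a month window that may cross the calendar boundary (Nov–Mar, Oct–Mar);
  cross-year windows are labelled by the year in which they *end*, and the
  whole index can be shifted so the covariate is indexed by brood year.
* **Lagged annual proxies** — hatchery releases, adult returns, whale
  abundance: the value for brood year ``b`` is the source value at calendar
  year ``b + lag`` (events ``lag`` years after spawning act on that cohort).

All covariates can be z-scored over exactly the years entering a fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CovariateError, DegenerateCovariateError, GapError

EVOS_YEAR = 1989
PERTURBATION_SHAPES = ("pulse", "press", "pulse_recovery")


@dataclass
class CovariateSeries:
    """A named, year-indexed driver series with lag/standardisation metadata."""

    name: str
    data: pd.Series  # index: brood_year (int)
    lag_years: int = 0
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise CovariateError(f"{self.name}: more than one value per year")
        self.data = self.data.sort_index().astype(float)
        self.data.index = self.data.index.astype(int)
        self.data.name = self.name

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()


@dataclass
class MonthlySeries:
    """A (year, month)-indexed series, e.g. monthly SST or an upwelling index."""

    name: str
    data: pd.Series  # MultiIndex (year, month)

    def __post_init__(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.MultiIndex) or idx.nlevels != 2:
            raise CovariateError("monthly series needs a (year, month) MultiIndex")
        months = idx.get_level_values(1)
        if ((months < 1) | (months > 12)).any():
            raise CovariateError("months must lie in 1..12")
        if idx.has_duplicates:
            raise CovariateError("more than one value per (year, month)")
        self.data = self.data.sort_index().astype(float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "monthly") -> "MonthlySeries":
        """Build from a frame with columns ``year, month, value``."""
        s = df.set_index(["year", "month"])["value"]
        return cls(name=name, data=s)


def build_evos_covariate(
    shape: str,
    lag: int,
    years: range | np.ndarray,
    event_year: int = EVOS_YEAR,
    recovery_span: int = 20,
) -> CovariateSeries:
    """Build a pulse / press / pulse-recovery perturbation covariate.

    Parameters
    ----------
    shape
        ``"pulse"`` — 1 in the affected brood year only. ``"press"`` — 0
        before, 1 from the affected brood year onward. ``"pulse_recovery"`` —
        1 in the affected brood year, declining linearly to 0 over
        ``recovery_span`` years.
    lag
        Years the affected brood year precedes the event (0, 1 or 2 in
        practice): the affected brood year is ``event_year - lag``.
    years
        Brood years the covariate should cover; must include the affected year.
    """
    if shape not in PERTURBATION_SHAPES:
        raise CovariateError(
            f"unknown perturbation shape {shape!r}; expected one of {PERTURBATION_SHAPES}"
        )
    yrs = np.asarray(sorted(int(y) for y in years))
    onset = event_year - lag
    if onset not in yrs:
        raise CovariateError(
            f"affected brood year {onset} (event {event_year}, lag {lag}) "
            f"outside covered years {yrs[0]}-{yrs[-1]}"
        )
    if shape == "pulse":
        vals = (yrs == onset).astype(float)
    elif shape == "press":
        vals = (yrs >= onset).astype(float)
    else:
        k = yrs - onset
        vals = np.where((k >= 0) & (k <= recovery_span), 1.0 - k / recovery_span, 0.0)
    name = f"evos_{shape}_lag{lag}"
    return CovariateSeries(name=name, data=pd.Series(vals, index=yrs), lag_years=lag)


def build_seasonal_index(
    monthly: MonthlySeries,
    window: tuple[int, int],
    lag: int = 0,
    name: str | None = None,
) -> CovariateSeries:
    """Average a monthly series over a month window, per year, then lag it.

    ``window = (start_month, end_month)`` is inclusive and may cross the
    calendar boundary (e.g. ``(11, 3)`` for Nov–Mar); a cross-year window is
    assigned to the year in which it **ends**.  The index is then shifted so
    that the covariate value at brood year ``b`` is the window mean of
    assignment year ``b + lag`` (a positive lag looks forward from spawning,
    matching e.g. "Jan–Apr SST with a 2-year lag" for a cohort entering the
    ocean two years after its brood year; a negative lag looks back).

    Raises
    ------
    GapError
        If any month inside a requested window is missing, naming the first
        missing (year, month).
    """
    start, end = window
    if not (1 <= start <= 12 and 1 <= end <= 12):
        raise CovariateError(f"window months must be in 1..12, got {window}")
    crosses = start > end
    months = (
        list(range(start, 13)) + list(range(1, end + 1))
        if crosses
        else list(range(start, end + 1))
    )
    by_year = monthly.data
    years = sorted(by_year.index.get_level_values(0).unique())

    values: dict[int, float] = {}
    for assign_year in years:
        window_vals = []
        complete = True
        for m in months:
            src_year = assign_year - 1 if (crosses and m >= start) else assign_year
            try:
                window_vals.append(by_year.loc[(src_year, m)])
            except KeyError:
                if src_year < years[0] or src_year > years[-1]:
                    complete = False  # window runs off the series edge: skip year
                    break
                raise GapError(
                    f"{monthly.name}: missing month ({src_year}, {m}) "
                    f"inside window {start}-{end}"
                )
        if complete:
            values[assign_year] = float(np.mean(window_vals))

    if not values:
        raise CovariateError(f"{monthly.name}: no complete {start}-{end} window")
    idx = pd.Series(values).sort_index()
    # shift so covariate year = brood year: value at b comes from year b + lag
    idx.index = idx.index - lag
    label = name or f"{monthly.name}_m{start:02d}{end:02d}_lag{lag}"
    return CovariateSeries(name=label, data=idx, lag_years=lag)


def build_lagged_annual(annual: CovariateSeries, lag: int, name: str | None = None) -> CovariateSeries:
    """Re-index an annual series so brood year ``b`` carries the value of
    calendar year ``b + lag``.

    A hatchery-release series lagged by 1 places the releases of calendar 1981
    at brood year 1980: those juveniles compete with the 1980 cohort in its
    first year.  ``lag = 0`` is the identity.
    """
    if lag < 0:
        raise CovariateError("lag must be >= 0 for annual proxies")
    if annual.data.empty:
        raise CovariateError(f"{annual.name}: empty source series")
    shifted = annual.data.copy()
    shifted.index = shifted.index - lag
    label = name or f"{annual.name}_lag{lag}"
    return CovariateSeries(name=label, data=shifted, lag_years=annual.lag_years + lag)


def standardize(cov: CovariateSeries, over_years=None) -> CovariateSeries:
    """Z-score a covariate over exactly the years entering a fit.

    Uses the sample standard deviation (denominator ``n - 1``).  Raises
    :class:`DegenerateCovariateError` if the covariate is constant over the
    selected years.
    """
    data = cov.data if over_years is None else cov.data.loc[sorted(over_years)]
    if data.nunique() < 2:
        raise DegenerateCovariateError(
            f"{cov.name}: zero variance over the {len(data)} selected years"
        )
    sd = data.std(ddof=1)
    z = (data - data.mean()) / sd
    return CovariateSeries(
        name=cov.name, data=z, lag_years=cov.lag_years, standardized=True
    )


def read_annual_covariate(path, name: str | None = None) -> CovariateSeries:
    """Read an annual covariate CSV with columns ``year,value``."""
    df = pd.read_csv(path)
    for col in ("year", "value"):
        if col not in df.columns:
            raise CovariateError(f"annual covariate file missing column {col!r}")
    s = pd.Series(df["value"].to_numpy(float), index=df["year"].astype(int).to_numpy())
    return CovariateSeries(name=name or "annual", data=s)


def read_monthly_covariate(path, name: str | None = None) -> MonthlySeries:
    """Read a monthly covariate CSV with columns ``year,month,value``."""
    df = pd.read_csv(path)
    for col in ("year", "month", "value"):
        if col not in df.columns:
            raise CovariateError(f"monthly covariate file missing column {col!r}")
    return MonthlySeries.from_frame(df, name=name or "monthly")
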