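"""Brood tables, log-productivity, and brood-year alignment.

A *brood table* records, per population and brood year, the spawning stock
(counts of fish, or metric tons of spawning biomass for herring) and the
recruits credited to that brood year (total adult returns summed over return
ages, or millions of age-3 fish for herring).  Productivity is recruits per
spawner, modelled on the natural-log scale: ``log_rs = ln(R/S)``.

Units are metadata only — each population is analysed on its native scale and
no conversion is attempted.  Brood years are plain integers; they need not be
contiguous, but must be unique within a population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptySeriesError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

BROOD_COLUMNS = ("population", "brood_year", "spawners", "recruits")


@dataclass
class BroodTable:
    """Per-population brood-year records of spawners and recruits.

    Parameters
    ----------
    data
        Frame with columns ``population``, ``brood_year``, ``spawners``,
        ``recruits`` and a boolean ``usable`` flag.  Rows with missing
        spawners or recruits are retained but flagged unusable.
    units
        Optional mapping ``population -> (spawner units, recruit units)``,
        carried through untouched.
    """

    data: pd.DataFrame
    units: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = _validate_brood_frame(self.data)

    @property
    def populations(self) -> list[str]:
        return list(self.data["population"].unique())

    @property
    def n_usable(self) -> int:
        return int(self.data["usable"].sum())

    def for_population(self, population: str) -> "BroodTable":
        sub = self.data[self.data["population"] == population]
        if sub.empty:
            raise KeyError(f"no records for population {population!r}")
        return BroodTable(sub.reset_index(drop=True), units=self.units)

    def to_csv(self, path: str | Path) -> None:
        """Write the retained fields back out (lossless for valid rows)."""
        self.data.loc[:, list(BROOD_COLUMNS)].to_csv(path, index=False)


def _validate_brood_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in BROOD_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"brood table is missing required column {col!r}")
    df = df.copy()
    df["brood_year"] = df["brood_year"].astype(int)
    for col in ("spawners", "recruits"):
        df[col] = pd.to_numeric(df[col], errors="raise")

    dup = df.duplicated(subset=["population", "brood_year"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["population", "brood_year"]].drop_duplicates()
        desc = ", ".join(f"{p}/{y}" for p, y in pairs.itertuples(index=False))
        raise ValidationError(f"duplicate (population, brood_year) records: {desc}")

    usable = df["spawners"].notna() & df["recruits"].notna()
    # spawners must be strictly positive on usable rows; recruits may be zero
    # (such rows survive validation but drop out of the log-productivity step)
    bad_spawn = usable & (df["spawners"] <= 0)
    if bad_spawn.any():
        years = df.loc[bad_spawn, "brood_year"].tolist()
        raise ValidationError(f"non-positive spawners in brood years {years}")
    bad_rec = usable & (df["recruits"] < 0)
    if bad_rec.any():
        years = df.loc[bad_rec, "brood_year"].tolist()
        raise ValidationError(f"negative recruits in brood years {years}")

    df["usable"] = usable
    df = df.sort_values(["population", "brood_year"]).reset_index(drop=True)
    return df


def read_brood_table(path: str | Path) -> BroodTable:
    """Read and validate a brood-table CSV.

    The file must have a header row with columns
    ``population,brood_year,spawners,recruits``.  Rows with blank spawners or
    recruits are retained but flagged unusable.

    Raises
    ------
    SchemaError
        If a required column is absent or a numeric field does not parse.
    ValidationError
        If a (population, brood_year) pair is duplicated, or spawners are
        non-positive / recruits negative on an otherwise complete row.
    """
    try:
        df = pd.read_csv(path)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    try:
        table = BroodTable(df)
    except (SchemaError, ValidationError):
        raise
    except ValueError as exc:
        raise SchemaError(f"unparseable numeric field in {path}: {exc}") from exc
    n_flagged = len(table.data) - table.n_usable
    if n_flagged:
        logger.info("read %s: %d rows flagged unusable (missing fields)", path, n_flagged)
    return table


@dataclass
class ProductivitySeries:
    """Log recruits-per-spawner by brood year for one population."""

    population_id: str
    data: pd.Series  # index: brood_year (int), values: log_rs

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValidationError("log-productivity contains non-finite values")
        self.data = self.data.sort_index()
        self.data.index = self.data.index.astype(int)
        self.data.name = "log_rs"

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()


def compute_productivity(table: BroodTable) -> list[ProductivitySeries]:
    """Compute ``log_rs = ln(recruits / spawners)`` per population.

    Records that are unusable (missing fields) or have ``recruits == 0`` are
    excluded; each exclusion is logged with its reason.  Returns one series
    per population, in the table's population order.

    Raises
    ------
    EmptySeriesError
        If no record in the table yields a finite log-productivity.
    """
    out: list[ProductivitySeries] = []
    for pop in table.populations:
        sub = table.data[table.data["population"] == pop]
        keep = sub["usable"] & (sub["recruits"] > 0)
        dropped = sub.loc[~keep]
        for _, row in dropped.iterrows():
            reason = "missing spawners/recruits" if not row["usable"] else "recruits = 0"
            logger.info(
                "excluding %s brood year %d from productivity: %s",
                pop, int(row["brood_year"]), reason,
            )
        kept = sub.loc[keep]
        if kept.empty:
            continue
        log_rs = np.log(kept["recruits"].to_numpy() / kept["spawners"].to_numpy())
        series = pd.Series(log_rs, index=kept["brood_year"].to_numpy())
        out.append(ProductivitySeries(population_id=pop, data=series))
    if not out:
        raise EmptySeriesError("no usable records: every row was excluded")
    return out


def productivity_for(table: BroodTable, population: str) -> ProductivitySeries:
    """Convenience: the productivity series of a single population."""
    for series in compute_productivity(table):
        if series.population_id == population:
            return series
    raise EmptySeriesError(f"no usable records for population {population!r}")


def align_frame(
    series: ProductivitySeries,
    covariates: Sequence,
    spawners_from: BroodTable | None = None,
) -> pd.DataFrame:
    """Inner-join response, spawners, and covariates on brood year.

    Produces the frame the likelihood consumes: index ``brood_year``, columns
    ``log_rs``, ``spawners`` (if a brood table is supplied), and one column
    per covariate (named by the covariate's ``name``).  Years missing any
    required covariate are dropped; the number of drops is logged.

    Raises
    ------
    AlignmentError
        If the intersection of the input year sets is empty.  The error
        message lists each input's year range.
    """
    frame = series.data.to_frame()
    ranges = [f"response {series.population_id}: {_span(series.years)}"]

    if spawners_from is not None:
        sub = spawners_from.data[
            (spawners_from.data["population"] == series.population_id)
            & spawners_from.data["usable"]
        ]
        spawn = pd.Series(
            sub["spawners"].to_numpy(), index=sub["brood_year"].to_numpy(), name="spawners"
        )
        ranges.append(f"spawners: {_span(spawn.index.to_numpy())}")
        frame = frame.join(spawn, how="inner")

    for cov in covariates:
        col = cov.data.rename(cov.name)
        ranges.append(f"{cov.name}: {_span(col.index.to_numpy())}")
        frame = frame.join(col, how="inner")

    frame = frame.dropna()
    if frame.empty:
        raise AlignmentError(
            "no brood years shared by all inputs; year ranges: " + "; ".join(ranges)
        )
    n_dropped = len(series.data) - len(frame)
    if n_dropped:
        logger.info(
            "align_frame %s: dropped %d of %d response years lacking a covariate",
            series.population_id, n_dropped, len(series.data),
        )
    frame.index.name = "brood_year"
    return frame


def _span(years: Iterable[int]) -> str:
    ys = sorted(int(y) for y in years)
    if not ys:
        return "(empty)"
    return f"{ys[0]}-{ys[-1]}"
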