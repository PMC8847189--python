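"""Cohort container, CSV readers/writers, and cohort-level filtering rules.

A cohort is a panel plus a table of donors. The table schema is

    sample_id, population, sex, age_years, <gene>_CpG<k>, ...

with methylation in percent (0-100, decimal point, UTF-8). Two filtering
operations mirror the analysis protocol: restriction to a closed age interval
(donors between 10 and 65 years in the original protocol, boundaries
included), and exclusion of panel sites whose absolute Spearman correlation
with age falls below a threshold (|R| < 0.75 removes the two weakest sites of
the default panel). The |R| rule is deliberately applied to the absolute
value: strongly negative correlations (EDARADD) are age-informative and are
retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import CohortValidationError, FormatError
from .panel import CpGPanel
from .stats import spearman_r

__all__ = [
    "Cohort",
    "ExcludedSite",
    "read_cohort",
    "write_cohort",
    "filter_age_range",
    "select_cpgs_by_correlation",
    "REQUIRED_COLUMNS",
    "SEX_LEVELS",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "population", "sex", "age_years")
SEX_LEVELS = ("female", "male")


@dataclass
class Cohort:
    """A panel plus one row per donor (population, sex, age, methylation)."""

    panel: CpGPanel
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        missing += [c for c in self.panel.columns if c not in self.data.columns]
        if missing:
            raise FormatError(f"cohort table lacks required column(s): {missing}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    @property
    def meth(self) -> np.ndarray:
        """(n, n_sites) methylation matrix aligned to panel order."""
        return self.data[self.panel.columns].to_numpy(dtype=float)

    @property
    def ages(self) -> np.ndarray:
        return self.data["age_years"].to_numpy(dtype=float)

    def population_cohort(self, label: str) -> "Cohort":
        mask = self.data["population"] == label
        return Cohort(self.panel, self.data.loc[mask].reset_index(drop=True))

    def with_panel(self, panel: CpGPanel) -> "Cohort":
        """View of the cohort restricted to the sites of ``panel``."""
        keep = list(REQUIRED_COLUMNS) + panel.columns
        return Cohort(panel, self.data[keep].copy())


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort as CSV with full float precision (lossless round trip)."""
    cols = list(REQUIRED_COLUMNS) + cohort.panel.columns
    cohort.data[cols].to_csv(path, index=False)


def read_cohort(path, panel: CpGPanel) -> Cohort:
    """Read a cohort CSV, validating the schema against ``panel``.

    Unknown columns are ignored with a logged warning. Methylation must lie in
    [0, 100] (missing values allowed); ages must be finite and non-negative.
    """
    df = pd.read_csv(path)
    expected = list(REQUIRED_COLUMNS) + panel.columns
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        logger.warning("%s: ignoring unknown column(s): %s", path, unknown)
        df = df.drop(columns=unknown)

    bad_sex = sorted(set(df["sex"].unique()) - set(SEX_LEVELS))
    if bad_sex:
        raise CohortValidationError(f"{path}: invalid sex value(s): {bad_sex}")
    ages = df["age_years"].to_numpy(dtype=float)
    if not np.isfinite(ages).all() or (ages < 0).any():
        rows = df.index[~np.isfinite(ages) | (ages < 0)].tolist()
        raise CohortValidationError(f"{path}: invalid ages at rows {rows}")

    meth = df[panel.columns].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_range = (meth < 0.0) | (meth > 100.0)
    if out_of_range.any():
        rows = sorted(set(np.nonzero(out_of_range)[0].tolist()))
        ids = df["sample_id"].iloc[rows].tolist()
        raise CohortValidationError(
            f"{path}: methylation outside [0, 100] for sample(s) {ids}"
        )
    return Cohort(panel, df[expected].reset_index(drop=True))


def filter_age_range(cohort: Cohort, min_age: float, max_age: float) -> Cohort:
    """Retain donors with ``min_age <= age <= max_age`` (closed interval)."""
    if min_age > max_age:
        raise ValueError("min_age must not exceed max_age")
    ages = cohort.ages
    mask = (ages >= min_age) & (ages <= max_age)
    kept = cohort.data.loc[mask].reset_index(drop=True)
    for pop, count in kept["population"].value_counts().items():
        logger.info("age filter [%g, %g]: %s retains %d donors", min_age, max_age, pop, count)
    if kept.empty:
        logger.warning("age filter [%g, %g] retained no samples", min_age, max_age)
    return Cohort(cohort.panel, kept)


@dataclass(frozen=True)
class ExcludedSite:
    column: str
    r: float  # nan when undefined
    reason: str


def select_cpgs_by_correlation(
    cohort: Cohort, threshold: float
) -> tuple[CpGPanel, list[ExcludedSite]]:
    """Exclude panel sites whose |Spearman R| with age is below ``threshold``.

    R is computed per site over the cohort passed in (pooled), with pairwise
    deletion of missing methylation values. Sites with undefined R (constant
    methylation) are excluded with a logged reason. Returns the reduced panel
    (order preserved) and the exclusion list.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    ages = cohort.ages
    excluded: list[ExcludedSite] = []
    kept: list[str] = []
    for col in cohort.panel.columns:
        y = cohort.data[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        r = spearman_r(ages[ok], y[ok]) if ok.sum() >= 3 else float("nan")
        if math.isnan(r):
            excluded.append(ExcludedSite(col, r, "undefined correlation (constant or too few values)"))
            logger.warning("excluding %s: undefined Spearman R", col)
        elif abs(r) < threshold:
            excluded.append(ExcludedSite(col, r, f"|R|={abs(r):.3f} < {threshold:g}"))
            logger.info("excluding %s: |R|=%.3f below %g", col, abs(r), threshold)
        else:
            kept.append(col)
    return cohort.panel.subset(kept), excluded
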