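"""Repeated matched-subsample ANCOVA per CpG with median-p aggregation.

The population-difference pipeline tests a fixed reference group (the
Japanese-like sample in the original protocol) against many age- and
sex-matched subsamples of a pool population (the German-like sample). For
every run and every panel CpG an age-adjusted ANCOVA compares the two groups;
per CpG the runs are aggregated into the median p-value and the percentage of
runs reaching significance.

Because the reference group is the same in every run, run-level p-values at a
given CpG are strongly dependent: the reference group's realised noise acts
as a persistent pseudo-effect shared by all runs. Aggregates therefore
scatter far more between CpGs than independent replicates would; see the
methods note for the quantitative picture.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .cohort import Cohort
from .errors import SingularDesignError
from .matching import draw_many
from .stats import ancova_group_test, ancova_many

__all__ = ["SiteDiff", "PopDiffResult", "run_popdiff", "classify_sites", "popdiff_to_tsv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteDiff:
    """Aggregate over runs for one CpG site."""

    median_p: float
    pct_runs_sig: float
    p_values: np.ndarray  # length = runs; NaN where the ANCOVA was singular
    n_missing: int


@dataclass(frozen=True)
class PopDiffResult:
    """Per-CpG median p and percent-significant over matched-subsample runs."""

    sites: tuple[str, ...]
    p_matrix: np.ndarray  # (runs, n_sites)
    runs: int
    alpha: float
    threshold: float
    seed: int
    per_cpg: Mapping[str, SiteDiff] = field(default_factory=dict)

    @property
    def median_p(self) -> np.ndarray:
        return np.array([self.per_cpg[c].median_p for c in self.sites])

    @property
    def pct_runs_sig(self) -> np.ndarray:
        return np.array([self.per_cpg[c].pct_runs_sig for c in self.sites])


def _aggregate(
    sites, p_matrix: np.ndarray, runs: int, alpha: float, threshold: float, seed: int
) -> PopDiffResult:
    per_cpg = {}
    for j, col in enumerate(sites):
        p = p_matrix[:, j]
        ok = np.isfinite(p)
        n_missing = int(runs - ok.sum())
        if n_missing:
            logger.warning("%s: %d of %d runs had a singular ANCOVA; excluded", col, n_missing, runs)
        per_cpg[col] = SiteDiff(
            median_p=float(np.median(p[ok])) if ok.any() else float("nan"),
            pct_runs_sig=float(100.0 * np.mean(p[ok] < alpha)) if ok.any() else float("nan"),
            p_values=p.copy(),
            n_missing=n_missing,
        )
    return PopDiffResult(
        sites=tuple(sites), p_matrix=p_matrix, runs=runs, alpha=alpha,
        threshold=threshold, seed=seed, per_cpg=per_cpg,
    )


def run_popdiff(
    cohort: Cohort,
    reference_pop: str,
    pool_pop: str,
    runs: int = 500,
    alpha: float = 0.05,
    match_threshold: float = 0.3,
    seed: int = 0,
    age_test: str = "welch",
) -> PopDiffResult:
    """Matched-subsample ANCOVA per CpG, aggregated over ``runs`` draws.

    The cohort should already be age-filtered. Per run, a matched subsample of
    the pool is drawn against the (fixed) reference group and each panel CpG
    is tested with the age-adjusted ANCOVA on reference plus subsample. Fully
    deterministic given ``seed``. Singular ANCOVAs are recorded as missing for
    that (run, CpG) and excluded from the aggregates with a logged count.
    """
    pops = cohort.populations
    for label in (reference_pop, pool_pop):
        if label not in pops:
            raise ValueError(f"population {label!r} not in cohort (has {pops})")
    ref = cohort.population_cohort(reference_pop)
    pool = cohort.population_cohort(pool_pop)
    if ref.n > pool.n:
        raise ValueError("reference group must not exceed the pool size")

    draws = draw_many(pool.data, ref.data, runs, threshold=match_threshold,
                      seed=seed, age_test=age_test)
    sites = cohort.panel.columns
    ref_meth = ref.meth
    pool_meth = pool.meth
    ref_ages = ref.ages
    pool_ages = pool.ages
    group = np.concatenate([np.zeros(ref.n), np.ones(ref.n)])

    p_matrix = np.full((runs, len(sites)), np.nan)
    for i, draw in enumerate(draws):
        Y = np.vstack([ref_meth, pool_meth[draw.indices]])
        age = np.concatenate([ref_ages, pool_ages[draw.indices]])
        finite_cols = np.isfinite(Y).all(axis=0)
        try:
            if finite_cols.all():
                p_matrix[i] = ancova_many(Y, age, group)
            else:
                p_matrix[i, finite_cols] = ancova_many(Y[:, finite_cols], age, group)
                for j in np.flatnonzero(~finite_cols):
                    ok = np.isfinite(Y[:, j])
                    try:
                        p_matrix[i, j] = ancova_group_test(
                            Y[ok, j], age[ok], group[ok]
                        ).p_value
                    except (SingularDesignError, ValueError):
                        pass  # left as NaN (missing for this run/CpG)
        except SingularDesignError:
            logger.warning("run %d: singular pooled design; all sites missing", i)
    return _aggregate(sites, p_matrix, runs, alpha, match_threshold, seed)


def classify_sites(
    result: PopDiffResult,
    alpha: float = 0.05,
    strong_pct: float = 75.0,
    suggestive_pct: float = 50.0,
    none_median: float = 0.3,
) -> dict[str, str]:
    """Qualitative evidence label per CpG.

    ``strong``: median p < alpha and > ``strong_pct`` % of runs significant;
    ``suggestive``: median p < alpha and > ``suggestive_pct`` %;
    ``none``: median p > ``none_median``; otherwise ``intermediate``.
    """
    labels = {}
    for col in result.sites:
        site = result.per_cpg[col]
        if site.median_p < alpha and site.pct_runs_sig > strong_pct:
            labels[col] = "strong"
        elif site.median_p < alpha and site.pct_runs_sig > suggestive_pct:
            labels[col] = "suggestive"
        elif site.median_p > none_median:
            labels[col] = "none"
        else:
            labels[col] = "intermediate"
    return labels


def popdiff_to_tsv(
    result: PopDiffResult,
    path,
    classifications: Optional[Mapping[str, str]] = None,
    p_matrix_path=None,
) -> None:
    """Write per-CpG aggregates (and optionally the full run-by-CpG p matrix)."""
    if classifications is None:
        classifications = classify_sites(result)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["marker", "cpg", "median_p", "pct_runs_sig", "n_missing", "classification"])
        for col in result.sites:
            gene, cpg = col.rsplit("_CpG", 1)
            site = result.per_cpg[col]
            writer.writerow(
                [gene, cpg, f"{site.median_p:.6g}", f"{site.pct_runs_sig:.4g}",
                 site.n_missing, classifications[col]]
            )
    if p_matrix_path is not None:
        header = "\t".join(["run"] + list(result.sites))
        rows = np.column_stack([np.arange(result.runs), result.p_matrix])
        np.savetxt(p_matrix_path, rows, delimiter="\t", header=header, comments="",
                   fmt=["%d"] + ["%.8g"] * len(result.sites))
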