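"""Age- and sex-matched subsampling from a donor pool against a reference group.

A matched draw is a subset of the pool with the reference group's size whose
age and sex composition is statistically indistinguishable from the reference:
every configured balance test must exceed the acceptance threshold (p > 0.3 in
the original protocol). The default strategy matches sex counts exactly
(stratified sampling within sex) and rejection-samples ages; whole candidate
subsets are resampled, never optimised pair-by-pair, so accepted draws remain
exchangeable subsamples of the pool.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MatchingFailureError

__all__ = [
    "MatchedDraw",
    "age_balance_p",
    "sex_balance_p",
    "balance_tests",
    "draw_matched",
    "draw_many",
    "draws_to_tsv",
]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


def age_balance_p(ages_a, ages_b, method: str = "welch") -> float:
    """Two-sample balance p-value for age.

    ``welch`` (default) is the unequal-variance two-sample t test; ``ks`` the
    two-sample Kolmogorov-Smirnov test. Two identical constant groups give
    p = 1 (perfect balance) rather than an undefined statistic.
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "welch":
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            return 1.0 if a[0] == b[0] else np.finfo(float).tiny
        p = sps.ttest_ind(a, b, equal_var=False).pvalue
    elif method == "ks":
        p = sps.ks_2samp(a, b).pvalue
    else:
        raise ValueError(f"unknown age balance test: {method!r}")
    return float(p)


def sex_balance_p(sex_a, sex_b) -> float:
    """Balance p-value for the 2x2 sex table.

    Chi-square with continuity correction; Fisher's exact test when any
    expected count falls below 5. Identical compositions (including the
    degenerate single-sex case) give p = 1.
    """
    a = pd.Series(sex_a)
    b = pd.Series(sex_b)
    levels = sorted(set(a.unique()) | set(b.unique()))
    ca = np.array([(a == lv).sum() for lv in levels])
    cb = np.array([(b == lv).sum() for lv in levels])
    if np.array_equal(ca, cb):
        return 1.0
    keep = (ca + cb) > 0
    table = np.vstack([ca[keep], cb[keep]])
    if table.shape[1] < 2:
        return 1.0
    expected = sps.contingency.expected_freq(table)
    if expected.min() < 5:
        return float(sps.fisher_exact(table).pvalue)
    return float(sps.chi2_contingency(table, correction=True).pvalue)


def balance_tests(candidate: pd.DataFrame, reference: pd.DataFrame, age_test: str = "welch") -> tuple[float, float]:
    """(p_age, p_sex) between a candidate subsample and the reference group."""
    if candidate.empty or reference.empty:
        raise ValueError("both groups must be non-empty")
    p_age = age_balance_p(candidate["age_years"], reference["age_years"], method=age_test)
    p_sex = sex_balance_p(candidate["sex"], reference["sex"])
    return p_age, p_sex


@dataclass(frozen=True)
class MatchedDraw:
    """One accepted draw: positional indices into the pool plus diagnostics."""

    indices: np.ndarray
    p_age: float
    p_sex: float
    n_attempts: int
    seed: int

    def __post_init__(self) -> None:
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("draw indices must be unique")


def draw_matched(
    pool: pd.DataFrame,
    reference: pd.DataFrame,
    threshold: float = 0.3,
    seed: int = 0,
    max_attempts: int = 10_000,
    strategy: str = "stratified",
    age_test: str = "welch",
) -> MatchedDraw:
    """Draw one subsample of the pool matched to the reference group.

    ``stratified`` (default) fixes the per-sex counts to the reference's and
    rejection-samples ages within sex; ``rejection`` resamples unrestricted
    subsets and tests both age and sex balance. Deterministic given ``seed``.
    Raises :class:`MatchingFailureError` (reporting the best attempt) if no
    draw passes within ``max_attempts``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    n_ref = len(reference)
    if len(pool) < n_ref:
        raise ValueError("pool must be at least as large as the reference group")
    if strategy not in ("stratified", "rejection"):
        raise ValueError(f"unknown strategy: {strategy!r}")
    rng = np.random.default_rng(seed)
    pool_ages = pool["age_years"].to_numpy(dtype=float)
    ref_ages = reference["age_years"].to_numpy(dtype=float)

    if strategy == "stratified":
        ref_counts = reference["sex"].value_counts()
        pool_sex = pool["sex"].to_numpy()
        sex_positions = {}
        for sex, need in ref_counts.items():
            positions = np.flatnonzero(pool_sex == sex)
            if len(positions) < need:
                raise MatchingFailureError(
                    f"pool has {len(positions)} {sex} donors but the reference needs {need}"
                )
            sex_positions[sex] = positions

    best_p_age, best_p_sex = -1.0, -1.0
    for attempt in range(1, max_attempts + 1):
        if strategy == "stratified":
            parts = [
                rng.choice(sex_positions[sex], size=int(need), replace=False)
                for sex, need in ref_counts.items()
            ]
            idx = np.concatenate(parts)
            p_sex = 1.0  # exact per-sex count match by construction
        else:
            idx = rng.choice(len(pool), size=n_ref, replace=False)
            p_sex = sex_balance_p(pool["sex"].to_numpy()[idx], reference["sex"])
        p_age = age_balance_p(pool_ages[idx], ref_ages, method=age_test)
        if min(p_age, p_sex) > threshold:
            return MatchedDraw(
                indices=np.sort(idx), p_age=p_age, p_sex=p_sex,
                n_attempts=attempt, seed=int(seed),
            )
        if min(p_age, p_sex) > min(best_p_age, best_p_sex):
            best_p_age, best_p_sex = p_age, p_sex
    raise MatchingFailureError(
        f"no draw with all balance p > {threshold} within {max_attempts} attempts "
        f"(best attempt: p_age={best_p_age:.4g}, p_sex={best_p_sex:.4g})",
        best_p_age=best_p_age,
        best_p_sex=best_p_sex,
    )


def draw_many(
    pool: pd.DataFrame,
    reference: pd.DataFrame,
    runs: int,
    threshold: float = 0.3,
    seed: int = 0,
    **kwargs,
) -> list[MatchedDraw]:
    """``runs`` independent accepted draws with per-run derived seeds.

    Draws are independent at the run level (subsamples may overlap across
    runs). A matching failure propagates with the failing run index attached.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    run_seeds = np.random.SeedSequence(seed).generate_state(runs) % _SEED_MOD
    draws = []
    for i, run_seed in enumerate(run_seeds):
        try:
            draws.append(
                draw_matched(pool, reference, threshold=threshold, seed=int(run_seed), **kwargs)
            )
        except MatchingFailureError as err:
            err.run_index = i
            raise MatchingFailureError(
                f"run {i}: {err}", best_p_age=err.best_p_age,
                best_p_sex=err.best_p_sex, run_index=i,
            ) from err
    return draws


def draws_to_tsv(draws: Sequence[MatchedDraw], pool: pd.DataFrame, path) -> None:
    """Audit trail: one row per draw with p-values and the drawn sample ids."""
    ids = pool["sample_id"].to_numpy()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["run", "n_attempts", "p_age", "p_sex", "sample_ids"])
        for i, d in enumerate(draws):
            writer.writerow(
                [i, d.n_attempts, f"{d.p_age:.6g}", f"{d.p_sex:.6g}",
                 ",".join(ids[d.indices])]
            )
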