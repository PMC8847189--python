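"""Elementary statistics of the analysis: Spearman R, linear fits, ANCOVA.

The ANCOVA here is the age-adjusted two-group comparison used throughout the
population-difference pipeline: methylation is modelled as

    y = b0 + b1 * age + b2 * group

and the group term is tested with an F statistic against the age-only model.
Sex is deliberately not a covariate — the pipeline controls sex composition by
matching, not by modelling. No age-by-group interaction is fitted by default
(slope homogeneity is assumed); an interaction mode exists for robustness
checks, as does a permutation-based p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import SingularDesignError

__all__ = ["AncovaResult", "LinFit", "spearman_r", "linfit", "ancova_group_test"]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class LinFit:
    intercept: float
    slope: float
    residual_sd: float  # n-2 denominator


@dataclass(frozen=True)
class AncovaResult:
    """Age-adjusted group comparison.

    ``group_effect`` is the adjusted difference (in percent methylation) of the
    group coded 1 relative to the group coded 0; ``f_stat`` has (1, n-3)
    degrees of freedom in the default no-interaction model.
    """

    group_effect: float
    f_stat: float
    p_value: float
    n: int
    df_num: int = 1
    df_den: int = 0


def spearman_r(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns ``nan`` (an explicit "undefined" sentinel, never silently 0) when
    either input is constant. Equals the Pearson correlation of the two rank
    vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx * sx).sum() * (sy * sy).sum())
    if denom == 0.0:  # constant input: undefined
        return float("nan")
    return float((sx * sy).sum() / denom)


def linfit(age, y) -> LinFit:
    """Ordinary least squares of ``y`` on ``age`` (simple linear regression)."""
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    if age.shape != y.shape or age.ndim != 1:
        raise ValueError("age and y must be 1-D vectors of equal length")
    n = age.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(age) == 0.0:
        raise SingularDesignError("age is constant; slope is unidentifiable")
    X = np.column_stack([np.ones(n), age])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    residual_sd = float(np.sqrt((resid * resid).sum() / (n - 2)))
    return LinFit(intercept=float(coef[0]), slope=float(coef[1]), residual_sd=residual_sd)


def _encode_group(group) -> np.ndarray:
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(
            f"group must have exactly 2 non-empty levels, got {levels.size}"
        )
    return (group == levels[1]).astype(float)


def ancova_group_test(
    y,
    age,
    group,
    *,
    interaction: bool = False,
    n_permutations: Optional[int] = None,
    seed: Optional[int] = None,
) -> AncovaResult:
    """Test for a group difference in ``y`` adjusted for ``age``.

    Fits ``y = b0 + b1*age + b2*group`` (plus ``b3*age*group`` when
    ``interaction`` is set) by least squares and compares it against the
    age-only model with an F test; ``p_value`` is the F(q, n-k) upper tail.
    With ``n_permutations`` the p-value is instead estimated by permuting the
    group labels.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    g = _encode_group(group)
    n = y.size
    if not (age.size == n == g.size):
        raise ValueError("y, age and group must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(age) == 0.0:
        raise SingularDesignError("age is constant in the pooled data")

    cols = [np.ones(n), age, g]
    if interaction:
        cols.append(age * g)
    X_full = np.column_stack(cols)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise SingularDesignError("singular design (group confounded with age?)")
    X_red = X_full[:, :2]

    def _f_stat(gvec: np.ndarray) -> tuple[float, float]:
        cols_f = [np.ones(n), age, gvec]
        if interaction:
            cols_f.append(age * gvec)
        Xf = np.column_stack(cols_f)
        coef, _, _, _ = np.linalg.lstsq(Xf, y, rcond=None)
        rss_full = float(np.sum((y - Xf @ coef) ** 2))
        coef_r, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
        rss_red = float(np.sum((y - X_red @ coef_r) ** 2))
        q = Xf.shape[1] - 2
        df_den = n - Xf.shape[1]
        if df_den < 1:
            raise ValueError("not enough observations for the full model")
        if rss_full <= 0.0:
            return float("inf"), float(coef[2])
        f = ((rss_red - rss_full) / q) / (rss_full / df_den)
        return max(f, 0.0), float(coef[2])

    f_obs, b2 = _f_stat(g)
    q = X_full.shape[1] - 2
    df_den = n - X_full.shape[1]

    if n_permutations is None:
        p = float(sps.f.sf(f_obs, q, df_den)) if np.isfinite(f_obs) else 0.0
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(int(n_permutations)):
            f_perm, _ = _f_stat(rng.permutation(g))
            if f_perm >= f_obs:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_permutations)
    p = max(p, _TINY)  # p lies in (0, 1]
    return AncovaResult(
        group_effect=b2, f_stat=f_obs, p_value=p, n=n, df_num=q, df_den=df_den
    )


def ancova_many(Y: np.ndarray, age: np.ndarray, g01: np.ndarray) -> np.ndarray:
    """Vectorised no-interaction ANCOVA p-values across response columns.

    ``Y`` is (n, m); ``g01`` must already be 0/1 coded. Shares the formulas of
    :func:`ancova_group_test` (full vs age-only RSS, F(1, n-3) upper tail) but
    solves all ``m`` regressions with one pseudo-inverse. Columns containing
    non-finite values must be handled by the caller.
    """
    n = age.size
    X_full = np.column_stack([np.ones(n), age, g01.astype(float)])
    if np.linalg.matrix_rank(X_full) < 3:
        raise SingularDesignError("singular pooled design")
    X_red = X_full[:, :2]
    coef_f = np.linalg.pinv(X_full) @ Y
    coef_r = np.linalg.pinv(X_red) @ Y
    rss_full = np.sum((Y - X_full @ coef_f) ** 2, axis=0)
    rss_red = np.sum((Y - X_red @ coef_r) ** 2, axis=0)
    df_den = n - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red - rss_full) / (rss_full / df_den)
    f = np.where(rss_full <= 0.0, np.inf, np.maximum(f, 0.0))
    p = sps.f.sf(f, 1, df_den)
    return np.maximum(p, _TINY)
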