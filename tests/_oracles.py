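"""Independent brute-force oracles used by the equivalence tests.

Everything here is deliberately written from first principles — explicit rank
enumeration, explicit normal equations, density quadrature for tail
probabilities — so that agreement with the package is a genuine two-route
check, not the same code called twice.
"""

import math

import numpy as np
from scipy.integrate import quad


def average_ranks(v):
    """Ranks with average ties, computed by explicit sorting and grouping."""
    v = list(map(float, v))
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # 1-based average rank of the tie group
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_oracle(x, y):
    """Rank-then-Pearson with explicit sums."""
    return pearson(average_ranks(x), average_ranks(y))


def linfit_oracle(age, y):
    """Simple-regression coefficients by explicit 2x2 normal-equation inversion."""
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    n = age.size
    s1, sx, sxx = float(n), age.sum(), (age * age).sum()
    sy, sxy = y.sum(), (age * y).sum()
    det = s1 * sxx - sx * sx
    intercept = (sxx * sy - sx * sxy) / det
    slope = (s1 * sxy - sx * sy) / det
    resid = y - intercept - slope * age
    residual_sd = math.sqrt(float(resid @ resid) / (n - 2))
    return intercept, slope, residual_sd


def _f_pdf(x, d1, d2):
    if x <= 0:
        return 0.0
    logp = (
        0.5 * d1 * math.log(d1 / d2)
        + (0.5 * d1 - 1.0) * math.log(x)
        - 0.5 * (d1 + d2) * math.log1p(d1 * x / d2)
        - (math.lgamma(0.5 * d1) + math.lgamma(0.5 * d2) - math.lgamma(0.5 * (d1 + d2)))
    )
    return math.exp(logp)


def f_tail_oracle(f_obs, d1, d2):
    """Upper tail of the F distribution by numerical integration of the density."""
    val, _ = quad(_f_pdf, f_obs, np.inf, args=(d1, d2), limit=200)
    return val


def _chi2_pdf(x, k):
    if x <= 0:
        return 0.0
    logp = (0.5 * k - 1.0) * math.log(x) - 0.5 * x - 0.5 * k * math.log(2.0) - math.lgamma(0.5 * k)
    return math.exp(logp)


def chi2_tail_oracle(stat, k):
    val, _ = quad(_chi2_pdf, stat, np.inf, args=(k,), limit=200)
    return val


def _t_pdf(x, v):
    logp = (
        math.lgamma(0.5 * (v + 1.0))
        - math.lgamma(0.5 * v)
        - 0.5 * math.log(v * math.pi)
        - 0.5 * (v + 1.0) * math.log1p(x * x / v)
    )
    return math.exp(logp)


def welch_oracle(a, b):
    """Welch two-sample t: explicit statistic, Satterthwaite df, tail by quadrature."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    va = float(np.sum((a - a.mean()) ** 2)) / (na - 1)
    vb = float(np.sum((b - b.mean()) ** 2)) / (nb - 1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    tail, _ = quad(_t_pdf, abs(t), np.inf, args=(df,), limit=200)
    return t, df, 2.0 * tail


def _ols_rss(X, y):
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ coef
    return float(resid @ resid), coef


def ancova_oracle(y, age, group01):
    """Explicit-RSS F test of the group term, tail by F-density quadrature."""
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    g = np.asarray(group01, dtype=float)
    n = y.size
    X_full = np.column_stack([np.ones(n), age, g])
    X_red = X_full[:, :2]
    rss_full, coef = _ols_rss(X_full, y)
    rss_red, _ = _ols_rss(X_red, y)
    f = (rss_red - rss_full) / (rss_full / (n - 3))
    p = f_tail_oracle(f, 1, n - 3)
    return coef[2], f, p


def quantile_edges_lower(values, n_bins):
    """'lower' order-statistic quantile edges, written independently."""
    s = sorted(map(float, values))
    n = len(s)
    edges = []
    for k in range(1, n_bins):
        h = (k / n_bins) * (n - 1)
        edges.append(s[int(math.floor(h))])
    return edges


def bin_codes(values, n_bins):
    edges = quantile_edges_lower(values, n_bins)
    return [sum(v > e for e in edges) for v in values]


def chi2_independence_oracle(xcodes, ycodes, n_bins):
    """Chi-square independence test on enumerated contingency cells."""
    table = [[0] * n_bins for _ in range(n_bins)]
    for xc, yc in zip(xcodes, ycodes):
        table[xc][yc] += 1
    n = len(xcodes)
    rows = [sum(r) for r in table]
    cols = [sum(table[i][j] for i in range(n_bins)) for j in range(n_bins)]
    stat = 0.0
    for i in range(n_bins):
        for j in range(n_bins):
            e = rows[i] * cols[j] / n
            if e > 0:
                stat += (table[i][j] - e) ** 2 / e
    df = (sum(r > 0 for r in rows) - 1) * (sum(c > 0 for c in cols) - 1)
    return stat, df, chi2_tail_oracle(stat, df) if df >= 1 else 1.0


def reference_tree_predictions(X, y, min_leaf, n_bins):
    """Training-set predictions of a reference tree built by exhaustive enumeration.

    Same selection rule as the package (argmin chi-square p over predictors,
    then the SSE-minimising threshold) but implemented with plain loops over
    every (predictor, threshold) pair.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    pred = np.empty_like(y)

    def node(rows):
        yn = y[rows]
        if rows.size < 2 * min_leaf or np.ptp(yn) == 0.0:
            pred[rows] = yn.mean()
            return
        ycodes = bin_codes(yn, n_bins)
        best_p, best_j = None, None
        for j in range(X.shape[1]):
            xcodes = bin_codes(X[rows, j], n_bins)
            _, df, p = chi2_independence_oracle(xcodes, ycodes, n_bins)
            if df < 1:
                continue
            # ties break to the lowest index; tolerance absorbs quadrature noise
            if best_p is None or p < best_p - 1e-9:
                best_p, best_j = p, j
        if best_j is None:
            pred[rows] = yn.mean()
            return
        xj = X[rows, best_j]
        best_sse, best_thr = None, None
        for thr in sorted(set((a + b) / 2.0 for a, b in zip(sorted(xj)[:-1], sorted(xj)[1:]))):
            left = xj <= thr
            if left.sum() < min_leaf or (~left).sum() < min_leaf:
                continue
            sse = float(np.sum((yn[left] - yn[left].mean()) ** 2)) + float(
                np.sum((yn[~left] - yn[~left].mean()) ** 2)
            )
            if best_sse is None or sse < best_sse - 1e-12:
                best_sse, best_thr = sse, thr
        if best_thr is None:
            pred[rows] = yn.mean()
            return
        left = xj <= best_thr
        node(rows[left])
        node(rows[~left])

    node(np.arange(y.size))
    return pred
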