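"""Random-forest age regressor with curvature-test split-predictor selection.

Each tree is grown on a with-replacement bootstrap of the training set. At
every node the split *predictor* is chosen by the curvature test: predictor
and response are discretised into up-to-``n_bins`` quantile bins over the
node's rows, a chi-square test of independence is computed for each candidate
predictor against the binned response, and the predictor with the smallest
p-value wins (ties break to the lowest column index). The split *threshold*
on the chosen predictor then minimises the weighted child variance of the
response over all admissible midpoints. Leaves predict the mean training age
reaching them; the forest prediction is the arithmetic mean over trees.

Quantile bin edges use the ``lower`` order-statistic method, so binning — and
with it predictor selection — is invariant under strictly increasing
transforms of a continuous predictor. A two-level categorical such as sex,
encoded 0/1, reduces to a single binary split and needs no special casing.

All candidate predictors are considered at every node (no per-node feature
subsampling): the curvature test itself decorrelates predictor selection from
the number of split points, which is the bias the test is designed to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import chdtrc
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigurationError

__all__ = [
    "curvature_select",
    "grow_tree",
    "Tree",
    "CurvatureForestRegressor",
    "fit_forest",
    "predict_age",
    "cohort_features",
]

_LEAF = -1


def _quantile_codes(M: np.ndarray, n_bins: int) -> np.ndarray:
    """Integer bin codes per column from up-to-``n_bins`` quantile bins.

    Edges are actual order statistics (``method='lower'``), which makes the
    codes invariant under strictly increasing per-column transforms.
    """
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(M, qs, axis=0, method="lower")
    codes = np.zeros(M.shape, dtype=np.int64)
    for k in range(edges.shape[0]):
        codes += M > edges[k]
    return codes


def curvature_select(
    X: np.ndarray,
    y: np.ndarray,
    candidate_set: Optional[Sequence[int]] = None,
    n_bins: int = 4,
) -> tuple[Optional[int], np.ndarray]:
    """Chi-square (curvature test) split-predictor selection at one node.

    Returns ``(best, p_values)`` where ``best`` is the winning column index of
    ``X`` (``None`` when every candidate is constant over the node, i.e. no
    test has at least one degree of freedom) and ``p_values`` is aligned with
    ``candidate_set``. Requires at least two distinct response values.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(y, dtype=float)
    m = y.size
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 distinct response values at the node")
    candidates = (
        np.arange(X.shape[1]) if candidate_set is None else np.asarray(candidate_set)
    )
    ybin = _quantile_codes(y[:, None], n_bins)[:, 0]
    xbin = _quantile_codes(X[:, candidates], n_bins)

    k = candidates.size
    flat = (np.arange(k) * n_bins * n_bins)[None, :] + xbin * n_bins + ybin[:, None]
    counts = np.bincount(flat.ravel(), minlength=k * n_bins * n_bins).reshape(
        k, n_bins, n_bins
    ).astype(float)
    rows = counts.sum(axis=2)
    cols = counts.sum(axis=1)
    expected = rows[:, :, None] * cols[:, None, :] / m
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = cells.sum(axis=(1, 2))
    df = ((rows > 0).sum(axis=1) - 1) * ((cols > 0).sum(axis=1) - 1)
    valid = df >= 1
    p_values = np.ones(k)
    p_values[valid] = chdtrc(df[valid].astype(float), stat[valid])
    if not valid.any():
        return None, p_values
    best_local = int(np.argmin(np.where(valid, p_values, np.inf)))
    return int(candidates[best_local]), p_values


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int) -> Optional[float]:
    """Threshold minimising child SSE, both children >= ``min_leaf`` rows."""
    m = x.size
    if m < 2 * min_leaf:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    ks = np.arange(min_leaf, m - min_leaf + 1)  # left-child sizes
    valid = xs[ks - 1] < xs[ks]
    if not valid.any():
        return None
    csum = np.cumsum(ys)
    total = csum[-1]
    left = csum[ks - 1]
    # child SSE up to a constant: minimise -(L^2/k + R^2/(m-k))
    score = -(left**2 / ks + (total - left) ** 2 / (m - ks))
    k = ks[int(np.argmin(np.where(valid, score, np.inf)))]
    return float(0.5 * (xs[k - 1] + xs[k]))


@dataclass
class Tree:
    """Flat-array regression tree: ``feature < 0`` marks a leaf."""

    feature: np.ndarray  # int32, -1 for leaves
    threshold: np.ndarray  # float64
    left: np.ndarray  # int32
    right: np.ndarray  # int32
    value: np.ndarray  # float64, leaf prediction (mean response)
    n_node: np.ndarray  # int32, training rows reaching the node

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feat = self.feature[idx]
            internal = feat >= 0
            if not internal.any():
                return self.value[idx]
            rows = np.flatnonzero(internal)
            f = feat[rows]
            go_left = X[rows, f] <= self.threshold[idx[rows]]
            idx[rows] = np.where(go_left, self.left[idx[rows]], self.right[idx[rows]])

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    @property
    def depth(self) -> int:
        depths = np.zeros(self.feature.size, dtype=int)
        for i in range(self.feature.size):
            if self.feature[i] >= 0:
                depths[self.left[i]] = depths[i] + 1
                depths[self.right[i]] = depths[i] + 1
        return int(depths.max())

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "n_node": self.n_node.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int32),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.int32),
            right=np.asarray(d["right"], dtype=np.int32),
            value=np.asarray(d["value"], dtype=float),
            n_node=np.asarray(d["n_node"], dtype=np.int32),
        )


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf: int = 5,
    n_bins: int = 4,
    rng: Optional[np.random.Generator] = None,
) -> Tree:
    """Grow one regression tree (deterministic; ``rng`` reserved for extensions).

    A node becomes a leaf when it has fewer than ``2 * min_leaf`` rows, zero
    response variance, no non-constant candidate predictor, or no admissible
    threshold on the selected predictor.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    n_node: list[int] = []

    def build(rows: np.ndarray) -> int:
        node = len(feature)
        feature.append(_LEAF)
        threshold.append(np.nan)
        left.append(_LEAF)
        right.append(_LEAF)
        yn = y[rows]
        value.append(float(yn.mean()))
        n_node.append(rows.size)
        if rows.size < 2 * min_leaf or np.ptp(yn) == 0.0:
            return node
        Xn = X[rows]
        best, _ = curvature_select(Xn, yn, n_bins=n_bins)
        if best is None:
            return node
        thr = _best_split(Xn[:, best], yn, min_leaf)
        if thr is None:
            return node
        go_left = Xn[:, best] <= thr
        feature[node] = best
        threshold[node] = thr
        left[node] = build(rows[go_left])
        right[node] = build(rows[~go_left])
        return node

    build(np.arange(y.size))
    return Tree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        value=np.asarray(value, dtype=float),
        n_node=np.asarray(n_node, dtype=np.int32),
    )


class CurvatureForestRegressor(RegressorMixin, BaseEstimator):
    """Bootstrap forest of curvature-test regression trees.

    Parameters
    ----------
    n_estimators:
        Number of bootstrap trees (10,000 in the original protocol; smaller
        values are adequate for exploratory runs).
    min_samples_leaf:
        Minimum training rows per leaf.
    n_bins:
        Maximum quantile bins used by the curvature test for both predictors
        and response.
    random_state:
        Seed for the bootstrap streams; fits are fully reproducible.
    compute_oob:
        When set, keep per-tree out-of-bag bookkeeping and expose
        ``oob_prediction_`` and ``oob_mae_``.
    """

    def __init__(
        self,
        n_estimators: int = 10_000,
        min_samples_leaf: int = 5,
        n_bins: int = 4,
        random_state: Optional[int] = None,
        compute_oob: bool = False,
    ):
        self.n_estimators = n_estimators
        self.min_samples_leaf = min_samples_leaf
        self.n_bins = n_bins
        self.random_state = random_state
        self.compute_oob = compute_oob

    def _validate_X(self, X, fitted: bool) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if fitted and self.feature_names_in_ is not None:
                missing = [c for c in self.feature_names_in_ if c not in X.columns]
                if missing:
                    raise ValueError(f"missing feature(s): {missing}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if fitted and X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X must be finite")
        return X

    def fit(self, X, y) -> "CurvatureForestRegressor":
        if self.n_estimators < 1:
            raise ConfigurationError("n_estimators must be >= 1")
        if self.min_samples_leaf < 1:
            raise ConfigurationError("min_samples_leaf must be >= 1")
        self.feature_names_in_ = (
            np.asarray(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        Xa = self._validate_X(X, fitted=False)
        y = np.asarray(y, dtype=float)
        n = y.size
        if n == 0 or Xa.shape[0] != n:
            raise ValueError("X and y must be non-empty with matching rows")
        if not np.isfinite(y).all():
            raise ValueError("y must be finite")

        self.n_features_in_ = Xa.shape[1]
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        children = np.random.SeedSequence(self.random_state).spawn(self.n_estimators)
        self.trees_ = []
        if self.compute_oob:
            tree_preds = np.empty((self.n_estimators, n))
            oob = np.zeros((self.n_estimators, n), dtype=bool)
        for t, child in enumerate(children):
            rng = np.random.default_rng(child)
            rows = rng.integers(0, n, size=n)
            tree = grow_tree(
                Xa[rows], y[rows], min_leaf=self.min_samples_leaf, n_bins=self.n_bins
            )
            self.trees_.append(tree)
            if self.compute_oob:
                tree_preds[t] = tree.predict(Xa)
                mask = np.ones(n, dtype=bool)
                mask[rows] = False
                oob[t] = mask
        if self.compute_oob:
            self._oob_tree_preds = tree_preds
            self._oob_masks = oob
            self._oob_y = y.copy()
            self.oob_prediction_, self.oob_mae_ = self._oob_stats(self.n_estimators)
        return self

    def _oob_stats(self, n_trees: int) -> tuple[np.ndarray, float]:
        masks = self._oob_masks[:n_trees]
        preds = self._oob_tree_preds[:n_trees]
        counts = masks.sum(axis=0)
        sums = (preds * masks).sum(axis=0)
        with np.errstate(invalid="ignore"):
            oob_pred = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        covered = counts > 0
        mae = float(np.mean(np.abs(oob_pred[covered] - self._oob_y[covered])))
        return oob_pred, mae

    def oob_error_curve(self, tree_counts: Sequence[int]) -> list[float]:
        """Out-of-bag MAE using only the first ``k`` trees, for each ``k``.

        Requires ``compute_oob=True`` at fit time. Evaluating nested prefixes
        of the same tree sequence keeps the curve comparable point-to-point.
        """
        if not hasattr(self, "_oob_masks"):
            raise RuntimeError("fit with compute_oob=True to use oob_error_curve")
        return [self._oob_stats(int(k))[1] for k in tree_counts]

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "trees_"):
            raise RuntimeError("estimator is not fitted")
        Xa = self._validate_X(X, fitted=True)
        total = np.zeros(Xa.shape[0])
        for tree in self.trees_:
            total += tree.predict(Xa)
        return total / len(self.trees_)

    def to_json(self, path=None) -> str:
        """Versioned, self-describing JSON; round-trips to bit-identical predictions."""
        doc = {
            "schema": "methylage.curvature_forest/1",
            "params": self.get_params(),
            "n_features_in": self.n_features_in_,
            "feature_names": (
                None
                if self.feature_names_in_ is None
                else [str(c) for c in self.feature_names_in_]
            ),
            "y_range": [self.y_min_, self.y_max_],
            "trees": [t.to_dict() for t in self.trees_],
        }
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CurvatureForestRegressor":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        if doc.get("schema") != "methylage.curvature_forest/1":
            raise ValueError(f"unsupported model schema: {doc.get('schema')!r}")
        model = cls(**doc["params"])
        model.n_features_in_ = int(doc["n_features_in"])
        names = doc["feature_names"]
        model.feature_names_in_ = None if names is None else np.asarray(names)
        model.y_min_, model.y_max_ = map(float, doc["y_range"])
        model.trees_ = [Tree.from_dict(d) for d in doc["trees"]]
        return model


_SEX_CODE = {"female": 0.0, "male": 1.0}


def cohort_features(data: pd.DataFrame, panel) -> pd.DataFrame:
    """Feature frame for age prediction: panel methylation columns plus sex (0/1)."""
    missing = [c for c in panel.columns if c not in data.columns]
    if missing:
        raise ValueError(f"missing feature(s): {missing}")
    feats = data[panel.columns].astype(float).copy()
    feats["sex"] = data["sex"].map(_SEX_CODE).astype(float)
    return feats


def fit_forest(
    train,
    panel=None,
    n_estimators: int = 10_000,
    min_samples_leaf: int = 5,
    n_bins: int = 4,
    seed: Optional[int] = None,
    compute_oob: bool = False,
) -> CurvatureForestRegressor:
    """Fit a curvature forest on a training cohort (methylation + sex -> age)."""
    import logging

    panel = panel if panel is not None else train.panel
    if len(panel) != 20:
        logging.getLogger(__name__).warning(
            "training on %d CpG features (the reference protocol uses 20)", len(panel)
        )
    feats = cohort_features(train.data, panel)
    model = CurvatureForestRegressor(
        n_estimators=n_estimators,
        min_samples_leaf=min_samples_leaf,
        n_bins=n_bins,
        random_state=seed,
        compute_oob=compute_oob,
    )
    return model.fit(feats, train.data["age_years"].to_numpy(dtype=float))


def predict_age(model: CurvatureForestRegressor, samples) -> np.ndarray:
    """Predict ages for a cohort or feature frame with a fitted forest."""
    data = samples.data if hasattr(samples, "data") else samples
    if model.feature_names_in_ is not None and "sex" in model.feature_names_in_ and "sex" not in data.columns:
        raise ValueError("missing feature(s): ['sex']")
    if isinstance(data, pd.DataFrame) and model.feature_names_in_ is not None:
        site_cols = [c for c in model.feature_names_in_ if c != "sex"]
        missing = [c for c in site_cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing feature(s): {missing}")
        feats = data[site_cols].astype(float).copy()
        if "sex" in model.feature_names_in_:
            feats["sex"] = data["sex"].map(_SEX_CODE).astype(float)
        return model.predict(feats)
    return model.predict(data)
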