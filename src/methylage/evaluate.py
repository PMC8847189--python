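"""Repeated matched train/test evaluation of cross-population age prediction.

Per run: (1) an age- and sex-matched test subsample of the pool population is
drawn against the fixed reference group; (2) a fresh forest is trained on the
pool *minus* that subsample (strict train/test separation — one model per
run, no caching); (3) the model predicts the held-out pool subsample and the
fixed reference group; (4) the mean absolute error (MAE) and the mean age-gap
deviation (mean of estimated minus chronological age, the bias) are recorded
for both test groups. Means and medians over runs summarise each group.

Because the reference test group is identical in every run, its per-run MAEs
vary only through model retraining and scatter far less than the pool
subsamples' MAEs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import Cohort
from .forest import CurvatureForestRegressor, cohort_features
from .matching import draw_matched

__all__ = ["EvalRun", "EvalSummary", "run_eval", "summarize", "runs_to_tsv", "summary_to_json", "plot_eval"]

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


@dataclass(frozen=True)
class EvalRun:
    """Metrics of one train/test run (two matched test groups)."""

    run_index: int
    test_ids: tuple[str, ...]  # held-out pool donors of this run
    mae_pool: float
    mae_reference: float
    bias_pool: float  # mean(estimated - chronological), years
    bias_reference: float


@dataclass(frozen=True)
class EvalSummary:
    """Mean and median over runs, per test group and metric.

    Medians use the arithmetic-midpoint convention for even run counts.
    """

    mae_pool_mean: float
    mae_pool_median: float
    mae_reference_mean: float
    mae_reference_median: float
    bias_pool_mean: float
    bias_pool_median: float
    bias_reference_mean: float
    bias_reference_median: float
    runs: int
    seed: int = 0
    forest_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mae": {
                "pool": {"mean": self.mae_pool_mean, "median": self.mae_pool_median},
                "reference": {
                    "mean": self.mae_reference_mean,
                    "median": self.mae_reference_median,
                },
            },
            "bias": {
                "pool": {"mean": self.bias_pool_mean, "median": self.bias_pool_median},
                "reference": {
                    "mean": self.bias_reference_mean,
                    "median": self.bias_reference_median,
                },
            },
            "runs": self.runs,
            "seed": self.seed,
            "forest_params": dict(self.forest_params),
        }


def summarize(runs: Sequence[EvalRun], seed: int = 0, forest_params: dict | None = None) -> EvalSummary:
    """Exact means and medians over the run list (permutation-invariant)."""
    if not runs:
        raise ValueError("need at least one run")
    mp = np.array([r.mae_pool for r in runs])
    mr = np.array([r.mae_reference for r in runs])
    bp = np.array([r.bias_pool for r in runs])
    br = np.array([r.bias_reference for r in runs])
    return EvalSummary(
        mae_pool_mean=float(mp.mean()),
        mae_pool_median=float(np.median(mp)),
        mae_reference_mean=float(mr.mean()),
        mae_reference_median=float(np.median(mr)),
        bias_pool_mean=float(bp.mean()),
        bias_pool_median=float(np.median(bp)),
        bias_reference_mean=float(br.mean()),
        bias_reference_median=float(np.median(br)),
        runs=len(runs),
        seed=seed,
        forest_params=dict(forest_params or {}),
    )


def run_eval(
    cohort: Cohort,
    train_pop: str,
    reference_pop: str,
    runs: int = 500,
    match_threshold: float = 0.3,
    seed: int = 0,
    n_estimators: int = 10_000,
    min_samples_leaf: int = 5,
    n_bins: int = 4,
    age_test: str = "welch",
) -> tuple[list[EvalRun], EvalSummary]:
    """The repeated matched train/test protocol; deterministic given ``seed``.

    The cohort should already be age-filtered and CpG-screened. Training data
    never overlap the run's held-out pool test subsample (asserted per run).
    """
    pops = cohort.populations
    for label in (train_pop, reference_pop):
        if label not in pops:
            raise ValueError(f"population {label!r} not in cohort (has {pops})")
    pool = cohort.population_cohort(train_pop)
    ref = cohort.population_cohort(reference_pop)
    if pool.n <= ref.n:
        raise ValueError("pool must be larger than the reference group")

    ref_feats = cohort_features(ref.data, cohort.panel)
    ref_ages = ref.ages
    pool_feats_all = cohort_features(pool.data, cohort.panel).to_numpy(dtype=float)
    pool_ages = pool.ages
    pool_ids = pool.data["sample_id"].to_numpy()

    forest_params = {
        "n_estimators": n_estimators,
        "min_samples_leaf": min_samples_leaf,
        "n_bins": n_bins,
    }
    root = np.random.SeedSequence(seed)
    run_children = root.spawn(runs)
    results: list[EvalRun] = []
    for i, child in enumerate(run_children):
        draw_ss, fit_ss = child.spawn(2)
        draw_seed = int(draw_ss.generate_state(1)[0] % _SEED_MOD)
        fit_seed = int(fit_ss.generate_state(1)[0] % _SEED_MOD)
        draw = draw_matched(
            pool.data, ref.data, threshold=match_threshold, seed=draw_seed,
            age_test=age_test,
        )
        test_mask = np.zeros(pool.n, dtype=bool)
        test_mask[draw.indices] = True
        train_X = pool_feats_all[~test_mask]
        train_y = pool_ages[~test_mask]
        if train_X.shape[0] < 2 * min_samples_leaf:
            raise ValueError(
                f"run {i}: training set of {train_X.shape[0]} rows is too small"
            )
        assert not set(pool_ids[test_mask]) & set(pool_ids[~test_mask])

        model = CurvatureForestRegressor(
            n_estimators=n_estimators,
            min_samples_leaf=min_samples_leaf,
            n_bins=n_bins,
            random_state=fit_seed,
        ).fit(train_X, train_y)
        pred_pool = model.predict(pool_feats_all[test_mask])
        pred_ref = model.predict(ref_feats)
        gap_pool = pred_pool - pool_ages[test_mask]
        gap_ref = pred_ref - ref_ages
        results.append(
            EvalRun(
                run_index=i,
                test_ids=tuple(pool_ids[test_mask]),
                mae_pool=float(np.mean(np.abs(gap_pool))),
                mae_reference=float(np.mean(np.abs(gap_ref))),
                bias_pool=float(np.mean(gap_pool)),
                bias_reference=float(np.mean(gap_ref)),
            )
        )
        if (i + 1) % 25 == 0:
            logger.info("evaluation run %d/%d complete", i + 1, runs)
    return results, summarize(results, seed=seed, forest_params=forest_params)


def runs_to_tsv(runs: Sequence[EvalRun], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["run", "mae_pool", "mae_reference", "bias_pool", "bias_reference"])
        for r in runs:
            writer.writerow(
                [r.run_index, f"{r.mae_pool:.6g}", f"{r.mae_reference:.6g}",
                 f"{r.bias_pool:.6g}", f"{r.bias_reference:.6g}"]
            )


def summary_to_json(summary: EvalSummary, path=None) -> str:
    text = json.dumps(summary.to_dict(), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def plot_eval(runs: Sequence[EvalRun], path) -> None:
    """Two scatter panels: per-run MAE and per-run mean age-gap, both groups."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = [r.run_index for r in runs]
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.scatter(idx, [r.mae_pool for r in runs], s=8, label="pool test groups")
    ax1.scatter(idx, [r.mae_reference for r in runs], s=8, label="reference group")
    ax1.set_xlabel("run")
    ax1.set_ylabel("MAE (years)")
    ax1.legend(frameon=False)
    ax2.scatter(idx, [r.bias_pool for r in runs], s=8, label="pool test groups")
    ax2.scatter(idx, [r.bias_reference for r in runs], s=8, label="reference group")
    ax2.axhline(0.0, lw=0.8, color="grey")
    ax2.set_xlabel("run")
    ax2.set_ylabel("mean age gap (years)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
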