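"""Repeated holdout validation and calibration sweeps.

The validation protocol is plain repeated random splitting: 70% learning /
30% test by default, repeated 5 times, without stratification.  Models are
fitted on the learning set only; the training-derived score threshold then
classifies the test instances, and test metrics come from cutting the test
ranking at the number of instances scoring at or above the threshold.

The calibration sweep refits on the full table for each parameter setting
(no validation split) and reports, per setting, the mean number of positives
found in the top 1% and top 10% of the kept models' rankings plus the best
top-10% count — the three headline calibration metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EFOConfig
from .engine import FitResult, fit_efo
from .metrics import (
    EvaluationReport,
    evaluate_ranking,
    rank,
    top_fraction_size,
)
from .table import DescriptorTable

logger = logging.getLogger(__name__)

__all__ = ["SplitSpec", "make_splits", "evaluate_split", "calibration_sweep"]


@dataclass
class SplitSpec:
    """One random train/test partition of a table's instance ids."""

    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    repeat_index: int
    seed: int | None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def make_splits(
    table: DescriptorTable,
    fraction: float = 0.70,
    repeats: int = 5,
    seed: int | None = None,
) -> list[SplitSpec]:
    """Plain (non-stratified) random splits, deterministic per seed.

    ``round(fraction * N)`` instances go to the learning set.  A split whose
    learning set lacks positives (or negatives — either makes the fit
    impossible) is resampled, with a log message.
    """
    if table.n_total < 10:
        raise ValueError("need at least 10 instances to split")
    table.check_fit_ready()
    N = table.n_total
    n_train = int(np.floor(fraction * N + 0.5))
    if not 0 < n_train < N:
        raise ValueError(f"fraction {fraction} leaves an empty side")
    rng = np.random.default_rng(seed)
    ids = np.asarray(table.instance_ids, dtype=object)
    labels = table.labels
    splits = []
    for r in range(repeats):
        for attempt in range(1000):
            perm = rng.permutation(N)
            train, test = perm[:n_train], perm[n_train:]
            p_train = int(labels[train].sum())
            if 0 < p_train < n_train:
                break
            logger.info("degenerate split (repeat %d); resampling", r)
        else:  # pragma: no cover - 1000 failures means pathological labels
            raise RuntimeError("could not draw a non-degenerate split")
        splits.append(
            SplitSpec(
                train_ids=list(ids[np.sort(train)]),
                test_ids=list(ids[np.sort(test)]),
                fraction=fraction,
                repeat_index=r,
                seed=seed,
            )
        )
    return splits


def evaluate_split(
    table: DescriptorTable,
    split: SplitSpec,
    config: EFOConfig | None = None,
) -> tuple[FitResult, list[EvaluationReport]]:
    """Fit on the learning half of a split and evaluate on the test half.

    The cluster size defaults to the number of learning-set positives.  Test
    predictions use the training-derived threshold: the number of test
    instances scoring at or above it cuts the test ranking into predicted
    positives and negatives, from which the confusion matrix and metrics
    follow.
    """
    config = config or EFOConfig()
    train = table.subset(split.train_ids)
    test = table.subset(split.test_ids)
    assert not set(train.instance_ids) & set(test.instance_ids)
    fit = fit_efo(train, config)
    reports = []
    for model in fit.models:
        test_ranking = rank(test, model)
        n_pred = int((model.score(test) >= model.threshold).sum())
        reports.append(
            evaluate_ranking(
                test_ranking,
                n_predicted_positive=n_pred,
                cluster_size=min(max(1, model.cluster_size), test.n_total - 1),
            )
        )
    return fit, reports


def _top_counts(fit: FitResult, table: DescriptorTable) -> tuple[list, list]:
    """Positives found in the top 1% / top 10% of each kept model's ranking."""
    m1 = top_fraction_size(table.n_total, 0.01)
    m10 = top_fraction_size(table.n_total, 0.10)
    top1, top10 = [], []
    for model in fit.models:
        labels = rank(table, model).labels
        top1.append(int(labels[:m1].sum()))
        top10.append(int(labels[:m10].sum()))
    return top1, top10


def calibration_sweep(
    table: DescriptorTable,
    grid: list[dict],
    base_config: EFOConfig | None = None,
) -> pd.DataFrame:
    """Refit on the full table for each setting and tabulate top-rank counts.

    ``grid`` is a list of config-override dicts (keys are EFOConfig fields,
    e.g. ``{"n_variables": 3}`` or ``{"ef_filter_cutoff": 1.0}``).  Each row
    of the result records the setting, the number of descriptors the filter
    discarded, the mean top-1% and top-10% positive counts over the kept
    models (one decimal), and the best top-10% count.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    base = base_config or EFOConfig()
    rows = []
    for overrides in grid:
        config = base.replace(**overrides)
        fit = fit_efo(table, config)
        top1, top10 = _top_counts(fit, table)
        rows.append(
            {
                "cluster_size": (
                    config.cluster_size
                    if config.cluster_size is not None
                    else table.n_positive
                ),
                "cycles": config.sampling_cycles_per_variable,
                "variables": config.n_variables,
                "cutoff": config.ef_filter_cutoff,
                "n_discarded": fit.filter_result.n_discarded,
                "mean_top1": round(float(np.mean(top1)), 1),
                "mean_top10": round(float(np.mean(top10)), 1),
                "best_top10": int(max(top10)),
            }
        )
    return pd.DataFrame(rows)
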