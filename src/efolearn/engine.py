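"""The EFO learner.

Model generation proceeds in stages:

1. *Filtering*: each descriptor is ranked on its own, in both directions, and
   kept only if its best top-5% enrichment factor exceeds a cut-off
   (default 2.0).  This discards descriptors that cannot individually
   concentrate positives at the top of a ranking.
2. *Combination*: the kept descriptors are systematically combined into
   candidate variable sets of the requested size (exhaustive when feasible,
   greedy forward construction beyond a combination cap).
3. *Coefficient optimization*: for each variable set, random starting
   vectors (12 per included variable by default) seed a Hooke-Jeeves pattern
   search that maximizes the ranking-quality function (asymmetry index x
   first-cluster positive percentage).
4. *Threshold and probabilities*: the score of the rank-n training instance
   (n = number of training positives) becomes the classification threshold,
   and the training ranking is binned into percentile slices whose positive
   fractions serve as score-based probabilities for new instances.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .config import EFOConfig
from .metrics import (
    EvaluationReport,
    cluster_distribution,
    enrichment_factor,
    evaluate_ranking,
    rank,
    rank_scores,
)
from .model import LinearModel, ProbabilityProfile
from .optimize import default_step, hooke_jeeves, random_starts
from .table import DescriptorTable

logger = logging.getLogger(__name__)

__all__ = [
    "FilterResult",
    "FitResult",
    "filter_descriptors",
    "optimize_combination",
    "fit_efo",
    "set_threshold",
    "probability_profile",
    "predict_table",
    "write_fit_outputs",
]


# --------------------------------------------------------------------- filter
@dataclass
class FilterResult:
    """Outcome of single-descriptor enrichment filtering.

    ``kept``/``discarded`` hold ``(name, direction, ef_top5)`` and
    ``(name, ef_top5)`` tuples; ``direction`` records whether the descriptor
    enriches positives when ranked descending or ascending.  Constant
    descriptors are always discarded (their EF is meaningless) and get
    ``ef_top5 = 0``.
    """

    cutoff: float
    kept: list = field(default_factory=list)
    discarded: list = field(default_factory=list)

    @property
    def kept_names(self) -> list[str]:
        return [name for name, _, _ in self.kept]

    @property
    def n_discarded(self) -> int:
        return len(self.discarded)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "kept": [
                {"name": n, "direction": d, "ef_top5": e} for n, d, e in self.kept
            ],
            "discarded": [{"name": n, "ef_top5": e} for n, e in self.discarded],
        }


def filter_descriptors(table: DescriptorTable, cutoff: float = 2.0) -> FilterResult:
    """Keep descriptors whose best-direction top-5% EF strictly exceeds cutoff.

    Each descriptor is used alone as a score, both descending and ascending;
    the larger of the two top-5% enrichment factors decides.  A cutoff <= 0
    disables the filter: every non-constant descriptor is kept.  On balanced
    data the EF ceiling drops (2.0 for a 50/50 split), so the default cutoff
    of 2.0 is unattainable there and must be lowered or removed.
    """
    table.check_fit_ready()
    result = FilterResult(cutoff=float(cutoff))
    ids, labels = table.instance_ids, table.labels
    for j, name in enumerate(table.descriptor_names):
        col = table.values[:, j]
        if np.ptp(col) == 0.0:
            logger.info("descriptor %r is constant; discarded", name)
            result.discarded.append((name, 0.0))
            continue
        ef_desc = enrichment_factor(rank_scores(ids, col, labels), 0.05)
        ef_asc = enrichment_factor(rank_scores(ids, -col, labels), 0.05)
        if ef_desc >= ef_asc:
            direction, ef_best = "descending", ef_desc
        else:
            direction, ef_best = "ascending", ef_asc
        if cutoff <= 0 or ef_best > cutoff:
            result.kept.append((name, direction, ef_best))
        else:
            result.discarded.append((name, ef_best))
    return result


# ------------------------------------------------------------------ objective
def _make_objective(X: np.ndarray, labels: np.ndarray, cluster_size: int):
    """Quality of the ranking induced by coefficients c on matrix X.

    Inlined (rather than composed from rank/cluster_distribution) because it
    sits in the optimizer's innermost loop; equivalence with the public
    functions is asserted in the test suite.
    """
    N = len(labels)
    edges = np.arange(0, N, cluster_size)
    sizes = np.diff(np.append(edges, N)).astype(float)
    labels64 = labels.astype(np.int64)
    if len(edges) < 2:  # a single cluster has no shape to score
        raise ValueError("cluster_size must give at least 2 clusters")

    def objective(c: np.ndarray) -> float:
        order = np.argsort(-(X @ c), kind="stable")
        p = 100.0 * np.add.reduceat(labels64[order], edges) / sizes
        d = p - p.mean()
        m2 = float(np.mean(d * d))
        if m2 < 1e-24:
            return 0.0
        return float(np.mean(d * d * d)) / m2**1.5 * p[0]

    return objective


def _resolve_cluster_size(table: DescriptorTable, config: EFOConfig) -> int:
    cs = config.cluster_size if config.cluster_size is not None else table.n_positive
    return max(1, min(int(cs), table.n_total))


# --------------------------------------------------------------- optimization
def optimize_combination(
    table: DescriptorTable,
    variables: list[str],
    config: EFOConfig,
    rng: np.random.Generator,
) -> LinearModel:
    """Optimize coefficients for one variable set and return the fitted model.

    All random starts are scored; full pattern searches run from the best
    ``config.hj_starts`` of them and the best terminal point wins.  The
    winning vector is normalized so the leading coefficient is +-1 (rotating
    the variable order if the leading coefficient is ~0), which leaves the
    ranking untouched; the classification threshold is then set from the
    training ranking.
    """
    table.check_fit_ready()
    k = len(variables)
    X = table.columns(variables)
    cluster_size = _resolve_cluster_size(table, config)
    objective = _make_objective(X, table.labels, cluster_size)

    cycles = config.sampling_cycles_per_variable * k
    sigma = X.std(axis=0, ddof=1) if table.n_total > 1 else np.ones(k)
    starts = random_starts(k, cycles, rng, scales=sigma)
    start_values = np.array([objective(c) for c in starts])
    order = np.argsort(-start_values, kind="stable")

    best_x, best_f = None, -np.inf
    budget_exhausted = False
    for i in order[: config.hj_starts]:
        res = hooke_jeeves(
            objective,
            starts[i],
            step0=default_step(starts[i]),
            iterations=config.hj_iterations,
            rms_tol=config.hj_rms_tol,
        )
        budget_exhausted |= not res.converged
        if res.fun > best_f:
            best_x, best_f = res.x, res.fun
    if budget_exhausted:
        logger.info("pattern search hit the iteration budget for %s", variables)

    coeffs = np.asarray(best_x, dtype=float)
    variables = list(variables)
    if abs(coeffs[0]) < 1e-12:
        lead = int(np.argmax(np.abs(coeffs)))
        if abs(coeffs[lead]) < 1e-12:
            # fully degenerate optimum (flat objective); fall back to unit lead
            logger.info("all coefficients ~0 for %s; using unit lead", variables)
            coeffs[0] = 1.0
        else:
            logger.info(
                "leading coefficient ~0; rotating %r to front", variables[lead]
            )
            rot = [lead] + [j for j in range(len(coeffs)) if j != lead]
            variables = [variables[j] for j in rot]
            coeffs = coeffs[rot]
    coeffs = coeffs / abs(coeffs[0])

    model = LinearModel(
        variables=variables,
        coefficients=coeffs,
        train_quality=best_f,
        cluster_size=cluster_size,
        seed=config.seed,
        provenance={"config": config.to_dict()},
    )
    return set_threshold(model, table)


def set_threshold(model: LinearModel, training_table: DescriptorTable) -> LinearModel:
    """Set the threshold to the score of the rank-n training instance.

    n is the number of training positives: during learning the n best-scoring
    instances are taken as the predicted positives, so the n-th score is the
    natural cut separating them.  Prediction uses ``score >= threshold``
    (the boundary instance itself counts as positive).
    """
    training_table.check_fit_ready()
    scores = model.score(training_table)
    n = training_table.n_positive
    ranked = np.sort(scores)[::-1]
    model.threshold = float(ranked[n - 1])
    return model


def probability_profile(
    model: LinearModel,
    training_table: DescriptorTable,
    bin_fraction: float = 0.02,
) -> ProbabilityProfile:
    """Positive fraction per percentile bin of the training ranking.

    Bins hold ``ceil(bin_fraction * N)`` consecutive ranked instances each
    (default 2% of the training set).  The bin fractions are the model's
    score-based probabilities: a new score is assigned the positive fraction
    of the bin its value falls into.
    """
    if not 0 < bin_fraction <= 0.5:
        raise ValueError("bin_fraction must lie in (0, 0.5]")
    ranking = rank(training_table, model)
    N = ranking.n_total
    width = math.ceil(bin_fraction * N)
    edges = np.arange(0, N, width)
    sizes = np.diff(np.append(edges, N))
    counts = np.add.reduceat(ranking.labels.astype(np.int64), edges)
    last_in_bin = np.append(edges[1:], N) - 1
    return ProbabilityProfile(
        lower_bounds=ranking.scores[last_in_bin],
        bin_positive_fraction=counts / sizes,
        bin_fraction=float(bin_fraction),
    )


# ------------------------------------------------------------------------ fit
@dataclass
class FitResult:
    """Best models of one fit, sorted by descending training quality."""

    models: list[LinearModel]
    reports: list[EvaluationReport]  # training evaluation, aligned with models
    filter_result: FilterResult
    config: EFOConfig
    seed: int | None
    n_combinations: int  # number of variable sets optimized

    @property
    def best_model(self) -> LinearModel:
        return self.models[0]


def _ordered_combo(names: list[str], universe_order: dict) -> tuple:
    return tuple(sorted(names, key=universe_order.__getitem__))


def fit_efo(table: DescriptorTable, config: EFOConfig | None = None) -> FitResult:
    """Fit EFO models on a labeled descriptor table.

    Filters descriptors, enumerates all C(m, k) variable sets of the kept
    descriptors (or falls back to greedy forward construction when the count
    exceeds ``config.max_combinations``), optimizes each set's coefficients,
    and keeps the ``n_models_kept`` best by training quality.  Deterministic
    given (table, config, seed).
    """
    config = config or EFOConfig()
    table.check_fit_ready()
    k = config.n_variables
    cluster_size = _resolve_cluster_size(table, config)

    filt = filter_descriptors(table, config.ef_filter_cutoff)
    kept = filt.kept_names
    if len(kept) < k:
        raise ValueError(
            f"only {len(kept)} descriptors pass the EF filter at cutoff "
            f"{config.ef_filter_cutoff} but {k} variables were requested; "
            "lower ef_filter_cutoff (e.g. 1.0, or 0 to disable)"
        )

    ss = np.random.SeedSequence(config.seed if config.seed is not None else 0)
    universe_order = {name: i for i, name in enumerate(table.descriptor_names)}
    n_optimized = 0

    def optimize(variables: tuple) -> LinearModel:
        nonlocal n_optimized
        rng = np.random.default_rng(ss.spawn(1)[0])
        n_optimized += 1
        return optimize_combination(table, list(variables), config, rng)

    if comb(len(kept), k) <= config.max_combinations:
        combos = [
            _ordered_combo(list(c), universe_order)
            for c in itertools.combinations(kept, k)
        ]
        fitted = [optimize(c) for c in combos]
    else:
        # Greedy forward construction: grow the best variable sets one
        # descriptor at a time, mirroring staged search on a reduced input.
        logger.info(
            "C(%d, %d) exceeds max_combinations=%d; greedy forward search",
            len(kept), k, config.max_combinations,
        )
        frontier: list[tuple] = [()]
        fitted = []
        for size in range(1, k + 1):
            candidates = sorted(
                {
                    _ordered_combo(list(vs) + [d], universe_order)
                    for vs in frontier
                    for d in kept
                    if d not in vs
                },
                key=lambda c: tuple(universe_order[n] for n in c),
            )
            models = [optimize(c) for c in candidates]
            ranked = sorted(
                zip(candidates, models), key=lambda cm: -cm[1].train_quality
            )
            frontier = [c for c, _ in ranked[: config.n_models_kept]]
            if size == k:
                fitted = [m for _, m in ranked]

    fitted.sort(key=lambda m: -m.train_quality)
    fitted = fitted[: config.n_models_kept]

    reports = []
    for m in fitted:
        m.probability_profile = probability_profile(m, table, config.bin_fraction)
        r = rank(table, m)
        reports.append(
            evaluate_ranking(r, n_predicted_positive=table.n_positive,
                             cluster_size=cluster_size)
        )
    return FitResult(
        models=fitted,
        reports=reports,
        filter_result=filt,
        config=config,
        seed=config.seed,
        n_combinations=n_optimized,
    )


# -------------------------------------------------------------------- predict
def predict_table(model: LinearModel, table: DescriptorTable) -> pd.DataFrame:
    """Score a table with a fitted model.

    Returns a DataFrame with columns ``id``, ``score``, ``predicted`` (1 iff
    score >= threshold) and ``probability`` (positive fraction of the
    training-ranking bin containing the score; absent with a warning when the
    model carries no probability profile).
    """
    scores = model.score(table)
    out = pd.DataFrame({"id": table.instance_ids, "score": scores})
    if model.threshold is None:
        raise ValueError("model has no classification threshold; fit or set one")
    out["predicted"] = (scores >= model.threshold).astype(int)
    if model.probability_profile is None:
        warnings.warn(
            "model has no probability profile; probabilities omitted",
            stacklevel=2,
        )
    else:
        out["probability"] = model.probability_profile.probability(scores)
    return out


# ------------------------------------------------------------------- outputs
def write_fit_outputs(fit: FitResult, table: DescriptorTable, out_dir) -> dict:
    """Write the four run artifacts of a fit to ``out_dir``.

    (i) ``models.json`` — the kept models (plus ``best.json``, the top model
    alone, ready for ``predict``); (ii) ``run.log`` — config, seed and
    per-model qualities; (iii) ``scores.csv`` — per-instance score, class
    and probability for every kept model; (iv) ``reduced.csv`` — the input
    table restricted to the descriptors that passed the filter.  Returns
    the mapping of artifact name to path.
    """
    import json
    from pathlib import Path

    from .table import write_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "models": out_dir / "models.json",
        "best": out_dir / "best.json",
        "log": out_dir / "run.log",
        "scores": out_dir / "scores.csv",
        "reduced": out_dir / "reduced.csv",
    }

    paths["models"].write_text(
        json.dumps([m.to_dict() for m in fit.models], indent=2) + "\n"
    )
    from .model import write_model

    write_model(fit.best_model, paths["best"])

    lines = [
        "efolearn fit log",
        f"seed: {fit.seed}",
        f"config: {json.dumps(fit.config.to_dict())}",
        f"n_instances: {table.n_total}  n_positive: {table.n_positive}",
        f"filter cutoff: {fit.filter_result.cutoff}  "
        f"kept: {len(fit.filter_result.kept)}  "
        f"discarded: {fit.filter_result.n_discarded}",
        f"combinations optimized: {fit.n_combinations}",
        "models (quality | equation):",
    ]
    for m, rep in zip(fit.models, fit.reports):
        lines.append(
            f"  {m.train_quality:10.4f} | {m.equation()} "
            f"| train MCC {rep.mcc:.3f}"
        )
    paths["log"].write_text("\n".join(lines) + "\n")

    frames = [pd.DataFrame({"id": table.instance_ids})]
    for i, m in enumerate(fit.models, start=1):
        pred = predict_table(m, table)
        frames.append(
            pred[["score", "predicted", "probability"]].add_suffix(f"_m{i}")
        )
    pd.concat(frames, axis=1).to_csv(paths["scores"], index=False)

    write_table(table.select_descriptors(fit.filter_result.kept_names),
                paths["reduced"])
    return paths
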