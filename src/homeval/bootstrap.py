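"""Query-only bootstrap inference for benchmark metrics.

Replicate query sets are drawn by resampling the query set with
replacement while the library is held fixed: the library is treated as
large enough to be stable, and resampling it is known to bias replicate
top-1 accuracy downward because a resampled library loses diversity
(see :func:`library_resampling_top1`, kept as a diagnostic).

Confidence intervals use the percentile method: the B replicate metric
values are sorted and the interval endpoints are the order statistics at
ranks B*alpha/2 and B*(1-alpha/2) (1-based; ceil and floor respectively
when not integral, which widens the interval).  One-sided p-values for
"condition x beats condition y" average the strict-inequality indicator
over replicates, so comparing a condition against itself yields p = 1.

A metric is supplied as a factory ``metric(bench) -> evaluator`` where
``evaluator(query_ids)`` scores an arbitrary query multiset (duplicated
queries count with multiplicity).  :func:`top1_metric` and
:func:`fbeta_max_metric` provide the two statistics of interest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .evaluation import (
    Benchmark,
    UndefinedMetricError,
    _level_key,
    top1_accuracy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapPlan",
    "BootstrapResult",
    "resample_queries",
    "metric_ci",
    "metric_pvalue",
    "top1_metric",
    "fbeta_max_metric",
    "library_resampling_top1",
    "percentile_ranks",
]

MetricFactory = Callable[[Benchmark], Callable[[Sequence[str]], float]]


@dataclass(frozen=True)
class BootstrapPlan:
    """Resampling plan: B replicates, CI level alpha, RNG seed, pairing."""

    B: int = 1000
    alpha: float = 0.05
    seed: int = 0
    paired: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.B * self.alpha / 2 < 1:
            raise ValueError(
                f"B*alpha/2 = {self.B * self.alpha / 2} < 1: CI ranks undefined"
            )


@dataclass
class BootstrapResult:
    point_estimate: float
    lower: float
    upper: float
    replicate_values: np.ndarray  # length B; NaN marks an undefined replicate

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower > upper")


def _replicate_rng(seed: int, b: int) -> np.random.Generator:
    # each replicate's draws depend only on (seed, b): order-independent
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))


def resample_queries(
    query_ids: Sequence[str], B: int, seed: int
) -> list[list[str]]:
    """Draw B query multisets of size |Q|, i.i.d. uniform with replacement."""
    ids = list(query_ids)
    if not ids:
        raise ValueError("empty query set")
    if B < 1:
        raise ValueError("B must be >= 1")
    out = []
    for b in range(B):
        rng = _replicate_rng(seed, b)
        idx = rng.integers(0, len(ids), size=len(ids))
        out.append([ids[i] for i in idx])
    return out


def percentile_ranks(B: int, alpha: float) -> tuple[int, int]:
    """1-based order-statistic ranks (lower, upper) of the percentile CI.

    ceil(B*alpha/2) and floor(B*(1-alpha/2)); for B=1000, alpha=0.05
    this is (25, 975).
    """
    return math.ceil(B * alpha / 2), math.floor(B * (1 - alpha / 2))


def top1_metric(bench: Benchmark) -> Callable[[Sequence[str]], float]:
    """Top-1 accuracy evaluator honoring query multiplicity.

    Each query's correctness is precomputed once; a replicate's accuracy
    is the multiplicity-weighted fraction of correct queries, with
    unassignable queries excluded from the denominator as in the point
    estimate.
    """
    result = top1_accuracy(bench)
    correct = result.per_query_correct

    def evaluate(query_ids: Sequence[str]) -> float:
        n = hits = 0
        for q in query_ids:
            c = correct.get(q)
            if c is None:
                continue
            n += 1
            hits += c
        if n == 0:
            raise UndefinedMetricError("no assignable query in replicate")
        return hits / n

    return evaluate


def fbeta_max_metric(beta: float) -> MetricFactory:
    """Factory for a threshold-maximized F-beta evaluator over query multisets.

    Per-query cumulative detected/homolog counts at every observed
    threshold are precomputed; a replicate sums them with multiplicity,
    then maximizes F-beta over the shared threshold grid.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")

    def factory(bench: Benchmark) -> Callable[[Sequence[str]], float]:
        q_ids = list(bench.queries)
        q_index = {q: i for i, q in enumerate(q_ids)}
        lib_keys = {
            l_id: _level_key(rec.taxonomy, bench.level)
            for l_id, rec in bench.library.items()
        }
        key_counts: dict[tuple[int, ...], int] = {}
        for key in lib_keys.values():
            key_counts[key] = key_counts.get(key, 0) + 1
        positives = np.zeros(len(q_ids))
        for q_id in q_ids:
            key = _level_key(bench.queries[q_id].taxonomy, bench.level)
            positives[q_index[q_id]] = key_counts.get(key, 0) - (
                1 if q_id in bench.library else 0
            )

        frame = bench.scores.frame
        frame = frame[frame["query_id"] != frame["library_id"]]
        scores = frame["score"].to_numpy(dtype=float)
        qi = np.array([q_index[q] for q in frame["query_id"]])
        same = np.array(
            [
                _level_key(bench.queries[q].taxonomy, bench.level) == lib_keys[l]
                for q, l in zip(frame["query_id"], frame["library_id"])
            ],
            dtype=float,
        )
        distinct, inverse = np.unique(-scores, return_inverse=True)
        n_thr = distinct.size + 1  # + sentinel below the minimum
        counts = np.zeros((len(q_ids), distinct.size))
        same_counts = np.zeros_like(counts)
        np.add.at(counts, (qi, inverse), 1.0)
        np.add.at(same_counts, (qi, inverse), same)
        # strictly-above cumulative counts per query at each threshold
        above = np.zeros((len(q_ids), n_thr))
        same_above = np.zeros_like(above)
        above[:, 1:] = np.cumsum(counts, axis=1)
        same_above[:, 1:] = np.cumsum(same_counts, axis=1)

        def evaluate(query_ids: Sequence[str]) -> float:
            idx = np.array([q_index[q] for q in query_ids])
            n_pos = positives[idx].sum()
            if n_pos <= 0:
                raise UndefinedMetricError("replicate has no homologous pair")
            det = above[idx].sum(axis=0)
            hit = same_above[idx].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(det > 0, hit / np.maximum(det, 1), 1.0)
            r = hit / n_pos
            f = np.where(
                (p > 0) & (r > 0),
                (1 + beta**2) * p * r / (beta**2 * p + r),
                0.0,
            )
            return float(f.max())

        return evaluate

    return factory


def metric_ci(
    metric: MetricFactory, bench: Benchmark, plan: BootstrapPlan
) -> BootstrapResult:
    """Percentile bootstrap CI of a metric under query-only resampling.

    Replicates where the metric is undefined are recorded as NaN; if more
    than 1% are missing a coverage warning is logged and the ranks are
    taken over the defined replicates.
    """
    evaluator = metric(bench)
    q_ids = list(bench.queries)
    point = evaluator(q_ids)
    values = np.full(plan.B, np.nan)
    for b, replicate in enumerate(resample_queries(q_ids, plan.B, plan.seed)):
        try:
            values[b] = evaluator(replicate)
        except UndefinedMetricError:
            pass
    defined = values[~np.isnan(values)]
    n_missing = plan.B - defined.size
    if n_missing > 0.01 * plan.B:
        logger.warning(
            "%d/%d bootstrap replicates had an undefined metric; CI coverage "
            "may be degraded",
            n_missing,
            plan.B,
        )
    if defined.size == 0:
        raise UndefinedMetricError("metric undefined on every replicate")
    lo_rank, hi_rank = percentile_ranks(defined.size, plan.alpha)
    ordered = np.sort(defined)
    return BootstrapResult(
        point_estimate=point,
        lower=float(ordered[lo_rank - 1]),
        upper=float(ordered[hi_rank - 1]),
        replicate_values=values,
    )


def metric_pvalue(
    metric_x: MetricFactory,
    bench_x: Benchmark,
    metric_y: MetricFactory,
    bench_y: Benchmark,
    plan: BootstrapPlan,
) -> float:
    """One-sided bootstrap p-value for "x beats y".

    p = 1 - mean over replicates of I(metric_x > metric_y), where ties
    count against x (the indicator is 0 when x <= y).  When the two
    benchmarks share a query set and the plan is paired, the b-th
    replicate uses the same index draws for both conditions; otherwise
    the two replicate streams are independent.
    """
    qx, qy = list(bench_x.queries), list(bench_y.queries)
    shared = plan.paired and qx == qy
    ex, ey = metric_x(bench_x), metric_y(bench_y)
    reps_x = resample_queries(qx, plan.B, plan.seed)
    reps_y = (
        reps_x if shared else resample_queries(qy, plan.B, plan.seed + 1)
    )
    wins = total = 0
    for rx, ry in zip(reps_x, reps_y):
        try:
            vx, vy = ex(rx), ey(ry)
        except UndefinedMetricError:
            continue
        total += 1
        wins += vx > vy
    if total == 0:
        raise UndefinedMetricError("metric undefined on every replicate pair")
    if total < plan.B:
        logger.warning(
            "%d/%d replicate pairs dropped (undefined metric)", plan.B - total, plan.B
        )
    return 1.0 - wins / total


@dataclass
class LibraryResamplingDiagnostic:
    point_estimate: float
    replicate_values: np.ndarray

    @property
    def mean_replicate(self) -> float:
        return float(np.nanmean(self.replicate_values))


def library_resampling_top1(
    bench: Benchmark, B: int, seed: int
) -> LibraryResamplingDiagnostic:
    """Diagnostic: top-1 accuracy under (deliberate) library resampling.

    Resampling the library with replacement drops part of its diversity
    in every replicate, so the mean replicate accuracy falls below the
    point estimate — the bias that motivates query-only resampling.
    Not part of the inference API.
    """
    q_ids = list(bench.queries)
    l_ids = list(bench.library)
    S = np.full((len(q_ids), len(l_ids)), -np.inf)
    q_index = {q: i for i, q in enumerate(q_ids)}
    l_index = {l: j for j, l in enumerate(l_ids)}
    for rec in bench.scores:
        if rec.query_id != rec.library_id:
            S[q_index[rec.query_id], l_index[rec.library_id]] = rec.score
    match = np.array(
        [
            [
                _level_key(bench.queries[q].taxonomy, bench.level)
                == _level_key(bench.library[l].taxonomy, bench.level)
                for l in l_ids
            ]
            for q in q_ids
        ]
    )
    point = top1_accuracy(bench).accuracy
    values = np.full(B, np.nan)
    for b in range(B):
        rng = _replicate_rng(seed, b)
        cols = np.unique(rng.integers(0, len(l_ids), size=len(l_ids)))
        sub = S[:, cols]
        best = np.argmax(sub, axis=1)
        assigned = sub[np.arange(len(q_ids)), best] > -np.inf
        if not assigned.any():
            continue
        correct = match[np.arange(len(q_ids)), cols[best]]
        values[b] = correct[assigned].mean()
    return LibraryResamplingDiagnostic(point_estimate=point, replicate_values=values)
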