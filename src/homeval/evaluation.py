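"""Benchmark statistics for taxonomy-based homology detection.

Two statistics are computed over a query set Q and a library set L:

* **Top-1 accuracy** — the fraction of queries whose highest-scoring
  library domain (the identical domain excluded) shares the query's
  classification at the chosen level.
* **Restricted precision-recall** — precision and recall counted only
  over the ordered query x library pairs (never within-set pairs), with
  identical-domain pairs excluded and strict ``score > threshold``
  comparison.  F-beta summaries are maximized over all observed
  thresholds.

Classification levels follow the 4-level dotted hierarchy X.H.T.F:
``"H"`` requires equal X and H components (homology), ``"X"`` equal X
(possible homology), ``"F"`` all four (family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .io import DomainRecord, ScoreTable, TaxonomyId

logger = logging.getLogger(__name__)

__all__ = [
    "LEVELS",
    "UndefinedMetricError",
    "Benchmark",
    "Top1Result",
    "PrecisionRecallCurve",
    "ThresholdEntry",
    "ThresholdTable",
    "taxonomy_match",
    "top1_accuracy",
    "pr_curve",
    "f_beta",
    "f_beta_max",
    "select_thresholds",
    "write_threshold_table",
]

LEVELS = ("H", "X", "F")


class UndefinedMetricError(ValueError):
    """A statistic has an empty denominator (e.g. no homologous pairs)."""


def _level_key(tax: TaxonomyId, level: str) -> tuple[int, ...]:
    if level == "H":
        return (tax.x_id, tax.h_id)
    if level == "X":
        return (tax.x_id,)
    if level == "F":
        return tuple(tax)
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def taxonomy_match(a: TaxonomyId, b: TaxonomyId, level: str = "H") -> bool:
    """True when two identifiers agree at the given hierarchy level."""
    return _level_key(a, level) == _level_key(b, level)


@dataclass
class Benchmark:
    """A query set, a library set, their pairwise scores, and a level.

    Q and L may overlap (the all-vs-all case); only ordered Q x L pairs
    are ever evaluated, and the identical pair (q = l, same domain id)
    is excluded from every count.
    """

    queries: dict[str, DomainRecord]
    library: dict[str, DomainRecord]
    scores: ScoreTable
    level: str = "H"

    def __post_init__(self) -> None:
        _level_key(TaxonomyId(1, 1, 1, 1), self.level)  # validates level
        q_ids = set(self.queries)
        l_ids = set(self.library)
        sq = set(self.scores.frame["query_id"])
        sl = set(self.scores.frame["library_id"])
        if not sq <= q_ids:
            raise ValueError(f"scores reference unknown queries: {sorted(sq - q_ids)[:5]}")
        if not sl <= l_ids:
            raise ValueError(f"scores reference unknown library ids: {sorted(sl - l_ids)[:5]}")

    @classmethod
    def from_collections(
        cls,
        queries: Iterable[DomainRecord],
        library: Iterable[DomainRecord],
        scores: ScoreTable,
        level: str = "H",
    ) -> "Benchmark":
        return cls(
            queries={d.domain_id: d for d in queries},
            library={d.domain_id: d for d in library},
            scores=scores,
            level=level,
        )


class Assignment(NamedTuple):
    query_id: str
    best_library_id: str
    matched: bool


@dataclass
class Top1Result:
    accuracy: float
    assignments: list[Assignment]
    unassigned: list[str]

    @property
    def per_query_correct(self) -> dict[str, bool]:
        return {a.query_id: a.matched for a in self.assignments}


def top1_accuracy(bench: Benchmark) -> Top1Result:
    """Fraction of queries whose best-scoring library partner matches.

    For each query q the assigned library domain is the argmax of the
    score over l in L with l != q; score ties resolve to the
    lexicographically smallest library id.  Queries with no scored,
    non-identical partner are reported as unassigned and excluded from
    the denominator (with a warning).
    """
    frame = bench.scores.frame
    frame = frame[frame["query_id"] != frame["library_id"]]
    # sort so the first row per query is (max score, smallest library_id)
    frame = frame.sort_values(
        ["query_id", "score", "library_id"], ascending=[True, False, True]
    )
    best = frame.groupby("query_id", sort=False).first()

    assignments: list[Assignment] = []
    unassigned: list[str] = []
    for q_id, q_rec in bench.queries.items():
        if q_id not in best.index:
            unassigned.append(q_id)
            continue
        l_id = str(best.loc[q_id, "library_id"])
        matched = taxonomy_match(
            q_rec.taxonomy, bench.library[l_id].taxonomy, bench.level
        )
        assignments.append(Assignment(q_id, l_id, matched))
    if unassigned:
        logger.warning(
            "%d queries had no scored non-identical library partner and were "
            "excluded from the top-1 denominator",
            len(unassigned),
        )
    if not assignments:
        raise UndefinedMetricError("no query could be assigned")
    accuracy = sum(a.matched for a in assignments) / len(assignments)
    return Top1Result(accuracy, assignments, unassigned)


@dataclass
class PrecisionRecallCurve:
    """Precision/recall evaluated at every distinct observed score.

    ``thresholds`` is descending and ends with a ``-inf`` sentinel so the
    curve always reaches its maximal recall over scored pairs.  The
    comparison is strict: a pair counts as detected at threshold S only
    when its score is > S, and unscored Q x L pairs lie below every
    threshold.
    """

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_positive_pairs: int
    n_evaluated_pairs: int

    def __len__(self) -> int:
        return len(self.thresholds)

    def at_threshold(self, s: float) -> tuple[float, float]:
        """(precision, recall) under strict > comparison at arbitrary S."""
        # first index (descending order) whose threshold is <= s gives the
        # same strictly-above pair set as s itself
        i = int(np.argmax(self.thresholds <= s))
        return float(self.precision[i]), float(self.recall[i])


def pr_curve(bench: Benchmark) -> PrecisionRecallCurve:
    """Restricted precision-recall curve over the ordered Q x L pairs."""
    q_ids = list(bench.queries)
    lib_keys: dict[str, tuple[int, ...]] = {
        l_id: _level_key(rec.taxonomy, bench.level)
        for l_id, rec in bench.library.items()
    }
    key_counts: dict[tuple[int, ...], int] = {}
    for key in lib_keys.values():
        key_counts[key] = key_counts.get(key, 0) + 1

    n_overlap = sum(1 for q in q_ids if q in bench.library)
    n_evaluated = len(q_ids) * len(bench.library) - n_overlap
    n_positive = 0
    for q_id in q_ids:
        key = _level_key(bench.queries[q_id].taxonomy, bench.level)
        n_positive += key_counts.get(key, 0)
        if q_id in bench.library:
            n_positive -= 1  # the identical pair always matches; exclude it
    if n_positive < 1:
        raise UndefinedMetricError(
            f"no homologous Q x L pair at level {bench.level}; recall undefined"
        )

    frame = bench.scores.frame
    frame = frame[frame["query_id"] != frame["library_id"]]
    scores = frame["score"].to_numpy(dtype=float)
    same = np.array(
        [
            _level_key(bench.queries[q].taxonomy, bench.level) == lib_keys[l]
            for q, l in zip(frame["query_id"], frame["library_id"])
        ],
        dtype=bool,
    )

    distinct, inverse = np.unique(-scores, return_inverse=True)
    distinct = -distinct  # descending
    counts = np.bincount(inverse, minlength=distinct.size).astype(float)
    same_counts = np.bincount(
        inverse, weights=same.astype(float), minlength=distinct.size
    )
    # strictly-above counts: pairs at the threshold value itself are below it
    above = np.concatenate([[0.0], np.cumsum(counts)])
    same_above = np.concatenate([[0.0], np.cumsum(same_counts)])
    thresholds = np.concatenate([distinct, [-np.inf]])

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(above > 0, same_above / np.maximum(above, 1), 1.0)
    recall = same_above / n_positive
    return PrecisionRecallCurve(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        n_positive_pairs=int(n_positive),
        n_evaluated_pairs=int(n_evaluated),
    )


def f_beta(p: float, r: float, beta: float) -> float:
    """Weighted harmonic mean (1+b^2) p r / (b^2 p + r); 0 if either is 0."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if p == 0 or r == 0:
        return 0.0
    return (1 + beta**2) * p * r / (beta**2 * p + r)


def f_beta_max(curve: PrecisionRecallCurve, beta: float) -> tuple[float, float]:
    """Maximum F-beta over the curve and its threshold (ties -> higher S)."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if len(curve) == 0:
        raise ValueError("empty curve")
    p, r = curve.precision, curve.recall
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(
            (p > 0) & (r > 0), (1 + beta**2) * p * r / (beta**2 * p + r), 0.0
        )
    i = int(np.argmax(f))  # thresholds descend, so first max is the highest S
    return float(f[i]), float(curve.thresholds[i])


@dataclass
class ThresholdEntry:
    criterion: str
    attained: bool
    threshold: float | None = None
    precision: float | None = None
    recall: float | None = None
    f_value: float | None = None


@dataclass
class ThresholdTable:
    """Operating points for the five standard criteria.

    Criteria: smallest threshold with precision >= 0.99 and >= 0.90, and
    the thresholds maximizing F0.5, F1 and F2.  A precision target the
    curve never reaches is recorded as unattained, not an error.
    """

    entries: dict[str, ThresholdEntry] = field(default_factory=dict)

    def __getitem__(self, criterion: str) -> ThresholdEntry:
        return self.entries[criterion]


def select_thresholds(
    curve: PrecisionRecallCurve,
    precision_targets: Sequence[float] = (0.99, 0.90),
    betas: Sequence[float] = (0.5, 1.0, 2.0),
) -> ThresholdTable:
    table = ThresholdTable()
    for target in precision_targets:
        name = f"precision={target:g}"
        # the zero-detection point (vacuous precision 1) never attains a target
        ok = np.flatnonzero((curve.precision >= target) & (curve.recall > 0))
        if ok.size == 0:
            table.entries[name] = ThresholdEntry(name, attained=False)
            continue
        i = int(ok[-1])  # thresholds descend: last qualifying index = lowest S
        table.entries[name] = ThresholdEntry(
            name,
            attained=True,
            threshold=float(curve.thresholds[i]),
            precision=float(curve.precision[i]),
            recall=float(curve.recall[i]),
        )
    for beta in betas:
        name = f"maxF{beta:g}"
        f, thr = f_beta_max(curve, beta)
        p, r = curve.at_threshold(thr)
        table.entries[name] = ThresholdEntry(
            name, attained=True, threshold=thr, precision=p, recall=r, f_value=f
        )
    return table


def write_threshold_table(table: ThresholdTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("criterion\tattained\tthreshold\tprecision\trecall\tf_value\n")
        for entry in table.entries.values():
            def fmt(v: float | None) -> str:
                return f"{v:.6g}" if v is not None else ""
            fh.write(
                "\t".join(
                    [
                        entry.criterion,
                        "yes" if entry.attained else "no",
                        fmt(entry.threshold),
                        fmt(entry.precision),
                        fmt(entry.recall),
                        fmt(entry.f_value),
                    ]
                )
                + "\n"
            )
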