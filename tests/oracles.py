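"""Brute-force reference implementations used to cross-check the package.

These scan every pair explicitly and are independent of the vectorized
code paths in homeval.evaluation.
"""

from __future__ import annotations

import math

import numpy as np

from homeval.evaluation import Benchmark, _level_key
from homeval.io import DomainRecord, ScoreTable, TaxonomyId


def brute_force_top1(bench: Benchmark) -> tuple[float, dict[str, str]]:
    """Scan all pairs per query; ties to the lexicographically smallest id."""
    assigned: dict[str, str] = {}
    n_correct = 0
    n_assigned = 0
    for q_id, q in bench.queries.items():
        best_id, best_score = None, -math.inf
        for l_id in sorted(bench.library):
            if l_id == q_id:
                continue
            s = bench.scores.score_of(q_id, l_id)
            if s is None:
                continue
            if s > best_score:
                best_id, best_score = l_id, s
        if best_id is None:
            continue
        n_assigned += 1
        if _level_key(q.taxonomy, bench.level) == _level_key(
            bench.library[best_id].taxonomy, bench.level
        ):
            n_correct += 1
        assigned[q_id] = best_id
    return n_correct / n_assigned, assigned


def brute_force_pr(bench: Benchmark, threshold: float) -> tuple[float, float]:
    """Count pairs above a threshold (strict >) over all Q x L pairs."""
    n_pos = n_above = n_same_above = 0
    for q_id, q in bench.queries.items():
        for l_id, l in bench.library.items():
            if q_id == l_id:
                continue
            same = _level_key(q.taxonomy, bench.level) == _level_key(
                l.taxonomy, bench.level
            )
            n_pos += same
            s = bench.scores.score_of(q_id, l_id)
            if s is not None and s > threshold:
                n_above += 1
                n_same_above += same
    precision = n_same_above / n_above if n_above else 1.0
    recall = n_same_above / n_pos
    return precision, recall


def brute_force_fbeta_max(bench: Benchmark, beta: float) -> float:
    """Maximize F-beta by scanning every distinct observed threshold."""
    scores = sorted(
        {
            rec.score
            for rec in bench.scores
            if rec.query_id != rec.library_id
        }
    )
    best = 0.0
    for thr in scores + [min(scores) - 1.0]:
        p, r = brute_force_pr(bench, thr)
        if p > 0 and r > 0:
            f = (1 + beta**2) * p * r / (beta**2 * p + r)
            best = max(best, f)
    return best


def random_instance(
    rng: np.random.Generator,
    n_queries: int | None = None,
    n_library: int | None = None,
    allow_overlap: bool = True,
    score_fraction: float = 1.0,
    allow_ties: bool = True,
) -> Benchmark:
    """A small random benchmark with clustered taxonomy and arbitrary scores."""
    nq = n_queries or int(rng.integers(2, 9))
    nl = n_library or int(rng.integers(3, 13))
    n_groups = int(rng.integers(2, 5))

    def make(prefix: str, i: int, overlap_pool: list[DomainRecord]) -> DomainRecord:
        if overlap_pool and allow_overlap and rng.random() < 0.3:
            return overlap_pool[int(rng.integers(0, len(overlap_pool)))]
        x = int(rng.integers(1, n_groups + 1))
        tax = TaxonomyId(x, int(rng.integers(1, 3)), 1, int(rng.integers(1, 3)))
        return DomainRecord(
            domain_id=f"{prefix}{i}",
            pdb_id="0000",
            chain_id="A",
            release_date=None,
            n_residues=100,
            n_sse=5,
            taxonomy=tax,
        )

    library = [make("l", i, []) for i in range(nl)]
    # de-dup ids from the overlap trick
    queries: list[DomainRecord] = []
    seen: set[str] = set()
    for i in range(nq):
        d = make("q", i, library)
        if d.domain_id not in seen:
            seen.add(d.domain_id)
            queries.append(d)

    rows = []
    score_pool = [float(v) for v in rng.integers(0, 8, size=64)] if allow_ties else []
    for q in queries:
        for l in library:
            if rng.random() > score_fraction:
                continue
            if allow_ties:
                s = score_pool[int(rng.integers(0, len(score_pool)))]
            else:
                s = float(rng.standard_normal())
            rows.append((q.domain_id, l.domain_id, s))
    level = ["H", "X", "F"][int(rng.integers(0, 3))]
    return Benchmark.from_collections(
        queries, library, ScoreTable.from_records(rows), level=level
    )
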