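"""Synthetic benchmark generator.

Produces a self-contained cohort with the statistical structure the
evaluation pipeline assumes — a balanced 4-level taxonomy, pairwise
similarity scores whose distribution depends on how closely two domains
are related, predicted-structure scores degraded as model confidence
(pLDDT) drops, experimental-method labels, release dates spanning the
train/test cutoff, and a planted sequence-search hit list — together
with the ground truth needed to verify every downstream operation.

The score model draws each ordered query-library pair independently from
a normal distribution whose mean depends on the relationship level
(same family >= same H-group >= same X-group >= unrelated).  Predicted-
structure ("pred") scores take the experimental ("exp") draw and add a
confidence-dependent degradation

    pred = exp - gamma * (100 - pLDDT_q) * (1 + z),   z ~ N(0, 1)

i.e. a mean shift and a heteroscedastic noise term both proportional to
the query's missing confidence.  The noise term is what erodes
within-stratum separability (a pure shift would be absorbed by the
per-stratum threshold), producing the qualitative decline of F1 with
pLDDT; with gamma = 0 the two tables are identical.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datasets import HitList
from .evaluation import Benchmark, f_beta_max, pr_curve, top1_accuracy
from .io import (
    DomainRecord,
    ExperimentalMethod,
    ScoreTable,
    TaxonomyId,
    ValidationError,
    write_domain_table,
    write_score_table,
)

__all__ = [
    "RELATION_LEVELS",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticBenchmark",
    "WorkedExample",
    "generate_benchmark",
    "top1_truth",
    "generate_figure2_fixture",
    "generate_af_pdb_fixture",
    "generate_dssp_fixture",
    "write_benchmark_files",
]

RELATION_LEVELS = ("same_F", "same_H_diff_F", "same_X_diff_H", "diff_X")

_DEFAULT_SCORE_MODEL: dict[str, tuple[float, float]] = {
    "same_F": (12.0, 2.0),
    "same_H_diff_F": (8.0, 2.0),
    "same_X_diff_H": (4.0, 2.0),
    "diff_X": (0.0, 2.0),
}

_DEFAULT_METHOD_MIX: dict[ExperimentalMethod, float] = {
    ExperimentalMethod.XRAY: 0.7,
    ExperimentalMethod.NMR: 0.1,
    ExperimentalMethod.EM: 0.2,
}

_BIN_EDGES = ((50, 60), (60, 70), (70, 80), (80, 90), (90, 100))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of a synthetic benchmark.

    Defaults describe a modest cohort dominated by confident models and
    X-ray structures, with ~4-sd separation between homologous (same
    H-group) and unrelated score distributions.
    """

    n_x_groups: int = 6
    h_per_x: int = 2
    f_per_h: int = 2
    domains_per_f: int = 3
    score_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SCORE_MODEL)
    )
    plddt_bin_weights: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30, 0.35)
    gamma: float = 0.05
    method_mix: Mapping[ExperimentalMethod, float] = field(
        default_factory=lambda: dict(_DEFAULT_METHOD_MIX)
    )
    nmr_plddt_shift: float = 10.0
    date_start: _dt.date = _dt.date(2019, 1, 1)
    date_end: _dt.date = _dt.date(2022, 12, 31)
    cutoff_date: _dt.date = _dt.date(2021, 2, 15)
    test_fraction: float = 0.3
    no_hit_fraction: float = 0.16
    irregular_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (self.n_x_groups, self.h_per_x, self.f_per_h, self.domains_per_f):
            if name < 1:
                raise ValidationError("taxonomy shape parameters must be >= 1")
        missing = set(RELATION_LEVELS) - set(self.score_model)
        if missing:
            raise ValidationError(f"score_model missing levels: {sorted(missing)}")
        means = [self.score_model[lvl][0] for lvl in RELATION_LEVELS]
        if not all(a >= b for a, b in zip(means, means[1:])):
            raise ValidationError(
                "score means must be ordered same_F >= same_H_diff_F >= "
                f"same_X_diff_H >= diff_X, got {means}"
            )
        if any(self.score_model[lvl][1] <= 0 for lvl in RELATION_LEVELS):
            raise ValidationError("score standard deviations must be positive")
        if len(self.plddt_bin_weights) != 5 or any(
            w < 0 for w in self.plddt_bin_weights
        ):
            raise ValidationError("plddt_bin_weights must be five non-negative weights")
        if abs(sum(self.plddt_bin_weights) - 1.0) > 1e-9:
            raise ValidationError("plddt_bin_weights must sum to 1")
        if abs(sum(self.method_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("method_mix must sum to 1")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if not self.date_start < self.cutoff_date <= self.date_end:
            raise ValidationError("date_range must span the cutoff date")
        for frac in (self.test_fraction, self.no_hit_fraction, self.irregular_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must be in [0, 1]")

    @property
    def n_domains(self) -> int:
        return self.n_x_groups * self.h_per_x * self.f_per_h * self.domains_per_f


@dataclass
class SyntheticTruth:
    """Planted ground truth, recomputable from (config, seed) alone."""

    taxonomy: dict[str, TaxonomyId]
    irregular_ids: list[str]
    regular_ids: list[str]
    train_ids: list[str]  # regular domains released before the cutoff
    test_ids: list[str]
    no_hit_ids: list[str]  # regular test domains with no planted hit below E threshold
    plddt_bins: dict[str, list[str]]  # bin label -> regular domain ids
    below_50_ids: list[str]
    method_ids: dict[ExperimentalMethod, list[str]]
    top1_accuracy_exp: float
    f1_exp: float


@dataclass
class SyntheticBenchmark:
    config: SyntheticConfig
    domains: list[DomainRecord]
    scores_exp: ScoreTable
    scores_pred: ScoreTable
    hits: HitList
    truth: SyntheticTruth

    def benchmark(
        self, structures: str = "exp", level: str = "H"
    ) -> Benchmark:
        """All-vs-all benchmark over the generated cohort."""
        scores = self.scores_exp if structures == "exp" else self.scores_pred
        return Benchmark.from_collections(self.domains, self.domains, scores, level)


def _component_rngs(seed: int) -> dict[str, np.random.Generator]:
    # one sub-stream per component so regenerating one leaves others intact
    names = ["sizes", "dates", "methods", "plddt", "scores", "degrade", "hits", "flaws"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


_B36 = "0123456789abcdefghijklmnopqrstuvwxyz"


def _pseudo_pdb_id(i: int) -> str:
    out = ""
    for _ in range(4):
        out = _B36[i % 36] + out
        i //= 36
    return out


def generate_benchmark(cfg: SyntheticConfig) -> SyntheticBenchmark:
    """Generate the full cohort, score tables, hit list and ground truth.

    Deterministic given ``cfg`` (which includes the master seed).
    """
    rngs = _component_rngs(cfg.seed)
    n = cfg.n_domains

    # balanced taxonomy tree: X.H.1.F
    x_idx = np.repeat(
        np.arange(cfg.n_x_groups), cfg.h_per_x * cfg.f_per_h * cfg.domains_per_f
    )
    h_idx = np.tile(
        np.repeat(np.arange(cfg.h_per_x), cfg.f_per_h * cfg.domains_per_f),
        cfg.n_x_groups,
    )
    f_idx = np.tile(
        np.repeat(np.arange(cfg.f_per_h), cfg.domains_per_f),
        cfg.n_x_groups * cfg.h_per_x,
    )
    ids = [f"d{i:05d}" for i in range(n)]
    taxonomy = {
        ids[i]: TaxonomyId(int(x_idx[i]) + 1, int(h_idx[i]) + 1, 1, int(f_idx[i]) + 1)
        for i in range(n)
    }

    # sizes and planted regularity violations
    n_res = rngs["sizes"].integers(60, 301, size=n)
    n_sse = rngs["sizes"].integers(4, 13, size=n)
    obsolete = np.zeros(n, dtype=bool)
    irregular = rngs["flaws"].random(n) < cfg.irregular_fraction
    flaw_kind = rngs["flaws"].integers(0, 3, size=n)
    for i in np.flatnonzero(irregular):
        if flaw_kind[i] == 0:
            n_res[i] = rngs["flaws"].integers(20, 40)
        elif flaw_kind[i] == 1:
            n_sse[i] = rngs["flaws"].integers(0, 4)
        else:
            obsolete[i] = True

    # release dates: Bernoulli(test_fraction) picks the side of the cutoff
    is_test = rngs["dates"].random(n) < cfg.test_fraction
    span_train = (cfg.cutoff_date - cfg.date_start).days  # train: [start, cutoff)
    span_test = (cfg.date_end - cfg.cutoff_date).days + 1  # test: [cutoff, end]
    dates = []
    for i in range(n):
        if is_test[i]:
            off = int(rngs["dates"].integers(0, span_test))
            dates.append(cfg.cutoff_date + _dt.timedelta(days=off))
        else:
            off = int(rngs["dates"].integers(0, span_train))
            dates.append(cfg.date_start + _dt.timedelta(days=off))

    # experimental methods
    methods_order = list(cfg.method_mix)
    probs = np.array([cfg.method_mix[m] for m in methods_order])
    method_draw = rngs["methods"].choice(len(methods_order), size=n, p=probs)
    methods = [methods_order[k] for k in method_draw]

    # mean pLDDT: mixture over the five decade bins, uniform within a bin,
    # shifted down for NMR-determined domains
    bin_draw = rngs["plddt"].choice(5, size=n, p=np.asarray(cfg.plddt_bin_weights))
    u = rngs["plddt"].random(n)
    plddt = np.array(
        [lo + (hi - lo) * u[i] for i, (lo, hi) in enumerate(_BIN_EDGES[b] for b in bin_draw)]
    )
    for i in range(n):
        if methods[i] == ExperimentalMethod.NMR:
            plddt[i] = max(plddt[i] - cfg.nmr_plddt_shift, 30.0)

    domains = [
        DomainRecord(
            domain_id=ids[i],
            pdb_id=_pseudo_pdb_id(i),
            chain_id="A",
            uniprot_ac=f"P{i:05d}",
            release_date=dates[i],
            n_residues=int(n_res[i]),
            n_sse=int(n_sse[i]),
            experimental_method=methods[i],
            taxonomy=taxonomy[ids[i]],
            mean_plddt=float(plddt[i]),
            obsolete=bool(obsolete[i]),
        )
        for i in range(n)
    ]

    # pairwise scores for every ordered non-identical pair
    same_x = x_idx[:, None] == x_idx[None, :]
    same_h = same_x & (h_idx[:, None] == h_idx[None, :])
    same_f = same_h & (f_idx[:, None] == f_idx[None, :])
    relation = np.full((n, n), 3)  # diff_X
    relation[same_x] = 2
    relation[same_h] = 1
    relation[same_f] = 0
    means = np.array([cfg.score_model[lvl][0] for lvl in RELATION_LEVELS])
    sds = np.array([cfg.score_model[lvl][1] for lvl in RELATION_LEVELS])
    base = means[relation] + sds[relation] * rngs["scores"].standard_normal((n, n))
    deficit = 100.0 - plddt  # per query
    degrade = cfg.gamma * deficit[:, None] * (
        1.0 + rngs["degrade"].standard_normal((n, n))
    )
    pred = base - degrade

    off_diag = ~np.eye(n, dtype=bool)
    qi, li = np.nonzero(off_diag)
    id_arr = np.array(ids)
    scores_exp = ScoreTable.from_records(
        list(zip(id_arr[qi], id_arr[li], base[qi, li]))
    )
    scores_pred = ScoreTable.from_records(
        list(zip(id_arr[qi], id_arr[li], pred[qi, li]))
    )

    # planted sequence-search hit list: test domains may lack a close hit
    hits = HitList()
    no_hit = np.zeros(n, dtype=bool)
    for i in range(n):
        if is_test[i] and rngs["hits"].random() < cfg.no_hit_fraction:
            no_hit[i] = True
            if rngs["hits"].random() < 0.5:  # distant hit at E >= 0.001
                e = float(np.exp(rngs["hits"].uniform(math.log(1e-3), math.log(10.0))))
                hits[ids[i]] = [(f"pdbseq{i}", max(e, 1e-3))]
            # else: absent from the hit list entirely
        else:
            e = float(np.exp(rngs["hits"].uniform(math.log(1e-30), math.log(1e-4))))
            hits[ids[i]] = [(f"pdbseq{i}", e)]

    regular = ~irregular
    regular_ids = [ids[i] for i in np.flatnonzero(regular)]
    train_ids = [ids[i] for i in np.flatnonzero(regular & ~is_test)]
    test_ids = [ids[i] for i in np.flatnonzero(regular & is_test)]
    no_hit_ids = [ids[i] for i in np.flatnonzero(regular & is_test & no_hit)]
    plddt_bins: dict[str, list[str]] = {f"{lo}-{hi}": [] for lo, hi in _BIN_EDGES}
    below_50: list[str] = []
    for i in np.flatnonzero(regular):
        p = plddt[i]
        if p < 50:
            below_50.append(ids[i])
        elif p >= 90:
            plddt_bins["90-100"].append(ids[i])
        else:
            lo = 10 * int(p // 10)
            plddt_bins[f"{lo}-{lo + 10}"].append(ids[i])
    method_ids: dict[ExperimentalMethod, list[str]] = {
        m: [] for m in ExperimentalMethod
    }
    for i in np.flatnonzero(regular):
        method_ids[methods[i]].append(ids[i])

    full = Benchmark.from_collections(domains, domains, scores_exp, level="H")
    truth = SyntheticTruth(
        taxonomy=taxonomy,
        irregular_ids=[ids[i] for i in np.flatnonzero(irregular)],
        regular_ids=regular_ids,
        train_ids=train_ids,
        test_ids=test_ids,
        no_hit_ids=no_hit_ids,
        plddt_bins=plddt_bins,
        below_50_ids=below_50,
        method_ids=method_ids,
        top1_accuracy_exp=top1_accuracy(full).accuracy,
        f1_exp=f_beta_max(pr_curve(full), 1.0)[0],
    )
    return SyntheticBenchmark(cfg, domains, scores_exp, scores_pred, hits, truth)


def top1_truth(
    cfg: SyntheticConfig, level: str = "H", n_draws: int = 200_000, seed: int = 12345
) -> float:
    """Large-sample top-1 accuracy implied by the generative model.

    For a balanced taxonomy every query faces the same library
    composition (counts of same-family, same-H, same-X and unrelated
    partners), so the probability that the best-scoring partner is a
    homolog is a fixed functional of the score model; it is estimated by
    Monte Carlo with ``n_draws`` independent query draws.
    """
    k_f = cfg.domains_per_f - 1
    k_h = (cfg.f_per_h - 1) * cfg.domains_per_f
    k_x = (cfg.h_per_x - 1) * cfg.f_per_h * cfg.domains_per_f
    k_d = cfg.n_domains - cfg.h_per_x * cfg.f_per_h * cfg.domains_per_f
    counts = dict(zip(RELATION_LEVELS, (k_f, k_h, k_x, k_d)))
    if level == "H":
        pos_levels = {"same_F", "same_H_diff_F"}
    elif level == "X":
        pos_levels = {"same_F", "same_H_diff_F", "same_X_diff_H"}
    elif level == "F":
        pos_levels = {"same_F"}
    else:
        raise ValueError(f"unknown level {level!r}")

    rng = np.random.default_rng(seed)
    pos_max = np.full(n_draws, -np.inf)
    neg_max = np.full(n_draws, -np.inf)
    for lvl in RELATION_LEVELS:
        k = counts[lvl]
        if k == 0:
            continue
        mean, sd = cfg.score_model[lvl]
        m = (mean + sd * rng.standard_normal((n_draws, k))).max(axis=1)
        if lvl in pos_levels:
            pos_max = np.maximum(pos_max, m)
        else:
            neg_max = np.maximum(neg_max, m)
    return float(np.mean(pos_max > neg_max))


@dataclass
class WorkedExample:
    """A tiny two-query, six-library benchmark with a depicted threshold."""

    benchmark: Benchmark
    threshold: float


def generate_figure2_fixture() -> WorkedExample:
    """The worked toy example: |Q| = 2 over two families, |L| = 6 over three.

    Scores are arranged so q1's best partner shares its family while q2's
    does not (top-1 accuracy 1/2), and so that at the depicted threshold
    exactly 5 of the 12 evaluated pairs score above it, 2 of them
    same-family (precision 2/5, recall 2/4).
    """
    fam1 = TaxonomyId(1, 1, 1, 1)
    fam2 = TaxonomyId(2, 1, 1, 1)
    fam3 = TaxonomyId(3, 1, 1, 1)

    def dom(did: str, tax: TaxonomyId) -> DomainRecord:
        return DomainRecord(
            domain_id=did,
            pdb_id="0000",
            chain_id="A",
            release_date=_dt.date(2020, 1, 1),
            n_residues=100,
            n_sse=5,
            taxonomy=tax,
        )

    queries = [dom("q1", fam1), dom("q2", fam2)]
    library = [
        dom("l1", fam1),
        dom("l2", fam1),
        dom("l3", fam2),
        dom("l4", fam2),
        dom("l5", fam3),
        dom("l6", fam3),
    ]
    scores = ScoreTable.from_records(
        [
            ("q1", "l1", 10.0),
            ("q1", "l2", 5.0),
            ("q1", "l3", 6.0),
            ("q1", "l4", 2.0),
            ("q1", "l5", 1.0),
            ("q1", "l6", 1.0),
            ("q2", "l1", 1.0),
            ("q2", "l2", 1.0),
            ("q2", "l3", 7.0),
            ("q2", "l4", 2.0),
            ("q2", "l5", 9.0),
            ("q2", "l6", 6.5),
        ]
    )
    bench = Benchmark.from_collections(queries, library, scores, level="F")
    return WorkedExample(benchmark=bench, threshold=5.0)


def generate_af_pdb_fixture(
    n_res: int, plddt_values: Sequence[float], path: str | Path
) -> Path:
    """Write a minimal PDB model with one CA per residue, B-factor = pLDDT."""
    if len(plddt_values) != n_res:
        raise ValidationError(
            f"expected {n_res} pLDDT values, got {len(plddt_values)}"
        )
    for v in plddt_values:
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"pLDDT {v} out of [0,100]")
    path = Path(path)
    with open(path, "w") as fh:
        for i, b in enumerate(plddt_values):
            x = 3.8 * i
            fh.write(
                f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
                f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{b:6.2f}           C\n"
            )
        fh.write("END\n")
    return path


_SS_EXPAND = {"H": "HGI", "E": "EB", "C": " TS"}


def generate_dssp_fixture(
    labels: Sequence[str], path: str | Path, seed: int = 0
) -> Path:
    """Write a DSSP-format file whose parsed 3-state labels equal ``labels``.

    Each 3-state label is expanded to a randomly chosen 8-state code
    within its class (e.g. H -> one of H/G/I).
    """
    rng = np.random.default_rng(seed)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("==== Secondary Structure Definition (synthetic fixture) ====\n")
        fh.write(
            "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
            "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI\n"
        )
        for i, lab in enumerate(labels):
            if lab not in _SS_EXPAND:
                raise ValidationError(f"unknown 3-state label {lab!r}")
            code = _SS_EXPAND[lab][rng.integers(0, len(_SS_EXPAND[lab]))]
            fh.write(f"{i + 1:5d}{i + 1:5d} A A  {code}\n")
    return path


def write_benchmark_files(synth: SyntheticBenchmark, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as the on-disk fixtures the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "domains": outdir / "domains.tsv",
        "scores_exp": outdir / "scores_exp.tsv",
        "scores_pred": outdir / "scores_pred.tsv",
        "hits": outdir / "hits.tsv",
    }
    write_domain_table(synth.domains, paths["domains"])
    write_score_table(synth.scores_exp, paths["scores_exp"])
    write_score_table(synth.scores_pred, paths["scores_pred"])
    with open(paths["hits"], "w") as fh:
        fh.write("query_id\tsubject_id\te_value\n")
        for q, entries in synth.hits.items():
            for subject, e in entries:
                fh.write(f"{q}\t{subject}\t{e:.6g}\n")
    return paths
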