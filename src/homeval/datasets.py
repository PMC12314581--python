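"""Dataset construction and stratification.

Implements the benchmark cohort rules: the regularity filter (length and
secondary-structure-element floors, obsolete entries dropped), the
predicted-model correspondence filter, the release-date train/test split
around the 2021-02-15 template cutoff, "no sequence hit" query subsets,
stratification by residue-averaged pLDDT and by experimental method, and
secondary-structure composition summaries.

Boundary semantics follow the construction rules exactly: the residue,
SSE, identity, aligned-ratio and aligned-length floors are inclusive
("not less than"), while a sequence hit excludes a query only when its
E-value is strictly below the threshold.
"""

from __future__ import annotations

import datetime as _dt
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import Align

from .io import DomainRecord, ExperimentalMethod, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "SplitConfig",
    "HitList",
    "CorrespondenceAlignment",
    "PLDDT_BINS",
    "filter_regular",
    "correspondence_filter",
    "align_for_correspondence",
    "split_by_release_date",
    "no_hit_subset",
    "stratify_by_plddt",
    "stratify_by_method",
    "normalize_method",
    "ss_composition",
    "count_sse",
    "parse_hit_list",
    "write_id_list",
]


@dataclass(frozen=True)
class SplitConfig:
    """Release-date cutoff and sequence-hit E-value threshold."""

    cutoff_date: _dt.date = _dt.date(2021, 2, 15)
    evalue_threshold: float = 0.001

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")


class HitList(dict):
    """query_id -> list of (subject_id, e_value) from a sequence/HMM search."""

    def best_evalue(self, query_id: str) -> float | None:
        hits = self.get(query_id)
        if not hits:
            return None
        return min(e for _, e in hits)


@dataclass(frozen=True)
class CorrespondenceAlignment:
    """Alignment statistics between a classified domain and a predicted model."""

    ecod_domain_id: str
    model_id: str
    n_identical: int
    n_aligned: int
    ecod_length: int

    def __post_init__(self) -> None:
        if self.ecod_length < 1:
            raise ValueError("ecod_length must be >= 1")
        if not 0 <= self.n_identical <= self.n_aligned:
            raise ValueError("need 0 <= n_identical <= n_aligned")


class FilterReport(NamedTuple):
    kept: list[DomainRecord]
    rejected: dict[str, list[str]]  # domain_id -> failing criteria


def filter_regular(
    domains: Iterable[DomainRecord],
    min_residues: int = 40,
    min_sse: int = 4,
) -> FilterReport:
    """Keep domains with >= 40 residues, >= 4 SSEs, and a live PDB entry.

    Both floors are inclusive.  The report lists every failing criterion
    per rejected domain.
    """
    kept: list[DomainRecord] = []
    rejected: dict[str, list[str]] = {}
    for d in domains:
        reasons = []
        if d.n_residues < min_residues:
            reasons.append(f"n_residues {d.n_residues} < {min_residues}")
        if d.n_sse < min_sse:
            reasons.append(f"n_sse {d.n_sse} < {min_sse}")
        if d.obsolete:
            reasons.append("obsolete PDB entry")
        if reasons:
            rejected[d.domain_id] = reasons
        else:
            kept.append(d)
    return FilterReport(kept, rejected)


def correspondence_filter(
    aln: CorrespondenceAlignment,
    min_identity: float = 0.95,
    min_aligned_ratio: float = 0.95,
    min_aligned: int = 40,
) -> tuple[bool, str]:
    """Accept a predicted model for a domain when the alignment is near-exact.

    Requires identity (n_identical/n_aligned) >= 0.95, aligned ratio
    (n_aligned/ecod_length) >= 0.95, and >= 40 aligned residues, all
    inclusive.  The aligned ratio is not capped at 1 (insertions in the
    model may push n_aligned above the domain length).
    """
    if aln.n_aligned == 0:
        return False, "zero aligned residues"
    identity = aln.n_identical / aln.n_aligned
    ratio = aln.n_aligned / aln.ecod_length
    if identity < min_identity:
        return False, f"identity {identity:.4f} < {min_identity}"
    if ratio < min_aligned_ratio:
        return False, f"aligned ratio {ratio:.4f} < {min_aligned_ratio}"
    if aln.n_aligned < min_aligned:
        return False, f"aligned residues {aln.n_aligned} < {min_aligned}"
    return True, "accepted"


def align_for_correspondence(
    ecod_domain_id: str,
    ecod_seq: str,
    model_id: str,
    model_seq: str,
    match_score: float = 1.0,
    mismatch_score: float = 0.0,
    open_gap_score: float = -2.0,
    extend_gap_score: float = -0.5,
) -> CorrespondenceAlignment:
    """Global (Needleman-Wunsch) alignment statistics for the model filter."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match_score
    aligner.mismatch_score = mismatch_score
    aligner.open_gap_score = open_gap_score
    aligner.extend_gap_score = extend_gap_score
    aln = aligner.align(ecod_seq, model_seq)[0]
    n_aligned = n_identical = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        n_aligned += a_end - a_start
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            n_identical += ecod_seq[i] == model_seq[j]
    return CorrespondenceAlignment(
        ecod_domain_id=ecod_domain_id,
        model_id=model_id,
        n_identical=n_identical,
        n_aligned=n_aligned,
        ecod_length=len(ecod_seq),
    )


class DateSplit(NamedTuple):
    train: list[DomainRecord]
    test: list[DomainRecord]
    undated: list[DomainRecord]


def split_by_release_date(
    domains: Iterable[DomainRecord], cfg: SplitConfig = SplitConfig()
) -> DateSplit:
    """Partition into train (released strictly before the cutoff) and test.

    The cutoff day itself goes to the test set, mirroring the
    template-cutoff semantics of the structure predictor ("templates
    released before" the cutoff were available for training).  Domains
    without a release date are reported separately.
    """
    train: list[DomainRecord] = []
    test: list[DomainRecord] = []
    undated: list[DomainRecord] = []
    for d in domains:
        if d.release_date is None:
            undated.append(d)
        elif d.release_date < cfg.cutoff_date:
            train.append(d)
        else:
            test.append(d)
    if undated:
        logger.warning("%d domains had no release date and were excluded", len(undated))
    return DateSplit(train, test, undated)


def no_hit_subset(
    test_ids: Iterable[str],
    hits: HitList | Sequence[HitList],
    threshold: float = 0.001,
) -> list[str]:
    """Queries with no sequence hit at E-value strictly below the threshold.

    A query is removed only when some supplied hit list contains a hit
    with E < threshold; queries absent from every list are kept.  Passing
    several hit lists keeps only queries that survive all of them (e.g.
    no sequence hit *and* no profile hit).
    """
    hit_lists = [hits] if isinstance(hits, HitList) else list(hits)
    kept = []
    for q in test_ids:
        best = [
            e for hl in hit_lists if (e := hl.best_evalue(q)) is not None
        ]
        if not best or min(best) >= threshold:
            kept.append(q)
    return kept


PLDDT_BINS = ("50-60", "60-70", "70-80", "80-90", "90-100")


class PlddtStrata(NamedTuple):
    bins: dict[str, list[DomainRecord]]
    below_50: list[DomainRecord]
    no_model: list[DomainRecord]


def stratify_by_plddt(domains: Iterable[DomainRecord]) -> PlddtStrata:
    """Partition by residue-averaged pLDDT into the five decade bins.

    Bins are half-open [lo, hi) except the top bin, which is closed at
    100.  Domains with mean pLDDT below 50 and domains without a model
    (no pLDDT) are reported separately.
    """
    bins: dict[str, list[DomainRecord]] = {b: [] for b in PLDDT_BINS}
    below: list[DomainRecord] = []
    no_model: list[DomainRecord] = []
    for d in domains:
        p = d.mean_plddt
        if p is None:
            no_model.append(d)
        elif p < 50:
            below.append(d)
        elif p >= 90:
            bins["90-100"].append(d)
        else:
            lo = 10 * int(p // 10)
            bins[f"{lo}-{lo + 10}"].append(d)
    return PlddtStrata(bins, below, no_model)


_METHOD_MAP = {
    "X-RAY DIFFRACTION": ExperimentalMethod.XRAY,
    "XRAY": ExperimentalMethod.XRAY,
    "X-RAY": ExperimentalMethod.XRAY,
    "SOLUTION NMR": ExperimentalMethod.NMR,
    "SOLID-STATE NMR": ExperimentalMethod.NMR,
    "NMR": ExperimentalMethod.NMR,
    "ELECTRON MICROSCOPY": ExperimentalMethod.EM,
    "EM": ExperimentalMethod.EM,
}


def normalize_method(method: str | ExperimentalMethod) -> ExperimentalMethod:
    """Map a deposition method string to {XRAY, NMR, EM, OTHER}."""
    if isinstance(method, ExperimentalMethod):
        return method
    return _METHOD_MAP.get(method.strip().upper(), ExperimentalMethod.OTHER)


def stratify_by_method(
    domains: Iterable[DomainRecord],
) -> dict[ExperimentalMethod, list[DomainRecord]]:
    """Disjoint partition by experimental method."""
    out: dict[ExperimentalMethod, list[DomainRecord]] = {
        m: [] for m in ExperimentalMethod
    }
    for d in domains:
        out[d.experimental_method].append(d)
    return out


def ss_composition(labels: Sequence[str]) -> tuple[float, float, float]:
    """(helix, strand, coil) fractions of a 3-state label sequence; sums to 1."""
    if not labels:
        raise ValueError("empty label list")
    counts = Counter(labels)
    bad = set(counts) - {"H", "E", "C"}
    if bad:
        raise ValueError(f"unknown secondary-structure labels: {sorted(bad)}")
    n = len(labels)
    return counts["H"] / n, counts["E"] / n, counts["C"] / n


def count_sse(labels: Sequence[str], min_run: int = 3) -> int:
    """Number of secondary-structure elements in a 3-state label sequence.

    An element is a maximal run of consecutive identical H or E labels of
    length >= min_run.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if not labels:
        raise ValueError("empty label list")
    n = 0
    run_char, run_len = None, 0
    for c in list(labels) + [None]:
        if c == run_char:
            run_len += 1
            continue
        if run_char in ("H", "E") and run_len >= min_run:
            n += 1
        run_char, run_len = c, 1
    return n


def parse_hit_list(path: str | Path, dialect: str = "blast6") -> HitList:
    """Read a sequence-search hit list.

    ``dialect="blast6"`` expects 12-column tabular output (query, subject,
    ..., e-value in column 11); ``dialect="tsv"`` a 3-column
    query/subject/e-value table with header.
    """
    path = Path(path)
    hits = HitList()
    with open(path) as fh:
        if dialect == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["query_id", "subject_id", "e_value"]:
                raise FormatError(
                    f"{path}: expected header query_id/subject_id/e_value"
                )
        for lineno, line in enumerate(fh, start=2 if dialect == "tsv" else 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "blast6":
                    if len(fields) < 11:
                        raise ValueError("fewer than 11 columns")
                    query, subject, evalue = fields[0], fields[1], float(fields[10])
                elif dialect == "tsv":
                    query, subject, evalue = fields[0], fields[1], float(fields[2])
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if evalue <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive E-value {evalue}")
            hits.setdefault(query, []).append((subject, evalue))
    return hits


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    """Write subset membership as one domain id per line."""
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
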