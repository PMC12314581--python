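"""Readers and writers for domain metadata, taxonomy strings, score tables,
AlphaFold-style pLDDT and DSSP secondary-structure files.

The canonical on-disk dialect for domain metadata and score tables is a
TSV with a header row.  An adapter for ECOD-style ``*.domains.txt``
listings is provided on a best-effort basis (``dialect="ecod"``).
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentalMethod",
    "TaxonomyId",
    "DomainRecord",
    "ScoreRecord",
    "ScoreTable",
    "PlddtProfile",
    "FormatError",
    "ValidationError",
    "parse_taxonomy",
    "parse_domain_table",
    "write_domain_table",
    "parse_score_table",
    "write_score_table",
    "extract_plddt",
    "parse_dssp_ss",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input violating a semantic constraint (e.g. duplicate IDs)."""


class ExperimentalMethod(str, Enum):
    XRAY = "XRAY"
    NMR = "NMR"
    EM = "EM"
    OTHER = "OTHER"


class TaxonomyId(NamedTuple):
    """A four-level hierarchical classification identifier X.H.T.F.

    X groups possible homology, H confirmed homology, T topology and F
    family, written as dotted positive integers, e.g. ``3240.1.1.2``.
    """

    x_id: int
    h_id: int
    t_id: int
    f_id: int

    def __str__(self) -> str:
        return f"{self.x_id}.{self.h_id}.{self.t_id}.{self.f_id}"


_TAX_RE = re.compile(r"^(\d+)\.(\d+)\.(\d+)\.(\d+)$")


def parse_taxonomy(s: str) -> TaxonomyId:
    """Parse a dotted 4-level identifier such as ``"3240.1.1.2"``.

    Raises :class:`FormatError` if the string is not four dot-separated
    positive integers.
    """
    m = _TAX_RE.match(s.strip())
    if m is None:
        raise FormatError(f"not a 4-level dotted taxonomy id: {s!r}")
    parts = tuple(int(g) for g in m.groups())
    if any(p < 1 for p in parts):
        raise FormatError(f"taxonomy components must be >= 1: {s!r}")
    return TaxonomyId(*parts)


@dataclass
class DomainRecord:
    """One classified protein domain with the metadata evaluation needs."""

    domain_id: str
    pdb_id: str
    chain_id: str
    release_date: _dt.date | None
    n_residues: int
    taxonomy: TaxonomyId
    n_sse: int = 0
    uniprot_ac: str | None = None
    experimental_method: ExperimentalMethod = ExperimentalMethod.OTHER
    mean_plddt: float | None = None
    obsolete: bool = False

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValidationError(
                f"{self.domain_id}: n_residues must be >= 1, got {self.n_residues}"
            )
        if self.n_sse < 0:
            raise ValidationError(f"{self.domain_id}: n_sse must be >= 0")
        if self.mean_plddt is not None and not 0.0 <= self.mean_plddt <= 100.0:
            raise ValidationError(
                f"{self.domain_id}: mean_plddt out of [0,100]: {self.mean_plddt}"
            )


class ScoreRecord(NamedTuple):
    query_id: str
    library_id: str
    score: float


@dataclass
class ScoreTable:
    """Pairwise (query, library, score) records for one comparison method.

    Scores are stored post-transform: higher always means more similar.
    Backed by a DataFrame with columns ``query_id, library_id, score``.
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["query_id", "library_id", "score"]
        )
    )

    def __post_init__(self) -> None:
        missing = {"query_id", "library_id", "score"} - set(self.frame.columns)
        if missing:
            raise ValidationError(f"score table missing columns: {sorted(missing)}")
        scores = self.frame["score"].to_numpy(dtype=float)
        if scores.size and not np.all(np.isfinite(scores)):
            raise ValidationError("score table contains non-finite scores")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "ScoreTable":
        frame = pd.DataFrame(records, columns=["query_id", "library_id", "score"])
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield ScoreRecord(row.query_id, row.library_id, float(row.score))

    def score_of(self, query_id: str, library_id: str) -> float | None:
        sel = self.frame[
            (self.frame["query_id"] == query_id)
            & (self.frame["library_id"] == library_id)
        ]
        if sel.empty:
            return None
        return float(sel["score"].iloc[-1])


@dataclass
class PlddtProfile:
    """Per-residue predicted-confidence (pLDDT) values for one domain, 0-100."""

    domain_id: str
    per_residue: list[float]

    def __post_init__(self) -> None:
        if not self.per_residue:
            raise ValidationError(f"{self.domain_id}: empty pLDDT profile")
        for v in self.per_residue:
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{self.domain_id}: pLDDT {v} out of [0,100]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_residue))


# ---------------------------------------------------------------------------
# domain metadata tables

_DOMAIN_COLUMNS = [
    "domain_id",
    "pdb_id",
    "chain_id",
    "uniprot_ac",
    "release_date",
    "n_residues",
    "n_sse",
    "experimental_method",
    "taxonomy",
    "mean_plddt",
    "obsolete",
]

_REQUIRED_DOMAIN_COLUMNS = {
    "domain_id",
    "pdb_id",
    "chain_id",
    "release_date",
    "n_residues",
    "taxonomy",
}


def _parse_date(s: str) -> _dt.date | None:
    s = s.strip()
    if not s or s.lower() in {"na", "none", "-"}:
        return None
    return _dt.date.fromisoformat(s)


def parse_domain_table(path: str | Path, dialect: str = "tsv") -> list[DomainRecord]:
    """Read a domain metadata table.

    ``dialect="tsv"`` is the canonical TSV-with-header layout written by
    :func:`write_domain_table`.  ``dialect="ecod"`` accepts an ECOD-style
    ``domains.txt`` listing on a best-effort basis (comment lines starting
    with ``#``; columns uid, ecod_domain_id, manual_rep, f_id, pdb, chain,
    ...); metadata absent from that format is left at defaults.
    Malformed rows raise :class:`FormatError` with their line number.
    """
    path = Path(path)
    if dialect == "tsv":
        return _parse_domain_tsv(path)
    if dialect == "ecod":
        return _parse_ecod_listing(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _parse_domain_tsv(path: Path) -> list[DomainRecord]:
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        missing = _REQUIRED_DOMAIN_COLUMNS - set(header)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        idx = {name: i for i, name in enumerate(header)}
        records: list[DomainRecord] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )

            def get(col: str, default: str = "") -> str:
                return fields[idx[col]] if col in idx else default

            try:
                rec = DomainRecord(
                    domain_id=get("domain_id"),
                    pdb_id=get("pdb_id"),
                    chain_id=get("chain_id"),
                    uniprot_ac=get("uniprot_ac") or None,
                    release_date=_parse_date(get("release_date")),
                    n_residues=int(get("n_residues")),
                    n_sse=int(get("n_sse") or 0),
                    experimental_method=ExperimentalMethod(
                        get("experimental_method") or "OTHER"
                    ),
                    taxonomy=parse_taxonomy(get("taxonomy")),
                    mean_plddt=float(get("mean_plddt")) if get("mean_plddt") else None,
                    obsolete=get("obsolete", "0").strip().lower() in {"1", "true", "yes"},
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if rec.domain_id in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate domain_id {rec.domain_id!r}"
                )
            seen.add(rec.domain_id)
            records.append(rec)
    return records


def _parse_ecod_listing(path: Path) -> list[DomainRecord]:
    # Best-effort adapter for the public ECOD domains.txt column convention:
    # uid  ecod_domain_id  manual_rep  f_id  pdb  chain  pdb_range  seqid_range ...
    records: list[DomainRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 tab-separated fields")
            domain_id, f_id, pdb, chain = fields[1], fields[3], fields[4], fields[5]
            try:
                taxonomy = parse_taxonomy(f_id)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            n_residues = _ecod_range_length(fields[7]) if len(fields) > 7 else 1
            if domain_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate domain_id {domain_id!r}")
            seen.add(domain_id)
            records.append(
                DomainRecord(
                    domain_id=domain_id,
                    pdb_id=pdb,
                    chain_id=chain,
                    release_date=None,
                    n_residues=max(n_residues, 1),
                    taxonomy=taxonomy,
                )
            )
    return records


def _ecod_range_length(seqid_range: str) -> int:
    total = 0
    for part in seqid_range.split(","):
        m = re.search(r"(-?\d+)-(-?\d+)$", part.split(":")[-1])
        if m:
            total += int(m.group(2)) - int(m.group(1)) + 1
    return total


def write_domain_table(records: Sequence[DomainRecord], path: str | Path) -> None:
    """Write records in the canonical TSV dialect (round-trips with the parser)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_DOMAIN_COLUMNS) + "\n")
        for r in records:
            fields = [
                r.domain_id,
                r.pdb_id,
                r.chain_id,
                r.uniprot_ac or "",
                r.release_date.isoformat() if r.release_date else "",
                str(r.n_residues),
                str(r.n_sse),
                r.experimental_method.value,
                str(r.taxonomy),
                f"{r.mean_plddt:.6f}" if r.mean_plddt is not None else "",
                "1" if r.obsolete else "0",
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# score tables


def parse_score_table(path: str | Path) -> ScoreTable:
    """Read a pairwise score TSV with columns query_id, library_id, score.

    Duplicate (query, library) pairs are collapsed to the last occurrence
    with a logged warning.  A non-numeric score raises :class:`FormatError`
    with its line number.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        missing = {"query_id", "library_id", "score"} - set(header)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        idx = {name: i for i, name in enumerate(header)}
        rows: list[tuple[str, str, float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                score = float(fields[idx["score"]])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: bad score field: {exc}") from exc
            if not math.isfinite(score):
                raise FormatError(f"{path}:{lineno}: non-finite score {score}")
            rows.append((fields[idx["query_id"]], fields[idx["library_id"]], score))
    frame = pd.DataFrame(rows, columns=["query_id", "library_id", "score"])
    dup = frame.duplicated(subset=["query_id", "library_id"], keep="last")
    if dup.any():
        logger.warning(
            "%s: %d duplicate (query, library) pairs; keeping the last occurrence",
            path,
            int(dup.sum()),
        )
        frame = frame[~dup].reset_index(drop=True)
    return ScoreTable(frame)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# structural files


def extract_plddt(
    pdb_path: str | Path,
    residue_selection: Sequence[int] | None = None,
    domain_id: str | None = None,
) -> PlddtProfile:
    """Read per-residue pLDDT from the B-factor column of a PDB-format model.

    AlphaFold-style models store the residue's pLDDT in every atom's
    B-factor; the CA atom is read as the single per-residue value.
    ``residue_selection`` restricts to the given residue sequence numbers.
    """
    pdb_path = Path(pdb_path)
    structure = gemmi.read_pdb(str(pdb_path))
    wanted = set(residue_selection) if residue_selection is not None else None
    values: list[float] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                if wanted is not None and residue.seqid.num not in wanted:
                    continue
                ca = residue.find_atom("CA", "*")
                if ca is not None:
                    values.append(float(ca.b_iso))
        break  # first model only
    if not values:
        if wanted is not None:
            raise ValidationError(
                f"{pdb_path}: residue selection matched no CA atoms"
            )
        raise FormatError(f"{pdb_path}: no ATOM records with CA atoms")
    return PlddtProfile(domain_id=domain_id or pdb_path.stem, per_residue=values)


_SS_COLLAPSE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def parse_dssp_ss(path: str | Path) -> list[str]:
    """Read per-residue 3-state secondary structure from a DSSP v2 file.

    The 8-state code (column 17 of the per-residue section) collapses as
    H,G,I -> H; E,B -> E; everything else -> C.  Chain-break records
    (``!`` in the amino-acid column) are skipped.
    """
    path = Path(path)
    labels: list[str] = []
    in_body = False
    with open(path) as fh:
        for line in fh:
            if not in_body:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_body = True
                continue
            if len(line) < 17:
                continue
            if line[13] == "!":  # chain break / discontinuity
                continue
            code = line[16]
            labels.append(_SS_COLLAPSE.get(code, "C"))
    if not in_body:
        raise FormatError(f"{path}: missing '#  RESIDUE' header line")
    return labels
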