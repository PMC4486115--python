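"""Readers/writers for the pipeline's external formats and the shared domain types.

The pipeline exchanges four kinds of flat files:

* protein FASTA (database references and metagenome-derived CDS translations),
* tab-separated hit tables (query id, subject id, query coverage %, identity %),
* tab-separated CDS annotation tables carrying EC numbers,
* tab-separated per-organism annotation tables (taxon group, oxygen class,
  environment-term frequencies).

All coordinates are 1-based inclusive, matching the residue nomenclature used
in the hydrogenase literature (e.g. the small-subunit positions 62/163 and the
large-subunit H229).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: 20 standard amino acids plus X (unknown). X never matches an expected
#: signature residue.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

OXYGEN_CLASSES = ("aerobe", "anaerobe", "versatile", "unknown")
GROUPS = ("6C", "4C", "unknown")

_EC_FIELD = re.compile(r"^(\d+|-)$")


class FormatError(ValueError):
    """Raised for malformed input files (bad columns, ranges, coordinates)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence.

    Parameters
    ----------
    id : str
        Unique identifier within any one collection.
    sequence : str
        Uppercase amino-acid string over the 20 IUPAC letters plus X.
    description : str
        Free text carried from the FASTA header.
    source : {"database", "metagenome"}
        Whether the sequence came from the mined reference set or from
        metagenome-derived CDS translations.
    """

    id: str
    sequence: str
    description: str = ""
    source: Literal["database", "metagenome"] = "database"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"sequence for {self.id!r} is empty")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence for {self.id!r} contains invalid residue letters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One row of a sequence-search hit table."""

    query_id: str
    subject_id: str
    query_coverage: float
    identity: float

    def __post_init__(self) -> None:
        for name in ("query_coverage", "identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100] for query {self.query_id!r}")


@dataclass(frozen=True)
class CDSRecord:
    """One annotated coding sequence (1-based inclusive coordinates)."""

    contig_id: str
    cds_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    product: str = ""
    ec_numbers: tuple[str, ...] = ()
    translation: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CDS {self.cds_id!r}: start {self.start} > end {self.end}")
        for ec in self.ec_numbers:
            fields = ec.split(".")
            if len(fields) != 4 or not all(_EC_FIELD.match(f) for f in fields):
                raise ValueError(f"CDS {self.cds_id!r}: malformed EC number {ec!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-organism metadata attached to one sequence."""

    seq_id: str
    organism: str = ""
    group: str = "unknown"
    taxon_group: str = "unknown"
    oxygen_class: str = "unknown"
    env_terms: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group {self.group!r} not one of {GROUPS}")
        if self.oxygen_class not in OXYGEN_CLASSES:
            raise ValueError(
                f"oxygen_class {self.oxygen_class!r} not one of {OXYGEN_CLASSES}"
            )
        for term, n in self.env_terms.items():
            if n < 0:
                raise ValueError(f"negative frequency for env term {term!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path, source: Literal["database", "metagenome"] = "database"
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; line wrapping is ignored. Duplicate ids raise a
    :class:`FormatError` naming the offending id; an empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                description=desc,
                source=source,
            )
        )
    if not records:
        logger.warning("FASTA file %s contained no sequences", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA (60-column wrap)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_HITS_COLUMNS = ("query_id", "subject_id", "query_coverage", "identity")
_CDS_COLUMNS = ("contig_id", "cds_id", "start", "end", "strand")
_ANNOT_COLUMNS = ("seq_id",)


def parse_env_terms(cell: str) -> dict[str, int]:
    """Parse a ``term:count;term:count`` cell into a frequency map."""
    out: dict[str, int] = {}
    cell = cell.strip()
    if not cell:
        return out
    for chunk in cell.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        term, _, count = chunk.rpartition(":")
        if not term:
            raise FormatError(f"malformed env term entry {chunk!r}")
        try:
            out[term.strip()] = int(count)
        except ValueError as exc:
            raise FormatError(f"malformed env term count in {chunk!r}") from exc
    return out


def format_env_terms(terms: Mapping[str, int]) -> str:
    return ";".join(f"{t}:{n}" for t, n in sorted(terms.items()))


def _check_columns(header: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _rows(path: Path) -> tuple[list[str], list[tuple[int, dict[str, str]]]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        rows = [(i, row) for i, row in enumerate(reader, start=2)]
        return list(reader.fieldnames), rows


def _parse_float(value: str, what: str, path: Path, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path} line {line}: unparseable {what} {value!r}") from exc


def _parse_int(value: str, what: str, path: Path, line: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path} line {line}: unparseable {what} {value!r}") from exc


def read_hits(path: str | Path) -> list[HitRecord]:
    path = Path(path)
    header, rows = _rows(path)
    _check_columns(header, _HITS_COLUMNS, path)
    out = []
    for line, row in rows:
        cov = _parse_float(row["query_coverage"], "query_coverage", path, line)
        ident = _parse_float(row["identity"], "identity", path, line)
        try:
            out.append(
                HitRecord(
                    query_id=row["query_id"],
                    subject_id=row["subject_id"],
                    query_coverage=cov,
                    identity=ident,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {line}: {exc}") from exc
    return out


def read_cds(path: str | Path) -> list[CDSRecord]:
    path = Path(path)
    header, rows = _rows(path)
    _check_columns(header, _CDS_COLUMNS, path)
    out = []
    for line, row in rows:
        ec_cell = (row.get("ec_numbers") or "").strip()
        ecs = tuple(e.strip() for e in ec_cell.split(";") if e.strip())
        translation = (row.get("translation") or "").strip() or None
        try:
            out.append(
                CDSRecord(
                    contig_id=row["contig_id"],
                    cds_id=row["cds_id"],
                    start=_parse_int(row["start"], "coordinate", path, line),
                    end=_parse_int(row["end"], "coordinate", path, line),
                    strand=row["strand"],  # type: ignore[arg-type]
                    product=(row.get("product") or "").strip(),
                    ec_numbers=ecs,
                    translation=translation,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {line}: {exc}") from exc
    return out


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    path = Path(path)
    header, rows = _rows(path)
    _check_columns(header, _ANNOT_COLUMNS, path)
    out = []
    for line, row in rows:
        try:
            out.append(
                AnnotationRecord(
                    seq_id=row["seq_id"],
                    organism=(row.get("organism") or "").strip(),
                    group=(row.get("group") or "unknown").strip() or "unknown",
                    taxon_group=(row.get("taxon_group") or "unknown").strip()
                    or "unknown",
                    oxygen_class=(row.get("oxygen_class") or "unknown").strip()
                    or "unknown",
                    env_terms=parse_env_terms(row.get("env_terms") or ""),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {line}: {exc}") from exc
    return out


def read_table(
    path: str | Path, kind: Literal["hits", "cds", "annotations"]
) -> list[HitRecord] | list[CDSRecord] | list[AnnotationRecord]:
    """Read one of the pipeline's TSV dialects into typed records."""
    readers = {"hits": read_hits, "cds": read_cds, "annotations": read_annotations}
    try:
        reader = readers[kind]
    except KeyError:
        raise ValueError(f"unknown table kind {kind!r}") from None
    return reader(path)


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_HITS_COLUMNS)
        for h in hits:
            w.writerow([h.query_id, h.subject_id, f"{h.query_coverage:.2f}", f"{h.identity:.2f}"])


def write_cds(cds: Iterable[CDSRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(_CDS_COLUMNS) + ["product", "ec_numbers", "translation"])
        for c in cds:
            w.writerow(
                [c.contig_id, c.cds_id, c.start, c.end, c.strand, c.product,
                 ";".join(c.ec_numbers), c.translation or ""]
            )


def write_annotations(annots: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["seq_id", "organism", "group", "taxon_group", "oxygen_class", "env_terms"])
        for a in annots:
            w.writerow(
                [a.seq_id, a.organism, a.group, a.taxon_group, a.oxygen_class,
                 format_env_terms(a.env_terms)]
            )


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

def write_report(calls, placements, stats, path: str | Path) -> None:
    """Write the combined per-sequence + statistics report TSV.

    One data row per signature call: id, class label, per-position evidence,
    coverage count, large-subunit H check, placement group and support.
    Sequences without a placement get empty placement columns. A trailing
    section (lines prefixed ``#stats``) mirrors the three comparative axes
    (taxon, environment, oxygen requirement) when ``stats`` is given.

    Parameters
    ----------
    calls : list of SignatureCall
    placements : list of PlacementResult
    stats : EnrichmentReport or None
    """
    placement_by_id = {}
    for p in placements or []:
        if p.fragment_id in placement_by_id:
            raise ValueError(f"duplicate placement for id {p.fragment_id!r}")
        placement_by_id[p.fragment_id] = p
    call_ids = {c.seq_id for c in calls or []}
    orphans = set(placement_by_id) - call_ids
    if orphans:
        raise ValueError(
            f"placement(s) reference id(s) absent from calls: {sorted(orphans)}"
        )

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["seq_id", "label", "evidence", "n_covered", "large_subunit_h",
             "placement_group", "placement_support", "nearest_references"]
        )
        for c in calls or []:
            evidence = ";".join(
                f"{e.ref_position}:{e.status}:{e.observed_residue or '-'}"
                for e in c.evidence
            )
            p = placement_by_id.get(c.seq_id)
            w.writerow(
                [
                    c.seq_id,
                    c.label,
                    evidence,
                    c.n_covered,
                    c.large_subunit_h229,
                    p.assigned_group if p else "",
                    f"{p.support:.3f}" if p else "",
                    ";".join(f"{rid}:{d:.4f}" for rid, d in p.neighbors) if p else "",
                ]
            )
        if stats is not None:
            for line in stats.to_tsv_lines():
                fh.write("#stats\t" + line + "\n")
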