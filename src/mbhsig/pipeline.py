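"""End-to-end orchestration: ingest -> filter -> classify -> place -> ecology.

Mirrors the study's analysis order: mining filters (coverage, EC class) narrow
the inputs; the signature classifier splits the database set into 6C/4C;
classified references anchor nearest-reference placement of metagenome
fragments; and the comparative ecology statistics are computed from the
classified groups. Every stage output is persisted as the same TSV dialects
used for input, so each stage is independently invocable and reruns are
byte-identical given the same inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .align import AlignParams
from .ecology import EnrichmentReport, enrichment_report
from .mining import filter_hits_by_coverage, select_hydrogenase_cds
from .placement import PlacementResult, place_fragment
from .seqio import (
    AnnotationRecord,
    read_annotations,
    read_cds,
    read_fasta,
    read_hits,
    write_report,
)
from .signature import (
    STANDARD_4C,
    TOLERANT_6C,
    SignatureCall,
    classify_collection,
    load_scheme,
)

logger = logging.getLogger(__name__)

REQUIRED_FILES = ("database.fasta", "annotations.tsv", "hits.tsv", "cds.tsv", "scheme.cfg")

LABEL_TO_GROUP = {TOLERANT_6C: "6C", STANDARD_4C: "4C"}


class PipelineValidationError(ValueError):
    """Invalid or missing pipeline inputs (CLI exit code 2)."""


@dataclass
class PipelineResult:
    database_calls: list[SignatureCall]
    fragment_calls: list[SignatureCall]
    counts: dict[str, int]
    placements: list[PlacementResult]
    stats: EnrichmentReport | None
    n_hits_kept: int
    n_cds_kept: int


def run_pipeline(
    input_dir: str | Path,
    out_dir: str | Path,
    min_coverage: float = 80.0,
    ec_prefix: str = "1.12",
    k: int = 3,
    min_aligned: int = 25,
    params: AlignParams = AlignParams(),
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis over a dataset directory.

    The directory must contain ``database.fasta``, ``annotations.tsv``,
    ``hits.tsv``, ``cds.tsv`` and ``scheme.cfg`` (``metagenome.fasta`` is
    optional). Writes ``classification_report.tsv``, ``ecology.tsv``,
    ``summary.tsv`` and ``run.log`` into ``out_dir``.
    """
    input_dir = Path(input_dir)
    out_dir = Path(out_dir)
    missing = [f for f in REQUIRED_FILES if not (input_dir / f).exists()]
    if missing:
        raise PipelineValidationError(
            f"input directory {input_dir} is missing required file(s): {missing}"
        )
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage ingest: reading %s", input_dir)
    scheme = load_scheme(input_dir / "scheme.cfg")
    database = read_fasta(input_dir / "database.fasta", source="database")
    meta_path = input_dir / "metagenome.fasta"
    metagenome = read_fasta(meta_path, source="metagenome") if meta_path.exists() else []
    annotations = read_annotations(input_dir / "annotations.tsv")
    hits = read_hits(input_dir / "hits.tsv")
    cds = read_cds(input_dir / "cds.tsv")

    logger.info("stage filter: coverage >= %.1f%%, EC prefix %s", min_coverage, ec_prefix)
    kept_hits = filter_hits_by_coverage(hits, min_coverage)
    surviving = {h.query_id for h in kept_hits}
    database = [r for r in database if r.id in surviving]
    kept_cds = select_hydrogenase_cds(cds, ec_prefix)
    hydrogenase_ids = {c.cds_id for c in kept_cds}
    metagenome = [r for r in metagenome if r.id in hydrogenase_ids]
    if not database:
        raise PipelineValidationError("no database sequences survive the filters")

    logger.info("stage classify: %d database + %d metagenome sequences",
                len(database), len(metagenome))
    db_calls, counts = classify_collection(database, scheme, params)
    frag_calls, _ = classify_collection(metagenome, scheme, params)

    references = []
    call_group = {}
    db_by_id = {r.id: r for r in database}
    for call in db_calls:
        group = LABEL_TO_GROUP.get(call.label)
        call_group[call.seq_id] = group or "unknown"
        if group:
            references.append((db_by_id[call.seq_id], group))

    placements: list[PlacementResult] = []
    ref_groups = {g for _, g in references}
    if metagenome and {"6C", "4C"} <= ref_groups and len(references) >= k:
        logger.info("stage place: %d fragments against %d classified references",
                    len(metagenome), len(references))
        placements = [
            place_fragment(frag, references, k=k, min_aligned=min_aligned, params=params)
            for frag in metagenome
        ]
    elif metagenome:
        logger.warning("skipping placement: reference set lacks both groups or is too small")

    # ecology runs on classification-derived groups, not on any group column
    # already present in the annotations
    ecology_annots = []
    for a in annotations:
        if a.seq_id in call_group:
            ecology_annots.append(
                AnnotationRecord(
                    seq_id=a.seq_id, organism=a.organism,
                    group=call_group[a.seq_id], taxon_group=a.taxon_group,
                    oxygen_class=a.oxygen_class, env_terms=a.env_terms,
                )
            )
    stats: EnrichmentReport | None = None
    groups_present = {a.group for a in ecology_annots}
    if {"6C", "4C"} <= groups_present:
        logger.info("stage ecology: %d annotated sequences", len(ecology_annots))
        stats = enrichment_report(ecology_annots)
    else:
        logger.warning("skipping ecology: need both groups among annotated sequences")

    write_report(db_calls + frag_calls, placements, stats,
                 out_dir / "classification_report.tsv")
    if stats is not None:
        stats.write(out_dir / "ecology.tsv")
    with open(out_dir / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"hits_kept\t{len(kept_hits)}\n")
        fh.write(f"cds_kept\t{len(kept_cds)}\n")
        for label in sorted(counts):
            fh.write(f"database_{label}\t{counts[label]}\n")
        frag_counts: dict[str, int] = {}
        for c in frag_calls:
            frag_counts[c.label] = frag_counts.get(c.label, 0) + 1
        for label in sorted(frag_counts):
            fh.write(f"fragment_{label}\t{frag_counts[label]}\n")
        placed: dict[str, int] = {}
        for p in placements:
            placed[p.assigned_group] = placed.get(p.assigned_group, 0) + 1
        for g in sorted(placed):
            fh.write(f"placed_{g}\t{placed[g]}\n")
    with open(out_dir / "run.log", "w") as fh:
        fh.write(f"mbhsig {__version__}\n")
        fh.write(f"seed {seed}\n")
        fh.write(f"min_coverage {min_coverage}\nec_prefix {ec_prefix}\n")
        fh.write(f"k {k}\nmin_aligned {min_aligned}\n")
        fh.write(f"matrix {params.matrix} gap_open {params.gap_open} "
                 f"gap_extend {params.gap_extend}\n")

    return PipelineResult(
        database_calls=db_calls, fragment_calls=frag_calls, counts=counts,
        placements=placements, stats=stats,
        n_hits_kept=len(kept_hits), n_cds_kept=len(kept_cds),
    )
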