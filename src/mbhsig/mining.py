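"""Database-mining and metagenome-screening filters.

Three steps sit between raw search output and signature classification:

1. coverage elimination — hits whose query coverage falls below a threshold
   (default 80%) are discarded;
2. hydrogenase selection — CDS records are kept when at least one of their EC
   numbers falls under the hydrogenase class (EC 1.12), matched field-wise on
   the dotted hierarchy;
3. subunit assignment — candidate proteins are assigned small/large subunit
   by best identity against labelled exemplars.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Literal, Sequence

from .align import AlignParams, global_align
from .seqio import CDSRecord, HitRecord, ProteinRecord

logger = logging.getLogger(__name__)

_EC_PREFIX = re.compile(r"^\d+(\.\d+){0,3}$")


def filter_hits_by_coverage(
    hits: Sequence[HitRecord], min_coverage: float = 80.0
) -> list[HitRecord]:
    """Keep hits with query coverage >= ``min_coverage`` (strict elimination
    below the threshold; a hit at exactly the boundary is retained). Input
    order is preserved and the number removed is logged.
    """
    kept = [h for h in hits if h.query_coverage >= min_coverage]
    removed = len(hits) - len(kept)
    if removed:
        logger.info(
            "coverage filter: removed %d of %d hits below %.1f%%",
            removed, len(hits), min_coverage,
        )
    return kept


def _ec_matches_prefix(ec: str, prefix_fields: list[str]) -> bool:
    fields = ec.split(".")
    if len(fields) < len(prefix_fields):
        return False
    # "-" placeholders beyond the prefix are ignored; within the prefix
    # region the record's field must equal the prefix field exactly.
    return all(f == p for f, p in zip(fields, prefix_fields))


def select_hydrogenase_cds(
    cds: Sequence[CDSRecord], ec_prefix: str = "1.12"
) -> list[CDSRecord]:
    """Keep CDS records with >=1 EC number under the dotted prefix.

    EC numbers are hierarchical, so matching is field-wise on dotted
    components: prefix "1.12" matches "1.12.99.6" and "1.12.-.-" but not
    "1.1.1.1". A malformed prefix raises ``ValueError``.
    """
    if not _EC_PREFIX.match(ec_prefix):
        raise ValueError(f"malformed EC prefix {ec_prefix!r}")
    prefix_fields = ec_prefix.split(".")
    return [
        c for c in cds
        if any(_ec_matches_prefix(ec, prefix_fields) for ec in c.ec_numbers)
    ]


@dataclass(frozen=True)
class SubunitAssignment:
    subunit: Literal["small", "large", "unassigned"]
    exemplar_id: str | None
    identity: float | None


def assign_subunit(
    query: ProteinRecord,
    exemplars: Sequence[tuple[ProteinRecord, str]],
    min_identity: float = 30.0,
    min_aligned: int = 50,
    params: AlignParams = AlignParams(),
) -> SubunitAssignment:
    """Assign small/large subunit by best exemplar identity.

    The query is globally aligned to every exemplar; among alignments with at
    least ``min_aligned`` aligned residue pairs and identity >=
    ``min_identity``, the exemplar with highest identity wins (ties broken by
    lexicographically smallest exemplar id, making the result invariant to
    exemplar order). Returns ``unassigned`` when no exemplar passes.
    """
    if not exemplars:
        raise ValueError("exemplar set is empty")
    labels = {lab for _, lab in exemplars}
    if not {"small", "large"} <= labels:
        raise ValueError("exemplars must include both 'small' and 'large' labels")

    best: tuple[float, str, str] | None = None  # (identity, id, label)
    for ex, label in exemplars:
        aln = global_align(ex, query, params)
        if aln.aligned_pairs < min_aligned:
            continue
        ident = aln.identity
        if ident < min_identity:
            continue
        key = (ident, ex.id)
        if best is None or ident > best[0] or (ident == best[0] and ex.id < best[1]):
            best = (ident, ex.id, label)
    if best is None:
        return SubunitAssignment("unassigned", None, None)
    return SubunitAssignment(best[2], best[1], best[0])  # type: ignore[arg-type]
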