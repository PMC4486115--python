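"""Cysteine-signature classification of NiFe MBH small subunits.

O2-tolerant group 1 membrane-bound hydrogenases carry six conserved cysteines
(the 6C group) coordinating the proximal Fe-S cluster of the small subunit;
standard O2-sensitive enzymes (4C group) have glycine in place of cysteine at
the two supernumerary positions. Only those two discriminating positions
separate the classes — the other four cysteines are conserved in both groups,
so they are recorded as evidence but never decide the label. A supporting
histidine in the large subunit (position 229 in the scheme's reference frame)
further stabilises the proximal cluster under O2 and is checked separately.

Metagenomic fragments may cover only part of the reference: a fragment whose
aligned span misses both discriminating positions is INDETERMINATE; one
covered discriminating position suffices for a provisional call (confidence
records whether 1 or 2 of the discriminating positions back the label).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

from .align import AlignParams, PositionEvidence, global_align, map_reference_positions
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

TOLERANT_6C = "TOLERANT_6C"
STANDARD_4C = "STANDARD_4C"
AMBIGUOUS = "AMBIGUOUS"
INDETERMINATE = "INDETERMINATE"
LABELS = (TOLERANT_6C, STANDARD_4C, AMBIGUOUS, INDETERMINATE)


@dataclass(frozen=True)
class SignatureScheme:
    """The signature positions, expressed in a designated reference frame.

    All positions are 1-based coordinates of ``reference`` (small subunit)
    and ``large_reference`` (large subunit). ``discriminating`` is the
    supernumerary cysteine pair that separates the 6C and 4C groups
    (nominally positions 62 and 163); ``positions`` lists all six signature
    positions. The scheme is data, not code: load one with
    :func:`load_scheme`.
    """

    reference: ProteinRecord
    positions: tuple[int, ...]
    discriminating: tuple[int, int]
    tolerant_residue: str = "C"
    standard_residue: str = "G"
    large_reference: ProteinRecord | None = None
    large_position: int = 229
    large_residue: str = "H"

    def __post_init__(self) -> None:
        if len(self.positions) != 6:
            raise ValueError(f"expected 6 signature positions, got {len(self.positions)}")
        if len(set(self.positions)) != 6:
            raise ValueError("signature positions must be distinct")
        if len(self.discriminating) != 2 or not set(self.discriminating) <= set(self.positions):
            raise ValueError("discriminating must be exactly 2 of the 6 positions")
        if max(self.positions) > len(self.reference):
            raise ValueError("signature position beyond reference length")
        if self.large_reference is not None and self.large_position > len(self.large_reference):
            raise ValueError("large_position beyond large reference length")


@dataclass(frozen=True)
class SignatureCall:
    """Classification outcome for one sequence, with per-position evidence."""

    seq_id: str
    label: str
    evidence: tuple[PositionEvidence, ...]
    n_covered: int
    confidence: Literal["2-of-2", "1-of-2", "none"] = "none"
    large_subunit_h229: Literal["present", "absent", "uncovered", "not_tested"] = "not_tested"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        n = sum(1 for e in self.evidence if e.status == "covered")
        if n != self.n_covered:
            raise ValueError("n_covered disagrees with evidence")


def classify_small_subunit(
    query: ProteinRecord,
    scheme: SignatureScheme,
    params: AlignParams = AlignParams(),
) -> SignatureCall:
    """Read the six signature positions of ``query`` and call its group.

    The query is globally aligned to the scheme's reference and the six
    positions mapped through the alignment. The label is decided by the
    covered discriminating positions only:

    * all show the tolerant residue (Cys)      -> TOLERANT_6C
    * all show the standard residue (Gly)      -> STANDARD_4C
    * they disagree, or show another residue   -> AMBIGUOUS
    * neither is covered                       -> INDETERMINATE
    """
    aln = global_align(scheme.reference, query, params)
    evidence = tuple(map_reference_positions(aln, list(scheme.positions)))
    by_pos = {e.ref_position: e for e in evidence}
    disc = [by_pos[p] for p in scheme.discriminating]
    covered_disc = [e for e in disc if e.status == "covered"]

    if not covered_disc:
        label = INDETERMINATE
        confidence = "none"
    else:
        residues = {e.observed_residue for e in covered_disc}
        if residues == {scheme.tolerant_residue}:
            label = TOLERANT_6C
        elif residues == {scheme.standard_residue}:
            label = STANDARD_4C
        else:
            label = AMBIGUOUS
        confidence = "2-of-2" if len(covered_disc) == 2 else "1-of-2"

    return SignatureCall(
        seq_id=query.id,
        label=label,
        evidence=evidence,
        n_covered=sum(1 for e in evidence if e.status == "covered"),
        confidence=confidence,
    )


def check_large_subunit(
    query: ProteinRecord,
    scheme: SignatureScheme,
    params: AlignParams = AlignParams(),
) -> str:
    """Check the supporting large-subunit histidine (H at ``large_position``).

    Returns ``present`` / ``absent`` / ``uncovered``.
    """
    if scheme.large_reference is None:
        raise ValueError("scheme has no large-subunit reference")
    aln = global_align(scheme.large_reference, query, params)
    (ev,) = map_reference_positions(aln, [scheme.large_position])
    if ev.status == "covered":
        return "present" if ev.observed_residue == scheme.large_residue else "absent"
    return "uncovered"


def classify_collection(
    queries: Sequence[ProteinRecord],
    scheme: SignatureScheme,
    params: AlignParams = AlignParams(),
) -> tuple[list[SignatureCall], dict[str, int]]:
    """Classify every query; return per-sequence calls and counts per label.

    Counts are order-independent and always include every label (zero counts
    explicit). Duplicate query ids raise ``ValueError``.
    """
    ids = [q.id for q in queries]
    dups = [i for i, n in Counter(ids).items() if n > 1]
    if dups:
        raise ValueError(f"duplicate query id(s): {sorted(dups)}")
    calls = [classify_small_subunit(q, scheme, params) for q in queries]
    counts = {label: 0 for label in LABELS}
    for c in calls:
        counts[c.label] += 1
    return calls, counts


# ---------------------------------------------------------------------------
# Scheme config I/O (flat key = value file)
# ---------------------------------------------------------------------------

def save_scheme(scheme: SignatureScheme, path: str | Path) -> None:
    """Serialize a scheme as a flat key = value file (sequences inline)."""
    lines = [
        "# signature scheme: positions are 1-based in the reference frame below",
        f"reference_id = {scheme.reference.id}",
        f"reference_seq = {scheme.reference.sequence}",
        f"positions = {','.join(str(p) for p in scheme.positions)}",
        f"discriminating = {','.join(str(p) for p in scheme.discriminating)}",
        f"tolerant_residue = {scheme.tolerant_residue}",
        f"standard_residue = {scheme.standard_residue}",
        f"large_position = {scheme.large_position}",
        f"large_residue = {scheme.large_residue}",
    ]
    if scheme.large_reference is not None:
        lines += [
            f"large_reference_id = {scheme.large_reference.id}",
            f"large_reference_seq = {scheme.large_reference.sequence}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_scheme(path: str | Path) -> SignatureScheme:
    """Load a scheme from the flat key = value format written by save_scheme."""
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise ValueError(f"malformed scheme line: {raw!r}")
        kv[key.strip()] = value.strip()
    required = {"reference_id", "reference_seq", "positions", "discriminating"}
    missing = required - kv.keys()
    if missing:
        raise ValueError(f"scheme config missing key(s): {sorted(missing)}")
    large_ref = None
    if "large_reference_seq" in kv:
        large_ref = ProteinRecord(
            id=kv.get("large_reference_id", "large_ref"),
            sequence=kv["large_reference_seq"],
        )
    return SignatureScheme(
        reference=ProteinRecord(id=kv["reference_id"], sequence=kv["reference_seq"]),
        positions=tuple(int(p) for p in kv["positions"].split(",")),
        discriminating=tuple(int(p) for p in kv["discriminating"].split(",")),  # type: ignore[arg-type]
        tolerant_residue=kv.get("tolerant_residue", "C"),
        standard_residue=kv.get("standard_residue", "G"),
        large_reference=large_ref,
        large_position=int(kv.get("large_position", "229")),
        large_residue=kv.get("large_residue", "H"),
    )
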