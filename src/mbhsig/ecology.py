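"""Comparative distribution statistics for the 6C and 4C groups.

For each comparison axis — taxon group, oxygen class, environment terms — a
contingency table of category counts per group is built, converted to
within-group percentages (group sizes are unequal, so percentages, not raw
counts, are the comparable scale), and summarized as directional fold
differences: the ratio of the larger to the smaller percentage, pointing at
the enriched group. A category present in only one group is flagged exclusive
rather than given an infinite or pseudocounted fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .seqio import AnnotationRecord

logger = logging.getLogger(__name__)

Axis = Literal["taxon_group", "oxygen_class", "env_terms"]
AXES: tuple[Axis, ...] = ("taxon_group", "oxygen_class", "env_terms")


@dataclass(frozen=True)
class ContingencyTable:
    """Category counts per group with totals."""

    axis: str
    categories: tuple[str, ...]
    counts: Mapping[tuple[str, str], int]  # (group, category) -> count
    group_totals: Mapping[str, int]

    def __post_init__(self) -> None:
        for g, total in self.group_totals.items():
            s = sum(self.counts.get((g, c), 0) for c in self.categories)
            if s != total:
                raise ValueError(f"group {g} total {total} != summed counts {s}")
            if total <= 0:
                raise ValueError(f"group {g} has no observations")

    def percentage(self, group: str, category: str) -> float:
        return 100.0 * self.counts.get((group, category), 0) / self.group_totals[group]


@dataclass(frozen=True)
class FoldDifferenceResult:
    """Directional fold difference for one category.

    ``fold`` is max(pct)/min(pct) when both groups show the category; when one
    group's percentage is zero the fold is None and ``exclusive`` records
    which group owns the category.
    """

    category: str
    pct_6C: float
    pct_4C: float
    direction: Literal["6C", "4C", "equal"]
    fold: float | None
    exclusive: Literal["none", "only_6C", "only_4C"] = "none"

    def __post_init__(self) -> None:
        if self.fold is not None and self.fold < 1.0 - 1e-12:
            raise ValueError("fold must be >= 1")


@dataclass(frozen=True)
class EnrichmentReport:
    """Per-axis contingency tables and fold-difference results."""

    tables: Mapping[str, ContingencyTable]
    folds: Mapping[str, tuple[FoldDifferenceResult, ...]]

    def to_tsv_lines(self) -> list[str]:
        lines = ["axis\tcategory\tpct_6C\tpct_4C\tdirection\tfold\texclusive"]
        for axis in self.folds:
            for r in self.folds[axis]:
                fold = f"{r.fold:.2f}" if r.fold is not None else ""
                lines.append(
                    f"{axis}\t{r.category}\t{r.pct_6C:.2f}\t{r.pct_4C:.2f}"
                    f"\t{r.direction}\t{fold}\t{r.exclusive}"
                )
        return lines

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.to_tsv_lines()) + "\n")


def contingency(
    annotations: Sequence[AnnotationRecord],
    axis: Axis,
    weighted: bool = True,
) -> ContingencyTable:
    """Build the (group x category) count table for one axis.

    Records with group ``unknown`` are excluded with a warning. For the
    ``env_terms`` axis each record contributes its term frequencies (set
    ``weighted=False`` for presence/absence). Categories are sorted by
    descending total count, then lexicographically.
    """
    usable = [a for a in annotations if a.group in ("6C", "4C")]
    skipped = len(annotations) - len(usable)
    if skipped:
        logger.warning("excluded %d record(s) with unknown group", skipped)

    counts: dict[tuple[str, str], int] = {}
    for a in usable:
        if axis == "env_terms":
            for term, freq in a.env_terms.items():
                inc = freq if weighted else (1 if freq > 0 else 0)
                if inc:
                    counts[(a.group, term)] = counts.get((a.group, term), 0) + inc
        else:
            cat = getattr(a, axis)
            counts[(a.group, cat)] = counts.get((a.group, cat), 0) + 1

    group_totals = {
        g: sum(n for (gg, _), n in counts.items() if gg == g) for g in ("6C", "4C")
    }
    empty = [g for g, t in group_totals.items() if t == 0]
    if empty:
        raise ValueError(f"no usable observations for group(s) {empty} on axis {axis}")

    cat_totals: dict[str, int] = {}
    for (_, c), n in counts.items():
        cat_totals[c] = cat_totals.get(c, 0) + n
    categories = tuple(sorted(cat_totals, key=lambda c: (-cat_totals[c], c)))
    return ContingencyTable(
        axis=axis, categories=categories, counts=counts, group_totals=group_totals
    )


def fold_differences(table: ContingencyTable) -> list[FoldDifferenceResult]:
    """Directional fold differences of within-group percentages per category."""
    out: list[FoldDifferenceResult] = []
    for cat in table.categories:
        p6 = table.percentage("6C", cat)
        p4 = table.percentage("4C", cat)
        if p6 == 0.0 and p4 == 0.0:
            continue
        if p6 == 0.0:
            out.append(FoldDifferenceResult(cat, p6, p4, "4C", None, "only_4C"))
        elif p4 == 0.0:
            out.append(FoldDifferenceResult(cat, p6, p4, "6C", None, "only_6C"))
        elif p6 > p4:
            out.append(FoldDifferenceResult(cat, p6, p4, "6C", p6 / p4))
        elif p4 > p6:
            out.append(FoldDifferenceResult(cat, p6, p4, "4C", p4 / p6))
        else:
            out.append(FoldDifferenceResult(cat, p6, p4, "equal", 1.0))
    return out


def enrichment_report(
    annotations: Sequence[AnnotationRecord],
    axes: Sequence[Axis] = AXES,
    weighted: bool = True,
) -> EnrichmentReport:
    """Contingency tables plus fold results for every requested axis."""
    tables: dict[str, ContingencyTable] = {}
    folds: dict[str, tuple[FoldDifferenceResult, ...]] = {}
    for axis in axes:
        t = contingency(annotations, axis, weighted=weighted)
        tables[axis] = t
        folds[axis] = tuple(fold_differences(t))
    return EnrichmentReport(tables=tables, folds=folds)
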