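"""Distance-based reference trees and nearest-reference fragment placement.

The reference set (full-length, signature-classified sequences) is related by
a neighbor-joining tree built from pairwise alignment distances; metagenomic
fragments are then placed by the group membership of their k nearest
classified references, with distances computed only over mutually covered
columns so short fragments are not drowned by end gaps. This deterministic
desk-scale procedure answers the question the tree is used for — which group
(6C or 4C) a fragment segregates with.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .align import AlignParams, global_align
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

Correction = Literal["p", "poisson"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.d[i, j])


@dataclass(frozen=True)
class PlacementResult:
    """Group assignment of one fragment from its k nearest references."""

    fragment_id: str
    assigned_group: Literal["6C", "4C", "tie", "unplaced"]
    support: float
    neighbors: tuple[tuple[str, float], ...]


@dataclass
class TreeNode:
    """Node of a phylogenetic tree; children carry branch lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return self.name or ""
        parts = [
            f"{child._newick_inner()}:{length:.6f}" for child, length in self.children
        ]
        label = self.name or ""
        return f"({','.join(parts)}){label}"


def correct_distance(p: float, correction: Correction, max_distance: float = 10.0) -> float:
    """Turn a p-distance into the configured evolutionary distance.

    ``p``       — raw proportion of differing aligned columns;
    ``poisson`` — -ln(1 - p), capped at ``max_distance`` as p -> 1.
    """
    if correction == "p":
        return p
    if correction == "poisson":
        if p >= 1.0 - math.exp(-max_distance):
            return max_distance
        return -math.log1p(-p)
    raise ValueError(f"unknown correction {correction!r}")


def pair_distance(
    a: ProteinRecord,
    b: ProteinRecord,
    params: AlignParams = AlignParams(),
    correction: Correction = "poisson",
    max_distance: float = 10.0,
) -> tuple[float, int]:
    """Alignment distance between two sequences over mutually covered columns.

    Returns (distance, aligned_pairs). End gaps never contribute: the
    p-distance is 1 - identity/100 over residue-residue columns only.
    """
    aln = global_align(a, b, params)
    if aln.aligned_pairs == 0:
        raise ValueError(f"zero aligned residues between {a.id!r} and {b.id!r}")
    p = 1.0 - aln.identity / 100.0
    return correct_distance(p, correction, max_distance), aln.aligned_pairs


def distance_matrix(
    records: Sequence[ProteinRecord],
    params: AlignParams = AlignParams(),
    correction: Correction = "poisson",
    max_distance: float = 10.0,
) -> DistanceMatrix:
    """All-pairs alignment distances (see :func:`pair_distance`)."""
    if len(records) < 2:
        raise ValueError("need at least 2 records for a distance matrix")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist, _ = pair_distance(records[i], records[j], params, correction, max_distance)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=tuple(r.id for r in records), d=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    The Q matrix is minimized with ties broken by the smallest (i, j) index
    pair in the current node ordering; negative branch lengths are clamped to
    zero with the deficit logged. Returns an unrooted tree represented with a
    degree-3 internal node at the final join (degree-2 for n == 2); leaf
    names are the matrix ids.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    d = dm.d.astype(float).copy()

    def clamp(length: float, what: str) -> float:
        if length < 0:
            logger.info("clamped negative branch length %.3g at %s", length, what)
            return 0.0
        return length

    if n == 2:
        half = d[0, 1] / 2.0
        return TreeNode(children=[(nodes[0], clamp(half, dm.ids[0])),
                                  (nodes[1], clamp(half, dm.ids[1]))])

    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        li = d[i, j] / 2.0 + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        new = TreeNode(children=[(nodes[i], clamp(li, nodes[i].name or "internal")),
                                 (nodes[j], clamp(lj, nodes[j].name or "internal"))])
        # grow the matrix with the new node's distances
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    return TreeNode(children=[
        (nodes[i], clamp(li, nodes[i].name or "internal")),
        (nodes[j], clamp(lj, nodes[j].name or "internal")),
        (nodes[k], clamp(lk, nodes[k].name or "internal")),
    ])


def leaf_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Path-length distances between all leaves of the tree."""
    # build undirected adjacency then BFS from each leaf (trees are small)
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}

    def walk(node: TreeNode) -> None:
        adj.setdefault(id(node), [])
        if node.is_leaf():
            names[id(node)] = node.name or ""
        for child, length in node.children:
            adj.setdefault(id(child), [])
            adj[id(node)].append((id(child), length))
            adj[id(child)].append((id(node), length))
            walk(child)

    walk(tree)
    leaf_ids = sorted(names, key=lambda nid: names[nid])
    ids = tuple(names[nid] for nid in leaf_ids)
    n = len(ids)
    d = np.zeros((n, n))
    for a, src in enumerate(leaf_ids):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, length in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + length
                    stack.append(nb)
        for b, dst in enumerate(leaf_ids):
            d[a, b] = dist[dst]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=ids, d=(d + d.T) / 2.0)


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits of the tree, each given as its canonical side."""
    all_leaves = frozenset(l.name or "" for l in tree.leaves())
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.name or ""])
        below: set[str] = set()
        for child, _ in node.children:
            side = walk(child)
            if 1 < len(side) < len(all_leaves) - 1:
                other = all_leaves - side
                canonical = min(side, frozenset(other), key=lambda s: (len(s), sorted(s)))
                splits.add(frozenset(canonical))
            below |= side
        return frozenset(below)

    walk(tree)
    return splits


def place_fragment(
    fragment: ProteinRecord,
    references: Sequence[tuple[ProteinRecord, str]],
    k: int = 3,
    min_aligned: int = 25,
    params: AlignParams = AlignParams(),
    correction: Correction = "poisson",
    max_distance: float = 10.0,
) -> PlacementResult:
    """Assign a fragment to the 6C or 4C group by its k nearest references.

    Distances use only mutually covered columns (fragments are not penalized
    by end gaps). References with fewer than ``min_aligned`` aligned residue
    pairs are ignored; if none remain the fragment is ``unplaced``. The
    majority group among the k nearest wins; an equal split is a ``tie``.
    Deterministic and invariant to reference order (ties in distance broken
    by reference id).
    """
    if not references:
        raise ValueError("reference set is empty")
    groups = {g for _, g in references}
    if not {"6C", "4C"} <= groups:
        raise ValueError("references must include both 6C and 4C groups")
    if k > len(references):
        raise ValueError(f"k={k} exceeds reference count {len(references)}")
    if k < 1:
        raise ValueError("k must be positive")

    scored: list[tuple[float, str, str]] = []
    for ref, group in references:
        aln = global_align(ref, fragment, params)
        if aln.aligned_pairs < min_aligned:
            continue
        p = 1.0 - aln.identity / 100.0
        dist = correct_distance(p, correction, max_distance)
        scored.append((dist, ref.id, group))
    if not scored:
        return PlacementResult(fragment.id, "unplaced", 0.0, ())

    scored.sort(key=lambda t: (t[0], t[1]))
    nearest = scored[:k]
    votes_6c = sum(1 for _, _, g in nearest if g == "6C")
    votes_4c = sum(1 for _, _, g in nearest if g == "4C")
    if votes_6c > votes_4c:
        group, support = "6C", votes_6c / len(nearest)
    elif votes_4c > votes_6c:
        group, support = "4C", votes_4c / len(nearest)
    else:
        group, support = "tie", 0.5
    return PlacementResult(
        fragment_id=fragment.id,
        assigned_group=group,  # type: ignore[arg-type]
        support=support,
        neighbors=tuple((rid, dist) for dist, rid, _ in nearest),
    )
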