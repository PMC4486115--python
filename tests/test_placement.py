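"""Distance matrices, neighbor joining, Newick output, fragment placement."""

import math

import numpy as np
import pytest

from mbhsig.align import AlignParams
from mbhsig.placement import (
    DistanceMatrix,
    bipartitions,
    correct_distance,
    distance_matrix,
    leaf_distance_matrix,
    neighbor_joining,
    place_fragment,
)
from mbhsig.seqio import ProteinRecord

from conftest import random_protein

NOGAPS = AlignParams(matrix=None, match=1.0, mismatch=-1.0,
                     gap_open=-100.0, gap_extend=-100.0)


# --- independent random additive trees (test-local, not package code) -------

def random_additive_tree(n, rng):
    """Random unrooted binary tree as an adjacency map; leaves are 0..n-1."""
    nxt = n
    edges = {}

    def add(u, v, w):
        edges.setdefault(u, []).append((v, w))
        edges.setdefault(v, []).append((u, w))

    def remove(u, v):
        edges[u] = [(x, w) for x, w in edges[u] if x != v]
        edges[v] = [(x, w) for x, w in edges[v] if x != u]

    c = nxt
    nxt += 1
    for leaf in range(3):
        add(c, leaf, rng.uniform(0.1, 1.0))
    for leaf in range(3, n):
        all_edges = [(u, v, w) for u in edges for v, w in edges[u] if u < v]
        u, v, w = all_edges[rng.integers(len(all_edges))]
        remove(u, v)
        m = nxt
        nxt += 1
        t = rng.uniform(0.2, 0.8)
        add(u, m, w * t)
        add(m, v, w * (1 - t))
        add(m, leaf, rng.uniform(0.1, 1.0))
    return edges


def path_distances(edges, n):
    d = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb, w in edges[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + w
                    stack.append(nb)
        for dst in range(n):
            d[src, dst] = dist[dst]
    return d


def tree_splits(edges, n):
    leaves = frozenset(f"L{i}" for i in range(n))
    splits = set()
    for u in list(edges):
        for v, _ in edges[u]:
            if u < v:
                side = set()
                stack, seen = [v], {u, v}
                while stack:
                    cur = stack.pop()
                    if cur < n:
                        side.add(f"L{cur}")
                    for nb, _ in edges[cur]:
                        if nb not in seen:
                            seen.add(nb)
                            stack.append(nb)
                if 1 < len(side) < n - 1:
                    other = leaves - side
                    splits.add(frozenset(min(side, frozenset(other),
                                             key=lambda s: (len(s), sorted(s)))))
    return splits


class TestDistances:
    def test_identical_sequences_zero(self):
        rng = np.random.default_rng(61)
        a = random_protein(rng, 80, "a")
        b = ProteinRecord(id="b", sequence=a.sequence)
        dm = distance_matrix([a, b])
        assert dm[("a", "b")] == 0.0

    def test_poisson_closed_form(self):
        # p = 0.5 -> -ln(0.5)
        assert correct_distance(0.5, "poisson") == pytest.approx(math.log(2.0))
        assert correct_distance(0.3, "p") == 0.3

    def test_poisson_cap_at_saturation(self):
        assert correct_distance(1.0, "poisson", max_distance=10.0) == 10.0

    def test_matrix_matches_independent_recount(self):
        # rebuild each entry from the alignment strings directly
        from mbhsig.align import global_align

        rng = np.random.default_rng(67)
        recs = [random_protein(rng, 60, f"r{i}") for i in range(3)]
        dm = distance_matrix(recs, NOGAPS, correction="p")
        for i in range(3):
            for j in range(i + 1, 3):
                aln = global_align(recs[i], recs[j], NOGAPS)
                diffs = sum(
                    1 for x, y in zip(aln.ref_aln, aln.query_aln)
                    if x != "-" and y != "-" and x != y
                )
                assert dm.d[i, j] == pytest.approx(diffs / aln.aligned_pairs)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=("a", "b"), d=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_two_taxa_split_edge(self):
        dm = DistanceMatrix(ids=("a", "b"), d=np.array([[0.0, 3.0], [3.0, 0.0]]))
        tree = neighbor_joining(dm)
        assert sorted(l.name for l in tree.leaves()) == ["a", "b"]
        assert [length for _, length in tree.children] == [1.5, 1.5]

    def test_additive_four_taxon_exact(self):
        # a random additive quartet: exact topology and path-length recovery
        rng = np.random.default_rng(71)
        edges = random_additive_tree(4, rng)
        d = path_distances(edges, 4)
        dm = DistanceMatrix(ids=tuple(f"L{i}" for i in range(4)), d=d)
        tree = neighbor_joining(dm)
        rec = leaf_distance_matrix(tree)
        assert rec.ids == dm.ids
        np.testing.assert_allclose(rec.d, d, atol=1e-12)
        assert bipartitions(tree) == tree_splits(edges, 4)

    def test_random_additive_recovery(self):
        rng = np.random.default_rng(73)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            edges = random_additive_tree(n, rng)
            d = path_distances(edges, n)
            dm = DistanceMatrix(ids=tuple(f"L{i}" for i in range(n)), d=d)
            tree = neighbor_joining(dm)
            np.testing.assert_allclose(leaf_distance_matrix(tree).d, d, atol=1e-9)
            assert bipartitions(tree) == tree_splits(edges, n)

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(79)
        n = 6
        d = rng.uniform(0.5, 2.0, size=(n, n))
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix(ids=tuple(f"L{i}" for i in range(n)), d=d))

        def walk(node):
            for child, length in node.children:
                assert length >= 0.0
                walk(child)

        walk(tree)

    def test_newick_round_trip_via_dendropy(self):
        import dendropy

        rng = np.random.default_rng(83)
        edges = random_additive_tree(6, rng)
        d = path_distances(edges, 6)
        dm = DistanceMatrix(ids=tuple(f"L{i}" for i in range(6)), d=d)
        tree = neighbor_joining(dm)
        newick = tree.to_newick()
        dt = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        mine = leaf_distance_matrix(tree)
        for i, a in enumerate(mine.ids):
            for j, b in enumerate(mine.ids):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        mine.d[i, j], abs=1e-5
                    )


@pytest.fixture(scope="module")
def labelled_refs(references):
    from mbhsig.simulate import evolve_family

    ref6, ref4, _, scheme = references
    fam6, _ = evolve_family(ref6, 4, 0.05, 0.0, scheme.positions, seed=91,
                            id_prefix="r6")
    fam4, _ = evolve_family(ref4, 4, 0.05, 0.0, scheme.positions, seed=92,
                            id_prefix="r4")
    return [(r, "6C") for r in fam6] + [(r, "4C") for r in fam4]


class TestPlacement:

    def test_substring_fragment_joins_parent_group(self, labelled_refs):
        parent = labelled_refs[0][0]
        frag = ProteinRecord(id="f", sequence=parent.sequence[50:200],
                             source="metagenome")
        res = place_fragment(frag, labelled_refs, k=1)
        assert res.assigned_group == "6C"
        assert res.support == 1.0
        assert res.neighbors[0] == (parent.id, 0.0)

    def test_constructed_equidistant_tie(self):
        rng = np.random.default_rng(97)
        base = random_protein(rng, 60, "base").sequence
        # two references, each differing from the fragment at 2 positions
        ref_a = ProteinRecord(id="a6", sequence="W" + base[1:30] + "W" + base[31:])
        ref_b = ProteinRecord(id="b4", sequence=base[:10] + "W" + base[11:40] + "W" + base[41:])
        frag = ProteinRecord(id="f", sequence=base, source="metagenome")
        res = place_fragment(frag, [(ref_a, "6C"), (ref_b, "4C")], k=2, params=NOGAPS)
        assert res.assigned_group == "tie"
        assert res.support == 0.5

    def test_unplaceable_short_fragment(self, labelled_refs):
        frag = ProteinRecord(id="f", sequence="MKTWYACDEFHH", source="metagenome")
        res = place_fragment(frag, labelled_refs, k=3, min_aligned=25)
        assert res.assigned_group == "unplaced"
        assert res.neighbors == ()

    def test_invariant_to_reference_order(self, labelled_refs):
        frag = ProteinRecord(id="f",
                             sequence=labelled_refs[5][0].sequence[30:180],
                             source="metagenome")
        a = place_fragment(frag, labelled_refs, k=3)
        b = place_fragment(frag, list(reversed(labelled_refs)), k=3)
        assert a == b

    def test_majority_vote_support(self):
        # two clearly separated families: all k nearest share the parent group
        rng = np.random.default_rng(101)
        base6 = random_protein(rng, 200, "base6")
        base4 = random_protein(rng, 200, "base4")
        from mbhsig.simulate import evolve_family

        fam6, _ = evolve_family(base6, 3, 0.03, 0.0, (), seed=102, id_prefix="r6")
        fam4, _ = evolve_family(base4, 3, 0.03, 0.0, (), seed=103, id_prefix="r4")
        refs = [(r, "6C") for r in fam6] + [(r, "4C") for r in fam4]
        frag = ProteinRecord(id="f", sequence=base6.sequence[20:180],
                             source="metagenome")
        res = place_fragment(frag, refs, k=3)
        assert res.assigned_group == "6C"
        assert res.support == pytest.approx(1.0)
        assert {rid[:2] for rid, _ in res.neighbors} == {"r6"}

    def test_k_larger_than_reference_count_rejected(self, labelled_refs):
        frag = ProteinRecord(id="f", sequence=labelled_refs[0][0].sequence)
        with pytest.raises(ValueError, match="k="):
            place_fragment(frag, labelled_refs, k=99)

    def test_missing_group_rejected(self, labelled_refs):
        frag = ProteinRecord(id="f", sequence=labelled_refs[0][0].sequence)
        with pytest.raises(ValueError, match="both"):
            place_fragment(frag, labelled_refs[:4], k=2)
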