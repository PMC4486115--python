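"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

from mbhsig.align import AlignParams
from mbhsig.seqio import ProteinRecord
from mbhsig.simulate import SimulationConfig, make_dataset, make_references

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def simple_params() -> AlignParams:
    """Unit match/mismatch scoring with small affine gaps; keeps oracle
    arithmetic transparent."""
    return AlignParams(matrix=None, match=1.0, mismatch=-1.0,
                       gap_open=-2.0, gap_extend=-1.0)


@pytest.fixture(scope="session")
def references():
    """(ref_6C, ref_4C, ref_large, scheme) in a fixed synthetic frame."""
    return make_references(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def small_bundle():
    """A small complete synthetic dataset (10 x 6C, 8 x 4C, 30% fragments)."""
    return make_dataset(
        SimulationConfig(seed=7, n_6C=10, n_4C=8, fragment_fraction=0.3)
    )


def random_protein(rng: np.random.Generator, length: int, name: str = "r") -> ProteinRecord:
    seq = "".join(AA20[i] for i in rng.integers(0, 20, size=length))
    return ProteinRecord(id=name, sequence=seq)


# ---------------------------------------------------------------------------
# Independent alignment oracles
# ---------------------------------------------------------------------------

def enumerate_best_score(a: str, b: str, match: float, mismatch: float,
                         open_: float, ext: float) -> float:
    """Exhaustively enumerate every global alignment (no gap/gap columns) and
    return the best affine score. Exponential; lengths <= ~6 only."""
    best = [float("-inf")]

    def rec(i: int, j: int, last: str, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "D", score + s)
        if i < len(a):
            rec(i + 1, j, "U", score + (ext if last == "U" else open_))
        if j < len(b):
            rec(i, j + 1, "L", score + (ext if last == "L" else open_))

    rec(0, 0, "D", 0.0)
    return best[0]


def memo_best_score(a: str, b: str, match: float, mismatch: float,
                    open_: float, ext: float) -> float:
    """Top-down memoized optimum over the same alignment space; cheap enough
    for the exhaustive small-alphabet sweeps. Cross-validated against
    enumerate_best_score in the tests."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "D"))
        if i < len(a):
            best = max(best, (ext if last == "U" else open_) + rec(i + 1, j, "U"))
        if j < len(b):
            best = max(best, (ext if last == "L" else open_) + rec(i, j + 1, "L"))
        return best

    return rec(0, 0, "D")
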