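"""Hypergeometric gene-set overlap testing and recursive de-overlap.

Two gene sets A and B drawn from a universe of N genes share n genes; the
upper-tail hypergeometric probability P(X >= n) measures how surprising
that overlap is under independence.  Pairs with P < alpha are "similar",
and the reduction recursively removes the set with the highest similarity
degree until no similar pairs remain, leaving a collection of (almost)
disjoint sets suitable for pathway-restricted diversity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "SimilarityMatrix",
    "hypergeometric_overlap_p",
    "build_similarity_matrix",
    "reduce_overlap",
]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets over a common universe.

    The universe defaults to the union of all member sets; an explicit
    universe must contain every member gene.
    """

    sets: dict
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sets = {str(k): frozenset(map(str, v)) for k, v in self.sets.items()}
        if not self.sets:
            raise ValueError("collection must contain at least one gene set")
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")
        union = frozenset().union(*self.sets.values())
        if not self.universe:
            self.universe = union
        else:
            self.universe = frozenset(map(str, self.universe))
            stray = union - self.universe
            if stray:
                raise ValueError(
                    f"{len(stray)} member gene(s) outside the declared universe, "
                    f"e.g. {sorted(stray)[:5]}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SimilarityMatrix:
    """Binary set x set similarity indicator (diagonal fixed at 0)."""

    values: np.ndarray
    set_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        n = len(self.set_names)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("similarity matrix must be symmetric")
        np.fill_diagonal(self.values, 0)

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1)


def hypergeometric_overlap_p(N: int, N_A: int, N_B: int, n: int) -> float:
    """P(X >= n) for the overlap of two sets of sizes N_A, N_B in a universe of N.

    X is hypergeometric: the number of genes shared by a random N_B-subset
    with a fixed N_A-subset.  Exact upper-tail probability via the
    survival function at n - 1.
    """
    N, N_A, N_B, n = int(N), int(N_A), int(N_B), int(n)
    if min(N, N_A, N_B) < 0 or n < 0:
        raise ValueError("counts must be non-negative")
    if N_A > N or N_B > N:
        raise ValueError("set sizes cannot exceed the universe size")
    if n > min(N_A, N_B):
        raise ValueError("overlap cannot exceed the smaller set")
    if n == 0:
        return 1.0
    return float(stats.hypergeom.sf(n - 1, N, N_A, N_B))


def build_similarity_matrix(
    collection: GeneSetCollection, alpha: float = 0.05
) -> SimilarityMatrix:
    """Flag set pairs whose overlap is significant at level ``alpha``.

    Entry (A, B) is 1 iff ``P(X >= |A∩B|) < alpha`` with universe
    ``|universe|``; the statistic is symmetric in A and B, so the matrix
    is symmetric by construction.
    """
    names = collection.names
    if len(names) < 2:
        raise ValueError("need at least 2 gene sets")
    N = len(collection.universe)
    if N == 0:
        raise ValueError("empty gene universe")
    vals = np.zeros((len(names), len(names)), dtype=int)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            sa, sb = collection.sets[a], collection.sets[b]
            p = hypergeometric_overlap_p(N, len(sa), len(sb), len(sa & sb))
            if p < alpha:
                vals[i, j] = vals[j, i] = 1
    return SimilarityMatrix(vals, names)


def reduce_overlap(
    collection: GeneSetCollection,
    alpha: float = 0.05,
    return_log: bool = False,
):
    """Recursively remove the most-overlapping set until none are similar.

    At each step the set with the maximal row sum (degree) of the current
    similarity matrix is removed and the matrix is subset accordingly;
    pairwise similarity is a fixed property of each pair, so subsetting
    and recomputation coincide.  Ties on degree are broken by removing the
    larger set, then the lexicographically smallest name.

    Returns the surviving collection (whose similarity matrix is all
    zero at the same ``alpha``); with ``return_log=True`` also a list of
    ``(name, degree_at_removal, set_size)`` tuples.
    """
    names = collection.names
    log: list[tuple[str, int, int]] = []
    if len(names) < 2:
        result = GeneSetCollection(dict(collection.sets), collection.universe)
        return (result, log) if return_log else result
    sim = build_similarity_matrix(collection, alpha=alpha).values
    active = list(range(len(names)))
    while True:
        sub = sim[np.ix_(active, active)]
        deg = sub.sum(axis=1)
        dmax = deg.max(initial=0)
        if dmax == 0:
            break
        cands = [active[i] for i in np.flatnonzero(deg == dmax)]
        victim = min(
            cands, key=lambda i: (-len(collection.sets[names[i]]), names[i])
        )
        log.append((names[victim], int(dmax), len(collection.sets[names[victim]])))
        active.remove(victim)
    surviving = {names[i]: collection.sets[names[i]] for i in active}
    result = GeneSetCollection(surviving, collection.universe)
    return (result, log) if return_log else result
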