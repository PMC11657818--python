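"""The partition lattice of a small element set.

All partitions of a set, ordered by refinement, form a lattice: the
single-block partition at the top, the all-singletons partition at the
bottom, with Hasse (cover) edges joining partitions that differ by a
single block split.  The VI metric is aligned with this lattice — a
partition's nearest neighbors under VI are always one lump or split away,
never a "move" of an element between blocks — which is what makes VI
distances interpretable as amounts of refinement disagreement.

Enumeration is by restricted-growth strings, the canonical duplicate-free
encoding of set partitions, and is guarded by a hard cap because the Bell
numbers B(n) grow super-exponentially (B(12) = 4,213,597).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Sequence

import pandas as pd

from .partition import Partition, PartitionError, is_refinement
from .metrics import vi_distance

__all__ = [
    "bell_number",
    "enumerate_partitions",
    "LatticeGraph",
    "hasse_edges",
    "nearest_lattice_neighbors",
]

DEFAULT_ENUMERATION_CAP = 12


@lru_cache(maxsize=None)
def bell_number(n: int) -> int:
    """B(n), the number of set partitions of n elements (B(0) = 1)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    # Bell triangle
    row = [1]
    for _ in range(n):
        nxt = [row[-1]]
        for x in row:
            nxt.append(nxt[-1] + x)
        row = nxt
    return row[0]


def _restricted_growth_strings(n: int):
    """Yield all restricted-growth strings of length n.

    A restricted-growth string assigns element i a block index a[i] with
    a[0] = 0 and a[i] <= 1 + max(a[:i]); each set partition corresponds to
    exactly one such string.
    """
    a = [0] * n
    while True:
        yield tuple(a)
        # next string in lexicographic order
        for i in range(n - 1, 0, -1):
            if a[i] <= max(a[:i]):
                a[i] += 1
                for j in range(i + 1, n):
                    a[j] = 0
                break
        else:
            return


def enumerate_partitions(
    elements: Sequence[str],
    cap: int = DEFAULT_ENUMERATION_CAP,
    allow_large: bool = False,
) -> list[Partition]:
    """Every partition of *elements* exactly once, in deterministic order.

    Order: number of blocks K descending (finest first), then canonical
    block order.  The count is the Bell number B(n).  Raises for
    n > *cap* unless ``allow_large=True``; enumeration beyond a dozen
    elements is almost never what pairwise analysis wants.
    """
    elements = list(elements)
    n = len(elements)
    if n < 1:
        raise PartitionError("need at least one element")
    if len(set(elements)) != n:
        raise PartitionError("element labels must be unique")
    if n > cap and not allow_large:
        raise PartitionError(
            f"enumerating partitions of {n} elements exceeds the cap of {cap} "
            f"(B({n}) = {bell_number(n)} partitions); pass allow_large=True "
            "to override"
        )
    out = []
    for rgs in _restricted_growth_strings(n):
        k = max(rgs) + 1
        blocks: list[list[str]] = [[] for _ in range(k)]
        for lab, b in zip(elements, rgs):
            blocks[b].append(lab)
        out.append(Partition(blocks))
    out.sort(key=lambda p: (-p.num_blocks, p.blocks))
    for i, p in enumerate(out, start=1):
        out[i - 1] = p.with_fields(label=f"ptn_{i}")
    return out


@dataclass(frozen=True)
class LatticeGraph:
    """Hasse diagram of the partition lattice: nodes plus cover edges.

    Edges are directed coarser → finer; each edge corresponds to splitting
    exactly one block of the coarser partition into two, so endpoint block
    counts differ by exactly one.  The edge set is the transitive
    reduction of the refinement order.
    """

    nodes: tuple[Partition, ...]
    edges: tuple[tuple[int, int], ...]  # (coarser index, finer index)

    def edge_partitions(self) -> list[tuple[Partition, Partition]]:
        return [(self.nodes[i], self.nodes[j]) for i, j in self.edges]

    def to_edge_table(self) -> pd.DataFrame:
        """Two-column edge list (coarser label, finer label)."""
        return pd.DataFrame(
            [
                {"coarser": self.nodes[i].label, "finer": self.nodes[j].label}
                for i, j in self.edges
            ]
        )

    def to_dot(self) -> str:
        """Graphviz DOT for rendering the Hasse diagram."""

        def fmt(p: Partition) -> str:
            return "|".join(",".join(b) for b in p.blocks)

        lines = ["digraph partition_lattice {", "  rankdir=TB;"]
        for idx, p in enumerate(self.nodes):
            lines.append(f'  n{idx} [label="{fmt(p)}"];')
        for i, j in self.edges:
            lines.append(f"  n{i} -> n{j};")
        lines.append("}")
        return "\n".join(lines)


def hasse_edges(nodes: Sequence[Partition]) -> LatticeGraph:
    """Cover edges of the refinement order over a complete enumeration.

    *nodes* must be the full partition lattice of one element set (the
    output of :func:`enumerate_partitions`); an incomplete node set would
    silently produce spurious covers, so completeness is checked against
    the Bell number.
    """
    nodes = tuple(nodes)
    if not nodes:
        raise PartitionError("empty node set")
    domain = nodes[0].elements
    if any(p.elements != domain for p in nodes):
        raise PartitionError("lattice nodes must share one element set")
    n = len(domain)
    if len(set(nodes)) != bell_number(n):
        raise PartitionError(
            f"node set is not the complete lattice of {n} elements: "
            f"got {len(set(nodes))} distinct nodes, expected B({n}) = "
            f"{bell_number(n)}"
        )
    edges = []
    for i, coarse in enumerate(nodes):
        for j, fine in enumerate(nodes):
            # covers in the partition lattice are exactly the refinement
            # pairs whose block counts differ by one
            if fine.num_blocks == coarse.num_blocks + 1 and is_refinement(
                fine, coarse
            ):
                edges.append((i, j))
    return LatticeGraph(nodes=nodes, edges=tuple(edges))


def nearest_lattice_neighbors(
    p: Partition,
    universe: Sequence[Partition],
    metric: Callable[[Partition, Partition], float] = vi_distance,
) -> list[Partition]:
    """All partitions in *universe* at minimal metric distance from *p*.

    Ties are all returned: symmetric partitions produce exact ties and an
    arbitrary single winner would misrepresent the neighborhood.
    """
    if p not in universe:
        raise PartitionError("p must be a member of the universe")
    dists = [(metric(p, q), q) for q in universe if q != p]
    if not dists:
        return []
    dmin = min(d for d, _ in dists)
    return [q for d, q in dists if d == dmin]
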