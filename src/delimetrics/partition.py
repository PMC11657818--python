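"""Set partitions of lineage labels: the data model behind every metric.

A species delimitation model assigns each sampled lineage (or population)
to exactly one species unit.  Formally it is a set partition of the sample
labels: a collection of non-empty, pairwise-disjoint blocks whose union is
the full label set.  This module provides the :class:`Partition` container
in canonical form, collections of partitions over a shared label domain
(:class:`PartitionSet`), and the set-theoretic primitives the
information-theoretic machinery consumes: block probabilities, block
intersection counts (:class:`ContingencyTable`), the refinement partial
order, and the lattice meet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "PartitionError",
    "IncomparableDomainsError",
    "Partition",
    "PartitionSet",
    "ContingencyTable",
    "build_partition",
    "block_probabilities",
    "contingency_table",
    "is_refinement",
    "meet",
]


class PartitionError(ValueError):
    """A partition violates its structural invariants."""


class IncomparableDomainsError(PartitionError):
    """Two partitions do not share an identical element set.

    Partitions over different label sets are incomparable: no partition
    metric is defined between them, and silently restricting to the shared
    labels would change the quantity being measured.  The symmetric
    difference of the two domains is reported to aid debugging.
    """

    def __init__(self, left_only: Iterable[str], right_only: Iterable[str]) -> None:
        self.left_only = frozenset(left_only)
        self.right_only = frozenset(right_only)
        parts = []
        if self.left_only:
            parts.append(f"only in first: {sorted(self.left_only)}")
        if self.right_only:
            parts.append(f"only in second: {sorted(self.right_only)}")
        super().__init__(
            "partitions are over different element sets (" + "; ".join(parts) + ")"
        )


def _canonicalize(blocks: Iterable[Iterable[str]]) -> tuple[tuple[str, ...], ...]:
    """Validate raw blocks and return the canonical form.

    Canonical form: within each block labels sorted lexicographically;
    blocks ordered by descending size, ties broken by the lexicographically
    smallest member.  The canonical form is what equality, hashing, and all
    deterministic output ordering are defined on.
    """
    canon: list[tuple[str, ...]] = []
    seen: dict[str, int] = {}
    for bi, raw in enumerate(blocks):
        members = list(raw)
        if not members:
            raise PartitionError(f"block {bi} is empty")
        for lab in members:
            if not isinstance(lab, str) or not lab:
                raise PartitionError(
                    f"element labels must be non-empty strings, got {lab!r}"
                )
            if lab in seen:
                raise PartitionError(
                    f"element {lab!r} appears more than once "
                    f"(blocks {seen[lab]} and {bi})"
                )
            seen[lab] = bi
        canon.append(tuple(sorted(members)))
    if not canon:
        raise PartitionError("a partition must have at least one block")
    canon.sort(key=lambda b: (-len(b), b[0]))
    return tuple(canon)


class Partition:
    """One species-delimitation model in canonical form.

    Parameters
    ----------
    blocks:
        Iterable of iterables of element labels.  Blocks must be non-empty
    and pairwise disjoint; their union is the element set.
    label:
        Optional identifier for the model (e.g. its rank in an inference
        run).
    support:
        Optional non-negative score or probability from an inference
        method.  Carried as metadata; never required by the metrics.
    metadata:
        Free-form key/value map preserved through I/O round trips.

    Equality and hashing compare the canonical blocks only: two models
    that group the lineages identically are the same point of the metric
    space regardless of label or support.
    """

    __slots__ = ("blocks", "label", "support", "metadata", "_elements")

    def __init__(
        self,
        blocks: Iterable[Iterable[str]],
        label: str | None = None,
        support: float | None = None,
        metadata: Mapping[str, Any] | None = None,
    ) -> None:
        object.__setattr__(self, "blocks", _canonicalize(blocks))
        if support is not None:
            support = float(support)
            if support < 0:
                raise PartitionError(f"support must be non-negative, got {support}")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "metadata", dict(metadata or {}))
        object.__setattr__(
            self, "_elements", frozenset(lab for blk in self.blocks for lab in blk)
        )

    def __setattr__(self, name: str, value: Any) -> None:  # pragma: no cover
        raise AttributeError("Partition is immutable")

    # -- structure ---------------------------------------------------------

    @property
    def n(self) -> int:
        """Total number of elements."""
        return len(self._elements)

    @property
    def num_blocks(self) -> int:
        """Number of blocks (species units), K."""
        return len(self.blocks)

    # K is the symbol used throughout the literature.
    K = num_blocks

    @property
    def elements(self) -> frozenset[str]:
        """The element label set."""
        return self._elements

    def block_sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.blocks], dtype=np.int64)

    def block_of(self, element: str) -> tuple[str, ...]:
        """Return the block containing *element*."""
        for blk in self.blocks:
            if element in blk:
                return blk
        raise KeyError(element)

    def block_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(frozenset(b) for b in self.blocks)

    # -- identity ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.blocks == other.blocks

    def __hash__(self) -> int:
        return hash(self.blocks)

    def __repr__(self) -> str:
        blocks = ", ".join("{" + ",".join(b) + "}" for b in self.blocks)
        name = f" {self.label!r}" if self.label else ""
        return f"<Partition{name} n={self.n} K={self.num_blocks} {blocks}>"

    def with_fields(
        self,
        label: str | None = None,
        support: float | None = None,
        metadata: Mapping[str, Any] | None = None,
    ) -> "Partition":
        """Copy with replaced label/support/metadata (blocks unchanged)."""
        return Partition(
            self.blocks,
            label=label if label is not None else self.label,
            support=support if support is not None else self.support,
            metadata=metadata if metadata is not None else self.metadata,
        )


def build_partition(
    blocks: Iterable[Iterable[str]],
    label: str | None = None,
    support: float | None = None,
    metadata: Mapping[str, Any] | None = None,
) -> Partition:
    """Construct a canonicalized :class:`Partition` from raw blocks."""
    return Partition(blocks, label=label, support=support, metadata=metadata)


def block_probabilities(p: Partition) -> np.ndarray:
    """Block membership probabilities p(k) = n_k / n.

    A uniformly random element lands in block k with probability
    proportional to the block's size; this is the distribution whose
    Shannon entropy measures how finely the model divides the samples.
    """
    sizes = p.block_sizes()
    return sizes / sizes.sum()


def _check_same_domain(u: Partition, v: Partition) -> None:
    if u.elements != v.elements:
        raise IncomparableDomainsError(
            u.elements - v.elements, v.elements - u.elements
        )


@dataclass(frozen=True)
class ContingencyTable:
    """Block-intersection counts between two partitions of one element set.

    Entry (i, j) is the number of elements shared by block i of the row
    partition and block j of the column partition.  Normalized by n this
    is the joint block-membership distribution, the object from which
    mutual information is computed.
    """

    row_partition: Partition
    col_partition: Partition
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if not np.array_equal(counts.sum(axis=1), self.row_partition.block_sizes()):
            raise PartitionError("row sums do not match row-partition block sizes")
        if not np.array_equal(counts.sum(axis=0), self.col_partition.block_sizes()):
            raise PartitionError("column sums do not match col-partition block sizes")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def joint_probabilities(self) -> np.ndarray:
        """p(k_i, k_j) = |block_i ∩ block_j| / n."""
        return self.counts / self.counts.sum()

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.col_partition, self.row_partition, self.counts.T)


def contingency_table(u: Partition, v: Partition) -> ContingencyTable:
    """Block-intersection count matrix between two comparable partitions."""
    _check_same_domain(u, v)
    col_index: dict[str, int] = {}
    for j, blk in enumerate(v.blocks):
        for lab in blk:
            col_index[lab] = j
    counts = np.zeros((u.num_blocks, v.num_blocks), dtype=np.int64)
    for i, blk in enumerate(u.blocks):
        for lab in blk:
            counts[i, col_index[lab]] += 1
    return ContingencyTable(u, v, counts)


def is_refinement(u: Partition, v: Partition) -> bool:
    """True iff *u* is finer than or equal to *v*.

    u refines v when every block of u lies entirely inside some block of v
    — i.e. v can be obtained from u purely by lumping blocks together.
    This relation is the partial order of the partition lattice.
    """
    _check_same_domain(u, v)
    container: dict[str, frozenset[str]] = {}
    for blk in v.block_sets():
        for lab in blk:
            container[lab] = blk
    return all(set(blk) <= container[blk[0]] for blk in u.blocks)


def meet(u: Partition, v: Partition) -> Partition:
    """The lattice meet: coarsest common refinement (blockwise intersections).

    Its entropy is the joint entropy H(u, v); exposed for internal use and
    property testing rather than as a headline operation.
    """
    _check_same_domain(u, v)
    blocks = []
    for a in u.block_sets():
        for b in v.block_sets():
            cell = a & b
            if cell:
                blocks.append(sorted(cell))
    return Partition(blocks)


class PartitionSet:
    """An ordered collection of partitions over one common label domain.

    File order is preserved and authoritative: readers never reorder, and
    all pairwise tables index partitions by their position here.  Member
    labels must be unique within the set (unnamed members are assigned
    ``pt_1``, ``pt_2``, ... on construction).
    """

    def __init__(
        self,
        partitions: Iterable[Partition],
        source: str = "",
    ) -> None:
        members: list[Partition] = []
        labels: set[str] = set()
        for idx, p in enumerate(partitions, start=1):
            if p.label is None:
                p = p.with_fields(label=f"pt_{idx}")
            if p.label in labels:
                raise PartitionError(f"duplicate partition label {p.label!r}")
            labels.add(p.label)
            members.append(p)
        if not members:
            raise PartitionError("a PartitionSet must contain at least one partition")
        domain = members[0].elements
        for p in members[1:]:
            if p.elements != domain:
                raise IncomparableDomainsError(
                    domain - p.elements, p.elements - domain
                )
        self._partitions = tuple(members)
        self.element_domain = domain
        self.source = source

    def __iter__(self) -> Iterator[Partition]:
        return iter(self._partitions)

    def __len__(self) -> int:
        return len(self._partitions)

    def __getitem__(self, idx: int) -> Partition:
        return self._partitions[idx]

    @property
    def partitions(self) -> tuple[Partition, ...]:
        return self._partitions

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self._partitions)  # type: ignore[misc]

    def supports(self) -> list[float | None]:
        return [p.support for p in self._partitions]

    def collapse_duplicates(self) -> "PartitionSet":
        """Drop repeated identical partitions, keeping the first occurrence.

        Duplicates are common in ranked model lists; the default everywhere
        is keep-all, so collapsing is an explicit opt-in.
        """
        seen: set[Partition] = set()
        kept = []
        for p in self._partitions:
            if p not in seen:
                seen.add(p)
                kept.append(p)
        return PartitionSet(kept, source=self.source)

    def __repr__(self) -> str:
        return (
            f"<PartitionSet of {len(self)} partitions over "
            f"{len(self.element_domain)} elements>"
        )
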