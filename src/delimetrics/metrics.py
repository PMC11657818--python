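"""Information-theoretic statistics and distances between partitions.

The central quantity is the variation of information (VI),

    VI(u, v) = H(u) + H(v) - 2 I(u, v),

where H is the Shannon entropy of a partition's block-size distribution
and I is the mutual information of the joint (block-intersection)
distribution of two partitions.  VI is a true metric on the space of
partitions of a fixed element set: non-negative, symmetric, zero exactly
on equal partitions, and satisfying the triangle inequality.  It is also
aligned with the refinement lattice, convexly additive over disjoint
element sets, and n-invariant (it depends only on block proportions).

All quantities default to log base 2 (bits); pass ``base`` to change it.
The match ratio — a simple block-overlap similarity index in [0, 1] — is
included as the conventional point of comparison; unlike VI it is not a
metric and is blind to near-matches of blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .partition import (
    Partition,
    PartitionSet,
    _check_same_domain,
    block_probabilities,
    contingency_table,
)

__all__ = [
    "entropy",
    "mutual_information",
    "joint_entropy",
    "vi_distance",
    "normalized_vi",
    "match_ratio",
    "vi_upper_bound",
    "ComparisonRecord",
    "compare_all",
]

NviVariant = Literal["joint-entropy", "two-log-k", "log-n"]


def _xlogx(p: np.ndarray, base: float) -> np.ndarray:
    # 0 log 0 := 0 by continuity; zero cells are masked, not special-cased.
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out / math.log(base)


def entropy(p: Partition, base: float = 2.0) -> float:
    """Shannon entropy H(p) = -sum_k p(k) log p(k) of the block distribution.

    Zero for the single-block partition; at most log(n), attained by the
    all-singletons partition.
    """
    probs = block_probabilities(p)
    return float(-_xlogx(probs, base).sum())


def mutual_information(u: Partition, v: Partition, base: float = 2.0) -> float:
    """Mutual information I(u, v) of two partitions of one element set.

    I = sum_ij p(i, j) log[ p(i, j) / (p_u(i) p_v(j)) ] over the non-zero
    cells of the block-intersection table.  Symmetric, non-negative, and
    bounded by min(H(u), H(v)).
    """
    joint = contingency_table(u, v).joint_probabilities()
    pu = joint.sum(axis=1, keepdims=True)
    pv = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    ratio = np.ones_like(joint)
    ratio[nz] = joint[nz] / (pu @ pv)[nz]
    mi = float((joint[nz] * np.log(ratio[nz])).sum() / math.log(base))
    # clip the tiny negative round-off a sum of signed terms can produce
    return max(mi, 0.0)


def joint_entropy(u: Partition, v: Partition, base: float = 2.0) -> float:
    """Joint entropy H(u, v): entropy of the common refinement.

    Equals H(u) + H(v) - I(u, v); lies between max(H(u), H(v)) and
    H(u) + H(v).
    """
    joint = contingency_table(u, v).joint_probabilities()
    return float(-_xlogx(joint, base).sum())


def vi_distance(u: Partition, v: Partition, base: float = 2.0) -> float:
    """Variation of information VI(u, v) = H(u) + H(v) - 2 I(u, v).

    A true metric on partitions of a fixed element set, bounded above by
    log(n) and by 2 log max(K_u, K_v).
    """
    if u == v:
        # exact identity of the metric; avoids ~1e-16 residue from the two
        # different float paths of H and I
        return 0.0
    vi = entropy(u, base) + entropy(v, base) - 2.0 * mutual_information(u, v, base)
    return max(vi, 0.0)


def normalized_vi(
    u: Partition,
    v: Partition,
    base: float = 2.0,
    variant: NviVariant = "joint-entropy",
) -> float:
    """VI rescaled to [0, 1].

    The default divides by the joint entropy H(u, v) (equivalently
    1 - I/H(u,v)), which keeps the metric properties and remains
    comparable across datasets of different sizes.  The bound-based
    variants divide by 2 log K_max (``"two-log-k"``) or log n (``"log-n"``);
    they are provided because they are in common use, but they tie the
    scale to the dataset, which defeats cross-dataset comparison and
    breaks convex additivity.
    """
    vi = vi_distance(u, v, base)
    if variant == "joint-entropy":
        denom = joint_entropy(u, v, base)
    elif variant == "two-log-k":
        denom = 2.0 * math.log(max(u.num_blocks, v.num_blocks), base)
    elif variant == "log-n":
        denom = math.log(u.n, base)
    else:
        raise ValueError(
            f"unknown normalization variant {variant!r}; expected one of "
            "'joint-entropy', 'two-log-k', 'log-n'"
        )
    if denom == 0.0:
        # both partitions are the single-block partition: VI = 0 as well
        return 0.0
    return min(vi / denom, 1.0)


def match_ratio(u: Partition, v: Partition) -> float:
    """Match ratio MR = 2 m / (K_u + K_v), m = number of identical blocks.

    Blocks count as matched only under exact set equality, which is what
    makes MR discontinuous: splitting one element off a large block drops
    every match involving that block, however negligible the change.
    """
    _check_same_domain(u, v)
    m = len(set(u.block_sets()) & set(v.block_sets()))
    return 2.0 * m / (u.num_blocks + v.num_blocks)


def vi_upper_bound(
    n: int | None = None,
    max_k: int | None = None,
    base: float = 2.0,
) -> float:
    """Upper bound on VI: 2 log K_max if K is constrained, log n otherwise.

    When both constraints are supplied the tighter (smaller) bound applies.
    """
    bounds = []
    if max_k is not None:
        if max_k < 1:
            raise ValueError("max_k must be >= 1")
        bounds.append(2.0 * math.log(max_k, base))
    if n is not None:
        if n < 1:
            raise ValueError("n must be >= 1")
        bounds.append(math.log(n, base))
    if not bounds:
        raise ValueError("provide n (any partition possible) and/or max_k")
    return min(bounds)


@dataclass(frozen=True)
class ComparisonRecord:
    """One pairwise comparison row: all statistics for a pair of models."""

    label_1: str
    label_2: str
    H_1: float
    H_2: float
    mutual_information: float
    joint_entropy: float
    vi_distance: float
    vi_normalized: float
    match_ratio: float
    support_1: float | None = None
    support_2: float | None = None

    METRIC_COLUMNS = (
        "H_1",
        "H_2",
        "mutual_information",
        "joint_entropy",
        "vi_distance",
        "vi_normalized",
        "match_ratio",
    )


def compare_one(
    u: Partition,
    v: Partition,
    base: float = 2.0,
    nvi_variant: NviVariant = "joint-entropy",
) -> ComparisonRecord:
    """All pairwise statistics for one ordered pair of partitions."""
    h1 = entropy(u, base)
    h2 = entropy(v, base)
    # for equal partitions the identities I = H and VI = 0 are exact
    mi = h1 if u == v else mutual_information(u, v, base)
    return ComparisonRecord(
        label_1=u.label or "",
        label_2=v.label or "",
        H_1=h1,
        H_2=h2,
        mutual_information=mi,
        joint_entropy=h1 + h2 - mi,
        vi_distance=max(h1 + h2 - 2.0 * mi, 0.0),
        vi_normalized=normalized_vi(u, v, base, nvi_variant),
        match_ratio=match_ratio(u, v),
        support_1=u.support,
        support_2=v.support,
    )


def compare_all(
    ps: PartitionSet | Iterable[Partition],
    base: float = 2.0,
    nvi_variant: NviVariant = "joint-entropy",
) -> list[ComparisonRecord]:
    """Full ordered-pair comparison grid (self-pairs included).

    Emits one record for every ordered pair in input order, N^2 records
    for N partitions.  The full grid (rather than the upper triangle)
    makes square distance matrices and support-vs-distance scatters
    trivial to assemble; symmetry of VI is a checked invariant of the
    test suite, not an assumption baked into the writer.
    """
    members = list(ps)
    return [
        compare_one(u, v, base=base, nvi_variant=nvi_variant)
        for u in members
        for v in members
    ]
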