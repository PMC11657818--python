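"""Seeded generators of partitions, supported model sets, and format files.

Everything the test suite and the examples consume is generated here, so
no external dataset is ever required.  Two partition models are provided:

* ``uniform`` — an exact draw from the uniform distribution over all
  B(n) set partitions, via the first-element block-size recursion on the
  Bell numbers: the block containing the first remaining element has
  k - 1 further members with probability C(n-1, k-1) B(n-k) / B(n).
* ``crp`` — a Chinese restaurant process with concentration ``alpha``,
  the standard exchangeable prior over partitions; small alpha favors
  few large blocks (lumped models), large alpha many small ones.

``perturb_partition`` walks the partition lattice by random single
lump-or-split cover moves, which is how near-neighbor fixtures are built.
Support models emulate ranked inference output (a descending probability
profile per model, as a "most probable models" list would report).

One root seed drives a named substream per artifact (partition draws,
supports, file layout) so adding a generator never shifts existing
fixtures.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .lattice import bell_number
from .partition import Partition, PartitionError, PartitionSet
from . import io as dio

__all__ = [
    "GeneratorConfig",
    "default_elements",
    "random_partition",
    "random_partition_set",
    "perturb_partition",
    "fixture_files",
]

UNIFORM_N_CAP = 500  # Bell recursion with exact integers stays fast well past this


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of one root seed."""
    digest = hashlib.sha256(name.encode()).digest()[:4]
    key = int.from_bytes(digest, "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def default_elements(n: int) -> list[str]:
    width = len(str(n))
    return [f"L{str(i).zfill(width)}" for i in range(1, n + 1)]


@lru_cache(maxsize=None)
def _first_block_probs(n: int) -> np.ndarray:
    """P(first element's block has size k), k = 1..n, under the uniform law."""
    bn = bell_number(n)
    weights = [
        math.comb(n - 1, k - 1) * bell_number(n - k) for k in range(1, n + 1)
    ]
    return np.array([w / bn for w in weights])


def _uniform_blocks(elements: list[str], rng: np.random.Generator) -> list[list[str]]:
    remaining = list(elements)
    blocks = []
    while remaining:
        n = len(remaining)
        k = int(rng.choice(n, p=_first_block_probs(n))) + 1
        head, rest = remaining[0], remaining[1:]
        others = list(rng.choice(len(rest), size=k - 1, replace=False)) if k > 1 else []
        members = [head] + [rest[i] for i in others]
        blocks.append(members)
        chosen = set(others)
        remaining = [x for i, x in enumerate(rest) if i not in chosen]
    return blocks


def _crp_blocks(
    elements: list[str], alpha: float, rng: np.random.Generator
) -> list[list[str]]:
    blocks: list[list[str]] = []
    for i, lab in enumerate(elements):
        if not blocks:
            blocks.append([lab])
            continue
        weights = np.array([len(b) for b in blocks] + [alpha], dtype=float)
        choice = int(rng.choice(len(weights), p=weights / weights.sum()))
        if choice == len(blocks):
            blocks.append([lab])
        else:
            blocks[choice].append(lab)
    return blocks


def random_partition(
    n: int,
    seed: int | np.random.Generator,
    model: Literal["uniform", "crp"] = "uniform",
    crp_alpha: float = 1.5,
    elements: Sequence[str] | None = None,
    label: str | None = None,
) -> Partition:
    """Draw one random partition of *n* elements.

    ``seed`` may be an integer (a fresh stream is derived) or an existing
    :class:`numpy.random.Generator` to draw from in sequence.
    """
    if n < 1:
        raise PartitionError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else _substream(seed, "partition-draws")
    )
    elems = list(elements) if elements is not None else default_elements(n)
    if len(elems) != n:
        raise PartitionError(f"expected {n} elements, got {len(elems)}")
    if model == "uniform":
        if n > UNIFORM_N_CAP:
            raise PartitionError(
                f"uniform sampling capped at n = {UNIFORM_N_CAP} "
                f"(requested n = {n})"
            )
        blocks = _uniform_blocks(elems, rng)
    elif model == "crp":
        if crp_alpha <= 0:
            raise PartitionError("crp_alpha must be positive")
        blocks = _crp_blocks(elems, crp_alpha, rng)
    else:
        raise PartitionError(f"unknown model {model!r}; expected 'uniform' or 'crp'")
    return Partition(blocks, label=label)


def perturb_partition(
    p: Partition,
    steps: int,
    seed: int | np.random.Generator,
) -> Partition:
    """Apply *steps* random single lump-or-split moves (lattice cover moves).

    Each step merges two random blocks or splits one random block into
    two non-empty parts, with the move type drawn uniformly; a move
    blocked at the lattice top (nothing to split) or bottom (nothing to
    lump) falls back to the other type.  ``steps=0`` returns *p*
    unchanged.
    """
    if steps < 0:
        raise PartitionError("steps must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else _substream(seed, "perturbation")
    )
    blocks = [list(b) for b in p.blocks]
    for _ in range(steps):
        can_lump = len(blocks) >= 2
        can_split = any(len(b) >= 2 for b in blocks)
        if not can_lump and not can_split:
            break  # n = 1: the lattice is a single node
        lump = can_lump and (not can_split or rng.random() < 0.5)
        if lump:
            i, j = rng.choice(len(blocks), size=2, replace=False)
            merged = blocks[int(i)] + blocks[int(j)]
            blocks = [b for t, b in enumerate(blocks) if t not in (int(i), int(j))]
            blocks.append(merged)
        else:
            splittable = [t for t, b in enumerate(blocks) if len(b) >= 2]
            t = int(rng.choice(splittable))
            blk = blocks.pop(t)
            # random non-empty proper subset: flip fair coins, reject trivial cuts
            while True:
                mask = rng.random(len(blk)) < 0.5
                if 0 < mask.sum() < len(blk):
                    break
            blocks.append([x for x, m in zip(blk, mask) if m])
            blocks.append([x for x, m in zip(blk, mask) if not m])
    return Partition(blocks, label=p.label, support=p.support, metadata=p.metadata)


SupportModel = Literal["none", "dirichlet", "geometric"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible recipe for a supported partition-set fixture."""

    n_elements: int = 12
    n_partitions: int = 20
    seed: int = 1
    model: Literal["uniform", "crp", "perturbation"] = "uniform"
    crp_alpha: float = 1.5
    perturb_steps: int = 2
    support_model: SupportModel = "dirichlet"

    def __post_init__(self) -> None:
        if self.n_elements < 1 or self.n_partitions < 1:
            raise PartitionError("n_elements and n_partitions must be positive")
        if self.crp_alpha <= 0:
            raise PartitionError("crp_alpha must be positive")
        if self.perturb_steps < 0:
            raise PartitionError("perturb_steps must be >= 0")


def _supports(model: SupportModel, k: int, rng: np.random.Generator) -> list[float] | None:
    if model == "none":
        return None
    if model == "dirichlet":
        vals = rng.dirichlet(np.ones(k))
    elif model == "geometric":
        raw = 0.5 ** np.arange(k)
        vals = raw / raw.sum()
    else:
        raise PartitionError(f"unknown support model {model!r}")
    return sorted((float(v) for v in vals), reverse=True)


def random_partition_set(config: GeneratorConfig) -> PartitionSet:
    """Generate a seeded :class:`PartitionSet` with optional supports.

    The ``perturbation`` model draws one anchor partition uniformly and
    derives every subsequent model by ``perturb_steps`` lattice moves from
    it, emulating a posterior sample concentrated around one delimitation.
    Supports are sorted descending to emulate a ranked candidate list.
    """
    cfg = config
    draw_rng = _substream(cfg.seed, "partition-draws")
    support_rng = _substream(cfg.seed, "supports")
    elems = default_elements(cfg.n_elements)
    partitions: list[Partition] = []
    if cfg.model == "perturbation":
        anchor = random_partition(cfg.n_elements, draw_rng, "uniform", elements=elems)
        partitions.append(anchor.with_fields(label="pt_1"))
        for i in range(2, cfg.n_partitions + 1):
            partitions.append(
                perturb_partition(anchor, cfg.perturb_steps, draw_rng).with_fields(
                    label=f"pt_{i}"
                )
            )
    else:
        for i in range(1, cfg.n_partitions + 1):
            partitions.append(
                random_partition(
                    cfg.n_elements,
                    draw_rng,
                    cfg.model,
                    crp_alpha=cfg.crp_alpha,
                    elements=elems,
                    label=f"pt_{i}",
                )
            )
    sup = _supports(cfg.support_model, len(partitions), support_rng)
    if sup is not None:
        partitions = [p.with_fields(support=s) for p, s in zip(partitions, sup)]
    return PartitionSet(partitions, source=f"simulated:{cfg.model}")


def fixture_files(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write one partition set in all three exchange formats plus a manifest.

    Emits ``partitions.generic.json``, ``partitions.delineate.json`` and
    ``partitions.spart.xml`` encoding the same :class:`PartitionSet`, and
    ``manifest.json`` recording the expected canonical forms and supports.
    Identical configs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ps = random_partition_set(config)
    paths = {
        "generic-json": out / "partitions.generic.json",
        "delineate-json": out / "partitions.delineate.json",
        "spart-xml": out / "partitions.spart.xml",
    }
    dio.write_generic_json(ps, paths["generic-json"])
    dio.write_delineate_json(ps, paths["delineate-json"])
    dio.write_spart_xml(ps, paths["spart-xml"])
    manifest = {
        "config": {
            "n_elements": config.n_elements,
            "n_partitions": config.n_partitions,
            "seed": config.seed,
            "model": config.model,
            "crp_alpha": config.crp_alpha,
            "perturb_steps": config.perturb_steps,
            "support_model": config.support_model,
        },
        "files": {k: str(v.name) for k, v in paths.items()},
        "partitions": [
            {
                "label": p.label,
                "blocks": [list(b) for b in p.blocks],
                "support": p.support,
            }
            for p in ps
        ],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    manifest["files"]["manifest"] = manifest_path.name
    return manifest
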