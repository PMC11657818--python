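"""Exploratory plots over pairwise comparison records.

The headline view is the support-vs-distance scatter: every ordered pair
of models becomes a point at (log support of model 1, log support of
model 2), colored by the chosen distance on a blue (close) to red (far)
gradient.  The background is regionalized at the 0.25/0.5/0.75 quantiles
of the models' supports, shading each of the 4x4 cells by the mean
distance of the pairs falling in it.  Read together, the plot answers
questions like "are the well-supported models mutually close?" — a
compact high-support, low-distance corner indicates one good delimitation
with minor variations, while spread elsewhere flags fundamental conflict
among weaker models.

Every plotting routine returns its numeric summary (the grid, the binned
counts) so results are testable without image comparison; the figure file
is a side effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .metrics import ComparisonRecord
from .partition import PartitionError

__all__ = ["RegionalizedGrid", "support_vs_distance_plot", "metric_profile_plot"]


@dataclass(frozen=True)
class RegionalizedGrid:
    """Quantile-regionalized summary behind the support-vs-distance plot.

    ``quantile_breaks`` are the 0.25/0.5/0.75 quantiles of the pooled
    per-model support vector (identical for both axes).  ``cell_means``
    holds the mean metric value of the ordered non-self pairs whose two
    supports fall in each of the 4x4 quantile cells, with NaN marking an
    empty cell (no pairs), and ``cell_counts`` the pair count per cell.
    Cell [0, 0] is the lowest-support corner on both axes.
    """

    quantile_breaks: np.ndarray
    cell_means: np.ndarray
    cell_counts: np.ndarray
    metric_column: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "quantile_breaks", np.asarray(self.quantile_breaks, dtype=float)
        )
        object.__setattr__(self, "cell_means", np.asarray(self.cell_means, float))
        object.__setattr__(
            self, "cell_counts", np.asarray(self.cell_counts, dtype=np.int64)
        )

    def to_tsv(self, destination) -> None:
        import pandas as pd

        rows = []
        for i in range(self.cell_means.shape[0]):
            for j in range(self.cell_means.shape[1]):
                count = int(self.cell_counts[i, j])
                rows.append(
                    {
                        "support_bin_1": i,
                        "support_bin_2": j,
                        "pair_count": count,
                        "mean_" + self.metric_column: (
                            "" if count == 0 else f"{self.cell_means[i, j]:.9g}"
                        ),
                    }
                )
        pd.DataFrame(rows).to_csv(destination, sep="\t", index=False)


def _model_supports(records: Sequence[ComparisonRecord]) -> dict[str, float]:
    """One support value per model label, in first-appearance order."""
    supports: dict[str, float] = {}
    for r in records:
        for lab, sup in ((r.label_1, r.support_1), (r.label_2, r.support_2)):
            if lab not in supports:
                if sup is None or (isinstance(sup, float) and math.isnan(sup)):
                    raise PartitionError(
                        f"model {lab!r} has no support value; a support-vs-"
                        "distance plot needs supports for every model — use "
                        "metric_profile_plot for unsupported sets"
                    )
                supports[lab] = float(sup)
    return supports


def _check_metric_column(metric_column: str) -> None:
    if metric_column not in ComparisonRecord.METRIC_COLUMNS:
        raise PartitionError(
            f"unknown metric column {metric_column!r}; valid columns: "
            f"{', '.join(ComparisonRecord.METRIC_COLUMNS)}"
        )


def support_vs_distance_plot(
    records: Sequence[ComparisonRecord],
    metric_column: str = "vi_distance",
    output_path: str | None = None,
    log_base: float = 10.0,
    support_floor: float | None = None,
    cmap: str = "coolwarm",
) -> RegionalizedGrid:
    """Scatter of pairwise distances against the two models' log supports.

    Plots every ordered non-self pair (self-pairs carry zero distance and
    would only compress the color scale).  Supports must be strictly
    positive for the log axes; zero supports raise unless a
    *support_floor* is supplied to clamp them (the recommended floor is
    two orders of magnitude below the smallest positive support, so that
    floored points are visually separated rather than silently blended).

    Returns the :class:`RegionalizedGrid` used for the background shading;
    writes a figure to *output_path* when given.
    """
    _check_metric_column(metric_column)
    supports = _model_supports(records)
    vals = np.array(list(supports.values()))
    if support_floor is not None:
        vals = np.maximum(vals, float(support_floor))
        supports = dict(zip(supports.keys(), vals))
    if np.any(vals <= 0):
        raise PartitionError(
            "supports must be strictly positive for log scaling; pass "
            "support_floor to clamp zeros"
        )
    breaks = np.quantile(vals, [0.25, 0.5, 0.75])
    if np.unique(vals).size == 1:
        warnings.warn(
            "all supports are equal: quantile regions are degenerate "
            "(single region)",
            stacklevel=2,
        )

    pairs = [r for r in records if r.label_1 != r.label_2]
    if not pairs:
        raise PartitionError("no non-self pairs to plot")

    # quantile cell index per support: 0 = below the 0.25 quantile
    def cell(s: float) -> int:
        return int(np.searchsorted(breaks, s, side="right"))

    sums = np.zeros((4, 4))
    counts = np.zeros((4, 4), dtype=np.int64)
    xs, ys, cs = [], [], []
    for r in pairs:
        s1, s2 = supports[r.label_1], supports[r.label_2]
        m = getattr(r, metric_column)
        i, j = cell(s1), cell(s2)
        sums[i, j] += m
        counts[i, j] += 1
        xs.append(math.log(s1, log_base))
        ys.append(math.log(s2, log_base))
        cs.append(m)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    grid = RegionalizedGrid(
        quantile_breaks=breaks,
        cell_means=means,
        cell_counts=counts,
        metric_column=metric_column,
    )

    if output_path is not None:
        _render_support_plot(
            xs, ys, cs, breaks, grid, metric_column, log_base, output_path, cmap
        )
    return grid


def _render_support_plot(
    xs, ys, cs, breaks, grid, metric_column, log_base, output_path, cmap
):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import Normalize

    fig, ax = plt.subplots(figsize=(7, 6))
    log_breaks = [math.log(b, log_base) for b in breaks]
    lo = min(min(xs), min(ys))
    hi = max(max(xs), max(ys))
    pad = 0.05 * (hi - lo) if hi > lo else 0.5
    edges = [lo - pad, *log_breaks, hi + pad]
    norm = Normalize(vmin=min(cs), vmax=max(cs) if max(cs) > min(cs) else min(cs) + 1)
    cmap_obj = plt.get_cmap(cmap)
    for i in range(4):
        for j in range(4):
            if grid.cell_counts[i, j] > 0:
                ax.add_patch(
                    plt.Rectangle(
                        (edges[i], edges[j]),
                        edges[i + 1] - edges[i],
                        edges[j + 1] - edges[j],
                        facecolor=cmap_obj(norm(grid.cell_means[i, j])),
                        alpha=0.35,
                        edgecolor="none",
                        zorder=0,
                    )
                )
    sc = ax.scatter(xs, ys, c=cs, cmap=cmap_obj, norm=norm, s=18, zorder=2)
    for b in log_breaks:
        ax.axvline(b, color="grey", lw=0.5, zorder=1)
        ax.axhline(b, color="grey", lw=0.5, zorder=1)
    ax.set_xlabel(f"log{log_base:g}(support of model 1)")
    ax.set_ylabel(f"log{log_base:g}(support of model 2)")
    ax.set_xlim(edges[0], edges[-1])
    ax.set_ylim(edges[0], edges[-1])
    fig.colorbar(sc, ax=ax, label=metric_column)
    ax.set_title(f"{metric_column} vs model support")
    fig.tight_layout()
    fig.savefig(output_path)
    plt.close(fig)


def metric_profile_plot(
    records: Sequence[ComparisonRecord],
    metric_column: str = "vi_distance",
    output_path: str | None = None,
    bins: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of one metric over distinct (unordered, non-self) pairs.

    Returns ``(counts, bin_edges)``; the counts sum to the number of
    distinct pairs.  Writes a histogram + ECDF figure when *output_path*
    is given.  Useful when models carry no supports.
    """
    _check_metric_column(metric_column)
    if not records:
        raise PartitionError("no comparison records")
    seen: set[frozenset[str]] = set()
    values = []
    for r in records:
        if r.label_1 == r.label_2:
            continue
        key = frozenset((r.label_1, r.label_2))
        if key in seen:
            continue
        seen.add(key)
        values.append(getattr(r, metric_column))
    if not values:
        raise PartitionError("no non-self pairs among the records")
    counts, edges = np.histogram(values, bins=bins)

    if output_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        ax1.hist(values, bins=edges, color="steelblue", edgecolor="white")
        ax1.set_xlabel(metric_column)
        ax1.set_ylabel("pair count")
        sv = np.sort(values)
        ax2.step(sv, np.arange(1, len(sv) + 1) / len(sv), where="post")
        ax2.set_xlabel(metric_column)
        ax2.set_ylabel("ECDF")
        fig.tight_layout()
        fig.savefig(output_path)
        plt.close(fig)
    return counts, edges
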