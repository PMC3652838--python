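"""Barcode-gap detection and threshold clustering into putative species.

The barcode gap is the empty interval separating within-species from
between-species pairwise distances. Its location is searched either on the
sorted distances directly (``sorted_gap``, bin-free, the default) or on a
fixed-width histogram (``histogram``). Given a threshold, sequences are
partitioned into putative species as connected components of the graph that
joins pairs closer than the threshold (single linkage, the ABGD-style rule).

Thresholds, search windows and gap bounds are expressed in percent;
distance matrices hold proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

from .distance import PairwiseDistanceMatrix

__all__ = [
    "GapReport",
    "Delimitation",
    "PartitionComparison",
    "find_barcode_gap",
    "delimit_at_threshold",
    "threshold_profile",
    "compare_delimitations",
]

Linkage = Literal["single", "complete"]


@dataclass(frozen=True)
class GapReport:
    """Location of the barcode gap (bounds in percent), or absence thereof."""

    found: bool
    gap_low: float | None
    gap_high: float | None
    method: str
    search_window: tuple[float, float]
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.found:
            lo, hi = self.search_window
            assert self.gap_low is not None and self.gap_high is not None
            if not (self.gap_low < self.gap_high):
                raise ValueError("gap_low must be < gap_high")
            if self.gap_low < lo or self.gap_high > hi:
                raise ValueError("gap bounds must lie inside the search window")

    @property
    def width(self) -> float:
        return (self.gap_high - self.gap_low) if self.found else 0.0


@dataclass(frozen=True)
class Delimitation:
    """A threshold (percent) and the resulting partition into clusters."""

    threshold: float
    clusters: tuple[frozenset[str], ...]
    undefined_pairs: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset().union(*self.clusters)

    def labels_for(self, ids: Sequence[str]) -> list[int]:
        """Integer cluster label per id, in the given order."""
        lookup = {}
        for k, cluster in enumerate(self.clusters):
            for rec_id in cluster:
                lookup[rec_id] = k
        return [lookup[i] for i in ids]


@dataclass(frozen=True)
class PartitionComparison:
    """Pair-level agreement between two partitions of the same id set."""

    n_pairs: int
    n_agree_together: int
    n_agree_apart: int
    n_split: int       # together in a, apart in b
    n_merged: int      # apart in a, together in b
    adjusted_rand_index: float


def _candidate_gaps(values: np.ndarray) -> list[tuple[float, float]]:
    """Open intervals between consecutive distinct sorted values."""
    vals = np.unique(values)
    return [(float(vals[i]), float(vals[i + 1])) for i in range(len(vals) - 1)]


def find_barcode_gap(
    distances: Iterable[float],
    window: tuple[float, float] = (1.0, 10.0),
    method: Literal["sorted_gap", "histogram"] = "sorted_gap",
    bin_width: float = 0.5,
) -> GapReport:
    """Locate the widest distance-free interval intersecting the search window.

    ``distances`` are proportions; ``window``/``bin_width`` are percent.

    sorted_gap: among the open intervals between consecutive distinct sorted
    distances that intersect the window, pick the widest (tie -> the lower
    interval, i.e. the more conservative threshold); report it clipped to
    the window.

    histogram: find the longest maximal run of empty ``bin_width``-wide bins
    within the window, then refine its edges to the nearest observed
    distances on either side (clipped to the window).
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("search window must satisfy low < high")
    pct = np.asarray(list(distances), dtype=float) * 100.0
    pct = pct[~np.isnan(pct)]
    if pct.size < 2:
        raise ValueError("need at least 2 defined distances to search for a gap")

    no_gap = GapReport(found=False, gap_low=None, gap_high=None,
                       method=method, search_window=window,
                       bin_width=bin_width if method == "histogram" else None)

    if method == "sorted_gap":
        best: tuple[float, tuple[float, float]] | None = None
        for g_lo, g_hi in _candidate_gaps(pct):
            if g_hi <= lo or g_lo >= hi:
                continue
            clipped = (max(g_lo, lo), min(g_hi, hi))
            if clipped[1] - clipped[0] <= 0:
                continue
            width = g_hi - g_lo
            if best is None or width > best[0]:
                best = (width, clipped)
        # distances may all sit above/below the window: gap between the window
        # edge and the nearest distance
        below = pct[pct <= lo]
        above = pct[pct >= hi]
        inside = pct[(pct > lo) & (pct < hi)]
        if inside.size == 0 and below.size and above.size:
            best = (hi - lo, (lo, hi)) if best is None else best
        if best is None:
            return no_gap
        g_lo, g_hi = best[1]
        return GapReport(found=True, gap_low=g_lo, gap_high=g_hi,
                         method=method, search_window=window)

    if method == "histogram":
        edges = np.arange(np.floor(lo / bin_width),
                          np.ceil(hi / bin_width) + 1) * bin_width
        counts, _ = np.histogram(pct, bins=edges)
        empty = counts == 0
        best_run: tuple[int, int] | None = None  # (start, stop) bin indices
        start = None
        for k, e in enumerate(np.append(empty, False)):
            if e and start is None:
                start = k
            elif not e and start is not None:
                if best_run is None or (k - start) > (best_run[1] - best_run[0]):
                    best_run = (start, k)
                start = None
        if best_run is None:
            return no_gap
        run_lo = float(edges[best_run[0]])
        run_hi = float(edges[best_run[1]])
        lower_obs = pct[pct <= run_lo]
        upper_obs = pct[pct >= run_hi]
        gap_low = max(float(lower_obs.max()) if lower_obs.size else run_lo, lo)
        gap_high = min(float(upper_obs.min()) if upper_obs.size else run_hi, hi)
        if not gap_low < gap_high:
            return no_gap
        return GapReport(found=True, gap_low=gap_low, gap_high=gap_high,
                         method=method, search_window=window,
                         bin_width=bin_width)

    raise ValueError(f"unknown method {method!r}")


def delimit_at_threshold(
    m: PairwiseDistanceMatrix, t: float, linkage: Linkage = "single"
) -> Delimitation:
    """Cluster sequences at threshold ``t`` (percent).

    single (default): connected components of the graph with an edge where
    d < t; strict inequality, so a pair at exactly t is split. Undefined
    (NaN) distances are treated as >= t. complete: agglomerative
    complete-linkage cut at t, for sensitivity analysis.
    """
    if t <= 0:
        raise ValueError("threshold must be positive")
    t_prop = t / 100.0
    with np.errstate(invalid="ignore"):
        adj = m.d < t_prop  # NaN compares False -> treated as >= t
    iu = np.triu_indices(m.n, k=1)
    n_undef = int(np.isnan(m.d[iu]).sum())

    if linkage == "single":
        n_comp, labels = connected_components(
            csr_matrix(adj), directed=False
        )
    elif linkage == "complete":
        from scipy.cluster.hierarchy import complete, fcluster
        # undefined pairs pushed beyond any threshold
        cond = m.condensed().copy()
        cond[np.isnan(cond)] = np.nanmax(np.append(cond, t_prop)) + 1.0
        labels = fcluster(complete(cond), t=t_prop, criterion="distance") - 1
        n_comp = labels.max() + 1
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    clusters: dict[int, set[str]] = {}
    for rec_id, lab in zip(m.ids, labels):
        clusters.setdefault(int(lab), set()).add(rec_id)
    ordered = sorted(clusters.values(), key=lambda c: min(m.ids.index(i) for i in c))
    return Delimitation(
        threshold=t,
        clusters=tuple(frozenset(c) for c in ordered),
        undefined_pairs=n_undef,
    )


def threshold_profile(
    m: PairwiseDistanceMatrix, t_grid: Sequence[float], linkage: Linkage = "single"
) -> list[tuple[float, int]]:
    """Number of clusters at each threshold; non-increasing in t."""
    if not len(t_grid):
        raise ValueError("threshold grid must be non-empty")
    return [(float(t), delimit_at_threshold(m, t, linkage).n_clusters)
            for t in t_grid]


def _as_labels(x: "Delimitation | Mapping[str, str]", ids: list[str]) -> list:
    if isinstance(x, Delimitation):
        return x.labels_for(ids)
    return [x[i] for i in ids]


def compare_delimitations(
    a: Delimitation,
    b: "Delimitation | Mapping[str, str]",
) -> PartitionComparison:
    """Pairwise agreement and adjusted Rand index between two partitions.

    ``b`` may be another delimitation or a mapping id -> reference label
    (e.g. the simulator's truth). Both must cover the same id set.
    """
    ids_a = a.ids
    ids_b = b.ids if isinstance(b, Delimitation) else frozenset(b)
    if ids_a != ids_b:
        raise ValueError("partitions cover different id sets")
    ids = sorted(ids_a)
    la = _as_labels(a, ids)
    lb = _as_labels(b, ids)
    n = len(ids)
    together_a = np.equal.outer(la, la)
    together_b = np.equal.outer(np.asarray(lb, dtype=object),
                                np.asarray(lb, dtype=object)).astype(bool)
    iu = np.triu_indices(n, k=1)
    ta, tb = together_a[iu], together_b[iu]
    return PartitionComparison(
        n_pairs=n * (n - 1) // 2,
        n_agree_together=int((ta & tb).sum()),
        n_agree_apart=int((~ta & ~tb).sum()),
        n_split=int((ta & ~tb).sum()),
        n_merged=int((~ta & tb).sum()),
        adjusted_rand_index=float(adjusted_rand_score(lb, la)),
    )
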