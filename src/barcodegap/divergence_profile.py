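"""Divergence summaries by taxonomic level and by species/species-pair.

Partitions the pairwise distances of a dataset into three disjoint levels —
within species, within genus between species, within family between genera —
and summarizes each (average / min / max in percent plus comparison count),
the standard multi-level barcode-divergence profile.

Level assignment is exclusive and hierarchical: a congeneric pair is not also
counted as confamilial. A nested (cumulative) convention is available via
``nested=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np

from .distance import PairwiseDistanceMatrix

__all__ = [
    "LEVELS",
    "LevelSummary",
    "GroupSummary",
    "LevelPartition",
    "partition_pairs_by_level",
    "summarize_levels",
    "divergence_histogram",
    "per_group_summaries",
]

WITHIN_SPECIES = "within_species"
WITHIN_GENUS = "within_genus_between_species"
WITHIN_FAMILY = "within_family_between_genera"
LEVELS = (WITHIN_SPECIES, WITHIN_GENUS, WITHIN_FAMILY)


class _HasTaxonomy(Protocol):
    species: str | None
    genus: str | None
    family: str | None


@dataclass(frozen=True)
class LevelSummary:
    """Average/min/max divergence (percent) and comparison count at one level."""

    level: str
    avg: float
    min: float
    max: float
    n_comparisons: int
    n_undefined: int = 0

    def __post_init__(self) -> None:
        if not (self.min <= self.avg <= self.max):
            raise ValueError("summary must satisfy min <= avg <= max")
        if self.n_comparisons < 1:
            raise ValueError("a summary needs at least one comparison")


@dataclass(frozen=True)
class GroupSummary:
    """Divergence summary (percent) for one species or one species pair."""

    name: str
    avg: float
    min: float
    max: float
    n_comparisons: int
    n_undefined: int = 0


@dataclass
class LevelPartition:
    """Pair distances split by taxonomic level, with bookkeeping.

    ``distances[level]`` holds the (possibly NaN) distances of the pairs
    assigned to that level; ``n_skipped`` counts pairs lacking the labels
    needed for assignment; ``n_excluded`` counts cross-family pairs.
    """

    distances: dict[str, list[float]] = field(
        default_factory=lambda: {lv: [] for lv in LEVELS}
    )
    n_skipped: int = 0
    n_excluded: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.distances.values())


def _label(value: str | None) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return value or None


def partition_pairs_by_level(
    m: PairwiseDistanceMatrix,
    taxonomy: Mapping[str, _HasTaxonomy],
    nested: bool = False,
) -> LevelPartition:
    """Assign every unordered pair to exactly one taxonomic level.

    Same species -> within_species; different species, same genus ->
    within_genus; different genera, same family -> within_family; different
    families -> excluded. Pairs whose labels are missing at the level needed
    for the decision are skipped and counted.

    With ``nested=True`` a pair is additionally counted at every enclosing
    level (a conspecific pair also counts as congeneric and confamilial).
    """
    part = LevelPartition()
    labels = {}
    for rec_id in m.ids:
        rec = taxonomy[rec_id]
        labels[rec_id] = (
            _label(rec.species), _label(rec.genus), _label(rec.family)
        )
    for id_a, id_b, dist in m.iter_pairs():
        sp_a, ge_a, fa_a = labels[id_a]
        sp_b, ge_b, fa_b = labels[id_b]
        if None in (sp_a, sp_b):
            part.n_skipped += 1
            continue
        if sp_a == sp_b:
            part.distances[WITHIN_SPECIES].append(dist)
            if not nested:
                continue
        if None in (ge_a, ge_b):
            if sp_a != sp_b:
                part.n_skipped += 1
            continue
        if ge_a == ge_b:
            if sp_a != sp_b or nested:
                part.distances[WITHIN_GENUS].append(dist)
            if not nested:
                continue
        if None in (fa_a, fa_b):
            if ge_a != ge_b:
                part.n_skipped += 1
            continue
        if fa_a == fa_b:
            if ge_a != ge_b or nested:
                part.distances[WITHIN_FAMILY].append(dist)
        else:
            part.n_excluded += 1
    return part


def _summarize(values: Sequence[float]) -> tuple[float, float, float, int, int]:
    arr = np.asarray(values, dtype=float)
    defined = arr[~np.isnan(arr)]
    n_undef = arr.size - defined.size
    if defined.size == 0:
        raise ValueError("no defined distances to summarize")
    return (
        float(defined.mean()) * 100.0,
        float(defined.min()) * 100.0,
        float(defined.max()) * 100.0,
        int(defined.size),
        int(n_undef),
    )


def summarize_levels(partition: LevelPartition) -> list[LevelSummary]:
    """Per-level average/min/max (percent) and comparison counts.

    Levels without any pair are omitted; undefined distances are excluded
    from the statistics but reported in ``n_undefined``.
    """
    out = []
    for level in LEVELS:
        values = partition.distances[level]
        if not values:
            continue
        avg, mn, mx, n, n_undef = _summarize(values)
        out.append(LevelSummary(level=level, avg=avg, min=mn, max=mx,
                                n_comparisons=n, n_undefined=n_undef))
    return out


def divergence_histogram(
    distances: Iterable[float], bin_width: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of distances (input: proportions) on percent-scale bins.

    Bins are half-open ``[k*w, (k+1)*w)`` from 0 up to the maximum observed
    value; a value exactly on an edge falls in the upper bin. Returns
    ``(edges, counts)`` with ``len(edges) == len(counts) + 1``; NaN inputs
    are dropped. Counts sum to the number of defined distances.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pct = np.asarray(list(distances), dtype=float) * 100.0
    pct = pct[~np.isnan(pct)]
    if pct.size == 0:
        return np.array([]), np.array([], dtype=int)
    if (pct < 0).any():
        raise ValueError("distances must be non-negative")
    idx = np.floor(pct / bin_width).astype(int)
    counts = np.bincount(idx)
    edges = np.arange(len(counts) + 1) * bin_width
    return edges, counts


def per_group_summaries(
    m: PairwiseDistanceMatrix,
    group_labels: Mapping[str, str | None],
    mode: str = "intra",
    pair_list: Sequence[tuple[str, str]] | None = None,
) -> tuple[list[GroupSummary], list[str]]:
    """Within-group or between-group-pair divergence summaries.

    ``mode="intra"``: one summary per group with >= 2 members, over all
    within-group pairs; singleton groups are skipped and returned in the
    second element (they contribute no comparison).

    ``mode="inter"``: ``pair_list`` names group pairs; each summary covers
    all cross pairs between the two groups' members.
    """
    members: dict[str, list[str]] = {}
    for rec_id in m.ids:
        g = _label(group_labels.get(rec_id))
        if g is not None:
            members.setdefault(g, []).append(rec_id)

    summaries: list[GroupSummary] = []
    skipped: list[str] = []
    if mode == "intra":
        for g, ids in members.items():
            if len(ids) < 2:
                skipped.append(g)
                continue
            vals = [m.pair(a, b) for k, a in enumerate(ids) for b in ids[k + 1:]]
            avg, mn, mx, n, n_undef = _summarize(vals)
            summaries.append(GroupSummary(name=g, avg=avg, min=mn, max=mx,
                                          n_comparisons=n, n_undefined=n_undef))
    elif mode == "inter":
        if not pair_list:
            raise ValueError("inter mode requires pair_list")
        for g_a, g_b in pair_list:
            for g in (g_a, g_b):
                if g not in members:
                    raise ValueError(f"unknown group name {g!r} in pair_list")
            vals = [m.pair(a, b) for a in members[g_a] for b in members[g_b]]
            avg, mn, mx, n, n_undef = _summarize(vals)
            summaries.append(GroupSummary(
                name=f"{g_a}-{g_b}", avg=avg, min=mn, max=mx,
                n_comparisons=n, n_undefined=n_undef,
            ))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return summaries, skipped
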