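"""Uncorrected (p) and Kimura-2-parameter genetic distances.

Distances are computed with pairwise deletion: for each sequence pair, only
sites where both sequences carry an unambiguous A/C/G/T are compared. The
K2P correction,

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)],

uses the transition proportion P (A<->G, C<->T) and transversion proportion Q
among compared sites. A pair is *undefined* (saturated) when the logarithm's
argument is non-positive or no sites are comparable; undefined entries are
stored as NaN and never silently zeroed.

Distances are stored as proportions; human-facing reports multiply by 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal

import numpy as np

from .sequence_io import Alignment

__all__ = [
    "SiteClassCounts",
    "PairwiseDistanceMatrix",
    "count_site_classes",
    "p_distance",
    "k2p_distance",
    "distance_matrix",
    "encode_sequences",
]

# A=0, C=1, G=2, T=3; anything else (gaps, N, IUPAC ambiguity) = -1, excluded.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# purine (A,G) -> 0, pyrimidine (C,T) -> 1; a difference within a class is a
# transition, across classes a transversion
_CLASS = np.array([0, 1, 0, 1], dtype=np.int8)

Model = Literal["p", "k2p"]


@dataclass(frozen=True)
class SiteClassCounts:
    """Per-pair site classification under pairwise deletion."""

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if min(self.n_compared, self.n_transitions, self.n_transversions) < 0:
            raise ValueError("site counts must be non-negative")
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("differences cannot exceed compared sites")

    @property
    def P(self) -> float:
        """Transition proportion; NaN when no sites are comparable."""
        return self.n_transitions / self.n_compared if self.n_compared else math.nan

    @property
    def Q(self) -> float:
        """Transversion proportion; NaN when no sites are comparable."""
        return self.n_transversions / self.n_compared if self.n_compared else math.nan


def encode_sequences(sequences: list[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) int8 matrix (non-ACGT = -1)."""
    if not sequences:
        raise ValueError("no sequences to encode")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must have equal length")
    buf = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return _CODE[buf].reshape(len(sequences), L)


def count_site_classes(a: str, b: str) -> SiteClassCounts:
    """Classify shared unambiguous sites as identical/transition/transversion."""
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    ca, cb = encode_sequences([a, b])
    valid = (ca >= 0) & (cb >= 0)
    diff = valid & (ca != cb)
    ts = diff & (_CLASS[np.where(valid, ca, 0)] == _CLASS[np.where(valid, cb, 0)])
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return SiteClassCounts(
        n_compared=int(valid.sum()),
        n_transitions=n_ts,
        n_transversions=n_diff - n_ts,
    )


def p_distance_from_counts(c: SiteClassCounts) -> float:
    if c.n_compared == 0:
        return math.nan
    return (c.n_transitions + c.n_transversions) / c.n_compared


def k2p_distance_from_counts(c: SiteClassCounts) -> float:
    if c.n_compared == 0:
        return math.nan
    P, Q = c.P, c.Q
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return math.nan
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise-comparable sites."""
    return p_distance_from_counts(count_site_classes(a, b))


def k2p_distance(a: str, b: str) -> float:
    """Kimura-2-parameter distance; NaN when the correction saturates."""
    return k2p_distance_from_counts(count_site_classes(a, b))


@dataclass
class PairwiseDistanceMatrix:
    """Symmetric pairwise distance matrix with per-pair compared-site counts.

    ``d`` holds proportions (NaN = undefined pair); ``sites[i, j]`` is the
    number of sites compared for that pair under pairwise deletion.
    """

    ids: list[str]
    model: Model
    d: np.ndarray
    sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.sites.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        self._index = {rec_id: i for i, rec_id in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids in distance matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    @property
    def n_undefined(self) -> int:
        """Number of unordered pairs with an undefined (saturated) distance."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.d[iu]).sum())

    def pair(self, id_a: str, id_b: str) -> float:
        return float(self.d[self._index[id_a], self._index[id_b]])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in row-major pair order (may contain NaN)."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def iter_pairs(self) -> Iterator[tuple[str, str, float]]:
        for i in range(self.n):
            for j in range(i + 1, self.n):
                yield self.ids[i], self.ids[j], float(self.d[i, j])

    def submatrix(self, keep_ids: list[str]) -> "PairwiseDistanceMatrix":
        idx = [self._index[i] for i in keep_ids]
        return PairwiseDistanceMatrix(
            ids=list(keep_ids), model=self.model,
            d=self.d[np.ix_(idx, idx)].copy(),
            sites=self.sites[np.ix_(idx, idx)].copy(),
        )


def distance_matrix(aln: Alignment, model: Model = "k2p") -> PairwiseDistanceMatrix:
    """Compute all n(n-1)/2 pairwise distances for an alignment.

    Undefined pairs (no comparable sites, or saturated K2P correction) are
    stored as NaN and counted by ``n_undefined``.
    """
    if len(aln) < 2:
        raise ValueError("distance matrix needs at least 2 records")
    if model not in ("p", "k2p"):
        raise ValueError(f"unknown model {model!r}")
    codes = encode_sequences([r.sequence for r in aln.records])
    n = len(aln)
    valid = codes >= 0
    cls = _CLASS[np.where(valid, codes, 0)]

    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(sites, valid.sum(axis=1))
    for i in range(n - 1):
        v = valid[i] & valid[i + 1:]                      # (n-i-1, L)
        diff = v & (codes[i] != codes[i + 1:])
        ts = diff & (cls[i] == cls[i + 1:])
        n_comp = v.sum(axis=1).astype(float)
        n_diff = diff.sum(axis=1)
        n_ts = ts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            if model == "p":
                row = np.where(n_comp > 0, n_diff / n_comp, np.nan)
            else:
                P = n_ts / n_comp
                Q = (n_diff - n_ts) / n_comp
                arg1 = 1.0 - 2.0 * P - Q
                arg2 = 1.0 - 2.0 * Q
                ok = (n_comp > 0) & (arg1 > 0) & (arg2 > 0)
                row = np.where(ok, -0.5 * np.log(
                    np.where(ok, arg1 * np.sqrt(np.where(arg2 > 0, arg2, 1.0)), 1.0)
                ), np.nan)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
        sites[i, i + 1:] = v.sum(axis=1)
        sites[i + 1:, i] = sites[i, i + 1:]
    return PairwiseDistanceMatrix(ids=aln.ids, model=model, d=d, sites=sites)
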