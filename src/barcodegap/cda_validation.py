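"""Canonical discriminant analysis on distance-derived coordinates, with LOOCV.

A raw pairwise-distance matrix is not a feature matrix, so the validation
follows the DAPC strategy: embed the distances by classical principal
coordinates (PCoA), retain enough axes to keep the within-group scatter
invertible, then fit Fisher's canonical discriminant axes and classify by
nearest group centroid in canonical space with equal priors. Leave-one-out
cross-validation refits the discriminant n times, holding out one sample
per fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

from .distance import PairwiseDistanceMatrix

__all__ = [
    "OrdinationCoords",
    "CdaModel",
    "LoocvReport",
    "CdaError",
    "distances_to_coordinates",
    "choose_n_components",
    "fit_cda",
    "loocv_classify",
]

_EIG_TOL = 1e-9


class CdaError(ValueError):
    """Discriminant fit is ill-posed (singular within-group scatter)."""


@dataclass
class OrdinationCoords:
    """Principal-coordinate scores of the samples.

    Components are ordered by decreasing eigenvalue; only axes with positive
    eigenvalue are retained (negative-eigenvalue axes of a non-Euclidean
    distance matrix are dropped, with the count recorded).
    """

    ids: list[str]
    coords: np.ndarray          # (n, n_components)
    eigenvalues: np.ndarray     # (n_components,)
    n_dropped_negative: int = 0

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]

    def take(self, k: int) -> "OrdinationCoords":
        return OrdinationCoords(self.ids, self.coords[:, :k].copy(),
                                self.eigenvalues[:k].copy(),
                                self.n_dropped_negative)


@dataclass
class CdaModel:
    """Fitted canonical discriminant axes and group centroids."""

    axes: np.ndarray            # (n_features, n_axes) discriminant directions
    eigenvalues: np.ndarray     # (n_axes,) between/within variance ratios
    groups: list[str]           # group order (first occurrence in input)
    centroids: np.ndarray       # (n_groups, n_axes) in canonical space
    scores: np.ndarray          # (n_samples, n_axes) training scores

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.axes

    def classify(self, x: np.ndarray) -> list[str]:
        """Nearest-centroid assignment in canonical space (equal priors).

        Ties are broken by group order in the training input.
        """
        scores = self.transform(np.atleast_2d(x))
        d2 = ((scores[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return [self.groups[int(k)] for k in np.argmin(d2, axis=1)]


@dataclass
class LoocvReport:
    """Leave-one-out confusion matrix and percent-correct summary."""

    groups: list[str]
    confusion: np.ndarray       # (g, g) counts: rows true, cols predicted
    n_failed_folds: int = 0

    @property
    def row_totals(self) -> np.ndarray:
        return self.confusion.sum(axis=1)

    @property
    def per_group_correct(self) -> np.ndarray:
        """Percent correct per (true) group; NaN for empty rows."""
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * np.diag(self.confusion) / totals,
                            np.nan)

    @property
    def overall_correct(self) -> float:
        total = self.confusion.sum()
        return 100.0 * np.trace(self.confusion) / total if total else float("nan")


def distances_to_coordinates(
    m: PairwiseDistanceMatrix, n_components: int | None = None
) -> OrdinationCoords:
    """Classical metric scaling (PCoA) of a pairwise distance matrix.

    Double-centres the squared-distance matrix, eigendecomposes, and keeps
    the top axes with positive eigenvalue, so Euclidean distances in the
    full embedding approximate the input distances. Undefined pairs are not
    allowed (filter or impute upstream).
    """
    if np.isnan(m.d).any():
        raise ValueError(
            f"distance matrix has {m.n_undefined} undefined pair(s); "
            "PCoA needs a complete matrix"
        )
    n = m.n
    d2 = m.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    gram = (gram + gram.T) / 2.0
    eigval, eigvec = linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    positive = eigval > _EIG_TOL * scale
    n_dropped = int((eigval < -_EIG_TOL * scale).sum())
    eigval, eigvec = eigval[positive], eigvec[:, positive]
    if eigval.size == 0:  # all points coincide
        return OrdinationCoords(ids=list(m.ids),
                                coords=np.zeros((n, 1)),
                                eigenvalues=np.zeros(1),
                                n_dropped_negative=n_dropped)
    coords = eigvec * np.sqrt(eigval)
    if n_components is not None:
        coords = coords[:, :n_components]
        eigval = eigval[:n_components]
    return OrdinationCoords(ids=list(m.ids), coords=coords,
                            eigenvalues=eigval, n_dropped_negative=n_dropped)


def choose_n_components(
    eigenvalues: np.ndarray, n_samples: int, n_groups: int,
    variance_fraction: float = 0.95,
) -> int:
    """Retain axes explaining ``variance_fraction`` of positive-eigenvalue
    variance, capped at ``n_samples - n_groups - 1`` so the pooled
    within-group scatter stays invertible."""
    ev = np.asarray(eigenvalues, dtype=float)
    ev = ev[ev > 0]
    if ev.size == 0:
        return 1
    cum = np.cumsum(ev) / ev.sum()
    k = int(np.searchsorted(cum, variance_fraction) + 1)
    cap = max(n_samples - n_groups - 1, 1)
    return max(1, min(k, cap, ev.size))


def _group_index(labels: Sequence[str]) -> tuple[list[str], np.ndarray]:
    groups: list[str] = []
    idx = np.empty(len(labels), dtype=int)
    lookup: dict[str, int] = {}
    for i, lab in enumerate(labels):
        if lab not in lookup:
            lookup[lab] = len(groups)
            groups.append(lab)
        idx[i] = lookup[lab]
    return groups, idx


def fit_cda(
    coords: OrdinationCoords | np.ndarray,
    group_labels: Sequence[str],
    ridge: float = 0.0,
) -> CdaModel:
    """Fit canonical discriminant axes maximizing between- over within-group
    variance (generalized eigenproblem Sb v = λ Sw v).

    Singleton groups are allowed: they contribute a centroid but no within-
    group scatter. The number of axes is min(n_groups - 1, n_features).
    Raises :class:`CdaError` when the within-group scatter is singular —
    reduce ``n_components`` of the embedding or pass a small ``ridge``.
    """
    x = coords.coords if isinstance(coords, OrdinationCoords) else np.asarray(coords)
    if x.ndim != 2 or x.shape[0] != len(group_labels):
        raise ValueError("coords/labels shape mismatch")
    groups, gidx = _group_index(list(group_labels))
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    n, p = x.shape

    grand = x.mean(axis=0)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    means = np.empty((g, p))
    for k in range(g):
        xk = x[gidx == k]
        means[k] = xk.mean(axis=0)
        centred = xk - means[k]
        sw += centred.T @ centred
        sb += len(xk) * np.outer(means[k] - grand, means[k] - grand)
    if ridge > 0:
        sw = sw + ridge * np.trace(sw) / max(p, 1) * np.eye(p)

    try:
        eigval, eigvec = linalg.eigh(sb, sw)
    except linalg.LinAlgError as exc:
        raise CdaError(
            "within-group scatter is singular; reduce the number of "
            "principal-coordinate components or set ridge > 0"
        ) from exc
    if not np.isfinite(eigval).all():
        raise CdaError(
            "within-group scatter is singular; reduce the number of "
            "principal-coordinate components or set ridge > 0"
        )
    order = np.argsort(eigval)[::-1]
    n_axes = min(g - 1, p)
    eigval, eigvec = eigval[order[:n_axes]], eigvec[:, order[:n_axes]]
    # deterministic sign: largest-magnitude loading positive
    for k in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[pivot, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = x @ eigvec
    centroids = means @ eigvec
    return CdaModel(axes=eigvec, eigenvalues=eigval, groups=groups,
                    centroids=centroids, scores=scores)


def loocv_classify(
    coords: OrdinationCoords | np.ndarray,
    group_labels: Sequence[str],
    variance_fraction: float = 0.95,
    ridge: float = 0.0,
) -> LoocvReport:
    """Leave-one-out cross-validated nearest-centroid classification.

    Each fold refits the discriminant on the remaining n-1 samples (axes
    recomputed, component count re-capped for the fold) and classifies the
    held-out sample. A held-out member of a singleton group can only be
    misclassified (its group has no training members), matching the standard
    LOOCV treatment. Folds whose fit fails are skipped and counted.
    """
    if isinstance(coords, OrdinationCoords):
        x, ev = coords.coords, coords.eigenvalues
    else:
        x = np.asarray(coords)
        ev = np.ones(x.shape[1])
    labels = list(group_labels)
    groups, gidx = _group_index(labels)
    g = len(groups)
    n = x.shape[0]
    confusion = np.zeros((g, g), dtype=int)
    n_failed = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_labels = [labels[j] for j in range(n) if mask[j]]
        if len(set(train_labels)) < 2:
            # degenerate fold: a single training group -> classify to it
            pred = train_labels[0]
        else:
            k = choose_n_components(ev, n_samples=n - 1,
                                    n_groups=len(set(train_labels)),
                                    variance_fraction=variance_fraction)
            k = min(k, x.shape[1])
            try:
                model = fit_cda(x[mask][:, :k], train_labels, ridge=ridge)
                pred = model.classify(x[i, :k])[0]
            except CdaError:
                n_failed += 1
                continue
        confusion[gidx[i], groups.index(pred)] += 1
    return LoocvReport(groups=groups, confusion=confusion, n_failed_folds=n_failed)
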