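"""Cross-gene divergence comparison: paired signed-rank tests and regressions.

Given a panel of taxa with one alignment per mitochondrial gene, computes a
distance matrix per gene over the identical taxon pairs, compares each gene
against a reference gene (COI) with Wilcoxon signed-rank tests on the paired
per-pair distances, and fits per-gene OLS regressions of gene distance on
reference-gene distance.

The signed-rank test drops zero differences, uses midranks for tied absolute
differences, computes the exact tie-aware null distribution of W+ for
n <= 25 (generating-function convolution, equivalent to enumerating all
sign assignments), and a normal approximation with continuity and tie
correction above that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .distance import Model, PairwiseDistanceMatrix, distance_matrix
from .sequence_io import Alignment

__all__ = [
    "GenePanel",
    "WilcoxonResult",
    "GeneRegression",
    "panel_distances",
    "condensed_pair_vector",
    "paired_wilcoxon",
    "regress_vs_coi",
    "compare_panel_to_reference",
]

EXACT_N_MAX = 25


@dataclass
class GenePanel:
    """One alignment per gene over a fixed ordered taxon set."""

    taxa: list[str]
    alignments: dict[str, Alignment]

    def __post_init__(self) -> None:
        for gene, aln in self.alignments.items():
            if aln.ids != self.taxa:
                raise ValueError(
                    f"gene {gene!r}: alignment taxa differ from panel taxa"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.alignments)

    @property
    def n_pairs(self) -> int:
        n = len(self.taxa)
        return n * (n - 1) // 2


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank comparison of per-pair distances between two loci.

    ``w_plus``/``w_minus`` are the rank sums of positive/negative differences
    of ``x - y`` (zeros dropped, midranks for ties); ``p_one_sided`` is for
    the alternative chosen by the sign of the median difference; ``direction``
    is set only when p < 0.05.
    """

    locus_pair: tuple[str, str]
    w_plus: float
    w_minus: float
    n_used: int
    n_zero: int
    n_dropped: int
    p_one_sided: float
    direction: str  # "<locus_a><<locus_b>", "<locus_a>><locus_b>" or "none"

    def __post_init__(self) -> None:
        expected = self.n_used * (self.n_used + 1) / 2
        if abs(self.w_plus + self.w_minus - expected) > 1e-9:
            raise ValueError("rank sums must total n(n+1)/2")


@dataclass(frozen=True)
class GeneRegression:
    """OLS fit of one gene's pairwise distances against the reference gene."""

    gene: str
    slope: float
    intercept: float
    r: float
    n: int


def panel_distances(
    panel: GenePanel, model: Model = "k2p"
) -> dict[str, PairwiseDistanceMatrix]:
    """One distance matrix per gene, all over the same taxon pair order."""
    return {gene: distance_matrix(aln, model=model)
            for gene, aln in panel.alignments.items()}


def condensed_pair_vector(m: PairwiseDistanceMatrix) -> np.ndarray:
    """Upper-triangle distances in a fixed row-major pair order."""
    return m.condensed()


def _exact_sf_wplus(ranks: np.ndarray, w_plus: float) -> float:
    """P(W+ <= w_plus) and P(W+ >= w_plus) machinery for tied midranks.

    Doubling the midranks makes them integers; the null distribution of the
    doubled W+ is the convolution of independent {0, 2r_i} contributions.
    Returns the lower-tail probability P(W+ <= w_plus).
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    target = int(np.floor(2 * w_plus + 1e-9))
    return float(dist[: target + 1].sum())


def _normal_tail_wplus(ranks: np.ndarray, w_plus: float, n: int) -> float:
    """Lower-tail P(W+ <= w_plus), normal approximation with continuity and
    tie correction."""
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mu + 0.5) / np.sqrt(var)
    return float(stats.norm.cdf(z))


def paired_wilcoxon(
    x: Sequence[float],
    y: Sequence[float],
    locus_pair: tuple[str, str] = ("x", "y"),
    alternative: Literal["auto", "less", "greater", "two-sided"] = "auto",
    alpha: float = 0.05,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test of paired distances x vs y.

    Pairs with either value undefined (NaN) are dropped and counted; zero
    differences are dropped (Wilcoxon's original treatment) and counted.
    ``alternative="auto"`` picks the one-sided alternative from the sign of
    the median non-zero difference, mirroring a directional comparison of
    locus variability; "two-sided" doubles the smaller one-sided p.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(xa) | np.isnan(ya))
    n_dropped = int((~ok).sum())
    d = xa[ok] - ya[ok]
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n = d.size
    if n == 0:
        return WilcoxonResult(locus_pair=locus_pair, w_plus=0.0, w_minus=0.0,
                              n_used=0, n_zero=n_zero, n_dropped=n_dropped,
                              p_one_sided=1.0, direction="none")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    def lower_tail(w: float) -> float:
        if n <= EXACT_N_MAX:
            return _exact_sf_wplus(ranks, w)
        return _normal_tail_wplus(ranks, w, n)

    # null is symmetric in W+/W-; the lower tail of the side supporting the
    # alternative is the one-sided p
    p_less = lower_tail(w_plus)      # alternative x < y (differences negative)
    p_greater = lower_tail(w_minus)  # alternative x > y

    if alternative == "auto":
        alternative = "less" if np.median(d) < 0 else "greater"
    if alternative == "less":
        p = p_less
        direction = "x<y"
    elif alternative == "greater":
        p = p_greater
        direction = "x>y"
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_less, p_greater))
        direction = "x<y" if p_less < p_greater else "x>y"
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if p >= alpha:
        direction = "none"
    return WilcoxonResult(locus_pair=locus_pair, w_plus=w_plus, w_minus=w_minus,
                          n_used=n, n_zero=n_zero, n_dropped=n_dropped,
                          p_one_sided=float(p), direction=direction)


def regress_vs_coi(
    x: Sequence[float], y: Sequence[float], gene: str = "gene"
) -> GeneRegression:
    """OLS line and correlation of a gene's pair distances on the reference's."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[ok], ya[ok]
    if xa.size < 3:
        raise ValueError("need at least 3 defined pairs for a regression")
    if np.ptp(xa) == 0:
        raise ValueError("zero variance in reference-gene distances")
    fit = stats.linregress(xa, ya)
    return GeneRegression(gene=gene, slope=float(fit.slope),
                          intercept=float(fit.intercept),
                          r=float(fit.rvalue), n=int(xa.size))


def compare_panel_to_reference(
    panel: GenePanel,
    reference_gene: str = "COI",
    model: Model = "k2p",
) -> tuple[list[WilcoxonResult], list[GeneRegression]]:
    """Signed-rank tests and regressions of every gene against the reference."""
    if reference_gene not in panel.alignments:
        raise ValueError(f"reference gene {reference_gene!r} not in panel")
    matrices = panel_distances(panel, model=model)
    ref = condensed_pair_vector(matrices[reference_gene])
    tests: list[WilcoxonResult] = []
    fits: list[GeneRegression] = []
    for gene in panel.genes:
        if gene == reference_gene:
            continue
        other = condensed_pair_vector(matrices[gene])
        res = paired_wilcoxon(ref, other, locus_pair=(reference_gene, gene))
        # report field-facing direction labels
        direction = {"x<y": f"{reference_gene}<{gene}",
                     "x>y": f"{reference_gene}>{gene}",
                     "none": "none"}[res.direction]
        tests.append(WilcoxonResult(
            locus_pair=res.locus_pair, w_plus=res.w_plus, w_minus=res.w_minus,
            n_used=res.n_used, n_zero=res.n_zero, n_dropped=res.n_dropped,
            p_one_sided=res.p_one_sided, direction=direction,
        ))
        fits.append(regress_vs_coi(ref, other, gene=gene))
    return tests, fits
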