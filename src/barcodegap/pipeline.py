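"""End-to-end orchestration: trim -> dedup -> distances -> profile -> gap ->
delimit -> discriminant validation -> report.

Every stage writes its tabular artifacts into one output directory; the
machine-readable summary lands in ``report.json``. Reruns with the same
config and inputs reproduce the report byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import __version__
from .sequence_io import (
    Alignment, dedup_haplotypes, read_alignment, trim_to_reference_window,
    write_alignment, write_haplotype_map,
)
from .distance import Model, PairwiseDistanceMatrix, distance_matrix
from .divergence_profile import (
    divergence_histogram, partition_pairs_by_level, per_group_summaries,
    summarize_levels,
)
from .delimitation import (
    Delimitation, compare_delimitations, delimit_at_threshold, find_barcode_gap,
)
from .cda_validation import (
    choose_n_components, distances_to_coordinates, fit_cda, loocv_classify,
)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

log = logging.getLogger("barcodegap")

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_NUMERICAL_ERROR = 3


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run.

    ``thresholds`` (percent) are each applied for delimitation; the first is
    the primary threshold whose clusters feed the discriminant validation
    when no ``group`` taxonomy labels exist.
    """

    fasta: str
    taxonomy: str | None = None
    out_dir: str = "barcodegap_out"
    model: Model = "k2p"
    reference_id: str | None = None
    window_length: int | None = None
    thresholds: tuple[float, ...] = (3.5, 4.0)
    gap_window: tuple[float, float] = (1.0, 10.0)
    gap_method: str = "sorted_gap"
    bin_width: float = 0.5
    cda_variance_fraction: float = 0.95
    run_cda: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj, key=str)] \
            if isinstance(obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    return obj


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence[Any]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


def _delimitation_dict(d: Delimitation) -> dict[str, Any]:
    return {
        "threshold_pct": d.threshold,
        "n_clusters": d.n_clusters,
        "undefined_pairs": d.undefined_pairs,
        "clusters": [sorted(c) for c in d.clusters],
    }


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns the report dict (also written to
    ``<out_dir>/report.json``). Failures raise :class:`StageError` naming
    the stage; no partial report is written."""
    out = Path(cfg.out_dir)
    report: dict[str, Any] = {
        "provenance": {
            "tool": "barcodegap",
            "version": __version__,
            "config": cfg.to_dict(),
            "config_hash": cfg.digest(),
            "seed": cfg.seed,
        },
        "stages": {},
    }

    # -- stage: read ---------------------------------------------------------
    try:
        aln = read_alignment(cfg.fasta, cfg.taxonomy, reference_id=cfg.reference_id)
    except Exception as exc:
        raise StageError("read", str(exc)) from exc
    log.info("[read] %d records, %d columns", len(aln), aln.length)
    report["stages"]["read"] = {"n_records": len(aln), "n_columns": aln.length}

    # -- stage: trim ---------------------------------------------------------
    if cfg.window_length is not None:
        if cfg.reference_id is None:
            raise StageError("trim", "window_length set but no reference_id")
        try:
            aln = trim_to_reference_window(aln, cfg.reference_id, cfg.window_length)
        except Exception as exc:
            raise StageError("trim", str(exc)) from exc
        log.info("[trim] -> %d columns", aln.length)
        report["stages"]["trim"] = {"n_columns": aln.length,
                                    "window_length": cfg.window_length}

    # -- stage: dedup --------------------------------------------------------
    try:
        deduped, hap_map = dedup_haplotypes(aln)
    except Exception as exc:
        raise StageError("dedup", str(exc)) from exc
    n_collapsed = len(aln) - len(deduped)
    log.info("[dedup] %d -> %d haplotypes (%d collapsed)",
             len(aln), len(deduped), n_collapsed)
    report["stages"]["dedup"] = {
        "n_in": len(aln), "n_haplotypes": len(deduped), "n_collapsed": n_collapsed,
    }

    # -- stage: distances ----------------------------------------------------
    try:
        m = distance_matrix(deduped, model=cfg.model)
    except Exception as exc:
        raise StageError("distances", str(exc)) from exc
    log.info("[distances] %d pairs (%d undefined), model=%s",
             m.n_pairs, m.n_undefined, cfg.model)
    report["stages"]["distances"] = {
        "model": cfg.model, "n_pairs": m.n_pairs, "n_undefined": m.n_undefined,
    }

    # -- stage: profile ------------------------------------------------------
    taxonomy = {r.id: r for r in deduped.records}
    partition = partition_pairs_by_level(m, taxonomy)
    level_summaries = summarize_levels(partition)
    edges, counts = divergence_histogram(m.condensed(), bin_width=cfg.bin_width)
    group_labels = {r.id: r.group for r in deduped.records}
    have_groups = any(v for v in group_labels.values())
    intra_summaries, singletons = ([], [])
    if have_groups:
        intra_summaries, singletons = per_group_summaries(m, group_labels, "intra")
    report["stages"]["profile"] = {
        "levels": [_jsonable(s) for s in level_summaries],
        "n_skipped_pairs": partition.n_skipped,
        "n_excluded_cross_family": partition.n_excluded,
        "per_group_intra": [_jsonable(s) for s in intra_summaries],
        "singleton_groups": sorted(singletons),
    }

    # -- stage: gap ----------------------------------------------------------
    try:
        gap = find_barcode_gap(m.condensed(), window=cfg.gap_window,
                               method=cfg.gap_method, bin_width=cfg.bin_width)
    except Exception as exc:
        raise StageError("gap", str(exc)) from exc
    log.info("[gap] found=%s low=%s high=%s", gap.found, gap.gap_low, gap.gap_high)
    report["stages"]["gap"] = _jsonable(gap)

    # -- stage: delimit ------------------------------------------------------
    delimitations = {}
    for t in cfg.thresholds:
        d = delimit_at_threshold(m, t)
        delimitations[t] = d
        log.info("[delimit] t=%.2f%% -> %d clusters", t, d.n_clusters)
    report["stages"]["delimit"] = {
        f"{t:g}": _delimitation_dict(d) for t, d in delimitations.items()
    }
    if have_groups:
        primary = delimitations[cfg.thresholds[0]]
        truth = {i: g for i, g in group_labels.items() if g}
        if set(truth) == set(primary.ids):
            cmp_res = compare_delimitations(primary, truth)
            report["stages"]["delimit"]["vs_group_labels"] = _jsonable(cmp_res)

    # -- stage: cda ----------------------------------------------------------
    if cfg.run_cda:
        labels = [group_labels[i] or "unassigned" for i in m.ids] if have_groups \
            else None
        if labels is None:
            primary = delimitations[cfg.thresholds[0]]
            lab_idx = primary.labels_for(m.ids)
            labels = [f"cluster{k + 1}" for k in lab_idx]
        if m.n_undefined:
            log.warning("[cda] skipped: %d undefined pairs", m.n_undefined)
            report["stages"]["cda"] = {"skipped": True,
                                       "reason": "undefined distances"}
        elif len(set(labels)) < 2:
            report["stages"]["cda"] = {"skipped": True, "reason": "single group"}
        else:
            try:
                coords = distances_to_coordinates(m)
                k = choose_n_components(coords.eigenvalues, m.n, len(set(labels)),
                                        cfg.cda_variance_fraction)
                model = fit_cda(coords.take(k), labels)
                loocv = loocv_classify(coords.take(k), labels,
                                       cfg.cda_variance_fraction)
            except Exception as exc:
                raise StageError("cda", str(exc)) from exc
            report["stages"]["cda"] = {
                "n_components": k,
                "n_axes": model.n_axes,
                "loocv_overall_correct_pct": loocv.overall_correct,
                "loocv_per_group_correct_pct": _jsonable(loocv.per_group_correct),
                "loocv_groups": loocv.groups,
                "loocv_confusion": _jsonable(loocv.confusion),
                "loocv_failed_folds": loocv.n_failed_folds,
            }

    # -- write artifacts -----------------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    write_alignment(deduped, out / "haplotypes.fasta", out / "haplotypes.tsv")
    write_haplotype_map(hap_map, out / "haplotype_map.tsv")
    _write_tsv(out / "level_summaries.tsv",
               ["level", "avg_pct", "min_pct", "max_pct", "n_comparisons"],
               [[s.level, f"{s.avg:.1f}", f"{s.min:.1f}", f"{s.max:.1f}",
                 s.n_comparisons] for s in level_summaries])
    _write_tsv(out / "histogram.tsv",
               ["bin_low_pct", "bin_high_pct", "count"],
               [[f"{edges[i]:g}", f"{edges[i + 1]:g}", int(counts[i])]
                for i in range(len(counts))])
    for t, d in delimitations.items():
        rows = [[rec_id, k + 1] for k, cluster in enumerate(d.clusters)
                for rec_id in sorted(cluster)]
        _write_tsv(out / f"clusters_t{t:g}.tsv", ["id", "cluster"], rows)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("[report] written to %s", out / "report.json")
    return report
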