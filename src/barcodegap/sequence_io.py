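"""Reading, trimming and deduplicating aligned barcode sequences.

The universal input of the pipeline is a multiple sequence alignment of a
mitochondrial barcode region (typically the 3' ~650 bp of COI) together with
an optional taxonomy table assigning each sequence to species / genus /
family and an optional putative-group label.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "Alignment",
    "AlignmentError",
    "WindowError",
    "read_alignment",
    "read_taxonomy",
    "write_alignment",
    "write_haplotype_map",
    "trim_to_reference_window",
    "dedup_haplotypes",
]

GAP = "-"
TAXONOMY_COLUMNS = ("id", "species", "genus", "family", "group")


class AlignmentError(ValueError):
    """Input sequences violate an alignment invariant (lengths, duplicate ids)."""


class WindowError(ValueError):
    """The requested barcode window exceeds the reference sequence."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned barcode sequence with its taxonomy labels.

    ``None`` labels mean "unassigned". Labels are free strings, compared
    case-sensitively after whitespace trimming.
    """

    id: str
    sequence: str
    species: str | None = None
    genus: str | None = None
    family: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")


@dataclass(frozen=True)
class Alignment:
    """An ordered, equal-length collection of :class:`BarcodeRecord`."""

    records: tuple[BarcodeRecord, ...]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            bad = sorted({r.id for r in self.records
                          if len(r.sequence) != len(self.records[0].sequence)})
            raise AlignmentError(
                f"sequences are not all the same length; offending ids: {bad}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if self.reference_id is not None and self.reference_id not in set(ids):
            raise AlignmentError(
                f"reference_id {self.reference_id!r} not among record ids"
            )

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> BarcodeRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def slice_columns(self, start: int, stop: int) -> "Alignment":
        """Restrict to alignment columns [start, stop) (0-based half-open)."""
        new = tuple(replace(r, sequence=r.sequence[start:stop]) for r in self.records)
        return Alignment(records=new, reference_id=self.reference_id)


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str | None]]:
    """Read a taxonomy TSV with header ``id species genus family group``.

    Empty cells become ``None`` (unassigned); values are whitespace-trimmed.
    """
    table: dict[str, dict[str, str | None]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or reader.fieldnames[0] != "id":
            raise ValueError(
                f"taxonomy table must start with an 'id' column; got {reader.fieldnames}"
            )
        for row in reader:
            rec_id = (row.get("id") or "").strip()
            if not rec_id:
                raise ValueError("taxonomy table contains a row with empty id")
            if rec_id in table:
                raise ValueError(f"duplicate taxonomy id {rec_id!r}")
            table[rec_id] = {
                col: (row.get(col) or "").strip() or None
                for col in TAXONOMY_COLUMNS[1:]
            }
    return table


def read_alignment(
    fasta_path: str | Path,
    taxonomy_path: str | Path | None = None,
    reference_id: str | None = None,
) -> Alignment:
    """Read an aligned FASTA (plus optional taxonomy TSV) into an Alignment.

    Sequences are upper-cased. Records without a taxonomy row get unassigned
    labels. Taxonomy ids must be a subset of the FASTA ids.
    """
    raw: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise AlignmentError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        raw.append((rec.id, str(rec.seq).upper()))
    if not raw:
        raise AlignmentError(f"no sequences found in {fasta_path}")

    taxonomy = read_taxonomy(taxonomy_path) if taxonomy_path is not None else {}
    extra = set(taxonomy) - seen
    if extra:
        raise ValueError(
            f"taxonomy ids not present in FASTA: {sorted(extra)}"
        )

    records = []
    for rec_id, seq in raw:
        labels = taxonomy.get(rec_id, {})
        records.append(
            BarcodeRecord(
                id=rec_id,
                sequence=seq,
                species=labels.get("species"),
                genus=labels.get("genus"),
                family=labels.get("family"),
                group=labels.get("group"),
            )
        )
    return Alignment(records=tuple(records), reference_id=reference_id)


def write_alignment(aln: Alignment, fasta_path: str | Path,
                    taxonomy_path: str | Path | None = None) -> None:
    """Write FASTA (and, optionally, the taxonomy TSV) for an Alignment."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in aln.records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    if taxonomy_path is not None:
        with open(taxonomy_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(TAXONOMY_COLUMNS)
            for r in aln.records:
                writer.writerow([
                    r.id,
                    r.species or "", r.genus or "", r.family or "", r.group or "",
                ])


def _nongap_columns(sequence: str) -> list[int]:
    return [i for i, c in enumerate(sequence) if c != GAP]


def trim_to_reference_window(
    aln: Alignment, ref_id: str, window_length: int,
    warn_sparse: bool = True,
) -> Alignment:
    """Trim the alignment to the 3'-most ``window_length`` bases of a reference.

    The output spans the alignment columns from the column holding the
    reference's ``window_length``-th-from-last non-gap base through the column
    of its last non-gap base, keeping interleaved gap columns. The reference
    retains exactly ``window_length`` non-gap characters.

    Records whose trimmed sequence is more than 50% gaps/Ns are flagged with
    a warning but retained (use :func:`drop_sparse_records` to remove them).
    """
    if window_length < 1:
        raise WindowError("window_length must be >= 1")
    ref = aln[ref_id]
    nongap = _nongap_columns(ref.sequence)
    if len(nongap) < window_length:
        raise WindowError(
            f"reference {ref_id!r} has {len(nongap)} non-gap bases; "
            f"cannot take a {window_length}-base window"
        )
    start = nongap[-window_length]
    stop = nongap[-1] + 1
    out = aln.slice_columns(start, stop)
    if warn_sparse:
        for r in out.records:
            n_bad = sum(c in "-N" for c in r.sequence)
            if n_bad > 0.5 * len(r.sequence):
                warnings.warn(
                    f"record {r.id!r}: trimmed sequence is >50% gap/N "
                    f"({n_bad}/{len(r.sequence)}); retained",
                    stacklevel=2,
                )
    return out


def drop_sparse_records(aln: Alignment, max_frac_gap_n: float = 0.5) -> Alignment:
    """Remove records whose sequence exceeds the given gap/N fraction."""
    kept = tuple(
        r for r in aln.records
        if sum(c in "-N" for c in r.sequence) <= max_frac_gap_n * len(r.sequence)
        or r.id == aln.reference_id
    )
    return Alignment(records=kept, reference_id=aln.reference_id)


def dedup_haplotypes(aln: Alignment) -> tuple[Alignment, dict[str, list[str]]]:
    """Collapse byte-identical sequences to one representative haplotype.

    The representative is the first occurrence in input order; input order of
    representatives is preserved. Ambiguity codes are not resolved ("N" != "A").

    Returns the deduplicated alignment and a haplotype map
    ``{representative_id: [member ids, representative first]}``.
    """
    rep_for_seq: dict[str, str] = {}
    hap_map: dict[str, list[str]] = {}
    reps: list[BarcodeRecord] = []
    for r in aln.records:
        rep = rep_for_seq.get(r.sequence)
        if rep is None:
            rep_for_seq[r.sequence] = r.id
            hap_map[r.id] = [r.id]
            reps.append(r)
        else:
            hap_map[rep].append(r.id)
    return Alignment(records=tuple(reps), reference_id=None), hap_map


def write_haplotype_map(hap_map: Mapping[str, Sequence[str]],
                        path: str | Path) -> None:
    """Write a two-column TSV ``representative_id<TAB>member_id``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["representative_id", "member_id"])
        for rep, members in hap_map.items():
            for m in members:
                writer.writerow([rep, m])
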