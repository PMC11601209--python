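"""Reference-anchored indel-frequency analysis of a multiple sequence alignment.

Given an alignment with a designated reference row (e.g. the human α7 nicotinic
receptor subunit among a set of channel-forming subunits), each column is
classified relative to that reference:

* every row has a residue                  -> no indel, frequency 0
* some rows gapped, reference has residue  -> deletion,  frequency (n - x)/n
* some rows gapped, reference gapped       -> insertion, frequency x/n

where ``x`` is the number of rows carrying a residue in the column and ``n``
the number of rows.  For 72 sequences the attainable extremes are 71/72 ≈ 0.986
(a column private to the reference, or one missing only from it).  Maximal runs
of reference residues uninterrupted by indel columns — the "indel-free
stretches" — are reported in reference coordinates, 1-based on the analyzed
window, with an optional numbering offset for precursor coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "ColumnClassification",
    "IndelProfile",
    "read_alignment",
    "write_alignment",
    "trim_to_reference",
    "classify_columns",
    "indel_profile",
    "read_annotation",
]

GAP = "-"
_FORMATS = {"fasta", "clustal"}


@dataclass(frozen=True)
class Alignment:
    """Rows of equal-length gapped sequences with unique ids."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "seqs", tuple(str(s).upper().replace(".", GAP) for s in self.seqs))
        if len(self.ids) == 0:
            raise ValueError("alignment must be non-empty")
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if self.length == 0:
            raise ValueError("alignment has zero columns")

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.seqs[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no row with id {seq_id!r}")

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string, one character per row."""
        return "".join(s[j] for s in self.seqs)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown alignment format {fmt!r}; use one of {sorted(_FORMATS)}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in {".fa", ".fasta", ".faa", ".mfa"}:
        return "fasta"
    if suffix in {".aln", ".clustal", ".clw"}:
        return "clustal"
    raise ValueError(f"cannot infer alignment format from {path!r}; pass format=")


def read_alignment(path, format: str | None = None) -> Alignment:
    """Read a FASTA or Clustal alignment; '.' and '-' both count as gaps."""
    fmt = _infer_format(path, format)
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
    else:
        records = list(AlignIO.read(path, "clustal"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return Alignment(ids=tuple(r.id for r in records),
                     seqs=tuple(str(r.seq) for r in records))


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    if format not in _FORMATS:
        raise ValueError(f"unknown alignment format {format!r}")
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)]
    if format == "fasta":
        SeqIO.write(records, path, "fasta")
    else:
        AlignIO.write(MultipleSeqAlignment(records), path, "clustal")


def _reference_columns(aln: Alignment, ref_id: str) -> list[int]:
    """0-based alignment columns holding the reference's residues, in order."""
    ref = aln.row(ref_id)
    return [j for j, ch in enumerate(ref) if ch != GAP]


def trim_to_reference(aln: Alignment, ref_id: str, first_residue: int,
                      last_residue: int) -> Alignment:
    """Restrict to the columns spanned by reference residues first..last (1-based).

    Interior insertion columns (where the reference is gapped) between the two
    anchor residues are retained; flanking columns outside them are dropped.
    """
    ref_cols = _reference_columns(aln, ref_id)
    if not (1 <= first_residue <= last_residue <= len(ref_cols)):
        raise ValueError(
            f"residue window [{first_residue}, {last_residue}] outside the reference's "
            f"{len(ref_cols)} residues")
    start = ref_cols[first_residue - 1]
    stop = ref_cols[last_residue - 1] + 1
    return Alignment(ids=aln.ids, seqs=tuple(s[start:stop] for s in aln.seqs))


@dataclass(frozen=True)
class ColumnClassification:
    """One alignment column relative to the reference row."""

    column_index: int  # 1-based alignment column
    x: int             # rows carrying a residue
    kind: str          # "none" | "deletion" | "insertion"
    frequency: float


def classify_columns(aln: Alignment, ref_id: str) -> list[ColumnClassification]:
    """Classify every column as indel-free, deletion, or insertion.

    A full column scores zero frequency.  A partial column is a deletion when
    the reference keeps its residue (frequency (n - x)/n) and an insertion when
    the reference is gapped (frequency x/n).  Ambiguity codes (X, B, Z, ...)
    count as residues.
    """
    ref = aln.row(ref_id)
    n = aln.n_rows
    out = []
    for j in range(aln.length):
        col = aln.column(j)
        x = n - col.count(GAP)
        if x == 0:
            raise ValueError(f"column {j + 1} contains only gaps")
        if x == n:
            kind, freq = "none", 0.0
        elif ref[j] != GAP:
            kind, freq = "deletion", (n - x) / n
        else:
            kind, freq = "insertion", x / n
        out.append(ColumnClassification(column_index=j + 1, x=x, kind=kind, frequency=freq))
    return out


@dataclass(frozen=True)
class IndelProfile:
    """Per-column classifications plus reference mapping and indel-free stretches.

    ``column_to_ref[j]`` is the 1-based reference residue number in column j+1,
    or None for insertion columns.  ``stretches`` are maximal closed intervals
    [start, end] of reference positions whose own column is indel-free and with
    no insertion column before the next reference residue.
    """

    classifications: tuple[ColumnClassification, ...]
    column_to_ref: tuple[int | None, ...]
    stretches: tuple[tuple[int, int], ...]
    ref_id: str
    ref_offset: int = 0  # add to mature numbering to report precursor numbering

    @property
    def n_reference_residues(self) -> int:
        return sum(1 for r in self.column_to_ref if r is not None)

    def stretch_lengths(self) -> tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.stretches)

    def columns_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": [c.column_index for c in self.classifications],
            "ref_position": [r + self.ref_offset if r is not None else pd.NA
                             for r in self.column_to_ref],
            "x": [c.x for c in self.classifications],
            "kind": [c.kind for c in self.classifications],
            "frequency": [c.frequency for c in self.classifications],
        })

    def stretches_frame(self, annotations: Sequence[tuple[str, int, int]] | None = None
                        ) -> pd.DataFrame:
        rows = []
        for start, end in self.stretches:
            labels = ""
            if annotations:
                hits = [lab for lab, a, b in annotations if not (b < start or a > end)]
                labels = ";".join(hits)
            rows.append({"start": start + self.ref_offset, "end": end + self.ref_offset,
                         "length": end - start + 1, "annotations": labels})
        return pd.DataFrame(rows, columns=["start", "end", "length", "annotations"])


def indel_profile(classifications: Sequence[ColumnClassification], aln: Alignment,
                  ref_id: str, ref_offset: int = 0) -> IndelProfile:
    """Map columns to reference residues and find indel-free stretches.

    A reference position is interrupted when its own column is a deletion
    column, or when an insertion column lies between it and the next reference
    residue.  Stretches are the maximal runs of uninterrupted positions.
    """
    if len(classifications) != aln.length:
        raise ValueError("classifications were not computed on this alignment")
    ref = aln.row(ref_id)
    column_to_ref: list[int | None] = []
    pos = 0
    for j in range(aln.length):
        if ref[j] != GAP:
            pos += 1
            column_to_ref.append(pos)
        else:
            column_to_ref.append(None)
    n_ref = pos

    ref_col = {r: j for j, r in enumerate(column_to_ref) if r is not None}
    interrupted = [False] * (n_ref + 1)  # 1-based
    for p in range(1, n_ref + 1):
        j = ref_col[p]
        if classifications[j].kind == "deletion":
            interrupted[p] = True
            continue
        if p < n_ref:
            j_next = ref_col[p + 1]
            if any(classifications[t].kind == "insertion" for t in range(j + 1, j_next)):
                interrupted[p] = True

    stretches: list[tuple[int, int]] = []
    start = None
    for p in range(1, n_ref + 1):
        if not interrupted[p]:
            if start is None:
                start = p
        elif start is not None:
            stretches.append((start, p - 1))
            start = None
    if start is not None:
        stretches.append((start, n_ref))

    return IndelProfile(
        classifications=tuple(classifications),
        column_to_ref=tuple(column_to_ref),
        stretches=tuple(stretches),
        ref_id=ref_id,
        ref_offset=ref_offset,
    )


def read_annotation(path) -> list[tuple[str, int, int]]:
    """Read labeled reference-coordinate intervals (TSV: label, start, end; 1-based inclusive)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"annotation line needs 3 tab-separated fields: {line!r}")
            label, start, end = parts[0], int(parts[1]), int(parts[2])
            if start > end:
                raise ValueError(f"annotation interval reversed: {line!r}")
            out.append((label, start, end))
    return out
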