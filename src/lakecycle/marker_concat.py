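"""Concatenated ribosomal-protein supermatrix construction.

Input is one aligned FASTA per marker (the RP16 single-copy ribosomal
protein set by default).  Three steps mirror standard practice for
concatenated-gene phylogenies:

1. copy resolution — a genome with several aligned copies of one marker
   keeps the column-wise merge when the copies are complementary fragments
   of a split protein, else the copy covering more columns;
2. gap masking — alignment columns whose gap fraction exceeds a threshold
   (50% by default; 90% for very divergent single-gene trees) are removed;
3. concatenation — masked markers are joined in fixed order, missing
   markers padded with gaps, with a partition table recording coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

from .core_model import ValidationError

__all__ = [
    "RP16_MARKERS",
    "MarkerAlignment",
    "Supermatrix",
    "read_marker_alignment",
    "write_marker_alignment",
    "resolve_copies",
    "mask_columns",
    "concatenate",
]

RP16_MARKERS = (
    "rpL2", "rpL3", "rpL4", "rpL5", "rpL6", "rpL14", "rpL15", "rpL16",
    "rpL18", "rpL22", "rpL24", "rpS3", "rpS8", "rpS10", "rpS17", "rpS19",
)

GAP = "-"


@dataclass
class MarkerAlignment:
    """One marker's alignment: genome_id -> equal-length gapped rows."""

    marker_id: str
    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValidationError(f"unequal row lengths in marker {self.marker_id!r}: {lengths}")

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class Supermatrix:
    """Concatenated alignment with 1-based inclusive partition coordinates
    tiling [1, total_length]."""

    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    @property
    def total_length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def split_by_partitions(self) -> dict[str, MarkerAlignment]:
        out = {}
        for marker, start, end in self.partitions:
            out[marker] = MarkerAlignment(
                marker, {g: s[start - 1 : end] for g, s in self.rows.items()}
            )
        return out

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gid in sorted(self.rows):
                fh.write(f">{gid}\n{self.rows[gid]}\n")

    def write_partitions(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for marker, start, end in self.partitions:
                fh.write(f"PROT, {marker} = {start}-{end}\n")


def read_marker_alignment(path: str | Path, marker_id: str | None = None) -> MarkerAlignment:
    """Read one aligned FASTA; sequence ids are genome ids (a genome may
    appear several times before copy resolution — use
    ``read_marker_copies`` for that case)."""
    path = Path(path)
    marker_id = marker_id or path.stem
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValidationError(
                f"duplicate genome row {rec.id!r} in marker {marker_id!r}; resolve copies first"
            )
        rows[rec.id] = str(rec.seq).upper()
    return MarkerAlignment(marker_id, rows)


def read_marker_copies(path: str | Path, marker_id: str | None = None) -> dict[str, list[str]]:
    """Read an aligned FASTA allowing multiple rows per genome id."""
    path = Path(path)
    out: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out.setdefault(rec.id, []).append(str(rec.seq).upper())
    return out


def write_marker_alignment(aln: MarkerAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(aln.rows):
            fh.write(f">{gid}\n{aln.rows[gid]}\n")


def _nongap_columns(seq: str) -> set[int]:
    return {i for i, c in enumerate(seq) if c != GAP}


def resolve_copies(candidates: Sequence[str], overlap_tolerance: float = 0.1) -> str | None:
    """Collapse multiple aligned copies of one marker to one row.

    Fragments occupying (near-)disjoint column ranges are merged column-wise
    (a split protein); overlapping copies keep the one covering more
    non-gap columns.  *overlap_tolerance* is the allowed overlap as a
    fraction of the shorter fragment's non-gap length.  Empty input ->
    ``None`` (marker absent).
    """
    candidates = [c for c in candidates if c.strip(GAP)]
    if not candidates:
        return None
    if len({len(c) for c in candidates}) > 1:
        raise ValidationError("copies must be aligned to the same model coordinates")
    merged = candidates[0]
    for cand in candidates[1:]:
        cols_m = _nongap_columns(merged)
        cols_c = _nongap_columns(cand)
        overlap = len(cols_m & cols_c)
        shorter = min(len(cols_m), len(cols_c))
        if overlap <= overlap_tolerance * shorter:
            # split protein: fill merged's gap columns from the fragment
            merged = "".join(
                mc if mc != GAP else cc for mc, cc in zip(merged, cand)
            )
        elif len(cols_c) > len(cols_m):
            merged = cand
    return merged


def mask_columns(
    aln: MarkerAlignment, max_gap_fraction: float = 0.5, semantics: str = "max_gap"
) -> MarkerAlignment:
    """Remove gappy alignment columns.

    ``semantics="max_gap"`` (default) removes columns whose gap fraction
    exceeds *max_gap_fraction*; ``semantics="min_occupancy"`` keeps columns
    with non-gap fraction >= *max_gap_fraction* (the alternative reading of
    an "N% masking" instruction).
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ValidationError("max_gap_fraction must be in [0, 1]")
    if semantics not in {"max_gap", "min_occupancy"}:
        raise ValidationError(f"unknown masking semantics {semantics!r}")
    if not aln.rows:
        return MarkerAlignment(aln.marker_id, {})
    n = len(aln.rows)
    length = aln.alignment_length
    keep = []
    for col in range(length):
        gaps = sum(1 for s in aln.rows.values() if s[col] == GAP)
        if semantics == "max_gap":
            if gaps / n <= max_gap_fraction:
                keep.append(col)
        else:
            if (n - gaps) / n >= max_gap_fraction:
                keep.append(col)
    rows = {g: "".join(s[c] for c in keep) for g, s in aln.rows.items()}
    return MarkerAlignment(aln.marker_id, rows)


def concatenate(
    alignments: Sequence[MarkerAlignment],
    genomes: Sequence[str] | None = None,
    min_markers: int = 8,
) -> tuple[Supermatrix, list[str]]:
    """Concatenate resolved marker alignments in the given order.

    Genomes missing a marker are padded with gaps across that partition;
    genomes present in fewer than *min_markers* alignments are dropped.
    Returns the supermatrix and the list of dropped genome ids.
    """
    if genomes is None:
        seen: dict[str, None] = {}
        for aln in alignments:
            for g in aln.rows:
                seen.setdefault(g, None)
        genomes = list(seen)

    marker_count = {
        g: sum(1 for aln in alignments if g in aln.rows and aln.rows[g].strip(GAP))
        for g in genomes
    }
    kept = [g for g in genomes if marker_count[g] >= min_markers]
    dropped = [g for g in genomes if g not in kept]

    partitions: list[tuple[str, int, int]] = []
    pieces: dict[str, list[str]] = {g: [] for g in kept}
    pos = 1
    for aln in alignments:
        length = aln.alignment_length
        partitions.append((aln.marker_id, pos, pos + length - 1))
        pos += length
        for g in kept:
            pieces[g].append(aln.rows.get(g, GAP * length))
    rows = {g: "".join(parts) for g, parts in pieces.items()}
    return Supermatrix(rows=rows, partitions=partitions), dropped
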