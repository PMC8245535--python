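"""Domain types and file readers shared by every pipeline stage.

The central objects are :class:`GenomeRecord` (one MAG with its scaffolds and
quality/taxonomy metadata), :class:`SampleRecord` (one water-column metagenome
with station, depth and total read count), :class:`CoverageTable`
(scaffold x sample mean fold-coverage) and :class:`HitTable` (HMM search hits
consumed as a table).  Readers accept the plain-text dialects produced by the
standard tools in this field: FASTA genomes, CheckM-style metadata sidecars,
BBMap ``pileup.sh`` coverage tables, and ``hmmsearch`` tblout-style hit
tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ValidationError",
    "GenomeRecord",
    "SampleRecord",
    "CoverageTable",
    "HitTable",
    "PathwayDefinition",
    "read_genomes",
    "read_sample_table",
    "read_coverage_table",
    "write_coverage_table",
    "read_hit_table",
    "quality_filter",
]

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

UNKNOWN = "unknown"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class GenomeRecord:
    """One metagenome-assembled genome (MAG).

    ``completeness`` / ``contamination`` are CheckM-style percentages read
    from a metadata sidecar, never recomputed here; ``None`` means unknown
    and is treated fail-safe (the genome never passes quality selection).
    """

    genome_id: str
    scaffolds: list[tuple[str, str]]
    completeness: float | None = None
    contamination: float | None = None
    taxonomy: dict[str, str] = field(default_factory=dict)
    lineage: str = UNKNOWN
    is_cpr: bool = False
    is_dpann: bool = False
    is_archaea: bool = False
    source_label: str = ""

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.scaffolds]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate scaffold ids in genome {self.genome_id!r}")
        if self.completeness is not None and not (0.0 <= self.completeness <= 100.0):
            raise ValidationError(
                f"completeness {self.completeness} out of [0, 100] for {self.genome_id!r}"
            )
        if self.contamination is not None and self.contamination < 0:
            raise ValidationError(
                f"contamination {self.contamination} < 0 for {self.genome_id!r}"
            )

    @property
    def genome_size(self) -> int:
        """Total assembly length in bp (sum of scaffold lengths)."""
        return sum(len(seq) for _, seq in self.scaffolds)

    def sequence_iter(self) -> Iterable[str]:
        for _, seq in self.scaffolds:
            yield seq

    def rank(self, rank_name: str) -> str:
        return self.taxonomy.get(rank_name, UNKNOWN)


@dataclass(frozen=True)
class SampleRecord:
    """One metagenome sample: station, depth and the read count used for
    coverage normalization (raw vs. mapped totals is a documented config
    choice, not inferred; see docs/methods.md)."""

    sample_id: str
    station: str
    depth: float
    date: str
    total_reads: int
    zone: str | None = None

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValidationError(f"total_reads must be > 0 for sample {self.sample_id!r}")
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0 for sample {self.sample_id!r}")

    def with_zone(self, zone: str) -> "SampleRecord":
        return dataclasses.replace(self, zone=zone)


@dataclass
class CoverageTable:
    """Per-scaffold, per-sample mean fold-coverage plus scaffold lengths and
    the scaffold-to-genome binning map (partial: unbinned scaffolds allowed).
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    scaffold_to_genome: dict[str, str] = field(default_factory=dict)

    def add(self, scaffold_id: str, sample_id: str, coverage: float, length: int) -> None:
        if coverage < 0:
            raise ValidationError(
                f"negative coverage {coverage} for scaffold {scaffold_id!r}, sample {sample_id!r}"
            )
        known = self.scaffold_lengths.get(scaffold_id)
        if known is not None and known != length:
            raise ValidationError(
                f"conflicting lengths for scaffold {scaffold_id!r}: {known} vs {length}"
            )
        self.entries[(scaffold_id, sample_id)] = coverage
        self.scaffold_lengths[scaffold_id] = length

    @property
    def sample_ids(self) -> list[str]:
        return sorted({s for _, s in self.entries})

    def merge(self, other: "CoverageTable") -> "CoverageTable":
        out = CoverageTable(
            entries=dict(self.entries),
            scaffold_lengths=dict(self.scaffold_lengths),
            scaffold_to_genome=dict(self.scaffold_to_genome),
        )
        for (sid, samp), cov in other.entries.items():
            out.add(sid, samp, cov, other.scaffold_lengths[sid])
        out.scaffold_to_genome.update(other.scaffold_to_genome)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sid, samp, cov, self.scaffold_lengths[sid])
            for (sid, samp), cov in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["scaffold_id", "sample_id", "coverage", "length"])


HIT_COLUMNS = [
    "genome_id",
    "protein_id",
    "model_id",
    "bit_score",
    "e_value",
    "model_from",
    "model_to",
    "ali_length",
]


@dataclass
class HitTable:
    """HMM hits as a table. One protein may hit several models and vice
    versa; score filtering happens downstream (pathway_engine)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"hit table missing columns: {missing}")
        bad = self.frame["model_from"] > self.frame["model_to"]
        if bad.any():
            i = int(self.frame.index[bad][0])
            raise ValidationError(f"model_from > model_to at row {i}")
        if (self.frame["e_value"] < 0).any():
            raise ValidationError("negative e_value in hit table")

    def for_genome(self, genome_id: str) -> pd.DataFrame:
        return self.frame[self.frame["genome_id"] == genome_id]

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class PathwayDefinition:
    """One biogeochemical reaction defined as AND-of-OR-groups over HMM
    model ids: the reaction is present iff every group has at least one
    qualifying gene copy.  ``cutoffs`` holds per-model minimum bit scores;
    models absent from it fall back to a global floor unless
    ``use_trusted_cutoff`` demands explicit per-model values."""

    reaction_id: str
    cycle: str
    label: str
    logic: list[list[str]]
    substrate: str = ""
    product: str = ""
    cutoffs: dict[str, float] = field(default_factory=dict)
    use_trusted_cutoff: bool = False

    def __post_init__(self) -> None:
        if not self.logic:
            raise ValidationError(f"reaction {self.reaction_id!r} has empty logic")
        if any(not group for group in self.logic):
            raise ValidationError(f"reaction {self.reaction_id!r} has an empty OR-group")
        if self.cycle not in {"carbon", "nitrogen", "sulfur", "other"}:
            raise ValidationError(f"unknown cycle {self.cycle!r}")

    @property
    def model_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for group in self.logic:
            for m in group:
                seen.setdefault(m, None)
        return list(seen)


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_flag(value: object) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "t"}


def read_genome_metadata(path: str | Path) -> pd.DataFrame:
    """Read a CheckM-style genome metadata sidecar TSV.

    Expected columns: genome_id, completeness, contamination, optional
    taxonomy ranks (domain..species), lineage, is_cpr/is_dpann/is_archaea
    flags and source_label.  Missing values stay missing (never default to
    passing quality values).
    """
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    if "genome_id" not in df.columns:
        raise ValidationError(f"metadata table {path} lacks a genome_id column")
    if df["genome_id"].duplicated().any():
        dups = df.loc[df["genome_id"].duplicated(), "genome_id"].tolist()
        raise ValidationError(f"duplicate genome_id in metadata: {dups}")
    return df.set_index("genome_id")


def read_genomes(
    directory: str | Path, metadata: str | Path | pd.DataFrame | None = None
) -> list[GenomeRecord]:
    """Load one GenomeRecord per FASTA file in *directory*.

    Sequences are uppercased; ambiguity codes are kept (they count toward
    genome_size but are excluded later from k-mer sketching).  Quality and
    taxonomy come from the optional sidecar; anything missing is left
    unknown, never silently zero.
    """
    directory = Path(directory)
    fasta_paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".fa", ".fasta", ".fna"}
    )
    if not fasta_paths:
        raise ValidationError(f"no FASTA files (*.fa, *.fasta, *.fna) in {directory}")

    meta: pd.DataFrame | None
    if metadata is None:
        meta = None
    elif isinstance(metadata, pd.DataFrame):
        meta = metadata
    else:
        meta = read_genome_metadata(metadata)

    genomes: list[GenomeRecord] = []
    seen: set[str] = set()
    for path in fasta_paths:
        genome_id = path.stem
        if genome_id in seen:
            raise ValidationError(f"duplicate genome_id {genome_id!r}")
        seen.add(genome_id)
        try:
            records = list(SeqIO.parse(str(path), "fasta"))
        except OSError as exc:  # pragma: no cover - filesystem dependent
            raise OSError(f"cannot read genome file {path}: {exc}") from exc
        if not records:
            raise ValidationError(f"no sequences in {path}")
        scaffolds = [(rec.id, str(rec.seq).upper()) for rec in records]
        rec = GenomeRecord(genome_id=genome_id, scaffolds=scaffolds)
        if meta is not None and genome_id in meta.index:
            row = meta.loc[genome_id]
            if "completeness" in row and pd.notna(row["completeness"]):
                rec.completeness = float(row["completeness"])
            if "contamination" in row and pd.notna(row["contamination"]):
                rec.contamination = float(row["contamination"])
            rec.taxonomy = {
                r: str(row[r]) for r in TAXONOMY_RANKS if r in row.index and pd.notna(row[r])
            }
            if "lineage" in row.index and pd.notna(row["lineage"]):
                rec.lineage = str(row["lineage"])
            for flag in ("is_cpr", "is_dpann", "is_archaea"):
                if flag in row.index and pd.notna(row[flag]):
                    setattr(rec, flag, _parse_flag(row[flag]))
            if "source_label" in row.index and pd.notna(row["source_label"]):
                rec.source_label = str(row["source_label"])
        genomes.append(rec)
    return genomes


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the sample metadata TSV (sample_id, station, depth_m, date,
    total_reads)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "station": str, "date": str})
    required = {"sample_id", "station", "depth_m", "date", "total_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample table {path} missing columns {sorted(missing)}")
    return [
        SampleRecord(
            sample_id=row.sample_id,
            station=row.station,
            depth=float(row.depth_m),
            date=row.date,
            total_reads=int(row.total_reads),
        )
        for row in df.itertuples()
    ]


def read_coverage_table(
    path: str | Path,
    dialect: str = "long",
    sample_id: str | None = None,
    scaffold_to_genome: Mapping[str, str] | None = None,
) -> CoverageTable:
    """Read a coverage table.

    ``dialect="long"``: TSV with columns scaffold_id, sample_id, coverage,
    length.  ``dialect="pileup"``: BBMap pileup.sh output for ONE sample
    (header starts ``#ID``, columns include Avg_fold and Length); the sample
    id must then be supplied.
    """
    path = Path(path)
    table = CoverageTable()
    if scaffold_to_genome:
        table.scaffold_to_genome.update(scaffold_to_genome)

    if dialect == "pileup":
        if sample_id is None:
            raise ValidationError("pileup dialect needs an explicit sample_id")
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lstrip("#") for c in df.columns]
        for col in ("ID", "Avg_fold", "Length"):
            if col not in df.columns:
                raise ValidationError(f"pileup table {path} missing column {col!r}")
        for row in df.itertuples():
            table.add(str(row.ID), sample_id, float(row.Avg_fold), int(row.Length))
    elif dialect == "long":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"scaffold_id": str, "sample_id": str},
            float_precision="round_trip",
        )
        required = {"scaffold_id", "sample_id", "coverage", "length"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"coverage table {path} missing columns {sorted(missing)}")
        for row in df.itertuples():
            table.add(row.scaffold_id, row.sample_id, float(row.coverage), int(row.length))
    else:
        raise ValidationError(f"unknown coverage dialect {dialect!r}")
    return table


def write_coverage_table(table: CoverageTable, path: str | Path) -> None:
    """Write a CoverageTable in the long-format dialect (round-trips with
    ``read_coverage_table(dialect='long')``)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> HitTable:
    """Parse a whitespace-delimited hit table (hmmsearch tblout-style
    columns, ``#`` comment lines skipped)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(HIT_COLUMNS):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(HIT_COLUMNS)} columns, got {len(parts)}"
                )
            try:
                rows.append(
                    (
                        parts[0],
                        parts[1],
                        parts[2],
                        float(parts[3]),
                        float(parts[4]),
                        int(parts[5]),
                        int(parts[6]),
                        int(parts[7]),
                    )
                )
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    frame = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return HitTable(frame)


def write_hit_table(hits: HitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(HIT_COLUMNS) + "\n")
        for row in hits.frame.itertuples(index=False):
            fh.write(
                f"{row.genome_id}\t{row.protein_id}\t{row.model_id}\t{row.bit_score:g}\t"
                f"{row.e_value:g}\t{row.model_from}\t{row.model_to}\t{row.ali_length}\n"
            )


# ---------------------------------------------------------------------------
# Quality selection


def quality_filter(
    genomes: Sequence[GenomeRecord],
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    warn: bool = True,
) -> list[GenomeRecord]:
    """Select medium/high-quality MAGs: completeness >= *min_completeness*
    AND contamination strictly < *max_contamination* (the MIMAG medium-
    quality rule).  Genomes with unknown quality metrics are excluded,
    fail-safe."""
    import warnings

    kept: list[GenomeRecord] = []
    for g in genomes:
        if g.completeness is None or g.contamination is None:
            if warn:
                warnings.warn(
                    f"genome {g.genome_id!r} has unknown quality metrics; excluded",
                    stacklevel=2,
                )
            continue
        if g.completeness >= min_completeness and g.contamination < max_contamination:
            kept.append(g)
    return kept
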