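"""Genome-level, read-normalized relative abundance (RAR).

The chain is: per-scaffold mean fold-coverage -> genome coverage (summed
scaffold means, or a length-weighted mean) -> division by each sample's
total read count -> percent of the per-sample MAG total (RAR).  RAR columns
sum to 100 whenever any genome is detected in the sample; the denominator is
the sum over MAGs only (unbinned community mass is excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import CoverageTable, GenomeRecord, SampleRecord, ValidationError

__all__ = [
    "GenomeCoverage",
    "RARMatrix",
    "genome_coverage",
    "normalize_by_reads",
    "to_rar",
    "taxon_rar",
]

COVERAGE_MODES = ("sum_of_scaffold_means", "length_weighted_mean")


@dataclass
class GenomeCoverage:
    """Genome x sample coverage statistic and the mode that produced it."""

    matrix: pd.DataFrame  # genomes x samples, >= 0
    mode: str
    n_unbinned_scaffolds: int = 0


@dataclass
class RARMatrix:
    """Genome x sample percentages; each non-empty column sums to 100."""

    matrix: pd.DataFrame
    denominators: pd.Series  # per-sample normalized-coverage totals

    def write_wide(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="genome_id")

    def to_long(self) -> pd.DataFrame:
        long = self.matrix.stack().reset_index()
        long.columns = ["genome_id", "sample_id", "rar_percent"]
        return long


def genome_coverage(
    cov: CoverageTable,
    mode: str = "sum_of_scaffold_means",
    detection_floor: float = 0.01,
) -> GenomeCoverage:
    """Aggregate scaffold coverage to genomes.

    ``sum_of_scaffold_means`` (default) sums the per-scaffold mean coverages
    of a genome — simple and scaffold-count sensitive.  ``length_weighted_mean``
    computes sum(cov_i * len_i) / sum(len_i), the genome-wide mean depth.
    Genome coverages below *detection_floor* (x) are zeroed to suppress
    sub-read-level mapping noise; pass 0 to disable.  Unbinned scaffolds are
    ignored but counted.
    """
    if mode not in COVERAGE_MODES:
        raise ValidationError(f"unknown coverage mode {mode!r}; choose from {COVERAGE_MODES}")
    df = cov.to_frame()
    if df.empty:
        raise ValidationError("coverage table is empty")
    df["genome_id"] = df["scaffold_id"].map(cov.scaffold_to_genome)
    n_unbinned = int(df["genome_id"].isna().sum())
    df = df.dropna(subset=["genome_id"])
    if mode == "sum_of_scaffold_means":
        mat = df.pivot_table(
            index="genome_id", columns="sample_id", values="coverage", aggfunc="sum", fill_value=0.0
        )
    else:
        df = df.assign(weighted=df["coverage"] * df["length"])
        num = df.pivot_table(
            index="genome_id", columns="sample_id", values="weighted", aggfunc="sum", fill_value=0.0
        )
        den = df.pivot_table(
            index="genome_id", columns="sample_id", values="length", aggfunc="sum", fill_value=0
        )
        mat = num / den.replace(0, np.nan)
        mat = mat.fillna(0.0)
    mat = mat.sort_index().sort_index(axis=1)
    if detection_floor > 0:
        mat = mat.where(mat >= detection_floor, 0.0)
    return GenomeCoverage(matrix=mat, mode=mode, n_unbinned_scaffolds=n_unbinned)


def normalize_by_reads(
    gc: GenomeCoverage, samples: Sequence[SampleRecord] | Mapping[str, SampleRecord]
) -> pd.DataFrame:
    """Divide each sample's coverage column by that sample's total read
    count (normalizes for sequencing effort across metagenomes)."""
    if not isinstance(samples, Mapping):
        samples = {s.sample_id: s for s in samples}
    missing = [s for s in gc.matrix.columns if s not in samples]
    if missing:
        raise ValidationError(f"no sample metadata for samples {missing}")
    reads = pd.Series({s: samples[s].total_reads for s in gc.matrix.columns}, dtype=float)
    return gc.matrix / reads


def to_rar(normalized: pd.DataFrame, warn_empty: bool = True) -> RARMatrix:
    """Convert normalized coverage to relative read abundance: each column
    scaled so genomes sum to 100%.  All-zero columns stay zero."""
    import warnings

    if (normalized.values < 0).any():
        raise ValidationError("normalized coverage must be >= 0")
    sums = normalized.sum(axis=0)
    empty = sums[sums == 0].index.tolist()
    if empty and warn_empty:
        warnings.warn(f"no genome detected in samples {empty}; RAR left all-zero", stacklevel=2)
    safe = sums.replace(0, np.nan)
    rar = (normalized / safe * 100.0).fillna(0.0)
    return RARMatrix(matrix=rar, denominators=sums)


def taxon_rar(
    rar: RARMatrix,
    genomes: Sequence[GenomeRecord] | Mapping[str, str],
    group_by: str = "phylum",
) -> pd.DataFrame:
    """Sum member-genome RAR per taxon label and sample.

    *group_by* is a taxonomy rank or one of the flags ``is_cpr`` /
    ``is_dpann`` / ``is_archaea``; alternatively pass a ready
    genome_id -> label mapping.  Column sums are preserved exactly.
    """
    if isinstance(genomes, Mapping):
        label_of = dict(genomes)
    else:
        label_of = {}
        for g in genomes:
            if group_by in ("is_cpr", "is_dpann", "is_archaea"):
                label_of[g.genome_id] = group_by if getattr(g, group_by) else f"not_{group_by}"
            else:
                label_of[g.genome_id] = g.taxonomy.get(group_by, "")
    unlabeled = [gid for gid in rar.matrix.index if not label_of.get(gid)]
    if unlabeled:
        raise ValidationError(f"genomes without a {group_by!r} label: {unlabeled}")
    return rar.matrix.groupby([label_of[g] for g in rar.matrix.index]).sum()
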