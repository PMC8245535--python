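"""Rule-based metabolic capability calling from HMM hit tables.

A reaction is scored present in a genome iff every AND-term (OR-group) of
its gene logic has at least one hit meeting that model's score cutoff —
the one-copy-per-representative-gene rule.  Manual-curation decisions
(e.g. relabelling an amoA hit to pmoA, or forcing a cell) are applied
through an explicit override table so they stay auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .core_model import HitTable, PathwayDefinition, ValidationError

__all__ = [
    "load_pathways",
    "default_pathways",
    "qualifying_models",
    "evaluate_reaction",
    "build_function_matrix",
    "OverrideTable",
    "read_override_table",
    "apply_overrides",
    "CazymeProfile",
    "cazyme_density",
]

DEFAULT_BIT_SCORE_FLOOR = 50.0

_DATA_DIR = Path(__file__).parent / "data"


def load_pathways(path: str | Path) -> list[PathwayDefinition]:
    """Load pathway definitions from a YAML config.

    Layout::

        default_cutoff: 50
        reactions:
          - id: nitrogen_fixation
            cycle: nitrogen
            label: nitrogen fixation
            substrate: "N2 (0)"
            product: "NH3 (-III)"
            logic: [[nifH], [nifD], [nifK]]
            cutoffs: {nifH: 60}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    default_cutoff = float(doc.get("default_cutoff", DEFAULT_BIT_SCORE_FLOOR))
    pathways = []
    for entry in doc["reactions"]:
        logic = [[str(m) for m in group] for group in entry["logic"]]
        cutoffs = {str(m): float(v) for m, v in (entry.get("cutoffs") or {}).items()}
        for m in {m for group in logic for m in group}:
            cutoffs.setdefault(m, default_cutoff)
        pathways.append(
            PathwayDefinition(
                reaction_id=str(entry["id"]),
                cycle=str(entry["cycle"]),
                label=str(entry.get("label", entry["id"])),
                logic=logic,
                substrate=str(entry.get("substrate", "")),
                product=str(entry.get("product", "")),
                cutoffs=cutoffs,
                use_trusted_cutoff=bool(entry.get("use_trusted_cutoff", False)),
            )
        )
    ids = [p.reaction_id for p in pathways]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate reaction ids in pathway config")
    return pathways


def default_pathways() -> list[PathwayDefinition]:
    """The shipped carbon/nitrogen/sulfur reaction set (editable config)."""
    return load_pathways(_DATA_DIR / "pathways.yml")


def qualifying_models(
    hits: pd.DataFrame, pd_def: PathwayDefinition, default_cutoff: float | None = None
) -> set[str]:
    """Model ids of *pd_def* with at least one hit at/above their cutoff."""
    present: set[str] = set()
    for model in pd_def.model_ids:
        cutoff = pd_def.cutoffs.get(model)
        if cutoff is None:
            if default_cutoff is None:
                raise ValidationError(
                    f"no cutoff defined for model {model!r} in reaction {pd_def.reaction_id!r}"
                )
            cutoff = default_cutoff
        rows = hits[hits["model_id"] == model]
        if (rows["bit_score"] >= cutoff).any():
            present.add(model)
    return present


def evaluate_reaction(
    hits: pd.DataFrame, pd_def: PathwayDefinition, default_cutoff: float | None = None
) -> int:
    """1 iff every OR-group of the reaction's logic has >= 1 qualifying hit."""
    present = qualifying_models(hits, pd_def, default_cutoff)
    return int(all(any(m in present for m in group) for group in pd_def.logic))


def build_function_matrix(
    hits: HitTable,
    genome_ids: Sequence[str],
    pathways: Sequence[PathwayDefinition],
    default_cutoff: float | None = None,
) -> pd.DataFrame:
    """Complete genome x reaction 0/1 capability matrix."""
    frame = hits.frame
    by_genome = {gid: frame[frame["genome_id"] == gid] for gid in genome_ids}
    data = {
        p.reaction_id: [
            evaluate_reaction(by_genome[gid], p, default_cutoff) for gid in genome_ids
        ]
        for p in pathways
    }
    return pd.DataFrame(data, index=list(genome_ids), dtype=int)


@dataclass
class OverrideTable:
    """Manual curation actions: relabel a hit's model before re-evaluation,
    or force a capability cell directly.  Every applied change is logged."""

    rows: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for row in self.rows:
            if row["action"] not in {"force_present", "force_absent", "relabel"}:
                raise ValidationError(f"unknown override action {row['action']!r}")
            if row["action"] == "relabel" and not row.get("new_label"):
                raise ValidationError("relabel override requires new_label")


def read_override_table(path: str | Path) -> OverrideTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"genome_id", "target", "action"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"override table missing columns {sorted(missing)}")
    return OverrideTable(rows=df.to_dict("records"))


def apply_overrides(
    fm: pd.DataFrame,
    hits: HitTable,
    overrides: OverrideTable,
    pathways: Sequence[PathwayDefinition],
    default_cutoff: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Apply curation overrides; returns the new matrix and a provenance log
    (one line per changed cell)."""
    out = fm.copy()
    frame = hits.frame.copy()
    log: list[str] = []

    relabeled_genomes: set[str] = set()
    for row in overrides.rows:
        gid, target, action = row["genome_id"], row["target"], row["action"]
        if gid not in out.index:
            raise ValidationError(f"override references unknown genome {gid!r}")
        if action == "relabel":
            mask = (frame["genome_id"] == gid) & (frame["model_id"] == target)
            if not mask.any():
                raise ValidationError(f"no hit for model {target!r} in genome {gid!r} to relabel")
            frame.loc[mask, "model_id"] = row["new_label"]
            relabeled_genomes.add(gid)
            log.append(f"relabel {gid}:{target}->{row['new_label']} ({row.get('reason', '')})")

    # re-evaluate every reaction touching a relabeled model for those genomes
    for gid in relabeled_genomes:
        ghits = frame[frame["genome_id"] == gid]
        for p in pathways:
            new = evaluate_reaction(ghits, p, default_cutoff)
            if new != out.at[gid, p.reaction_id]:
                log.append(f"re-eval {gid}:{p.reaction_id} {out.at[gid, p.reaction_id]}->{new}")
                out.at[gid, p.reaction_id] = new

    for row in overrides.rows:
        gid, target, action = row["genome_id"], row["target"], row["action"]
        if action in {"force_present", "force_absent"}:
            if target not in out.columns:
                raise ValidationError(f"override references unknown reaction {target!r}")
            new = 1 if action == "force_present" else 0
            if out.at[gid, target] != new:
                log.append(f"{action} {gid}:{target} ({row.get('reason', '')})")
                out.at[gid, target] = new
    return out, log


CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")


@dataclass
class CazymeProfile:
    """Per-genome CAZy family class counts and hits-per-Mbp density."""

    genome_id: str
    class_counts: dict[str, int]
    density: float  # total hits per Mbp


def cazyme_density(
    cazyme_models: Iterable[str], genome_id: str, genome_size: int
) -> CazymeProfile:
    """Count CAZyme hits per class (by model-id prefix: GH, GT, PL, CE, AA,
    CBM) and normalize the total by genome size in Mbp."""
    if genome_size <= 0:
        raise ValidationError(f"genome_size must be > 0 for {genome_id!r}")
    counts = {c: 0 for c in CAZY_CLASSES}
    total = 0
    for model in cazyme_models:
        total += 1
        for c in CAZY_CLASSES:
            if model.upper().startswith(c):
                counts[c] += 1
                break
    return CazymeProfile(
        genome_id=genome_id, class_counts=counts, density=total / (genome_size / 1e6)
    )
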