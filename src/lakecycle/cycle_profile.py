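"""Depth-zone classification and abundance-weighted reaction profiles.

Stratified-lake samples fall into oxic, sub-oxic and anoxic zones by depth
(defaults 0-50 m / 50-120 m / below, set from the lake's oxygen profile and
fully configurable).  For each reaction, the profile reports the number of
capable genomes over the whole MAG set and, per sample, the summed RAR of
those genomes — capability weighted by community abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .abundance import RARMatrix
from .core_model import SampleRecord, ValidationError

__all__ = [
    "ZoneBounds",
    "classify_zone",
    "ReactionProfile",
    "reaction_profile",
    "taxon_function_presence",
]

ZONES = ("oxic", "sub_oxic", "anoxic")


@dataclass(frozen=True)
class ZoneBounds:
    """Depth cutoffs (m): oxic below *oxic_max*, sub-oxic below
    *subox_max*, anoxic deeper."""

    oxic_max: float = 50.0
    subox_max: float = 120.0

    def __post_init__(self) -> None:
        if not 0 < self.oxic_max < self.subox_max:
            raise ValidationError("need 0 < oxic_max < subox_max")


def classify_zone(sample: SampleRecord, bounds: ZoneBounds = ZoneBounds()) -> str:
    if sample.depth < bounds.oxic_max:
        return "oxic"
    if sample.depth < bounds.subox_max:
        return "sub_oxic"
    return "anoxic"


@dataclass
class ReactionProfile:
    """One reaction's capable-genome count (whole MAG set) and summed RAR
    of capable genomes per sample; ``n_detected`` additionally counts
    capable genomes with non-zero RAR per sample."""

    reaction_id: str
    cycle: str
    n_genomes: int
    rar_percent: dict[str, float] = field(default_factory=dict)
    n_detected: dict[str, int] = field(default_factory=dict)


def reaction_profile(
    fm: pd.DataFrame,
    rar: RARMatrix,
    samples: Sequence[str],
    cycles: Mapping[str, str] | None = None,
    detection_threshold: float = 0.0,
) -> list[ReactionProfile]:
    """Per-reaction community profile over the requested samples.

    ``detection_threshold`` (percent RAR) optionally zeroes per-genome
    contributions below it before summation; default none.
    """
    shared = fm.index.intersection(rar.matrix.index)
    if len(shared) != len(fm.index):
        raise ValidationError("function matrix and RAR matrix must share genome ids")
    missing = [s for s in samples if s not in rar.matrix.columns]
    if missing:
        raise ValidationError(f"samples absent from RAR matrix: {missing}")
    profiles = []
    rmat = rar.matrix
    if detection_threshold > 0:
        rmat = rmat.where(rmat >= detection_threshold, 0.0)
    for reaction in fm.columns:
        capable = fm.index[fm[reaction] == 1]
        sub = rmat.loc[capable, list(samples)]
        profiles.append(
            ReactionProfile(
                reaction_id=reaction,
                cycle=cycles.get(reaction, "other") if cycles else "other",
                n_genomes=int(len(capable)),
                rar_percent={s: float(sub[s].sum()) for s in samples},
                n_detected={s: int((sub[s] > 0).sum()) for s in samples},
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[ReactionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "reaction_id": p.reaction_id,
            "cycle": p.cycle,
            "n_genomes": p.n_genomes,
        }
        row.update({f"rar_{s}": v for s, v in p.rar_percent.items()})
        row.update({f"n_detected_{s}": v for s, v in p.n_detected.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def taxon_function_presence(
    fm: pd.DataFrame,
    taxonomy: Mapping[str, str],
    taxa: Sequence[str],
    reactions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary taxon x reaction table: present iff >= 1 member genome has
    the reaction (the filled/open-circle summary)."""
    reactions = list(reactions) if reactions is not None else list(fm.columns)
    unknown_rx = [r for r in reactions if r not in fm.columns]
    if unknown_rx:
        raise ValidationError(f"unknown reactions: {unknown_rx}")
    labels = pd.Series({g: taxonomy.get(g) for g in fm.index})
    out = {}
    for taxon in taxa:
        members = labels.index[labels == taxon]
        if len(members) == 0:
            raise ValidationError(f"taxon {taxon!r} has no member genomes")
        out[taxon] = (fm.loc[members, reactions].sum(axis=0) > 0).astype(int)
    return pd.DataFrame(out).T[reactions]
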