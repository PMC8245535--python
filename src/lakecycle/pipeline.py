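"""End-to-end pipeline orchestration.

A single structured config governs every stage and threshold (quality
selection, ANI/dereplication, abundance normalization, annotation cutoffs,
zone bounds), so each place where a study leaves a methodological gap is a
visible, versioned choice.  Outputs are deterministic for a fixed config +
seed; a manifest records sha256 checksums of all inputs and outputs, and a
stage is skipped on re-run only when its recorded input checksums still
match.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .abundance import genome_coverage, normalize_by_reads, taxon_rar, to_rar
from .ani_derep import dereplicate, pairwise_ani
from .core_model import (
    ValidationError,
    quality_filter,
    read_coverage_table,
    read_genomes,
    read_hit_table,
    read_sample_table,
)
from .cycle_profile import ZoneBounds, classify_zone, profiles_to_frame, reaction_profile
from .pathway_engine import (
    apply_overrides,
    build_function_matrix,
    default_pathways,
    load_pathways,
    read_override_table,
)
from .synthetic_data import SimulationConfig, simulate_community, write_community

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_status: int = 1):
        super().__init__(message)
        self.exit_status = exit_status


@dataclass
class RunConfig:
    """All pipeline knobs in one place (see docs/methods.md for defaults
    and rationale)."""

    out_dir: Path
    seed: int = 0
    simulate: dict[str, Any] | None = None  # SimulationConfig overrides, or None
    inputs: dict[str, str] = field(default_factory=dict)
    min_completeness: float = 50.0
    max_contamination: float = 10.0
    ani_k: int = 21
    ani_sketch_size: int = 5000
    ani_floor: float = 75.0
    ani_threshold: float = 99.0
    coverage_mode: str = "sum_of_scaffold_means"
    detection_floor: float = 0.01
    pathway_config: str | None = None
    override_table: str | None = None
    default_cutoff: float = 50.0
    oxic_max: float = 50.0
    subox_max: float = 120.0
    profile_samples: list[str] | None = None
    taxon_rank: str = "phylum"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "out_dir" not in doc:
            raise ValidationError(f"config {path} must set out_dir")
        doc["out_dir"] = Path(doc["out_dir"])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_prior_manifest(out: Path) -> dict[str, Any] | None:
    path = out / "manifest.json"
    if not path.exists():
        return None
    try:
        with open(path) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError):
        return None


def _checksum_tree(root: Path) -> dict[str, str]:
    if root.is_file():
        return {root.name: _sha256(root)}
    return {
        str(p.relative_to(root)): _sha256(p) for p in sorted(root.rglob("*")) if p.is_file()
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run simulate (optional) -> QC -> ANI/derep -> abundance -> annotate
    -> profile; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    prior = _load_prior_manifest(out)

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in vars(config).items()},
        "inputs": {},
        "outputs": {},
        "log": [],
    }
    log = manifest["log"].append

    inputs = dict(config.inputs)
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**config.simulate)
        truth = simulate_community(sim_cfg, seed=config.seed)
        sim_dir = out / "simulated"
        paths = write_community(truth, sim_dir)
        inputs = {
            "genomes": str(paths["genomes"]),
            "metadata": str(paths["metadata"]),
            "samples": str(paths["samples"]),
            "coverage": str(paths["coverage"]),
            "scaffold_map": str(paths["scaffold_map"]),
            "hits": str(paths["hits"]),
        }
        log(f"simulated community with {len(truth.genomes)} genomes")

    required = ["genomes", "metadata", "samples", "coverage", "scaffold_map", "hits"]
    for key in required:
        if key not in inputs:
            raise PipelineError(f"missing input {key!r} in config", exit_status=2)
        if not Path(inputs[key]).exists():
            raise PipelineError(f"input path does not exist: {inputs[key]}", exit_status=2)
        manifest["inputs"][key] = _checksum_tree(Path(inputs[key]))

    # caching contract: re-use the previous run only when every recorded
    # input checksum matches and every output is still intact
    if prior is not None and prior.get("inputs") == manifest["inputs"]:
        outputs = prior.get("outputs", {})
        if outputs and all(
            (out / name).exists() and _sha256(out / name) == digest
            for name, digest in outputs.items()
        ):
            prior["log"] = prior.get("log", []) + ["outputs up to date; stages skipped"]
            return prior

    # --- load + quality selection
    genomes = read_genomes(inputs["genomes"], metadata=inputs["metadata"])
    samples = read_sample_table(inputs["samples"])
    kept = quality_filter(
        genomes,
        min_completeness=config.min_completeness,
        max_contamination=config.max_contamination,
    )
    log(f"quality selection kept {len(kept)}/{len(genomes)} genomes")
    if not kept:
        raise PipelineError("no genome passed quality selection")

    # --- ANI + dereplication
    matrix = pairwise_ani(
        kept, k=config.ani_k, sketch_size=config.ani_sketch_size, floor=config.ani_floor
    )
    matrix.write(out / "ani.tsv")
    clusters = dereplicate(kept, matrix, ani_threshold=config.ani_threshold)
    clusters.write(out / "clusters.tsv")
    reps = set(clusters.representatives)
    rep_genomes = [g for g in kept if g.genome_id in reps]
    log(f"dereplication: {len(kept)} genomes -> {len(reps)} representatives")

    # --- abundance
    import pandas as pd

    scaffold_map = pd.read_csv(inputs["scaffold_map"], sep="\t").set_index("scaffold_id")[
        "genome_id"
    ]
    cov = read_coverage_table(inputs["coverage"], dialect="long")
    cov.scaffold_to_genome.update(
        {sid: gid for sid, gid in scaffold_map.items() if gid in reps}
    )
    gc = genome_coverage(cov, mode=config.coverage_mode, detection_floor=config.detection_floor)
    norm = normalize_by_reads(gc, samples)
    rar = to_rar(norm, warn_empty=False)
    rar.write_wide(out / "rar.tsv")
    taxonomy = {g.genome_id: g.rank(config.taxon_rank) for g in rep_genomes}
    taxon_table = taxon_rar(rar, taxonomy, group_by=config.taxon_rank)
    taxon_table.to_csv(out / "taxon_rar.tsv", sep="\t", index_label=config.taxon_rank)

    # --- annotation
    pathways = (
        load_pathways(config.pathway_config) if config.pathway_config else default_pathways()
    )
    hits = read_hit_table(inputs["hits"])
    rep_ids = sorted(g.genome_id for g in rep_genomes)
    fm = build_function_matrix(hits, rep_ids, pathways, default_cutoff=config.default_cutoff)
    if config.override_table:
        overrides = read_override_table(config.override_table)
        fm, override_log = apply_overrides(
            fm, hits, overrides, pathways, default_cutoff=config.default_cutoff
        )
        manifest["log"].extend(override_log)
    fm.to_csv(out / "function_matrix.tsv", sep="\t", index_label="genome_id")

    # --- depth-zone profiles
    bounds = ZoneBounds(oxic_max=config.oxic_max, subox_max=config.subox_max)
    zoned = [s.with_zone(classify_zone(s, bounds)) for s in samples]
    pd.DataFrame(
        [(s.sample_id, s.depth, s.zone) for s in zoned],
        columns=["sample_id", "depth_m", "zone"],
    ).to_csv(out / "zones.tsv", sep="\t", index=False)
    profile_samples = config.profile_samples or [s.sample_id for s in samples]
    cycles = {p.reaction_id: p.cycle for p in pathways}
    profiles = reaction_profile(fm, rar, profile_samples, cycles=cycles)
    profiles_to_frame(profiles).to_csv(out / "reaction_profiles.tsv", sep="\t", index=False)

    for name in (
        "ani.tsv",
        "clusters.tsv",
        "rar.tsv",
        "taxon_rar.tsv",
        "function_matrix.tsv",
        "zones.tsv",
        "reaction_profiles.tsv",
    ):
        manifest["outputs"][name] = _sha256(out / name)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
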