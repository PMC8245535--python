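"""Synthetic stratified-lake communities with full ground truth.

The generator emulates a depth-stratified freshwater metagenome study:
each genome gets a Gaussian depth niche (center and width in metres) and a
log-normal baseline, so per-sample relative abundances follow

    abundance_g(s)  ∝  base_g · exp(−(depth_s − μ_g)² / (2 σ_g²))

renormalized per sample.  Metabolic guilds tie functions to niches —
surface genomes carry CO2 fixation and organic carbon oxidation, deep
genomes methanogenesis / sulfite reduction / anammox — mirroring the
oxic-surface vs anoxic-deep community structure of meromictic lakes.
Coverage tables, HMM hit tables (planted genes above cutoff plus decoys
below), genome FASTAs with controlled-ANI cluster structure, and marker
alignments with split/duplicated copies are all emitted in the exact
dialects the readers consume, alongside a truth bundle for
parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    CoverageTable,
    GenomeRecord,
    HitTable,
    SampleRecord,
    ValidationError,
    write_coverage_table,
    write_hit_table,
)
from .marker_concat import RP16_MARKERS, GAP, MarkerAlignment
from .pathway_engine import build_function_matrix, default_pathways

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "gen_genome",
    "evolve_to_ani",
    "simulate_community",
    "write_community",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# guild -> reactions planted in every member (from the shipped defaults)
GUILD_REACTIONS = {
    "surface": ("co2_fixation", "organic_carbon_oxidation"),
    "deep": ("methanogenesis", "sulfite_reduction", "anammox"),
    "generalist": ("organic_carbon_oxidation", "fermentation"),
}

GUILD_TAXA = {
    "surface": (
        ("Bacteria", "Cyanobacteria"),
        ("Bacteria", "Actinobacteria"),
        ("Bacteria", "Proteobacteria"),
    ),
    "deep": (
        ("Archaea", "Euryarchaeota"),
        ("Bacteria", "Chlorobi"),
        ("Bacteria", "Planctomycetes"),
    ),
    "generalist": (
        ("Bacteria", "Bacteroidetes"),
        ("Bacteria", "Verrucomicrobia"),
    ),
}


def gen_genome(length: int, gc_content: float = 0.5, seed: int = 0) -> str:
    """Random nucleotide sequence with the requested GC content in
    expectation; deterministic for (length, gc_content, seed)."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    if not 0 < gc_content < 1:
        raise ValidationError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_at = (1 - gc_content) / 2
    p_gc = gc_content / 2
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[idx].tobytes().decode()


def evolve_to_ani(seq: str, target_ani: float, seed: int = 0) -> str:
    """Substitute each site independently with probability
    ``1 - target_ani/100`` to a uniformly chosen different base."""
    if not 0 < target_ani <= 100:
        raise ValidationError("target_ani must be in (0, 100]")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    p = 1.0 - target_ani / 100.0
    if p == 0.0:
        return seq
    hit = rng.random(arr.size) < p
    n = int(hit.sum())
    if n:
        code = np.searchsorted(_BASES, arr[hit])  # ACGT are sorted bytes
        shift = rng.integers(1, 4, size=n)
        arr[hit] = _BASES[(code + shift) % 4]
    return arr.tobytes().decode()


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic community.

    Defaults echo a water-column cast design: 8 depths from the oxygenated
    surface to 1200 m, 50 genomes with guild-structured niches, and a few
    planted near-identical genome clusters for dereplication tests.
    """

    n_genomes: int = 50
    depths: tuple[float, ...] = (0.0, 10.0, 50.0, 80.0, 120.0, 150.0, 600.0, 1200.0)
    genome_length: int = 30_000
    n_scaffolds: int = 3
    noise_sigma: float = 0.0  # multiplicative coverage noise sd
    depth_factor: float = 500.0  # mean community coverage scale per sample
    total_reads: int = 1_000_000
    n_clusters: int = 4  # planted near-duplicate clusters (2 extra members each)
    cluster_members: int = 2
    within_cluster_ani: float = 99.5
    surface_fraction: float = 0.4
    deep_fraction: float = 0.4
    decoy_fraction: float = 0.3  # per absent model, chance of a sub-cutoff decoy hit
    marker_length: int = 120
    split_copy_fraction: float = 0.1
    duplicate_copy_fraction: float = 0.1
    gap_column_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValidationError("n_genomes must be >= 1")
        if not self.depths:
            raise ValidationError("at least one sample depth required")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside the community files."""

    genomes: list[GenomeRecord]
    samples: list[SampleRecord]
    coverage: CoverageTable
    hits: HitTable
    abundance_truth: pd.DataFrame  # genome x sample fractions, columns sum to 1
    function_truth: pd.DataFrame  # genome x reaction 0/1
    ani_truth: dict[tuple[str, str], float]  # planted within-cluster pairs
    cluster_truth: dict[str, list[str]]  # base genome -> members
    guilds: dict[str, str]
    marker_alignments: dict[str, MarkerAlignment]
    marker_copies: dict[str, dict[str, list[str]]]  # pre-resolution rows
    seed: int
    config: SimulationConfig = field(repr=False, default=None)


def _plant_markers(
    rng: np.random.Generator, genome_ids: list[str], cfg: SimulationConfig
) -> tuple[dict[str, MarkerAlignment], dict[str, dict[str, list[str]]]]:
    """Per-marker alignments: a shared ancestral protein with per-genome
    substitutions, plus configured fractions of split copies, duplicate
    copies and all-gap-heavy columns."""
    aas = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
    resolved: dict[str, MarkerAlignment] = {}
    raw: dict[str, dict[str, list[str]]] = {}
    length = cfg.marker_length
    for marker in RP16_MARKERS:
        ancestor = aas[rng.integers(0, len(aas), size=length)]
        rows: dict[str, str] = {}
        copies: dict[str, list[str]] = {}
        for gid in genome_ids:
            seq = ancestor.copy()
            mut = rng.random(length) < 0.1
            seq[mut] = aas[rng.integers(0, len(aas), size=int(mut.sum()))]
            # sprinkle gap columns so masking has something to remove
            gaps = rng.random(length) < cfg.gap_column_fraction
            chars = np.where(gaps, np.uint8(ord(GAP)), seq)
            full = chars.tobytes().decode()
            rows[gid] = full
            u = rng.random()
            if u < cfg.split_copy_fraction:
                mid = length // 2
                copies[gid] = [full[:mid] + GAP * (length - mid), GAP * mid + full[mid:]]
            elif u < cfg.split_copy_fraction + cfg.duplicate_copy_fraction:
                # shorter overlapping duplicate: truncate a quarter
                q = length // 4
                copies[gid] = [full, full[: length - q] + GAP * q]
            else:
                copies[gid] = [full]
        resolved[marker] = MarkerAlignment(marker, rows)
        raw[marker] = copies
    return resolved, raw


def simulate_community(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Generate a full synthetic community and its ground truth."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    pathways = default_pathways()
    reaction_ids = [p.reaction_id for p in pathways]

    n_base = cfg.n_genomes
    # guild assignment
    n_surface = int(round(cfg.surface_fraction * n_base))
    n_deep = int(round(cfg.deep_fraction * n_base))
    guild_list = (
        ["surface"] * n_surface
        + ["deep"] * n_deep
        + ["generalist"] * (n_base - n_surface - n_deep)
    )
    rng.shuffle(guild_list)

    genomes: list[GenomeRecord] = []
    guilds: dict[str, str] = {}
    mus: dict[str, float] = {}
    sigmas: dict[str, float] = {}
    bases: dict[str, float] = {}
    ani_truth: dict[tuple[str, str], float] = {}
    cluster_truth: dict[str, list[str]] = {}

    max_depth = max(cfg.depths)

    def make_record(gid: str, seq: str, guild: str, gseed: int) -> GenomeRecord:
        n_scaf = cfg.n_scaffolds
        cuts = np.linspace(0, len(seq), n_scaf + 1).astype(int)
        scaffolds = [
            (f"{gid}_s{i}", seq[cuts[i] : cuts[i + 1]]) for i in range(n_scaf)
        ]
        domain, phylum = GUILD_TAXA[guild][gseed % len(GUILD_TAXA[guild])]
        rec = GenomeRecord(
            genome_id=gid,
            scaffolds=scaffolds,
            completeness=float(rng.uniform(70, 100)),
            contamination=float(rng.uniform(0, 5)),
            taxonomy={"domain": domain, "phylum": phylum},
            lineage=phylum,
            is_archaea=domain == "Archaea",
            source_label="synthetic",
        )
        return rec

    gid_width = len(str(n_base))
    base_seeds = rng.integers(0, 2**31 - 1, size=n_base)
    for i in range(n_base):
        gid = f"SYN{i:0{gid_width}d}"
        guild = guild_list[i]
        seq = gen_genome(cfg.genome_length, gc_content=0.5, seed=int(base_seeds[i]))
        rec = make_record(gid, seq, guild, i)
        genomes.append(rec)
        guilds[gid] = guild
        if guild == "surface":
            mus[gid] = float(rng.uniform(0, 60))
            sigmas[gid] = float(rng.uniform(40, 120))
        elif guild == "deep":
            mus[gid] = float(rng.uniform(max_depth * 0.4, max_depth))
            sigmas[gid] = float(rng.uniform(150, 400))
        else:
            mus[gid] = float(rng.uniform(0, max_depth))
            sigmas[gid] = float(rng.uniform(400, 1200))
        bases[gid] = float(rng.lognormal(0.0, 1.0))
        cluster_truth[gid] = [gid]

    # planted near-duplicate clusters for dereplication tests
    n_clustered = min(cfg.n_clusters, n_base)
    for ci in range(n_clustered):
        base = genomes[ci]
        base_seq = "".join(s for _, s in base.scaffolds)
        for mi in range(cfg.cluster_members):
            gid = f"{base.genome_id}dup{mi}"
            mseed = int(rng.integers(0, 2**31 - 1))
            seq = evolve_to_ani(base_seq, cfg.within_cluster_ani, seed=mseed)
            rec = make_record(gid, seq, guilds[base.genome_id], ci)
            # duplicates are strictly worse-quality copies, so the cluster
            # base always founds (and represents) the planted cluster
            rec.completeness = max(50.0, base.completeness - 5.0)
            rec.contamination = base.contamination
            genomes.append(rec)
            guilds[gid] = guilds[base.genome_id]
            mus[gid] = mus[base.genome_id]
            sigmas[gid] = sigmas[base.genome_id]
            bases[gid] = bases[base.genome_id] * 0.5
            ani_truth[(base.genome_id, gid)] = cfg.within_cluster_ani
            cluster_truth[base.genome_id].append(gid)

    genome_ids = [g.genome_id for g in genomes]

    # samples along the depth gradient
    samples = [
        SampleRecord(
            sample_id=f"KigCas{int(d)}m",
            station="Kigoma",
            depth=float(d),
            date="2015-07-01",
            total_reads=cfg.total_reads,
        )
        for d in cfg.depths
    ]
    sample_ids = [s.sample_id for s in samples]

    # abundance truth: Gaussian depth niches, renormalized per sample
    ab = np.zeros((len(genome_ids), len(samples)))
    for gi, gid in enumerate(genome_ids):
        for si, s in enumerate(samples):
            ab[gi, si] = bases[gid] * np.exp(
                -((s.depth - mus[gid]) ** 2) / (2.0 * sigmas[gid] ** 2)
            )
    ab /= ab.sum(axis=0, keepdims=True)
    abundance_truth = pd.DataFrame(ab, index=genome_ids, columns=sample_ids)

    # coverage: abundance * depth_factor * (1 + noise), per scaffold
    coverage = CoverageTable()
    for g in genomes:
        for sid, seq in g.scaffolds:
            coverage.scaffold_to_genome[sid] = g.genome_id
    for si, s in enumerate(samples):
        for gi, g in enumerate(genomes):
            depth_cov = ab[gi, si] * cfg.depth_factor
            for sid, seq in g.scaffolds:
                noise = 1.0 + rng.normal(0.0, cfg.noise_sigma) if cfg.noise_sigma > 0 else 1.0
                coverage.add(sid, s.sample_id, max(0.0, depth_cov * noise), len(seq))

    # hit table: every planted gene above cutoff, decoys below
    planted: dict[str, set[str]] = {gid: set() for gid in genome_ids}
    by_reaction = {p.reaction_id: p for p in pathways}
    for gid in genome_ids:
        for rid in GUILD_REACTIONS[guilds[gid]]:
            p = by_reaction[rid]
            for group in p.logic:
                planted[gid].add(group[0])
    all_models = sorted({m for p in pathways for m in p.model_ids})
    cutoff_of = {}
    for p in pathways:
        for m, c in p.cutoffs.items():
            cutoff_of[m] = max(cutoff_of.get(m, 0.0), c)
    rows = []
    for gid in genome_ids:
        pi = 0
        for model in all_models:
            cutoff = cutoff_of[model]
            if model in planted[gid]:
                score = cutoff * 2.0
            elif rng.random() < cfg.decoy_fraction:
                score = cutoff * 0.5
            else:
                continue
            rows.append(
                (gid, f"{gid}_p{pi:04d}", model, score, 1e-30, 1, 100, 100)
            )
            pi += 1
    hits = HitTable(pd.DataFrame(rows, columns=[
        "genome_id", "protein_id", "model_id", "bit_score",
        "e_value", "model_from", "model_to", "ali_length",
    ]))

    # function truth = boolean closure of the planted hits over the shipped
    # definitions (reactions share marker genes, so closure > planted set)
    function_truth = build_function_matrix(hits, genome_ids, pathways)

    marker_alignments, marker_copies = _plant_markers(rng, genome_ids, cfg)

    return SyntheticTruth(
        genomes=genomes,
        samples=samples,
        coverage=coverage,
        hits=hits,
        abundance_truth=abundance_truth,
        function_truth=function_truth,
        ani_truth=ani_truth,
        cluster_truth=cluster_truth,
        guilds=guilds,
        marker_alignments=marker_alignments,
        marker_copies=marker_copies,
        seed=seed,
        config=cfg,
    )


def write_community(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Emit the community in the dialects the readers consume, plus a truth
    bundle (TSVs and a JSON manifest recording seed and config)."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "markers").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    paths: dict[str, Path] = {}
    for g in truth.genomes:
        p = out / "genomes" / f"{g.genome_id}.fasta"
        with open(p, "w") as fh:
            for sid, seq in g.scaffolds:
                fh.write(f">{sid}\n{seq}\n")
    paths["genomes"] = out / "genomes"

    meta_rows = []
    for g in truth.genomes:
        meta_rows.append(
            {
                "genome_id": g.genome_id,
                "completeness": g.completeness,
                "contamination": g.contamination,
                "domain": g.taxonomy.get("domain", ""),
                "phylum": g.taxonomy.get("phylum", ""),
                "lineage": g.lineage,
                "is_cpr": int(g.is_cpr),
                "is_dpann": int(g.is_dpann),
                "is_archaea": int(g.is_archaea),
                "source_label": g.source_label,
            }
        )
    paths["metadata"] = out / "genome_metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(paths["metadata"], sep="\t", index=False)

    paths["samples"] = out / "samples.tsv"
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "station": s.station,
                "depth_m": s.depth,
                "date": s.date,
                "total_reads": s.total_reads,
            }
            for s in truth.samples
        ]
    ).to_csv(paths["samples"], sep="\t", index=False)

    paths["coverage"] = out / "coverage.tsv"
    write_coverage_table(truth.coverage, paths["coverage"])
    paths["scaffold_map"] = out / "scaffold_to_genome.tsv"
    pd.DataFrame(
        sorted(truth.coverage.scaffold_to_genome.items()),
        columns=["scaffold_id", "genome_id"],
    ).to_csv(paths["scaffold_map"], sep="\t", index=False)

    paths["hits"] = out / "hits.tsv"
    write_hit_table(truth.hits, paths["hits"])

    for marker, copies in truth.marker_copies.items():
        with open(out / "markers" / f"{marker}.faa", "w") as fh:
            for gid in sorted(copies):
                for seq in copies[gid]:
                    fh.write(f">{gid}\n{seq}\n")
    paths["markers"] = out / "markers"

    truth.abundance_truth.to_csv(out / "truth" / "abundance.tsv", sep="\t")
    truth.function_truth.to_csv(out / "truth" / "functions.tsv", sep="\t")
    pd.DataFrame(
        [(a, b, v) for (a, b), v in sorted(truth.ani_truth.items())],
        columns=["genome_a", "genome_b", "ani"],
    ).to_csv(out / "truth" / "ani.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.guilds.items()), columns=["genome_id", "guild"]
    ).to_csv(out / "truth" / "guilds.tsv", sep="\t", index=False)
    manifest = {
        "seed": truth.seed,
        "config": dataclasses.asdict(truth.config),
    }
    with open(out / "truth" / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["truth"] = out / "truth"
    return paths
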