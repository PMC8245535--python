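# Methods

This note documents the models and procedures `lakecycle` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## MAG quality selection

A genome is retained iff `completeness >= min_completeness` (default 50)
AND `contamination < max_contamination` (default 10, strict inequality) —
the MIMAG medium-quality rule with its exact boundary semantics.
Completeness and contamination are read from a CheckM-style sidecar table,
never recomputed; a genome with unknown metrics is excluded with a warning
rather than defaulted to passing values. The filter is idempotent and
order-independent.

## MinHash ANI

Each genome is reduced to the `sketch_size` (default 5000) smallest
distinct 64-bit hashes over canonical k-mers (default k = 21; the canonical
form is the lexicographic minimum of a k-mer and its reverse complement,
which under 2-bit A<C<G<T encoding is an integer minimum). Hashing is a
fixed-salt splitmix64 finalizer applied to the 2-bit k-mer code, vectorised
over numpy uint64, so sketches are identical across runs and machines.
Windows containing non-ACGT characters are skipped; ambiguity codes remain
in the stored sequence and count toward genome size.

The Jaccard index is estimated Mash-style from the merged sketch: with
`s = min(sketch_size, max(|A|, |B|))`, J = |bottom-s(A ∪ B) ∩ A ∩ B| / s.
ANI follows from the Mash distance,

    D = −(1/k) · ln( 2J / (1+J) ),     ANI = 100 · (1 − D), clamped to [0, 100].

Pairs with J = 0, or estimated ANI below the reporting floor (default 75%),
carry an explicit below-floor marker instead of a number: a MinHash sketch
at these parameters carries too few shared hashes below ~75–80% identity
for the estimate to be meaningful. In the 95–100% range relevant to
dereplication the estimator tracks the true per-site identity to within
about ±0.2 percentage points on 100-kb genomes (the acceptance script
measures the realized error; the tolerance asserted in tests is ±0.5).

## Dereplication

Single-stage greedy clustering at one ANI threshold (default 99%). Genomes
are ranked by a dRep-style score, `completeness − 5·contamination`
(weights configurable); the highest-scoring unassigned genome founds a
cluster and becomes its representative, and every unassigned genome with
ANI ≥ threshold to the representative joins. Ties in score break by larger
genome size, then lexicographic id, so the outcome is deterministic. The
resulting invariants: clusters partition the input; every member is within
the threshold of its representative; any two representatives are either
below the threshold of each other or were founded before a qualifying
representative existed. A published two-stage (Mash then alignment-based
gANI) workflow collapses here to one sketch-ANI stage: the threshold is the
single knob and is exposed in config.

## Cross-lake comparison

`compare_groups` labels each genome with its lake and reports mean ANI for
within-A, within-B and cross pairs, a 0.5-percentage-point-bin histogram
from the floor to 100, the best cross-lake pair, and pair counts above
chosen thresholds (defaults 75% and 97%). Means exclude self pairs and
below-floor pairs — whether a study's reported means included unreported
aligner failures is generally unknowable, so the exclusion is fixed and
documented here. `taxon_overlap` compares distinct taxon labels at a chosen
rank, optionally after dropping genomes below an abundance threshold in a
reference sample; the threshold is caller-supplied config, not hard-coded.

## Relative abundance (RAR)

Genome coverage aggregates per-scaffold mean fold-coverages in one of two
modes: `sum_of_scaffold_means` (default) simply sums them, which is
faithful to common practice but sensitive to scaffold count;
`length_weighted_mean` computes Σ(cov·len)/Σ(len), the genome-wide mean
depth, and is the statistically preferable choice used in the recovery
tests. A detection floor (default 0.01×, configurable) zeroes trace
coverage before normalization to suppress spurious sub-read-level signal
from cross-mapping; noiseless synthetic recovery runs disable it, since
there is no mapping noise to suppress.

Coverage is divided by each sample's total read count. Whether that count
is raw, quality-filtered or mapped reads is a documented config choice
(the sample table carries one `total_reads` per sample); the package does
not infer it. RAR is then each genome's percent of the per-sample MAG
total, so each non-empty column sums to 100 ± 1e-6 and the denominator
excludes unbinned community mass. `taxon_rar` sums member rows per taxon
label; because grouped floating-point summation reorders additions, its
column sums agree with the direct sums to machine rounding (≤ 1e-9),
not bitwise.

## Metabolic capability rule

A reaction definition is an AND-of-OR-groups formula over marker-gene
model ids; a genome gets a 1 iff every group has at least one hit meeting
that model's minimum bit score ("one copy of each representative gene").
Cutoffs default to a global floor (50 bits) unless the definition gives a
per-model value, mirroring trusted-cutoff semantics. The shipped
`data/pathways.yml` covers the carbon, nitrogen and sulfur reactions of a
redox-stratified water column (organic carbon oxidation through
methanogenesis/methanotrophy and CO₂ fixation; fixation through the
denitrification chain, DNRA, anammox and comammox; the sulfide/sulfur/
sulfite/thiosulfate oxidations and sulfate/sulfite/sulfur reductions plus
thiosulfate disproportionation). Its gene sets follow the marker
conventions of METABOLIC-style annotation suites and are editable
configuration, not a claim about any particular study's exact HMM set.
Comammox is expressed as the conjunction of the ammonia- and
nitrite-oxidation gene groups in a single genome.

Curation decisions enter through an override table: `relabel` rewrites a
hit's model id (e.g. an amoA hit that phylogeny places with pmoA) and
re-evaluates every reaction for the affected genome; `force_present` /
`force_absent` set cells directly. Every changed cell is logged with its
reason, so curation is auditable and reversible. CAZyme density is total
hits per Mbp with per-class (GH/GT/PL/CE/AA/CBM) counts.

## Depth zones and reaction profiles

Zone bounds default to oxic < 50 m ≤ sub-oxic < 120 m ≤ anoxic, an
oxygen-profile-motivated choice rather than a printed rule, and are fully
configurable. A reaction profile reports `n_genomes` — capable genomes
over the whole (dereplicated) set — alongside per-sample summed RAR of
capable genomes, and additionally a per-sample count of capable genomes
with non-zero RAR, since "genomes involved" is ambiguous between the two.
No detection threshold is applied before summation by default; one is
available in config.

## Marker supermatrices

Copy resolution for a genome with several aligned copies of one marker:
copies whose non-gap column sets overlap by at most 10% of the shorter
copy's length (configurable) are treated as fragments of a split protein
and merged column-wise; otherwise the copy covering more columns is kept.
Exact zero overlap is not required because real HMM hits have ragged ends.
Masking removes columns whose gap fraction exceeds the threshold (default
0.5); an alternative "minimum occupancy" semantics is selectable for
instructions phrased as "N% masking", defaulting to the gap-fraction
reading. Masking is idempotent and monotone in the threshold.
Concatenation joins markers in a fixed order (the RP16 set by default),
pads genomes missing a marker with gaps, drops genomes below `min_markers`
(default 8 of 16 — half, a package choice since no standard minimum
exists) and emits a RAxML-style partition table; splitting by partitions
recovers the masked alignments exactly. Alignment computation and tree
inference are consumed/produced as files, not re-implemented.

## Synthetic communities

The generator plants a community whose recovery exercises every stage:

- **Niches.** Each genome draws a depth-niche center μ_g and width σ_g by
  guild (surface: μ ∈ [0, 60] m; deep: μ in the lower 60% of the water
  column; generalist: anywhere, wide σ) and a log-normal baseline; sample
  abundance is base·exp(−(depth−μ)²/2σ²), renormalized per sample over
  the default 8 depths (0–1200 m, echoing a two-station cast design).
- **Guild-function coupling.** Surface genomes carry CO₂ fixation and
  organic carbon oxidation; deep genomes methanogenesis, sulfite reduction
  and anammox; generalists organic carbon oxidation and fermentation.
  The stored function truth is the boolean closure of the planted hits
  over the shipped definitions (reactions can share marker genes), so
  "exact recovery" is well-defined.
- **Coverage.** abundance × a per-sample scale (default 500×) × (1 +
  Gaussian noise σ), truncated at zero, written per scaffold. Noise is
  multiplicative on coverage rather than read-level simulation: the
  pipeline consumes coverage tables, so simulating reads would add cost
  without testing more code.
- **Hits.** Every planted gene appears at 2× its cutoff; absent models get
  decoy hits at 0.5× cutoff with probability 0.3, exercising the threshold
  logic.
- **ANI structure.** A configurable number of planted clusters add members
  mutated to 99.5% identity; members are strictly worse-quality copies of
  their base (completeness − 5, same contamination) so the base always
  founds and represents the cluster under the greedy rule, making the
  planted partition the unique correct dereplication. Unrelated genomes
  are independent random sequences (sketch ANI below floor).
- **Markers.** Per-marker alignments derive from a shared ancestral
  protein with 10% per-genome substitutions, ~10% gap columns, and
  configured fractions of split and truncated-duplicate copies whose
  resolution reproduces the planted row.

Defaults (50 genomes of 30 kb in 3 scaffolds, 8 samples, σ = 0) are sized
for fast, deterministic test runs; all are config. What the generator does
**not** emulate: real genome composition (no genes, GC structure or
repeats beyond i.i.d. bases), read-level noise and mapping bias,
incomplete binning (every scaffold is binned), HMM score distributions
(two point masses), or phylogenetically realistic marker evolution.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's arithmetic and logic under controlled conditions — not
robustness to assembly, binning or annotation error in field data.

## Numerical choices

- Sketch hashing uses a fixed salt; sketches, ANI matrices and all
  pipeline outputs are byte-deterministic for a fixed config and seed.
- ANI is clamped to [0, 100]; J ≥ 1 reports exactly 100.
- Greedy dereplication breaks score ties by genome size then id.
- The noiseless recovery path uses `length_weighted_mean` coverage with
  the detection floor off; tolerance 1e-9 on the percent scale.
- Coverage TSVs are re-read with round-trip float parsing so write/read
  is the identity.
- The pipeline caches at whole-run granularity: a re-run reuses existing
  outputs only when every recorded input checksum matches and every output
  checksum is intact.

## Known limitations

- Sketch ANI degrades below ~90% identity and is unreliable below the 75%
  floor; cross-lake mean ANIs computed here are estimator-specific and can
  differ from alignment-based values by a few tenths of a point.
- Capability is potential, not activity: a genome carrying a pathway need
  not express it at that depth.
- The RAR denominator covers binned genomes only; absolute community
  fractions would need the unbinned fraction, which the pipeline does not
  see.
- `sum_of_scaffold_means` inflates fragmented genomes' coverage by
  construction; prefer the length-weighted mode when comparing across
  genomes of different contiguity.
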