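"""Sketch ANI estimation, greedy dereplication and group comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lakecycle.ani_derep import (
    ANIMatrix,
    Sketch,
    ani_from_sketches,
    compare_groups,
    dereplicate,
    pairwise_ani,
    sketch_genome,
    taxon_overlap,
)
from lakecycle.core_model import GenomeRecord, ValidationError
from lakecycle.synthetic_data import evolve_to_ani, gen_genome


def genome(gid, seq, completeness=90.0, contamination=1.0):
    return GenomeRecord(gid, [(f"{gid}_s", seq)], completeness=completeness,
                        contamination=contamination)


REVCOMP = str.maketrans("ACGT", "TGCA")


class TestSketch:
    def test_identical_genomes_identical_sketches(self):
        seq = gen_genome(2000, seed=1)
        sa = sketch_genome(genome("a", seq))
        sb = sketch_genome(genome("b", seq))
        assert np.array_equal(sa.hashes, sb.hashes)

    def test_reverse_complement_gives_same_sketch(self):
        seq = gen_genome(2000, seed=2)
        rc = seq.translate(REVCOMP)[::-1]
        sa = sketch_genome(genome("a", seq))
        sb = sketch_genome(genome("b", rc))
        assert np.array_equal(sa.hashes, sb.hashes)

    def test_short_sequence_bounds_sketch_size(self):
        # 100 bp, k=21: at most 80 k-mers, so at most 80 hashes
        seq = gen_genome(100, seed=3)
        s = sketch_genome(genome("a", seq), k=21)
        assert len(s.hashes) <= 80

    def test_ambiguity_codes_excluded_from_kmers(self):
        seq = "ACGT" * 30
        with_n = seq[:50] + "N" * 30 + seq[50:]
        sa = sketch_genome(genome("a", seq))
        sb = sketch_genome(genome("b", with_n))
        # every k-mer of the N-containing genome is a k-mer of the clean one
        assert set(sb.hashes) <= set(sa.hashes)

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            sketch_genome(genome("a", "ACGT"))


class TestAniFromSketches:
    def test_full_jaccard_gives_100(self):
        h = np.arange(10, dtype=np.uint64)
        s = Sketch("a", 21, 10, h)
        assert ani_from_sketches(s, Sketch("b", 21, 10, h.copy())) == 100.0

    def test_closed_form_at_jaccard_half(self):
        # crafted sketches with J = 0.5: ANI = 100*(1 + ln(2*0.5/1.5)/21) = 98.069
        a = Sketch("a", 21, 100, np.arange(100, dtype=np.uint64))
        b_h = np.concatenate([np.arange(50), np.arange(200, 250)]).astype(np.uint64)
        b = Sketch("b", 21, 100, b_h)
        ani = ani_from_sketches(a, b)
        expected = 100.0 * (1.0 + math.log(2 * 0.5 / 1.5) / 21)
        assert ani == pytest.approx(expected, abs=1e-9)
        assert ani == pytest.approx(98.069, abs=0.001)

    def test_disjoint_sketches_below_floor(self):
        a = Sketch("a", 21, 10, np.arange(10, dtype=np.uint64))
        b = Sketch("b", 21, 10, np.arange(100, 110, dtype=np.uint64))
        assert ani_from_sketches(a, b) is None

    def test_k_mismatch_rejected(self):
        a = Sketch("a", 21, 10, np.arange(10, dtype=np.uint64))
        b = Sketch("b", 17, 10, np.arange(10, dtype=np.uint64))
        with pytest.raises(ValidationError, match="k mismatch"):
            ani_from_sketches(a, b)


class TestPairwiseAni:
    def test_identical_pair_and_symmetry(self):
        seq = gen_genome(5000, seed=4)
        m = pairwise_ani([genome("a", seq), genome("b", seq)])
        assert m.ani("a", "b") == 100.0
        assert m.ani("a", "a") == 100.0
        assert m.values.equals(m.values.T)

    def test_unrelated_genome_below_floor(self):
        a = gen_genome(5000, seed=5)
        b = gen_genome(5000, seed=6)
        c = gen_genome(5000, seed=7)
        m = pairwise_ani([genome("a", a), genome("b", b), genome("c", c)])
        assert m.ani("a", "c") is None and m.ani("b", "c") is None

    def test_two_percent_mutated_copy_recovered(self):
        # oracle: direct positional identity count on the planted pair
        base = gen_genome(100_000, seed=8)
        mut = evolve_to_ani(base, 98.0, seed=9)
        ident = 100.0 * np.mean(
            np.frombuffer(base.encode(), np.uint8) == np.frombuffer(mut.encode(), np.uint8)
        )
        m = pairwise_ani([genome("a", base), genome("b", mut)])
        assert m.ani("a", "b") == pytest.approx(ident, abs=0.5)
        assert m.ani("a", "b") == pytest.approx(98.0, abs=0.5)

    def test_higher_mutation_rate_never_higher_ani(self):
        # expectation over seeds: estimated ANI ordered with planted identity
        rates = [100.0, 99.0, 98.0, 95.0]
        means = []
        for target in rates:
            vals = []
            for seed in range(5):
                base = gen_genome(20_000, seed=seed)
                mut = evolve_to_ani(base, target, seed=seed + 100)
                m = pairwise_ani([genome("a", base), genome("b", mut)])
                vals.append(m.ani("a", "b"))
            means.append(np.mean(vals))
        assert all(means[i] >= means[i + 1] for i in range(len(means) - 1))


def hand_matrix(ids, pairs, floor=75.0):
    mat = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i in ids:
        mat.at[i, i] = 100.0
    for (a, b), v in pairs.items():
        mat.at[a, b] = v
        mat.at[b, a] = v
    return ANIMatrix(list(ids), mat, floor=floor)


class TestDereplicate:
    def test_greedy_hand_example(self):
        genomes = [genome("A", "ACGT" * 10, 90, 2), genome("B", "ACGT" * 10, 80, 1),
                   genome("C", "ACGT" * 10, 70, 0)]
        m = hand_matrix(["A", "B", "C"], {("A", "B"): 99.5, ("A", "C"): 80.0, ("B", "C"): 80.0})
        cs = dereplicate(genomes, m, ani_threshold=99.0)
        # scores: A 80, B 75, C 70 -> A founds, absorbs B; C singleton
        assert cs.clusters == {"A": ["A", "B"], "C": ["C"]}

    def test_all_below_threshold_all_singletons(self):
        ids = ["a", "b", "c"]
        genomes = [genome(i, "ACGT" * 10) for i in ids]
        m = hand_matrix(ids, {("a", "b"): 90.0, ("a", "c"): 90.0, ("b", "c"): 90.0})
        cs = dereplicate(genomes, m)
        assert sorted(cs.clusters) == ids
        assert all(len(v) == 1 for v in cs.clusters.values())

    def test_equal_scores_tie_broken_by_size_then_id(self):
        big = genome("zzz", "ACGT" * 20, 90, 1)
        small = genome("aaa", "ACGT" * 10, 90, 1)
        m = hand_matrix(["aaa", "zzz"], {("aaa", "zzz"): 100.0})
        cs = dereplicate([small, big], m)
        assert list(cs.clusters) == ["zzz"]  # larger genome wins the tie
        same = genome("aaa2", "ACGT" * 20, 90, 1)
        m2 = hand_matrix(["aaa2", "zzz"], {("aaa2", "zzz"): 100.0})
        cs2 = dereplicate([same, big], m2)
        assert list(cs2.clusters) == ["aaa2"]  # equal size: lexicographic id

    @pytest.mark.parametrize("seed", range(6))
    def test_soundness_against_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        ids = [f"g{i}" for i in range(n)]
        genomes = [
            genome(gid, "ACGT" * int(rng.integers(5, 20)),
                   float(rng.uniform(50, 100)), float(rng.uniform(0, 10)))
            for gid in ids
        ]
        pairs = {}
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.5:
                pairs[(a, b)] = float(rng.uniform(95, 100))
        m = hand_matrix(ids, pairs)
        cs = dereplicate(genomes, m, ani_threshold=99.0)
        membership = cs.membership()
        assert sorted(membership) == ids  # partition covers input
        # every member within threshold of its representative
        for member, rep in membership.items():
            if member != rep:
                assert m.ani(rep, member) is not None
                assert m.ani(rep, member) >= 99.0
        # greedy property: a representative founded later must be < threshold
        # from every earlier-founded representative
        reps_in_order = sorted(cs.clusters, key=lambda r: -cs.scores[r])
        for i, later in enumerate(reps_in_order):
            for earlier in reps_in_order[:i]:
                v = m.ani(earlier, later)
                assert v is None or v < 99.0


class TestCompareGroups:
    def test_singleton_groups_cross_only(self):
        m = hand_matrix(["a", "b"], {("a", "b"): 90.0})
        cmp = compare_groups(m, {"a": "LT", "b": "LB"})
        assert cmp.cross_mean == 90.0
        assert cmp.within_a_mean is None and cmp.within_b_mean is None

    def test_hand_matrix_means_match_brute_force(self):
        ids = ["a1", "a2", "b1", "b2"]
        pairs = {("a1", "a2"): 99.0, ("b1", "b2"): 97.0, ("a1", "b1"): 80.0,
                 ("a1", "b2"): 82.0, ("a2", "b1"): 84.0}  # (a2,b2) below floor
        m = hand_matrix(ids, pairs)
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        cmp = compare_groups(m, labels)
        assert cmp.within_a_mean == pytest.approx(99.0)
        assert cmp.within_b_mean == pytest.approx(97.0)
        assert cmp.cross_mean == pytest.approx((80.0 + 82.0 + 84.0) / 3)
        assert cmp.max_cross_pair == ("a2", "b1", 84.0)
        assert cmp.counts_above[75.0]["A_vs_B"] == 3

    def test_unlabeled_genome_rejected(self):
        m = hand_matrix(["a", "b"], {("a", "b"): 90.0})
        with pytest.raises(ValidationError, match="unlabeled"):
            compare_groups(m, {"a": "LT"})


class TestTaxonOverlap:
    def taxon_genomes(self, labels):
        return [GenomeRecord(f"g{i}_{t}", [("s", "ACGT")], taxonomy={"phylum": t})
                for i, t in enumerate(labels)]

    def test_half_overlap(self):
        a = self.taxon_genomes(["x", "y"])
        b = self.taxon_genomes(["y", "z"])
        ov = taxon_overlap(a, b, "phylum")
        assert ov.unique_a_fraction == 0.5
        assert ov.unique_b_fraction == 0.5
        assert ov.shared == {"y"}

    def test_identical_sets_no_unique(self):
        a = self.taxon_genomes(["x", "y"])
        ov = taxon_overlap(a, a, "phylum")
        assert ov.unique_a_fraction == 0.0 and ov.unique_b_fraction == 0.0

    def test_abundance_filter_drops_low_taxa(self):
        a = self.taxon_genomes(["x", "y", "z"])
        b = self.taxon_genomes(["z"])
        abundance = {g.genome_id: 1.0 for g in a + b}
        abundance[a[1].genome_id] = 0.01  # drop y from A
        ov = taxon_overlap(a, b, "phylum", abundance=abundance, min_abundance=0.5)
        assert ov.unique_a_fraction == 0.5

    def test_missing_rank_rejected(self):
        a = [GenomeRecord("g", [("s", "ACGT")], taxonomy={})]
        with pytest.raises(ValidationError, match="lacks rank"):
            taxon_overlap(a, a, "order")
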