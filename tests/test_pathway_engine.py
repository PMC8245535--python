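"""The one-copy-per-gene boolean rule engine, overrides and CAZyme density."""

import itertools

import pandas as pd
import pytest

from lakecycle.core_model import HIT_COLUMNS, HitTable, PathwayDefinition, ValidationError
from lakecycle.pathway_engine import (
    OverrideTable,
    apply_overrides,
    build_function_matrix,
    cazyme_density,
    default_pathways,
    evaluate_reaction,
    load_pathways,
)


def hits_frame(rows):
    """rows: (genome_id, model_id, bit_score)"""
    return pd.DataFrame(
        [(g, f"{g}_p{i}", m, s, 1e-20, 1, 100, 100) for i, (g, m, s) in enumerate(rows)],
        columns=HIT_COLUMNS,
    )


def pdef(reaction_id, logic, cutoffs=None, cycle="nitrogen"):
    cut = {m: 50.0 for group in logic for m in group}
    cut.update(cutoffs or {})
    return PathwayDefinition(reaction_id, cycle, reaction_id, logic=logic, cutoffs=cut)


NIF = pdef("nitrogen_fixation", [["nifH"], ["nifD"], ["nifK"]])
NAR = pdef("nitrate_reduction", [["narG", "napA"], ["narH", "napB"]])


class TestEvaluateReaction:
    def test_missing_one_and_gene_gives_absent(self):
        h = hits_frame([("g", "nifH", 100), ("g", "nifD", 100)])
        assert evaluate_reaction(h, NIF) == 0

    def test_all_genes_present(self):
        h = hits_frame([("g", "nifH", 100), ("g", "nifD", 100), ("g", "nifK", 100)])
        assert evaluate_reaction(h, NIF) == 1

    def test_or_groups_satisfied_by_alternatives(self):
        h = hits_frame([("g", "napA", 100), ("g", "narH", 100)])
        assert evaluate_reaction(h, NAR) == 1

    def test_hit_below_cutoff_does_not_qualify(self):
        h = hits_frame([("g", "nifH", 25), ("g", "nifD", 100), ("g", "nifK", 100)])
        assert evaluate_reaction(h, NIF) == 0

    def test_missing_cutoff_without_default_rejected(self):
        pd_def = PathwayDefinition("r", "carbon", "r", logic=[["x"]], cutoffs={})
        with pytest.raises(ValidationError, match="no cutoff"):
            evaluate_reaction(hits_frame([("g", "x", 100)]), pd_def)

    @pytest.mark.parametrize("pd_def", [NIF, NAR, pdef("two_or", [["a", "b", "c"]])])
    def test_matches_exhaustive_boolean_evaluation(self, pd_def):
        models = pd_def.model_ids
        for n_present in range(len(models) + 1):
            for present in itertools.combinations(models, n_present):
                h = hits_frame([("g", m, 100) for m in present])
                expected = int(all(any(m in present for m in grp) for grp in pd_def.logic))
                assert evaluate_reaction(h, pd_def) == expected

    def test_adding_qualifying_hit_never_removes_capability(self):
        base = [("g", "nifH", 100), ("g", "nifD", 100), ("g", "nifK", 100)]
        h = hits_frame(base)
        assert evaluate_reaction(h, NIF) == 1
        for extra in ("nifH", "napA", "zzz"):
            h2 = hits_frame(base + [("g", extra, 999)])
            assert evaluate_reaction(h2, NIF) == 1


class TestBuildFunctionMatrix:
    def test_matches_per_cell_oracle(self):
        rows = [("g1", "nifH", 100), ("g1", "nifD", 100), ("g1", "nifK", 100),
                ("g2", "napA", 100), ("g2", "narH", 100)]
        hits = HitTable(hits_frame(rows))
        fm = build_function_matrix(hits, ["g1", "g2"], [NIF, NAR])
        for gid in ("g1", "g2"):
            for p in (NIF, NAR):
                assert fm.at[gid, p.reaction_id] == evaluate_reaction(
                    hits.for_genome(gid), p
                )

    def test_genome_without_hits_all_zero(self):
        hits = HitTable(hits_frame([("g1", "nifH", 100)]))
        fm = build_function_matrix(hits, ["g1", "g2"], [NIF, NAR])
        assert (fm.loc["g2"] == 0).all()

    def test_duplicate_hits_change_nothing(self):
        rows = [("g1", "napA", 100), ("g1", "narH", 100)]
        fm1 = build_function_matrix(HitTable(hits_frame(rows)), ["g1"], [NAR])
        fm2 = build_function_matrix(HitTable(hits_frame(rows * 3)), ["g1"], [NAR])
        assert fm1.equals(fm2)


AMO = pdef("ammonia_oxidation", [["amoA"], ["amoB"]])
PMO = pdef("methanotrophy", [["pmoA", "mmoX"]], cycle="carbon")


class TestApplyOverrides:
    def test_relabel_moves_hit_and_reevaluates(self):
        rows = [("g", "amoA", 100), ("g", "amoB", 100)]
        hits = HitTable(hits_frame(rows))
        fm = build_function_matrix(hits, ["g"], [AMO, PMO])
        assert fm.at["g", "ammonia_oxidation"] == 1
        assert fm.at["g", "methanotrophy"] == 0
        ov = OverrideTable(rows=[{"genome_id": "g", "target": "amoA",
                                  "action": "relabel", "new_label": "pmoA",
                                  "reason": "phylogeny places it with pmoA"}])
        out, log = apply_overrides(fm, hits, ov, [AMO, PMO])
        assert out.at["g", "ammonia_oxidation"] == 0
        assert out.at["g", "methanotrophy"] == 1
        assert any("relabel" in line for line in log)

    def test_empty_override_is_identity(self):
        hits = HitTable(hits_frame([("g", "amoA", 100)]))
        fm = build_function_matrix(hits, ["g"], [AMO])
        out, log = apply_overrides(fm, hits, OverrideTable(rows=[]), [AMO])
        assert out.equals(fm) and log == []

    def test_force_absent_clears_cell(self):
        hits = HitTable(hits_frame([("g", "amoA", 100), ("g", "amoB", 100)]))
        fm = build_function_matrix(hits, ["g"], [AMO])
        ov = OverrideTable(rows=[{"genome_id": "g", "target": "ammonia_oxidation",
                                  "action": "force_absent"}])
        out, _ = apply_overrides(fm, hits, ov, [AMO])
        assert out.at["g", "ammonia_oxidation"] == 0

    def test_unknown_genome_rejected(self):
        hits = HitTable(hits_frame([("g", "amoA", 100)]))
        fm = build_function_matrix(hits, ["g"], [AMO])
        ov = OverrideTable(rows=[{"genome_id": "nope", "target": "ammonia_oxidation",
                                  "action": "force_absent"}])
        with pytest.raises(ValidationError, match="unknown genome"):
            apply_overrides(fm, hits, ov, [AMO])

    def test_relabel_requires_new_label(self):
        with pytest.raises(ValidationError, match="new_label"):
            OverrideTable(rows=[{"genome_id": "g", "target": "amoA", "action": "relabel"}])


class TestCazymeDensity:
    def test_hits_per_mbp(self):
        profile = cazyme_density(["GH13"] * 30, "g", 3_000_000)
        assert profile.density == pytest.approx(10.0)
        assert profile.class_counts["GH"] == 30

    def test_no_hits_zero_density(self):
        assert cazyme_density([], "g", 2_000_000).density == 0.0

    def test_density_scales_inversely_with_genome_size(self):
        a = cazyme_density(["GH1"] * 10, "a", 2_000_000)
        b = cazyme_density(["GH1"] * 10, "b", 4_000_000)
        assert a.density == pytest.approx(2 * b.density)

    def test_zero_genome_size_rejected(self):
        with pytest.raises(ValidationError, match="genome_size"):
            cazyme_density(["GH1"], "g", 0)


class TestShippedDefinitions:
    def test_defaults_load_and_cover_three_cycles(self):
        pathways = default_pathways()
        cycles = {p.cycle for p in pathways}
        assert {"carbon", "nitrogen", "sulfur"} <= cycles
        ids = {p.reaction_id for p in pathways}
        assert {"methanogenesis", "anammox", "comammox", "sulfate_reduction"} <= ids
        for p in pathways:
            assert all(m in p.cutoffs for m in p.model_ids)

    def test_comammox_requires_both_oxidation_steps(self):
        by_id = {p.reaction_id: p for p in default_pathways()}
        com = by_id["comammox"]
        amo_plus_nxr = hits_frame(
            [("g", m, 200) for m in ("amoA", "amoB", "nxrA", "nxrB")]
        )
        assert evaluate_reaction(amo_plus_nxr, com) == 1
        amo_only = hits_frame([("g", m, 200) for m in ("amoA", "amoB")])
        assert evaluate_reaction(amo_only, com) == 0

    def test_duplicate_reaction_ids_rejected(self, tmp_path):
        p = tmp_path / "bad.yml"
        p.write_text(
            "reactions:\n"
            "  - {id: r1, cycle: carbon, logic: [[a]]}\n"
            "  - {id: r1, cycle: carbon, logic: [[b]]}\n"
        )
        with pytest.raises(ValidationError, match="duplicate reaction ids"):
            load_pathways(p)
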