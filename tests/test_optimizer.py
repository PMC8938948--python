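"""Two-pass optimizer: objectives, hard constraints, hotspot repair, audit."""

import pytest
from Bio.Seq import Seq

from seqstab.codon_usage import SUPPORTED_ORGANISMS, build_codon_table
from seqstab.fixtures import hotspot_free_sequence, plant_motif, random_orf
from seqstab.hotspot_detection import find_rmd_sites, find_ssr_sites, rank_sites
from seqstab.motif_scanning import scan_sequence
from seqstab.mutation_rates import rip_score
from seqstab.optimizer import (
    AuditError,
    Change,
    OptimizationSpec,
    UnsatisfiableConstraintError,
    codon_objective_score,
    derive_avoid_constraints,
    first_pass,
    second_pass,
    verify_result,
)

from conftest import build_orf_fixture


def _run_pipeline(sequence, spec, pssms=()):
    report = []
    semi = first_pass(sequence, spec, report)
    sites = rank_sites(find_ssr_sites(semi), spec.site_budget) + rank_sites(
        find_rmd_sites(semi), spec.site_budget
    )
    if pssms:
        sites += rank_sites(scan_sequence(semi, list(pssms)), spec.site_budget)
    constraints, skipped = derive_avoid_constraints(
        sites, spec.locked_regions, {p.name: p for p in pssms}
    )
    result = second_pass(semi, spec, constraints, skipped)
    return semi, constraints, result


class TestCodonTables:
    @pytest.mark.parametrize(
        "organism",
        [
            "B. subtilis", "C. elegans", "D. melanogaster", "E. coli", "G. gallus",
            "H. sapiens", "M. musculus", "M. musculus domesticus", "S. cerevisiae",
        ],
    )
    def test_every_supported_organism_loads_normalised(self, organism):
        table = build_codon_table(organism)
        for aa, codons in table.families.items():
            assert sum(table.frequency[c] for c in codons) == pytest.approx(1.0, abs=1e-6)
        assert sum(len(v) for v in table.families.values()) == 64

    def test_unknown_organism_lists_supported(self):
        with pytest.raises(ValueError, match="X. laevis"):
            build_codon_table("X. laevis")
        assert len(SUPPORTED_ORGANISMS) == 9


class TestObjectiveScore:
    def test_all_best_codons_scores_one(self):
        table = build_codon_table("e_coli")
        orf = "".join(table.best_codon(aa) for aa in "MKLVFHDE")
        assert codon_objective_score(orf, (0, len(orf)), table, "use_best_codon") == 1.0

    def test_matching_usage_scores_zero_distance(self):
        table = build_codon_table("e_coli")
        orf = "ATGATG"  # Met only: observed frequencies equal the table trivially
        assert codon_objective_score(orf, (0, 6), table, "match_codon_usage") == 0.0

    def test_internal_stop_rejected(self):
        table = build_codon_table("e_coli")
        with pytest.raises(ValueError, match="stop"):
            codon_objective_score("ATGTAAGGG", (0, 9), table, "use_best_codon")

    def test_greedy_replacement_improves_monotonically(self):
        table = build_codon_table("e_coli")
        orf = random_orf("MKHLVDFEQRNSTY" * 3, seed=8, stop=False)
        codons = [orf[i : i + 3] for i in range(0, len(orf), 3)]
        scores = [codon_objective_score("".join(codons), (0, len(orf)), table, "use_best_codon")]
        from seqstab.codon_usage import STANDARD_CODE

        for i, codon in enumerate(codons):
            codons[i] = table.best_codon(STANDARD_CODE[codon])
            scores.append(
                codon_objective_score("".join(codons), (0, len(orf)), table, "use_best_codon")
            )
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        assert scores[-1] == 1.0


class TestSpecValidation:
    def test_orf_not_divisible_by_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            OptimizationSpec(orf_regions=((0, 10),)).validate(100)

    def test_overlapping_orfs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            OptimizationSpec(orf_regions=((0, 30), (27, 60))).validate(100)

    def test_inverted_gc_bounds_rejected(self):
        with pytest.raises(ValueError):
            OptimizationSpec(gc_min=0.6, gc_max=0.4).validate(100)


class TestFirstPass:
    def test_fixed_point_when_already_optimal(self):
        table = build_codon_table("e_coli")
        orf = "".join(table.best_codon(aa) for aa in "MKLVFHDEQR")
        spec = OptimizationSpec(organism="E. coli", orf_regions=((0, len(orf)),))
        assert first_pass(orf, spec) == orf

    def test_without_organism_only_constraints_resolved(self):
        seq = hotspot_free_sequence(400, seed=41)
        spec = OptimizationSpec(organism=None, gc_min=0.0, gc_max=1.0)
        assert first_pass(seq, spec) == seq

    def test_at_rich_orf_pulled_into_gc_bounds(self):
        code = {"M": "ATG", "L": "TTA", "S": "TCA", "I": "ATT", "K": "AAA", "N": "AAT"}
        orf = "".join(code[a] for a in "MLSISLKNSLLNKS" * 5)
        spec = OptimizationSpec(gc_min=0.4, gc_max=0.8, orf_regions=((0, len(orf)),))
        out = first_pass(orf, spec)
        assert str(Seq(out).translate()) == str(Seq(orf).translate())
        for lo in range(0, len(out), 50):
            window = out[lo : lo + 50]
            assert sum(b in "GC" for b in window) / len(window) >= 0.4 - 1e-12

    def test_locked_window_out_of_bounds_raises_named_error(self):
        seq = "AT" * 100
        spec = OptimizationSpec(gc_min=0.4, gc_max=0.8, locked_regions=((0, 200),))
        with pytest.raises(UnsatisfiableConstraintError, match=r"\[0, 50\)"):
            first_pass(seq, spec)

    def test_deterministic(self):
        seq, orf_span = build_orf_fixture(7)
        spec = OptimizationSpec(
            organism="H. sapiens", method="match_codon_usage", orf_regions=(orf_span,)
        )
        assert first_pass(seq, spec) == first_pass(seq, spec)


class TestDeriveConstraints:
    def test_ssr_constraint_targets_alternating_copies(self):
        seq, _ = ("CC" + "AT" * 4 + "GG", None)
        sites = find_ssr_sites(seq)
        constraints, skipped = derive_avoid_constraints(sites)
        assert constraints[0].kind == "ssr_units"
        assert constraints[0].span == (2, 10)
        assert not skipped

    def test_rmd_constraint_spans_first_copy(self):
        background = hotspot_free_sequence(500, seed=51)
        from seqstab.fixtures import plant_rmd

        seq, _ = plant_rmd(background, 20, 30, 100)
        constraints, _ = derive_avoid_constraints(find_rmd_sites(seq))
        assert constraints[0].kind == "recombination_15mer"
        assert constraints[0].span == (100, 120)

    def test_locked_site_skipped_with_warning(self, pssms):
        background = hotspot_free_sequence(500, seed=52)
        seq, _ = plant_motif(background, pssms[0], 100, "+")
        hits = [h for h in scan_sequence(seq, pssms) if h.start == 100]
        constraints, skipped = derive_avoid_constraints(hits, locked_regions=((95, 120),))
        assert constraints == []
        assert any("locked" in s for s in skipped)


class TestSecondPass:
    def test_no_sites_is_identity(self):
        seq = hotspot_free_sequence(600, seed=61)
        result = second_pass(seq, OptimizationSpec(), [])
        assert result.sequence == seq and result.changes == []

    def test_lysine_homopolymer_rewritten_synonymously(self):
        # KKK run encoded AAA x3 inside an ORF, flanked by editable codons.
        # (Four lysines are provably unbreakable: every Lys codon starts AA,
        # so any AAA not in final position restores an A4 run and an all-AAG
        # choice is itself an AAG tandem.)
        orf = random_orf("MFH", seed=62, stop=False) + "AAA" * 3 + random_orf("HFD", seed=63)
        background = hotspot_free_sequence(600, seed=62)
        seq = background[:100] + orf + background[100 + len(orf) :]
        spec = OptimizationSpec(orf_regions=((100, 100 + len(orf)),))
        semi, constraints, result = _run_pipeline(seq, spec)
        assert result.remaining == {"ssr": 0, "rmd": 0, "motif": 0}
        out = result.sequence
        assert str(Seq(out[100 : 100 + len(orf)]).translate()) == str(
            Seq(orf).translate()
        )
        assert "AAAAAAAAA" not in out[100 : 100 + len(orf)]

    def test_duplicated_20mer_in_orf_removed(self):
        seq, orf_span = build_orf_fixture(5)
        spec = OptimizationSpec(orf_regions=(orf_span,))
        semi, constraints, result = _run_pipeline(seq, spec)
        assert find_rmd_sites(result.sequence) == []
        assert result.removed["rmd"] >= 1

    def test_determinism_given_seed(self):
        seq, orf_span = build_orf_fixture(9)
        spec = OptimizationSpec(
            organism="E. coli", gc_min=0.3, gc_max=0.7, orf_regions=(orf_span,), seed=3
        )
        runs = [_run_pipeline(seq, spec)[2].sequence for _ in range(2)]
        assert runs[0] == runs[1]

    def test_rip_strictly_decreases_on_hotspot_fixtures(self):
        seq, orf_span = build_orf_fixture(12)
        spec = OptimizationSpec(orf_regions=(orf_span,))
        semi, constraints, result = _run_pipeline(seq, spec)
        before = rip_score(len(semi), find_ssr_sites(semi), find_rmd_sites(semi))
        after = rip_score(
            len(result.sequence),
            find_ssr_sites(result.sequence),
            find_rmd_sites(result.sequence),
        )
        assert after < before

    def test_locked_region_never_edited(self):
        seq, orf_span = build_orf_fixture(3)
        lock = (orf_span[0] + 60, orf_span[0] + 90)
        spec = OptimizationSpec(orf_regions=(orf_span,), locked_regions=(lock,))
        _, _, result = _run_pipeline(seq, spec)
        assert result.sequence[lock[0] : lock[1]] == seq[lock[0] : lock[1]]


class TestAudit:
    def test_valid_result_summarised_by_reason(self):
        seq, orf_span = build_orf_fixture(15)
        spec = OptimizationSpec(orf_regions=(orf_span,))
        semi, constraints, result = _run_pipeline(seq, spec)
        summary = verify_result(semi, result, spec, constraints)
        assert summary.n_changes == len(result.changes)
        assert set(summary.by_reason) <= {"ssr_break", "rmd_break", "motif_break", "gc_content", "hotspot_cleanup"}

    def test_tampered_lock_raises(self):
        seq, orf_span = build_orf_fixture(16)
        lock = (10, 40)
        spec = OptimizationSpec(orf_regions=(orf_span,), locked_regions=(lock,))
        semi, constraints, result = _run_pipeline(seq, spec)
        tampered = result.sequence[:20] + ("A" if result.sequence[20] != "A" else "C") + result.sequence[21:]
        result.sequence = tampered
        result.changes = result.changes + [Change(20, semi[20], tampered[20], "tamper")]
        with pytest.raises(AuditError, match="locked"):
            verify_result(semi, result, spec, constraints)

    def test_change_count_must_equal_hamming_distance(self):
        seq, orf_span = build_orf_fixture(17)
        spec = OptimizationSpec(orf_regions=(orf_span,))
        semi, constraints, result = _run_pipeline(seq, spec)
        result.changes = result.changes[:-1]
        with pytest.raises(AuditError, match="Hamming"):
            verify_result(semi, result, spec, constraints)
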