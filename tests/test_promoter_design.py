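"""Upstream mining, candidate assessment, host exclusion, UP elements and
chimera combinatorics."""
import numpy as np
import pandas as pd
import pytest

from ecfkit._seq import random_dna, revcomp
from ecfkit.errors import ValidationError
from ecfkit.motif_model import scan_promoter, score_block
from ecfkit.promoter_design import (
    SpecificityClasses,
    apply_up_element,
    assess_candidates,
    build_chimeric_promoter,
    default_host_models,
    enumerate_chimeras,
    extract_upstream,
    host_exclusion_screen,
    sigma70_model,
)
from ecfkit.roster_io import PromoterRecord
from ecfkit.synthetic_data import (
    MotifSpec,
    gen_subgroup_promoters,
    gen_toy_genome,
    model_from_motif_spec,
)


# ---------------------------------------------------------------------------
# Upstream extraction


class TestExtractUpstream:
    def test_walks_operon_to_head_and_contains_planted_promoter(self):
        toy = gen_toy_genome(10, intergenic_gap=30, seed=21)
        second = [p for p in toy.planted if p.sigma_gene_id != p.operon_head_id]
        assert second, "fixture must include a sigma as second operon gene"
        for planted in second:
            region = extract_upstream(
                toy.genome, toy.annotation, planted.sigma_gene_id, max_len=300, operon_gap=50
            )
            assert region.operon_members[0] == planted.operon_head_id
            # region covers -60..-1 of the planted window (the +1..+20 part
            # of the window is the start of the head gene itself)
            assert planted.promoter_seq[:60] in region.region

    def test_gap_wider_than_threshold_stops_the_walk(self):
        toy = gen_toy_genome(10, intergenic_gap=30, seed=21)
        second = [p for p in toy.planted if p.sigma_gene_id != p.operon_head_id][0]
        region = extract_upstream(
            toy.genome, toy.annotation, second.sigma_gene_id, max_len=300, operon_gap=10
        )
        assert region.operon_members == [second.sigma_gene_id]

    def test_genome_edge_truncates(self):
        genome = "ACGTACGTAC" + "ATG" * 200
        ann = pd.DataFrame(
            [{"gene_id": "g1", "start": 11, "end": 400, "strand": "+", "contig": "c"}]
        )
        region = extract_upstream(genome, ann, "g1", max_len=300)
        assert region.truncated
        assert region.length == 10

    def test_minus_strand_region_is_reverse_complement(self):
        genome = random_dna(np.random.default_rng(0), 500)
        ann = pd.DataFrame(
            [{"gene_id": "g1", "start": 101, "end": 300, "strand": "-", "contig": "c"}]
        )
        region = extract_upstream(genome, ann, "g1", max_len=100)
        assert region.region == revcomp(genome[300:400])

    def test_absent_gene_rejected(self):
        toy = gen_toy_genome(2, seed=0)
        with pytest.raises(ValidationError):
            extract_upstream(toy.genome, toy.annotation, "nope")


# ---------------------------------------------------------------------------
# Candidate assessment


class TestAssessCandidates:
    def test_planted_promoters_classified_to_cognate_model(self, separated_specs):
        spec_a, spec_b = separated_specs
        proms = gen_subgroup_promoters(spec_a, 20, seed=1, subgroup=1) + gen_subgroup_promoters(
            spec_b, 20, seed=2, subgroup=2
        )
        models = [
            model_from_motif_spec(spec_a, subgroup=1),
            model_from_motif_spec(spec_b, subgroup=2),
        ]
        cognate = {p.id: 1 if p.id.startswith("P_01") else 2 for p in proms}
        out = assess_candidates(proms, models, cognate)
        correct = sum(1 for c in out if c.margin > 0)
        assert correct >= 38

    def test_single_model_margin_is_infinite(self, two_block_spec):
        prom = gen_subgroup_promoters(two_block_spec, 1, seed=0)[0]
        model = model_from_motif_spec(two_block_spec)
        (c,) = assess_candidates([prom], [model], {prom.id: 1})
        assert c.best_offtarget_score == float("-inf")
        assert c.margin == float("inf")

    def test_promoter_equal_to_noncognate_consensus_points_at_that_model(self, separated_specs):
        spec_a, spec_b = separated_specs
        exact_b = MotifSpec(
            consensus35=spec_b.consensus35,
            consensus10=spec_b.consensus10,
            per_position_mutation_rate=0.0,
            spacer_distribution={17: 1.0},
        )
        prom = gen_subgroup_promoters(exact_b, 1, seed=0, subgroup=1)[0]
        models = [
            model_from_motif_spec(spec_a, subgroup=1),
            model_from_motif_spec(spec_b, subgroup=2),
        ]
        (c,) = assess_candidates([prom], models, {prom.id: 1})
        assert c.offtarget_model == 2
        assert c.margin < 0

    def test_ranking_invariant_to_input_order(self, separated_specs):
        spec_a, spec_b = separated_specs
        proms = gen_subgroup_promoters(spec_a, 6, seed=3, subgroup=1) + gen_subgroup_promoters(
            spec_b, 6, seed=4, subgroup=2
        )
        models = [
            model_from_motif_spec(spec_a, subgroup=1),
            model_from_motif_spec(spec_b, subgroup=2),
        ]
        cognate = {p.id: 1 if p.id.startswith("P_01") else 2 for p in proms}
        fwd = assess_candidates(proms, models, cognate)
        rev = assess_candidates(proms[::-1], models, cognate)
        assert [c.promoter.id for c in fwd] == [c.promoter.id for c in rev]

    def test_missing_model_rejected(self, two_block_spec):
        prom = gen_subgroup_promoters(two_block_spec, 1, seed=0)[0]
        with pytest.raises(ValidationError):
            assess_candidates([prom], [], {prom.id: 9})


# ---------------------------------------------------------------------------
# Host exclusion


class TestHostExclusion:
    def test_host_consensus_at_modal_spacing_is_flagged(self):
        host = sigma70_model()
        seq = (
            random_dna(np.random.default_rng(1), 25)
            + "TTGACA" + "A" * 17 + "TATAAT"
            + random_dna(np.random.default_rng(2), 21)
        )
        rec = PromoterRecord("P_01_1001", seq)
        assert host_exclusion_screen(rec, [host])

    def test_random_background_rarely_flagged(self):
        rng = np.random.default_rng(7)
        models = default_host_models()
        flagged = sum(
            host_exclusion_screen(PromoterRecord("P_01_1001", random_dna(rng, 80)), models)
            for _ in range(100)
        )
        assert flagged <= 5

    def test_infinite_cutoff_never_flags(self):
        rec = PromoterRecord("P_01_1001", "TTGACA" + "A" * 17 + "TATAAT" + "G" * 51)
        assert not host_exclusion_screen(rec, default_host_models(), cutoff=float("inf"))


# ---------------------------------------------------------------------------
# UP element


class TestApplyUpElement:
    def test_rename_follows_convention(self):
        rec = PromoterRecord("P_15_436", "ACGT" * 20)
        assert apply_up_element(rec).id == "P_15_UP436"

    def test_length_preserved_and_suffix_untouched(self):
        rec = PromoterRecord("P_15_436", "ACGT" * 20)
        out = apply_up_element(rec)
        assert len(out.sequence) == 80
        assert out.sequence[25:] == rec.sequence[25:]
        assert out.up_modified

    def test_wrong_length_up_element_rejected(self):
        rec = PromoterRecord("P_15_436", "ACGT" * 20)
        with pytest.raises(ValidationError):
            apply_up_element(rec, "AT" * 5)


# ---------------------------------------------------------------------------
# Chimeras


class TestEnumerateChimeras:
    def test_sixteen_by_ten_gives_160(self):
        classes = SpecificityClasses(
            classes35={i: f"c35_{i % 16}" for i in range(1, 44)},
            classes10={i: f"c10_{i % 10}" for i in range(1, 44)},
        )
        count, combos, _ = enumerate_chimeras(classes)
        assert count == 160
        assert len(combos) == 160

    def test_single_class_pair(self):
        classes = SpecificityClasses(classes35={1: "a"}, classes10={1: "x"})
        count, combos, novel = enumerate_chimeras(classes)
        assert count == 1
        assert novel == []

    def test_three_by_four_with_five_natural(self):
        c35 = {1: "a", 2: "b", 3: "c", 4: "a", 5: "b"}
        c10 = {1: "w", 2: "x", 3: "y", 4: "z", 5: "w"}
        # natural combos: (a,w) (b,x) (c,y) (a,z) (b,w) -> 5 distinct
        count, combos, novel = enumerate_chimeras(
            SpecificityClasses(classes35=c35, classes10=c10)
        )
        assert count == 12
        assert len(novel) == 7


class TestBuildChimericPromoter:
    @pytest.fixture
    def donors(self, separated_specs):
        spec_a, spec_b = separated_specs
        return (
            model_from_motif_spec(spec_a, subgroup=2),
            model_from_motif_spec(spec_b, subgroup=11),
        )

    @pytest.fixture
    def context(self, two_block_spec):
        return gen_subgroup_promoters(two_block_spec, 1, seed=5)[0]

    def test_self_chimera_installs_own_consensus(self, donors, context):
        a, _ = donors
        out = build_chimeric_promoter(a, a, a.spacer.modal_length, context)
        hit = scan_promoter(a, out.sequence)
        assert hit.total == pytest.approx(a.consensus_score())
        assert hit.spacer_penalty == 0.0

    def test_chimeric_model_scores_at_least_parent_minus_weak_block(self, donors, context):
        from dataclasses import replace as dc_replace

        a, b = donors
        spacer = a.spacer.modal_length
        out = build_chimeric_promoter(a, b, spacer, context)
        chimera_model = dc_replace(b, pwm35=a.pwm35, spacer=a.spacer)
        chimera_score = scan_promoter(chimera_model, out.sequence).total
        # the chimera carries A's -35 and B's -10 consensus: the chimeric
        # model must reach both blocks' consensus scores
        assert chimera_score == pytest.approx(a.pwm35.max_score + b.pwm10.max_score)
        parent_a = scan_promoter(a, out.sequence).total
        parent_b = scan_promoter(b, out.sequence).total
        assert chimera_score >= parent_a - 1e-9
        assert chimera_score >= parent_b - 1e-9

    def test_downstream_of_minus10_unchanged(self, donors, context):
        a, b = donors
        out = build_chimeric_promoter(a, b, a.spacer.modal_length, context)
        end10 = context.position_to_index(-7) + 1
        assert out.sequence[end10:] == context.sequence[end10:]

    def test_infeasible_spacer_rejected(self, donors, context):
        a, b = donors
        with pytest.raises(ValidationError):
            build_chimeric_promoter(a, b, 3, context)


# ---------------------------------------------------------------------------
# Combinatorial orthogonality


class TestCombinatorialOrthogonality:
    def test_bipartite_margin_exceeds_single_block_margins(self):
        """Two subgroups sharing a -35 block but differing in -10 and spacer:
        the full-model margin strictly exceeds both single-block margins."""
        shared35 = "GGAACTT"
        spec_a = MotifSpec(
            consensus35=shared35, consensus10="GTCTGA",
            per_position_mutation_rate=0.0, spacer_distribution={15: 1.0},
        )
        spec_b = MotifSpec(
            consensus35=shared35, consensus10="CAGAGT",
            per_position_mutation_rate=0.0, spacer_distribution={18: 1.0},
        )
        model_a = model_from_motif_spec(spec_a, subgroup=1)
        model_b = model_from_motif_spec(spec_b, subgroup=2)
        prom = gen_subgroup_promoters(spec_a, 1, seed=0)[0]

        full_margin = (
            scan_promoter(model_a, prom.sequence).total
            - scan_promoter(model_b, prom.sequence).total
        )
        # single-block margins: best -35-only and best -10-only scores
        def best_block(pwm, seq):
            return max(
                score_block(pwm, seq[i : i + pwm.width])
                for i in range(len(seq) - pwm.width + 1)
            )

        margin35 = best_block(model_a.pwm35, prom.sequence) - best_block(
            model_b.pwm35, prom.sequence
        )
        margin10 = best_block(model_a.pwm10, prom.sequence) - best_block(
            model_b.pwm10, prom.sequence
        )
        assert full_margin > margin35 + 1e-9
        assert full_margin > margin10 + 1e-9
        assert margin35 == pytest.approx(0.0, abs=1e-9)  # shared block alone: no margin
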