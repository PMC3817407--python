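"""Bipartite promoter model: PWM arithmetic, spacer penalties, scanning
against an exhaustive oracle, and Gibbs discovery of planted motifs."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ecfkit._seq import random_dna
from ecfkit.errors import ValidationError
from ecfkit.motif_model import (
    PWM,
    PromoterModel,
    SpacerModel,
    build_pwm,
    discover_two_block,
    information_content,
    scan_promoter,
    score_block,
    spacer_penalty,
)
from ecfkit.synthetic_data import MotifSpec, gen_subgroup_promoters, model_from_motif_spec

DNA = st.text(alphabet="ACGT", min_size=1)


# ---------------------------------------------------------------------------
# PWM construction and scoring


class TestBuildPwm:
    def test_column_matching_background_has_zero_logodds(self):
        pwm = build_pwm(["A", "C", "G", "T"], pseudocount=0.0)
        assert np.allclose(pwm.logodds, 0.0)

    def test_hand_computed_probabilities_and_logodds(self):
        # 4 sites, pseudocount 1, uniform background:
        # column 2 has A three times -> p = (3 + 0.25) / 5 = 0.65
        pwm = build_pwm(["TGA", "TGA", "TGA", "TGC"], pseudocount=1.0)
        assert pwm.probs[2, 0] == pytest.approx(0.65)
        assert pwm.logodds[2, 0] == pytest.approx(np.log2(0.65 / 0.25), abs=1e-9)
        assert pwm.logodds[2, 0] == pytest.approx(1.379, abs=1e-3)

    def test_unequal_site_lengths_rejected(self):
        with pytest.raises(ValidationError):
            build_pwm(["ACG", "ACGT"])

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValidationError):
            build_pwm([])

    def test_pseudocount_keeps_probabilities_interior(self):
        pwm = build_pwm(["AAAA"] * 50, pseudocount=1.0)
        assert (pwm.probs > 0).all() and (pwm.probs < 1).all()
        assert np.isfinite(pwm.logodds).all()


class TestScoreBlock:
    @pytest.fixture
    def pwm(self):
        return build_pwm(["TGA", "TGA", "TGA", "TGC"], pseudocount=1.0)

    def test_independent_column_sum_oracle(self, pwm):
        expected = sum(pwm.logodds[i, "ACGT".index(b)] for i, b in enumerate("TGA"))
        assert score_block(pwm, "TGA") == pytest.approx(expected, abs=1e-12)

    def test_consensus_is_maximal(self, pwm, rng):
        consensus_score = score_block(pwm, pwm.consensus)
        assert consensus_score == pytest.approx(pwm.max_score)
        for _ in range(200):
            assert score_block(pwm, random_dna(rng, 3)) <= consensus_score + 1e-12

    def test_length_mismatch_and_ambiguity_rejected(self, pwm):
        with pytest.raises(ValidationError):
            score_block(pwm, "TG")
        with pytest.raises(ValidationError):
            score_block(pwm, "TGN")


class TestInformationContent:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.0),
            ([1.0, 0.0, 0.0, 0.0], 2.0),
            ([0.5, 0.5, 0.0, 0.0], 1.0),
        ],
    )
    def test_closed_form_columns(self, column, expected):
        pwm = PWM(probs=np.array([column]))
        per_pos, total = information_content(pwm)
        assert per_pos[0] == pytest.approx(expected, abs=1e-12)
        assert total == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Spacer penalty


class TestSpacerPenalty:
    def test_modal_length_has_zero_penalty(self):
        model = SpacerModel(counts={16: 10, 17: 5}, pseudocount=1.0, support=(15, 18))
        assert model.penalty(16) == 0.0

    def test_hand_computed_penalty(self):
        model = SpacerModel(counts={16: 10, 17: 5}, pseudocount=1.0, support=(15, 18))
        assert spacer_penalty(model, 17) == pytest.approx(np.log2(6 / 11), abs=1e-12)
        assert spacer_penalty(model, 17) == pytest.approx(-0.874, abs=1e-3)

    def test_outside_support_is_minus_infinity(self):
        model = SpacerModel(counts={16: 10, 17: 5}, pseudocount=1.0, support=(15, 18))
        assert spacer_penalty(model, 14) == float("-inf")

    def test_penalty_nonpositive_over_support(self):
        model = SpacerModel(counts={15: 2, 16: 9, 18: 1}, pseudocount=0.5, support=(14, 19))
        for L in range(14, 20):
            assert model.penalty(L) <= 0.0


# ---------------------------------------------------------------------------
# Scanning


def brute_force_scan(model: PromoterModel, seq: str):
    """Exhaustive placement enumeration, independent of the scanner."""
    w35, w10 = model.pwm35.width, model.pwm10.width
    lo, hi = model.spacer.support
    best = None
    for start35 in range(0, len(seq) - w35 + 1):
        for spacer in range(lo, hi + 1):
            start10 = start35 + w35 + spacer
            if start10 + w10 > len(seq):
                continue
            total = (
                score_block(model.pwm35, seq[start35 : start35 + w35])
                + score_block(model.pwm10, seq[start10 : start10 + w10])
                + model.spacer.penalty(spacer)
            )
            # ascending (start35, spacer) iteration: keep the incumbent on
            # numerical ties, matching the scanner's documented tie-break
            if best is None or total > best[2] + 1e-9:
                best = (start35, spacer, total)
    return best


@pytest.fixture
def planted_model(two_block_spec):
    return model_from_motif_spec(two_block_spec)


class TestScanPromoter:
    def test_matches_exhaustive_oracle_on_random_sequences(self, planted_model, rng):
        for _ in range(50):
            seq = random_dna(rng, 110)
            hit = scan_promoter(planted_model, seq)
            o, sp, total = brute_force_scan(planted_model, seq)
            assert (hit.start35, hit.spacer_length) == (o, sp)
            assert hit.total == pytest.approx(total, abs=1e-9)

    def test_recovers_planted_consensus_placement(self, two_block_spec, planted_model):
        spec = MotifSpec(
            consensus35=two_block_spec.consensus35,
            consensus10=two_block_spec.consensus10,
            per_position_mutation_rate=0.0,
            spacer_distribution={16: 1.0},
        )
        for seed in range(20):
            rec = gen_subgroup_promoters(spec, 1, seed=seed)[0]
            hit = scan_promoter(planted_model, rec.sequence)
            # -10 anchored at window position -7 (index 53), spacer 16
            assert hit.start10 == 53 - 6
            assert hit.spacer_length == 16
            assert hit.spacer_penalty == 0.0
            assert hit.total == pytest.approx(
                planted_model.pwm35.max_score + planted_model.pwm10.max_score
            )

    def test_total_decomposes_into_terms(self, planted_model, rng):
        hit = scan_promoter(planted_model, random_dna(rng, 90))
        assert hit.total == pytest.approx(
            hit.score35 + hit.score10 + hit.spacer_penalty + hit.up_term
        )
        assert hit.start10 == hit.start35 + planted_model.pwm35.width + hit.spacer_length

    def test_flanking_sequence_never_decreases_best_score(self, planted_model, rng):
        for _ in range(20):
            core = random_dna(rng, 80)
            flanked = random_dna(rng, 15) + core + random_dna(rng, 15)
            assert (
                scan_promoter(planted_model, flanked).total
                >= scan_promoter(planted_model, core).total - 1e-9
            )

    def test_too_short_sequence_rejected(self, planted_model):
        with pytest.raises(ValidationError):
            scan_promoter(planted_model, "ACGT" * 6)


# ---------------------------------------------------------------------------
# Gibbs discovery


def consensus_recovery(model, spec):
    hits = sum(
        a == b for a, b in zip(model.pwm35.consensus, spec.consensus35)
    ) + sum(a == b for a, b in zip(model.pwm10.consensus, spec.consensus10))
    return hits / (len(spec.consensus35) + len(spec.consensus10))


def discover_from_spec(spec, seed, n=30, **kw):
    recs = gen_subgroup_promoters(spec, n, seed=seed)
    return discover_two_block(
        [r.sequence for r in recs], len(spec.consensus35), len(spec.consensus10),
        (13, 18), seed=seed, **kw
    )


class TestDiscoverTwoBlock:
    def test_recovers_planted_motif(self, two_block_spec):
        passes = 0
        for seed in range(3):
            model = discover_from_spec(two_block_spec, seed)
            passes += consensus_recovery(model, two_block_spec) >= 0.9
        assert passes >= 2

    def test_planted_data_beats_pure_background(self, two_block_spec, rng):
        wins = 0
        for seed in range(3):
            _, det_planted = discover_from_spec(
                two_block_spec, seed, return_details=True
            )
            null_seqs = [random_dna(rng, 80) for _ in range(30)]
            _, det_null = discover_two_block(
                null_seqs, 7, 6, (13, 18), seed=seed, return_details=True
            )
            wins += det_planted.ic_final > det_null.ic_final
        assert wins == 3

    def test_greedy_finalization_never_loses_information(self, two_block_spec):
        _, det = discover_from_spec(two_block_spec, seed=5, return_details=True)
        assert det.ic_after_finalize >= det.ic_after_sampling - 1e-9
        assert det.ic_final >= det.ic_after_finalize - 1e-9

    def test_deterministic_for_fixed_seed(self, two_block_spec):
        m1 = discover_from_spec(two_block_spec, seed=3, n_restarts=2, iters=40)
        m2 = discover_from_spec(two_block_spec, seed=3, n_restarts=2, iters=40)
        assert np.allclose(m1.pwm35.probs, m2.pwm35.probs)
        assert m1.spacer.counts == m2.spacer.counts

    def test_recovery_degrades_with_mutation_rate(self, two_block_spec):
        rates = [0.0, 0.15, 0.3]
        means = []
        for rate in rates:
            spec = MotifSpec(
                consensus35=two_block_spec.consensus35,
                consensus10=two_block_spec.consensus10,
                per_position_mutation_rate=rate,
                spacer_distribution=two_block_spec.spacer_distribution,
            )
            recov = [
                consensus_recovery(
                    discover_from_spec(spec, seed, n=20, n_restarts=3, iters=80), spec
                )
                for seed in range(3)
            ]
            means.append(np.mean(recov))
        assert means[0] >= means[-1]
        assert stats.spearmanr(rates, means).statistic <= 0

    def test_inverted_spacer_range_rejected(self, two_block_spec):
        recs = gen_subgroup_promoters(two_block_spec, 6, seed=0)
        with pytest.raises(ValidationError):
            discover_two_block([r.sequence for r in recs], 7, 6, (18, 13))

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValidationError):
            discover_two_block(["ACGT" * 20] * 4, 7, 6, (13, 18))
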