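"""Posttest log-odds aggregation, overrides, and ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syncopedx import (
    AnswerSet,
    AnswerValue,
    Etiology,
    LhrPair,
    compute_differential,
    log_odds_from_probability,
    posttest_log_odds,
    posttest_log_odds_beta,
    probability_from_log_odds,
)

from conftest import answers_of, odds_product_oracle, random_answers, random_engine_kb


class TestLogOddsAggregation:
    def test_empty_answers_return_pretest_log_odds(self, kb):
        lo = posttest_log_odds(0.345, AnswerSet(), kb, Etiology.VASOVAGAL)
        assert lo == pytest.approx(math.log(0.345 / 0.655), abs=1e-12)

    @pytest.mark.parametrize(
        "value, expected_probability",
        [(AnswerValue.YES, 0.7970), (AnswerValue.NO, 0.1391)],
    )
    def test_single_age_answer_matches_hand_product(self, kb, value, expected_probability):
        # hand oracle: (0.35/0.65) * LHR -> odds/(1+odds)
        answers = AnswerSet({"age_le_35": value})
        lo = posttest_log_odds(0.35, answers, kb, Etiology.VASOVAGAL)
        p = probability_from_log_odds(lo)
        assert p == pytest.approx(expected_probability, abs=5e-5)
        assert p == pytest.approx(
            odds_product_oracle(0.35, answers, kb, Etiology.VASOVAGAL), rel=1e-12
        )

    def test_unknown_and_absent_cells_are_neutral(self, kb):
        baseline = posttest_log_odds(0.3, AnswerSet(), kb, Etiology.VASOVAGAL)
        neutral = answers_of(
            unknown=["age_le_35"],  # unknown answer
            yes=["qtc_prolonged"],  # cell absent for vasovagal
        )
        assert posttest_log_odds(0.3, neutral, kb, Etiology.VASOVAGAL) == baseline

    @pytest.mark.parametrize("prior", [0.0, 1.0, -0.2, 1.5])
    def test_prior_outside_open_interval_rejected(self, kb, prior):
        with pytest.raises(ValueError, match="prior"):
            posttest_log_odds(prior, AnswerSet(), kb, Etiology.VASOVAGAL)

    def test_unknown_question_id_raises_key_error(self, kb):
        with pytest.raises(KeyError, match="no_such_question"):
            posttest_log_odds(
                0.3, AnswerSet({"no_such_question": AnswerValue.YES}), kb,
                Etiology.VASOVAGAL,
            )

    def test_beta_parameterization_identical(self):
        # the regression form beta0' + sum(beta_i x_i) must agree with the
        # sequential-LHR form on random KBs and answer sets
        rng = np.random.default_rng(1234)
        for _ in range(200):
            kb = random_engine_kb(rng)
            answers = random_answers(rng, kb)
            prior = float(rng.uniform(0.02, 0.95))
            for etiology in Etiology:
                a = posttest_log_odds(prior, answers, kb, etiology)
                b = posttest_log_odds_beta(prior, answers, kb, etiology)
                assert b == pytest.approx(a, abs=1e-10)


class TestProbabilityTransform:
    @pytest.mark.parametrize(
        "log_odds, expected",
        [
            (0.0, 0.5),
            (math.log(3.9254), 3.9254 / 4.9254),
            (math.log(0.345 / 0.655), 0.345),
        ],
    )
    def test_known_points(self, log_odds, expected):
        assert probability_from_log_odds(log_odds) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [math.inf, -math.inf, math.nan])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            probability_from_log_odds(bad)

    # beyond |logit| ~ 15 the probability saturates in double precision
    # and the inverse is no longer numerically meaningful
    @given(st.floats(min_value=-15, max_value=15))
    @settings(derandomize=True)
    def test_strictly_increasing_and_inverts_logit(self, log_odds):
        p = probability_from_log_odds(log_odds)
        assert 0.0 < p < 1.0
        assert probability_from_log_odds(log_odds + 1e-3) > p
        assert log_odds_from_probability(p) == pytest.approx(log_odds, abs=1e-8)


class TestEngineProperties:
    def test_oracle_equivalence_random_trials(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            kb = random_engine_kb(rng)
            answers = random_answers(rng, kb)
            for etiology in Etiology:
                prior = kb.priors[etiology]
                p = probability_from_log_odds(
                    posttest_log_odds(prior, answers, kb, etiology)
                )
                assert p == pytest.approx(
                    odds_product_oracle(prior, answers, kb, etiology), rel=1e-10
                )

    def test_all_unknown_recovers_priors(self, kb):
        answers = answers_of(unknown=[q.id for q in kb.questions])
        differential = compute_differential(answers, kb)
        for posterior in differential:
            assert posterior.probability == pytest.approx(
                kb.priors[posterior.etiology], abs=1e-12
            )
        # ranking then equals descending prior order
        assert [p.etiology for p in differential] == [
            Etiology.VASOVAGAL,
            Etiology.CARDIOGENIC,
            Etiology.ORTHOSTATIC,
            Etiology.NEUROGENIC_LOC,
        ]

    @pytest.mark.parametrize("qid, etiology", [
        ("age_le_35", Etiology.VASOVAGAL),       # LHR+ 7.29 > LHR- 0.30
        ("heart_disease_history", Etiology.CARDIOGENIC),
    ])
    def test_monotone_increasing_cell(self, kb, qid, etiology):
        prior = kb.priors[etiology]
        p_no = probability_from_log_odds(
            posttest_log_odds(prior, answers_of(no=[qid]), kb, etiology))
        p_yes = probability_from_log_odds(
            posttest_log_odds(prior, answers_of(yes=[qid]), kb, etiology))
        assert p_yes > p_no

    def test_monotone_decreasing_cell(self, kb):
        # vasovagal heart-disease cell has LHR+ 0.072 < LHR- 1.82
        prior = kb.priors[Etiology.VASOVAGAL]
        p_no = probability_from_log_odds(posttest_log_odds(
            prior, answers_of(no=["heart_disease_history"]), kb, Etiology.VASOVAGAL))
        p_yes = probability_from_log_odds(posttest_log_odds(
            prior, answers_of(yes=["heart_disease_history"]), kb, Etiology.VASOVAGAL))
        assert p_yes < p_no

    @given(prior=st.floats(min_value=0.01, max_value=0.99))
    @settings(derandomize=True)
    def test_neutral_cell_leaves_posterior_unchanged(self, prior):
        rng = np.random.default_rng(5)
        kb = random_engine_kb(rng, n_questions=3)
        kb.questions[0].lhr[Etiology.CARDIOGENIC] = LhrPair(1.0, 1.0)
        for value in (AnswerValue.YES, AnswerValue.NO):
            lo = posttest_log_odds(
                prior, AnswerSet({kb.questions[0].id: value}), kb,
                Etiology.CARDIOGENIC,
            )
            assert lo == pytest.approx(
                log_odds_from_probability(prior), abs=1e-12
            )

    def test_answer_iteration_order_irrelevant(self, kb):
        yes = ["age_le_35", "trigger_context", "nausea_warmth"]
        no = ["heart_disease_history", "hypoxia"]
        forward = answers_of(yes=yes, no=no)
        shuffled = AnswerSet(dict(reversed(list(forward.answers.items()))))
        for etiology in Etiology:
            a = posttest_log_odds(0.3, forward, kb, etiology)
            b = posttest_log_odds(0.3, shuffled, kb, etiology)
            assert b == pytest.approx(a, abs=1e-12)

    def test_probabilities_never_renormalized(self, kb):
        # four independent binary models: each ranked probability must equal
        # its own single-model computation, and their sum is free to differ
        # from 1
        answers = answers_of(yes=["age_le_35", "trigger_context"])
        differential = compute_differential(answers, kb)
        for posterior in differential:
            standalone = probability_from_log_odds(posttest_log_odds(
                kb.priors[posterior.etiology], answers, kb, posterior.etiology))
            assert posterior.probability == standalone
        assert sum(p.probability for p in differential) != pytest.approx(1.0, abs=1e-3)


class TestOverrides:
    def test_both_orthostatic_questions_promote(self, kb):
        # strong cardiogenic evidence, yet a unanimous orthostatic answer
        # pair must head the differential
        answers = answers_of(
            yes=["orthostatic_vitals", "orthostasis_suspected",
                 "heart_disease_history", "chest_pain", "exertion"],
        )
        differential = compute_differential(answers, kb)
        assert differential.app_top is Etiology.ORTHOSTATIC
        top = differential[0]
        assert top.overridden
        # probability untouched: still the prior (no LHR cells for orthostatic)
        assert top.probability == pytest.approx(kb.priors[Etiology.ORTHOSTATIC])

    def test_single_orthostatic_yes_does_not_promote(self, kb):
        answers = answers_of(yes=["orthostatic_vitals"],
                             no=["orthostasis_suspected"])
        differential = compute_differential(answers, kb)
        assert not differential.posterior(Etiology.ORTHOSTATIC).overridden
        assert differential.app_top is Etiology.VASOVAGAL  # highest prior

    def test_neurogenic_pair_promotes_with_flag(self, kb):
        answers = answers_of(yes=["neuro_symptoms", "focal_neuro_exam"])
        differential = compute_differential(answers, kb)
        assert differential.app_top is Etiology.NEUROGENIC_LOC
        assert differential[0].overridden

    def test_neurogenic_precedes_orthostatic_when_both_fire(self, kb):
        answers = answers_of(
            yes=["neuro_symptoms", "focal_neuro_exam",
                 "orthostatic_vitals", "orthostasis_suspected"],
        )
        differential = compute_differential(answers, kb)
        assert [p.etiology for p in differential[:2]] == [
            Etiology.NEUROGENIC_LOC, Etiology.ORTHOSTATIC
        ]
        assert differential[0].overridden and differential[1].overridden

    def test_no_override_is_pure_probability_order(self, kb):
        answers = answers_of(yes=["heart_disease_history", "chest_pain",
                                  "exertion"],
                             no=["trigger_context", "nausea_warmth"])
        differential = compute_differential(answers, kb)
        assert differential.app_top is Etiology.CARDIOGENIC
        probs = [p.probability for p in differential]
        assert probs == sorted(probs, reverse=True)
        assert not any(p.overridden for p in differential)
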