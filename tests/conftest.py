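"""Shared fixtures: the default KB, frozen table expectations, and the
independent brute-force odds-product oracle."""

from __future__ import annotations

import numpy as np
import pytest

from syncopedx import (
    DIAGNOSIS_CARDIAC,
    DIAGNOSIS_VASOVAGAL,
    AnswerSet,
    AnswerValue,
    CssConfig,
    CssItemDef,
    Etiology,
    KnowledgeBase,
    LhrPair,
    PriorSet,
    QuestionDef,
    RecommendationTexts,
    RiskClass,
    load_knowledge_base,
)

# Frozen expectation of every published LHR cell, keyed by question id:
# (vasovagal LHR+, LHR-), (cardiogenic LHR+, LHR-); None = absent cell.
EXPECTED_LHR_CELLS: dict[str, tuple[tuple[float, float] | None, tuple[float, float] | None]] = {
    "age_le_35": ((7.29, 0.30), (0.13, 3.24)),
    "heart_disease_history": ((0.072, 1.82), (2.93, 0.74)),
    "trigger_context": ((8.85, 0.498), (0.167, 1.43)),
    "chest_pain": (None, (4.25, 0.881)),
    "palpitations": (None, (3.78, 0.853)),
    "exertion": (None, (4.36, 0.896)),
    "position_change": (None, None),
    "hypoxia": ((0.104, 1.08), (3.74, 0.94)),
    "nausea_warmth": ((5.10, 0.552), (0.354, 1.38)),
    "neuro_symptoms": (None, (0.170, 1.21)),
    "convulsions": (None, None),
    "new_murmur": (None, None),
    "abnormal_sbp": (None, (5.88, 0.894)),
    "orthostatic_vitals": (None, None),
    "orthostasis_suspected": (None, None),
    "focal_neuro_exam": (None, None),
    "qrs_axis_abnormal": (None, None),
    "qrs_prolonged": (None, None),
    "qtc_prolonged": (None, None),
    "troponin_elevated": (None, (1.98, 0.534)),
}

EXPECTED_FLAGS = {
    "css_input": {
        "heart_disease_history",
        "trigger_context",
        "abnormal_sbp",
        "qrs_axis_abnormal",
        "qrs_prolonged",
        "qtc_prolonged",
        "troponin_elevated",
    },
    "prompt_only": {"position_change", "convulsions", "new_murmur"},
    "override_orthostatic": {"orthostatic_vitals", "orthostasis_suspected"},
    "override_neurogenic": {"neuro_symptoms", "focal_neuro_exam"},
}


@pytest.fixture(scope="session")
def kb() -> KnowledgeBase:
    return load_knowledge_base()


def answers_of(yes=(), no=(), unknown=(), user=None) -> AnswerSet:
    """Terse AnswerSet builder for tests."""
    mapping: dict[str, AnswerValue] = {}
    for qid in yes:
        mapping[qid] = AnswerValue.YES
    for qid in no:
        mapping[qid] = AnswerValue.NO
    for qid in unknown:
        mapping[qid] = AnswerValue.UNKNOWN
    return AnswerSet(answers=mapping, user_selected_ddx=user)


def odds_product_oracle(
    prior: float, answers: AnswerSet, kb: KnowledgeBase, etiology: Etiology
) -> float:
    """Independent oracle: sequential pretest-odds x prod(LHR) on the
    probability scale, iterating the raw answer map (not KB order)."""
    odds = prior / (1.0 - prior)
    for qid, value in answers.answers.items():
        if value is AnswerValue.UNKNOWN:
            continue
        pair = kb.question(qid).lhr.get(etiology)
        if pair is None:
            continue
        odds *= pair.lhr_pos if value is AnswerValue.YES else pair.lhr_neg
    return odds / (1.0 + odds)


def random_engine_kb(rng: np.random.Generator, n_questions: int = 8) -> KnowledgeBase:
    """A structurally minimal random KB for engine property tests."""
    questions = []
    for i in range(n_questions):
        lhr = {}
        for etiology in Etiology:
            if rng.random() < 0.6:
                lhr[etiology] = LhrPair(
                    float(rng.uniform(0.05, 12.0)), float(rng.uniform(0.05, 12.0))
                )
        questions.append(QuestionDef(id=f"q{i}", text=f"question {i}?", lhr=lhr))
    priors = PriorSet(
        {e: float(rng.uniform(0.02, 0.9)) for e in Etiology}
    )
    css = CssConfig(
        items=(
            CssItemDef("diagnosis_vasovagal", DIAGNOSIS_VASOVAGAL, -2),
            CssItemDef("diagnosis_cardiac", DIAGNOSIS_CARDIAC, 2),
        ),
        low_below=1,
        high_above=3,
    )
    recs = RecommendationTexts(
        primary={e: f"primary {e.value}" for e in Etiology},
        secondary={
            (a, u): f"secondary {a.value}|{u.value}"
            for a in Etiology
            for u in Etiology
            if a is not u
        },
        question_specific={},
        disposition={r: f"disposition {r.value}" for r in RiskClass},
    )
    return KnowledgeBase(
        version="random-test",
        questions=questions,
        priors=priors,
        css=css,
        recommendations=recs,
    )


def random_answers(rng: np.random.Generator, kb: KnowledgeBase) -> AnswerSet:
    values = list(AnswerValue)
    return AnswerSet(
        answers={
            q.id: values[int(rng.integers(len(values)))]
            for q in kb.questions
            if rng.random() < 0.8
        }
    )
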