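"""Assemble the recommendation bundle: primary, secondary, question-specific,
and the risk-based disposition.

Primary recommendations follow the working diagnosis (user pick, else the
engine's top etiology). A secondary recommendation appears only when the
engine's top etiology is discordant with the clinician's selection, keyed
by the ordered pair (app, user). Question-specific recommendations fire
for an override-flagged etiology answered partially positive (at least
one but not all of its flagged questions yes — a full yes set promotes
the etiology instead) and for prompt-only questions answered yes.
Bundle assembly is a pure function of its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .ddx_engine import (
    AnswerSet,
    AnswerValue,
    Differential,
    compute_differential,
)
from .knowledge_base import Etiology, KnowledgeBase, RiskClass
from .risk_css import CssResult, compute_css, resolve_diagnosis

__all__ = [
    "RecommendationBundle",
    "Assessment",
    "build_recommendations",
    "disposition_for_risk",
    "assess_case",
]


@dataclass
class RecommendationBundle:
    primary_etiology: Etiology
    primary_text: str
    secondary_key: Optional[tuple[Etiology, Etiology]]  # (app_top, user)
    secondary_text: Optional[str]
    question_specific: list[tuple[str, str]]  # (question id, text)
    risk_class: RiskClass
    disposition_text: str

    def to_dict(self) -> dict:
        return {
            "primary": {
                "etiology": self.primary_etiology.value,
                "text": self.primary_text,
            },
            "secondary": (
                {
                    "app_top": self.secondary_key[0].value,
                    "user_selected": self.secondary_key[1].value,
                    "text": self.secondary_text,
                }
                if self.secondary_key is not None
                else None
            ),
            "question_specific": [
                {"question_id": qid, "text": text}
                for qid, text in self.question_specific
            ],
            "disposition": {
                "risk_class": self.risk_class.value,
                "text": self.disposition_text,
            },
        }


def disposition_for_risk(risk: RiskClass, kb: KnowledgeBase) -> str:
    """The configured disposition text for a risk class."""
    return kb.recommendations.disposition[risk]


def build_recommendations(
    differential: Differential,
    answers: AnswerSet,
    css: CssResult,
    kb: KnowledgeBase,
) -> RecommendationBundle:
    texts = kb.recommendations

    primary_etiology = css.diagnosis_used
    primary_text = texts.primary[primary_etiology]

    secondary_key = None
    secondary_text = None
    user = answers.user_selected_ddx
    if user is not None and differential.app_top is not user:
        secondary_key = (differential.app_top, user)
        secondary_text = texts.secondary[secondary_key]

    question_specific: list[tuple[str, str]] = []
    partial_ids: set[str] = set()
    for etiology in Etiology:
        flagged = kb.override_questions(etiology)
        if not flagged:
            continue
        yes = [q for q in flagged if answers.get(q.id) is AnswerValue.YES]
        if yes and len(yes) < len(flagged):
            partial_ids.update(q.id for q in yes)
    # emit in KB question order for stable output
    for q in kb.questions:
        fired = q.id in partial_ids or (
            q.prompt_only and answers.get(q.id) is AnswerValue.YES
        )
        if fired:
            question_specific.append((q.id, texts.question_specific[q.id]))

    return RecommendationBundle(
        primary_etiology=primary_etiology,
        primary_text=primary_text,
        secondary_key=secondary_key,
        secondary_text=secondary_text,
        question_specific=question_specific,
        risk_class=css.risk_class,
        disposition_text=disposition_for_risk(css.risk_class, kb),
    )


@dataclass
class Assessment:
    """One complete evaluation: differential, CSS, recommendations."""

    answers: AnswerSet
    differential: Differential
    css: CssResult
    recommendations: RecommendationBundle

    def to_dict(self) -> dict:
        return {
            "answers": self.answers.to_dict(),
            "differential": [
                {
                    "etiology": p.etiology.value,
                    "log_odds": p.log_odds,
                    "probability": p.probability,
                    "overridden": p.overridden,
                }
                for p in self.differential
            ],
            "app_top": self.differential.app_top.value,
            "css": self.css.to_dict(),
            "recommendations": self.recommendations.to_dict(),
        }


def assess_case(answers: AnswerSet, kb: KnowledgeBase) -> Assessment:
    """Run the full pipeline for one encounter."""
    differential = compute_differential(answers, kb)
    diagnosis, source = resolve_diagnosis(answers, differential)
    css = compute_css(answers, diagnosis, kb, diagnosis_source=source)
    bundle = build_recommendations(differential, answers, css, kb)
    return Assessment(
        answers=answers, differential=differential, css=css, recommendations=bundle
    )
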