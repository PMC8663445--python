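"""Canadian Syncope Score (CSS) tally and risk classification.

The CSS is an additive point score predicting serious adverse events
after syncope. Seven items are extracted from the assessment answers
(ECG findings, troponin, blood pressure, vasovagal predisposition,
cardiac history) and two are derived from the working diagnosis — the
clinician's selection when present, otherwise the engine's top-ranked
etiology. The total maps to low (<1), intermediate (1-3) or high (>3)
risk, which drives disposition.

Unknown answers leave an item untriggered (conservative toward fewer
points); the itemized output keeps the untriggered items visible so the
untallied evidence is apparent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .ddx_engine import AnswerSet, AnswerValue, Differential
from .knowledge_base import (
    DIAGNOSIS_CARDIAC,
    DIAGNOSIS_VASOVAGAL,
    Etiology,
    KnowledgeBase,
    RiskClass,
)

__all__ = [
    "DiagnosisSource",
    "CssItem",
    "CssResult",
    "CssConfigurationError",
    "resolve_diagnosis",
    "compute_css",
    "classify_risk",
]


class DiagnosisSource(str, Enum):
    USER = "user"
    APP = "app"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class CssConfigurationError(RuntimeError):
    """A CSS item references a question the knowledge base does not define."""


@dataclass(frozen=True)
class CssItem:
    name: str
    points: int
    triggered: bool
    source: str  # question id or diagnosis-derived marker


@dataclass
class CssResult:
    items: list[CssItem]
    total: int
    risk_class: RiskClass
    diagnosis_used: Etiology
    diagnosis_source: DiagnosisSource

    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "name": i.name,
                    "points": i.points,
                    "triggered": i.triggered,
                    "source": i.source,
                }
                for i in self.items
            ],
            "total": self.total,
            "risk_class": self.risk_class.value,
            "diagnosis_used": self.diagnosis_used.value,
            "diagnosis_source": self.diagnosis_source.value,
        }


def resolve_diagnosis(
    answers: AnswerSet, differential: Differential
) -> tuple[Etiology, DiagnosisSource]:
    """The clinician's pick when present, else the engine's top-ranked etiology."""
    if answers.user_selected_ddx is not None:
        return answers.user_selected_ddx, DiagnosisSource.USER
    return differential.app_top, DiagnosisSource.APP


def compute_css(
    answers: AnswerSet,
    diagnosis: Etiology,
    kb: KnowledgeBase,
    *,
    diagnosis_source: DiagnosisSource = DiagnosisSource.USER,
) -> CssResult:
    """Tally the configured CSS items against answers and diagnosis."""
    items: list[CssItem] = []
    for item in kb.css.items:
        if item.source == DIAGNOSIS_VASOVAGAL:
            triggered = diagnosis is Etiology.VASOVAGAL
        elif item.source == DIAGNOSIS_CARDIAC:
            triggered = diagnosis is Etiology.CARDIOGENIC
        else:
            if item.source not in kb:
                raise CssConfigurationError(
                    f"CSS item {item.name!r} references question "
                    f"{item.source!r}, which the knowledge base does not define"
                )
            triggered = answers.get(item.source) is AnswerValue.YES
        items.append(
            CssItem(
                name=item.name,
                points=item.points,
                triggered=triggered,
                source=item.source,
            )
        )
    total = sum(i.points for i in items if i.triggered)
    return CssResult(
        items=items,
        total=total,
        risk_class=classify_risk(total, kb),
        diagnosis_used=diagnosis,
        diagnosis_source=diagnosis_source,
    )


def classify_risk(total: int, kb: KnowledgeBase) -> RiskClass:
    """Map an integer total to low (< low_below) / intermediate / high (> high_above).

    With the default cut points this is the printed partition: low (<1),
    intermediate (1-3 inclusive), high (>3).
    """
    if total < kb.css.low_below:
        return RiskClass.LOW
    if total > kb.css.high_above:
        return RiskClass.HIGH
    return RiskClass.INTERMEDIATE
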