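"""Labeled synthetic case generation consistent with the configured LHRs.

No real patient data ship with the package; end-to-end behaviour is
exercised on synthetic answer vectors whose etiology-conditional
yes-rates follow from the knowledge base itself. For a question with an
*informative, orientation-consistent* likelihood-ratio pair
(LHR+ > 1 > LHR-), the pair inverts uniquely to a sensitivity and
specificity:

    specificity = (LHR+ - 1) / (LHR+ - LHR-)
    sensitivity = LHR+ * (1 - specificity)

A case with true etiology E answers such a question yes with probability
``sensitivity``. Cells that are absent or not invertible fall back to a
neutral yes-rate (default 0.2). Answers are conditionally independent
given the etiology — an explicit simplification; real findings are
correlated. Each answer is independently blanked to ``unknown`` with a
configurable rate to emulate partial data entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .ddx_engine import AnswerSet, AnswerValue
from .knowledge_base import Etiology, KnowledgeBase

__all__ = [
    "NEUTRAL_YES_RATE",
    "GeneratorConfig",
    "sens_spec_from_lhr",
    "generate_case",
    "generate_cohort",
]

#: Yes-rate for questions carrying no invertible evidence for the true etiology.
NEUTRAL_YES_RATE = 0.2


@dataclass
class GeneratorConfig:
    """Cohort generation settings.

    ``mix`` defaults to the KB priors renormalized to sum to 1;
    ``unknown_rate`` is the per-answer probability of being left
    unanswered.
    """

    seed: int
    n: int
    mix: Optional[Mapping[Etiology, float]] = None
    unknown_rate: float = 0.0
    neutral_yes_rate: float = NEUTRAL_YES_RATE

    def resolved_mix(self, kb: KnowledgeBase) -> dict[Etiology, float]:
        if self.mix is None:
            total = sum(p for _, p in kb.priors.items())
            mix = {e: p / total for e, p in kb.priors.items()}
        else:
            mix = {Etiology(e): float(p) for e, p in self.mix.items()}
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"etiology mix must sum to 1 (got {total}); normalize first"
                )
        return mix

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if not (0.0 <= self.unknown_rate < 1.0):
            raise ValueError(
                f"unknown_rate must lie in [0, 1), got {self.unknown_rate}"
            )


def sens_spec_from_lhr(lhr_pos: float, lhr_neg: float) -> tuple[float, float]:
    """Invert an informative LHR pair to (sensitivity, specificity).

    Solving sens / (1 - spec) = LHR+ and (1 - sens) / spec = LHR-
    simultaneously gives spec = (LHR+ - 1) / (LHR+ - LHR-) and
    sens = LHR+ * (1 - spec). The system has a solution in (0,1)^2 only
    for an orientation-consistent pair LHR+ > 1 > LHR- > 0; anything else
    raises ``ValueError`` and the caller falls back to the neutral rate.
    """
    if not (lhr_pos > 1.0 > lhr_neg > 0.0):
        raise ValueError(
            "likelihood-ratio pair is not invertible: need "
            f"LHR+ > 1 > LHR- > 0, got ({lhr_pos}, {lhr_neg})"
        )
    specificity = (lhr_pos - 1.0) / (lhr_pos - lhr_neg)
    sensitivity = lhr_pos * (1.0 - specificity)
    return sensitivity, specificity


def _yes_rate(question, etiology: Etiology, neutral: float) -> float:
    pair = question.lhr.get(etiology)
    if pair is None:
        return neutral
    try:
        sensitivity, _ = sens_spec_from_lhr(pair.lhr_pos, pair.lhr_neg)
    except ValueError:
        return neutral
    return sensitivity


def generate_case(
    etiology: Etiology,
    kb: KnowledgeBase,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[AnswerSet, Etiology]:
    """Draw one labeled answer vector for a case with true etiology ``etiology``."""
    answers: dict[str, AnswerValue] = {}
    for question in kb.questions:
        if rng.random() < config.unknown_rate:
            answers[question.id] = AnswerValue.UNKNOWN
            continue
        rate = _yes_rate(question, etiology, config.neutral_yes_rate)
        answers[question.id] = (
            AnswerValue.YES if rng.random() < rate else AnswerValue.NO
        )
    return AnswerSet(answers=answers), etiology


def generate_cohort(
    config: GeneratorConfig, kb: KnowledgeBase
) -> list[tuple[AnswerSet, Etiology]]:
    """Draw ``config.n`` labeled cases; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mix = config.resolved_mix(kb)
    etiologies = list(mix)
    weights = np.array([mix[e] for e in etiologies], dtype=float)
    weights = weights / weights.sum()
    cohort = []
    for _ in range(config.n):
        label = etiologies[rng.choice(len(etiologies), p=weights)]
        cohort.append(generate_case(label, kb, config, rng))
    return cohort
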