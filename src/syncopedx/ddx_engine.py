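"""Posttest log-odds differential diagnosis over the four etiologies.

Each etiology is an independent binary logistic model. Evidence
accumulates on the log-odds scale:

    log-odds_post = logit(prior) + sum over answered questions of
                    ln(LHR+) if yes, ln(LHR-) if no

Questions answered ``unknown``, prompt-only questions, and absent LHR
cells contribute a neutral factor of 1 (0 on the log scale), so a
partially completed assessment still yields a differential and an empty
one recovers the priors exactly. The four models are never renormalized
against each other: the ranked output carries raw per-etiology posttest
probabilities.

Two etiologies (orthostatic syncope and neurogenic LOC) have no
literature likelihood ratios; they are promoted by an artificial-weighting
override when *all* of their flagged questions are answered yes. The
override changes rank only, never the computed probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .knowledge_base import Etiology, KnowledgeBase

__all__ = [
    "AnswerValue",
    "AnswerSet",
    "EtiologyPosterior",
    "Differential",
    "posttest_log_odds",
    "posttest_log_odds_beta",
    "probability_from_log_odds",
    "log_odds_from_probability",
    "apply_overrides",
    "compute_differential",
]


class AnswerValue(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class AnswerSet:
    """One encounter's responses plus the clinician's optional diagnosis pick.

    ``answers`` maps question id to yes/no/unknown; at most one answer per
    question is structural (it is a mapping). ``unknown`` is an explicit
    third state so progressive data entry degrades gracefully rather than
    forcing a default of "no".
    """

    answers: dict[str, AnswerValue] = field(default_factory=dict)
    user_selected_ddx: Optional[Etiology] = None

    @classmethod
    def from_dict(cls, doc: dict) -> "AnswerSet":
        """Build from the case-file JSON form (see ``case.schema.json``)."""
        if not isinstance(doc, dict) or "answers" not in doc:
            raise ValueError("case document must be an object with an 'answers' map")
        raw = doc["answers"]
        if not isinstance(raw, dict):
            raise ValueError("'answers' must be a map of question id to response")
        answers = {}
        for qid, value in raw.items():
            try:
                answers[str(qid)] = AnswerValue(value)
            except ValueError:
                raise ValueError(
                    f"answers.{qid}: invalid response {value!r} "
                    "(expected 'yes', 'no' or 'unknown')"
                ) from None
        user = doc.get("user_selected_ddx")
        user_etiology = None
        if user is not None:
            try:
                user_etiology = Etiology(user)
            except ValueError:
                raise ValueError(
                    f"user_selected_ddx: invalid etiology {user!r}"
                ) from None
        return cls(answers=answers, user_selected_ddx=user_etiology)

    def to_dict(self) -> dict:
        doc: dict = {"answers": {q: v.value for q, v in self.answers.items()}}
        if self.user_selected_ddx is not None:
            doc["user_selected_ddx"] = self.user_selected_ddx.value
        return doc

    def get(self, question_id: str) -> AnswerValue:
        return self.answers.get(question_id, AnswerValue.UNKNOWN)

    def validate_against(self, kb: KnowledgeBase) -> None:
        """Raise ``KeyError`` if any answered id is not a KB question."""
        unknown_ids = [q for q in self.answers if q not in kb]
        if unknown_ids:
            raise KeyError(
                f"answers reference unknown question ids: {sorted(unknown_ids)}"
            )


@dataclass
class EtiologyPosterior:
    """One etiology's posttest state: log-odds, probability, override flag."""

    etiology: Etiology
    log_odds: float
    probability: float
    overridden: bool = False


@dataclass
class Differential:
    """The ranked differential; rank 1 first."""

    posteriors: list[EtiologyPosterior]

    @property
    def app_top(self) -> Etiology:
        return self.posteriors[0].etiology

    def __iter__(self):
        return iter(self.posteriors)

    def __getitem__(self, i: int) -> EtiologyPosterior:
        return self.posteriors[i]

    def posterior(self, etiology: Etiology) -> EtiologyPosterior:
        for p in self.posteriors:
            if p.etiology is etiology:
                return p
        raise KeyError(etiology)


# ---------------------------------------------------------------------------
# Log-odds aggregation
# ---------------------------------------------------------------------------

def probability_from_log_odds(log_odds: float) -> float:
    """Inverse-logit: p = 1 / (1 + exp(-log_odds)); strictly increasing."""
    if not math.isfinite(log_odds):
        raise ValueError(f"log-odds must be finite, got {log_odds}")
    if log_odds >= 0:
        return 1.0 / (1.0 + math.exp(-log_odds))
    # rearranged for numerical symmetry at large negative values
    z = math.exp(log_odds)
    return z / (1.0 + z)


def log_odds_from_probability(p: float) -> float:
    """logit: ln(p / (1 - p)) for p in the open interval (0, 1)."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"probability must lie in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def posttest_log_odds(
    prior: float,
    answers: AnswerSet,
    kb: KnowledgeBase,
    etiology: Etiology,
) -> float:
    """Accumulate ln(LHR) evidence onto the pretest log-odds.

    Summation runs in KB question order so results are reproducible
    bit-for-bit for a given KB; permuting the answer map cannot change
    the result beyond floating-point noise (~1e-12) because only the KB
    order is used.
    """
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must lie in the open interval (0, 1), got {prior}")
    answers.validate_against(kb)
    log_odds = log_odds_from_probability(prior)
    for question in kb.questions:
        value = answers.answers.get(question.id)
        if value is None or value is AnswerValue.UNKNOWN:
            continue
        pair = question.lhr.get(etiology)
        if pair is None:
            continue  # absent cell / prompt-only: neutral factor 1
        lhr = pair.lhr_pos if value is AnswerValue.YES else pair.lhr_neg
        log_odds += math.log(lhr)
    return log_odds


def posttest_log_odds_beta(
    prior: float,
    answers: AnswerSet,
    kb: KnowledgeBase,
    etiology: Etiology,
) -> float:
    """The same posttest log-odds via the regression parameterization.

    The intercept absorbs the negative-finding evidence of every answered
    cell, beta0' = logit(prior) + sum ln(LHR-), and each yes contributes
    beta_i = ln(LHR+ / LHR-). Algebraically identical to
    :func:`posttest_log_odds`; implemented separately as a cross-check.
    """
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must lie in the open interval (0, 1), got {prior}")
    answers.validate_against(kb)
    log_odds = log_odds_from_probability(prior)
    for question in kb.questions:
        value = answers.answers.get(question.id)
        if value is None or value is AnswerValue.UNKNOWN:
            continue
        pair = question.lhr.get(etiology)
        if pair is None:
            continue
        log_odds += math.log(pair.lhr_neg)  # intercept contribution
        if value is AnswerValue.YES:
            log_odds += math.log(pair.lhr_pos / pair.lhr_neg)
    return log_odds


# ---------------------------------------------------------------------------
# Overrides and ranking
# ---------------------------------------------------------------------------

def _override_fires(etiology: Etiology, answers: AnswerSet, kb: KnowledgeBase) -> bool:
    flagged = kb.override_questions(etiology)
    return bool(flagged) and all(
        answers.get(q.id) is AnswerValue.YES for q in flagged
    )


def apply_overrides(
    posteriors: Iterable[EtiologyPosterior],
    answers: AnswerSet,
    kb: KnowledgeBase,
) -> list[EtiologyPosterior]:
    """Mark fired overrides and rank the differential.

    An etiology with override-flagged questions is promoted iff *all* of
    them are answered yes. Overridden etiologies outrank every
    non-overridden one (among several overridden, the configured risk
    precedence applies, so neurogenic LOC precedes orthostatic). Within
    the non-overridden block the order is probability descending with the
    risk precedence breaking exact ties. Probabilities are never altered.
    """
    precedence = {e: i for i, e in enumerate(kb.tie_break_order)}
    ranked = []
    for p in posteriors:
        ranked.append(
            EtiologyPosterior(
                etiology=p.etiology,
                log_odds=p.log_odds,
                probability=p.probability,
                overridden=_override_fires(p.etiology, answers, kb),
            )
        )

    def sort_key(p: EtiologyPosterior):
        if p.overridden:
            return (0, precedence[p.etiology], 0.0)
        return (1, 0, -p.probability, precedence[p.etiology])

    ranked.sort(key=sort_key)
    return ranked


def compute_differential(answers: AnswerSet, kb: KnowledgeBase) -> Differential:
    """Full pipeline: log-odds per etiology -> probabilities -> overrides -> rank."""
    answers.validate_against(kb)
    posteriors = []
    for etiology in Etiology:
        lo = posttest_log_odds(kb.priors[etiology], answers, kb, etiology)
        posteriors.append(
            EtiologyPosterior(
                etiology=etiology,
                log_odds=lo,
                probability=probability_from_log_odds(lo),
            )
        )
    return Differential(posteriors=apply_overrides(posteriors, answers, kb))
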