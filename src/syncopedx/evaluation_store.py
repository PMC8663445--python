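"""Append-only evaluation log and the app-vs-user congruence report.

Each completed assessment is persisted as one JSON line (schema
``record.schema.json``): the answers, the engine's top-ranked etiology,
the clinician's selection (if any), the CSS total and class, and the
recommendation keys used. Records are anonymous by construction — the
schema has no field that could carry a patient identifier; the record id
is an opaque random token.

The congruence report measures how often the engine's top-ranked
etiology matched the clinician's pick, optionally restricted to a subset
of user-selected etiologies (restricting to cardiogenic and vasovagal
reproduces the metric definition used for the deployed model's
evaluation). Records flagged hypothetical — entered to try the tool, not
to document a real case — are excluded by default.
"""

from __future__ import annotations

import json
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .ddx_engine import AnswerSet, AnswerValue
from .knowledge_base import Etiology, KnowledgeBase, RiskClass
from .recommendations import Assessment, assess_case

__all__ = [
    "EvaluationRecord",
    "IntegrityError",
    "CongruenceReport",
    "build_record",
    "append_record",
    "read_records",
    "congruence_report",
]


class IntegrityError(ValueError):
    """A record's stored results disagree with re-running the engine."""


@dataclass
class EvaluationRecord:
    record_id: str
    timestamp: str
    answers: dict[str, AnswerValue]
    app_top: Etiology
    user_selected_ddx: Optional[Etiology]
    css_total: int
    risk_class: RiskClass
    recommendation_keys: dict = field(default_factory=dict)
    hypothetical: bool = False

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "timestamp": self.timestamp,
            "answers": {q: v.value for q, v in self.answers.items()},
            "app_top": self.app_top.value,
            "user_selected_ddx": (
                self.user_selected_ddx.value if self.user_selected_ddx else None
            ),
            "css_total": self.css_total,
            "risk_class": self.risk_class.value,
            "recommendation_keys": self.recommendation_keys,
            "hypothetical": self.hypothetical,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationRecord":
        user = doc.get("user_selected_ddx")
        return cls(
            record_id=str(doc["record_id"]),
            timestamp=str(doc["timestamp"]),
            answers={q: AnswerValue(v) for q, v in doc["answers"].items()},
            app_top=Etiology(doc["app_top"]),
            user_selected_ddx=Etiology(user) if user is not None else None,
            css_total=int(doc["css_total"]),
            risk_class=RiskClass(doc["risk_class"]),
            recommendation_keys=dict(doc.get("recommendation_keys", {})),
            hypothetical=bool(doc.get("hypothetical", False)),
        )

    def answer_set(self) -> AnswerSet:
        return AnswerSet(
            answers=dict(self.answers), user_selected_ddx=self.user_selected_ddx
        )


def build_record(
    answers: AnswerSet,
    kb: KnowledgeBase,
    *,
    record_id: Optional[str] = None,
    timestamp: Optional[str] = None,
    hypothetical: bool = False,
    assessment: Optional[Assessment] = None,
) -> EvaluationRecord:
    """Run the pipeline (unless ``assessment`` is supplied) and build a record."""
    if assessment is None:
        assessment = assess_case(answers, kb)
    bundle = assessment.recommendations
    keys = {
        "primary": bundle.primary_etiology.value,
        "secondary": (
            f"{bundle.secondary_key[0].value}|{bundle.secondary_key[1].value}"
            if bundle.secondary_key
            else None
        ),
        "question_specific": [qid for qid, _ in bundle.question_specific],
        "disposition": bundle.risk_class.value,
    }
    return EvaluationRecord(
        record_id=record_id or uuid.uuid4().hex,
        timestamp=timestamp or datetime.now(timezone.utc).isoformat(),
        answers=dict(answers.answers),
        app_top=assessment.differential.app_top,
        user_selected_ddx=answers.user_selected_ddx,
        css_total=assessment.css.total,
        risk_class=assessment.css.risk_class,
        recommendation_keys=keys,
        hypothetical=hypothetical,
    )


def _verify(record: EvaluationRecord, kb: KnowledgeBase) -> None:
    assessment = assess_case(record.answer_set(), kb)
    problems = []
    if assessment.differential.app_top is not record.app_top:
        problems.append(
            f"app_top {record.app_top.value!r} != recomputed "
            f"{assessment.differential.app_top.value!r}"
        )
    if assessment.css.total != record.css_total:
        problems.append(
            f"css_total {record.css_total} != recomputed {assessment.css.total}"
        )
    if assessment.css.risk_class is not record.risk_class:
        problems.append(
            f"risk_class {record.risk_class.value!r} != recomputed "
            f"{assessment.css.risk_class.value!r}"
        )
    if problems:
        raise IntegrityError(
            f"record {record.record_id}: " + "; ".join(problems)
        )


def append_record(
    path: Union[str, Path],
    record: EvaluationRecord,
    kb: Optional[KnowledgeBase] = None,
) -> EvaluationRecord:
    """Append one record as a JSON line; verify consistency when ``kb`` given.

    Raises :class:`IntegrityError` if the stored app_top / CSS disagree
    with re-running the engine on the stored answers, and ``OSError`` if
    the path is not writable. Returns the record for chaining.
    """
    if kb is not None:
        _verify(record, kb)
    line = json.dumps(record.to_dict(), sort_keys=True)
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(line + "\n")
    return record


def read_records(path: Union[str, Path]) -> list[EvaluationRecord]:
    """Read all records back, in append order."""
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(EvaluationRecord.from_dict(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise ValueError(
                    f"{path}, line {lineno}: malformed record ({exc})"
                ) from exc
    return records


@dataclass
class CongruenceReport:
    """App-vs-user agreement over the eligible records.

    ``fraction`` is None when no record is eligible (empty report rather
    than a division error).
    """

    total_records: int
    eligible: int
    concordant: int
    fraction: Optional[float]
    by_user_etiology: dict[str, dict[str, int]]
    restrict_to: Optional[list[str]] = None

    def to_dict(self) -> dict:
        return {
            "total_records": self.total_records,
            "eligible": self.eligible,
            "concordant": self.concordant,
            "fraction": self.fraction,
            "by_user_etiology": self.by_user_etiology,
            "restrict_to": self.restrict_to,
        }


def congruence_report(
    records: Iterable[EvaluationRecord],
    restrict_to: Optional[Sequence[Etiology]] = None,
    *,
    include_hypothetical: bool = False,
) -> CongruenceReport:
    """Fraction of records whose app_top matched the user's selection.

    Records with no user selection are excluded; ``restrict_to`` filters
    on the *user-selected* etiology. The report is permutation-invariant
    over the input order.
    """
    restriction = set(restrict_to) if restrict_to is not None else None
    records = list(records)
    eligible = 0
    concordant = 0
    by_user: dict[str, dict[str, int]] = {}
    for record in records:
        if record.hypothetical and not include_hypothetical:
            continue
        user = record.user_selected_ddx
        if user is None:
            continue
        if restriction is not None and user not in restriction:
            continue
        eligible += 1
        bucket = by_user.setdefault(
            user.value, {"eligible": 0, "concordant": 0}
        )
        bucket["eligible"] += 1
        if record.app_top is user:
            concordant += 1
            bucket["concordant"] += 1
    return CongruenceReport(
        total_records=len(records),
        eligible=eligible,
        concordant=concordant,
        fraction=(concordant / eligible) if eligible else None,
        by_user_etiology=by_user,
        restrict_to=(
            sorted(e.value for e in restriction) if restriction is not None else None
        ),
    )
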