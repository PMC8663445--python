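"""Declarative knowledge base for the syncope differential-diagnosis engine.

The knowledge base is the single declarative artifact that drives every
downstream computation: the twenty binary assessment questions with their
per-etiology positive/negative likelihood ratios (LHR+/LHR-), the pretest
prevalences used as priors, the Canadian Syncope Score (CSS) item weights
and risk cut points, and the recommendation texts.

It is stored as JSON (YAML accepted as a 1:1 convenience dialect); the
published contract lives in ``data/kb.schema.json``. An absent LHR cell —
a question that carries no evidence for an etiology — is encoded as JSON
``null`` and contributes a neutral factor of 1 to the odds product.

The packaged default (``data/default_kb.json``) encodes the curated
question list: most cells are defined for vasovagal and cardiogenic
syncope, the two most prevalent causes of transient loss of consciousness;
orthostatic syncope and neurogenic loss of consciousness carry no
literature LHRs and are instead handled by override flags on dedicated
questions (see :mod:`syncopedx.ddx_engine`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "Etiology",
    "RiskClass",
    "RISK_PRECEDENCE",
    "DIAGNOSIS_VASOVAGAL",
    "DIAGNOSIS_CARDIAC",
    "LhrPair",
    "QuestionDef",
    "Threshold",
    "PriorSet",
    "CssItemDef",
    "CssConfig",
    "RecommendationTexts",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "validate_knowledge_base",
    "serialize_knowledge_base",
]


class Etiology(str, Enum):
    """The four modelled causes of transient loss of consciousness.

    Three are true syncope (global cerebral hypoperfusion with spontaneous
    recovery); neurogenic LOC (e.g. seizure) is the highest-risk
    non-syncopal mimic and is carried in the differential so that it can
    be routed to a neurologic workup.
    """

    VASOVAGAL = "vasovagal"
    ORTHOSTATIC = "orthostatic"
    CARDIOGENIC = "cardiogenic"
    NEUROGENIC_LOC = "neurogenic_loc"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RiskClass(str, Enum):
    """CSS risk classes driving disposition."""

    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Default tie-break precedence: the riskier etiology surfaces first.
RISK_PRECEDENCE: tuple[Etiology, ...] = (
    Etiology.NEUROGENIC_LOC,
    Etiology.CARDIOGENIC,
    Etiology.ORTHOSTATIC,
    Etiology.VASOVAGAL,
)

#: Sentinel sources for the two diagnosis-derived CSS items.
DIAGNOSIS_VASOVAGAL = "diagnosis:vasovagal"
DIAGNOSIS_CARDIAC = "diagnosis:cardiac"


class KnowledgeBaseError(ValueError):
    """Raised when a knowledge-base document cannot be parsed or validated."""


@dataclass(frozen=True)
class LhrPair:
    """A positive/negative likelihood-ratio pair for one (question, etiology) cell.

    ``lhr_pos`` multiplies the etiology's odds when the question is answered
    yes, ``lhr_neg`` when answered no. Both are dimensionless and strictly
    positive. A cell is either fully present or fully absent.
    """

    lhr_pos: float
    lhr_neg: float


@dataclass(frozen=True)
class Threshold:
    """A numeric cutoff documented in a question's wording (e.g. 480 ms)."""

    value: float
    unit: str
    label: Optional[str] = None


@dataclass
class QuestionDef:
    """One binary assessment question.

    ``css_input`` marks questions that feed a CSS item; ``prompt_only``
    questions carry no likelihood ratios and exist only to prompt
    additional clinical considerations; ``override_for`` marks the
    questions whose unanimous yes answers artificially promote an
    etiology to the top of the differential.
    """

    id: str
    text: str
    lhr: dict[Etiology, LhrPair] = field(default_factory=dict)
    css_input: bool = False
    prompt_only: bool = False
    override_for: Optional[Etiology] = None
    thresholds: tuple[Threshold, ...] = ()


@dataclass(frozen=True)
class PriorSet:
    """Pretest probability per etiology.

    Each prior lives in the open interval (0, 1). The four binary models
    are independent, so the priors need not (and in the default do not)
    sum to 1.
    """

    probabilities: Mapping[Etiology, float]

    def __getitem__(self, etiology: Etiology) -> float:
        return self.probabilities[etiology]

    def items(self):
        return self.probabilities.items()


@dataclass(frozen=True)
class CssItemDef:
    """One CSS point item: sourced from a question or from the diagnosis."""

    name: str
    source: str  # question id, or DIAGNOSIS_VASOVAGAL / DIAGNOSIS_CARDIAC
    points: int

    @property
    def diagnosis_derived(self) -> bool:
        return self.source in (DIAGNOSIS_VASOVAGAL, DIAGNOSIS_CARDIAC)


@dataclass(frozen=True)
class CssConfig:
    """CSS items plus the low/high cut points.

    The printed classification is low (<1), intermediate (1-3), high (>3):
    ``low_below`` is the exclusive upper bound of the low class and
    ``high_above`` the exclusive lower bound of the high class.
    """

    items: tuple[CssItemDef, ...]
    low_below: int
    high_above: int


@dataclass(frozen=True)
class RecommendationTexts:
    """Configured recommendation prose, keyed by the engine's decisions."""

    primary: Mapping[Etiology, str]
    secondary: Mapping[tuple[Etiology, Etiology], str]  # (app_top, user)
    question_specific: Mapping[str, str]  # question id -> text
    disposition: Mapping[RiskClass, str]


@dataclass
class KnowledgeBase:
    """The validated declarative model served to every other module."""

    version: str
    questions: list[QuestionDef]
    priors: PriorSet
    css: CssConfig
    recommendations: RecommendationTexts
    tie_break_order: tuple[Etiology, ...] = RISK_PRECEDENCE

    def __post_init__(self) -> None:
        self._by_id = {q.id: q for q in self.questions}

    def question(self, question_id: str) -> QuestionDef:
        """Look up a question by id; raises ``KeyError`` if absent."""
        return self._by_id[question_id]

    def question_ids(self) -> list[str]:
        return [q.id for q in self.questions]

    def __contains__(self, question_id: str) -> bool:
        return question_id in self._by_id

    def override_questions(self, etiology: Etiology) -> list[QuestionDef]:
        """Questions whose unanimous yes answers promote ``etiology``."""
        return [q for q in self.questions if q.override_for is etiology]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_etiology(raw: str, context: str) -> Etiology:
    try:
        return Etiology(raw)
    except ValueError:
        raise KnowledgeBaseError(
            f"{context}: unknown etiology {raw!r}; expected one of "
            f"{[e.value for e in Etiology]}"
        ) from None


def _parse_question(raw: dict, index: int) -> QuestionDef:
    ctx = f"questions[{index}]"
    try:
        qid = raw["id"]
        text = raw["text"]
    except KeyError as exc:
        raise KnowledgeBaseError(f"{ctx}: missing required field {exc}") from None
    lhr: dict[Etiology, LhrPair] = {}
    for key, cell in (raw.get("lhr") or {}).items():
        etiology = _parse_etiology(key, f"{ctx}.lhr")
        if cell is None:
            continue  # JSON null mirrors the table's NULL: no evidence
        if not isinstance(cell, dict) or set(cell) != {"pos", "neg"}:
            raise KnowledgeBaseError(
                f"{ctx}.lhr.{key}: a cell must be null or an object with "
                "exactly the keys 'pos' and 'neg'"
            )
        lhr[etiology] = LhrPair(float(cell["pos"]), float(cell["neg"]))
    override_raw = raw.get("override_for")
    override = (
        _parse_etiology(override_raw, f"{ctx}.override_for")
        if override_raw is not None
        else None
    )
    thresholds = tuple(
        Threshold(float(t["value"]), str(t["unit"]), t.get("label"))
        for t in raw.get("thresholds") or ()
    )
    return QuestionDef(
        id=str(qid),
        text=str(text),
        lhr=lhr,
        css_input=bool(raw.get("css_input", False)),
        prompt_only=bool(raw.get("prompt_only", False)),
        override_for=override,
        thresholds=thresholds,
    )


def _parse_document(doc: dict) -> KnowledgeBase:
    if not isinstance(doc, dict):
        raise KnowledgeBaseError("knowledge base document must be a JSON object")
    missing = {"version", "questions", "priors", "css", "recommendations"} - set(doc)
    if missing:
        raise KnowledgeBaseError(
            f"knowledge base missing top-level keys: {sorted(missing)}"
        )

    questions = [_parse_question(q, i) for i, q in enumerate(doc["questions"])]

    priors_raw = doc["priors"]
    priors = PriorSet(
        {
            _parse_etiology(k, "priors"): float(v)
            for k, v in priors_raw.items()
        }
    )

    css_raw = doc["css"]
    try:
        items = tuple(
            CssItemDef(str(i["name"]), str(i["source"]), int(i["points"]))
            for i in css_raw["items"]
        )
        thresholds = css_raw["thresholds"]
        css = CssConfig(
            items=items,
            low_below=int(thresholds["low_below"]),
            high_above=int(thresholds["high_above"]),
        )
    except (KeyError, TypeError) as exc:
        raise KnowledgeBaseError(f"css section malformed: {exc}") from None

    rec_raw = doc["recommendations"]
    try:
        primary = {
            _parse_etiology(k, "recommendations.primary"): str(v)
            for k, v in rec_raw["primary"].items()
        }
        secondary: dict[tuple[Etiology, Etiology], str] = {}
        for key, text in rec_raw["secondary"].items():
            app_part, _, user_part = key.partition("|")
            if not user_part:
                raise KnowledgeBaseError(
                    f"recommendations.secondary key {key!r} must be "
                    "'app_etiology|user_etiology'"
                )
            secondary[
                (
                    _parse_etiology(app_part, "recommendations.secondary"),
                    _parse_etiology(user_part, "recommendations.secondary"),
                )
            ] = str(text)
        question_specific = {
            str(k): str(v) for k, v in rec_raw["question_specific"].items()
        }
        disposition = {
            RiskClass(k): str(v) for k, v in rec_raw["disposition"].items()
        }
    except KeyError as exc:
        raise KnowledgeBaseError(
            f"recommendations section missing key {exc}"
        ) from None
    except ValueError as exc:
        raise KnowledgeBaseError(f"recommendations section malformed: {exc}") from None

    tie_break_raw = doc.get("tie_break_order")
    tie_break = (
        tuple(_parse_etiology(e, "tie_break_order") for e in tie_break_raw)
        if tie_break_raw
        else RISK_PRECEDENCE
    )

    return KnowledgeBase(
        version=str(doc["version"]),
        questions=questions,
        priors=priors,
        css=css,
        recommendations=RecommendationTexts(
            primary=primary,
            secondary=secondary,
            question_specific=question_specific,
            disposition=disposition,
        ),
        tie_break_order=tie_break,
    )


def load_knowledge_base(
    path: Union[str, Path, None] = None, *, validate: bool = True
) -> KnowledgeBase:
    """Load a knowledge base from ``path`` or the packaged default.

    Parameters
    ----------
    path
        A JSON (``.json``) or YAML (``.yaml``/``.yml``) document matching
        ``kb.schema.json``. When ``None`` the packaged default content —
        the curated twenty-question table — is loaded.
    validate
        When true (default), :func:`validate_knowledge_base` is run and a
        :class:`KnowledgeBaseError` listing *every* violation is raised if
        any are found.
    """
    if path is None:
        text = (
            resources.files("syncopedx.data")
            .joinpath("default_kb.json")
            .read_text(encoding="utf-8")
        )
        doc = json.loads(text)
    else:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in (".yaml", ".yml"):
            try:
                doc = yaml.safe_load(text)
            except yaml.YAMLError as exc:
                mark = getattr(exc, "problem_mark", None)
                line = f" at line {mark.line + 1}" if mark else ""
                raise KnowledgeBaseError(
                    f"could not parse YAML knowledge base {path}{line}: {exc}"
                ) from exc
        else:
            try:
                doc = json.loads(text)
            except json.JSONDecodeError as exc:
                raise KnowledgeBaseError(
                    f"could not parse JSON knowledge base {path} "
                    f"at line {exc.lineno}: {exc.msg}"
                ) from exc

    kb = _parse_document(doc)
    if validate:
        violations = validate_knowledge_base(kb)
        if violations:
            raise KnowledgeBaseError(
                "knowledge base failed validation:\n  - "
                + "\n  - ".join(violations)
            )
    return kb


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_knowledge_base(kb: KnowledgeBase) -> list[str]:
    """Check every structural invariant; return all violations (empty = valid).

    Violations are collected, not raised, so a caller can report a complete
    diagnosis of a broken document in one pass.
    """
    violations: list[str] = []

    # Questions ------------------------------------------------------------
    seen: set[str] = set()
    for q in kb.questions:
        if q.id in seen:
            violations.append(f"question id {q.id!r} is duplicated")
        seen.add(q.id)
        for etiology, pair in q.lhr.items():
            for label, value in (("LHR+", pair.lhr_pos), ("LHR-", pair.lhr_neg)):
                if not (math.isfinite(value) and value > 0):
                    violations.append(
                        f"question {q.id!r}, etiology {etiology.value}: "
                        f"{label} = {value}; likelihood ratio must be > 0"
                    )
        if q.prompt_only and q.lhr:
            violations.append(
                f"question {q.id!r}: prompt-only questions carry no "
                "likelihood ratios"
            )

    # Priors ---------------------------------------------------------------
    for etiology in Etiology:
        if etiology not in kb.priors.probabilities:
            violations.append(f"priors: missing etiology {etiology.value}")
            continue
        p = kb.priors[etiology]
        if not (math.isfinite(p) and 0.0 < p < 1.0):
            violations.append(
                f"priors: {etiology.value} = {p}; pretest probability must "
                "lie in the open interval (0, 1)"
            )

    # CSS ------------------------------------------------------------------
    diag_items = [i for i in kb.css.items if i.diagnosis_derived]
    if len(diag_items) != 2 or {i.source for i in diag_items} != {
        DIAGNOSIS_VASOVAGAL,
        DIAGNOSIS_CARDIAC,
    }:
        violations.append(
            "css: exactly two diagnosis-derived items are required "
            f"({DIAGNOSIS_VASOVAGAL!r} and {DIAGNOSIS_CARDIAC!r}); found "
            f"{[i.source for i in diag_items]}"
        )
    if not kb.css.low_below < kb.css.high_above:
        violations.append(
            f"css thresholds: low_below ({kb.css.low_below}) must be "
            f"strictly below high_above ({kb.css.high_above})"
        )
    question_sources: dict[str, int] = {}
    for item in kb.css.items:
        if item.diagnosis_derived:
            continue
        if item.source not in kb:
            violations.append(
                f"css item {item.name!r}: source question {item.source!r} "
                "does not exist"
            )
            continue
        question_sources[item.source] = question_sources.get(item.source, 0) + 1
    for q in kb.questions:
        n = question_sources.get(q.id, 0)
        if q.css_input and n != 1:
            violations.append(
                f"question {q.id!r} is flagged css_input but maps to "
                f"{n} CSS items (expected exactly 1)"
            )
        elif not q.css_input and n > 0:
            violations.append(
                f"question {q.id!r} sources a CSS item but is not flagged "
                "css_input"
            )

    # Recommendations ------------------------------------------------------
    for etiology in Etiology:
        if etiology not in kb.recommendations.primary:
            violations.append(
                f"recommendations.primary: missing text for {etiology.value}"
            )
    for risk in RiskClass:
        if risk not in kb.recommendations.disposition:
            violations.append(
                f"recommendations.disposition: missing text for {risk.value}"
            )
    for app in Etiology:
        for user in Etiology:
            if app is user:
                continue
            if (app, user) not in kb.recommendations.secondary:
                violations.append(
                    "recommendations.secondary: missing text for discordant "
                    f"pair ({app.value}, {user.value})"
                )
    for q in kb.questions:
        if (q.override_for is not None or q.prompt_only) and (
            q.id not in kb.recommendations.question_specific
        ):
            violations.append(
                "recommendations.question_specific: missing text for "
                f"question {q.id!r} (reachable via its "
                f"{'override' if q.override_for else 'prompt-only'} flag)"
            )

    # Tie-break order ------------------------------------------------------
    if set(kb.tie_break_order) != set(Etiology) or len(kb.tie_break_order) != 4:
        violations.append(
            "tie_break_order must be a permutation of the four etiologies"
        )

    return violations


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def serialize_knowledge_base(kb: KnowledgeBase) -> dict:
    """Render a KnowledgeBase back to its JSON-document form.

    ``load`` of the serialized document reproduces the original
    field-for-field (the round-trip property the tests pin down).
    """
    def cell(pair: Optional[LhrPair]):
        if pair is None:
            return None
        return {"pos": pair.lhr_pos, "neg": pair.lhr_neg}

    return {
        "version": kb.version,
        "tie_break_order": [e.value for e in kb.tie_break_order],
        "questions": [
            {
                "id": q.id,
                "text": q.text,
                "lhr": {e.value: cell(q.lhr.get(e)) for e in Etiology},
                "css_input": q.css_input,
                "prompt_only": q.prompt_only,
                "override_for": q.override_for.value if q.override_for else None,
                "thresholds": [
                    {
                        "value": t.value,
                        "unit": t.unit,
                        **({"label": t.label} if t.label else {}),
                    }
                    for t in q.thresholds
                ],
            }
            for q in kb.questions
        ],
        "priors": {e.value: p for e, p in kb.priors.items()},
        "css": {
            "items": [
                {"name": i.name, "source": i.source, "points": i.points}
                for i in kb.css.items
            ],
            "thresholds": {
                "low_below": kb.css.low_below,
                "high_above": kb.css.high_above,
            },
        },
        "recommendations": {
            "primary": {e.value: t for e, t in kb.recommendations.primary.items()},
            "secondary": {
                f"{app.value}|{user.value}": t
                for (app, user), t in kb.recommendations.secondary.items()
            },
            "question_specific": dict(kb.recommendations.question_specific),
            "disposition": {
                r.value: t for r, t in kb.recommendations.disposition.items()
            },
        },
    }
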