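"""Questionnaire scoring to a 0-15 recall score.

Each item awards its full points for a correct answer; multi-select items
award proportional credit for correct selections, penalized by incorrect
ones and floored at zero.  The per-item point allocation is configuration:
the shipped default spreads 15 points equally across the four item kinds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SchemeItem",
    "ScoringScheme",
    "RecallScore",
    "default_scheme",
    "load_scheme",
    "score_questionnaire",
]

ITEM_KINDS = ("spontaneous_message", "emotion_match", "suggested_yesno",
              "suggested_message")
TOTAL_POINTS = 15.0


@dataclass(frozen=True)
class SchemeItem:
    item_id: str
    kind: str
    max_points: float
    key: str | tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ITEM_KINDS:
            raise ValueError(f"unknown item kind {self.kind!r}")
        if self.max_points < 0:
            raise ValueError("max_points must be >= 0")
        if self.kind == "suggested_message" and isinstance(self.key, str):
            object.__setattr__(self, "key", (self.key,))


@dataclass(frozen=True)
class ScoringScheme:
    items: tuple[SchemeItem, ...]

    def __post_init__(self) -> None:
        total = sum(i.max_points for i in self.items)
        if abs(total - TOTAL_POINTS) > 1e-9:
            raise ValueError(f"scheme max_points sum to {total}, "
                             f"expected {TOTAL_POINTS}")
        ids = [i.item_id for i in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in scheme")

    def item(self, item_id: str) -> SchemeItem:
        for i in self.items:
            if i.item_id == item_id:
                return i
        raise KeyError(item_id)


@dataclass(frozen=True)
class RecallScore:
    subject_id: str
    score: float
    per_item_points: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.per_item_points.values())
        if abs(total - self.score) > 1e-9:
            raise ValueError("score must equal the sum of per-item points")
        if not (-1e-9 <= self.score <= TOTAL_POINTS + 1e-9):
            raise ValueError("score outside [0, 15]")


def default_scheme() -> ScoringScheme:
    """Equal weights across the four item kinds, summing to 15."""
    w = TOTAL_POINTS / 4
    return ScoringScheme(items=(
        SchemeItem("spontaneous_message", "spontaneous_message", w, "correct"),
        SchemeItem("emotion_match", "emotion_match", w, "correct"),
        SchemeItem("suggested_yesno", "suggested_yesno", w, "yes"),
        SchemeItem("suggested_message", "suggested_message", w,
                   ("m1", "m2", "m3")),
    ))


def load_scheme(path) -> ScoringScheme:
    """Read a scheme from YAML/JSON: a list of item mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    items = tuple(
        SchemeItem(item_id=d["item_id"], kind=d["kind"],
                   max_points=float(d["max_points"]),
                   key=tuple(d["key"]) if isinstance(d["key"], list)
                   else d["key"])
        for d in raw)
    return ScoringScheme(items)


def _multi_select_points(answer, item: SchemeItem) -> float:
    if answer is None or answer == "":
        selections: set[str] = set()
    elif isinstance(answer, str):
        selections = {a.strip() for a in answer.split(";") if a.strip()}
    else:
        selections = {str(a) for a in answer}
    key = set(item.key)
    correct = len(selections & key)
    wrong = len(selections - key)
    frac = max(0.0, (correct - wrong) / len(key))
    return item.max_points * frac


def score_questionnaire(responses: Mapping[str, object],
                        scheme: ScoringScheme,
                        subject_id: str = "") -> RecallScore:
    """Score one subject's answers for one spot against the scheme.

    Missing items score zero (logged); answers for item ids not in the
    scheme are an error.
    """
    known = {i.item_id for i in scheme.items}
    unknown = set(responses) - known
    if unknown:
        raise ValueError(f"unknown item ids in responses: {sorted(unknown)}")
    per_item: dict[str, float] = {}
    for item in scheme.items:
        if item.item_id not in responses or responses[item.item_id] is None:
            logger.info("subject %s: missing answer for %s (0 points)",
                        subject_id, item.item_id)
            per_item[item.item_id] = 0.0
            continue
        answer = responses[item.item_id]
        if item.kind == "suggested_message":
            per_item[item.item_id] = _multi_select_points(answer, item)
        else:
            match = str(answer).strip().lower() == str(item.key).strip().lower()
            per_item[item.item_id] = item.max_points if match else 0.0
    return RecallScore(subject_id=subject_id,
                       score=sum(per_item.values()),
                       per_item_points=per_item)
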