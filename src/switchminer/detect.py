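"""Relevance filtering, switch detection and cue-based classification.

Switch events are extracted with an ordered rule grammar over a normalized
token stream in which each drug mention is replaced by an indexed slot
token.  Each rule binds a FROM and a TO slot; direction comes from the
rule, never from mention order.  Reasons, conversation category, theme and
sentiment are assigned from small editable cue lexicons; the reason
precedence order (used when several cues co-occur in the clause window) is
the descending published frequency of the nine reason categories.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import timedelta
from enum import Enum
from importlib import resources
from pathlib import Path

from .corpus import Post
from .lexicon import DrugClass, DrugMention, Lexicon, match_mentions

log = logging.getLogger(__name__)

#: Window for the author-level duplicate-text rule (the single documented
#: cross-post dependency of the per-post annotation).
DEDUP_WINDOW_DAYS = 7


class Reason(str, Enum):
    SIDE_EFFECTS = "SIDE_EFFECTS"
    LACK_OF_EFFICACY = "LACK_OF_EFFICACY"
    PHYSICIAN_ADVICE = "PHYSICIAN_ADVICE"
    EASE_OF_USE = "EASE_OF_USE"
    QOL_WORSENING = "QOL_WORSENING"
    SAFETY_CONCERNS = "SAFETY_CONCERNS"
    INSURANCE = "INSURANCE"
    COST = "COST"
    OTHER = "OTHER"
    UNSPECIFIED = "UNSPECIFIED"


class Category(str, Enum):
    INFO_SHARING = "INFO_SHARING"
    INFO_SEEKING = "INFO_SEEKING"


class Theme(str, Enum):
    COST = "COST"
    EFFICACY = "EFFICACY"
    SIDE_EFFECTS = "SIDE_EFFECTS"
    ADHERENCE = "ADHERENCE"
    NONE = "NONE"


class Sentiment(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NEUTRAL = "NEUTRAL"


@dataclass(frozen=True)
class SwitchEvent:
    """A directed treatment switch reported in one post."""

    post_id: str
    from_drug: str
    to_drug: str
    from_class: DrugClass
    to_class: DrugClass
    pattern_id: str
    reason: Reason = Reason.UNSPECIFIED

    def __post_init__(self):
        if self.from_drug == self.to_drug:
            raise ValueError("switch event cannot link a drug to itself")


@dataclass
class PostAnnotation:
    post_id: str
    relevant: bool
    category: Category = Category.INFO_SHARING
    theme: Theme = Theme.NONE
    sentiment: Sentiment = Sentiment.NEUTRAL
    switches: list[SwitchEvent] = field(default_factory=list)
    provenance: str = "AUTO"

    def to_record(self) -> dict:
        return {
            "post_id": self.post_id,
            "relevant": self.relevant,
            "category": self.category.value,
            "theme": self.theme.value,
            "sentiment": self.sentiment.value,
            "provenance": self.provenance,
            "switches": [
                {
                    "from_drug": s.from_drug,
                    "to_drug": s.to_drug,
                    "from_class": s.from_class.value,
                    "to_class": s.to_class.value,
                    "pattern_id": s.pattern_id,
                    "reason": s.reason.value,
                }
                for s in self.switches
            ],
        }


# ---------------------------------------------------------------------------
# cue lexicons

def _load_json(name: str) -> dict:
    with (resources.files("switchminer") / "data" / name).open(encoding="utf-8") as fh:
        return json.load(fh)


class Cues:
    """Reason/theme/sentiment/category/spam cue lexicons."""

    def __init__(self, data: dict):
        self.reason_order = [Reason[r] for r in data["reason_order"]]
        self.reason_cues = {Reason[k]: v for k, v in data["reason_cues"].items()}
        self.theme_order = [Theme[t] for t in data["theme_order"]]
        self.theme_cues = {Theme[k]: v for k, v in data["theme_cues"].items()}
        self.positive = data["sentiment_positive"]
        self.negative = data["sentiment_negative"]
        self.seeking_openers = data["seeking_openers"]
        self.spam_cues = data["spam_cues"]

    @classmethod
    def load(cls, path: str | Path | None = None) -> "Cues":
        if path is None:
            return cls(_load_json("cues.json"))
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))


_DEFAULT_CUES: Cues | None = None


def default_cues() -> Cues:
    global _DEFAULT_CUES
    if _DEFAULT_CUES is None:
        _DEFAULT_CUES = Cues.load()
    return _DEFAULT_CUES


# ---------------------------------------------------------------------------
# pattern grammar

@dataclass(frozen=True)
class GrammarRule:
    rule_id: str
    family: str
    pattern: str
    regex: re.Pattern


class Grammar:
    """Ordered switch-pattern rule set; earlier rules win on conflicts."""

    def __init__(self, rules: list[GrammarRule]):
        self.rules = list(rules)

    @classmethod
    def load(cls, path: str | Path | None = None) -> "Grammar":
        data = _load_json("grammar.json") if path is None else json.load(open(path, encoding="utf-8"))
        rules = []
        for spec in data["rules"]:
            pat = spec["pattern"]
            pat = pat.replace("{FROM}", r"drugslot(?P<f>\d+)")
            pat = pat.replace("{TO}", r"drugslot(?P<t>\d+)")
            rules.append(
                GrammarRule(
                    rule_id=spec["rule_id"],
                    family=spec.get("family", "other"),
                    pattern=spec["pattern"],
                    regex=re.compile(pat),
                )
            )
        return cls(rules)


def _slotted_text(text: str, mentions: list[DrugMention]) -> str:
    """Lowercased token stream with each mention replaced by ``drugslotN``."""
    parts: list[str] = []
    last = 0
    for i, m in enumerate(mentions):
        parts.append(text[last:m.start])
        parts.append(f" drugslot{i} ")
        last = m.end
    parts.append(text[last:])
    s = re.sub(r"[^a-z0-9]+", " ", "".join(parts).lower())
    return f" {s.strip()} "


_SENTENCE_RE = re.compile(r"[^.!?]*[.!?]?")


def _sentence_window(text: str, pos: int) -> str:
    """The sentence of ``text`` containing character position ``pos``."""
    for m in _SENTENCE_RE.finditer(text):
        if m.start() <= pos < max(m.end(), m.start() + 1):
            return m.group(0)
    return text


def classify_reason(
    post_text: str,
    anchor: int | None = None,
    cues: Cues | None = None,
) -> Reason:
    """Reason for a detected switch, from cue phrases in the clause window.

    The window is the sentence containing ``anchor`` (the TO-mention
    position); cues are evaluated in the fixed precedence order and the
    first category with a hit wins.  No cue found -> UNSPECIFIED.
    """
    cues = cues or default_cues()
    window = post_text if anchor is None else _sentence_window(post_text, anchor)
    low = window.casefold()
    for reason in cues.reason_order:
        if any(c in low for c in cues.reason_cues.get(reason, ())):
            return reason
    return Reason.UNSPECIFIED


def detect_switches(
    post: Post,
    mentions: list[DrugMention],
    grammar: Grammar,
    lexicon: Lexicon,
    cues: Cues | None = None,
) -> list[SwitchEvent]:
    """Apply the grammar to one post; at most one event per ordered drug pair.

    Overlapping rule matches on the same ordered pair are resolved by rule
    priority (grammar order), then leftmost match.
    """
    if len(mentions) < 2:
        return []
    slotted = _slotted_text(post.text, mentions)
    events: list[tuple[int, int, SwitchEvent]] = []
    taken: set[tuple[str, str]] = set()
    for prio, rule in enumerate(grammar.rules):
        for m in rule.regex.finditer(slotted):
            fi, ti = int(m.group("f")), int(m.group("t"))
            if fi == ti or fi >= len(mentions) or ti >= len(mentions):
                continue
            fm, tm = mentions[fi], mentions[ti]
            if fm.brand == tm.brand:
                continue
            pair = (fm.brand, tm.brand)
            if pair in taken:
                continue
            taken.add(pair)
            reason = classify_reason(post.text, anchor=tm.start, cues=cues)
            events.append(
                (
                    prio,
                    min(fm.start, tm.start),
                    SwitchEvent(
                        post_id=post.post_id,
                        from_drug=fm.brand,
                        to_drug=tm.brand,
                        from_class=lexicon.drug_class(fm.brand),
                        to_class=lexicon.drug_class(tm.brand),
                        pattern_id=rule.rule_id,
                        reason=reason,
                    ),
                )
            )
    events.sort(key=lambda x: (x[1], x[0]))
    return [e for _, _, e in events]


# ---------------------------------------------------------------------------
# relevance

def _normtext(text: str) -> str:
    return re.sub(r"\s+", " ", text.casefold()).strip()


def _is_spam(text: str, cues: Cues) -> bool:
    low = text.casefold()
    if any(c in low for c in cues.spam_cues):
        return True
    stripped = re.sub(r"https?://\S+", "", text).strip()
    return bool(re.search(r"https?://", text)) and len(stripped) < 10


class RelevanceFilter:
    """Stateful relevance classifier with the author duplicate-text rule.

    Posts must be fed in (timestamp, post_id) order for the duplicate rule
    to be deterministic.
    """

    def __init__(self, window_days: int = DEDUP_WINDOW_DAYS, cues: Cues | None = None):
        self.window = timedelta(days=window_days)
        self.cues = cues or default_cues()
        self._seen: dict[tuple[str, str], object] = {}

    def classify(self, post: Post, mentions: list[DrugMention]) -> bool:
        if not mentions:
            return False
        if _is_spam(post.text, self.cues):
            return False
        key = (post.author_key, _normtext(post.text))
        prev = self._seen.get(key)
        self._seen[key] = post.timestamp
        if prev is not None and (post.timestamp - prev) <= self.window:
            return False
        return True


def classify_relevance(
    post: Post,
    mentions: list[DrugMention],
    filter: RelevanceFilter | None = None,
) -> bool:
    """True iff the post has >=1 drug mention and passes the spam/dup filter."""
    if filter is not None:
        return filter.classify(post, mentions)
    return bool(mentions) and not _is_spam(post.text, default_cues())


# ---------------------------------------------------------------------------
# category / theme / sentiment

def _count_cues(low: str, cue_list: list[str]) -> int:
    n = 0
    for c in cue_list:
        n += len(re.findall(r"(?<!\w)" + re.escape(c) + r"(?!\w)", low))
    return n


def classify_category_theme_sentiment(
    text: str, cues: Cues | None = None
) -> tuple[Category, Theme, Sentiment]:
    """Rule-based conversation labels.

    Category is INFO_SEEKING when interrogative cues dominate (a question
    mark anywhere, or the post opens with an interrogative); theme comes
    from the first keyword map with a hit (NONE fallback); sentiment is the
    sign of the positive-minus-negative cue count.
    """
    cues = cues or default_cues()
    low = text.casefold().strip()

    seeking = "?" in low or any(low.startswith(op + " ") or low == op for op in cues.seeking_openers)
    category = Category.INFO_SEEKING if seeking else Category.INFO_SHARING

    theme = Theme.NONE
    for t in cues.theme_order:
        if any(c in low for c in cues.theme_cues.get(t, ())):
            theme = t
            break

    score = _count_cues(low, cues.positive) - _count_cues(low, cues.negative)
    sentiment = (
        Sentiment.POSITIVE if score > 0 else Sentiment.NEGATIVE if score < 0 else Sentiment.NEUTRAL
    )
    return category, theme, sentiment


# ---------------------------------------------------------------------------
# corpus-level annotation and manual overrides

def annotate_corpus(
    posts: list[Post],
    lexicon: Lexicon,
    grammar: Grammar | None = None,
    max_edit: int = 0,
    cues: Cues | None = None,
    window_days: int = DEDUP_WINDOW_DAYS,
) -> dict[str, PostAnnotation]:
    """Annotate every post: mentions -> relevance -> switches -> labels.

    Returns annotations keyed by post_id.  Switch detection runs only on
    relevant posts (the spam/duplicate filter gates it).
    """
    grammar = grammar or Grammar.load()
    cues = cues or default_cues()
    rel = RelevanceFilter(window_days=window_days, cues=cues)
    out: dict[str, PostAnnotation] = {}
    for post in sorted(posts, key=lambda p: (p.timestamp, p.post_id)):
        mentions = match_mentions(post.text, lexicon, max_edit=max_edit, post_id=post.post_id)
        relevant = rel.classify(post, mentions)
        switches = (
            detect_switches(post, mentions, grammar, lexicon, cues=cues) if relevant else []
        )
        category, theme, sentiment = classify_category_theme_sentiment(post.text, cues=cues)
        out[post.post_id] = PostAnnotation(
            post_id=post.post_id,
            relevant=relevant,
            category=category,
            theme=theme,
            sentiment=sentiment,
            switches=switches,
        )
    return out


_OVERRIDE_FIELDS = {"relevant", "category", "theme", "sentiment", "reason"}


def apply_overrides(
    annotations: dict[str, PostAnnotation],
    overrides: list[dict] | str | Path,
) -> dict[str, PostAnnotation]:
    """Apply manual-review overrides field-wise; provenance becomes MANUAL.

    ``overrides`` is a list of records (or a JSONL path), each keyed by
    ``post_id`` plus any of relevant/category/theme/sentiment/reason.  A
    ``reason`` override rewrites the reason of every switch in the post.
    Unknown post ids are skipped with a warning; illegal labels raise.
    """
    if not isinstance(overrides, list):
        records = []
        with open(overrides, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
        overrides = records
    for rec in overrides:
        pid = rec.get("post_id")
        if pid not in annotations:
            log.warning("override for unknown post_id %r skipped", pid)
            continue
        ann = annotations[pid]
        unknown = set(rec) - _OVERRIDE_FIELDS - {"post_id"}
        if unknown:
            raise ValueError(f"unknown override fields {sorted(unknown)} for post {pid}")
        if "relevant" in rec:
            if not isinstance(rec["relevant"], bool):
                raise ValueError(f"relevant override must be boolean for post {pid}")
            ann.relevant = rec["relevant"]
        if "category" in rec:
            ann.category = Category[rec["category"]]
        if "theme" in rec:
            ann.theme = Theme[rec["theme"]]
        if "sentiment" in rec:
            ann.sentiment = Sentiment[rec["sentiment"]]
        if "reason" in rec:
            reason = Reason[rec["reason"]]
            ann.switches = [replace(s, reason=reason) for s in ann.switches]
        ann.provenance = "MANUAL"
    return annotations


def annotations_to_jsonl(annotations: dict[str, PostAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(annotations):
            fh.write(json.dumps(annotations[pid].to_record(), sort_keys=True))
            fh.write("\n")
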