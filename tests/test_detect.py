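"""Switch-pattern grammar, reason precedence, labels, relevance, overrides."""

from datetime import datetime, timedelta, timezone

import pytest

from switchminer.detect import (
    Category,
    PostAnnotation,
    Reason,
    RelevanceFilter,
    Sentiment,
    SwitchEvent,
    Theme,
    annotate_corpus,
    apply_overrides,
    classify_category_theme_sentiment,
    classify_reason,
    classify_relevance,
    detect_switches,
)
from switchminer.lexicon import DrugClass, match_mentions
from switchminer.synth import CorpusConfig, generate_corpus

from conftest import make_post


def detect_on(text, lexicon, grammar, max_edit=0):
    post = make_post(text)
    mentions = match_mentions(text, lexicon, max_edit=max_edit, post_id=post.post_id)
    return detect_switches(post, mentions, grammar, lexicon)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("I switched from Copaxone to Tecfidera last month", [("Copaxone", "Tecfidera")]),
        ("Moving from Avonex to Gilenya next week", [("Avonex", "Gilenya")]),
        ("Stopping Tysabri, starting Aubagio tomorrow", [("Tysabri", "Aubagio")]),
        ("Switched to Tecfidera from Rebif", [("Rebif", "Tecfidera")]),  # direction from rule
        ("Finally went from Betaseron to Gilenya", [("Betaseron", "Gilenya")]),
        ("Replaced Extavia with Tecfidera", [("Extavia", "Tecfidera")]),
        ("I love Tecfidera", []),
        ("Copaxone and Gilenya are both options", []),
        ("Weighing Copaxone against Tecfidera, tough call", []),
        (
            "I switched from Copaxone to Tecfidera and then switched from Tecfidera to Tysabri",
            [("Copaxone", "Tecfidera"), ("Tecfidera", "Tysabri")],
        ),
    ],
)
def test_pattern_grammar_directions(lexicon, grammar, text, expected):
    events = detect_on(text, lexicon, grammar)
    assert [(e.from_drug, e.to_drug) for e in events] == expected


def test_event_classes_follow_lexicon(lexicon, grammar):
    [event] = detect_on("stopping Tysabri, starting Aubagio because of side effects",
                        lexicon, grammar)
    assert (event.from_class, event.to_class) == (DrugClass.IV, DrugClass.ORAL)
    assert event.reason is Reason.SIDE_EFFECTS
    assert event.pattern_id == "stop_start"


def test_one_event_per_ordered_pair(lexicon, grammar):
    # two rules could fire on the same pair; only the higher-priority one counts
    text = "I switched from Copaxone to Tecfidera, yes switched from Copaxone to Tecfidera"
    events = detect_on(text, lexicon, grammar)
    assert len(events) == 1


def test_self_switch_never_emitted(lexicon, grammar):
    assert detect_on("I switched from Gilenya to Gilenya", lexicon, grammar) == []


@pytest.mark.parametrize(
    "clause, expected",
    [
        ("because the shots gave me horrible site reactions", Reason.SIDE_EFFECTS),
        ("because my neurologist recommended it", Reason.PHYSICIAN_ADVICE),
        ("since it's easier to take", Reason.EASE_OF_USE),
        ("because my insurance stopped covering it", Reason.INSURANCE),
        ("because the copay was crazy expensive", Reason.COST),
        ("for personal reasons", Reason.OTHER),
        ("just felt like a change", Reason.UNSPECIFIED),
    ],
)
def test_reason_cue_map(clause, expected):
    text = f"I switched from Copaxone to Tecfidera {clause}"
    assert classify_reason(text) is expected


def test_reason_precedence_prefers_more_frequent_category():
    # side effects outranks physician advice when both cues are present
    text = "I switched because of side effects and because my doctor said so"
    assert classify_reason(text) is Reason.SIDE_EFFECTS


def test_reason_window_is_the_anchor_sentence():
    text = "Switched from Copaxone to Tecfidera. My insurance is great by the way."
    anchor = text.index("Tecfidera")
    assert classify_reason(text, anchor=anchor) is Reason.UNSPECIFIED


@pytest.mark.parametrize(
    "text, expected",
    [
        ("Has anyone tried Gilenya?", (Category.INFO_SEEKING, Theme.NONE, Sentiment.NEUTRAL)),
        ("Tecfidera works great for me", (Category.INFO_SHARING, Theme.EFFICACY, Sentiment.POSITIVE)),
        ("", (Category.INFO_SHARING, Theme.NONE, Sentiment.NEUTRAL)),
        ("The copay is so expensive", (Category.INFO_SHARING, Theme.COST, Sentiment.NEGATIVE)),
        ("why is this flaring up again", (Category.INFO_SEEKING, Theme.NONE, Sentiment.NEUTRAL)),
    ],
)
def test_category_theme_sentiment_rules(text, expected):
    assert classify_category_theme_sentiment(text) == expected


# ---------------------------------------------------------------------------
# relevance

def test_relevance_requires_a_mention(lexicon):
    post = make_post("feeling fine today")
    assert classify_relevance(post, match_mentions(post.text, lexicon)) is False
    post2 = make_post("Copaxone day, feeling fine")
    assert classify_relevance(post2, match_mentions(post2.text, lexicon)) is True


def test_spam_posts_are_irrelevant(lexicon):
    post = make_post("buy Gilenya cheap online, click here http://x.example")
    assert classify_relevance(post, match_mentions(post.text, lexicon)) is False


def test_duplicate_text_same_author_within_window(lexicon):
    filt = RelevanceFilter()
    t0 = datetime(2014, 3, 1, tzinfo=timezone.utc)
    first = make_post("Copaxone day", post_id="a", when=t0)
    dup = make_post("Copaxone day", post_id="b", when=t0 + timedelta(hours=4))
    later = make_post("Copaxone day", post_id="c", when=t0 + timedelta(days=30))
    other = make_post("Copaxone day", post_id="d", author="u2", when=t0)
    m = match_mentions("Copaxone day", lexicon)
    assert filt.classify(first, m) is True
    assert filt.classify(dup, m) is False        # same author, same day
    assert filt.classify(later, m) is True       # outside the window
    assert filt.classify(other, m) is True       # different author


# ---------------------------------------------------------------------------
# overrides

def _small_annotations(lexicon, grammar):
    posts, _ = generate_corpus(
        CorpusConfig(seed=2, n_posts_per_platform={"twitter": 120}, switch_rate=0.3)
    )
    return posts, annotate_corpus(posts, lexicon, grammar)


def test_override_reason_shifts_reason_table_by_one(lexicon, grammar):
    from switchminer.aggregate import reason_frequencies

    posts, ann = _small_annotations(lexicon, grammar)
    pid = next(
        p for p in sorted(ann) if ann[p].switches and ann[p].switches[0].reason is not Reason.COST
    )
    before = reason_frequencies([s for a in ann.values() for s in a.switches])
    n_cost_before = before.counts.get(Reason.COST, 0)
    apply_overrides(ann, [{"post_id": pid, "reason": "COST"}])
    after = reason_frequencies([s for a in ann.values() for s in a.switches])
    assert after.counts[Reason.COST] == n_cost_before + len(ann[pid].switches)
    assert ann[pid].provenance == "MANUAL"


def test_empty_overrides_change_nothing(lexicon, grammar):
    _, ann = _small_annotations(lexicon, grammar)
    snapshot = {k: v.to_record() for k, v in ann.items()}
    apply_overrides(ann, [])
    assert {k: v.to_record() for k, v in ann.items()} == snapshot


def test_override_unknown_post_id_is_skipped_with_warning(lexicon, grammar, caplog):
    _, ann = _small_annotations(lexicon, grammar)
    with caplog.at_level("WARNING"):
        apply_overrides(ann, [{"post_id": "nope", "sentiment": "POSITIVE"}])
    assert "unknown post_id" in caplog.text


def test_override_illegal_label_raises(lexicon, grammar):
    _, ann = _small_annotations(lexicon, grammar)
    pid = sorted(ann)[0]
    with pytest.raises(KeyError):
        apply_overrides(ann, [{"post_id": pid, "reason": "BOREDOM"}])
    with pytest.raises(ValueError):
        apply_overrides(ann, [{"post_id": pid, "mood": "HAPPY"}])


def test_switch_events_imply_relevance(lexicon, grammar):
    posts, ann = _small_annotations(lexicon, grammar)
    for a in ann.values():
        if a.switches:
            assert a.relevant


def test_self_switch_construction_rejected():
    with pytest.raises(ValueError):
        SwitchEvent("p", "Gilenya", "Gilenya", DrugClass.ORAL, DrugClass.ORAL, "x")
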