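"""Lexicon loading and mention matching, including the brute-force oracle."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from switchminer.lexicon import (
    DrugClass,
    DrugEntry,
    Lexicon,
    LexiconError,
    load_lexicon,
    match_mentions,
)


# ---------------------------------------------------------------------------
# reference edit distance (independent of edlib)

def levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_mentions(text, lexicon, max_edit):
    """Reference matcher: position scan for exact surfaces (leftmost, longest
    at each position), then token-by-token edit-distance comparison."""
    surfaces = sorted(lexicon.surface_map, key=len, reverse=True)
    bound = r"[A-Za-z0-9'-]"
    out = []
    low = text.casefold()
    i = 0
    while i < len(low):
        hit = None
        for s in surfaces:
            if low.startswith(s, i):
                before_ok = i == 0 or not re.match(bound, low[i - 1])
                after = i + len(s)
                after_ok = after == len(low) or not re.match(bound, low[after])
                if before_ok and after_ok:
                    hit = s
                    break
        if hit:
            out.append((lexicon.surface_map[hit], i, i + len(hit),
                        hit in lexicon.alias_surfaces))
            i += len(hit)
        else:
            i += 1
    if max_edit > 0:
        covered = [(s, e) for _, s, e, _ in out]
        for tok in re.finditer(r"[A-Za-z](?:[A-Za-z'-]*[A-Za-z])?", text):
            s, e = tok.span()
            if any(s < ce and cs < se for cs, ce in covered for se in [e]):
                continue
            word = tok.group(0).casefold()
            if len(word) < 5 or word in lexicon.surface_map:
                continue
            from switchminer.lexicon import _FUZZY_STOPLIST
            if word in _FUZZY_STOPLIST:
                continue
            best, brands = max_edit + 1, set()
            for surf, brand in lexicon.fuzzy_surfaces.items():
                d = levenshtein(word, surf)
                if d < best:
                    best, brands = d, {brand}
                elif d == best:
                    brands.add(brand)
            if len(brands) == 1 and best <= max_edit:
                out.append((brands.pop(), s, e, True))
    return sorted(out, key=lambda t: (t[1], t[2]))


# ---------------------------------------------------------------------------

def test_default_lexicon_has_ten_drugs_in_three_classes(lexicon):
    assert len(lexicon) == 10
    counts = lexicon.class_counts()
    assert counts[DrugClass.ORAL] == 3
    assert counts[DrugClass.INJECTABLE] == 5
    assert counts[DrugClass.IV] == 2


def test_empty_lexicon_file_warns(tmp_path, caplog):
    path = tmp_path / "lex.csv"
    path.write_text("brand,generic,class,aliases\n")
    with caplog.at_level("WARNING"):
        lex = load_lexicon(path)
    assert len(lex) == 0
    assert "empty" in caplog.text


def test_cross_brand_alias_collision_rejected(tmp_path):
    path = tmp_path / "lex.csv"
    path.write_text(
        "brand,generic,class,aliases\n"
        "Gilenya,fingolimod,ORAL,gilenia\n"
        "Aubagio,teriflunomide,ORAL,gilenia\n"
    )
    with pytest.raises(LexiconError, match="gilenia"):
        load_lexicon(path)


def test_unknown_class_label_rejected(tmp_path):
    path = tmp_path / "lex.csv"
    path.write_text("brand,generic,class,aliases\nGilenya,fingolimod,TOPICAL,\n")
    with pytest.raises(LexiconError, match="TOPICAL"):
        load_lexicon(path)


def test_ambiguous_generics_do_not_match(lexicon):
    # interferon beta-1a belongs to two brands and must resolve to neither
    assert match_mentions("starting interferon beta-1a", lexicon) == []
    # unambiguous generics normalize to the brand
    [m] = match_mentions("on dimethyl fumarate now", lexicon)
    assert m.brand == "Tecfidera" and m.fuzzy is False


def test_exact_mentions_with_spans(lexicon):
    text = "I switched from Copaxone to Gilenya"
    mentions = match_mentions(text, lexicon)
    assert [(m.brand, m.start, m.end) for m in mentions] == [
        ("Copaxone", text.index("Copaxone"), text.index("Copaxone") + 8),
        ("Gilenya", text.index("Gilenya"), text.index("Gilenya") + 7),
    ]
    for m in mentions:
        assert text[m.start:m.end].casefold() == m.surface.casefold()


def test_empty_text_yields_no_mentions(lexicon):
    assert match_mentions("", lexicon) == []
    assert match_mentions("no drugs here at all", lexicon) == []


@pytest.fixture(scope="module")
def bare_lexicon():
    """Lexicon without aliases, so misspellings can only match fuzzily."""
    entries = [
        DrugEntry(e.brand, e.generic, e.drug_class, frozenset())
        for e in load_lexicon().entries
    ]
    return Lexicon(entries)


def test_fuzzy_match_unique_nearest_brand(bare_lexicon):
    # oracle: gilenia is at distance 1 from Gilenya and >1 from all others
    dists = {
        e.brand: levenshtein("gilenia", e.brand.lower()) for e in bare_lexicon.entries
    }
    assert dists["Gilenya"] == 1 and all(d > 1 for b, d in dists.items() if b != "Gilenya")
    [m] = match_mentions("starting gilenia next week", bare_lexicon, max_edit=1)
    assert m.brand == "Gilenya" and m.fuzzy is True


def test_fuzzy_disabled_at_zero_edit(bare_lexicon):
    assert match_mentions("starting gilenia next week", bare_lexicon, max_edit=0) == []


def test_exact_match_beats_fuzzy(lexicon):
    # "Rebif" is exact; it must never be reassigned by a fuzzy competitor
    mentions = match_mentions("moving to Rebif", lexicon, max_edit=1)
    assert [(m.brand, m.fuzzy) for m in mentions] == [("Rebif", False)]


def test_alias_match_is_flagged_fuzzy(lexicon):
    [m] = match_mentions("starting gilenia next week", lexicon, max_edit=0)
    assert m.brand == "Gilenya" and m.fuzzy is True


def test_short_and_stoplisted_tokens_never_match_fuzzily(bare_lexicon):
    # 'rebi' is distance 1 from Rebif but below the length-5 floor
    assert match_mentions("rebi is short", bare_lexicon, max_edit=1) == []
    # common words are stoplisted even if some surface were close
    assert match_mentions("think about doctor", bare_lexicon, max_edit=1) == []


def test_negative_max_edit_rejected(lexicon):
    with pytest.raises(ValueError):
        match_mentions("text", lexicon, max_edit=-1)


def test_matching_is_deterministic(lexicon):
    text = "stopping Tysabri, starting aubagio because of gilenia"
    a = match_mentions(text, lexicon, max_edit=1)
    b = match_mentions(text, lexicon, max_edit=1)
    assert a == b


_WORDS = st.sampled_from(
    ["i", "am", "taking", "the", "copaxone", "Gilenya", "tecfidera", "tysabri",
     "gilenia", "tecfidara", "avonex", "rebif", "tablet", "needle", "nurse",
     "mri", "flare", "fatigue", "walk", "well-being", "copaxon", "tysabry",
     "aubagio", "betaseron", "novantrone", "extavia", "dimethyl", "fumarate"]
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(_WORDS, min_size=0, max_size=12), st.integers(min_value=0, max_value=1))
def test_matcher_equals_brute_force_oracle(lexicon, words, max_edit):
    """Regex+edlib matcher agrees with a pure-Python position/token scan."""
    text = " ".join(words)[:200]
    got = [(m.brand, m.start, m.end, m.fuzzy) for m in match_mentions(text, lexicon, max_edit)]
    assert got == brute_force_mentions(text, lexicon, max_edit)
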