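"""Drug lexicon and mention matching.

The study drugs are the multiple-sclerosis disease-modifying therapies
available on the US market in 2013-2014, grouped into three routes of
administration: three orals (Tecfidera, Gilenya, Aubagio), the five
injectable BRACE therapies (Betaseron, Rebif, Avonex, Copaxone, Extavia)
and two IV infusions (Tysabri, Novantrone).  Brand names act as proxies
for the class; generic names normalize to the brand.  Patient spelling is
noisy, so matching combines a curated alias/misspelling list with
optional bounded-edit-distance (Levenshtein) fuzzy matching on tokens.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import edlib

log = logging.getLogger(__name__)

__all__ = [
    "DrugClass",
    "DrugEntry",
    "DrugMention",
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "default_lexicon_path",
    "match_mentions",
]


class DrugClass(str, Enum):
    """Route-of-administration class of a disease-modifying therapy."""

    ORAL = "ORAL"
    INJECTABLE = "INJECTABLE"
    IV = "IV"


@dataclass(frozen=True)
class DrugEntry:
    """One lexicon record: canonical brand, generic, class and alternate surfaces."""

    brand: str
    generic: str
    drug_class: DrugClass
    aliases: frozenset[str]


@dataclass(frozen=True)
class DrugMention:
    """A located drug occurrence in a post.

    ``start``/``end`` are a 0-based half-open character interval into the
    post text; ``surface`` is the matched substring; ``fuzzy`` is True when
    the match came from an alias/misspelling or edit distance rather than
    the exact brand or generic.
    """

    post_id: str
    brand: str
    start: int
    end: int
    surface: str
    fuzzy: bool = False


class LexiconError(ValueError):
    """Raised when a lexicon file violates a structural invariant."""


# Frequent English words that fuzzy matching must never touch, plus a few
# MS-conversation words that sit close to nothing but could still be noisy.
_FUZZY_STOPLIST = frozenset(
    """about above after again other their there these those which while would
    could should think thing things going doing taking makes wanted started
    starting stopped stopping switch switched moving month months years today
    because people really still since being every never always where three
    great avenue review relief between before under might first hello world
    thanks right place sound found friend doctor nurse tablet needle""".split()
)

# Tokens: letters with internal hyphens/apostrophes (URL/handle fragments
# containing digits or other symbols never form a token).
_TOKEN_RE = re.compile(r"[A-Za-z](?:[A-Za-z'-]*[A-Za-z])?")
_BOUND_L = r"(?<![A-Za-z0-9'-])"
_BOUND_R = r"(?![A-Za-z0-9'-])"


class Lexicon:
    """Validated set of :class:`DrugEntry` with derived matching tables."""

    def __init__(self, entries: list[DrugEntry]):
        self.entries: tuple[DrugEntry, ...] = tuple(entries)
        self._by_brand: dict[str, DrugEntry] = {}
        for e in self.entries:
            key = e.brand.casefold()
            if key in self._by_brand:
                raise LexiconError(f"duplicate brand: {e.brand!r}")
            self._by_brand[key] = e

        # surface (casefolded) -> brand, for exact matching
        surface_map: dict[str, str] = {}
        owners: dict[str, set[str]] = {}

        def claim(surface: str, brand: str, kind: str) -> None:
            s = surface.casefold().strip()
            if not s:
                return
            owners.setdefault(s, set()).add(brand)
            prev = surface_map.get(s)
            if prev is not None and prev != brand:
                if kind == "generic":
                    return  # resolved below: ambiguous generics are dropped
                raise LexiconError(
                    f"surface {surface!r} maps to both {prev!r} and {brand!r}"
                )
            surface_map[s] = brand

        generic_surfaces: dict[str, set[str]] = {}
        for e in self.entries:
            claim(e.brand, e.brand, "brand")
            generic_surfaces.setdefault(e.generic.casefold().strip(), set()).add(e.brand)
        for e in self.entries:
            for a in e.aliases:
                claim(a, e.brand, "alias")
        for g, brands in generic_surfaces.items():
            if not g:
                continue
            if len(brands) > 1:
                log.warning(
                    "generic %r is shared by %s; excluded from matching",
                    g,
                    sorted(brands),
                )
                continue
            (brand,) = brands
            prev = surface_map.get(g)
            if prev is not None and prev != brand:
                raise LexiconError(
                    f"generic {g!r} collides with a surface of {prev!r}"
                )
            surface_map[g] = brand

        self.surface_map = surface_map
        # alias surfaces carry fuzzy=True on match (non-canonical spelling)
        canonical = {e.brand.casefold() for e in self.entries} | {
            e.generic.casefold() for e in self.entries
        }
        self.alias_surfaces: set[str] = {
            a.casefold() for e in self.entries for a in e.aliases
        } - canonical
        # fuzzy candidates: single-token brand and alias surfaces (not generics)
        brand_alias: set[str] = set()
        for e in self.entries:
            brand_alias.add(e.brand.casefold())
            brand_alias.update(a.casefold() for a in e.aliases)
        self.fuzzy_surfaces: dict[str, str] = {
            s: b for s, b in surface_map.items() if " " not in s and s in brand_alias
        }

        if surface_map:
            alts = sorted(surface_map, key=len, reverse=True)
            pat = "|".join(re.escape(s).replace(r"\ ", r"\s+") for s in alts)
            self._exact_re: re.Pattern | None = re.compile(
                _BOUND_L + "(?:" + pat + ")" + _BOUND_R, re.IGNORECASE
            )
        else:
            self._exact_re = None
        self._fuzzy_cache: dict[tuple[str, int], str | None] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __contains__(self, brand: str) -> bool:
        return brand.casefold() in self._by_brand

    def entry(self, brand: str) -> DrugEntry:
        return self._by_brand[brand.casefold()]

    def drug_class(self, brand: str) -> DrugClass:
        return self.entry(brand).drug_class

    def class_counts(self) -> dict[DrugClass, int]:
        out: dict[DrugClass, int] = {c: 0 for c in DrugClass}
        for e in self.entries:
            out[e.drug_class] += 1
        return out

    def brands_in_class(self, drug_class: DrugClass) -> list[str]:
        return [e.brand for e in self.entries if e.drug_class == drug_class]

    def _fuzzy_lookup(self, token: str, max_edit: int) -> str | None:
        """Unique brand within ``max_edit`` of ``token``, or None."""
        key = (token, max_edit)
        if key in self._fuzzy_cache:
            return self._fuzzy_cache[key]
        best_d = max_edit + 1
        best_brands: set[str] = set()
        for surface, brand in self.fuzzy_surfaces.items():
            if abs(len(surface) - len(token)) > max_edit:
                continue
            d = edlib.align(token, surface, task="distance")["editDistance"]
            if d < best_d:
                best_d, best_brands = d, {brand}
            elif d == best_d:
                best_brands.add(brand)
        result = best_brands.pop() if len(best_brands) == 1 else None
        self._fuzzy_cache[key] = result
        return result


def default_lexicon_path() -> Path:
    """Path of the lexicon shipped with the package (the ten study drugs)."""
    return Path(str(resources.files("switchminer") / "data" / "lexicon.csv"))


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load and validate a lexicon CSV (columns brand, generic, class, aliases).

    Aliases are pipe-separated within the cell.  Raises :class:`LexiconError`
    on duplicate brands, cross-brand alias collisions or unknown class labels.
    An empty file yields an empty lexicon with a warning.
    """
    path = Path(path) if path is not None else default_lexicon_path()
    entries: list[DrugEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
        if reader.fieldnames is not None:
            missing = {"brand", "generic", "class", "aliases"} - set(reader.fieldnames)
            if missing:
                raise LexiconError(f"lexicon missing columns: {sorted(missing)}")
    for row in rows:
        cls = row["class"].strip().upper()
        if cls not in DrugClass.__members__:
            raise LexiconError(f"unknown drug class {row['class']!r} for {row['brand']!r}")
        aliases = frozenset(
            a.strip() for a in row["aliases"].split("|") if a.strip()
        )
        entries.append(
            DrugEntry(
                brand=row["brand"].strip(),
                generic=row["generic"].strip(),
                drug_class=DrugClass[cls],
                aliases=aliases,
            )
        )
    if not entries:
        log.warning("lexicon %s is empty", path)
    return Lexicon(entries)


def match_mentions(
    text: str,
    lexicon: Lexicon,
    max_edit: int = 0,
    post_id: str = "",
) -> list[DrugMention]:
    """Find all drug mentions in ``text``, ordered by span start.

    Exact matches (brand, unambiguous generic, alias) are found first, on
    word-token boundaries, case-insensitively, longest surface preferred.
    When ``max_edit > 0``, remaining tokens of length >= 5 that are not on
    the common-word stoplist are matched fuzzily against single-token brand
    and alias surfaces; a fuzzy match is emitted only when a unique brand
    attains the minimum distance within ``max_edit``.
    """
    if max_edit < 0:
        raise ValueError("max_edit must be nonnegative")
    if not text or lexicon._exact_re is None:
        return []

    mentions: list[DrugMention] = []
    covered: list[tuple[int, int]] = []
    for m in lexicon._exact_re.finditer(text):
        surface = m.group(0)
        key = re.sub(r"\s+", " ", surface.casefold())
        brand = lexicon.surface_map[key]
        mentions.append(
            DrugMention(post_id=post_id, brand=brand, start=m.start(), end=m.end(),
                        surface=surface, fuzzy=key in lexicon.alias_surfaces)
        )
        covered.append((m.start(), m.end()))

    if max_edit > 0:
        for tok in _TOKEN_RE.finditer(text):
            s, e = tok.span()
            if any(s < ce and cs < e for cs, ce in covered):
                continue
            word = tok.group(0)
            if len(word) < 5:
                continue
            low = word.casefold()
            if low in _FUZZY_STOPLIST or low in lexicon.surface_map:
                continue
            brand = lexicon._fuzzy_lookup(low, max_edit)
            if brand is not None:
                mentions.append(
                    DrugMention(post_id=post_id, brand=brand, start=s, end=e,
                                surface=word, fuzzy=True)
                )

    mentions.sort(key=lambda m: (m.start, m.end))
    return mentions
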