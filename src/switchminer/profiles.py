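"""Per-author demographics from self-declared text and record fields.

Social-media users occasionally state their age, sex, diagnosis year and
location in their posts or account fields.  These declarations are pulled
out with small regular-expression patterns and a US-state/country
gazetteer, resolved per author by the most recent declaration, and used
for the population-inclusion filter (US residents only for the switchover
stream) and the demographic summary tables.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dfield
from datetime import datetime
from importlib import resources
from pathlib import Path

from .corpus import Post

UNKNOWN = "UNKNOWN"

#: Age-bin edges for the demographic tables: <20, 20-29, ..., 60-69, >=70.
AGE_BINS: list[tuple[str, int, int]] = [
    ("<20", 0, 20),
    ("20-29", 20, 30),
    ("30-39", 30, 40),
    ("40-49", 40, 50),
    ("50-59", 50, 60),
    ("60-69", 60, 70),
    (">70", 70, 200),
]

#: Disease-duration bins (years, half-open upper edges): 0-6 mo, 6-12 mo,
#: 1-3 y = [1,4), 4-8 y = [4,9), 9-10 y = [9,11), >10 y = [11, inf).
YSD_BINS: list[tuple[str, float, float]] = [
    ("0-6 months", 0.0, 0.5),
    ("6-12 months", 0.5, 1.0),
    ("1-3 years", 1.0, 4.0),
    ("4-8 years", 4.0, 9.0),
    ("9-10 years", 9.0, 11.0),
    (">10 years", 11.0, float("inf")),
]


def age_bin(age: int) -> str:
    for label, lo, hi in AGE_BINS:
        if lo <= age < hi:
            return label
    raise ValueError(f"age out of range: {age}")


def ysd_bin(ysd: float) -> str:
    for label, lo, hi in YSD_BINS:
        if lo <= ysd < hi:
            return label
    raise ValueError(f"duration out of range: {ysd}")


@dataclass
class PatientProfile:
    author_key: str
    sex: str = UNKNOWN  # "F" / "M" / UNKNOWN
    age: int | str = UNKNOWN
    years_since_diagnosis: float | str = UNKNOWN
    country: str = UNKNOWN  # ISO alpha-2 or UNKNOWN
    platforms: set[str] = dfield(default_factory=set)
    n_posts: int = 0


# ---------------------------------------------------------------------------
# declaration patterns

_AGE_PATTERNS = [
    re.compile(r"\bI'?\s?m\s+(\d{1,3})\b(?!\s*(?:%|percent|months?|weeks?))", re.IGNORECASE),
    re.compile(r"\bI\s+am\s+(\d{1,3})\b(?!\s*(?:%|percent|months?|weeks?))", re.IGNORECASE),
    re.compile(r"\b(\d{1,3})\s*(?:yo|y/o)\b", re.IGNORECASE),
    re.compile(r"\bage\s+(\d{1,3})\b", re.IGNORECASE),
    re.compile(r"\b(\d{1,3})\s+years\s+old\b", re.IGNORECASE),
]

_DX_AGO = re.compile(
    r"\b(?:diagnosed|dx(?:'?d)?)\s+(?:about\s+|over\s+)?(\d{1,3})\s+(year|month)s?\s+ago\b",
    re.IGNORECASE,
)
_DX_YEAR = re.compile(r"\b(?:diagnosed|dx(?:'?d)?)\s+(?:in\s+)?((?:19|20)\d{2})\b", re.IGNORECASE)

_FEMALE_CUES = ["i'm a woman", "i am a woman", "i'm a girl", "as a mom", "as a mother",
                "as a wife", "my husband"]
_MALE_CUES = ["i'm a man", "i am a man", "i'm a guy", "as a dad", "as a father",
              "as a husband", "my wife"]

_LOCATION_TEXT = re.compile(
    r"\b(?:i live in|living in|located in)\s+([A-Za-z][A-Za-z ,.]*?)(?:[.!?]|$)", re.IGNORECASE
)


def _load_gazetteer() -> dict:
    with (resources.files("switchminer") / "data" / "gazetteer.json").open(encoding="utf-8") as fh:
        return json.load(fh)


_GAZ = _load_gazetteer()
_STATE_ABBREVS = {v.casefold() for v in _GAZ["us_states"].values()}


def resolve_country(location: str) -> str:
    """Map a free-text location string to an ISO country code via the gazetteer.

    US state names and abbreviations resolve to ``US``; unrecognized
    strings resolve to UNKNOWN (conservative: never guessed).
    """
    low = location.casefold().strip().strip(".")
    if not low:
        return UNKNOWN
    if low in _GAZ["countries"]:
        return _GAZ["countries"][low]
    if low in _GAZ["us_states"] or low in _STATE_ABBREVS:
        return "US"
    # try comma-separated parts, last first ("Austin, TX"; "London, UK")
    parts = [p.strip().strip(".") for p in low.split(",")]
    for part in reversed(parts):
        if part in _GAZ["countries"]:
            return _GAZ["countries"][part]
        if part in _GAZ["us_states"] or part in _STATE_ABBREVS:
            return "US"
    # single trailing token ("rural Ohio")
    tokens = low.replace(",", " ").split()
    for tok in reversed(tokens):
        if tok in _GAZ["us_states"] or tok in _STATE_ABBREVS or tok in _GAZ["countries"]:
            return "US" if tok in _GAZ["us_states"] or tok in _STATE_ABBREVS else _GAZ["countries"][tok]
    return UNKNOWN


def _declarations(post: Post) -> dict[str, object]:
    """Field declarations found in one post (text patterns + declared fields)."""
    out: dict[str, object] = {}
    text = post.text

    age = None
    if "age" in post.declared:
        try:
            age = int(post.declared["age"])
        except ValueError:
            age = None
    if age is None:
        for pat in _AGE_PATTERNS:
            m = pat.search(text)
            if m:
                age = int(m.group(1))
                break
    if age is not None and 0 <= age <= 120:
        out["age"] = age

    m = _DX_AGO.search(text)
    if m:
        qty, unit = int(m.group(1)), m.group(2).lower()
        out["ysd"] = qty / 12.0 if unit == "month" else float(qty)
    else:
        m = _DX_YEAR.search(text)
        if m:
            dur = post.timestamp.year - int(m.group(1))
            if dur >= 0:
                out["ysd"] = float(dur)

    sex = post.declared.get("sex", "").strip().upper()[:1]
    if sex in ("F", "M"):
        out["sex"] = sex
    else:
        low = text.casefold()
        f = any(c in low for c in _FEMALE_CUES)
        mm = any(c in low for c in _MALE_CUES)
        if f != mm:
            out["sex"] = "F" if f else "M"

    loc = post.declared.get("location")
    if loc is None:
        m = _LOCATION_TEXT.search(text)
        if m:
            loc = m.group(1)
    if loc:
        country = resolve_country(loc)
        if country != UNKNOWN:
            out["country"] = country

    return out


def extract_profile(author_posts: list[Post]) -> PatientProfile:
    """Resolve one author's profile; conflicts go to the most recent post."""
    if not author_posts:
        raise ValueError("extract_profile requires at least one post")
    keys = {p.author_key for p in author_posts}
    if len(keys) != 1:
        raise ValueError(f"posts span multiple authors: {sorted(keys)}")

    latest: dict[str, tuple[datetime, object]] = {}
    for post in sorted(author_posts, key=lambda p: (p.timestamp, p.post_id)):
        for field_name, value in _declarations(post).items():
            latest[field_name] = (post.timestamp, value)

    profile = PatientProfile(
        author_key=author_posts[0].author_key,
        platforms={p.platform for p in author_posts},
        n_posts=len(author_posts),
    )
    if "sex" in latest:
        profile.sex = str(latest["sex"][1])
    if "age" in latest:
        profile.age = int(latest["age"][1])
    if "ysd" in latest:
        profile.years_since_diagnosis = float(latest["ysd"][1])
    if "country" in latest:
        profile.country = str(latest["country"][1])
    # structural constraint: disease duration cannot exceed age
    if (
        profile.age != UNKNOWN
        and profile.years_since_diagnosis != UNKNOWN
        and profile.years_since_diagnosis > profile.age
    ):
        profile.years_since_diagnosis = UNKNOWN
    return profile


def extract_profiles(posts: list[Post]) -> dict[str, PatientProfile]:
    """One profile per author_key over the whole corpus."""
    by_author: dict[str, list[Post]] = {}
    for p in posts:
        by_author.setdefault(p.author_key, []).append(p)
    return {k: extract_profile(v) for k, v in sorted(by_author.items())}


# ---------------------------------------------------------------------------
# inclusion filter and author dedup

NO_LOCATION = "NO_LOCATION"
NON_US = "NON_US"


def filter_us(
    profiles: dict[str, PatientProfile],
) -> tuple[dict[str, PatientProfile], list[tuple[PatientProfile, str]]]:
    """Partition profiles into US-included and excluded-with-cause.

    The exclusion applies to the switchover analysis stream only; callers
    keep reporting demographics of the full population.
    """
    included: dict[str, PatientProfile] = {}
    excluded: list[tuple[PatientProfile, str]] = []
    for key in sorted(profiles):
        prof = profiles[key]
        if prof.country == "US":
            included[key] = prof
        elif prof.country == UNKNOWN:
            excluded.append((prof, NO_LOCATION))
        else:
            excluded.append((prof, NON_US))
    return included, excluded


def _norm_key(author_key: str) -> str:
    return author_key.casefold().strip()


def dedup_authors(
    profiles: dict[str, PatientProfile],
    posts: list[Post] | None = None,
) -> dict[str, PatientProfile]:
    """Merge profiles whose normalized screen names are exactly equal.

    Deliberately conservative: no fuzzy identity.  Merge unions platforms,
    sums post counts, and resolves conflicting fields by re-extracting from
    the pooled posts when available (most-recent declaration wins),
    otherwise by preferring known over UNKNOWN.
    """
    groups: dict[str, list[PatientProfile]] = {}
    for key in sorted(profiles):
        groups.setdefault(_norm_key(key), []).append(profiles[key])

    by_author_posts: dict[str, list[Post]] = {}
    if posts:
        for p in posts:
            by_author_posts.setdefault(_norm_key(p.author_key), []).append(p)

    merged: dict[str, PatientProfile] = {}
    for norm, profs in groups.items():
        if len(profs) == 1:
            merged[norm] = profs[0]
            continue
        if norm in by_author_posts:
            base = extract_profile(
                [Post(p.post_id, p.platform, p.timestamp, norm, p.text, p.declared)
                 for p in by_author_posts[norm]]
            )
            base.platforms = set().union(*(p.platforms for p in profs))
            base.n_posts = sum(p.n_posts for p in profs)
        else:
            base = PatientProfile(author_key=norm)
            for p in profs:
                base.platforms |= p.platforms
                base.n_posts += p.n_posts
                if base.sex == UNKNOWN:
                    base.sex = p.sex
                if base.age == UNKNOWN:
                    base.age = p.age
                if base.years_since_diagnosis == UNKNOWN:
                    base.years_since_diagnosis = p.years_since_diagnosis
                if base.country == UNKNOWN:
                    base.country = p.country
        merged[norm] = base
    return merged


def profiles_to_csv(profiles: dict[str, PatientProfile], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["author_key", "sex", "age", "years_since_diagnosis", "country", "platforms", "n_posts"]
        )
        for key in sorted(profiles):
            p = profiles[key]
            writer.writerow(
                [p.author_key, p.sex, p.age, p.years_since_diagnosis, p.country,
                 "|".join(sorted(p.platforms)), p.n_posts]
            )
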