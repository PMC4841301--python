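"""Synthetic social-media corpus generator with ground-truth annotations.

The generator emulates the statistical structure of the 2013-2014 US
multiple-sclerosis social-listening dataset the pipeline is designed for:
four platforms with fixed relevant-post volumes, a mostly-female adult
population with the published age and disease-duration mix, switch posts
whose (from-class, to-class) pairs and stated reasons follow the published
shares, plus non-switch drug chatter, spam and off-topic noise.  Posts are
filled from a template bank; every planted fact (mentions, switches,
reasons, labels, author demographics) is recorded as ground truth so the
whole pipeline can be scored without any real data.

All randomness flows from a single ``numpy`` generator keyed by the seed;
draws happen in a fixed documented order, so a seed+config pair always
yields a byte-identical corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import yaml

from .corpus import PLATFORMS, Post
from .detect import (
    DEDUP_WINDOW_DAYS,
    Category,
    Reason,
    Sentiment,
    Theme,
    _normtext,
)
from .lexicon import DrugClass, Lexicon, load_lexicon

# ---------------------------------------------------------------------------
# default study conditions

#: Posts generated per platform.  Chosen so that, at the default relevance
#: rate, expected relevant volumes match the published per-platform counts
#: (8672 / 6919 / 6505 / 791) and the total matches the 25,073 extracted.
DEFAULT_VOLUMES = {"twitter": 9500, "facebook": 7580, "forum": 7126, "blog": 867}

#: Fraction of posts mentioning at least one study drug (22887 / 25073).
DEFAULT_RELEVANCE_RATE = 22887 / 25073

#: Fraction of drug-mentioning posts that report a true switch
#: (1684 switch data points over 22887 relevant posts).
DEFAULT_SWITCH_RATE = 1684 / 22887

#: Default (from_class, to_class) weights.  Built from the mutually
#: consistent published counts: 1114 switches away from injectables (927 to
#: oral), 265 away from IV (259 to oral, 6 to injectable), 1326 switches to
#: oral in total, 1684 overall; the residual 305 from-oral events are split
#: 140 oral->oral / 80 oral->injectable / 85 oral->IV to respect the
#: reported to-oral total and the "no clear preference" description.
DEFAULT_CLASS_PAIR_WEIGHTS: dict[tuple[str, str], float] = {
    ("ORAL", "ORAL"): 140,
    ("ORAL", "INJECTABLE"): 80,
    ("ORAL", "IV"): 85,
    ("INJECTABLE", "ORAL"): 927,
    ("INJECTABLE", "INJECTABLE"): 90,
    ("INJECTABLE", "IV"): 97,
    ("IV", "ORAL"): 259,
    ("IV", "INJECTABLE"): 6,
    ("IV", "IV"): 0,
}

#: Published reason frequencies (n of 1234 reason-classified switches) plus
#: an UNSPECIFIED mass of 450 = 1684 - 1234 switch data points whose reason
#: was never classified.
DEFAULT_REASON_WEIGHTS: dict[str, float] = {
    "SIDE_EFFECTS": 464,
    "LACK_OF_EFFICACY": 310,
    "PHYSICIAN_ADVICE": 193,
    "EASE_OF_USE": 163,
    "QOL_WORSENING": 39,
    "SAFETY_CONCERNS": 38,
    "INSURANCE": 13,
    "COST": 7,
    "OTHER": 7,
    "UNSPECIFIED": 450,
}

#: Demographic marginals: sex share, age bins (half-open, years) and
#: time-since-diagnosis bins (half-open, years) with the published shares;
#: country mix is not published and defaults to a mostly-US split.
DEFAULT_DEMOGRAPHICS = {
    "sex": {"F": 0.7673, "M": 0.2327},
    "age_bins": [
        [13, 20, 0.0049],
        [20, 30, 0.1974],
        [30, 40, 0.2689],
        [40, 50, 0.3832],
        [50, 60, 0.0938],
        [60, 70, 0.0505],
        [70, 90, 0.0013],
    ],
    "ysd_bins": [
        [0.0, 0.5, 0.098],
        [0.5, 1.0, 0.038],
        [1.0, 4.0, 0.200],
        [4.0, 9.0, 0.241],
        [9.0, 11.0, 0.089],
        [11.0, 20.0, 0.335],
    ],
    "country": {
        "US": 0.75,
        "GB": 0.03,
        "CA": 0.03,
        "DE": 0.02,
        "AU": 0.01,
        "FR": 0.01,
        "UNKNOWN": 0.15,
    },
}


@dataclass
class CorpusConfig:
    """Generator configuration; defaults encode the study conditions."""

    seed: int = 0
    n_posts_per_platform: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_VOLUMES))
    relevance_rate: float = DEFAULT_RELEVANCE_RATE
    switch_rate: float = DEFAULT_SWITCH_RATE
    class_pair_weights: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PAIR_WEIGHTS)
    )
    reason_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REASON_WEIGHTS))
    demographics: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_DEMOGRAPHICS)))
    misspell_rate: float = 0.05
    paraphrase_rate: float = 0.10
    spam_rate: float = 0.02
    chain_rate: float = 0.0
    duplicate_author_rate: float = 0.05
    profile_mention_rate: float = 0.6
    posts_per_author_mean: float = 5.85
    date_range: tuple[str, str] = ("2013-10", "2014-10")

    def validate(self) -> None:
        rates = {
            "relevance_rate": self.relevance_rate,
            "switch_rate": self.switch_rate,
            "misspell_rate": self.misspell_rate,
            "paraphrase_rate": self.paraphrase_rate,
            "spam_rate": self.spam_rate,
            "chain_rate": self.chain_rate,
            "duplicate_author_rate": self.duplicate_author_rate,
            "profile_mention_rate": self.profile_mention_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if not self.n_posts_per_platform:
            raise ValueError("at least one platform is required")
        for p, n in self.n_posts_per_platform.items():
            if p not in PLATFORMS:
                raise ValueError(f"unknown platform {p!r}")
            if n <= 0:
                raise ValueError(f"platform {p!r} must have a positive post count")
        if any(w < 0 for w in self.class_pair_weights.values()):
            raise ValueError("class_pair_weights must be nonnegative")
        if any(w < 0 for w in self.reason_weights.values()):
            raise ValueError("reason_weights must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "class_pair_weights" in raw:
            raw["class_pair_weights"] = {
                tuple(k.split("->")): float(v) for k, v in raw["class_pair_weights"].items()
            }
        if "date_range" in raw:
            raw["date_range"] = tuple(raw["date_range"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# ground truth containers

@dataclass
class TruthSwitch:
    from_drug: str
    to_drug: str
    reason: Reason


@dataclass
class PostTruth:
    post_id: str
    relevant: bool
    category: Category
    theme: Theme
    sentiment: Sentiment
    switches: list[TruthSwitch] = field(default_factory=list)


@dataclass
class AuthorTruth:
    author_key: str
    sex: str  # "F" / "M"
    age: int
    ysd: float  # years since diagnosis (quantized to what the text declares)
    country: str  # ISO code or "UNKNOWN"
    platforms: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    posts: dict[str, PostTruth] = field(default_factory=dict)
    authors: dict[str, AuthorTruth] = field(default_factory=dict)

    def switch_events(self) -> list[tuple[str, str, str, Reason]]:
        """All planted events as (post_id, from_drug, to_drug, reason)."""
        out = []
        for pid in sorted(self.posts):
            for s in self.posts[pid].switches:
                out.append((pid, s.from_drug, s.to_drug, s.reason))
        return out

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        with open(out_dir / "truth_posts.jsonl", "w", encoding="utf-8") as fh:
            for pid in sorted(self.posts):
                t = self.posts[pid]
                rec = {
                    "post_id": t.post_id,
                    "relevant": t.relevant,
                    "category": t.category.value,
                    "theme": t.theme.value,
                    "sentiment": t.sentiment.value,
                    "switches": [
                        {"from_drug": s.from_drug, "to_drug": s.to_drug, "reason": s.reason.value}
                        for s in t.switches
                    ],
                }
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        with open(out_dir / "truth_authors.jsonl", "w", encoding="utf-8") as fh:
            for key in sorted(self.authors):
                fh.write(json.dumps(asdict(self.authors[key]), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# template bank

_TIME_FILLERS = ["last month", "today", "this week", "last year", "yesterday"]

# Detectable switch families mirror the three core keyword-pattern families;
# the "paraphrase" family is deliberately outside the shipped grammar's
# coverage so detection tests can separate pattern coverage from noise.
_SWITCH_TEMPLATES = {
    "switch": [
        "I switched from {A} to {B} {time}",
        "Just switched over from {A} to {B}",
        "Finally switched from {A} over to {B}",
    ],
    "move": [
        "I'm moving from {A} to {B} {time}",
        "Moved from {A} to {B} in January",
        "We are moving from {A} to {B} soon",
    ],
    "stop_start": [
        "Stopping {A}, starting {B}",
        "I stopped {A} and started {B} {time}",
        "Stopped {A} then started on {B}",
    ],
    "paraphrase": [
        "My neuro took me off {A}, now I'm on {B}",
        "Done with {A}; {B} is next for me",
        "After years on {A} I am now on {B}",
    ],
}
DETECTABLE_FAMILIES = ("switch", "move", "stop_start")

_CHAIN_TEMPLATE = "I switched from {A} to {B} and then switched from {B} to {C}"

# (clause, theme, sentiment) per reason; the labels are the hand-traced
# output of the shipped cue lexicons on the clause text.
_REASON_CLAUSES: dict[Reason, list[tuple[str, Theme, Sentiment]]] = {
    Reason.SIDE_EFFECTS: [
        ("because of the horrible side effects", Theme.SIDE_EFFECTS, Sentiment.NEGATIVE),
        ("because the side effects were unbearable", Theme.SIDE_EFFECTS, Sentiment.NEGATIVE),
    ],
    Reason.LACK_OF_EFFICACY: [
        ("because it just wasn't working", Theme.EFFICACY, Sentiment.NEUTRAL),
        ("because I kept relapsing on it", Theme.EFFICACY, Sentiment.NEUTRAL),
    ],
    Reason.PHYSICIAN_ADVICE: [
        ("because my neurologist recommended it", Theme.NONE, Sentiment.NEUTRAL),
        ("on my doctor's advice", Theme.NONE, Sentiment.NEUTRAL),
    ],
    Reason.EASE_OF_USE: [
        ("because a pill is so much easier", Theme.NONE, Sentiment.POSITIVE),
        ("since it's easier to take", Theme.NONE, Sentiment.POSITIVE),
    ],
    Reason.QOL_WORSENING: [
        ("because my quality of life kept getting worse", Theme.NONE, Sentiment.NEGATIVE),
        ("since my quality of life was suffering", Theme.NONE, Sentiment.NEUTRAL),
    ],
    Reason.SAFETY_CONCERNS: [
        ("because of safety concerns", Theme.NONE, Sentiment.NEUTRAL),
        ("because of the pml risk", Theme.NONE, Sentiment.NEUTRAL),
    ],
    Reason.INSURANCE: [
        ("because my insurance stopped covering it", Theme.COST, Sentiment.NEUTRAL),
        ("after an insurance denial", Theme.COST, Sentiment.NEUTRAL),
    ],
    Reason.COST: [
        ("because the copay was crazy expensive", Theme.COST, Sentiment.NEGATIVE),
        ("because I could not afford it anymore", Theme.COST, Sentiment.NEUTRAL),
    ],
    Reason.OTHER: [
        ("for personal reasons", Theme.NONE, Sentiment.NEUTRAL),
        ("for other reasons I won't get into", Theme.NONE, Sentiment.NEUTRAL),
    ],
}

# Non-switch drug chatter: (template, category, theme, sentiment), labels
# hand-traced against the shipped cue lexicons.
_NOISE_TEMPLATES = [
    ("Has anyone tried {A}?", Category.INFO_SEEKING, Theme.NONE, Sentiment.NEUTRAL),
    ("What do you think of {A}?", Category.INFO_SEEKING, Theme.NONE, Sentiment.NEUTRAL),
    ("{A} works great for me so far", Category.INFO_SHARING, Theme.EFFICACY, Sentiment.POSITIVE),
    ("I love {A}, no regrets", Category.INFO_SHARING, Theme.NONE, Sentiment.POSITIVE),
    ("The side effects of {A} are awful", Category.INFO_SHARING, Theme.SIDE_EFFECTS, Sentiment.NEGATIVE),
    ("Week 2 on {A}, feeling okay", Category.INFO_SHARING, Theme.NONE, Sentiment.NEUTRAL),
    ("The {A} copay is so expensive", Category.INFO_SHARING, Theme.COST, Sentiment.NEGATIVE),
    ("Anyone else forget doses of {A}?", Category.INFO_SEEKING, Theme.ADHERENCE, Sentiment.NEUTRAL),
    ("Weighing {A} against {B}, tough call", Category.INFO_SHARING, Theme.NONE, Sentiment.NEUTRAL),
    ("Started {A} two weeks ago and feeling good", Category.INFO_SHARING, Theme.NONE, Sentiment.POSITIVE),
]

_IRRELEVANT_TEMPLATES = [
    ("MS fatigue is rough this week", Category.INFO_SHARING, Theme.NONE, Sentiment.NEUTRAL),
    ("Newly diagnosed and looking for support", Category.INFO_SHARING, Theme.NONE, Sentiment.NEUTRAL),
    ("Heading to my appointment this afternoon", Category.INFO_SHARING, Theme.NONE, Sentiment.NEUTRAL),
    ("Anybody else going to the MS walk this weekend?", Category.INFO_SEEKING, Theme.NONE, Sentiment.NEUTRAL),
]

_SPAM_TEMPLATE = "Miracle deal - buy {A} cheap online, click here http://pills.example/{n}"

_US_LOCATIONS = [
    "Austin, TX", "Boston, MA", "Ohio", "Seattle, WA", "Lubbock, TX",
    "Florida", "Independence, MO", "Denver, CO", "Chicago, IL", "Oregon",
]
_NONUS_LOCATIONS = {
    "GB": "London, UK",
    "CA": "Toronto, Canada",
    "DE": "Berlin, Germany",
    "AU": "Sydney, Australia",
    "FR": "Paris, France",
}

_PROFILE_SEX_SENTENCES = {
    "F": "As a mom, I take it one day at a time.",
    "M": "As a dad, I take it one day at a time.",
}


def _novel_misspellings(lexicon: Lexicon, max_per_brand: int = 4) -> dict[str, list[str]]:
    """Deterministic out-of-lexicon single-edit variants per brand.

    Each variant is guaranteed to fuzzy-resolve uniquely back to its brand
    at max_edit=1 under the mention matcher's own rules (length >= 5, not a
    lexicon surface, unique nearest brand), so planted misspellings are
    recoverable by design.
    """
    out: dict[str, list[str]] = {}
    for entry in lexicon.entries:
        base = entry.brand.lower()
        cands: list[str] = []
        for i in range(len(base)):  # double a letter
            cands.append(base[:i] + base[i] + base[i:])
        for i in range(len(base)):  # drop a letter
            cands.append(base[:i] + base[i + 1:])
        keep: list[str] = []
        for c in cands:
            if len(c) < 5 or c in lexicon.surface_map or c in keep:
                continue
            if lexicon._fuzzy_lookup(c, 1) == entry.brand:
                keep.append(c)
            if len(keep) >= max_per_brand:
                break
        out[entry.brand] = keep
    return out


# ---------------------------------------------------------------------------
# generator

def _month_bounds(date_range: tuple[str, str]) -> tuple[datetime, datetime]:
    start = datetime.strptime(date_range[0], "%Y-%m").replace(tzinfo=timezone.utc)
    end_first = datetime.strptime(date_range[1], "%Y-%m").replace(tzinfo=timezone.utc)
    # end of the last month
    if end_first.month == 12:
        end = end_first.replace(year=end_first.year + 1, month=1)
    else:
        end = end_first.replace(month=end_first.month + 1)
    return start, end


def _draw_from_bins(rng: np.random.Generator, bins: list[list[float]]) -> tuple[float, float]:
    probs = np.array([b[2] for b in bins], dtype=float)
    probs = probs / probs.sum()
    i = int(rng.choice(len(bins), p=probs))
    return bins[i][0], bins[i][1]


def _draw_categorical(rng: np.random.Generator, weights: dict) -> object:
    keys = list(weights.keys())
    w = np.array([float(weights[k]) for k in keys], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive mass")
    return keys[int(rng.choice(len(keys), p=w / total))]


def _quantize_ysd(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Pick a declared-precision duration inside a half-open bin."""
    if hi <= 1.0:  # sub-year bin: whole months
        lo_m, hi_m = max(1, int(round(lo * 12))), int(round(hi * 12))
        return int(rng.integers(lo_m, hi_m)) / 12.0
    return float(int(rng.integers(int(lo), int(hi))))


class _AuthorFactory:
    def __init__(self, config: CorpusConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.counter = 0

    def new_author(self) -> AuthorTruth:
        rng = self.rng
        demo = self.config.demographics
        self.counter += 1
        sex = str(_draw_categorical(rng, demo["sex"]))
        lo, hi = _draw_from_bins(rng, demo["age_bins"])
        age = int(rng.integers(int(lo), int(hi)))
        for _ in range(50):
            blo, bhi = _draw_from_bins(rng, demo["ysd_bins"])
            ysd = _quantize_ysd(rng, blo, bhi)
            if ysd < age:
                break
        else:
            ysd = 1 / 12.0
        country = str(_draw_categorical(rng, demo["country"]))
        return AuthorTruth(
            author_key=f"user{self.counter:05d}",
            sex=sex,
            age=age,
            ysd=ysd,
            country=country,
            platforms=[],
        )


def _ysd_phrase(ysd: float) -> str:
    if ysd < 1.0:
        months = max(1, int(round(ysd * 12)))
        return f"{months} month{'s' if months != 1 else ''} ago"
    years = int(ysd)
    return f"{years} year{'s' if years != 1 else ''} ago"


def generate_corpus(config: CorpusConfig) -> tuple[list[Post], GroundTruth]:
    """Generate a corpus and its ground truth from ``config`` (deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lexicon = load_lexicon()
    novel = _novel_misspellings(lexicon)
    factory = _AuthorFactory(config, rng)
    truth = GroundTruth()
    posts: list[Post] = []

    start, end = _month_bounds(config.date_range)
    span_seconds = (end - start).total_seconds()

    brands_by_class = {c: lexicon.brands_in_class(c) for c in DrugClass}
    all_brands = [e.brand for e in lexicon.entries]
    pair_weights = {k: v for k, v in config.class_pair_weights.items() if v > 0}

    def render_drug(brand: str) -> str:
        if config.misspell_rate > 0 and rng.random() < config.misspell_rate:
            pool = sorted(lexicon.entry(brand).aliases) + novel.get(brand, [])
            if pool:
                return pool[int(rng.integers(len(pool)))]
        return brand

    def pick_pair() -> tuple[str, str]:
        fc, tc = _draw_categorical(rng, pair_weights)
        from_drug = brands_by_class[DrugClass[fc]][int(rng.integers(len(brands_by_class[DrugClass[fc]])))]
        choices = [b for b in brands_by_class[DrugClass[tc]] if b != from_drug]
        to_drug = choices[int(rng.integers(len(choices)))]
        return from_drug, to_drug

    spam_counter = 0
    for platform in PLATFORMS:
        n = config.n_posts_per_platform.get(platform, 0)
        if n == 0:
            continue
        # plan authors for this platform
        plan: list[tuple[AuthorTruth, int]] = []
        remaining = n
        while remaining > 0:
            reusable = [
                a for a in truth.authors.values() if platform not in a.platforms
            ]
            if reusable and rng.random() < config.duplicate_author_rate:
                author = reusable[int(rng.integers(len(reusable)))]
            else:
                author = factory.new_author()
                truth.authors[author.author_key] = author
            author.platforms.append(platform)
            k = min(1 + int(rng.poisson(max(config.posts_per_author_mean - 1, 0))), remaining)
            plan.append((author, k))
            remaining -= k

        for author, k in plan:
            for _ in range(k):
                post_id = f"{platform[:2]}-{len(posts):06d}"
                ts = start + timedelta(seconds=float(rng.random()) * span_seconds)
                category, theme, sentiment = Category.INFO_SHARING, Theme.NONE, Sentiment.NEUTRAL
                switches: list[TruthSwitch] = []
                relevant = False
                declared: dict[str, str] = {}

                if rng.random() < config.relevance_rate:  # mentions a drug
                    if rng.random() < config.spam_rate:
                        spam_counter += 1
                        brand = all_brands[int(rng.integers(len(all_brands)))]
                        text = _SPAM_TEMPLATE.format(A=brand, n=spam_counter)
                    elif rng.random() < config.switch_rate:
                        relevant = True
                        from_drug, to_drug = pick_pair()
                        reason = Reason[str(_draw_categorical(rng, config.reason_weights))]
                        use_para = rng.random() < config.paraphrase_rate
                        chain = (not use_para) and config.chain_rate > 0 and rng.random() < config.chain_rate
                        if chain:
                            third = [b for b in all_brands if b != to_drug]
                            c_drug = third[int(rng.integers(len(third)))]
                            text = _CHAIN_TEMPLATE.format(
                                A=render_drug(from_drug), B=render_drug(to_drug), C=render_drug(c_drug)
                            )
                            switches = [
                                TruthSwitch(from_drug, to_drug, reason),
                                TruthSwitch(to_drug, c_drug, reason),
                            ]
                        else:
                            family = (
                                "paraphrase"
                                if use_para
                                else DETECTABLE_FAMILIES[int(rng.integers(len(DETECTABLE_FAMILIES)))]
                            )
                            bank = _SWITCH_TEMPLATES[family]
                            tmpl = bank[int(rng.integers(len(bank)))]
                            text = tmpl.format(
                                A=render_drug(from_drug),
                                B=render_drug(to_drug),
                                time=_TIME_FILLERS[int(rng.integers(len(_TIME_FILLERS)))],
                            )
                            switches = [TruthSwitch(from_drug, to_drug, reason)]
                        if reason is not Reason.UNSPECIFIED:
                            clauses = _REASON_CLAUSES[reason]
                            clause, theme, sentiment = clauses[int(rng.integers(len(clauses)))]
                            text = f"{text} {clause}"
                    else:
                        relevant = True
                        tmpl, category, theme, sentiment = _NOISE_TEMPLATES[
                            int(rng.integers(len(_NOISE_TEMPLATES)))
                        ]
                        a = all_brands[int(rng.integers(len(all_brands)))]
                        b = all_brands[int(rng.integers(len(all_brands)))]
                        while b == a:
                            b = all_brands[int(rng.integers(len(all_brands)))]
                        text = tmpl.format(A=render_drug(a), B=render_drug(b))
                else:
                    tmpl, category, theme, sentiment = _IRRELEVANT_TEMPLATES[
                        int(rng.integers(len(_IRRELEVANT_TEMPLATES)))
                    ]
                    text = tmpl

                if rng.random() < config.profile_mention_rate:
                    text = (
                        f"{text}. I'm {author.age} and was diagnosed "
                        f"{_ysd_phrase(author.ysd)}. {_PROFILE_SEX_SENTENCES[author.sex]}"
                    )
                if author.country != "UNKNOWN" and rng.random() < config.profile_mention_rate:
                    if author.country == "US":
                        declared["location"] = _US_LOCATIONS[int(rng.integers(len(_US_LOCATIONS)))]
                    else:
                        declared["location"] = _NONUS_LOCATIONS[author.country]

                posts.append(
                    Post(
                        post_id=post_id,
                        platform=platform,
                        timestamp=ts,
                        author_key=author.author_key,
                        text=text,
                        declared=declared,
                    )
                )
                truth.posts[post_id] = PostTruth(
                    post_id=post_id,
                    relevant=relevant,
                    category=category,
                    theme=theme,
                    sentiment=sentiment,
                    switches=switches,
                )

    _apply_truth_dedup(posts, truth)
    return posts, truth


def _apply_truth_dedup(posts: list[Post], truth: GroundTruth) -> None:
    """Mirror the detector's author duplicate-text rule in the ground truth."""
    window = timedelta(days=DEDUP_WINDOW_DAYS)
    seen: dict[tuple[str, str], datetime] = {}
    for post in sorted(posts, key=lambda p: (p.timestamp, p.post_id)):
        key = (post.author_key, _normtext(post.text))
        prev = seen.get(key)
        seen[key] = post.timestamp
        if prev is not None and (post.timestamp - prev) <= window:
            t = truth.posts[post.post_id]
            t.relevant = False
            t.switches = []
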