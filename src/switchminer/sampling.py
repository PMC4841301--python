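"""Platform x month stratification and Cochran sample-size planning.

Relevant data points are stratified by (platform, UTC calendar month).
Per-stratum sample sizes use Cochran's formula for a proportion at the
configured confidence level and margin of error, with finite-population
correction and ceiling to an integer:

    n0 = z^2 p (1 - p) / e^2,   n = ceil( n0 / (1 + (n0 - 1) / N) )

with z the standard-normal quantile at (1 + confidence) / 2, p the assumed
proportion (0.5 by default, the maximum-variance choice) and e the margin
of error.  Defaults (95% confidence, 5% margin) give the familiar
large-population n = 385.  Draws are simple random samples without
replacement from per-stratum substreams deterministically derived from the
master seed.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .corpus import Post

log = logging.getLogger(__name__)


def derive_seed(master_seed: int, *parts: object) -> int:
    """Stable sub-seed from the master seed and labels (below 2**31)."""
    key = "|".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stratify(posts: list[Post]) -> dict[tuple[str, str], list[str]]:
    """Group post ids into (platform, YYYY-MM) strata.

    Returns an ordered mapping; per-stratum id lists are sorted so that
    downstream draws are reproducible regardless of input order.
    """
    strata: dict[tuple[str, str], list[str]] = {}
    for p in posts:
        strata.setdefault((p.platform, p.month()), []).append(p.post_id)
    return {k: sorted(v) for k, v in sorted(strata.items())}


def stratum_counts(strata: dict[tuple[str, str], list[str]]) -> dict[tuple[str, str], int]:
    return {k: len(v) for k, v in strata.items()}


def sample_size(N: int, confidence: float = 0.95, moe: float = 0.05, p: float = 0.5) -> int:
    """Cochran sample size with finite-population correction, capped at N."""
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if moe <= 0:
        raise ValueError(f"margin of error must be positive, got {moe}")
    if not 0 <= p <= 1:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    if N < 0:
        raise ValueError("population size must be nonnegative")
    if N == 0:
        return 0
    z = norm.ppf((1 + confidence) / 2)
    n0 = z * z * p * (1 - p) / (moe * moe)
    n = math.ceil(n0 / (1 + (n0 - 1) / N))
    return min(n, N)


def draw_sample(post_ids: list[str], n: int, seed: int) -> list[str]:
    """Simple random sample of ``n`` ids without replacement (deterministic)."""
    if n > len(post_ids):
        raise ValueError(f"cannot draw {n} from a stratum of {len(post_ids)}")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    picked = rng.choice(np.array(sorted(post_ids), dtype=object), size=n, replace=False)
    return sorted(picked.tolist())


@dataclass
class StratumPlan:
    platform: str
    month: str
    N: int
    n: int
    sampled_ids: list[str] = field(default_factory=list)


@dataclass
class SamplingPlan:
    strata: list[StratumPlan]
    confidence: float = 0.95
    moe: float = 0.05
    p: float = 0.5
    seed: int = 0

    def total_sampled(self) -> int:
        return sum(s.n for s in self.strata)

    def sampled_by_platform(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.strata:
            out[s.platform] = out.get(s.platform, 0) + s.n
        return out

    def all_sampled_ids(self) -> set[str]:
        return {pid for s in self.strata for pid in s.sampled_ids}


def build_plan(
    strata: dict[tuple[str, str], list[str]],
    confidence: float = 0.95,
    moe: float = 0.05,
    p: float = 0.5,
    seed: int = 0,
    per_platform: bool = False,
) -> SamplingPlan:
    """Size and draw every stratum; ``per_platform=True`` pools months first."""
    if per_platform:
        pooled: dict[tuple[str, str], list[str]] = {}
        for (platform, _), ids in strata.items():
            pooled.setdefault((platform, "all"), []).append(ids)
        strata = {k: sorted(sum(v, [])) for k, v in sorted(pooled.items())}
    plans: list[StratumPlan] = []
    for (platform, month), ids in strata.items():
        N = len(ids)
        n = sample_size(N, confidence, moe, p)
        sub = derive_seed(seed, platform, month)
        plans.append(
            StratumPlan(platform=platform, month=month, N=N, n=n,
                        sampled_ids=draw_sample(ids, n, sub))
        )
    return SamplingPlan(strata=plans, confidence=confidence, moe=moe, p=p, seed=seed)


def build_validation_sets(
    strata: dict[tuple[str, str], list[str]],
    k_months: int = 3,
    seed: int = 0,
    confidence: float = 0.95,
    moe: float = 0.05,
    p: float = 0.5,
) -> dict[str, SamplingPlan]:
    """Per-platform validation plans on ``k_months`` randomly chosen months.

    Validation draws are fresh random draws; overlap with the primary
    sample is permitted.  Platforms with fewer than ``k_months`` nonempty
    months use all of them, with a warning.
    """
    months_by_platform: dict[str, list[str]] = {}
    for (platform, month), ids in strata.items():
        if ids:
            months_by_platform.setdefault(platform, []).append(month)
    out: dict[str, SamplingPlan] = {}
    for platform in sorted(months_by_platform):
        months = sorted(months_by_platform[platform])
        if len(months) < k_months:
            log.warning(
                "platform %s has only %d nonempty months (< %d); using all",
                platform, len(months), k_months,
            )
            chosen = months
        else:
            rng = np.random.default_rng(derive_seed(seed, "validation", platform))
            chosen = sorted(
                rng.choice(np.array(months, dtype=object), size=k_months, replace=False).tolist()
            )
        plans = []
        for month in chosen:
            ids = strata[(platform, month)]
            N = len(ids)
            n = sample_size(N, confidence, moe, p)
            sub = derive_seed(seed, "validation", platform, month)
            plans.append(StratumPlan(platform, month, N, n, draw_sample(ids, n, sub)))
        out[platform] = SamplingPlan(strata=plans, confidence=confidence, moe=moe, p=p, seed=seed)
    return out
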