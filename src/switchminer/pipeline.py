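"""End-to-end run: detect -> profiles -> US filter -> sample -> aggregate.

The report bundle mirrors the analysis funnel: extracted posts, relevant
posts, the stratified sample, switch data points, and the aggregate
tables, each percentage carrying its scope and denominator.  Two scopes
are always produced and labeled, because it is ambiguous whether published
switch percentages were computed on the full relevant set or the manually
reviewed sample: ``relevant_us`` (all relevant posts by US-located
authors) and ``sampled_us`` (the stratified-sample subset of those).

Given identical inputs, seed and configuration the bundle is
byte-identical: all tables are sorted, floats are written with a fixed
format, and the manifest contains no wall-clock information.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import sampling
from .aggregate import (
    DemographicsSummary,
    ReasonTable,
    SwitchMatrix,
    build_switch_matrix,
    compare_representativeness,
    demographics_summary,
    reason_frequencies,
    top_reasons_by_source_class,
)
from .corpus import Post
from .detect import Grammar, PostAnnotation, SwitchEvent, annotate_corpus, apply_overrides
from .lexicon import Lexicon, load_lexicon
from .profiles import (
    PatientProfile,
    _norm_key,
    dedup_authors,
    extract_profiles,
    filter_us,
    profiles_to_csv,
)
from .published import COMMUNITY_SURVEY


@dataclass
class ReportBundle:
    annotations: dict[str, PostAnnotation]
    profiles: dict[str, PatientProfile]
    included: dict[str, PatientProfile]
    excluded: list[tuple[PatientProfile, str]]
    plan: sampling.SamplingPlan
    validation: dict[str, sampling.SamplingPlan]
    events: dict[str, list[SwitchEvent]]  # scope -> events
    matrices: dict[str, SwitchMatrix]
    reasons: dict[str, ReasonTable]
    demographics: DemographicsSummary
    representativeness: pd.DataFrame
    funnel: dict[str, int]
    manifest: dict = field(default_factory=dict)


def _config_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(
    posts: list[Post],
    lexicon: Lexicon | None = None,
    grammar: Grammar | None = None,
    *,
    seed: int = 0,
    max_edit: int = 1,
    confidence: float = 0.95,
    moe: float = 0.05,
    p: float = 0.5,
    k_validation_months: int = 3,
    overrides: list[dict] | str | None = None,
) -> ReportBundle:
    """Run the full analysis over an in-memory corpus."""
    if not posts:
        raise ValueError("pipeline requires a nonempty corpus")
    lexicon = lexicon or load_lexicon()
    grammar = grammar or Grammar.load()
    params = {
        "seed": seed, "max_edit": max_edit, "confidence": confidence,
        "moe": moe, "p": p, "k_validation_months": k_validation_months,
    }

    annotations = annotate_corpus(posts, lexicon, grammar, max_edit=max_edit)
    if overrides is not None:
        annotations = apply_overrides(annotations, overrides)

    relevant_posts = [p_ for p_ in posts if annotations[p_.post_id].relevant]

    profiles = dedup_authors(extract_profiles(posts), posts)
    included, excluded = filter_us(profiles)

    strata = sampling.stratify(relevant_posts)
    plan = sampling.build_plan(strata, confidence=confidence, moe=moe, p=p, seed=seed)
    validation = sampling.build_validation_sets(
        strata, k_months=k_validation_months, seed=seed,
        confidence=confidence, moe=moe, p=p,
    )
    sampled_ids = plan.all_sampled_ids()

    post_author = {p_.post_id: _norm_key(p_.author_key) for p_ in posts}
    events_us = [
        e
        for pid in sorted(annotations)
        for e in annotations[pid].switches
        if post_author[pid] in included
    ]
    events_sampled = [e for e in events_us if e.post_id in sampled_ids]
    events = {"relevant_us": events_us, "sampled_us": events_sampled}

    matrices = {scope: build_switch_matrix(ev) for scope, ev in events.items()}
    reasons = {scope: reason_frequencies(ev) for scope, ev in events.items()}

    switching_keys = {post_author[e.post_id] for e in events_us}
    demo = demographics_summary(profiles, switching_keys)
    rep = compare_representativeness(demo, COMMUNITY_SURVEY)

    funnel = {
        "extracted": len(posts),
        "relevant": len(relevant_posts),
        "sampled": plan.total_sampled(),
        "authors": len(profiles),
        "authors_us": len(included),
        "authors_excluded_no_location": sum(1 for _, c in excluded if c == "NO_LOCATION"),
        "authors_excluded_non_us": sum(1 for _, c in excluded if c == "NON_US"),
        "switch_data_points_us": len(events_us),
        "switch_data_points_sampled_us": len(events_sampled),
        "reason_classified_us": reasons["relevant_us"].denominator,
        "switching_patients_us": len(switching_keys & set(included)),
    }

    manifest = {
        "parameters": params,
        "config_hash": _config_hash(params),
        "n_lexicon_entries": len(lexicon),
        "n_grammar_rules": len(grammar.rules),
        "funnel": funnel,
        "sampled_by_platform": plan.sampled_by_platform(),
    }

    return ReportBundle(
        annotations=annotations, profiles=profiles, included=included,
        excluded=excluded, plan=plan, validation=validation, events=events,
        matrices=matrices, reasons=reasons, demographics=demo,
        representativeness=rep, funnel=funnel, manifest=manifest,
    )


# ---------------------------------------------------------------------------
# deterministic serialization

_FLOAT_FMT = "%.6g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def matrix_long_frame(matrices: dict[str, SwitchMatrix]) -> pd.DataFrame:
    rows = []
    for scope in sorted(matrices):
        m = matrices[scope]
        shares = m.share_of_total()
        rowcond = m.row_conditional()
        for fc in m.counts.index:
            for tc in m.counts.columns:
                rows.append({
                    "scope": scope, "from_class": fc, "to_class": tc,
                    "n": int(m.counts.loc[fc, tc]), "total": m.total,
                    "pct_of_total": shares.loc[fc, tc],
                    "pct_of_source_class": rowcond.loc[fc, tc],
                })
    return pd.DataFrame(rows)


def reasons_long_frame(reasons: dict[str, ReasonTable]) -> pd.DataFrame:
    rows = []
    for scope in sorted(reasons):
        t = reasons[scope]
        for rec in t.to_frame().to_dict("records"):
            rows.append({"scope": scope, **rec})
        rows.append({"scope": scope, "reason": "UNSPECIFIED", "n": t.unspecified,
                     "pct": None, "denominator": t.denominator})
    return pd.DataFrame(rows, columns=["scope", "reason", "n", "pct", "denominator"])


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write the report bundle as CSV tables + JSON manifest (deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _write_csv(matrix_long_frame(bundle.matrices), out / "switch_matrix.csv")
    _write_csv(reasons_long_frame(bundle.reasons), out / "reason_table.csv")
    _write_csv(bundle.demographics.to_frame(), out / "demographics.csv")
    _write_csv(bundle.representativeness, out / "representativeness.csv")

    top = top_reasons_by_source_class(bundle.events["relevant_us"])
    rows = [
        {"from_class": cls, "rank": i + 1, "reason": r, "n": n, "pct_of_class": p_}
        for cls, items in sorted(top.items())
        for i, (r, n, p_) in enumerate(items)
    ]
    _write_csv(pd.DataFrame(rows, columns=["from_class", "rank", "reason", "n", "pct_of_class"]),
               out / "top_reasons_by_class.csv")

    _write_csv(
        pd.DataFrame(
            [{"stage": k, "count": v} for k, v in bundle.funnel.items()],
            columns=["stage", "count"],
        ),
        out / "funnel.csv",
    )
    plan_rows = [
        {"platform": s.platform, "month": s.month, "N": s.N, "n": s.n,
         "sampled_ids": "|".join(s.sampled_ids)}
        for s in bundle.plan.strata
    ]
    _write_csv(pd.DataFrame(plan_rows, columns=["platform", "month", "N", "n", "sampled_ids"]),
               out / "sampling_plan.csv")
    val_rows = [
        {"platform": platform, "month": s.month, "N": s.N, "n": s.n,
         "sampled_ids": "|".join(s.sampled_ids)}
        for platform in sorted(bundle.validation)
        for s in bundle.validation[platform].strata
    ]
    _write_csv(pd.DataFrame(val_rows, columns=["platform", "month", "N", "n", "sampled_ids"]),
               out / "validation_plan.csv")

    profiles_to_csv(bundle.profiles, out / "profiles.csv")
    excl_rows = [
        {"author_key": prof.author_key, "country": prof.country, "cause": cause}
        for prof, cause in bundle.excluded
    ]
    _write_csv(pd.DataFrame(excl_rows, columns=["author_key", "country", "cause"]),
               out / "exclusions.csv")

    with open(out / "annotations.jsonl", "w", encoding="utf-8") as fh:
        for pid in sorted(bundle.annotations):
            fh.write(json.dumps(bundle.annotations[pid].to_record(), sort_keys=True) + "\n")

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")

    with open(out / "run.log", "w", encoding="utf-8") as fh:
        for stage, count in bundle.funnel.items():
            fh.write(f"stage {stage}: {count}\n")
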