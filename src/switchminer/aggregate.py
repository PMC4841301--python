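"""Aggregation of switch events and profiles into result tables.

Percentages are always computed at full precision on a stated numerator
and denominator and rounded half-up to two decimals only at presentation;
every percentage in the output carries its denominator.  The three study
denominators (switch data points, reason-classified switches, switching
patients) are never pooled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .detect import Reason, SwitchEvent
from .lexicon import DrugClass
from .profiles import AGE_BINS, UNKNOWN, YSD_BINS, PatientProfile, age_bin, ysd_bin

CLASS_ORDER = (DrugClass.ORAL, DrugClass.INJECTABLE, DrugClass.IV)


def pct(numerator: float, denominator: float, digits: int = 2) -> float | None:
    """100 * numerator / denominator, rounded half-up; None when undefined."""
    if denominator == 0:
        return None
    if float(numerator).is_integer() and float(denominator).is_integer():
        exact = Decimal(int(numerator)) / Decimal(int(denominator)) * 100
    else:
        exact = Decimal(float(numerator)) / Decimal(float(denominator)) * 100
    q = Decimal(1).scaleb(-digits)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# switch matrix

@dataclass
class SwitchMatrix:
    """3x3 switch counts indexed (from_class, to_class)."""

    counts: pd.DataFrame  # index = from_class, columns = to_class

    @classmethod
    def from_counts(cls, counts: dict[tuple[str, str], int]) -> "SwitchMatrix":
        labels = [c.value for c in CLASS_ORDER]
        df = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for (fc, tc), n in counts.items():
            df.loc[str(fc), str(tc)] += int(n)
        return cls(df)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def cell(self, from_class: str | DrugClass, to_class: str | DrugClass) -> int:
        return int(self.counts.loc[str(getattr(from_class, "value", from_class)),
                                   str(getattr(to_class, "value", to_class))])

    def share_of_total(self) -> pd.DataFrame:
        """Each cell as a percent of all switches (None-safe when empty)."""
        return self.counts.map(lambda c: pct(c, self.total))

    def row_conditional(self) -> pd.DataFrame:
        """Destination shares within each source class."""
        out = self.counts.astype(object).copy()
        for fc in out.index:
            row_total = int(self.counts.loc[fc].sum())
            out.loc[fc] = [pct(self.counts.loc[fc, tc], row_total) for tc in out.columns]
        return out

    def source_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def destination_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def build_switch_matrix(events: list[SwitchEvent]) -> SwitchMatrix:
    """Count validated events by (from_class, to_class)."""
    counts: dict[tuple[str, str], int] = {}
    for e in events:
        key = (e.from_class.value, e.to_class.value)
        counts[key] = counts.get(key, 0) + 1
    return SwitchMatrix.from_counts(counts)


# ---------------------------------------------------------------------------
# reason table

@dataclass
class ReasonTable:
    """Reason counts over reason-classified events (UNSPECIFIED kept apart)."""

    counts: dict[Reason, int]
    unspecified: int = 0

    @property
    def denominator(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[Reason, float | None]:
        return {r: pct(n, self.denominator) for r, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reason": r.value, "n": n, "pct": pct(n, self.denominator),
             "denominator": self.denominator}
            for r, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0].value))
        ]
        return pd.DataFrame(rows, columns=["reason", "n", "pct", "denominator"])


def reason_frequencies(events: list[SwitchEvent]) -> ReasonTable:
    counts: dict[Reason, int] = {}
    unspecified = 0
    for e in events:
        if e.reason is Reason.UNSPECIFIED:
            unspecified += 1
        else:
            counts[e.reason] = counts.get(e.reason, 0) + 1
    return ReasonTable(counts=counts, unspecified=unspecified)


def top_reasons_by_source_class(
    events: list[SwitchEvent], k: int = 3
) -> dict[str, list[tuple[str, int, float | None]]]:
    """Top-k reasons per source class as (reason, n, pct-of-class-classified)."""
    by_class: dict[str, dict[Reason, int]] = {}
    for e in events:
        if e.reason is Reason.UNSPECIFIED:
            continue
        d = by_class.setdefault(e.from_class.value, {})
        d[e.reason] = d.get(e.reason, 0) + 1
    out: dict[str, list[tuple[str, int, float | None]]] = {}
    for cls_label, d in sorted(by_class.items()):
        denom = sum(d.values())
        top = sorted(d.items(), key=lambda kv: (-kv[1], kv[0].value))[:k]
        out[cls_label] = [(r.value, n, pct(n, denom)) for r, n in top]
    return out


# ---------------------------------------------------------------------------
# demographics

def _mean_sd(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


@dataclass
class DemographicsSummary:
    """Two-column demographic summary (all patients vs switching patients).

    Each panel carries its own denominator: sex uses all profiles, the age
    panel uses profiles with known age, the disease-duration panel uses
    profiles with known duration.
    """

    panels: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for col in ("all", "switching"):
            p = self.panels[col]
            rows.append({"population": col, "variable": "n", "value": p["n"], "pct": None})
            rows.append({"population": col, "variable": "female_n", "value": p["female_n"],
                         "pct": p["female_pct"]})
            rows.append({"population": col, "variable": "age_mean", "value": p["age_mean"], "pct": None})
            rows.append({"population": col, "variable": "age_sd", "value": p["age_sd"], "pct": None})
            for label, _, _ in AGE_BINS:
                rows.append({"population": col, "variable": f"age {label}",
                             "value": p["age_bins"][label],
                             "pct": pct(p["age_bins"][label], p["age_n"])})
            rows.append({"population": col, "variable": "ysd_mean", "value": p["ysd_mean"], "pct": None})
            rows.append({"population": col, "variable": "ysd_sd", "value": p["ysd_sd"], "pct": None})
            for label, _, _ in YSD_BINS:
                rows.append({"population": col, "variable": f"ysd {label}",
                             "value": p["ysd_bins"][label],
                             "pct": pct(p["ysd_bins"][label], p["ysd_n"])})
        return pd.DataFrame(rows, columns=["population", "variable", "value", "pct"])


def _panel(profiles: list[PatientProfile]) -> dict:
    n = len(profiles)
    female = sum(1 for p in profiles if p.sex == "F")
    ages = [int(p.age) for p in profiles if p.age != UNKNOWN]
    ysds = [float(p.years_since_diagnosis) for p in profiles
            if p.years_since_diagnosis != UNKNOWN]
    age_mean, age_sd = _mean_sd([float(a) for a in ages])
    ysd_mean, ysd_sd = _mean_sd(ysds)
    age_bins = {label: 0 for label, _, _ in AGE_BINS}
    for a in ages:
        age_bins[age_bin(a)] += 1
    ysd_bins = {label: 0 for label, _, _ in YSD_BINS}
    for y in ysds:
        ysd_bins[ysd_bin(y)] += 1
    return {
        "n": n,
        "female_n": female,
        "female_pct": pct(female, n),
        "age_n": len(ages),
        "age_mean": age_mean,
        "age_sd": age_sd,
        "age_bins": age_bins,
        "ysd_n": len(ysds),
        "ysd_mean": ysd_mean,
        "ysd_sd": ysd_sd,
        "ysd_bins": ysd_bins,
    }


def demographics_summary(
    profiles: dict[str, PatientProfile],
    switching_author_keys: set[str],
) -> DemographicsSummary:
    """Summarize all patients and the switching subpopulation side by side."""
    all_profiles = [profiles[k] for k in sorted(profiles)]
    switching = [profiles[k] for k in sorted(switching_author_keys) if k in profiles]
    return DemographicsSummary(panels={"all": _panel(all_profiles), "switching": _panel(switching)})


# ---------------------------------------------------------------------------
# representativeness

#: Age bins of the community-survey comparison; the first merges <20 + 20-29.
COMPARISON_AGE_BINS = ("<30", "30-39", "40-49", "50-59", "60-69", ">70")


def summary_to_comparison_bins(summary: DemographicsSummary) -> dict[str, float | None]:
    """Study column for the representativeness table, on the comparison bins."""
    p = summary.panels["all"]
    merged_lt30 = p["age_bins"]["<20"] + p["age_bins"]["20-29"]
    out: dict[str, float | None] = {"<30": pct(merged_lt30, p["age_n"])}
    for label in COMPARISON_AGE_BINS[1:]:
        out[label] = pct(p["age_bins"][label], p["age_n"])
    return out


def compare_representativeness(
    summary: DemographicsSummary | dict,
    reference: dict,
) -> pd.DataFrame:
    """Study vs reference populations with absolute percentage-point gaps.

    ``reference`` follows the community-survey structure: population ->
    {female_pct, age_pct: {bin: pct}}.  No hypothesis test is performed.
    Raises on any age bin present in a reference but absent from the study
    summary.
    """
    if isinstance(summary, DemographicsSummary):
        study_female = summary.panels["all"]["female_pct"]
        study_age = summary_to_comparison_bins(summary)
    else:
        study_female = summary["female_pct"]
        study_age = dict(summary["age_pct"])

    rows = []
    for pop, ref in reference.items():
        if pop == "study":
            continue
        rows.append({"population": pop, "variable": "female",
                     "study_pct": study_female, "reference_pct": ref["female_pct"],
                     "abs_diff": round(abs(study_female - ref["female_pct"]), 2)})
        for bin_label, ref_pct in ref.get("age_pct", {}).items():
            if bin_label not in study_age or study_age[bin_label] is None:
                raise ValueError(f"age bin {bin_label!r} missing from the study summary")
            s = study_age[bin_label]
            rows.append({"population": pop, "variable": f"age {bin_label}",
                         "study_pct": s, "reference_pct": ref_pct,
                         "abs_diff": round(abs(s - ref_pct), 2)})
    return pd.DataFrame(rows, columns=["population", "variable", "study_pct",
                                       "reference_pct", "abs_diff"])


def plot_switch_matrix(matrix: SwitchMatrix, path: str) -> None:
    """Optional cosmetic bar chart of source-class switch shares."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    totals = matrix.source_totals()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(totals.index, totals.values)
    ax.set_ylabel("switch data points")
    ax.set_xlabel("source class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
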