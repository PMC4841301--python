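"""Count-faithful fixtures built from the published summary tables.

Each builder expands published counts into concrete domain objects (switch
events, profiles) so the aggregation operations can recompute the printed
percentages from their own printed numerators and denominators.  The
fixtures are synthetic stand-ins for the unavailable raw data: only their
counts are faithful, not their text or identities.
"""

from __future__ import annotations

from . import published
from .detect import Reason, SwitchEvent
from .lexicon import DrugClass
from .profiles import AGE_BINS, YSD_BINS, PatientProfile

#: One representative brand per class, used only to give fixture events
#: lexicon-consistent drug fields.
_CLASS_BRANDS = {
    DrugClass.ORAL: ("Tecfidera", "Gilenya"),
    DrugClass.INJECTABLE: ("Copaxone", "Rebif"),
    DrugClass.IV: ("Tysabri", "Novantrone"),
}


def events_from_matrix_counts(counts: dict[tuple[str, str], int]) -> list[SwitchEvent]:
    """Expand (from_class, to_class) counts into that many switch events."""
    events: list[SwitchEvent] = []
    i = 0
    for (fc_label, tc_label), n in sorted(counts.items()):
        fc, tc = DrugClass[str(fc_label)], DrugClass[str(tc_label)]
        from_drug = _CLASS_BRANDS[fc][0]
        to_drug = _CLASS_BRANDS[tc][0] if _CLASS_BRANDS[tc][0] != from_drug else _CLASS_BRANDS[tc][1]
        for _ in range(int(n)):
            events.append(
                SwitchEvent(
                    post_id=f"fixture-{i:05d}",
                    from_drug=from_drug,
                    to_drug=to_drug,
                    from_class=fc,
                    to_class=tc,
                    pattern_id="fixture",
                )
            )
            i += 1
    return events


def events_from_claim(numerator: int, denominator: int,
                      cell: tuple[str, str], rest: tuple[str, str]) -> list[SwitchEvent]:
    """Events realizing one printed claim: ``numerator`` events in ``cell``
    and ``denominator - numerator`` in ``rest``."""
    return events_from_matrix_counts({cell: numerator, rest: denominator - numerator})


def events_from_reason_counts(counts: dict[str, int], unspecified: int = 0) -> list[SwitchEvent]:
    """Expand reason counts into events (INJECTABLE->ORAL placeholders)."""
    events: list[SwitchEvent] = []
    i = 0
    items = list(sorted(counts.items())) + [("UNSPECIFIED", unspecified)]
    for reason_label, n in items:
        for _ in range(int(n)):
            events.append(
                SwitchEvent(
                    post_id=f"fixture-r{i:05d}",
                    from_drug="Copaxone",
                    to_drug="Tecfidera",
                    from_class=DrugClass.INJECTABLE,
                    to_class=DrugClass.ORAL,
                    pattern_id="fixture",
                    reason=Reason[reason_label],
                )
            )
            i += 1
    return events


def profiles_from_demographics_counts(panel: dict, prefix: str) -> dict[str, PatientProfile]:
    """Expand one published demographics panel into profiles.

    ``panel`` holds n_total, female, age_known, age_bins, ysd_known,
    ysd_bins.  Ages are placed at bin-interior representative values;
    profiles beyond the known-age (known-duration) count stay UNKNOWN, so
    every panel reproduces its own published denominator.  Sex, age and
    duration margins are filled independently: only the marginal counts
    are faithful, joint structure is not claimed.
    """
    n_total = int(panel["n_total"])
    profiles: dict[str, PatientProfile] = {}
    for i in range(n_total):
        key = f"{prefix}{i:05d}"
        profiles[key] = PatientProfile(author_key=key, country="US")

    keys = sorted(profiles)
    for i in range(int(panel["female"])):
        profiles[keys[i]].sex = "F"
    for i in range(int(panel["female"]), n_total):
        profiles[keys[i]].sex = "M"

    age_reps = {label: (lo + 5 if hi > 190 else (lo + hi) // 2) for label, lo, hi in AGE_BINS}
    idx = 0
    for label, _, _ in AGE_BINS:
        for _ in range(int(panel["age_bins"].get(label, 0))):
            profiles[keys[idx]].age = int(age_reps[label])
            idx += 1
    assert idx == int(panel["age_known"]), "age bin counts must sum to the known-age n"

    ysd_reps = {}
    for label, lo, hi in YSD_BINS:
        ysd_reps[label] = lo + 1.0 if hi == float("inf") else (lo + hi) / 2
    idx = 0
    for label, _, _ in YSD_BINS:
        for _ in range(int(panel["ysd_bins"].get(label, 0))):
            profiles[keys[idx]].years_since_diagnosis = float(ysd_reps[label])
            idx += 1
    assert idx == int(panel["ysd_known"]), "duration bin counts must sum to the known-duration n"
    return profiles


def demographics_fixture() -> tuple[dict[str, PatientProfile], set[str]]:
    """Nested population reproducing both published demographics columns.

    The switching patients are a subset of the full population, so a single
    summary call reproduces the switching column from the switching panel's
    counts and the all-patients column from the full-population counts
    (non-switching profiles carry the count differences between panels).
    """
    all_panel = published.DEMOGRAPHICS_COUNTS["all"]
    sw_panel = published.DEMOGRAPHICS_COUNTS["switching"]
    residual = {
        "n_total": all_panel["n_total"] - sw_panel["n_total"],
        "female": all_panel["female"] - sw_panel["female"],
        "age_known": all_panel["age_known"] - sw_panel["age_known"],
        "age_bins": {k: all_panel["age_bins"][k] - sw_panel["age_bins"][k]
                     for k in all_panel["age_bins"]},
        "ysd_known": all_panel["ysd_known"] - sw_panel["ysd_known"],
        "ysd_bins": {k: all_panel["ysd_bins"][k] - sw_panel["ysd_bins"][k]
                     for k in all_panel["ysd_bins"]},
    }
    if any(v < 0 for v in residual["age_bins"].values()) or any(
        v < 0 for v in residual["ysd_bins"].values()
    ):
        raise ValueError("switching panel exceeds the full population in some bin")
    switching = profiles_from_demographics_counts(sw_panel, prefix="sw")
    rest = profiles_from_demographics_counts(residual, prefix="ns")
    profiles = {**switching, **rest}
    return profiles, set(switching)
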