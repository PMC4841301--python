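"""Published reference constants for count fixtures and representativeness.

These are read-only summary numbers from the 2013-2014 US multiple-
sclerosis social-listening study this pipeline reimplements, from the MS
community surveys in three US communities (Texas, Missouri, Ohio) used as
its representativeness comparator, and from three large US administrative
claims databases.  They serve two purposes only: building count-faithful
fixtures for the aggregation operations, and the external columns of the
representativeness comparison.  Nothing here is ever used by the detection
or extraction code paths.
"""

from __future__ import annotations

# -- switch-matrix claims, each as (numerator, denominator) ------------------

SWITCH_CLAIMS = {
    "injectable_to_oral_of_total": (927, 1684),
    "iv_to_oral_of_total": (259, 1684),
    "to_oral_of_total": (1326, 1684),
    "from_injectable_of_total": (1114, 1684),
    "from_oral_of_total": (160, 1684),  # internally inconsistent with the totals; kept as printed
    "injectable_to_oral_of_from_injectable": (927, 1114),
    "iv_to_oral_of_from_iv": (259, 265),
}

#: Total switch data points / reason-classified switches / switching patients.
#: The three denominators are not mutually derivable and are never pooled.
TOTAL_SWITCH_DATA_POINTS = 1684
TOTAL_REASON_CLASSIFIED = 1234
TOTAL_SWITCHING_PATIENTS = 991

# -- reason frequency table (n of 1234) --------------------------------------

REASON_COUNTS = {
    "SIDE_EFFECTS": 464,
    "LACK_OF_EFFICACY": 310,
    "PHYSICIAN_ADVICE": 193,
    "EASE_OF_USE": 163,
    "QOL_WORSENING": 39,
    "SAFETY_CONCERNS": 38,
    "INSURANCE": 13,
    "COST": 7,
    "OTHER": 7,
}

# -- demographics table counts ------------------------------------------------

DEMOGRAPHICS_COUNTS = {
    "all": {
        "n_total": 3911,
        "female": 3001,
        "age_known": 2239,
        "age_bins": {"<20": 11, "20-29": 442, "30-39": 602, "40-49": 858,
                     "50-59": 210, "60-69": 113, ">70": 3},
        "ysd_known": 992,
        "ysd_bins": {"0-6 months": 97, "6-12 months": 38, "1-3 years": 198,
                     "4-8 years": 239, "9-10 years": 88, ">10 years": 332},
        "age_mean": 39, "age_sd": 11, "ysd_mean": 6.8, "ysd_sd": 4.5,
    },
    "switching": {
        "n_total": 991,
        "female": 819,
        "age_known": 515,
        "age_bins": {"<20": 7, "20-29": 102, "30-39": 139, "40-49": 167,
                     "50-59": 57, "60-69": 43, ">70": 0},
        "ysd_known": 429,
        "ysd_bins": {"0-6 months": 8, "6-12 months": 7, "1-3 years": 106,
                     "4-8 years": 97, "9-10 years": 38, ">10 years": 173},
        "age_mean": 40, "age_sd": 12, "ysd_mean": 7.5, "ysd_sd": 4.3,
    },
}

# -- platform volumes and funnel ----------------------------------------------

EXTRACTED_TOTAL = 25073
RELEVANT_BY_PLATFORM = {"twitter": 8672, "facebook": 6919, "forum": 6505, "blog": 791}
SAMPLED_BY_PLATFORM = {"twitter": 3025, "facebook": 3771, "forum": 2773, "blog": 691}

# -- external reference populations -------------------------------------------

#: Community-survey MS populations (percent); age distribution over the
#: known-age subpopulation, with the study column's <30 bin merging the
#: study's <20 and 20-29 bins.
COMMUNITY_SURVEY = {
    "study": {
        "n": 3911,
        "female_pct": 76.73,
        "age_n": 2239,
        "age_pct": {"<30": 20.23, "30-39": 26.89, "40-49": 38.32,
                    "50-59": 9.38, "60-69": 5.05, ">70": 0.13},
    },
    "texas": {
        "n": 182,
        "female_pct": 80.1,
        "age_pct": {"<30": 10.4, "30-39": 32.4, "40-49": 26.9,
                    "50-59": 9.3, "60-69": 2.2, ">70": 0.5},
    },
    "missouri": {
        "n": 106,
        "female_pct": 81.1,
        "age_pct": {"<30": 3.8, "30-39": 12.3, "40-49": 37.7,
                    "50-59": 32.1, "60-69": 10.4, ">70": 3.8},
    },
    "ohio": {
        "n": 320,
        "female_pct": 74.1,
        "age_pct": {"<30": 3.1, "30-39": 10.6, "40-49": 30.3,
                    "50-59": 31.9, "60-69": 12.5, ">70": 11.6},
    },
}

#: Female share in three large US administrative claims databases (percent).
CLAIMS_FEMALE_PCT = {
    "MarketScan": 76.4,
    "PharMetrics Plus": 76.5,
    "Department of Defense": 76.4,
}
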