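"""Published constants for the Lee-index life-expectancy calculator.

The Lee mortality index assigns points to 12 risk factors (age band, sex,
six comorbidity/behaviour items, four functional items) and stratifies
community-dwelling adults aged 50+ into 15 risk groups (0, 1, ..., 13, 14+
points).  The constants below are the published point weights, the
point-score distributions of the three cohorts used to develop and validate
the Gompertz life-expectancy calculator (a US development cohort, a US
internal-validation cohort, and an English external-validation cohort), and
the published Gompertz-predicted survival quantiles per risk group.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Lee-index point weights
# ---------------------------------------------------------------------------

#: Age bands in years -> points.  Edges inclusive; no 6-point band exists.
AGE_BANDS: tuple[tuple[int, int, int], ...] = (
    (50, 59, 0),
    (60, 64, 1),
    (65, 69, 2),
    (70, 74, 3),
    (75, 79, 4),
    (80, 84, 5),
    (85, 200, 7),
)

#: Points for each binary item.
ITEM_POINTS: dict[str, int] = {
    "male": 2,
    "diabetes": 1,
    "cancer": 2,
    "lung_disease": 2,
    "heart_failure": 2,
    "bmi_under_25": 1,
    "current_smoker": 2,
    "difficulty_bathing": 2,
    "difficulty_finances": 2,
    "difficulty_walking_blocks": 2,
    "difficulty_push_pull": 1,
}

#: Maximum attainable point total (age 85+ plus every item).
MAX_POINTS = 7 + sum(ITEM_POINTS.values())  # 26

#: Scores at or above this value are pooled into the top ("14+") group.
GROUP_CAP = 14

N_GROUPS = 15

GROUP_LABELS: tuple[str, ...] = tuple(str(g) for g in range(14)) + ("14+",)

# ---------------------------------------------------------------------------
# Cohort point-score distributions (persons per risk group, groups 0..14+)
# ---------------------------------------------------------------------------

GROUP_COUNTS: dict[str, tuple[int, ...]] = {
    # US Health and Retirement Study, 1998 wave, East/Midwest/West regions
    "development": (742, 1368, 1480, 1448, 1334, 1168, 890, 762,
                    552, 409, 324, 244, 177, 315, 488),
    # US Health and Retirement Study, 1998 wave, South region
    "validation": (494, 889, 973, 994, 845, 762, 638, 501,
                   404, 310, 233, 192, 159, 260, 355),
    # English Longitudinal Study of Ageing, 2004 wave
    "elsa": (459, 503, 1013, 937, 868, 810, 589, 517,
             405, 296, 202, 154, 118, 67, 104),
}

#: Follow-up horizon (years of administrative censoring) per cohort.
FOLLOWUP_YEARS: dict[str, float] = {
    "development": 10.0,
    "validation": 10.0,
    "elsa": 8.0,
}

# ---------------------------------------------------------------------------
# Item prevalences (fraction of cohort) for factor-level simulation
# ---------------------------------------------------------------------------

#: Development-cohort marginal prevalences.  Age is a distribution over the
#: seven bands; the remaining items are Bernoulli fractions.
ITEM_PREVALENCE: dict[str, dict] = {
    "development": {
        "age_band_counts": (3154, 2145, 1798, 1669, 1362, 856, 715),
        "male": 5062 / 11701,
        "diabetes": 1608 / 11701,
        "cancer": 1349 / 11701,
        "lung_disease": 443 / 11701,
        "heart_failure": 298 / 11701,
        "bmi_under_25": 4402 / 11701,
        "current_smoker": 1813 / 11701,
        "difficulty_bathing": 754 / 11701,
        "difficulty_finances": 887 / 11701,
        "difficulty_walking_blocks": 3167 / 11701,
        "difficulty_push_pull": 3329 / 11701,
    },
    "validation": {
        "age_band_counts": (2328, 1547, 1188, 1017, 909, 533, 487),
        "male": 3493 / 8009,
        "diabetes": 1246 / 8009,
        "cancer": 862 / 8009,
        "lung_disease": 376 / 8009,
        "heart_failure": 240 / 8009,
        "bmi_under_25": 2981 / 8009,
        "current_smoker": 1416 / 8009,
        "difficulty_bathing": 644 / 8009,
        "difficulty_finances": 737 / 8009,
        "difficulty_walking_blocks": 2542 / 8009,
        "difficulty_push_pull": 2604 / 8009,
    },
    "elsa": {
        "age_band_counts": (2197, 1215, 1198, 971, 732, 481, 248),
        "male": 3173 / 7042,
        "diabetes": 541 / 7042,
        "cancer": 536 / 7042,
        "lung_disease": 445 / 7042,
        "heart_failure": 1360 / 7042,
        "bmi_under_25": 1954 / 7042,
        "current_smoker": 1019 / 7042,
        "difficulty_bathing": 706 / 7042,
        "difficulty_finances": 145 / 7042,
        "difficulty_walking_blocks": 722 / 7042,
        "difficulty_push_pull": 1171 / 7042,
    },
}

# ---------------------------------------------------------------------------
# Published Gompertz-predicted survival quantiles per risk group
# ---------------------------------------------------------------------------

#: group -> (time to 25% mortality, median, time to 75% mortality), years,
#: as fitted in the development cohort and printed to 0.1 y.
PREDICTED_QUANTILES: dict[int, tuple[float, float, float]] = {
    0: (27.8, 35.4, 41.5),
    1: (25.5, 33.1, 39.1),
    2: (22.7, 30.1, 36.1),
    3: (16.7, 23.7, 29.5),
    4: (14.4, 21.1, 26.8),
    5: (11.4, 17.7, 23.2),
    6: (8.7, 14.3, 19.6),
    7: (7.4, 12.6, 17.6),
    8: (5.8, 10.3, 14.9),
    9: (4.7, 8.8, 13.1),
    10: (3.8, 7.3, 11.2),
    11: (2.9, 5.9, 9.4),
    12: (2.6, 5.3, 8.6),
    13: (2.3, 4.8, 7.8),
    14: (1.6, 3.4, 5.9),
}

#: Published Harrell's c of the point score (development cohort).
HARRELLS_C: dict[str, float] = {
    "development": 0.790,
    "validation": 0.779,
    "elsa": 0.801,
}
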