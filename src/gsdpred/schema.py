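"""Cohort schema: feature order, response vocabularies, pose codes.

The analysis uses 25 scalar ("non-WBB") features per subject: age, sex,
19 survey responses, and 4 grip-strength measures (right/left hand, two
trials, kg).  Survey items are either 5-level Likert ratings (0-4),
yes/no items, or non-negative fall/near-fall counts.  The fixed order
below is the canonical encoding order used by every downstream stage.
"""

from __future__ import annotations

# Balance-test pose codes: eyes open/closed x feet apart/together.
POSES = ("EO_FA", "EO_FT", "EC_FA", "EC_FT")
TRIALS = (1, 2)

# Self-rated health: 0 = Poor ... 4 = Excellent.
HEALTH_LEVELS = ("Poor", "Fair", "Good", "Very good", "Excellent")
# Task difficulty: 0 = No Difficulty ... 4 = Unable to do.
DIFFICULTY_LEVELS = (
    "No Difficulty",
    "A Little Difficulty",
    "Some Difficulty",
    "Much Difficulty",
    "Unable to do",
)
YESNO_LEVELS = ("No", "Yes")
SEX_LEVELS = ("Male", "Female")  # female encoded 1, male 0

# (column name, kind). Kinds: likert_health, likert_difficulty, yesno, count.
SURVEY_ITEMS = (
    ("near_fall_past_year", "yesno"),
    ("n_near_falls", "count"),
    ("fallen_past_year", "yesno"),
    ("n_falls", "count"),
    ("fall_inside_home", "yesno"),
    ("fall_outside_home", "yesno"),
    ("fall_in_community", "yesno"),
    ("diff_shopping", "yesno"),
    ("diff_managing_money", "yesno"),
    ("diff_walking_across_room", "yesno"),
    ("diff_light_housework", "yesno"),
    ("diff_bathing", "yesno"),
    ("health_rating", "likert_health"),
    ("diff_stooping", "likert_difficulty"),
    ("diff_lifting_10lb", "likert_difficulty"),
    ("diff_reaching_overhead", "likert_difficulty"),
    ("diff_writing_grasping", "likert_difficulty"),
    ("diff_walking_quarter_mile", "likert_difficulty"),
    ("diff_heavy_housework", "likert_difficulty"),
)

GRIP_COLUMNS = ("grip_r1", "grip_l1", "grip_r2", "grip_l2")

# The canonical 25-feature order: age, sex, 19 survey items, 4 grips.
FEATURE_ORDER = (
    ("age",)
    + ("sex",)
    + tuple(name for name, _ in SURVEY_ITEMS)
    + GRIP_COLUMNS
)

FLAG_COLUMNS = (
    "flag_equipment_error",
    "flag_missing_survey",
    "flag_missing_wbb",
    "flag_unable_to_complete",
)

LABEL_POSITIVE = "GSD+"
LABEL_NEGATIVE = "GSD-"
LABELS = (LABEL_NEGATIVE, LABEL_POSITIVE)


def survey_kind(name: str) -> str:
    for item, kind in SURVEY_ITEMS:
        if item == name:
            return kind
    raise KeyError(name)
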