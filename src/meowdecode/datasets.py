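"""Published count tables from a 225-listener meow-classification survey.

These are the absolute frequencies of correct/incorrect context assignment
reported by a survey in which 225 adults classified one medioid and one
outlier meow per emission context, overall and broken down by listener
attributes.  They serve as worked-example inputs for the contingency
statistics: percentages and chi-square tests recomputed from these counts
reproduce the published accuracy rates and significance levels.
"""

from __future__ import annotations

#: (correct, incorrect) medioid/outlier assignment counts per context.
ASSIGNMENT_COUNTS = {
    "waiting_for_food": {"medioid": (91, 134), "outlier": (61, 164)},
    "isolation": {"medioid": (60, 165), "outlier": (32, 193)},
    "brushing": {"medioid": (74, 151), "outlier": (30, 195)},
}

#: Medioid assignment counts by listener attribute: per context, per
#: attribute, rows are (level, correct, incorrect).
ATTRIBUTE_COUNTS = {
    "waiting_for_food": {
        "gender": [("male", 27, 52), ("female", 64, 82)],
        "parent": [("parent", 24, 48), ("nonparent", 67, 86)],
        "cat_owner": [("owner", 48, 60), ("nonowner", 43, 74)],
        "grew_up_with_cats": [("yes", 51, 71), ("no", 40, 63)],
    },
    "isolation": {
        "gender": [("male", 14, 65), ("female", 46, 100)],
        "parent": [("parent", 14, 58), ("nonparent", 46, 107)],
        "cat_owner": [("owner", 38, 70), ("nonowner", 22, 95)],
        "grew_up_with_cats": [("yes", 38, 84), ("no", 22, 81)],
    },
    "brushing": {
        "gender": [("male", 19, 60), ("female", 55, 91)],
        "parent": [("parent", 18, 54), ("nonparent", 56, 97)],
        "cat_owner": [("owner", 48, 60), ("nonowner", 26, 91)],
        "grew_up_with_cats": [("yes", 44, 78), ("no", 30, 73)],
    },
}

N_PARTICIPANTS = 225
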