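"""Bundled reference tables from the original two-chamber strawberry trial.

The trial reported its grade distributions as percentages per treatment
group.  The integer counts below are the unique reconstruction that makes
every printed percentage an exact count given the group totals (cooling
CL n = 80, heating HT n = 91, shared control CT n = 83); e.g. 10.0 % of 80
is exactly 8 fruits.  They drive the worked examples and the statistics
regression tests; they are inputs, not outputs, of this package.
"""

from __future__ import annotations

from .quality import GradeTable

__all__ = [
    "CL_CT_GRADES",
    "HT_CT_GRADES",
    "CLASS_COUNTS",
    "reference_grade_tables",
]

# group -> grade -> fruit count (nonstandard fruits already excluded)
CL_CT_GRADES = GradeTable(
    {
        "CL": {"3L": 8, "2L": 36, "L": 20, "M": 14, "S": 2},
        "CT": {"3L": 18, "2L": 24, "L": 23, "M": 16, "S": 2},
    }
)

HT_CT_GRADES = GradeTable(
    {
        "HT": {"3L": 16, "2L": 20, "L": 34, "M": 17, "S": 4},
        "CT": {"3L": 18, "2L": 24, "L": 23, "M": 16, "S": 2},
    }
)

# group -> (premium KJ count, marketable KJ+B count, total fruits)
CLASS_COUNTS = {
    "CL": (71, 76, 80),
    "HT": (76, 87, 91),
    "CT": (71, 80, 83),
}


def reference_grade_tables() -> dict[str, GradeTable]:
    return {"CL-CT": CL_CT_GRADES, "HT-CT": HT_CT_GRADES}
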