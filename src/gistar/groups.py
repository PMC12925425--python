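"""Built-in population-group vocabulary.

Maps group names to the ACS table B03002 variable that counts them.  The
four default groups are the ones shipped in the reference datasets; the
remaining entries cover the other B03002 populations commonly requested.
"""

from __future__ import annotations

#: Group name -> B03002 count variable.
B03002_GROUP_VARIABLES: dict = {
    "nhWhite": "B03002_003",
    "nhBlack": "B03002_004",
    "nhAIAN": "B03002_005",
    "nhAsian": "B03002_006",
    "nhNHPI": "B03002_007",
    "nhOther": "B03002_008",
    "nhTwoOrMore": "B03002_009",
    "Hispanic": "B03002_012",
    "hWhite": "B03002_013",
    "hBlack": "B03002_014",
    "hAIAN": "B03002_015",
}

#: Denominator for every proportion.
TOTAL_POPULATION_VARIABLE = "B03002_001"

#: Groups used when no explicit list is configured.
DEFAULT_GROUPS: tuple = ("nhWhite", "nhBlack", "nhAsian", "Hispanic")
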