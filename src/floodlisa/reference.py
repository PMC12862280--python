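"""Published statewide reference tables (North Carolina, 2,672 tracts).

Transcribed summary tables from the published statewide flood-risk /
inequality cluster analysis this package reimplements. They serve as
round-trip fixtures: the profiling arithmetic (percentages from counts,
deltas from cluster and state means) must reproduce the printed values
from the printed inputs. They are inputs for validation, never outputs of
this package's computations.

``TABLE1`` — cluster membership: tract counts, populations, densities.
``TABLE2`` — high-high cluster demographic means vs the state average,
with the printed delta (the parenthetical) per concentration-index
variant; dollar-valued rows are flagged.
``TABLE3`` — rural/suburban/urban counts and printed percentages per
cluster and variant.
``GLOBAL_MORAN`` — published univariate global Moran's I values.
"""

from __future__ import annotations

# (variant, cluster) -> (tracts, population, density per sq mi)
TABLE1 = {
    ("ice_income", "HH"): (140, 392_558, 323.97),
    ("ice_income", "LL"): (283, 1_385_593, 1407.45),
    ("ice_income", "LH"): (110, 396_556, 444.69),
    ("ice_income", "HL"): (236, 929_036, 1525.45),
    ("ice_race", "HH"): (38, 74_916, 267.59),
    ("ice_race", "LL"): (240, 1_067_853, 1167.24),
    ("ice_race", "LH"): (212, 714_198, 396.71),
    ("ice_race", "HL"): (280, 1_246_766, 1713.22),
    ("ice_race_income", "HH"): (82, 223_523, 362.39),
    ("ice_race_income", "LL"): (266, 1_273_130, 1247.40),
    ("ice_race_income", "LH"): (168, 565_591, 384.25),
    ("ice_race_income", "HL"): (255, 1_041_489, 1683.45),
}

ALL_TRACTS = {"tracts": 2672, "population": 10_584_340, "density": 1374.44}

# indicator -> (is_dollar, {variant: (cluster_mean, printed_delta)}, state_mean)
TABLE2 = {
    "Median age (years)": (
        False,
        {"ice_income": (41.5, 0.8), "ice_race": (35.1, -5.6), "ice_race_income": (44.6, 3.9)},
        40.7,
    ),
    "Under 5 years old (%)": (
        False,
        {"ice_income": (3.6, -1.9), "ice_race": (2.6, -2.9), "ice_race_income": (3.1, -2.4)},
        5.5,
    ),
    "Over 65 years old (%)": (
        False,
        {"ice_income": (35.6, 18.4), "ice_race": (22.4, 5.2), "ice_race_income": (31.6, 14.4)},
        17.2,
    ),
    "No high school (%)": (
        False,
        {"ice_income": (10.2, -1.3), "ice_race": (8.3, -3.2), "ice_race_income": (10.7, -0.8)},
        11.5,
    ),
    "Unemployment (%)": (
        False,
        {"ice_income": (4.9, -0.6), "ice_race": (4.2, -1.3), "ice_race_income": (4.6, -0.9)},
        5.5,
    ),
    "No health insurance (%)": (
        False,
        {"ice_income": (10.8, -0.1), "ice_race": (7.8, -3.1), "ice_race_income": (10.9, 0.0)},
        10.9,
    ),
    "Renters (%)": (
        False,
        {"ice_income": (26.2, -7.7), "ice_race": (19.6, -14.3), "ice_race_income": (28.2, -5.7)},
        33.9,
    ),
    "Mobile homes (%)": (
        False,
        {"ice_income": (17.2, 4.5), "ice_race": (12.1, -0.6), "ice_race_income": (17.0, 4.3)},
        12.7,
    ),
    "Median housing value ($)": (
        True,
        {
            "ice_income": (204_741, -9_391),
            "ice_race": (100_263, -113_869),
            "ice_race_income": (162_546, -51_586),
        },
        214_132,
    ),
    "Rent burden > 30% income (%)": (
        False,
        {"ice_income": (41.5, 1.4), "ice_race": (22.6, -17.4), "ice_race_income": (39.8, -0.2)},
        40.0,
    ),
    "Median household income ($)": (
        True,
        {
            "ice_income": (46_708, -17_752),
            "ice_race": (32_769, -31_691),
            "ice_race_income": (39_920, -24_540),
        },
        64_460,
    ),
    "Social security benefits (%)": (
        False,
        {"ice_income": (39.9, 6.5), "ice_race": (27.6, -5.8), "ice_race_income": (36.2, 2.8)},
        33.4,
    ),
    "White (%)": (
        False,
        {"ice_income": (73.4, 6.7), "ice_race": (30.3, -36.4), "ice_race_income": (61.0, -5.7)},
        66.7,
    ),
    "Black (%)": (
        False,
        {"ice_income": (6.9, -14.3), "ice_race": (20.9, -0.3), "ice_race_income": (11.4, -9.8)},
        21.2,
    ),
    "Asian (%)": (
        False,
        {"ice_income": (0.5, -2.2), "ice_race": (0.3, -2.3), "ice_race_income": (0.5, -2.2)},
        2.7,
    ),
    "Hispanic (%)": (
        False,
        {"ice_income": (5.3, -4.0), "ice_race": (4.5, -4.8), "ice_race_income": (5.6, -3.7)},
        9.3,
    ),
    "No vehicle available (%)": (
        False,
        {"ice_income": (6.4, 0.5), "ice_race": (5.8, -0.1), "ice_race_income": (7.7, 1.8)},
        5.9,
    ),
    "No internet access (%)": (
        False,
        {"ice_income": (13.0, 0.3), "ice_race": (9.9, -2.8), "ice_race_income": (13.2, 0.5)},
        12.7,
    ),
    "No computer (%)": (
        False,
        {"ice_income": (9.6, 1.1), "ice_race": (7.8, -0.7), "ice_race_income": (9.5, 1.0)},
        8.5,
    ),
}

# (variant, cluster) -> {class: (count, printed_percent)}
TABLE3 = {
    ("ice_income", "HH"): {"rural": (36, 25.7), "suburban": (23, 16.4), "urban": (81, 57.8)},
    ("ice_race", "HH"): {"rural": (13, 34.2), "suburban": (8, 21.0), "urban": (17, 44.7)},
    ("ice_race_income", "HH"): {"rural": (25, 30.5), "suburban": (16, 19.5), "urban": (41, 50.0)},
    ("ice_income", "LL"): {"rural": (1, 0.3), "suburban": (5, 1.7), "urban": (277, 97.8)},
    ("ice_race", "LL"): {"rural": (2, 0.8), "suburban": (11, 4.5), "urban": (227, 94.5)},
    ("ice_race_income", "LL"): {"rural": (1, 0.3), "suburban": (6, 2.2), "urban": (259, 97.7)},
    ("ice_income", "LH"): {"rural": (9, 8.1), "suburban": (23, 20.9), "urban": (78, 70.9)},
    ("ice_race", "LH"): {"rural": (32, 15.0), "suburban": (38, 17.9), "urban": (142, 66.9)},
    ("ice_race_income", "LH"): {"rural": (20, 11.9), "suburban": (30, 17.8), "urban": (118, 70.2)},
    ("ice_income", "HL"): {"rural": (6, 2.5), "suburban": (23, 9.7), "urban": (207, 87.5)},
    ("ice_race", "HL"): {"rural": (5, 1.7), "suburban": (18, 6.4), "urban": (257, 91.7)},
    ("ice_race_income", "HL"): {"rural": (6, 2.3), "suburban": (24, 9.4), "urban": (225, 88.2)},
}

#: Rows of TABLE3 whose printed percentage is arithmetically inconsistent
#: with the printed counts themselves (off by more than one unit in the
#: last printed decimal under any rounding convention). Kept for the
#: record; the validation suite documents them as discrepancies.
TABLE3_KNOWN_DISCREPANT = {
    ("ice_race_income", "LL", "urban"),  # 259/266 = 97.4, printed 97.7
    ("ice_income", "HL", "urban"),       # 207/236 = 87.7, printed 87.5
}

# univariate global Moran's I, statewide
GLOBAL_MORAN = {
    "ice_income": 0.568,
    "ice_race": 0.669,
    "ice_race_income": 0.565,
    "p_flood_high": 0.554,
}
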