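"""Bundled example data: a published dual-platform miRNA comparison.

A two-library sequencing experiment (non-aestivation NA vs deep-
aestivation DA sea-cucumber intestine) profiled by both deep sequencing
and microarray. The printed differential table and mapping totals are
embedded here as regression fixtures for the scoring, intersection and
mapping-statistics engines.

Columns of :func:`dual_platform_table`:
    id        miRNA name
    x, y      per-library sequencing counts (printed in the RPM columns)
    sig_na, sig_da   microarray mean signals
    fc_array, q_array  microarray log2 fold change and FDR
    starred   flagged in the source as concordant on both platforms
"""

from __future__ import annotations

import pandas as pd

#: total clean reads in the NA and DA sequencing libraries
LIBRARY_TOTALS = (10_876_248, 11_194_928)

#: mapping totals: unique tags and reads, per library
MAPPING = {
    "total_unique": (561_504, 690_419),
    "total_reads": (10_876_248, 11_194_928),
    "mirna_unique": (14_687, 20_110),
    "mirna_reads": (6_782_785, 6_715_567),
}

#: the two dominant tags' per-library counts (same family)
DOMINANT_TAG_COUNTS = {
    "miR-10a": (2_973_660, 1_482_171),
    "miR-10a-5p": (2_891_589, 1_423_173),
}

# id, x, y, sig_na, sig_da, fc_array, q_array, starred
_DUAL_ROWS = [
    ("miR-200-3p", 1011, 3148, 1359, 6563, 2.27, 2.08e-04, True),
    ("miR-2004", 2633, 7067, 19984, 49699, 1.31, 6.88e-05, True),
    ("miR-2010", 3564, 14243, 659, 5803, 3.14, 1.65e-04, True),
    ("miR-22", 181, 736, 135, 641, 2.25, 5.04e-05, True),
    ("miR-252a", 114, 355, 104, 591, 2.51, 2.31e-07, True),
    ("miR-252a-5p", 116, 357, 103, 593, 2.53, 1.05e-07, True),
    ("miR-7", 10559, 29640, 440, 4101, 3.22, 7.78e-05, True),
    ("miR-92", 55629, 142056, 4758, 9777, 1.04, 4.31e-08, True),
    ("miR-92a", 43473, 90546, 4217, 8821, 1.06, 8.41e-08, True),
    ("miR-153", 58, 299, 5378, 4439, -0.28, 1.10e-03, False),
    ("miR-153-3p", 51, 268, 4662, 2884, -0.68, 2.64e-05, False),
    ("miR-2008", 405, 1618, 9953, 1092, -3.19, 8.60e-08, False),
    ("miR-310", 33, 184, 483, 823, 0.77, 9.84e-06, False),
    ("miR-310-3p", 25, 84, 1670, 1114, -0.58, 1.38e-02, False),
    ("miR-71a", 153, 410, 1798, 1550, -0.21, 5.32e-02, False),
    ("miR-71a-5p", 25, 84, 8982, 9585, 0.09, 9.82e-02, False),
    ("miR-92c", 41719, 85216, 4241, 8728, 1.04, 3.45e-08, False),
    ("miR-92-3p", 40066, 81951, 4146, 8610, 1.05, 5.91e-08, False),
    ("miR-235a", 6071, 10122, 4720, 9771, 1.05, 5.72e-07, False),
    ("miR-7-5p", 13133, 23804, 454, 4611, 3.34, 6.57e-05, False),
    ("miR-2012-5p", 475339, 804653, 3150, 6703, 1.09, 2.05e-04, False),
    ("let-7a-5p", 817, 1658, 4284, 1488, -1.53, 7.45e-05, False),
    ("miR-210", 91179, 86593, 13777, 2116, -2.70, 4.12e-04, False),
    ("miR-210-3p", 93148, 88209, 13782, 2108, -2.71, 4.28e-04, False),
    ("let-7-5p", 996, 1456, 645, 107, -2.59, 5.00e-04, False),
    ("miR-31a-5p", 2181, 1517, 11587, 4989, -1.22, 1.38e-03, False),
    ("miR-2011", 290828, 305417, 57203, 14562, -1.97, 1.96e-03, False),
    ("miR-375-3p", 90125, 119762, 613, 101, -2.60, 2.21e-03, False),
    ("miR-31-5p", 209383, 168625, 11128, 5180, -1.10, 2.36e-03, False),
    ("miR-72-5p", 191131, 158706, 10172, 4848, -1.07, 2.57e-03, False),
    ("miR-375", 96422, 129304, 646, 101, -2.68, 3.36e-03, False),
    ("miR-29a", 2032, 3541, 1621, 342, -2.25, 4.76e-03, False),
    ("miR-375b-3p", 68871, 90878, 673, 124, -2.44, 4.94e-03, False),
    ("miR-10a-5p", 2891589, 1423173, 27597, 26595, -0.05, 3.02e-03, False),
    ("miR-2006", 6401, 1762, 4292, 2835, -0.60, 1.49e-04, False),
]

#: printed sequencing log2 fold changes, at the table's printed precision
PRINTED_FC = {
    "miR-200-3p": 1.60, "miR-2004": 1.38, "miR-2010": 1.96, "miR-22": 1.98,
    "miR-252a": 1.60, "miR-252a-5p": 1.58, "miR-7": 1.45, "miR-92": 1.31,
    "miR-92a": 1.02, "miR-153": 2.32, "miR-153-3p": 2.35, "miR-2008": 1.96,
    "miR-310": 2.44, "miR-310-3p": 1.71, "miR-71a": 1.38, "miR-71a-5p": 1.71,
    "miR-92c": 0.9888, "miR-92-3p": 0.9907, "miR-235a": 0.6958,
    "miR-7-5p": 0.8163, "miR-2012-5p": 0.7177, "let-7a-5p": 0.9794,
    "miR-210": -0.116, "miR-210-3p": -0.12, "let-7-5p": 0.5061,
    "miR-31a-5p": -0.565, "miR-2011": 0.0289, "miR-375-3p": 0.3685,
    "miR-31-5p": -0.354, "miR-72-5p": -0.31, "miR-375": 0.3817,
    "miR-29a": 0.7596, "miR-375b-3p": 0.3584, "miR-10a-5p": -1.06,
    "miR-2006": -1.90,
}

#: decimals printed per row of the fold-change column
PRINTED_FC_DECIMALS = {
    mid: len(str(v).split(".")[1]) for mid, v in PRINTED_FC.items()
}


def dual_platform_table() -> pd.DataFrame:
    return pd.DataFrame(
        _DUAL_ROWS,
        columns=["id", "x", "y", "sig_na", "sig_da", "fc_array", "q_array",
                 "starred"])


def starred_set() -> set[str]:
    return {r[0] for r in _DUAL_ROWS if r[-1]}
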