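"""Bundled reference dataset: per-sample duplex yields and unique
mutation counts for a published-style cohort of six young men with
matched blood and sperm duplex sequencing over the standard 48 kb panel.

Only raw inputs are stored (duplex bases sequenced and unique mutation
counts by variant class); every frequency is recomputed by the burden
module.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["cohort_summary"]

_ROWS = [
    # sample, tissue, duplex_bases, SNV, MNV, indel, SV
    ("blood1", "blood", 1_354_242_708, 137, 1, 8, 0),
    ("blood2", "blood", 1_353_042_031, 175, 2, 17, 0),
    ("blood3", "blood", 1_200_540_488, 114, 0, 9, 1),
    ("blood4", "blood", 1_336_908_675, 182, 2, 6, 0),
    ("blood5", "blood", 1_341_009_611, 188, 5, 11, 1),
    ("blood6", "blood", 1_310_508_887, 154, 0, 9, 1),
    ("sperm1", "sperm", 1_129_894_519, 32, 0, 107, 13),
    ("sperm2", "sperm", 1_302_208_129, 32, 1, 69, 4),
    ("sperm3", "sperm", 1_214_503_210, 29, 0, 67, 15),
    ("sperm4", "sperm", 1_301_231_218, 33, 2, 105, 7),
    ("sperm5", "sperm", 1_236_182_547, 31, 0, 92, 10),
    ("sperm6", "sperm", 1_280_782_498, 27, 0, 98, 19),
]


def cohort_summary() -> pd.DataFrame:
    """Per-sample duplex bases and unique mutation counts by class."""
    return pd.DataFrame(
        _ROWS,
        columns=["sample_id", "tissue", "duplex_bases", "SNV", "MNV", "indel", "SV"],
    )
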