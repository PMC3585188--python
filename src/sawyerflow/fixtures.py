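"""Published summary tables for the 14-population Chinese *M. alternatus* survey.

These are the published summary inputs the association stage can run on directly when
raw sequences are unavailable: the per-province covariates (marine-port
presence, pinewood-nematode infestation status, 11-year mean GDP in billion
yuan, 10-year mean regional freight turnover in billion tonne-km) and the
haplotype incidence listing (which haplotypes occur in which population).
Per-population haplotype *counts* were never published, so the haplotype
table carries incidence only — diversity statistics that need frequencies
cannot be computed from it, and the fixture does not pretend otherwise.

The three-level economic-status grouping is reconstructed from the published
per-group private-haplotype totals (16/22/5), which force a unique assignment
given the per-population private counts.
"""

from __future__ import annotations

import pandas as pd

from .association import CovariateTable
from .seqio import HaplotypeTable

# region, code, port, pwn, gdp (billion yuan), rft (billion tkm)
_TABLE1 = [
    ("Eastern", "JS", 1, 1, 2052.93, 305.10),
    ("Eastern", "SD", 1, 1, 2081.32, 661.37),
    ("Eastern", "ZJ", 1, 1, 1470.77, 358.48),
    ("Eastern", "FJ", 1, 1, 773.46, 172.16),
    ("Southern", "GD", 1, 1, 2412.89, 396.87),
    ("Central", "AH", 0, 0, 625.58, 279.01),
    ("Central", "HA", 0, 1, 1196.59, 318.00),
    ("Central", "HB", 1, 1, 804.91, 168.85),
    ("Central", "HN", 0, 0, 780.28, 175.62),
    ("Central", "JX", 0, 1, 457.92, 126.00),
    ("Southwestern", "CQ", 1, 0, 368.08, 86.29),
    ("Southwestern", "GX", 1, 0, 457.14, 137.79),
    ("Southwestern", "GZ", 0, 1, 228.62, 66.12),
    ("Southwestern", "YN", 0, 0, 392.04, 69.34),
]

# population -> haplotype incidence
_TABLE2 = {
    "JS": ["H33", "H34", "H35", "H36", "H49", "H50"],
    "SD": ["H41", "H42", "H43", "H44", "H45"],
    "ZJ": ["H47", "H48", "H49", "H50", "H51", "H52", "H53", "H54"],
    "FJ": ["H8", "H9", "H10", "H13", "H32", "H45", "H48"],
    "GD": ["H11", "H12", "H13", "H14", "H43", "H52"],
    "AH": ["H1", "H2", "H3", "H4", "H49", "H50"],
    "HA": ["H50", "H52"],
    "HB": ["H19", "H20", "H21", "H22", "H23", "H24", "H25", "H29", "H32"],
    "HN": ["H26", "H27", "H28", "H29", "H30", "H31", "H32"],
    "JX": ["H37", "H38", "H39", "H40", "H43", "H48"],
    "CQ": ["H5", "H6", "H7", "H19"],
    "GX": ["H15", "H16", "H17"],
    "GZ": ["H18", "H42"],
    "YN": ["H46"],
}

ECON_STATUS = {
    "JS": "developed", "SD": "developed", "ZJ": "developed",
    "FJ": "developed", "GD": "developed",
    "AH": "less-developed", "HA": "less-developed", "HB": "less-developed",
    "HN": "less-developed", "JX": "less-developed", "CQ": "less-developed",
    "GX": "underdeveloped", "GZ": "underdeveloped", "YN": "underdeveloped",
}


def covariate_fixture() -> CovariateTable:
    """The 14-province covariate table, with region and economic-status columns."""
    df = pd.DataFrame(
        _TABLE1, columns=["region", "population", "port", "pwn", "gdp", "rft"]
    ).set_index("population")
    df["econ_status"] = pd.Series(ECON_STATUS)
    return CovariateTable(df)


def haplotype_fixture() -> HaplotypeTable:
    """The published haplotype incidence (54 haplotypes over 14 populations).

    Sequences and per-population counts are absent (not published at the
    individual level); shared/private structure and R_shr are fully defined.
    """
    pops = [row[1] for row in _TABLE1]
    order: list[str] = []
    incidence: dict[str, set[str]] = {}
    for pop in pops:
        for h in _TABLE2[pop]:
            if h not in incidence:
                incidence[h] = set()
                order.append(h)
            incidence[h].add(pop)
    order = sorted(order, key=lambda h: int(h[1:]))
    return HaplotypeTable([(h, None) for h in order], incidence, pops)


def fixture_from_tables() -> tuple[HaplotypeTable, CovariateTable]:
    """Both published-table fixtures, ready for the association stage."""
    return haplotype_fixture(), covariate_fixture()
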