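"""Published cohort tabulations bundled as ready-made contingency tables.

These are the printed counts from a 131-patient laparoscopic partial
nephrectomy cohort (cT1a tumors, segmental artery clamping under a 3D
perfusion model), cross-tabulating categorical tumor characteristics against
the number of feeding lobar arteries (1-2 vs 3-5) and the number of target
segmental arteries (1 vs 2-3).  The first row of each table is the reference
level; the second column is the event (more feeding arteries).
"""

from __future__ import annotations

from .cohortstats import ContingencyTable

__all__ = [
    "growth_pattern_vs_lobar",
    "nearness_vs_lobar",
    "location_vs_lobar",
    "growth_pattern_vs_segmental",
    "nearness_vs_segmental",
    "location_vs_segmental",
    "lobar_group_tables",
]

_FLA = ("FLA 1-2", "FLA 3-5")
_TSA = ("TSA 1", "TSA 2-3")


def growth_pattern_vs_lobar() -> ContingencyTable:
    """Exophytic/mesophytic/endophytic growth vs feeding lobar artery group."""
    return ContingencyTable(
        ("Exophytic", "Mesophytic", "Endophytic"), _FLA,
        [[46, 22], [24, 29], [7, 3]],
    )


def nearness_vs_lobar() -> ContingencyTable:
    """Nearness to UCS/sinus (>=7 / 4-7 / <=4 mm) vs feeding lobar group."""
    return ContingencyTable(
        (">=7 mm", "<7 mm and >4 mm", "<=4 mm"), _FLA,
        [[22, 3], [37, 27], [18, 24]],
    )


def location_vs_lobar() -> ContingencyTable:
    """Location relative to the polar lines vs feeding lobar group."""
    return ContingencyTable(
        ("Entirely at the polar", "Mostly at the polar", "Mostly between polar lines"),
        _FLA,
        [[42, 19], [26, 19], [9, 16]],
    )


def growth_pattern_vs_segmental() -> ContingencyTable:
    return ContingencyTable(
        ("Exophytic", "Mesophytic", "Endophytic"), _TSA,
        [[43, 25], [28, 25], [8, 2]],
    )


def nearness_vs_segmental() -> ContingencyTable:
    return ContingencyTable(
        (">=7 mm", "<7 mm and >4 mm", "<=4 mm"), _TSA,
        [[19, 6], [37, 27], [23, 19]],
    )


def location_vs_segmental() -> ContingencyTable:
    return ContingencyTable(
        ("Entirely at the polar", "Mostly at the polar", "Mostly between polar lines"),
        _TSA,
        [[38, 23], [27, 18], [14, 11]],
    )


def lobar_group_tables() -> dict[str, ContingencyTable]:
    """The three categorical predictors against the feeding-lobar outcome."""
    return {
        "growth_pattern": growth_pattern_vs_lobar(),
        "nearness": nearness_vs_lobar(),
        "location": location_vs_lobar(),
    }
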