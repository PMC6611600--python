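"""Programmatic fixtures: the published genotype and culture tables.

These are the printed summary tables of the emulated study, re-expressed
as per-embryo records so the tabulation and scoring code paths can
reconstruct them.  Where only aggregate counts were printed, litter and
embryo identities are synthetic (ids invented, embryos distributed
round-robin over the printed number of litters); every count-level
quantity matches the published tables.
"""

from __future__ import annotations

import pandas as pd

from .culture import CultureRecord
from .io import UNTYPED

__all__ = [
    "weaning_counts",
    "hetxwt_embryo_counts",
    "hetxhet_inbred_records",
    "hetxhet_mixed_records",
    "blastocyst_culture_records",
    "wildtype_culture_records",
]


def weaning_counts() -> dict[str, dict[str, int]]:
    """Weaning genotype counts of het×WT litters, per genetic background.

    The inbred background shows a heterozygote deficit (chi-square P<0.01);
    the mixed background fits 1:1.
    """
    return {
        "CD1;FvB": {"+/+": 312, "+/-": 285},
        "C57BL/6": {"+/+": 62, "+/-": 36},
    }


def hetxwt_embryo_counts() -> dict[str, dict[str, int]]:
    """Genotypes of het×WT embryos on the inbred background (two stages)."""
    return {
        "E15.5": {"+/+": 3, "+/-": 5},
        "E18.5": {"+/+": 12, "+/-": 8},
    }


# (stage, +/+, +/-, -/-, untyped, of-which-resorbed, litters)
_HETXHET_INBRED = [
    ("E3.5", 3, 9, 2, 0, 0, 3),
    ("E9.5", 1, 11, 0, 1, 1, 2),
    ("E11.5", 1, 3, 0, 1, 1, 1),
    ("E16.5", 2, 2, 0, 1, 1, 1),
    ("E17.5", 1, 7, 0, 2, 2, 2),
]

_HETXHET_MIXED = [
    ("E3.5", 37, 63, 42, 17, 0, 14),
    ("E7.5", 10, 19, 0, 7, 6, 4),
    ("E8.5", 9, 31, 0, 19, 15, 4),
    ("E9.5", 39, 72, 0, 23, 21, 10),
    ("E10.5", 17, 43, 0, 16, 16, 7),
    ("E11.5", 5, 26, 0, 9, 9, 3),
    ("E14.5", 27, 41, 0, 15, 14, 7),
    ("E16.5", 14, 25, 0, 11, 11, 5),
    ("E17.5", 15, 17, 0, 6, 6, 3),
    ("E18.5", 18, 34, 0, 18, 18, 6),
]


def _expand(rows) -> pd.DataFrame:
    records = []
    for stage, wt, het, hom, nt, resorbed, litters in rows:
        embryos = (
            ["+/+"] * wt + ["+/-"] * het + ["-/-"] * hom + [UNTYPED] * nt
        )
        # resorptions sit among the untyped embryos in these tables
        resorbed_flags = [False] * (len(embryos) - nt) + [True] * resorbed + [
            False
        ] * (nt - resorbed)
        for i, (genotype, res) in enumerate(zip(embryos, resorbed_flags)):
            records.append(
                {
                    "stage": stage,
                    "genotype": genotype,
                    "resorbed": res,
                    "litter": f"{stage}-litter{i % litters + 1}",
                }
            )
    return pd.DataFrame(records, columns=["stage", "genotype", "resorbed", "litter"])


def hetxhet_inbred_records() -> pd.DataFrame:
    """Per-embryo records of the het×het cross on the inbred background.

    Homozygous mutants appear only at E3.5; the cross totals 42 embryos
    over 9 litters.
    """
    return _expand(_HETXHET_INBRED)


def hetxhet_mixed_records() -> pd.DataFrame:
    """Per-embryo records of the het×het cross on the mixed background.

    E3.5 counts (37, 63, 42) fit 1:2:1 (chi-square p = 0.3405); every
    post-implantation stage lacks homozygotes entirely.
    """
    return _expand(_HETXHET_MIXED)


def blastocyst_culture_records() -> list[CultureRecord]:
    """Daily records of the 44-embryo het×het E3.5 culture cohort.

    Trajectories are reconstructed to match the published per-day status
    table exactly: new deaths (1, 4, 5, 1, 0) on days 1–5 and per-day live
    counts for each ladder status.  The day-1 death was a 4-cell embryo
    that never compacted; the day-2..4 deaths include one genotyped
    heterozygote and two homozygous mutants.
    """
    # (n, genotype, statuses for days 1..5; None = dead from that day on)
    trajectories = [
        (1, None, []),  # 4-cell embryo, dead on day 1
        (1, None, ["compacted_morula"]),
        (1, "+/-", ["blastocyst"]),
        (2, None, ["blastocyst"]),
        (1, None, ["compacted_morula", "compacted_morula"]),
        (1, "-/-", ["compacted_morula", "blastocyst"]),
        (3, None, ["compacted_morula", "blastocyst"]),
        (1, "-/-", ["compacted_morula", "compacted_morula", "blastocyst"]),
        (1, None, ["compacted_morula"] * 5),
        # two day-1 blastocysts expand on day 2 and attach on day 3
        (2, None, ["blastocyst", "expanded_blastocyst"] + ["outgrowth"] * 3),
        # thirty day-1 expanded blastocysts
        (3, None, ["expanded_blastocyst"] * 2 + ["outgrowth"] * 3),
        (2, None, ["expanded_blastocyst"] * 5),
        (1, None, ["expanded_blastocyst"] * 4 + ["outgrowth"]),
        (1, None, ["expanded_blastocyst"] * 3 + ["hatched", "outgrowth"]),
        (1, None, ["expanded_blastocyst"] * 3 + ["outgrowth"] * 2),
        (19, None, ["expanded_blastocyst", "hatched"] + ["outgrowth"] * 3),
        (2, None, ["expanded_blastocyst", "hatched", "hatched"] + ["outgrowth"] * 2),
        (1, None, ["expanded_blastocyst"] + ["hatched"] * 4),
    ]
    records: list[CultureRecord] = []
    eid = 0
    for n, genotype, statuses in trajectories:
        for _ in range(n):
            eid += 1
            embryo = f"b{eid:02d}"
            for day in range(1, 6):
                status = statuses[day - 1] if day <= len(statuses) else "dead"
                records.append(
                    CultureRecord(
                        embryo_id=embryo,
                        day=day,
                        status=status,
                        genotype=genotype,
                        litter=f"litter{eid % 6 + 1}",
                    )
                )
    return records


def wildtype_culture_records() -> list[CultureRecord]:
    """Daily records of the 25-embryo wild-type culture cohort.

    All embryos survive; on day 5, 18 show ICM/trophectoderm outgrowth and
    4 more have hatched (22/25 = 88% hatched-or-beyond, 18/25 = 72%
    outgrowth), the remaining 3 being unhatched expanded blastocysts.
    """
    trajectories = (
        [["expanded_blastocyst", "hatched"] + ["outgrowth"] * 3] * 18
        + [["expanded_blastocyst"] * 2 + ["hatched"] * 3] * 4
        + [["expanded_blastocyst"] * 5] * 3
    )
    records: list[CultureRecord] = []
    for i, statuses in enumerate(trajectories, start=1):
        for day, status in enumerate(statuses, start=1):
            records.append(
                CultureRecord(
                    embryo_id=f"wt{i:02d}",
                    day=day,
                    status=status,
                    genotype="+/+",
                    litter=f"litter{i % 4 + 1}",
                )
            )
    return records
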