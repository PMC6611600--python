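"""Mendelian genotype-ratio bookkeeping and chi-square goodness-of-fit.

Genotype counts per developmental stage (with untyped embryos and
resorptions kept aside) are tested against the cross's expected ratio —
1:2:1 for het×het, 1:1 for het×WT — with the Pearson statistic
Σ(O−E)²/E, no continuity correction, and df = k−1 where k counts the
categories with a nonzero expectation.  Untyped and resorbed embryos are
excluded from every test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GENOTYPES, UNTYPED

__all__ = [
    "STAGE_ORDER",
    "ChiSquareResult",
    "GenotypeStageTable",
    "parse_ratio",
    "chisq_gof",
    "tabulate_genotypes",
    "mendelian_report",
]

#: Default ordered stage vocabulary (embryonic days then postnatal days).
STAGE_ORDER = (
    "E3.5",
    "E7.5",
    "E8.5",
    "E9.5",
    "E10.5",
    "E11.5",
    "E14.5",
    "E15.5",
    "E16.5",
    "E17.5",
    "E18.5",
    "P0",
    "P21",
)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0 <= self.p_value <= 1 or self.df < 1:
            raise ValueError("invalid chi-square result")


@dataclass
class GenotypeStageTable:
    """Genotype counts at one stage, with untyped/resorption bookkeeping."""

    stage: str
    counts: dict[str, int] = field(default_factory=dict)
    untyped: int = 0
    resorptions: int = 0
    litters: int = 0

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {g}")
        if self.untyped < 0 or self.resorptions < 0:
            raise ValueError("negative bookkeeping counts")

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.untyped


def parse_ratio(text: str) -> tuple[float, ...]:
    """Parse "1:2:1" into ratio weights."""
    try:
        weights = tuple(float(w) for w in text.split(":"))
    except ValueError as exc:
        raise ValueError(f"cannot parse ratio {text!r}") from exc
    if not weights or any(w < 0 for w in weights) or sum(weights) == 0:
        raise ValueError(f"ratio weights must be non-negative with a positive sum: {text!r}")
    return weights


def chisq_gof(
    observed: Sequence[int] | Mapping[str, int],
    expected_ratio: Sequence[float],
) -> ChiSquareResult:
    """Pearson goodness-of-fit of observed counts against a ratio.

    Expected counts are the ratio-normalised total; no continuity
    correction; p comes from the chi-square upper tail with df = k−1.
    Categories with a zero ratio weight are dropped with a warning (a cross
    that cannot produce a genotype contributes no expectation).
    """
    if isinstance(observed, Mapping):
        observed = [observed[k] for k in observed]
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError(
            f"observed has {obs.size} categories but the ratio has {ratio.size}"
        )
    if (obs < 0).any() or (ratio < 0).any():
        raise ValueError("counts and ratio weights must be non-negative")
    if (ratio == 0).any():
        dropped = np.flatnonzero(ratio == 0)
        warnings.warn(
            f"{dropped.size} categories have zero expectation under the ratio "
            f"({int(obs[dropped].sum())} observed counts); dropped from the test",
            stacklevel=2,
        )
        obs, ratio = obs[ratio > 0], ratio[ratio > 0]
    if obs.sum() == 0:
        raise ValueError("zero total observed count")
    if obs.size < 2:
        raise ValueError("need at least two categories with nonzero expectation")
    expected = obs.sum() * ratio / ratio.sum()
    statistic, p_value = stats.chisquare(obs, f_exp=expected)
    return ChiSquareResult(float(statistic), int(obs.size - 1), float(p_value))


def tabulate_genotypes(
    records: pd.DataFrame,
    stage_order: Sequence[str] = STAGE_ORDER,
) -> list[GenotypeStageTable]:
    """Aggregate per-embryo rows into per-stage tables plus a TOTAL row.

    ``records`` needs columns stage, genotype ("n.t." for untyped),
    resorbed (bool) and litter.  Stages must come from ``stage_order``;
    litters are counted as distinct litter ids.
    """
    if records.empty:
        return []
    unknown_geno = set(records["genotype"]) - set(GENOTYPES) - {UNTYPED}
    if unknown_geno:
        raise ValueError(f"unknown genotypes {sorted(unknown_geno)}")
    unknown_stage = set(records["stage"]) - set(stage_order)
    if unknown_stage:
        raise ValueError(
            f"unknown stages {sorted(unknown_stage)}; expected {list(stage_order)}"
        )
    tables: list[GenotypeStageTable] = []
    present = [s for s in stage_order if s in set(records["stage"])]
    for stage in present:
        sub = records[records["stage"] == stage]
        tables.append(
            GenotypeStageTable(
                stage=stage,
                counts={g: int((sub["genotype"] == g).sum()) for g in GENOTYPES},
                untyped=int((sub["genotype"] == UNTYPED).sum()),
                resorptions=int(sub["resorbed"].sum()),
                litters=int(sub["litter"].nunique()),
            )
        )
    tables.append(
        GenotypeStageTable(
            stage="TOTAL",
            counts={g: sum(t.counts[g] for t in tables) for g in GENOTYPES},
            untyped=sum(t.untyped for t in tables),
            resorptions=sum(t.resorptions for t in tables),
            litters=int(records["litter"].nunique()),
        )
    )
    return tables


def mendelian_report(
    tables: Sequence[GenotypeStageTable],
    expected_ratio: Sequence[float] | str,
    alpha: float = 0.05,
    genotype_order: Sequence[str] = GENOTYPES,
) -> pd.DataFrame:
    """Chi-square test of every stage row against the cross's ratio.

    ``expected_ratio`` aligns with ``genotype_order`` (het×WT → 1:1:0,
    het×het → 1:2:1).  Stages without typed embryos are skipped with a
    warning; a stage is flagged when p < ``alpha``.
    """
    if isinstance(expected_ratio, str):
        expected_ratio = parse_ratio(expected_ratio)
    ratio = list(expected_ratio)
    if len(ratio) != len(genotype_order):
        raise ValueError("ratio length must match the genotype order")
    rows = []
    for t in tables:
        observed = [t.counts.get(g, 0) for g in genotype_order]
        row: dict = {
            "stage": t.stage,
            **{g: t.counts.get(g, 0) for g in genotype_order},
            "untyped": t.untyped,
            "resorptions": t.resorptions,
            "litters": t.litters,
            "typed": sum(observed),
            "total": t.total,
        }
        if sum(observed) == 0:
            warnings.warn(f"stage {t.stage}: no typed embryos, test skipped", stacklevel=2)
            row.update({"statistic": np.nan, "df": np.nan, "p_value": np.nan, "flagged": False})
        else:
            res = chisq_gof(observed, ratio)
            row.update(
                {
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "flagged": res.p_value < alpha,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
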