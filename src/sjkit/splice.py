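"""Splice-junction differential-usage analysis.

The procedure, end to end:

1. keep genes whose raw count mean is ≥ ``gene_count_mean_min`` in *both*
   genotype groups;
2. keep junctions on those genes whose unique-read count mean is ≥
   ``junction_mean_min`` in at least one group;
3. group the kept junctions into *anchor sets* — junctions sharing a common
   start, or conversely a common end;
4. within each anchor set and sample, a junction's *usage* is its count
   divided by the set total (undefined on a zero denominator);
5. a two-sided two-sample t-test (Welch by default) compares usage between
   groups; a junction is significant when p < ``p_cutoff`` *and* the
   absolute group usage difference is ≥ ``usage_delta_min``;
6. a Benjamini–Hochberg variant adjusts the p-values jointly across all
   tested (junction, side) pairs at ``fdr_alpha``.

The module also provides the cassette-exon inclusion statistic
Ψ = (I/2) / ((I/2) + S) with I the summed reads of the two inclusion
junctions and S the skipping-junction reads, the per-sample unannotated
junction percentage comparison, and the up/down expression-table filter
(padj < 0.05 with fold change ≥ 1.5 or ≤ 0.67).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import JUNCTION_INDEX, GeneModel, JunctionTable, SampleInfo

__all__ = [
    "AnalysisConfig",
    "AnchorSet",
    "CassetteEvent",
    "PsiResult",
    "UnannotatedResult",
    "filter_expressed_genes",
    "filter_junctions",
    "assign_junctions_to_genes",
    "gene_counts_from_junctions",
    "build_anchor_sets",
    "compute_usage",
    "test_differential_usage",
    "apply_fdr",
    "compute_psi",
    "unannotated_junction_percentage",
    "filter_de_table",
    "differential_usage_analysis",
]


@dataclass
class AnalysisConfig:
    """Thresholds of the differential-splicing procedure.

    Defaults are the study's published rules: expressed genes need a raw
    count mean ≥ 100 in both groups; junctions a mean ≥ 10 in at least one
    group; a junction is called at p < 0.05 with |Δusage| ≥ 0.20; the FDR
    re-analysis uses Benjamini–Hochberg at 0.05; expression tables are
    filtered at padj < 0.05 with fold change ≥ 1.5 (up) or ≤ 0.67 (down).
    """

    gene_count_mean_min: float = 100.0
    junction_mean_min: float = 10.0
    p_cutoff: float = 0.05
    usage_delta_min: float = 0.20
    fdr_alpha: float = 0.05
    de_padj_max: float = 0.05
    de_fc_up: float = 1.5
    de_fc_down: float = 0.67
    ttest_flavor: str = "welch"  # "welch" or "student"

    def __post_init__(self) -> None:
        for name in (
            "gene_count_mean_min",
            "junction_mean_min",
            "p_cutoff",
            "fdr_alpha",
            "de_padj_max",
            "de_fc_up",
            "de_fc_down",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.usage_delta_min <= 1:
            raise ValueError("usage_delta_min must be in (0, 1]")
        if self.ttest_flavor not in ("welch", "student"):
            raise ValueError("ttest_flavor must be 'welch' or 'student'")


@dataclass(frozen=True)
class AnchorSet:
    """Junctions sharing a donor (shared_start) or acceptor (shared_end)."""

    anchor_side: str  # "shared_start" | "shared_end"
    chrom: str
    anchor_coord: int
    strand: str
    members: tuple  # junction keys, sorted

    def __post_init__(self) -> None:
        if self.anchor_side not in ("shared_start", "shared_end"):
            raise ValueError(f"bad anchor_side {self.anchor_side!r}")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in anchor set")
        pos = 1 if self.anchor_side == "shared_start" else 2
        for key in self.members:
            if (key[0], key[pos], key[3]) != (self.chrom, self.anchor_coord, self.strand):
                raise ValueError(f"member {key} does not share the anchor coordinate")

    @property
    def testable(self) -> bool:
        """Singleton sets have constant usage 1 and carry no signal."""
        return len(self.members) >= 2


@dataclass(frozen=True)
class CassetteEvent:
    """A cassette exon named by its three junctions.

    ``inclusion`` holds the upstream-exon→cassette and cassette→downstream
    junction keys; ``skip`` joins the flanking exons directly.
    """

    inclusion: tuple
    skip: tuple
    gene_id: str | None = None


@dataclass
class PsiResult:
    """Per-sample Ψ of a cassette exon plus per-group mean ± SD."""

    per_sample: pd.DataFrame  # columns: group, I, S, psi
    group_stats: pd.DataFrame  # index group; columns: mean, sd, n

    @property
    def psi_per_sample(self) -> pd.Series:
        return self.per_sample["psi"]


@dataclass
class UnannotatedResult:
    """Per-sample unannotated-junction fractions and the two-group t-test."""

    per_sample: pd.Series  # fraction in [0, 1], NaN when a sample has no junctions
    group_means: dict
    p_value: float
    degenerate: bool

    @property
    def percentages(self) -> pd.Series:
        """Reporting-boundary view: fractions × 100."""
        return self.per_sample * 100.0


def _groups(samples: Sequence[SampleInfo]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(s.group, []).append(s.sample_id)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {sorted(groups)}")
    for g, ids in groups.items():
        if not ids:
            raise ValueError(f"group {g} has no samples")
    return groups


def _group_order(groups: Mapping[str, list[str]]) -> tuple[str, str]:
    """Reference group first: WT if present, else lexicographic."""
    names = sorted(groups)
    if "WT" in groups:
        other = [g for g in names if g != "WT"]
        return "WT", other[0]
    return names[0], names[1]


def filter_expressed_genes(
    gene_counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    config: AnalysisConfig | None = None,
) -> set[str]:
    """Genes whose raw count mean is ≥ threshold in both groups (inclusive)."""
    config = config or AnalysisConfig()
    groups = _groups(samples)
    keep = pd.Series(True, index=gene_counts.index)
    for ids in groups.values():
        keep &= gene_counts[ids].mean(axis=1) >= config.gene_count_mean_min
    return set(gene_counts.index[keep])


def assign_junctions_to_genes(
    keys: Iterable[tuple], genes: Sequence[GeneModel]
) -> dict[str, list[tuple]]:
    """Map gene_id → junction keys with both intron ends strictly inside the
    gene span.  A junction inside several genes is assigned to all of them."""
    by_gene: dict[str, list[tuple]] = {}
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for key in keys:
        chrom, start, end, strand = key
        for g in genes_by_chrom.get(chrom, []):
            if g.span_start < start and end < g.span_end:
                if strand != "." and g.strand not in (".", strand):
                    continue
                by_gene.setdefault(g.gene_id, []).append(key)
    return by_gene


def gene_counts_from_junctions(
    table: JunctionTable, genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Gene × sample totals: the summed unique counts of each gene's junctions.

    A stand-in for exon-level gene counts when only junction tables exist.
    """
    assignment = assign_junctions_to_genes(table.junction_keys, genes)
    rows = {}
    for gid, keys in assignment.items():
        rows[gid] = table.counts.loc[keys].sum(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out.empty:
        out = pd.DataFrame(columns=table.samples)
    return out.reindex(columns=table.samples).fillna(0).astype("int64").sort_index()


def filter_junctions(
    counts: pd.DataFrame,
    samples: Sequence[SampleInfo],
    config: AnalysisConfig | None = None,
) -> pd.MultiIndex:
    """Junctions whose count mean is ≥ threshold in at least one group."""
    config = config or AnalysisConfig()
    groups = _groups(samples)
    keep = pd.Series(False, index=counts.index)
    for ids in groups.values():
        keep |= counts[ids].mean(axis=1) >= config.junction_mean_min
    return counts.index[keep]


def build_anchor_sets(keys: Iterable[tuple]) -> list[AnchorSet]:
    """One shared_start set per distinct (chrom, intron_start, strand) and
    one shared_end set per distinct (chrom, intron_end, strand).

    Every junction appears in exactly one set per side; singleton sets are
    produced but flagged untestable.
    """
    keys = list(keys)
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate junction keys")
    sets: list[AnchorSet] = []
    for side, pos in (("shared_start", 1), ("shared_end", 2)):
        grouped: dict[tuple, list[tuple]] = {}
        for key in keys:
            grouped.setdefault((key[0], key[pos], key[3]), []).append(key)
        for (chrom, coord, strand), members in sorted(grouped.items()):
            sets.append(
                AnchorSet(side, chrom, coord, strand, tuple(sorted(members)))
            )
    return sets


def compute_usage(anchor_set: AnchorSet, counts: pd.DataFrame) -> pd.DataFrame:
    """Member × sample usage fractions within one anchor set.

    usage(j, s) = count(j, s) / Σ_{k∈set} count(k, s); NaN when the set
    total is zero in that sample.
    """
    sub = counts.loc[list(anchor_set.members)]
    totals = sub.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = sub.div(totals.where(totals > 0), axis=1)
    return usage


def _usage_matrix(counts: pd.DataFrame, side: str) -> pd.DataFrame:
    """Usage fractions for every junction under one anchor side, vectorised."""
    pos = "intron_start" if side == "shared_start" else "intron_end"
    levels = ["chrom", pos, "strand"]
    totals = counts.groupby(level=levels).transform("sum").astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = counts / totals.where(totals > 0)
    return usage


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, flavor: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided two-sample t-test on rows of ``a`` and ``b``.

    NaN entries are excluded per row.  Rows where both groups have zero
    variance get p = 1 for equal means and p = 0 for differing means (the
    limit of the statistic); callers flag those rows as degenerate.
    Returns (p, degenerate_mask).
    """
    n1 = np.sum(~np.isnan(a), axis=1)
    n2 = np.sum(~np.isnan(b), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
    p = np.full(a.shape[0], np.nan)
    valid = (n1 >= 2) & (n2 >= 2)
    both_flat = valid & (v1 == 0) & (v2 == 0)
    degenerate = both_flat & (m1 != m2)
    p[both_flat] = np.where(m1[both_flat] == m2[both_flat], 1.0, 0.0)
    rest = valid & ~both_flat
    if rest.any():
        if flavor == "welch":
            se2 = v1[rest] / n1[rest] + v2[rest] / n2[rest]
            t = (m1[rest] - m2[rest]) / np.sqrt(se2)
            num = se2**2
            den = (v1[rest] / n1[rest]) ** 2 / (n1[rest] - 1) + (
                v2[rest] / n2[rest]
            ) ** 2 / (n2[rest] - 1)
            df = num / den
        else:
            df = n1[rest] + n2[rest] - 2
            sp2 = ((n1[rest] - 1) * v1[rest] + (n2[rest] - 1) * v2[rest]) / df
            t = (m1[rest] - m2[rest]) / np.sqrt(sp2 * (1 / n1[rest] + 1 / n2[rest]))
        p[rest] = 2.0 * stats.t.sf(np.abs(t), df)
    return p, degenerate


def test_differential_usage(
    table: JunctionTable,
    anchor_sets: Sequence[AnchorSet],
    samples: Sequence[SampleInfo],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-(junction, side) usage comparison between the two groups.

    Returns one row per junction per anchor side with group usage means,
    delta (non-reference minus reference group), the t-test p-value, the
    BH-adjusted p-value across all tested pairs, the dual-threshold
    ``significant`` call and the FDR call.  Junctions with fewer than two
    defined usages in either group are reported untested with a reason.
    """
    config = config or AnalysisConfig()
    groups = _groups(samples)
    ref, alt = _group_order(groups)
    counts = table.counts
    member_keys = sorted({k for s in anchor_sets for k in s.members})
    counts = counts.loc[member_keys]
    set_size: dict[str, dict[tuple, int]] = {}
    for s in anchor_sets:
        for k in s.members:
            set_size.setdefault(s.anchor_side, {})[k] = len(s.members)
    frames = []
    sides_present = sorted({s.anchor_side for s in anchor_sets})
    for side in sides_present:
        keys = sorted({k for s in anchor_sets if s.anchor_side == side for k in s.members})
        usage = _usage_matrix(counts.loc[keys], side)
        a = usage[groups[ref]].to_numpy(float)
        b = usage[groups[alt]].to_numpy(float)
        n_ref = np.sum(~np.isnan(a), axis=1)
        n_alt = np.sum(~np.isnan(b), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_ref = np.nanmean(a, axis=1)
            mean_alt = np.nanmean(b, axis=1)
        p, degenerate = _two_sample_t(a, b, config.ttest_flavor)
        singleton = np.array([set_size[side][k] < 2 for k in usage.index])
        p[singleton] = np.nan
        df = pd.DataFrame(
            {
                "side": side,
                f"n_{ref}": n_ref,
                f"n_{alt}": n_alt,
                f"mean_{ref}": mean_ref,
                f"mean_{alt}": mean_alt,
                "delta": mean_alt - mean_ref,
                "p_value": p,
                "degenerate": degenerate & ~singleton,
                "singleton": singleton,
            },
            index=usage.index,
        )
        frames.append(df)
    out = pd.concat(frames)
    tested = ~out["p_value"].isna()
    out["tested"] = tested
    out["reason"] = np.where(
        tested,
        "",
        np.where(out["singleton"], "singleton_anchor_set", "fewer_than_2_defined_usages_in_a_group"),
    )
    out["p_adjusted"] = np.nan
    if tested.any():
        adjusted, _ = apply_fdr(out.loc[tested, "p_value"].to_numpy(), config.fdr_alpha)
        out.loc[tested, "p_adjusted"] = adjusted
    out["significant"] = (
        tested
        & (out["p_value"] < config.p_cutoff)
        & (out["delta"].abs() >= config.usage_delta_min)
    )
    out["significant_fdr"] = (
        tested
        & (out["p_adjusted"] <= config.fdr_alpha)
        & (out["delta"].abs() >= config.usage_delta_min)
    )
    return out


def apply_fdr(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Returns (adjusted p-values, significant mask) with significance defined
    as adjusted ≤ alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, adjusted <= alpha


def compute_psi(
    event: CassetteEvent,
    table: JunctionTable,
    samples: Sequence[SampleInfo],
) -> PsiResult:
    """Cassette-exon inclusion per sample: Ψ = (I/2) / ((I/2) + S).

    I sums the two inclusion junctions' unique counts (each inclusion read
    supports one of two junctions, hence the halving); S is the skipping
    junction's count.  Ψ is undefined when I = S = 0; such samples are
    excluded from the group mean ± SD with a warning.
    """
    counts = table.counts
    for key in (*event.inclusion, event.skip):
        if key not in counts.index:
            raise KeyError(f"event junction {key} absent from the junction table")
    inc = counts.loc[list(event.inclusion)].sum(axis=0).astype(float)
    skip = counts.loc[event.skip].astype(float)
    denom = inc / 2.0 + skip
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = (inc / 2.0) / denom.where(denom > 0)
    group = pd.Series({s.sample_id: s.group for s in samples})
    per_sample = pd.DataFrame(
        {"group": group, "I": inc, "S": skip, "psi": psi}
    ).loc[[s.sample_id for s in samples]]
    undefined = per_sample.index[per_sample["psi"].isna()]
    if len(undefined):
        warnings.warn(
            f"Ψ undefined (I = S = 0) in samples {list(undefined)}; "
            "excluded from group summaries",
            stacklevel=2,
        )
    stats_rows = {}
    for g, sub in per_sample.groupby("group"):
        vals = sub["psi"].dropna()
        stats_rows[g] = {
            "mean": vals.mean() if len(vals) else np.nan,
            "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            "n": len(vals),
        }
    return PsiResult(per_sample=per_sample, group_stats=pd.DataFrame(stats_rows).T)


def unannotated_junction_percentage(
    table: JunctionTable,
    genes: Sequence[GeneModel],
    samples: Sequence[SampleInfo],
    expressed_genes: set[str] | None = None,
    config: AnalysisConfig | None = None,
) -> UnannotatedResult:
    """Per-sample fraction of unannotated junctions, compared between groups.

    Junctions are restricted to those lying within expressed genes; within
    each sample, the junctions detected there (count > 0) are split by
    whether their intron coordinates appear among the annotation's
    transcript junctions.  A two-group t-test compares the per-sample
    fractions; when every sample has an identical fraction the test is
    degenerate and no significance is claimed.
    """
    config = config or AnalysisConfig()
    groups = _groups(samples)
    ref, alt = _group_order(groups)
    if expressed_genes is None:
        gene_counts = gene_counts_from_junctions(table, genes)
        expressed_genes = filter_expressed_genes(gene_counts, samples, config)
    kept_genes = [g for g in genes if g.gene_id in expressed_genes]
    assignment = assign_junctions_to_genes(table.junction_keys, kept_genes)
    keys = sorted({k for ks in assignment.values() for k in ks})
    annotated_pairs = {
        (g.chrom, s, e) for g in kept_genes for (s, e) in g.annotated_junctions
    }
    is_annotated = pd.Series(
        [(k[0], k[1], k[2]) in annotated_pairs for k in keys],
        index=pd.MultiIndex.from_tuples(keys, names=JUNCTION_INDEX),
    )
    counts = table.counts.loc[keys]
    fractions = {}
    for s in samples:
        present = counts[s.sample_id] > 0
        total = int(present.sum())
        if total == 0:
            warnings.warn(
                f"sample {s.sample_id} has no junctions on expressed genes; "
                "excluded from the comparison",
                stacklevel=2,
            )
            fractions[s.sample_id] = np.nan
        else:
            fractions[s.sample_id] = float((present & ~is_annotated).sum()) / total
    frac = pd.Series(fractions)
    a = frac[groups[ref]].dropna().to_numpy()
    b = frac[groups[alt]].dropna().to_numpy()
    if len(a) >= 2 and len(b) >= 2:
        p, degen = _two_sample_t(a[None, :], b[None, :], config.ttest_flavor)
        constant = (a == a[0]).all() and (b == b[0]).all()
        degenerate = bool(degen[0]) or constant
        p_value = float(p[0]) if not degenerate else np.nan
    else:
        p_value, degenerate = np.nan, True
    return UnannotatedResult(
        per_sample=frac,
        group_means={ref: float(np.mean(a)) if len(a) else np.nan,
                     alt: float(np.mean(b)) if len(b) else np.nan},
        p_value=p_value,
        degenerate=degenerate,
    )


def filter_de_table(
    de_table: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[list[str], list[str]]:
    """Split an expression table into up-/down-regulated gene lists.

    Up: padj < 0.05 and fold change ≥ 1.5; down: padj < 0.05 and fold
    change ≤ 0.67; everything else unclassified.  ``de_table`` needs
    columns gene, fold_change, p_adjusted; fold changes must be positive.
    """
    config = config or AnalysisConfig()
    for col in ("gene", "fold_change", "p_adjusted"):
        if col not in de_table.columns:
            raise ValueError(f"missing column {col!r}")
    fc = de_table["fold_change"].astype(float)
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive")
    sig = de_table["p_adjusted"].astype(float) < config.de_padj_max
    up = de_table.loc[sig & (fc >= config.de_fc_up), "gene"].tolist()
    down = de_table.loc[sig & (fc <= config.de_fc_down), "gene"].tolist()
    return up, down


def differential_usage_analysis(
    table: JunctionTable,
    genes: Sequence[GeneModel],
    samples: Sequence[SampleInfo],
    config: AnalysisConfig | None = None,
    gene_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full pipeline: gene filter → junction filter → anchor sets → t-tests.

    ``gene_counts`` may supply externally quantified gene totals; otherwise
    gene expression is proxied by summed junction counts.
    """
    config = config or AnalysisConfig()
    if gene_counts is None:
        gene_counts = gene_counts_from_junctions(table, genes)
    expressed = filter_expressed_genes(gene_counts, samples, config)
    kept_genes = [g for g in genes if g.gene_id in expressed]
    assignment = assign_junctions_to_genes(table.junction_keys, kept_genes)
    keys = sorted({k for ks in assignment.values() for k in ks})
    if not keys:
        return pd.DataFrame()
    kept = filter_junctions(table.counts.loc[keys], samples, config)
    if kept.empty:
        return pd.DataFrame()
    sets = build_anchor_sets(list(kept))
    return test_differential_usage(table, sets, samples, config)
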