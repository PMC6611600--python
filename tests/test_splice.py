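"""Differential junction usage: filters, anchor sets, tests, Ψ, FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_table
from sjkit.io import GeneModel, SampleInfo
from sjkit.splice import (
    AnalysisConfig,
    AnchorSet,
    CassetteEvent,
    apply_fdr,
    build_anchor_sets,
    compute_psi,
    compute_usage,
    differential_usage_analysis,
    filter_de_table,
    filter_expressed_genes,
    filter_junctions,
    test_differential_usage as diff_usage,
    unannotated_junction_percentage,
)

WT3 = [SampleInfo(f"wt{i}", "WT", f"l{i}") for i in (1, 2, 3)]
HET3 = [SampleInfo(f"het{i}", "HET", f"l{i}") for i in (1, 2, 3)]
SAMPLES = WT3 + HET3
COLS = [s.sample_id for s in SAMPLES]


def usage_rows(wt, het):
    """Anchor-set fixture: two junctions with complementary usage."""
    a = [round(u * 100) for u in wt + het]
    b = [100 - x for x in a]
    table = make_table(
        {("chr1", 10, 50, "+"): a, ("chr1", 10, 90, "+"): b}, COLS
    )
    sets = build_anchor_sets(list(table.junction_keys))
    return table, sets


class TestFilters:
    def test_gene_filter_requires_threshold_in_both_groups(self):
        counts = pd.DataFrame(
            {
                "wt1": [150, 150, 0], "wt2": [150, 150, 0], "wt3": [150, 150, 0],
                "het1": [90, 100, 0], "het2": [90, 100, 0], "het3": [90, 100, 0],
            },
            index=["below_in_het", "boundary", "silent"],
        )
        kept = filter_expressed_genes(counts, SAMPLES)
        # the mean-100 boundary is inclusive; a group mean of 90 excludes
        assert kept == {"boundary"}

    def test_all_zero_counts_give_empty_set(self):
        counts = pd.DataFrame(0, index=["g1", "g2"], columns=COLS)
        assert filter_expressed_genes(counts, SAMPLES) == set()

    def test_gene_filter_requires_two_groups(self):
        counts = pd.DataFrame(1000, index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="two groups"):
            filter_expressed_genes(counts, [SampleInfo("a", "WT", "l"), SampleInfo("b", "WT", "l")])

    @pytest.mark.parametrize(
        "wt_counts, het_counts, kept",
        [
            ([12, 12, 12], [3, 3, 3], True),  # one group suffices
            ([9, 10, 10], [9, 10, 10], False),  # mean 9.67 in both
            ([10, 10, 10], [0, 0, 0], True),  # boundary mean exactly 10
        ],
    )
    def test_junction_filter_needs_one_group_at_threshold(self, wt_counts, het_counts, kept):
        table = make_table({("chr1", 10, 50, "+"): wt_counts + het_counts}, COLS)
        result = filter_junctions(table.counts, SAMPLES)
        assert (len(result) == 1) is kept


class TestAnchorSets:
    def test_shared_start_pair_and_singleton_ends(self):
        sets = build_anchor_sets([("chr1", 101, 200, "+"), ("chr1", 101, 400, "+")])
        starts = [s for s in sets if s.anchor_side == "shared_start"]
        ends = [s for s in sets if s.anchor_side == "shared_end"]
        assert len(starts) == 1 and len(starts[0].members) == 2 and starts[0].testable
        assert len(ends) == 2 and all(not s.testable for s in ends)

    def test_cassette_exon_topology(self):
        up = ("chr1", 101, 200, "+")
        skip = ("chr1", 101, 400, "+")
        down = ("chr1", 301, 400, "+")
        sets = {(s.anchor_side, s.anchor_coord): set(s.members)
                for s in build_anchor_sets([up, skip, down])}
        assert sets[("shared_start", 101)] == {up, skip}
        assert sets[("shared_end", 400)] == {down, skip}

    def test_no_junctions_give_empty_list(self):
        assert build_anchor_sets([]) == []

    @given(
        st.lists(
            st.tuples(st.integers(1, 5), st.integers(6, 12)).map(
                lambda t: ("chr1", t[0], t[0] + t[1], "+")
            ),
            unique=True,
            max_size=12,
        )
    )
    def test_every_junction_in_exactly_one_set_per_side(self, keys):
        sets = build_anchor_sets(keys)
        for side in ("shared_start", "shared_end"):
            members = [k for s in sets if s.anchor_side == side for k in s.members]
            assert sorted(members) == sorted(keys)


class TestUsage:
    def test_usage_is_count_over_set_total(self):
        table = make_table(
            {("chr1", 10, 50, "+"): [80] * 6, ("chr1", 10, 90, "+"): [20] * 6}, COLS
        )
        (start_set,) = [s for s in build_anchor_sets(list(table.junction_keys))
                        if s.anchor_side == "shared_start"]
        usage = compute_usage(start_set, table.counts)
        assert np.allclose(usage.loc[("chr1", 10, 50, "+")], 0.8)
        assert np.allclose(usage.loc[("chr1", 10, 90, "+")], 0.2)

    def test_zero_denominator_is_undefined_and_singleton_is_one(self):
        table = make_table(
            {("chr1", 10, 50, "+"): [0] * 6, ("chr1", 10, 90, "+"): [0] * 6,
             ("chr2", 5, 9, "+"): [7] * 6},
            COLS,
        )
        sets = build_anchor_sets(list(table.junction_keys))
        zero_set = [s for s in sets if s.chrom == "chr1" and s.anchor_side == "shared_start"][0]
        assert compute_usage(zero_set, table.counts).isna().all().all()
        singleton = [s for s in sets if s.chrom == "chr2" and s.anchor_side == "shared_start"][0]
        assert (compute_usage(singleton, table.counts) == 1.0).all().all()

    @given(
        st.lists(st.lists(st.integers(0, 500), min_size=3, max_size=3),
                 min_size=2, max_size=5)
    )
    def test_defined_usages_sum_to_one_within_a_set(self, counts):
        keys = [("chr1", 10, 50 + 10 * i, "+") for i in range(len(counts))]
        table = make_table(dict(zip(keys, counts)), ["s1", "s2", "s3"])
        (start_set,) = [s for s in build_anchor_sets(keys) if s.anchor_side == "shared_start"]
        usage = compute_usage(start_set, table.counts)
        totals = usage.sum(axis=0, skipna=False)
        defined = totals.dropna()
        assert np.allclose(defined, 1.0, atol=1e-12)


def welch_p(x, y):
    """Hand-rolled Welch t-test, the oracle for the vectorised path."""
    n1, n2 = len(x), len(y)
    m1, m2 = np.mean(x), np.mean(y)
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    from scipy.stats import t as tdist

    return 2 * tdist.sf(abs(t), df)


def permutation_p(x, y):
    """Exact two-sided permutation p-value of the mean difference."""
    pooled = list(x) + list(y)
    observed = abs(np.mean(x) - np.mean(y))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(x)):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(np.mean(a) - np.mean(b)) >= observed - 1e-12:
            count += 1
    return count / total


class TestDifferentialUsage:
    def test_clear_shift_is_significant_and_matches_hand_welch(self):
        wt, het = [0.98, 1.00, 0.96], [0.52, 0.48, 0.50]
        table, sets = usage_rows(wt, het)
        out = diff_usage(table, sets, SAMPLES)
        row = out[(out["side"] == "shared_start")].loc[[("chr1", 10, 50, "+")]].iloc[0]
        assert row["significant"]
        assert abs(row["delta"]) >= 0.20 and row["p_value"] < 0.05
        assert row["p_value"] == pytest.approx(welch_p(wt, het), rel=1e-9)

    def test_small_delta_never_significant(self):
        table, sets = usage_rows([0.50, 0.52, 0.48], [0.49, 0.51, 0.50])
        out = diff_usage(table, sets, SAMPLES)
        assert not out["significant"].any()

    def test_identical_groups_have_zero_delta(self):
        table, sets = usage_rows([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        out = diff_usage(table, sets, SAMPLES)
        assert np.allclose(out.loc[out["tested"], "delta"], 0.0)
        assert not out["significant"].any()

    def test_zero_variance_degeneracy(self):
        # equal constant usage → p = 1; differing constants → p = 0, flagged
        table, sets = usage_rows([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        out = diff_usage(table, sets, SAMPLES)
        assert (out.loc[out["tested"], "p_value"] == 1.0).all()
        assert not out["degenerate"].any()
        table, sets = usage_rows([1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        out = diff_usage(table, sets, SAMPLES)
        tested = out[out["tested"]]
        assert (tested["p_value"] == 0.0).all()
        assert tested["degenerate"].all()
        assert tested["significant"].all()

    def test_undefined_samples_drop_junction_below_two(self):
        # zero totals in two WT samples leave only one defined WT usage
        table = make_table(
            {("chr1", 10, 50, "+"): [0, 0, 80, 40, 42, 44],
             ("chr1", 10, 90, "+"): [0, 0, 20, 60, 58, 56]},
            COLS,
        )
        sets = [s for s in build_anchor_sets(list(table.junction_keys)) if s.testable]
        out = diff_usage(table, sets, SAMPLES)
        assert not out["tested"].any()
        assert (out["reason"] == "fewer_than_2_defined_usages_in_a_group").all()

    def test_singleton_sets_reported_untestable(self):
        table = make_table({("chr1", 10, 50, "+"): [30] * 6}, COLS)
        out = diff_usage(
            table, build_anchor_sets(list(table.junction_keys)), SAMPLES
        )
        assert not out["tested"].any()
        assert (out["reason"] == "singleton_anchor_set").all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_student_t_tracks_exact_permutation_oracle(self, seed):
        # n = 3 + 3: all 20 relabelings enumerate the permutation null
        rng = np.random.default_rng(seed)
        wt = np.round(rng.uniform(0.3, 0.7, 3), 2)
        het = np.round(np.clip(wt + rng.normal(0.1, 0.1, 3), 0, 1), 2)
        table, sets = usage_rows(list(wt), list(het))
        config = AnalysisConfig(ttest_flavor="student")
        out = diff_usage(table, sets, SAMPLES, config)
        p_t = out.loc[out["tested"], "p_value"].iloc[0]
        p_perm = permutation_p(wt, het)
        # permutation granularity with 20 relabelings is 0.1
        assert abs(p_t - p_perm) <= 0.2


class TestFdr:
    def test_closed_form_adjustments(self):
        adjusted, _ = apply_fdr([0.01])
        assert adjusted[0] == pytest.approx(0.01)
        adjusted, _ = apply_fdr([0.01, 0.02, 0.03])
        assert np.allclose(adjusted, [0.03, 0.03, 0.03])

    def test_all_ones_reject_nothing(self):
        _, reject = apply_fdr([1.0] * 5)
        assert not reject.any()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            apply_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_order_follows_raw_order(self, ps):
        adjusted, _ = apply_fdr(ps)
        order = np.argsort(ps)
        assert (np.diff(adjusted[order]) >= -1e-12).all()
        assert ((adjusted >= np.asarray(ps) - 1e-12) & (adjusted <= 1.0)).all()


EVENT = CassetteEvent(
    inclusion=(("chr1", 101, 200, "+"), ("chr1", 301, 400, "+")),
    skip=("chr1", 101, 400, "+"),
)


def psi_table(I_half, S):
    """Table with both inclusion junctions at I/2 and the skip at S."""
    return make_table(
        {EVENT.inclusion[0]: I_half, EVENT.inclusion[1]: I_half, EVENT.skip: S},
        COLS,
    )


class TestPsi:
    def test_formula_plug_ins(self):
        table = psi_table([50] * 6, [0] * 6)  # I = 100, S = 0
        res = compute_psi(EVENT, table, SAMPLES)
        assert (res.psi_per_sample == 1.0).all()
        table = psi_table([50] * 6, [50] * 6)  # I = 100, S = 50
        res = compute_psi(EVENT, table, SAMPLES)
        assert np.allclose(res.psi_per_sample, 0.5)
        assert np.allclose(res.group_stats["mean"], 0.5)

    def test_missing_event_junction_raises(self):
        table = psi_table([50] * 6, [0] * 6)
        bad = CassetteEvent(inclusion=EVENT.inclusion, skip=("chr9", 1, 2, "+"))
        with pytest.raises(KeyError):
            compute_psi(bad, table, SAMPLES)

    def test_undefined_samples_warn_and_are_excluded(self):
        table = psi_table([0, 50, 50, 50, 50, 50], [0, 0, 0, 50, 50, 50])
        with pytest.warns(UserWarning, match="undefined"):
            res = compute_psi(EVENT, table, SAMPLES)
        assert math.isnan(res.per_sample.loc["wt1", "psi"])
        assert res.group_stats.loc["WT", "n"] == 2

    @pytest.mark.filterwarnings("ignore:Ψ undefined")
    @given(st.integers(0, 400), st.integers(0, 400))
    def test_psi_bounded_and_monotone(self, i_half, s):
        table = psi_table([i_half] * 6, [s] * 6)
        res = compute_psi(EVENT, table, SAMPLES)
        psi = res.psi_per_sample.iloc[0]
        if i_half + s == 0:
            assert math.isnan(psi)
            return
        assert 0.0 <= psi <= 1.0
        # monotone: more inclusion raises Ψ, more skipping lowers it
        up = compute_psi(EVENT, psi_table([i_half + 1] * 6, [s] * 6), SAMPLES)
        assert up.psi_per_sample.iloc[0] >= psi
        down = compute_psi(EVENT, psi_table([i_half] * 6, [s + 1] * 6), SAMPLES)
        assert down.psi_per_sample.iloc[0] <= psi


class TestUnannotated:
    def make_gene(self):
        return GeneModel.from_transcripts(
            "g", "chr1", "+", {"t": [(1, 100), (201, 300), (401, 500), (601, 10000)]}
        )

    def test_fraction_of_detected_junctions(self):
        gene = self.make_gene()
        keys = {("chr1", 101, 200, "+"): [500] * 6,  # annotated
                ("chr1", 301, 400, "+"): [500] * 6,  # annotated
                ("chr1", 501, 600, "+"): [500] * 6,  # annotated
                ("chr1", 150, 250, "+"): [500] * 6,  # unannotated
                ("chr1", 155, 255, "+"): [500] * 6}  # unannotated
        table = make_table(keys, COLS)
        res = unannotated_junction_percentage(table, [gene], SAMPLES)
        assert np.allclose(res.percentages, 40.0)  # 2 of 5
        assert res.degenerate  # identical in every sample → no claim

    def test_all_annotated_gives_zero_and_degenerate_flag(self):
        gene = self.make_gene()
        table = make_table({("chr1", 101, 200, "+"): [500] * 6}, COLS)
        res = unannotated_junction_percentage(table, [gene], SAMPLES)
        assert (res.per_sample == 0).all()
        assert res.degenerate and math.isnan(res.p_value)


class TestDeFilter:
    def test_threshold_rule(self):
        de = pd.DataFrame(
            {
                "gene": ["up", "flat", "down", "weak_p"],
                "fold_change": [1.6, 1.2, 0.5, 2.0],
                "p_adjusted": [0.01, 0.001, 0.04, 0.2],
            }
        )
        up, down = filter_de_table(de)
        assert up == ["up"] and down == ["down"]

    def test_non_positive_fold_change_rejected(self):
        de = pd.DataFrame({"gene": ["g"], "fold_change": [0.0], "p_adjusted": [0.01]})
        with pytest.raises(ValueError, match="positive"):
            filter_de_table(de)


class TestPipeline:
    def test_junctions_outside_expressed_genes_are_excluded(self, six_samples):
        genes = [
            GeneModel.from_transcripts("hi", "chr1", "+", {"t": [(1, 100), (201, 300), (401, 500)]}),
            GeneModel.from_transcripts("lo", "chr2", "+", {"t": [(1, 100), (201, 300)]}),
        ]
        table = make_table(
            {("chr1", 101, 200, "+"): [200] * 6,
             ("chr1", 101, 400, "+"): [100] * 6,
             ("chr2", 101, 200, "+"): [10] * 6},
            [s.sample_id for s in six_samples],
        )
        out = differential_usage_analysis(table, genes, six_samples)
        assert ("chr2", 101, 200, "+") not in out.index
        assert {k for k, *_ in out.index.tolist()} == {"chr1"}
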