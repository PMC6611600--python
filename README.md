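# sjkit

Splice-junction differential-usage analysis, cassette-exon inclusion (Ψ),
Mendelian genotype-ratio statistics and blastocyst-culture outcome scoring —
the computational toolbox for a mouse loss-of-function study of a core
spliceosome gene, usable on STAR junction tables, plain CSV records, or the
package's own synthetic data.

It is written for developmental biologists and bioinformaticians who have
per-sample splice-junction counts (STAR `SJ.out.tab`), genotyping records
from timed matings, or daily pre-implantation embryo-culture scores, and
want the corresponding statistics without a full isoform-quantification
stack.

## What it computes

**Differential junction usage.** Genes are kept when their raw count mean is
≥ 100 in both genotype groups; junctions on those genes when their mean
unique-read count is ≥ 10 in at least one group. Kept junctions are grouped
into *anchor sets* — junctions sharing a donor (common start) or an acceptor
(common end). Within a set and sample, a junction's usage is

    u(j, s) = n(j, s) / Σ_{k ∈ set} n(k, s),

undefined when the denominator is zero. A two-sided two-sample t-test
(Welch by default) compares usage between groups; a junction is called
significant when p < 0.05 **and** |Δu| ≥ 0.20. A Benjamini–Hochberg variant
adjusts p-values jointly across all tested (junction, side) pairs at
FDR = 0.05.

**Cassette-exon inclusion.** For an exon with inclusion junctions carrying
I reads (summed over the two flanking junctions) and a skipping junction
carrying S reads,

    Ψ = (I/2) / ((I/2) + S),

reported per sample with group mean ± SD. Per-sample unannotated-junction
percentages and the up/down expression-table filter
(padj < 0.05, fold change ≥ 1.5 or ≤ 0.67) round out the RNA-seq side.

**Mendelian ratios.** Genotype counts per developmental stage are tested
against the cross's expectation (1:2:1 for het×het, 1:1 for het×WT) with the
Pearson statistic Σ(O−E)²/E, df = k−1, no continuity correction; untyped
embryos and resorptions are tracked but excluded from tests.

**Embryo culture.** Daily records on the six-level ladder (compacted morula
< blastocyst < expanded blastocyst < hatched < ICM/trophectoderm outgrowth,
plus absorbing `dead`) are validated (no regressions, death absorbing) and
summarised into per-day status tables, cumulative mortality and
hatched/outgrowth rates.

**Synthetic data.** Generators emulate the study designs: litter-paired
3 vs 3 junction counts with one planted heterozygous cassette deletion
(half of mutant transcripts skip the exon), Mendelian crosses with
stage-specific homozygous lethality, and culture cohorts in which blocked
genotypes never hatch. See `docs/methods.md` for the count model.

## Worked example

Simulate a dataset, estimate the planted exon's inclusion, and run the
usage analysis:

```bash
sjkit simulate junctions --seed 11 --out run
sjkit psi --sj-dir run --samples run/samples.csv --truth run/truth.json --out psi
sjkit splice-usage --sj-dir run --samples run/samples.csv \
    --annotation run/annotation.tsv --out usage
```

prints

```
wrote 6 samples to run
        mean        sd    n
HET  0.51271  0.005533  3.0
WT   1.00000  0.000000  3.0
tested 436 junction sides; 4 significant
```

The heterozygous group includes the planted exon in ~51% of transcripts
(truth: 50%) while every wild-type transcript includes it (Ψ = 1 exactly,
since no wild-type read supports the skipping junction). The four
significant (junction, side) pairs are the planted skip and inclusion
junctions, each tested once per anchor side.

The published E3.5 genotype counts test like this:

```python
>>> from sjkit.mendel import chisq_gof
>>> r = chisq_gof([37, 63, 42], [1, 2, 1])
>>> print(f"chi2 = {r.statistic:.4f}, df = {r.df}, p = {r.p_value:.4f}")
chi2 = 2.1549, df = 2, p = 0.3405
```

— consistent with 1:2:1 segregation at E3.5, in contrast to the later
stages where homozygotes are absent and the test rejects.

## Layout

- `src/sjkit/io.py` — STAR `SJ.out.tab`, GTF-lite annotation and CSV
  readers/writers; coordinate conventions.
- `src/sjkit/splice.py` — filters, anchor sets, usage t-tests, FDR, Ψ,
  unannotated percentages, expression-table filter.
- `src/sjkit/mendel.py` — genotype tabulation and chi-square goodness-of-fit.
- `src/sjkit/culture.py` — scoring ladder, trajectory validation, summaries.
- `src/sjkit/simulate.py` — the three generators.
- `src/sjkit/datasets.py` — the published tables as per-embryo fixtures.
- `src/sjkit/cli.py` — `sjkit` command-line entry point.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
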