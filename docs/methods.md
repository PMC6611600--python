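# Methods

## The junction-usage model

The unit of analysis is the *anchor set*: all splice junctions sharing a
donor coordinate (shared start) or, conversely, an acceptor coordinate
(shared end), on the same chromosome and strand. Junctions competing for a
splice site partition its reads, so within one set and sample the defined
usage fractions sum to one; a two-junction set is the simplest alternative
splicing event (an alternative acceptor/donor or, combined across the two
sides, a cassette exon). Every junction belongs to exactly one set per
side and is therefore tested twice; results are reported per
(junction, side), and an event can be called through either side.
Singleton sets have constant usage 1 and are reported untestable.

Selection happens before testing: genes with raw count mean ≥ 100 in both
groups (the boundary is inclusive), then junctions on those genes — both
intron ends strictly inside the gene span; a junction inside several genes
counts for all of them — with mean unique-read count ≥ 10 in at least one
group. Counts are raw, uniquely-mapping reads: the thresholds are
calibrated on that scale, and multi-mapped junction reads are parsed but
never used.

The group comparison is a two-sided two-sample t-test on per-sample usage
fractions, Welch by default (`AnalysisConfig.ttest_flavor="student"`
switches to the pooled-variance form; a litter-paired test is deliberately
not the default because the procedure treats samples as exchangeable
within group). Samples with a zero set total have undefined usage and are
excluded per junction; if a group retains fewer than two defined values
the junction is reported untested with a reason code rather than being
given a fabricated 0/0. When both groups have zero variance the t
statistic degenerates: equal means give p = 1, differing means give p = 0
with a `degenerate` flag, the deterministic limit of the statistic. A
junction is *significant* when p < 0.05 and the absolute group usage
difference is ≥ 0.20 — the dual rule guards against tiny-variance,
tiny-effect calls at n = 3. The FDR variant applies Benjamini–Hochberg
jointly across all tested (junction, side) pairs (the re-analysis is
global, not per gene) and rejects at adjusted p ≤ 0.05.

### Cassette-exon inclusion

For an exon with two inclusion junctions (upstream→exon, exon→downstream)
carrying I reads in total and one skipping junction carrying S reads,

Ψ = (I/2) / ((I/2) + S).

Each included transcript contributes one read opportunity to *each*
inclusion junction but a skipping transcript only one to the skip
junction; halving I puts both paths on the same per-transcript scale, so
Ψ estimates the fraction of transcripts including the exon. Ψ is
undefined at I = S = 0 (such samples are excluded from group summaries
with a warning), equals 1 when S = 0 and I > 0, and is monotone
increasing in I and decreasing in S. Group summaries are mean ± SD
(ddof = 1).

### Unannotated junction burden

Per sample, among the junctions detected (count > 0) on expressed genes,
the fraction absent from the annotation's transcript junctions is the
unannotated percentage; groups are compared with the same t-test. No
junction-level abundance filter is applied here — low-count novel
junctions are exactly the signal of interest. Fractions are carried
internally and converted to percentages only at the reporting boundary,
which prevents 100× unit bugs. When every sample shows the identical
fraction the comparison is degenerate and no significance is claimed.

## Mendelian statistics

Pearson goodness-of-fit Σ(O−E)²/E with expected counts from the
ratio-normalised total, df = (categories with nonzero expectation) − 1,
upper-tail chi-square p, no Yates correction — the uncorrected statistic
is what reproduces the published E3.5 value (χ² = 2.1549, p = 0.3405 for
37/63/42 vs 1:2:1). Ratio weights are scale-invariant (1:2:1 ≡ 2:4:2).
Categories a cross cannot produce (e.g. homozygous mutants from het×WT)
carry zero weight and are dropped with a warning. Untyped embryos and
resorptions are tabulated but excluded from every test: only typed, live
genotypes enter the statistic. Per-stage reports flag p < α and include
both the typed total (the convention of the published tables) and the
full collected total.

## Embryo-culture scoring

The six-level ladder — compacted morula, blastocyst, expanded blastocyst,
hatched, ICM/trophectoderm outgrowth, dead — is ordinal with absorbing
death; validation rejects status regressions and post-death records. A
`pre_morula` pre-ladder status is accepted for the rare embryo that never
compacted (it occurs in the published cohort only as a day-1 death).
Summaries count each embryo once per day at its current status; the dead
row reports that day's new deaths with the cumulative percentage of the
cohort, to one decimal. Prose-style outcome rates (hatched-or-beyond,
outgrowth) are rounded to whole percent, with either the full cohort or
the surviving embryos as denominator.

## The generators

### Junction counts

Design: `n_per_group` (default 3) samples per genotype group, each WT/HET
pair sharing a litter (litter pairing on by default). Genes sit on one
chromosome as three-exon models. Per gene g:

- baseline λ_g ~ LogNormal(0, 0.5) — a spread of expression levels around
  the nominal depth;
- a gene-specific litter multiplier exp(N(0, `litter_sd`)), shared by the
  two samples of a litter (default SD 0.3 on the log scale);
- a per-sample overdispersion factor Gamma(1/α, α) with
  α = `nb_dispersion` = 0.1, shared by all of the gene's junctions;
- junction counts Poisson with mean (inclusion share) × λ_g ×
  litter multiplier × `depth_scale` (default 300 expected reads per
  constitutive junction).

Marginally each junction count is negative binomial with variance
μ + αμ² — the standard RNA-seq count model. The overdispersion is drawn
once per gene per sample rather than per junction because gene-level
expression noise scales all of a gene's junctions together; it therefore
cancels in usage and Ψ ratios, leaving binomial-scale sampling noise, as
in real data. (Fully independent negative-binomial draws per junction
would make Ψ noise grow with α regardless of depth and no finite depth
could recover inclusion fractions to ±0.05 at α = 0.1.)

One randomly placed gene carries the planted heterozygous cassette
deletion: inclusion fraction 1 in WT and 1 − `planted_skip_fraction`
(default 0.5, i.e. one transcript in two skips the exon) in HET samples.
Its skipping junction is deliberately written as *unannotated* in the
emitted annotation — the emulated skipped isoform is known in human but
not annotated in mouse. A fraction `alt_gene_fraction` (default 0.5) of
the other genes carry a group-balanced cassette event with gene-specific
inclusion ρ_g ~ U(0.3, 0.7), annotated through a second transcript; real
transcriptomes splice alternatively, and without such genes every null
anchor set would be a singleton and the type-I behaviour of the usage
test could never be exercised. Remaining genes are constitutive.
Unannotated noise junctions sharing an existing donor are added per gene
at rate `unannotated_noise_rate` (default 0.02) with Poisson mean 2
counts. Truth (planted keys, per-sample inclusion, λ, classes, litter
effects) is emitted beside every dataset and suffices to compute every
downstream expectation without re-simulation.

What the generator does *not* emulate: read-level artefacts (mismapping,
overhang filters), positional coverage bias, more than one isoform
dimension per gene, correlated gene-gene expression programs, and library
size differences beyond the litter effect. Passing tests therefore show
the statistics behave correctly under the stated sampling model, not that
the pipeline is robust to alignment artefacts.

### Crosses and culture

`simulate_cross` draws litter sizes Poisson(mean 8, truncated ≥ 1) and
genotypes multinomially from the cross ratio; a genotype mapped to a last
viable stage is recorded as untyped when collected later, resorbed with
probability `resorption_rate` (default 1 — a post-implantation death is
seen as a resorption). `simulate_culture_cohort` starts embryos at
compacted morula / blastocyst / expanded blastocyst with probabilities
(0.2, 0.1, 0.7) — the day-1 mix of the published cohort — then each day
applies a death hazard followed by a one-rung advance with probability
0.7. Blocked genotypes (default the homozygous mutant) never pass
expanded blastocyst and face a daily hazard of 0.65, so nearly all die
within five days; in a het×het cohort a quarter of embryos are blocked
and cohort mortality lands near the observed 25%.

All generator randomness flows from one root seed through substreams
labelled by CRC-32 of a purpose string, so every output is reproducible
byte-for-byte from (seed, config).

## Numerical and design choices

- Coordinates are 1-based, fully closed intron positions (the STAR
  `SJ.out.tab` convention); strand unknown (code 0) is retained and part
  of junction identity, so antisense overlaps never collapse.
- Usage sums are validated to 1 within 1e-12; degenerate-variance
  detection in the scalar (unannotated) comparison uses exact value
  identity rather than a variance threshold, because the variance of
  floating-point-identical values need not be exactly zero.
- BH significance uses adjusted p ≤ α; adjusted values are monotone in
  the raw ranks.
- Problem sizes in the test suite (200 genes, 100 replicate seeds for
  recovery and detection properties, 30 null datasets for ≥10,000 tests,
  100,000 Monte-Carlo draws for the chi-square oracle) are chosen so every
  distributional claim has enough resolution at its stated tolerance while
  the whole suite stays fast enough to run on every change.

## Known limitations

- The usage t-test at n = 3 per group relies on approximate normality of
  usage fractions; at the simulated depths the Welch test is mildly
  conservative (observed null rate ≈ 0.034 at nominal 0.05), which is the
  safe direction but costs some power.
- The per-(junction, side) reporting tests correlated hypotheses (the two
  members of a two-junction set, and the two sides of one junction, carry
  the same information); BH is applied to this correlated family, which
  is valid but slightly conservative.
- Ψ assumes exactly one cassette exon with both inclusion junctions
  observed; multi-exon skipping or intron retention need a different
  statistic.
- The culture model has no day-varying hazards and no partial
  progressions; it reproduces cohort-level outcome frequencies, not
  individual trajectories.
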