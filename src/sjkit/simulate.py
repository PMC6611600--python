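"""Synthetic-data generators matching the statistical structure the
analyses assume.

Three generators:

* :func:`simulate_junction_counts` — splice-junction count tables for a
  litter-paired two-group RNA-seq design (default 3 WT vs 3 HET pooled
  samples) with one planted heterozygous cassette-exon deletion whose
  skipped allele contributes half of the gene's transcripts, a background
  of constitutive and group-balanced alternatively spliced genes,
  gene-specific litter effects, and sparse unannotated noise junctions.
* :func:`simulate_cross` — per-embryo genotype records from a Mendelian
  cross with optional stage-specific lethality (embryos whose genotype is
  dead by the collection stage are recorded untyped/resorbed).
* :func:`simulate_culture_cohort` — daily blastocyst-culture trajectories
  in which designated genotypes never hatch from the zona pellucida and
  die with a daily hazard.

Counts follow a negative-binomial law with variance μ + αμ², realised as
a per-gene Gamma(1/α, α) intensity shared by all of the gene's junctions
times independent Poisson draws per junction.  The shared intensity makes
gene-level overdispersion cancel in usage and Ψ ratios, as it does in
real data where expression noise scales all of a gene's junctions
together.

All randomness derives from one root seed through labelled substreams, so
identical (seed, config) pairs give byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .culture import DEAD, LADDER, CultureRecord
from .io import (
    GENOTYPES,
    JUNCTION_INDEX,
    UNTYPED,
    GeneModel,
    JunctionTable,
    SampleInfo,
)
from .mendel import STAGE_ORDER

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_junction_counts",
    "simulate_cross",
    "simulate_culture_cohort",
    "labelled_rng",
]


def labelled_rng(seed: int, label: str) -> np.random.Generator:
    """A generator for one named substream of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


@dataclass
class SimConfig:
    """Study-design parameters of the junction-count generator.

    Defaults mirror the emulated experiment: 3 litter-paired WT/HET sample
    pairs, one heterozygous cassette-exon deletion with skip fraction 0.5
    (half of HET transcripts lack the exon; WT transcripts all include it),
    ~300 expected reads per constitutive junction, negative-binomial
    dispersion 0.1 and a log-scale litter effect SD of 0.3.
    """

    n_genes: int = 200
    n_per_group: int = 3
    litter_pairing: bool = True
    depth_scale: float = 300.0
    nb_dispersion: float = 0.1
    litter_sd: float = 0.3
    planted_skip_fraction: float = 0.5
    unannotated_noise_rate: float = 0.02
    seed: int = 0
    # Background structure: baseline expression spread and the fraction of
    # null genes carrying a group-balanced cassette event (real
    # transcriptomes splice alternatively; without them no null anchor set
    # would be testable).
    gene_lognorm_sd: float = 0.5
    alt_gene_fraction: float = 0.5
    noise_count_mean: float = 2.0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be ≥ 2 (group tests need ≥ 2 samples)")
        if not 0.0 <= self.planted_skip_fraction <= 1.0:
            raise ValueError("planted_skip_fraction must lie in [0, 1]")
        for name in ("n_genes", "depth_scale", "nb_dispersion", "litter_sd",
                     "gene_lognorm_sd", "noise_count_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.unannotated_noise_rate <= 1.0:
            raise ValueError("unannotated_noise_rate must lie in [0, 1]")
        if not 0.0 <= self.alt_gene_fraction <= 1.0:
            raise ValueError("alt_gene_fraction must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    planted_gene: str
    inclusion_keys: list
    skip_key: tuple
    true_inclusion: dict[str, float]  # per sample
    gene_lambda: dict[str, float]
    gene_class: dict[str, str]  # constitutive | alternative | planted
    gene_rho: dict[str, float]  # balanced inclusion of alternative genes
    litter_effects: dict[str, list[float]]  # litter → per-gene multiplier
    config: dict

    def to_json(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        payload["inclusion_keys"] = [list(k) for k in self.inclusion_keys]
        payload["skip_key"] = list(self.skip_key)
        path.write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload["inclusion_keys"] = [tuple(k) for k in payload["inclusion_keys"]]
        payload["skip_key"] = tuple(payload["skip_key"])
        return cls(**payload)


@dataclass
class SimResult:
    table: JunctionTable
    genes: list[GeneModel]
    samples: list[SampleInfo]
    truth: SimTruth

    def write(self, directory: str | Path) -> None:
        """Write SJ.out.tab files, annotation, sample sheet and truth JSON."""
        from . import io as sjio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_sj_files(directory)
        sjio.write_annotation(self.genes, directory / "annotation.tsv")
        sjio.write_sample_sheet(self.samples, directory / "samples.csv")
        self.truth.to_json(directory / "truth.json")


# gene geometry: 3 exons of 200 bp separated by ~1.2 kb introns
_GENE_PITCH = 10_000
_EXON_LEN = 200


def _gene_coords(i: int) -> dict:
    s = i * _GENE_PITCH + 1
    e1 = (s, s + _EXON_LEN - 1)
    e2 = (s + 1400, s + 1400 + _EXON_LEN - 1)
    e3 = (s + 2800, s + 2800 + _EXON_LEN - 1)
    return {
        "exons": [e1, e2, e3],
        "j1": (e1[1] + 1, e2[0] - 1),  # upstream inclusion junction
        "j2": (e2[1] + 1, e3[0] - 1),  # downstream inclusion junction
        "j3": (e1[1] + 1, e3[0] - 1),  # skipping junction
    }


def simulate_junction_counts(config: SimConfig | None = None) -> SimResult:
    """Simulate junction count tables with one planted cassette deletion.

    Per gene g the baseline λ_g is log-normal; each sample's gene intensity
    is λ_g × a gene-specific litter multiplier × depth_scale × a shared
    Gamma(1/α, α) overdispersion draw.  Constitutive genes express the two
    consecutive junctions; "alternative" genes splice their middle exon in
    and out with a gene-specific, group-balanced inclusion ρ_g; the planted
    gene has inclusion 1 in WT and 1 − skip_fraction in HET samples.
    Unannotated noise junctions sharing an existing donor are added at the
    configured per-gene rate with low Poisson counts.
    """
    config = config or SimConfig()
    chrom, strand = "chr1", "+"
    n = config.n_per_group
    samples = [
        SampleInfo(f"wt{i + 1}", "WT", f"litter{i + 1}" if config.litter_pairing else f"litter{i + 1}")
        for i in range(n)
    ] + [
        SampleInfo(
            f"het{i + 1}",
            "HET",
            f"litter{i + 1}" if config.litter_pairing else f"litter{n + i + 1}",
        )
        for i in range(n)
    ]
    litters = sorted({s.litter for s in samples})

    rng_struct = labelled_rng(config.seed, "structure")
    rng_litter = labelled_rng(config.seed, "litter")
    rng_counts = labelled_rng(config.seed, "counts")

    gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    lam = np.exp(rng_struct.normal(0.0, config.gene_lognorm_sd, size=config.n_genes))
    planted_idx = int(rng_struct.integers(config.n_genes))
    is_alt = rng_struct.random(config.n_genes) < config.alt_gene_fraction
    is_alt[planted_idx] = False
    rho = rng_struct.uniform(0.3, 0.7, size=config.n_genes)
    has_noise = rng_struct.random(config.n_genes) < config.unannotated_noise_rate
    noise_offset = rng_struct.integers(100, 900, size=config.n_genes)

    litter_fx = {
        lit: np.exp(rng_litter.normal(0.0, config.litter_sd, size=config.n_genes))
        for lit in litters
    }

    genes: list[GeneModel] = []
    counts_rows: dict[tuple, np.ndarray] = {}
    annotated_flags: dict[tuple, bool] = {}
    shape = 1.0 / config.nb_dispersion

    sample_ids = [s.sample_id for s in samples]
    sample_litter = {s.sample_id: s.litter for s in samples}
    sample_group = {s.sample_id: s.group for s in samples}

    het_inclusion = 1.0 - config.planted_skip_fraction
    true_inclusion = {
        s.sample_id: (1.0 if s.group == "WT" else het_inclusion) for s in samples
    }

    for i, gid in enumerate(gene_ids):
        coords = _gene_coords(i)
        planted = i == planted_idx
        alt = bool(is_alt[i])
        transcripts = {f"{gid}.t1": coords["exons"]}
        if alt:
            transcripts[f"{gid}.t2"] = [coords["exons"][0], coords["exons"][2]]
        genes.append(GeneModel.from_transcripts(gid, chrom, strand, transcripts))

        # per-sample gene intensity with shared overdispersion
        overdisp = rng_counts.gamma(shape, 1.0 / shape, size=len(sample_ids))
        intensity = np.array(
            [
                lam[i]
                * litter_fx[sample_litter[sid]][i]
                * config.depth_scale
                * overdisp[k]
                for k, sid in enumerate(sample_ids)
            ]
        )
        if planted:
            incl = np.array([true_inclusion[sid] for sid in sample_ids])
        elif alt:
            incl = np.full(len(sample_ids), rho[i])
        else:
            incl = np.ones(len(sample_ids))

        j1 = (chrom, *coords["j1"], strand)
        j2 = (chrom, *coords["j2"], strand)
        j3 = (chrom, *coords["j3"], strand)
        counts_rows[j1] = rng_counts.poisson(incl * intensity)
        counts_rows[j2] = rng_counts.poisson(incl * intensity)
        annotated_flags[j1] = True
        annotated_flags[j2] = True
        if planted or alt:
            counts_rows[j3] = rng_counts.poisson((1.0 - incl) * intensity)
            # the planted skipped isoform is not in the annotation
            annotated_flags[j3] = alt
        if has_noise[i]:
            jn = (chrom, coords["j1"][0], coords["j1"][1] - int(noise_offset[i]), strand)
            if jn not in counts_rows:
                counts_rows[jn] = rng_counts.poisson(
                    config.noise_count_mean, size=len(sample_ids)
                )
                annotated_flags[jn] = False

    index = pd.MultiIndex.from_tuples(sorted(counts_rows), names=JUNCTION_INDEX)
    counts = pd.DataFrame(
        [counts_rows[k] for k in index], index=index, columns=sample_ids
    )
    annotated = pd.Series([annotated_flags[k] for k in index], index=index, dtype=bool)
    table = JunctionTable(counts, annotated)

    pg = gene_ids[planted_idx]
    pc = _gene_coords(planted_idx)
    truth = SimTruth(
        planted_gene=pg,
        inclusion_keys=[(chrom, *pc["j1"], strand), (chrom, *pc["j2"], strand)],
        skip_key=(chrom, *pc["j3"], strand),
        true_inclusion=true_inclusion,
        gene_lambda={g: float(l) for g, l in zip(gene_ids, lam)},
        gene_class={
            g: ("planted" if i == planted_idx else "alternative" if is_alt[i] else "constitutive")
            for i, g in enumerate(gene_ids)
        },
        gene_rho={g: float(r) for g, (r, a) in zip(gene_ids, zip(rho, is_alt)) if a},
        litter_effects={lit: [float(x) for x in fx] for lit, fx in litter_fx.items()},
        config=asdict(config),
    )
    return SimResult(table=table, genes=genes, samples=samples, truth=truth)


def simulate_cross(
    stage: str,
    n_litters: int,
    ratio: Sequence[float] = (1, 2, 1),
    litter_size_mean: float = 8.0,
    lethality: Mapping[str, str] | None = None,
    resorption_rate: float = 1.0,
    seed: int = 0,
    stage_order: Sequence[str] = STAGE_ORDER,
) -> pd.DataFrame:
    """Per-embryo genotype records of litters collected at one stage.

    ``ratio`` aligns with (+/+, +/-, -/-); het×WT is (1, 1, 0).  Litter
    sizes are Poisson(``litter_size_mean``) truncated at 1 and genotypes
    multinomial within each litter.  ``lethality`` maps a genotype to the
    last stage at which it is recoverable; an embryo of that genotype
    collected later is recorded untyped, and as a resorption with
    probability ``resorption_rate``.
    """
    if stage not in stage_order:
        raise ValueError(f"unknown stage {stage!r}; expected one of {list(stage_order)}")
    lethality = dict(lethality or {})
    for g, s in lethality.items():
        if g not in GENOTYPES:
            raise ValueError(f"unknown genotype {g!r} in lethality map")
        if s not in stage_order:
            raise ValueError(f"impossible lethality stage {s!r}")
    weights = np.asarray(ratio, dtype=float)
    if weights.shape != (3,) or (weights < 0).any() or weights.sum() == 0:
        raise ValueError("ratio must be three non-negative weights with positive sum")
    probs = weights / weights.sum()
    rng = labelled_rng(seed, f"cross:{stage}")
    stage_idx = {s: i for i, s in enumerate(stage_order)}
    rows = []
    for lit in range(1, n_litters + 1):
        size = max(1, int(rng.poisson(litter_size_mean)))
        genos = rng.choice(len(GENOTYPES), size=size, p=probs)
        for g_idx in genos:
            genotype = GENOTYPES[g_idx]
            dead = (
                genotype in lethality
                and stage_idx[stage] > stage_idx[lethality[genotype]]
            )
            if dead:
                rows.append(
                    {
                        "stage": stage,
                        "genotype": UNTYPED,
                        "resorbed": bool(rng.random() < resorption_rate),
                        "litter": f"litter{lit}",
                    }
                )
            else:
                rows.append(
                    {
                        "stage": stage,
                        "genotype": genotype,
                        "resorbed": False,
                        "litter": f"litter{lit}",
                    }
                )
    return pd.DataFrame(rows, columns=["stage", "genotype", "resorbed", "litter"])


def simulate_culture_cohort(
    genotypes: Sequence[str] | pd.DataFrame,
    progression_prob: float = 0.7,
    hatch_block: Iterable[str] = ("-/-",),
    block_death_hazard: float = 0.65,
    base_death_hazard: float = 0.0,
    init_status_probs: Sequence[float] = (0.2, 0.1, 0.7),
    n_days: int = 5,
    seed: int = 0,
) -> list[CultureRecord]:
    """Simulate daily culture trajectories for a genotyped cohort.

    Embryos start (day 1) at compacted morula / blastocyst / expanded
    blastocyst with probabilities ``init_status_probs`` and each later day
    first face a death hazard, then advance one ladder rung with
    probability ``progression_prob``.  Genotypes in ``hatch_block`` never
    pass the expanded-blastocyst rung and face ``block_death_hazard`` daily
    instead of ``base_death_hazard``.  Defaults emulate a het×het E3.5
    cohort in which the quarter of embryos that are homozygous mutants
    cannot hatch and nearly all die within the 5-day culture (~25% cohort
    mortality).
    """
    if isinstance(genotypes, pd.DataFrame):
        genotypes = list(genotypes["genotype"])
    probs = np.asarray(init_status_probs, dtype=float)
    if probs.shape != (3,) or (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
        raise ValueError("init_status_probs must be three probabilities summing to 1")
    for p in (progression_prob, block_death_hazard, base_death_hazard):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    blocked = set(hatch_block)
    rng = labelled_rng(seed, "culture")
    start_statuses = ("compacted_morula", "blastocyst", "expanded_blastocyst")
    cap = LADDER.index("expanded_blastocyst")
    records: list[CultureRecord] = []
    for i, genotype in enumerate(genotypes):
        embryo = f"embryo{i + 1:03d}"
        rank = LADDER.index(start_statuses[rng.choice(3, p=probs)])
        dead = False
        hazard = block_death_hazard if genotype in blocked else base_death_hazard
        for day in range(1, n_days + 1):
            if not dead and day > 1:
                if rng.random() < hazard:
                    dead = True
                elif rng.random() < progression_prob:
                    rank += 1
                    if genotype in blocked:
                        rank = min(rank, cap)
                    rank = min(rank, len(LADDER) - 1)
            elif not dead and day == 1 and rng.random() < hazard:
                dead = True
            records.append(
                CultureRecord(
                    embryo_id=embryo,
                    day=day,
                    status=DEAD if dead else LADDER[rank],
                    genotype=genotype if genotype in GENOTYPES else None,
                )
            )
    return records
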