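"""Readers and writers for the tabular formats used throughout the package.

This module is the single home for coordinate and dialect conventions:

* Splice junctions use the STAR ``SJ.out.tab`` dialect — nine tab-separated
  columns, 1-based fully-closed *intron* coordinates (column 2 is the first
  intronic base, column 3 the last), strand encoded 0/1/2 for
  unknown/+/−, column 6 a 0/1 annotated flag and column 7 the uniquely
  mapping read count.  Only unique-read counts feed downstream statistics;
  multi-mapper counts are parsed and discarded.
* Annotations are a GTF-lite TSV with ``gene`` and ``exon`` rows.
* Sample sheets, genotype records and embryo-culture records are plain CSV
  with a header row, "." decimals and UTF-8 encoding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "JunctionRecord",
    "JunctionTable",
    "SampleInfo",
    "GeneModel",
    "read_sj_tab",
    "write_sj_tab",
    "read_annotation",
    "write_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_genotype_records",
    "write_genotype_records",
    "read_culture_records",
    "write_culture_records",
]

#: Index level names for junction keys, used everywhere downstream.
JUNCTION_INDEX = ("chrom", "intron_start", "intron_end", "strand")

_STRAND_FROM_CODE = {"0": ".", "1": "+", "2": "-"}
_STRAND_TO_CODE = {".": "0", "+": "1", "-": "2"}

#: Genotype vocabulary for cross records; "n.t." marks untyped embryos.
GENOTYPES = ("+/+", "+/-", "-/-")
UNTYPED = "n.t."

#: The six-level blastocyst scoring vocabulary (see :mod:`sjkit.culture`).
CULTURE_STATUSES = (
    "compacted_morula",
    "blastocyst",
    "expanded_blastocyst",
    "hatched",
    "outgrowth",
    "dead",
)
#: Pre-ladder status for embryos that never compacted (rare; fixture-only).
PRE_LADDER_STATUS = "pre_morula"


class ParseError(ValueError):
    """Raised when an input file violates its dialect."""


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction in one sample (STAR ``SJ.out.tab`` line)."""

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    annotated: bool
    unique_count: int

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ParseError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.intron_start < 1:
            raise ParseError(f"coordinates are 1-based, got start {self.intron_start}")
        if self.unique_count < 0:
            raise ParseError(f"negative unique count {self.unique_count}")
        if self.strand not in _STRAND_TO_CODE:
            raise ParseError(f"strand must be one of +, -, '.'; got {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


@dataclass(frozen=True)
class SampleInfo:
    """One RNA-seq sample: id, genotype group and litter of origin."""

    sample_id: str
    group: str
    litter: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ParseError("empty sample_id")
        if not self.group:
            raise ParseError(f"sample {self.sample_id}: empty group")
        if not self.litter:
            raise ParseError(f"sample {self.sample_id}: empty litter")


@dataclass
class GeneModel:
    """A gene with its exon structure and the junctions its transcripts splice.

    ``exons`` is the sorted, merged union of all transcript exons;
    ``annotated_junctions`` contains the 1-based closed intron coordinates
    between consecutive exons of every transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    span_start: int
    span_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    annotated_junctions: set[tuple[int, int]] = field(default_factory=set)
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_transcripts(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        transcripts: Mapping[str, Sequence[tuple[int, int]]],
    ) -> "GeneModel":
        """Build a gene model, deriving span, merged exons and junctions."""
        all_exons = sorted(e for exs in transcripts.values() for e in exs)
        if not all_exons:
            raise ParseError(f"gene {gene_id}: no exons")
        for s, e in all_exons:
            if s > e:
                raise ParseError(f"gene {gene_id}: exon start {s} > end {e}")
        span_start = min(s for s, _ in all_exons)
        span_end = max(e for _, e in all_exons)
        merged: list[tuple[int, int]] = []
        for s, e in all_exons:
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        junctions: set[tuple[int, int]] = set()
        for exs in transcripts.values():
            ordered = sorted(exs)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if s2 <= e1:
                    raise ParseError(
                        f"gene {gene_id}: overlapping exons within one transcript"
                    )
                junctions.add((e1 + 1, s2 - 1))
        return cls(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            span_start=span_start,
            span_end=span_end,
            exons=merged,
            annotated_junctions=junctions,
            transcripts={t: sorted(exs) for t, exs in transcripts.items()},
        )


class JunctionTable:
    """Junction × sample matrix of unique-read counts.

    ``counts`` is an integer DataFrame indexed by the 4-tuple junction key
    (chrom, intron_start, intron_end, strand) with one column per sample.
    ``annotated`` is a boolean Series on the same index carrying the
    aligner's annotated flag (the OR across samples).
    """

    def __init__(self, counts: pd.DataFrame, annotated: pd.Series) -> None:
        if list(counts.index.names) != list(JUNCTION_INDEX):
            raise ValueError(f"counts index must be named {JUNCTION_INDEX}")
        if not counts.index.is_unique:
            raise ValueError("duplicate junction keys")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        annotated = annotated.reindex(counts.index)
        if annotated.isna().any():
            raise ValueError("annotated flags missing for some junctions")
        self.counts = counts.astype("int64").sort_index()
        self.annotated = annotated.astype(bool).sort_index()

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def junction_keys(self) -> pd.MultiIndex:
        return self.counts.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JunctionTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.annotated.equals(
            other.annotated
        )

    @classmethod
    def from_records(
        cls, records_by_sample: Mapping[str, Iterable[JunctionRecord]]
    ) -> "JunctionTable":
        columns: dict[str, pd.Series] = {}
        flags: dict[tuple, bool] = {}
        for sample_id, records in records_by_sample.items():
            data: dict[tuple, int] = {}
            for rec in records:
                if rec.key in data:
                    raise ParseError(
                        f"sample {sample_id}: duplicate junction {rec.key}"
                    )
                data[rec.key] = rec.unique_count
                flags[rec.key] = flags.get(rec.key, False) or rec.annotated
            idx = pd.MultiIndex.from_tuples(data.keys(), names=JUNCTION_INDEX)
            columns[sample_id] = pd.Series(list(data.values()), index=idx)
        counts = pd.DataFrame(columns).fillna(0).astype("int64")
        counts.index.names = list(JUNCTION_INDEX)
        annotated = pd.Series(
            {k: v for k, v in flags.items()}, dtype=bool
        )
        annotated.index = pd.MultiIndex.from_tuples(flags.keys(), names=JUNCTION_INDEX)
        return cls(counts, annotated)

    @classmethod
    def from_sj_files(cls, paths_by_sample: Mapping[str, str | Path]) -> "JunctionTable":
        return cls.from_records(
            {s: read_sj_tab(p, sample_id=s) for s, p in paths_by_sample.items()}
        )

    def to_sj_files(self, directory: str | Path) -> dict[str, Path]:
        """Write one ``<sample>.SJ.out.tab`` per sample; returns the paths.

        Every junction row is written for every sample (zero counts
        included) so that write → read round-trips bit-exactly.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out: dict[str, Path] = {}
        for sample in self.samples:
            path = directory / f"{sample}.SJ.out.tab"
            write_sj_tab(self.sample_records(sample), path)
            out[sample] = path
        return out

    def sample_records(self, sample_id: str) -> list[JunctionRecord]:
        col = self.counts[sample_id]
        return [
            JunctionRecord(
                chrom=key[0],
                intron_start=key[1],
                intron_end=key[2],
                strand=key[3],
                annotated=bool(self.annotated.loc[key]),
                unique_count=int(count),
            )
            for key, count in col.items()
        ]


def read_sj_tab(path: str | Path, sample_id: str | None = None) -> list[JunctionRecord]:
    """Read a STAR ``SJ.out.tab`` file into junction records.

    Column 7 (unique reads) becomes ``unique_count``; column 6 becomes the
    annotated flag; columns 5 (motif), 8 (multi-mapped reads) and 9 (max
    overhang) are parsed for dialect validation but discarded.
    """
    path = Path(path)
    label = sample_id or path.name
    records: list[JunctionRecord] = []
    seen: set[tuple] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{label}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                strand = _STRAND_FROM_CODE.get(fields[3])
                if strand is None:
                    raise ValueError(f"bad strand code {fields[3]!r}")
                annotated = int(fields[5]) != 0
                unique = int(fields[6])
                int(fields[4]), int(fields[7]), int(fields[8])
            except ValueError as exc:
                raise ParseError(f"{label}:{lineno}: {exc}") from exc
            try:
                rec = JunctionRecord(chrom, start, end, strand, annotated, unique)
            except ParseError as exc:
                raise ParseError(f"{label}:{lineno}: {exc}") from exc
            if rec.key in seen:
                raise ParseError(f"{label}:{lineno}: duplicate junction {rec.key}")
            seen.add(rec.key)
            records.append(rec)
    return records


def write_sj_tab(records: Iterable[JunctionRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(rec.intron_start),
                        str(rec.intron_end),
                        _STRAND_TO_CODE[rec.strand],
                        "0",
                        "1" if rec.annotated else "0",
                        str(rec.unique_count),
                        "0",
                        "0",
                    ]
                )
                + "\n"
            )


_ANNOTATION_HEADER = ["feature", "gene_id", "transcript_id", "chrom", "strand", "start", "end"]


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GTF-lite TSV annotation into gene models.

    The file has a header row and ``gene``/``exon`` feature rows.  Junctions
    between consecutive exons of each transcript become annotated junctions.
    An exon outside its gene's declared span is a validation error.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(_ANNOTATION_HEADER) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path.name}: missing annotation columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            feature = row["feature"]
            gene_id = row["gene_id"]
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            if feature == "gene":
                if gene_id in genes:
                    raise ParseError(f"{path.name}:{lineno}: duplicate gene {gene_id}")
                genes[gene_id] = {
                    "chrom": row["chrom"],
                    "strand": row["strand"],
                    "span": (start, end),
                    "transcripts": {},
                }
                order.append(gene_id)
            elif feature == "exon":
                if gene_id not in genes:
                    raise ParseError(
                        f"{path.name}:{lineno}: exon for undeclared gene {gene_id}"
                    )
                info = genes[gene_id]
                if start < info["span"][0] or end > info["span"][1]:
                    raise ParseError(
                        f"{path.name}:{lineno}: exon ({start}, {end}) outside "
                        f"gene {gene_id} span {info['span']}"
                    )
                tid = row["transcript_id"] or gene_id
                info["transcripts"].setdefault(tid, []).append((start, end))
            else:
                raise ParseError(f"{path.name}:{lineno}: unknown feature {feature!r}")
    models = []
    for gid in order:
        info = genes[gid]
        if not info["transcripts"]:
            raise ParseError(f"gene {gid}: no exons")
        models.append(
            GeneModel.from_transcripts(gid, info["chrom"], info["strand"], info["transcripts"])
        )
    return models


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_HEADER)
        for g in genes:
            writer.writerow(["gene", g.gene_id, "", g.chrom, g.strand, g.span_start, g.span_end])
            for tid in sorted(g.transcripts):
                for s, e in g.transcripts[tid]:
                    writer.writerow(["exon", g.gene_id, tid, g.chrom, g.strand, s, e])


def _read_csv_rows(path: str | Path, required: Sequence[str]) -> list[dict]:
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(required) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path.name}: missing columns {sorted(missing)}")
        return list(reader)


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """Read the sample sheet CSV (sample_id, group, litter)."""
    rows = _read_csv_rows(path, ["sample_id", "group", "litter"])
    samples: list[SampleInfo] = []
    seen: set[str] = set()
    for row in rows:
        info = SampleInfo(row["sample_id"], row["group"], row["litter"])
        if info.sample_id in seen:
            raise ParseError(f"duplicate sample_id {info.sample_id!r}")
        seen.add(info.sample_id)
        samples.append(info)
    return samples


def write_sample_sheet(samples: Iterable[SampleInfo], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "group", "litter"])
        for s in samples:
            writer.writerow([s.sample_id, s.group, s.litter])


def read_genotype_records(path: str | Path) -> pd.DataFrame:
    """Read per-embryo genotype records (stage, genotype, resorbed, litter).

    ``genotype`` must be one of +/+, +/-, -/- or "n.t." for untyped embryos;
    ``resorbed`` is 0/1 (or true/false).
    """
    rows = _read_csv_rows(path, ["stage", "genotype", "resorbed", "litter"])
    parsed = []
    legal = set(GENOTYPES) | {UNTYPED}
    for i, row in enumerate(rows, start=2):
        if row["genotype"] not in legal:
            raise ParseError(
                f"line {i}: unknown genotype {row['genotype']!r}; "
                f"expected one of {sorted(legal)}"
            )
        resorbed = str(row["resorbed"]).strip().lower()
        if resorbed not in {"0", "1", "true", "false"}:
            raise ParseError(f"line {i}: resorbed must be 0/1, got {row['resorbed']!r}")
        parsed.append(
            {
                "stage": row["stage"],
                "genotype": row["genotype"],
                "resorbed": resorbed in {"1", "true"},
                "litter": row["litter"],
            }
        )
    return pd.DataFrame(parsed, columns=["stage", "genotype", "resorbed", "litter"])


def write_genotype_records(records: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = records.copy()
    records["resorbed"] = records["resorbed"].astype(int)
    records.to_csv(path, index=False, lineterminator="\n")


def read_culture_records(path: str | Path):
    """Read per-embryo daily culture-status records.

    Returns a list of :class:`sjkit.culture.CultureRecord`.  The status
    vocabulary is the six-level scoring ladder; anything else is rejected
    with a message listing the legal statuses.
    """
    from .culture import CultureRecord  # local import avoids a cycle

    rows = _read_csv_rows(path, ["embryo_id", "day", "status"])
    legal = set(CULTURE_STATUSES) | {PRE_LADDER_STATUS}
    records = []
    for i, row in enumerate(rows, start=2):
        if row["status"] not in legal:
            raise ParseError(
                f"line {i}: unknown culture status {row['status']!r}; the six "
                f"legal statuses are {', '.join(CULTURE_STATUSES)} "
                f"(plus pre-ladder {PRE_LADDER_STATUS!r})"
            )
        try:
            day = int(row["day"])
        except ValueError as exc:
            raise ParseError(f"line {i}: {exc}") from exc
        genotype = row.get("genotype") or None
        if genotype is not None and genotype not in set(GENOTYPES) | {UNTYPED}:
            raise ParseError(f"line {i}: unknown genotype {genotype!r}")
        records.append(
            CultureRecord(
                embryo_id=row["embryo_id"],
                day=day,
                status=row["status"],
                genotype=genotype,
                litter=row.get("litter") or None,
            )
        )
    return records


def write_culture_records(records, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["embryo_id", "day", "status", "genotype", "litter"])
        for r in records:
            writer.writerow([r.embryo_id, r.day, r.status, r.genotype or "", r.litter or ""])
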