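"""Readers/writers for external formats and the canonical in-memory genomic types.

All internal coordinates are 0-based half-open intervals on a named chromosome;
GFF3's 1-based closed coordinates are converted at the boundary.  Single-bp
"positions" (TSSs, summits, CDS 5' ends) are 0-based indices of the base
itself, so the 5' end of a minus-strand feature with half-open span ``[s, e)``
is ``e - 1``.

File dialects
-------------
* GFF3 gene models: ``gene``/``mRNA``/``exon``/``CDS`` features with
  ``ID``/``Parent`` attributes (parsed with :mod:`gffutils`).
* ENCODE narrowPeak (10 columns).  The score column carries the summit pileup
  depth, ``signalValue`` the enrichment score, ``pValue`` the (possibly
  fractional) read count in the peak, ``qValue`` the raw BH q-value (not
  -log10), and the final column the summit offset from the interval start
  (-1 = summit unknown).
* BED6 alignment dialect: one aligned location per line; the score column
  carries ``n_hits``, the total number of genomic hits of the read.
* BED6 TSS dialect: the score column carries the supporting read depth; the
  name column optionally links the TSS to a gene/transcript id (``.`` = none).
* bedGraph: per-strand files, half-open non-overlapping intervals; gaps are
  zero coverage.

Unknown chromosomes or out-of-bounds intervals in any file are hard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomeLayout",
    "Transcript",
    "GeneModel",
    "TssRecord",
    "ReadAlignment",
    "CoverageTrack",
    "Peak",
    "read_genome_tsv",
    "write_genome_tsv",
    "read_gff3",
    "write_gff3",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_coverage_bedgraph",
    "write_coverage_bedgraph",
    "read_alignments_bed",
    "write_alignments_bed",
    "read_tss_bed",
    "write_tss_bed",
]

STRANDS = ("+", "-")


class FormatError(ValueError):
    """A file violates its declared dialect or references unknown coordinates."""


# ---------------------------------------------------------------------------
# domain types


class GenomeLayout:
    """Chromosome name -> length (bp).  Lengths must be positive and unique."""

    def __init__(self, lengths: Mapping[str, int]):
        if not lengths:
            raise ValueError("genome layout must contain at least one chromosome")
        self._lengths: dict[str, int] = {}
        for name, length in lengths.items():
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._lengths[name] = length

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise FormatError(f"unknown chromosome {chrom!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    def items(self):
        return self._lengths.items()

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        length = self[chrom]
        if not (0 <= start < end <= length):
            raise FormatError(
                f"interval [{start}, {end}) out of bounds for {chrom!r} (length {length})"
            )

    def check_position(self, chrom: str, position: int) -> None:
        length = self[chrom]
        if not 0 <= position < length:
            raise FormatError(
                f"position {position} out of bounds for {chrom!r} (length {length})"
            )


@dataclass(frozen=True)
class Transcript:
    """One transcript of a gene model.

    ``cds_5prime`` is the genomic position (0-based, single bp) of the 5' end
    of the first CDS in transcript orientation: the smallest CDS start on the
    plus strand, the largest CDS coordinate (``end - 1``) on the minus strand.
    ``None`` for non-coding transcripts.  ``first_cds`` is the half-open span
    of that CDS segment.
    """

    transcript_id: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds_5prime: int | None = None
    first_cds: tuple[int, int] | None = None

    def five_prime(self, strand: str) -> int:
        return self.start if strand == "+" else self.end - 1


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[Transcript, ...] = ()

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"empty gene span for {self.gene_id}")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def overlaps(self, other: "GeneModel") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TssRecord:
    chrom: str
    strand: str
    position: int
    read_depth: int
    linked_id: str | None = None
    source: str = "."

    def __post_init__(self):
        if self.read_depth < 0:
            raise ValueError("TSS read depth must be >= 0")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned location of a read.

    ``n_hits`` is the total number of genomic locations the read aligns to
    (1 = unique); multimapping reads appear as ``n_hits`` separate records.
    """

    chrom: str
    strand: str
    start: int
    end: int
    n_hits: int = 1
    library: str = "ip"
    replicate: str = "1"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("alignment end must exceed start")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")

    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class CoverageTrack:
    """Per-bp pileup depth for one strand over a whole genome."""

    def __init__(self, genome: GenomeLayout, strand: str, data: dict[str, np.ndarray] | None = None):
        if strand not in STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        self.genome = genome
        self.strand = strand
        if data is None:
            data = {c: np.zeros(l, dtype=np.float64) for c, l in genome.items()}
        else:
            for chrom, arr in data.items():
                if len(arr) != genome[chrom]:
                    raise ValueError(f"track length mismatch on {chrom!r}")
                if np.any(arr < 0):
                    raise ValueError("coverage values must be >= 0")
        self.data = data

    def __getitem__(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            raise FormatError(f"unknown chromosome {chrom!r}")
        return self.data[chrom]

    @property
    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    @property
    def mean(self) -> float:
        return self.total / self.genome.total_bp


@dataclass
class Peak:
    """A (possibly refined) enrichment interval.

    ``summit`` is an absolute genomic position or ``None`` when unknown.
    ``read_count`` may be fractional after multimapper weighting.
    """

    chrom: str
    start: int
    end: int
    strand: str
    summit: int | None = None
    summit_coverage: float = 0.0
    read_count: float = 0.0
    enrichment_score: float = 0.0
    q_value: float = 1.0
    name: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("peak width must be >= 1")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError("summit must lie inside the peak interval")
        if self.enrichment_score < 0:
            raise ValueError("enrichment score must be >= 0")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError("q-value must be in [0, 1]")

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# genome layout TSV


def read_genome_tsv(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return GenomeLayout(dict(zip(df["chrom"], df["length"])))


def write_genome_tsv(genome: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# GFF3


def _first_cds(cds_spans: Sequence[tuple[int, int]], strand: str) -> tuple[int, int]:
    if strand == "+":
        return min(cds_spans, key=lambda s: s[0])
    return max(cds_spans, key=lambda s: s[1])


def read_gff3(path, genome: GenomeLayout | None = None) -> list[GeneModel]:
    """Parse gene models from GFF3 (1-based closed -> 0-based half-open)."""
    import gffutils

    path = Path(path)
    text = path.read_text()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return []
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise FormatError(f"malformed GFF3 in {path}: {exc}") from exc

    mrna_parent: dict[str, str] = {}
    genes: dict[str, dict] = {}
    for gene in db.features_of_type("gene"):
        if genome is not None:
            genome.check_interval(gene.seqid, gene.start - 1, gene.end)
        genes[gene.id] = {
            "chrom": gene.seqid,
            "strand": gene.strand,
            "start": gene.start - 1,
            "end": gene.end,
            "transcripts": [],
        }
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or parents[0] not in genes:
            raise FormatError(f"mRNA {mrna.id} has no parent gene")
        mrna_parent[mrna.id] = parents[0]
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or all(p not in mrna_parent for p in parents):
            raise FormatError(f"CDS at {cds.seqid}:{cds.start} has no parent mRNA")

    for mrna in db.features_of_type("mRNA"):
        gene_entry = genes[mrna_parent[mrna.id]]
        strand = mrna.strand
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise FormatError(f"overlapping exons in transcript {mrna.id}")
        cds_spans = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        cds5 = None
        first = None
        if cds_spans:
            first = _first_cds(cds_spans, strand)
            cds5 = first[0] if strand == "+" else first[1] - 1
            if not (mrna.start - 1 <= cds5 < mrna.end):
                raise FormatError(f"CDS 5' end outside mRNA span in {mrna.id}")
        gene_entry["transcripts"].append(
            Transcript(
                transcript_id=mrna.id,
                start=mrna.start - 1,
                end=mrna.end,
                exons=tuple(exons),
                cds_5prime=cds5,
                first_cds=first,
            )
        )

    return [
        GeneModel(
            gene_id=gid,
            chrom=info["chrom"],
            strand=info["strand"],
            start=info["start"],
            end=info["end"],
            transcripts=tuple(info["transcripts"]),
        )
        for gid, info in genes.items()
    ]


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tripfoot\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tripfoot\tmRNA\t{t.start + 1}\t{t.end}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chrom}\tripfoot\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                    )
                if t.first_cds is not None:
                    s, e = t.first_cds
                    fh.write(
                        f"{g.chrom}\tripfoot\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={t.transcript_id}.cds;Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# narrowPeak

_NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def read_narrowpeak(path, genome: GenomeLayout | None = None) -> list[Peak]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 10:
        raise FormatError(
            f"narrowPeak requires 10 columns, found {df.shape[1]} in {path}"
        )
    df.columns = _NARROWPEAK_COLS
    peaks = []
    for row in df.itertuples(index=False):
        if genome is not None:
            genome.check_interval(row.chrom, int(row.start), int(row.end))
        offset = int(row.peak)
        summit = None if offset == -1 else int(row.start) + offset
        peaks.append(
            Peak(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                summit=summit,
                summit_coverage=float(row.score),
                read_count=float(row.pValue),
                enrichment_score=float(row.signalValue),
                q_value=float(row.qValue),
                name=str(row.name),
            )
        )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            offset = -1 if p.summit is None else p.summit - p.start
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        repr(float(p.summit_coverage)),
                        p.strand,
                        repr(float(p.enrichment_score)),
                        repr(float(p.read_count)),
                        repr(float(p.q_value)),
                        str(offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph / BED6


def read_coverage_bedgraph(path, genome: GenomeLayout, strand: str) -> CoverageTrack:
    track = CoverageTrack(genome, strand)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return track
    if df.shape[1] != 4:
        raise FormatError(f"bedGraph requires 4 columns, found {df.shape[1]} in {path}")
    df.columns = ["chrom", "start", "end", "value"]
    for row in df.itertuples(index=False):
        genome.check_interval(row.chrom, int(row.start), int(row.end))
        if row.value < 0:
            raise FormatError("bedGraph coverage must be >= 0")
        track.data[row.chrom][int(row.start):int(row.end)] = row.value
    return track


def write_coverage_bedgraph(track: CoverageTrack, path) -> None:
    """Write runs of constant non-zero coverage (gaps are implicit zeros)."""
    with open(path, "w") as fh:
        for chrom, arr in track.data.items():
            if not len(arr):
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    v_out = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{s}\t{e}\t{v_out}\n")


def _read_bed6(path) -> pd.DataFrame | None:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    except pd.errors.EmptyDataError:
        return None
    if df.shape[1] != 6:
        raise FormatError(f"BED6 requires 6 columns, found {df.shape[1]} in {path}")
    df.columns = ["chrom", "start", "end", "name", "score", "strand"]
    return df


def read_alignments_bed(
    path, genome: GenomeLayout | None = None, library: str = "ip", replicate: str = "1"
) -> list[ReadAlignment]:
    df = _read_bed6(path)
    if df is None:
        return []
    out = []
    for row in df.itertuples(index=False):
        if genome is not None:
            genome.check_interval(row.chrom, int(row.start), int(row.end))
        out.append(
            ReadAlignment(
                chrom=row.chrom,
                strand=str(row.strand),
                start=int(row.start),
                end=int(row.end),
                n_hits=int(row.score),
                library=library,
                replicate=replicate,
            )
        )
    return out


def write_alignments_bed(alignments: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(alignments):
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\tread{i}\t{a.n_hits}\t{a.strand}\n")


def read_tss_bed(path, genome: GenomeLayout | None = None, source: str = ".") -> list[TssRecord]:
    df = _read_bed6(path)
    if df is None:
        return []
    out = []
    for row in df.itertuples(index=False):
        pos = int(row.start)
        if int(row.end) != pos + 1:
            raise FormatError("TSS BED records must span exactly 1 bp")
        if genome is not None:
            genome.check_position(row.chrom, pos)
        out.append(
            TssRecord(
                chrom=row.chrom,
                strand=str(row.strand),
                position=pos,
                read_depth=int(row.score),
                linked_id=None if row.name in (".", "") else str(row.name),
                source=source,
            )
        )
    return out


def write_tss_bed(records: Iterable[TssRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            name = r.linked_id if r.linked_id is not None else "."
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t{name}\t{r.read_depth}\t{r.strand}\n"
            )
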