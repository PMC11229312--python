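"""TSS curation, annotation extension and (transcript, TSS, peak) association.

Sign convention (used throughout): ``signed_distance(a, b, strand)`` is
``a - b`` on the plus strand and ``b - a`` on the minus strand, so a negative
distance always means *a is upstream (5') of b* in transcript orientation.

Association heuristics
----------------------
Given curated TSSs and quality-filtered peaks, the most likely
(transcript, TSS, peak) triples are resolved with four deterministic rules:

(i)   each TSS is assigned the nearest transcript downstream, measured to the
      5' end of the first CDS; a TSS may sit at most 50 bp *downstream* of
      that 5' end, and only when it falls inside the first CDS (rescues
      transcripts with mis-annotated start codons);
(ii)  each TSS is assigned the nearest peak by absolute summit-to-TSS
      distance;
(iii) a peak claimed by several TSSs keeps only the TSS with the smallest
      absolute distance (the losing TSSs become peakless);
(iv)  a transcript with several surviving pairs keeps the pair with the
      smallest |TSS-peak| distance, ties broken by smaller |TSS-CDS| distance,
      then by leftmost peak.

All peak distances are measured from the peak summit.  A transcript whose
peak summit is strictly upstream of the CDS 5' end (distance < 0) is
predicted to be spliced-leader trans-spliced; distance 0 counts as
downstream/overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneModel, Peak, Transcript, TssRecord

__all__ = [
    "AmbiguityError",
    "AssociationRecord",
    "signed_distance",
    "curate_tss",
    "match_tss_to_gene",
    "extend_annotation",
    "associate",
    "distance_distributions",
]


class AmbiguityError(ValueError):
    """Extending an annotation would overlap a neighbouring gene."""


def signed_distance(a: int, b: int, strand: str) -> int:
    """Signed bp offset of ``a`` relative to ``b`` in transcript orientation
    (negative = ``a`` upstream of ``b``)."""
    if strand == "+":
        return a - b
    if strand == "-":
        return b - a
    raise ValueError(f"invalid strand {strand!r}")


@dataclass(frozen=True)
class AssociationRecord:
    """Resolved association for one transcript.

    ``predicted_trans_spliced`` is ``None`` when no peak was assigned;
    otherwise it equals ``d_peak_cds < 0``.
    """

    transcript_id: str
    tss: TssRecord | None = None
    peak: Peak | None = None
    d_tss_peak: int | None = None
    d_peak_cds: int | None = None
    d_tss_cds: int | None = None
    predicted_trans_spliced: bool | None = None


# ---------------------------------------------------------------------------
# curation and gene matching


def curate_tss(
    records_by_group: Mapping[str, Sequence[TssRecord]],
    five_prime_of: Mapping[str, int] | None = None,
) -> dict[str, TssRecord]:
    """One TSS per group (transcript): highest read depth wins; ties are
    broken by the shorter distance to the transcript 5' end (when known),
    then by leftmost position for determinism."""
    curated: dict[str, TssRecord] = {}
    for group, records in records_by_group.items():
        if not records:
            continue

        def key(r: TssRecord):
            if five_prime_of is not None and group in five_prime_of:
                dist = abs(r.position - five_prime_of[group])
            else:
                dist = 0
            return (-r.read_depth, dist, r.position)

        curated[group] = min(records, key=key)
    return curated


def match_tss_to_gene(tss: TssRecord, genes: Sequence[GeneModel]) -> GeneModel | None:
    """The overlapping gene, else the nearest gene strictly downstream of the
    TSS in its strand orientation.  When the TSS carries a linked gene id,
    the match is kept only if the ids agree (mirrors an id-concordance check
    after a nearest-feature lookup)."""
    best: GeneModel | None = None
    best_key = None
    for g in genes:
        if g.chrom != tss.chrom or g.strand != tss.strand:
            continue
        if g.start <= tss.position < g.end:
            d = 0
        else:
            d = signed_distance(g.five_prime, tss.position, tss.strand)
            if d <= 0:  # gene not strictly downstream
                continue
        key = (d, g.gene_id)
        if best_key is None or key < best_key:
            best, best_key = g, key
    if best is None:
        return None
    if tss.linked_id is not None and tss.linked_id != best.gene_id:
        return None
    return best


def extend_annotation(
    gene: GeneModel, tss: TssRecord, neighbours: Iterable[GeneModel] = ()
) -> GeneModel:
    """Extend the gene span upstream to include the TSS so that reads from the
    TSS overlap the annotation.  Raises :class:`AmbiguityError` if the
    extension would overlap a same-strand neighbour."""
    if gene.start <= tss.position < gene.end:
        return gene
    if gene.strand == "+":
        if tss.position > gene.start:
            raise ValueError("TSS is downstream of the gene span")
        extended = GeneModel(gene.gene_id, gene.chrom, gene.strand,
                             tss.position, gene.end, gene.transcripts)
    else:
        if tss.position < gene.end:
            raise ValueError("TSS is downstream of the gene span")
        extended = GeneModel(gene.gene_id, gene.chrom, gene.strand,
                             gene.start, tss.position + 1, gene.transcripts)
    for other in neighbours:
        if other.gene_id != gene.gene_id and extended.overlaps(other):
            raise AmbiguityError(
                f"extending {gene.gene_id} to TSS {tss.position} overlaps {other.gene_id}"
            )
    return extended


# ---------------------------------------------------------------------------
# association heuristics


@dataclass(frozen=True)
class _TranscriptRef:
    transcript_id: str
    chrom: str
    strand: str
    cds_5prime: int
    first_cds: tuple[int, int] | None


def _transcript_refs(genes: Iterable[GeneModel]) -> list[_TranscriptRef]:
    refs = []
    for g in genes:
        for t in g.transcripts:
            if t.cds_5prime is None:
                continue
            refs.append(_TranscriptRef(t.transcript_id, g.chrom, g.strand,
                                       t.cds_5prime, t.first_cds))
    return refs


def associate(
    genes: Sequence[GeneModel],
    tss_list: Sequence[TssRecord],
    peaks: Sequence[Peak],
    max_downstream_in_cds: int = 50,
) -> list[AssociationRecord]:
    """Resolve (transcript, TSS, peak) triples with heuristics (i)-(iv).

    ``peaks`` are expected to have passed the quality filter and carry set
    summits.  Returns one record per coding transcript (records may have
    empty TSS/peak slots).
    """
    transcripts = _transcript_refs(genes)

    # rule (i): TSS -> nearest downstream transcript (to first-CDS 5' end)
    tss_transcript: list[tuple[TssRecord, _TranscriptRef, int]] = []
    for tss in tss_list:
        best = None
        best_key = None
        for tr in transcripts:
            if tr.chrom != tss.chrom or tr.strand != tss.strand:
                continue
            d = signed_distance(tss.position, tr.cds_5prime, tss.strand)
            if d > 0:
                inside = (
                    tr.first_cds is not None
                    and tr.first_cds[0] <= tss.position < tr.first_cds[1]
                )
                if d > max_downstream_in_cds or not inside:
                    continue
            key = (abs(d), tr.transcript_id)
            if best_key is None or key < best_key:
                best, best_key = (tr, d), key
        if best is not None:
            tss_transcript.append((tss, best[0], best[1]))

    # rule (ii): TSS -> nearest peak by |summit - TSS|
    candidates: list[dict] = []
    for tss, tr, d_tss_cds in tss_transcript:
        best_peak = None
        best_key = None
        for idx, p in enumerate(peaks):
            if p.chrom != tss.chrom or p.strand != tss.strand or p.summit is None:
                continue
            d = signed_distance(p.summit, tss.position, tss.strand)
            key = (abs(d), p.summit, p.start)
            if best_key is None or key < best_key:
                best_peak, best_key = (idx, p, d), key
        entry = {"tss": tss, "transcript": tr, "d_tss_cds": d_tss_cds,
                 "peak_idx": None, "peak": None, "d_tss_peak": None}
        if best_peak is not None:
            entry.update(peak_idx=best_peak[0], peak=best_peak[1], d_tss_peak=best_peak[2])
        candidates.append(entry)

    # rule (iii): a peak claimed by several TSSs keeps the closest TSS
    by_peak: dict[int, list[dict]] = {}
    for entry in candidates:
        if entry["peak_idx"] is not None:
            by_peak.setdefault(entry["peak_idx"], []).append(entry)
    for entries in by_peak.values():
        entries.sort(key=lambda e: (abs(e["d_tss_peak"]), e["tss"].position))
        for loser in entries[1:]:
            loser.update(peak_idx=None, peak=None, d_tss_peak=None)

    # rule (iv): one pair per transcript (smallest |d_tss_peak|, then
    # |d_tss_cds|, then leftmost peak); peakless entries rank last
    by_transcript: dict[str, list[dict]] = {}
    for entry in candidates:
        by_transcript.setdefault(entry["transcript"].transcript_id, []).append(entry)

    records: list[AssociationRecord] = []
    for tr in transcripts:
        entries = by_transcript.get(tr.transcript_id, [])
        if not entries:
            records.append(AssociationRecord(transcript_id=tr.transcript_id))
            continue
        entries.sort(
            key=lambda e: (
                e["peak"] is None,
                abs(e["d_tss_peak"]) if e["d_tss_peak"] is not None else 0,
                abs(e["d_tss_cds"]),
                e["peak"].start if e["peak"] is not None else e["tss"].position,
            )
        )
        chosen = entries[0]
        peak = chosen["peak"]
        d_peak_cds = None
        predicted = None
        if peak is not None:
            d_peak_cds = signed_distance(peak.summit, tr.cds_5prime, tr.strand)
            predicted = d_peak_cds < 0
        records.append(
            AssociationRecord(
                transcript_id=tr.transcript_id,
                tss=chosen["tss"],
                peak=peak,
                d_tss_peak=chosen["d_tss_peak"],
                d_peak_cds=d_peak_cds,
                d_tss_cds=chosen["d_tss_cds"],
                predicted_trans_spliced=predicted,
            )
        )
    return records


def distance_distributions(
    records: Sequence[AssociationRecord],
    cds_window: tuple[int, int] = (-3000, 1000),
    tss_window: tuple[int, int] = (-1000, 1000),
) -> dict[str, np.ndarray]:
    """Signed-distance vectors, full and restricted to display windows."""
    d_peak_cds = np.array(
        [r.d_peak_cds for r in records if r.d_peak_cds is not None], dtype=np.int64
    )
    d_tss_peak = np.array(
        [r.d_tss_peak for r in records if r.d_tss_peak is not None], dtype=np.int64
    )
    return {
        "d_peak_cds": d_peak_cds,
        "d_tss_peak": d_tss_peak,
        "d_peak_cds_windowed": d_peak_cds[
            (d_peak_cds >= cds_window[0]) & (d_peak_cds <= cds_window[1])
        ],
        "d_tss_peak_windowed": d_tss_peak[
            (d_tss_peak >= tss_window[0]) & (d_tss_peak <= tss_window[1])
        ],
    }
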