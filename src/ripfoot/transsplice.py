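"""Spliced-leader trans-splicing classification from acceptor/junction evidence.

A gene is classified trans-spliced when the read depth of its best spliced
leader acceptor site is at least 2.9% of the gene's background expression,
the empirical lower-quartile of genome-wide acceptor:background ratios.
Acceptors must have >= 100 supporting reads and lie any distance upstream or
at most 50 bp downstream of the 5' end of the first CDS.  Background
expression is the median exon-exon junction read depth of the most strongly
expressed junction class (constitutive or major, compared by class median).

A gene with junction background but no qualifying acceptor is classified
*not* trans-spliced; the call is undetermined only when no background can be
estimated.  Concordance between these bona fide calls and the peak-location
predictions is tested with a Pearson 2x2 chi-square (no continuity
correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .nullstats import Chi2Result, pearson_chi2_2x2
from .tss_assoc import AssociationRecord, signed_distance

__all__ = [
    "AcceptorSite",
    "JunctionRecord",
    "AcceptorCall",
    "select_acceptor",
    "background_depth",
    "classify_gene",
    "ratio_quantiles",
    "concordance_test",
    "ConcordanceResult",
]

RATIO_THRESHOLD = 0.029
MIN_ACCEPTOR_DEPTH = 100
MAX_DOWNSTREAM = 50


@dataclass(frozen=True)
class AcceptorSite:
    gene_id: str
    chrom: str
    strand: str
    position: int
    read_depth: int

    def __post_init__(self):
        if self.read_depth < 0:
            raise ValueError("acceptor read depth must be >= 0")


@dataclass(frozen=True)
class JunctionRecord:
    gene_id: str
    junction_class: str  # constitutive | major | minor
    read_depth: int

    def __post_init__(self):
        if self.read_depth < 0:
            raise ValueError("junction read depth must be >= 0")
        if self.junction_class not in ("constitutive", "major", "minor"):
            raise ValueError(f"unknown junction class {self.junction_class!r}")


@dataclass(frozen=True)
class AcceptorCall:
    gene_id: str
    acceptor: AcceptorSite | None
    background: float | None
    ratio: float | None
    trans_spliced: bool | None  # None = undetermined


def select_acceptor(
    strand: str,
    cds_5prime: int,
    sites: Sequence[AcceptorSite],
    min_depth: int = MIN_ACCEPTOR_DEPTH,
    max_downstream: int = MAX_DOWNSTREAM,
) -> AcceptorSite | None:
    """The single highest-depth acceptor located upstream of, or at most
    ``max_downstream`` bp downstream of, the CDS 5' end; ``None`` if the best
    eligible site has fewer than ``min_depth`` reads."""
    eligible = [
        s for s in sites
        if signed_distance(s.position, cds_5prime, strand) <= max_downstream
    ]
    if not eligible:
        return None
    best = min(eligible, key=lambda s: (-s.read_depth, s.position))
    return best if best.read_depth >= min_depth else None


def background_depth(junctions: Sequence[JunctionRecord]) -> float | None:
    """Median junction depth of the most strongly expressed junction class
    (constitutive vs major, compared by class median; minor is ignored)."""
    by_class: dict[str, list[int]] = {}
    for j in junctions:
        if j.junction_class in ("constitutive", "major"):
            by_class.setdefault(j.junction_class, []).append(j.read_depth)
    if not by_class:
        return None
    medians = {c: float(np.median(d)) for c, d in by_class.items()}
    # tie -> constitutive
    best = max(medians, key=lambda c: (medians[c], c == "constitutive"))
    return medians[best]


def classify_gene(
    gene_id: str,
    acceptor: AcceptorSite | None,
    background: float | None,
    ratio_threshold: float = RATIO_THRESHOLD,
) -> AcceptorCall:
    """Classify one gene.  Ratio >= threshold (inclusive) => trans-spliced;
    background present but no qualifying acceptor => not trans-spliced;
    missing or zero background => undetermined."""
    if background is None or background <= 0:
        if background is not None and background <= 0:
            warnings.warn(f"gene {gene_id}: zero background depth, call undetermined")
        return AcceptorCall(gene_id, acceptor, background, None, None)
    if acceptor is None:
        return AcceptorCall(gene_id, None, background, None, False)
    ratio = acceptor.read_depth / background
    return AcceptorCall(gene_id, acceptor, background, ratio, ratio >= ratio_threshold)


def ratio_quantiles(calls: Iterable[AcceptorCall]) -> tuple[float, float]:
    """(median, lower quartile) of defined acceptor:background ratios
    (linear-interpolation quantiles)."""
    ratios = [c.ratio for c in calls if c.ratio is not None]
    if not ratios:
        raise ValueError("no calls with a defined ratio")
    return float(np.quantile(ratios, 0.5)), float(np.quantile(ratios, 0.25))


@dataclass(frozen=True)
class ConcordanceResult:
    """2x2 concordance of peak-location predictions vs bona fide calls.

    ``table[i][j]``: rows = predicted trans-spliced (True, False), columns =
    bona fide trans-spliced (True, False).  ``proportions`` are the row-wise
    fractions of bona fide trans-spliced genes.
    """

    table: np.ndarray
    proportions: tuple[float, float]
    chi2: Chi2Result | None
    n: int


def concordance_test(
    records: Sequence[AssociationRecord],
    calls: Mapping[str, AcceptorCall],
    transcript_to_gene: Mapping[str, str],
) -> ConcordanceResult:
    """Cross-tabulate predicted (peak upstream of CDS) against bona fide
    trans-splicing status over genes with both a prediction and a determined
    status.  The chi-square test is skipped when any marginal is zero."""
    table = np.zeros((2, 2), dtype=np.int64)
    for r in records:
        if r.predicted_trans_spliced is None:
            continue
        gene_id = transcript_to_gene.get(r.transcript_id)
        if gene_id is None or gene_id not in calls:
            continue
        call = calls[gene_id]
        if call.trans_spliced is None:
            continue
        i = 0 if r.predicted_trans_spliced else 1
        j = 0 if call.trans_spliced else 1
        table[i, j] += 1

    def row_prop(i: int) -> float:
        total = table[i].sum()
        return float(table[i, 0] / total) if total > 0 else float("nan")

    chi2 = None
    if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
        chi2 = pearson_chi2_2x2(table)
    return ConcordanceResult(
        table=table,
        proportions=(row_prop(0), row_prop(1)),
        chi2=chi2,
        n=int(table.sum()),
    )
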