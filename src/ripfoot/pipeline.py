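"""End-to-end orchestration: peak calling -> refinement -> TSS association ->
random-peak null check -> trans-splicing classification -> quantification.

Each stage is a thin composition of the per-module operations; the result
object keeps every intermediate product so tests and reports can interrogate
any stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import peakcall, peakrefine, ripquant, transsplice
from .io_formats import (
    CoverageTrack,
    GeneModel,
    GenomeLayout,
    Peak,
    ReadAlignment,
    TssRecord,
    STRANDS,
)
from .nullstats import NullComparison, null_comparison
from .peakcall import CallerParams
from .tss_assoc import (
    AssociationRecord,
    associate,
    curate_tss,
    extend_annotation,
    match_tss_to_gene,
)
from .transsplice import AcceptorCall, AcceptorSite, JunctionRecord, ConcordanceResult

logger = logging.getLogger("ripfoot")

__all__ = ["PipelineResult", "refine_peaks", "curate_and_match_tss", "classify_genes",
           "run_pipeline"]


@dataclass
class PipelineResult:
    peaks_called: list[Peak]
    peaks_refined: list[Peak]
    records: list[AssociationRecord]
    curated_tss: list[TssRecord]
    extended_genes: list[GeneModel]
    calls: dict[str, AcceptorCall]
    concordance: ConcordanceResult | None
    null: NullComparison | None
    counts: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    transcript_to_gene: dict[str, str]

    def report(self) -> dict:
        """Machine-readable per-stage summary."""
        n_assoc = sum(1 for r in self.records if r.peak is not None)
        predicted = [r.predicted_trans_spliced for r in self.records
                     if r.predicted_trans_spliced is not None]
        rep = {
            "peaks_called": len(self.peaks_called),
            "peaks_after_filter": len(self.peaks_refined),
            "transcripts": len(self.records),
            "transcripts_with_peak": n_assoc,
            "predicted_trans_spliced": int(sum(predicted)),
            "predicted_upstream_fraction": (
                float(np.mean(predicted)) if predicted else float("nan")
            ),
            "genes_classified": sum(
                1 for c in self.calls.values() if c.trans_spliced is not None
            ),
        }
        if self.concordance is not None:
            rep["concordance"] = {
                "table": self.concordance.table.tolist(),
                "proportions": list(self.concordance.proportions),
                "chi2": (
                    None if self.concordance.chi2 is None
                    else {"statistic": self.concordance.chi2.statistic,
                          "df": self.concordance.chi2.df,
                          "p_value": self.concordance.chi2.p_value}
                ),
                "n": self.concordance.n,
            }
        if self.null is not None:
            rep["null"] = {
                "metric": self.null.metric,
                "median_D": self.null.median_D,
                "max_p": self.null.max_p,
                "n_reps": len(self.null.replicates),
            }
        if self.enrichment is not None:
            rep["genes_enriched"] = int(self.enrichment["enriched"].sum())
        return rep


def refine_peaks(
    peaks: Sequence[Peak],
    ip_coverage: Mapping[str, CoverageTrack],
    min_reads: float = 20,
    min_enrichment: float = 5.0,
    min_width: int = 30,
    max_width: int = 90,
) -> list[Peak]:
    """Re-anchor summits on the raw (unextended) IP coverage, trim shoulders
    at 50% of summit coverage, then apply the quality filter."""
    refined = []
    for p in peaks:
        track = ip_coverage[p.strand]
        p2 = peakrefine.resummit(p, track)
        if p2.summit_coverage <= 0:
            continue
        refined.append(peakrefine.trim_shoulders(p2, track))
    return peakrefine.filter_peaks(
        refined, min_reads=min_reads, min_enrichment=min_enrichment,
        min_width=min_width, max_width=max_width,
    )


def curate_and_match_tss(
    tss_records: Sequence[TssRecord], genes: Sequence[GeneModel]
) -> tuple[list[TssRecord], list[GeneModel]]:
    """Curate one TSS per linked group, keep TSSs whose nearest
    downstream/overlapping gene matches their link, and extend the matched
    gene annotations upstream to the TSS."""
    groups: dict[str, list[TssRecord]] = {}
    for r in tss_records:
        groups.setdefault(r.linked_id or f"@{r.chrom}:{r.position}:{r.strand}", []).append(r)
    five_prime = {}
    for g in genes:
        for t in g.transcripts:
            five_prime.setdefault(g.gene_id, t.five_prime(g.strand))
    curated = curate_tss(groups, five_prime)

    kept: list[TssRecord] = []
    extended: dict[str, GeneModel] = {g.gene_id: g for g in genes}
    for tss in curated.values():
        gene = match_tss_to_gene(tss, genes)
        if gene is None:
            continue
        kept.append(tss)
        extended[gene.gene_id] = extend_annotation(
            extended[gene.gene_id], tss, neighbours=genes
        )
    return kept, list(extended.values())


def classify_genes(
    genes: Sequence[GeneModel],
    acceptor_sites: Sequence[AcceptorSite],
    junctions: Sequence[JunctionRecord],
    ratio_threshold: float = transsplice.RATIO_THRESHOLD,
    min_depth: int = transsplice.MIN_ACCEPTOR_DEPTH,
    max_downstream: int = transsplice.MAX_DOWNSTREAM,
) -> dict[str, AcceptorCall]:
    """Acceptor-based trans-splicing call for every coding gene."""
    sites_by_gene: dict[str, list[AcceptorSite]] = {}
    for s in acceptor_sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)
    junc_by_gene: dict[str, list[JunctionRecord]] = {}
    for j in junctions:
        junc_by_gene.setdefault(j.gene_id, []).append(j)

    calls: dict[str, AcceptorCall] = {}
    for g in genes:
        coding = [t for t in g.transcripts if t.cds_5prime is not None]
        if not coding:
            continue
        cds5 = coding[0].cds_5prime
        acceptor = transsplice.select_acceptor(
            g.strand, cds5, sites_by_gene.get(g.gene_id, ()),
            min_depth=min_depth, max_downstream=max_downstream,
        )
        background = transsplice.background_depth(junc_by_gene.get(g.gene_id, ()))
        calls[g.gene_id] = transsplice.classify_gene(
            g.gene_id, acceptor, background, ratio_threshold=ratio_threshold
        )
    return calls


def run_pipeline(
    genome: GenomeLayout,
    genes: Sequence[GeneModel],
    tss_records: Sequence[TssRecord],
    ip_alignments: Mapping[str, Sequence[ReadAlignment]],
    control_alignments: Mapping[str, Sequence[ReadAlignment]],
    acceptor_sites: Sequence[AcceptorSite] = (),
    junctions: Sequence[JunctionRecord] = (),
    params: CallerParams | None = None,
    null_reps: int = 10,
    seed: int = 0,
    quantify: bool = True,
) -> PipelineResult:
    params = params or CallerParams()
    t0 = time.time()

    pooled_ip = [a for rep in sorted(ip_alignments) for a in ip_alignments[rep]]
    pooled_ctrl = [a for rep in sorted(control_alignments) for a in control_alignments[rep]]
    peaks = peakcall.call_peaks(pooled_ip, pooled_ctrl, genome, params)
    logger.info("callpeaks: %d peaks (%.1fs)", len(peaks), time.time() - t0)

    ip_cov = {s: peakcall.raw_coverage(pooled_ip, genome, s) for s in STRANDS}
    refined = refine_peaks(peaks, ip_cov)
    logger.info("refine: %d peaks survive the quality filter", len(refined))

    curated, extended_genes = curate_and_match_tss(tss_records, genes)
    records = associate(extended_genes, curated, refined)
    logger.info("associate: %d transcripts, %d with peaks",
                len(records), sum(1 for r in records if r.peak is not None))

    null = None
    if null_reps > 0 and any(r.peak is not None for r in records):
        null = null_comparison(records, extended_genes, curated, genome,
                               n_reps=null_reps, seed=seed)
        logger.info("nullcheck: median D=%.3f max p=%.3g", null.median_D, null.max_p)

    transcript_to_gene = {
        t.transcript_id: g.gene_id for g in genes for t in g.transcripts
    }
    calls: dict[str, AcceptorCall] = {}
    concordance = None
    if acceptor_sites or junctions:
        calls = classify_genes(extended_genes, acceptor_sites, junctions)
        concordance = transsplice.concordance_test(records, calls, transcript_to_gene)
        logger.info("classify: %d genes determined",
                    sum(1 for c in calls.values() if c.trans_spliced is not None))

    counts = None
    enrichment = None
    if quantify:
        libs = {f"ip_{rep}": reads for rep, reads in ip_alignments.items()}
        libs.update({f"control_{rep}": reads for rep, reads in control_alignments.items()})
        counts = pd.DataFrame(
            {name: ripquant.count_reads(reads, extended_genes) for name, reads in libs.items()}
        )
        ip_cols = [c for c in counts.columns if c.startswith("ip_")]
        ctrl_cols = [c for c in counts.columns if c.startswith("control_")]
        if len(ip_cols) + len(ctrl_cols) >= 2:
            enrichment = ripquant.enrichment_table(counts, ip_cols, ctrl_cols)
        logger.info("quantify: %d genes counted over %d libraries", *counts.shape)

    return PipelineResult(
        peaks_called=peaks,
        peaks_refined=refined,
        records=records,
        curated_tss=curated,
        extended_genes=extended_genes,
        calls=calls,
        concordance=concordance,
        null=null,
        counts=counts,
        enrichment=enrichment,
        transcript_to_gene=transcript_to_gene,
    )
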