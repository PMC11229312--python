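"""Ground-truth-labelled synthetic RIP-Seq datasets.

The generator emulates the statistical structure the analysis assumes for a
nematode-style genome: non-overlapping gene models on both strands, ~85% of
genes carrying an outron with a spliced-leader acceptor site just upstream of
the first CDS, stranded IP read coverage forming ~60 nt protected-fragment
footprints anchored at each transcription start site on top of uniform
background, uniform control coverage, a small stratum of short "SmY-like"
non-coding genes with very high enrichment, multimapping reads, and per-gene
acceptor/junction depth tables.

IP alignments are given the protected-fragment length (drawn around the
configured footprint width) rather than the sequencer read length: reads
longer than the protected insert align only over the insert, and it is the
insert pileup that shoulder trimming operates on.

One global seed drives a deterministic per-component seed sequence, so the
same config always yields byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    GeneModel,
    GenomeLayout,
    ReadAlignment,
    Transcript,
    TssRecord,
    write_alignments_bed,
    write_genome_tsv,
    write_gff3,
    write_tss_bed,
)
from .transsplice import AcceptorCall, AcceptorSite, JunctionRecord
from .tss_assoc import AssociationRecord

__all__ = ["SynthConfig", "Bundle", "generate", "truth_report"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic dataset (defaults are the
    conditions the pipeline is validated under)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 650_000
    n_genes: int = 500
    frac_trans_spliced: float = 0.85

    # gene geometry (bp)
    gene_min_len: int = 800
    gene_max_len: int = 1500
    gap_min: int = 500
    gap_max: int = 800
    outron_mean: float = 200.0
    outron_sd: float = 50.0
    outron_min: int = 50
    outron_max: int = 400
    sl_utr: int = 8          # acceptor-to-CDS offset on trans-spliced genes
    utr5_max: int = 30       # 5' UTR of non-trans-spliced genes

    # footprint / reads
    footprint_mean: float = 60.0
    footprint_sd: float = 5.0
    read_jitter_sd: float = 8.0   # dispersion of capped 5' ends
    tss_jitter_sd: float = 5.0    # error of the annotated TSS position
    background_rate: float = 0.01  # background reads / bp / strand / library
    ip_enrichment: float = 100.0   # fold elevation of read starts in footprints
    n_replicates: int = 2
    frac_multimappers: float = 0.05
    multimapper_hits: int = 2

    # SmY-like contaminant stratum
    n_smy_like: int = 5
    smy_len_min: int = 70
    smy_len_max: int = 90
    smy_reads: int = 1000  # per gene per replicate

    # TSS catalogue
    frac_extra_tss: float = 0.3
    tss_depth_min: int = 50
    tss_depth_max: int = 500

    # acceptor / junction tables
    junction_log_mean: float = float(np.log(5000.0))
    junction_log_sd: float = 0.3
    acceptor_ratio_log_mean: float = float(np.log(0.113))
    acceptor_ratio_log_sd: float = 0.5
    spurious_acceptor_frac: float = 0.3
    spurious_ratio_log_mean: float = float(np.log(0.005))
    spurious_ratio_log_sd: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.frac_trans_spliced <= 1.0:
            raise ValueError("frac_trans_spliced must be in [0, 1]")
        for name in ("chrom_length", "n_genes", "n_chroms", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.footprint_mean <= 0 or self.background_rate <= 0 or self.ip_enrichment <= 0:
            raise ValueError("rates and widths must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


@dataclass
class Bundle:
    """In-memory synthetic dataset plus writers for the file bundle."""

    config: SynthConfig
    genome: GenomeLayout
    genes: list[GeneModel]
    tss_records: list[TssRecord]
    ip_alignments: dict[str, list[ReadAlignment]]       # replicate -> reads
    control_alignments: dict[str, list[ReadAlignment]]
    acceptor_sites: list[AcceptorSite]
    junctions: list[JunctionRecord]
    lfq: pd.DataFrame
    lfq_truth: pd.Series
    truth: pd.DataFrame

    @property
    def pooled_ip(self) -> list[ReadAlignment]:
        return [a for rep in sorted(self.ip_alignments) for a in self.ip_alignments[rep]]

    @property
    def pooled_control(self) -> list[ReadAlignment]:
        return [a for rep in sorted(self.control_alignments) for a in self.control_alignments[rep]]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome_tsv(self.genome, outdir / "genome.tsv")
        write_gff3(self.genes, outdir / "genes.gff3")
        write_tss_bed(self.tss_records, outdir / "tss.bed")
        for rep, reads in self.ip_alignments.items():
            write_alignments_bed(reads, outdir / f"ip_rep{rep}.bed")
        for rep, reads in self.control_alignments.items():
            write_alignments_bed(reads, outdir / f"control_rep{rep}.bed")
        pd.DataFrame(
            [
                {"gene_id": s.gene_id, "chrom": s.chrom, "strand": s.strand,
                 "position": s.position, "depth": s.read_depth}
                for s in self.acceptor_sites
            ],
            columns=["gene_id", "chrom", "strand", "position", "depth"],
        ).to_csv(outdir / "acceptors.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"gene_id": j.gene_id, "class": j.junction_class, "depth": j.read_depth}
                for j in self.junctions
            ],
            columns=["gene_id", "class", "depth"],
        ).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
        self.lfq.to_csv(outdir / "lfq.tsv", sep="\t")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _gene_layout(cfg: SynthConfig, rng: np.random.Generator):
    """Pack gene slots sequentially across chromosomes on alternating random
    strands; raises when the genome is too small."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    slots = []
    n_total = cfg.n_genes + cfg.n_smy_like
    smy_flags = np.zeros(n_total, dtype=bool)
    if cfg.n_smy_like:
        smy_idx = rng.choice(n_total, size=cfg.n_smy_like, replace=False)
        smy_flags[smy_idx] = True
    chrom_i = 0
    cursor = int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
    for i in range(n_total):
        if smy_flags[i]:
            body_len = int(rng.integers(cfg.smy_len_min, cfg.smy_len_max + 1))
            lead = 0
        else:
            body_len = int(rng.integers(cfg.gene_min_len, cfg.gene_max_len + 1))
            lead = cfg.outron_max + 50  # room for the outron/TSS upstream
        strand = "+" if rng.random() < 0.5 else "-"
        slot_len = lead + body_len
        while cursor + slot_len + cfg.gap_max >= cfg.chrom_length:
            chrom_i += 1
            if chrom_i >= len(chroms):
                raise ValueError(
                    "synthetic genes do not fit the genome; increase chrom_length or n_chroms"
                )
            cursor = int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
        slots.append(
            {
                "chrom": chroms[chrom_i],
                "strand": strand,
                "slot_start": cursor,
                "slot_end": cursor + slot_len,
                "smy": bool(smy_flags[i]),
            }
        )
        cursor += slot_len + int(rng.integers(cfg.gap_min, cfg.gap_max + 1))
    genome = GenomeLayout({c: cfg.chrom_length for c in chroms})
    return genome, slots


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    x = rng.normal(mean, sd)
    return float(min(max(x, lo), hi))


def _footprint_reads(rng, cfg, chrom, strand, anchor, n, chrom_len, replicate, library="ip"):
    """Protected-fragment alignments anchored at the 5' position ``anchor``."""
    reads = []
    for _ in range(n):
        five = anchor + int(round(rng.normal(0.0, cfg.read_jitter_sd)))
        length = max(20, int(round(rng.normal(cfg.footprint_mean, cfg.footprint_sd))))
        if strand == "+":
            s, e = five, five + length
        else:
            s, e = five - length + 1, five + 1
        s, e = max(0, s), min(chrom_len, e)
        if e - s >= 20:
            reads.append(ReadAlignment(chrom, strand, s, e, 1, library, replicate))
    return reads


def _background_reads(rng, cfg, genome, replicate, library):
    reads = []
    for chrom, length in genome.items():
        for strand in ("+", "-"):
            n = rng.poisson(cfg.background_rate * length)
            starts = rng.integers(0, length, size=n)
            lens = np.maximum(
                20, np.round(rng.normal(cfg.footprint_mean, cfg.footprint_sd, size=n))
            ).astype(int)
            for s, l in zip(starts, lens):
                e = min(length, int(s) + int(l))
                if e - s >= 20:
                    reads.append(ReadAlignment(chrom, strand, int(s), e, 1, library, replicate))
    return reads


def _apply_multimappers(rng, cfg, reads, genome):
    """A fraction of reads becomes multimappers: the original location plus
    extra copies at uniform random positions, all recording the total hits."""
    if cfg.frac_multimappers <= 0 or cfg.multimapper_hits < 2:
        return reads
    chroms = list(genome.chroms)
    out = []
    for r in reads:
        if rng.random() < cfg.frac_multimappers:
            k = cfg.multimapper_hits
            out.append(dataclasses.replace(r, n_hits=k))
            length = r.end - r.start
            for _ in range(k - 1):
                c = chroms[rng.integers(0, len(chroms))]
                clen = genome[c]
                s = int(rng.integers(0, max(1, clen - length)))
                strand = "+" if rng.random() < 0.5 else "-"
                out.append(
                    ReadAlignment(c, strand, s, s + length, k, r.library, r.replicate)
                )
        else:
            out.append(r)
    return out


def _synthetic_lfq(rng) -> tuple[pd.DataFrame, pd.Series]:
    """Small LFQ table with known bait-relative molar ratios (synthetic)."""
    proteins = {
        # id: (MW kDa, true molar ratio vs bait)
        "BAIT": (50.0, 1.0),
        "PARTNER-EQ": (25.0, 1.0),
        "PARTNER-HALF": (100.0, 0.5),
        "ASSOC-LOW": (30.0, 0.02),
        "TRACE": (80.0, 0.0005),
    }
    bait_lfq = 1e9
    rows = {}
    for pid, (mw, ratio) in proteins.items():
        intensities = []
        for _ in range(3):
            noise = 1.0 if pid == "BAIT" else float(np.exp(rng.normal(0.0, 0.05)))
            intensities.append(ratio * bait_lfq * (mw / 50.0) * noise)
        rows[pid] = [mw] + intensities
    lfq = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mw_kda", "rep1", "rep2", "rep3"]
    )
    lfq.index.name = "protein_id"
    truth = pd.Series({pid: ratio for pid, (_, ratio) in proteins.items()}, name="true_ratio")
    return lfq, truth


def generate(config: SynthConfig | None = None) -> Bundle:
    cfg = config or SynthConfig()
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_layout = np.random.default_rng(seeds[0])
    rng_reads = np.random.default_rng(seeds[1])
    rng_tss = np.random.default_rng(seeds[2])
    rng_tables = np.random.default_rng(seeds[3])
    rng_multi = np.random.default_rng(seeds[4])
    rng_lfq = np.random.default_rng(seeds[5])

    genome, slots = _gene_layout(cfg, rng_layout)

    genes: list[GeneModel] = []
    tss_records: list[TssRecord] = []
    acceptors: list[AcceptorSite] = []
    junctions: list[JunctionRecord] = []
    truth_rows = []
    footprints = []  # (chrom, strand, anchor 5' pos, n reads per replicate)

    gene_no = 0
    smy_no = 0
    for slot in slots:
        chrom, strand = slot["chrom"], slot["strand"]
        if slot["smy"]:
            smy_no += 1
            gid = f"smy{smy_no}"
            start, end = slot["slot_start"], slot["slot_end"]
            tx = Transcript(f"{gid}.1", start, end, exons=((start, end),))
            genes.append(GeneModel(gid, chrom, strand, start, end, (tx,)))
            anchor = start if strand == "+" else end - 1
            footprints.append((chrom, strand, anchor, "smy", gid, start, end))
            truth_rows.append(
                {"gene_id": gid, "transcript_id": f"{gid}.1", "chrom": chrom,
                 "strand": strand, "true_tss": anchor, "cds_5prime": -1,
                 "acceptor_pos": -1, "trans_spliced": False, "smy_like": True}
            )
            continue

        gene_no += 1
        gid = f"g{gene_no:04d}"
        tid = f"{gid}.1"
        trans_spliced = bool(rng_layout.random() < cfg.frac_trans_spliced)
        body_len = slot["slot_end"] - slot["slot_start"] - (cfg.outron_max + 50)

        # orientation-independent geometry, then mirror for minus strand
        if trans_spliced:
            outron = int(round(_truncated_normal(
                rng_layout, cfg.outron_mean, cfg.outron_sd, cfg.outron_min, cfg.outron_max)))
            utr_to_cds = cfg.sl_utr
        else:
            outron = 0
            utr_to_cds = int(rng_layout.integers(0, cfg.utr5_max + 1))

        if strand == "+":
            tss = slot["slot_start"] + (cfg.outron_max + 50) - outron
            mrna_start = slot["slot_start"] + (cfg.outron_max + 50)  # acceptor / cap
            mrna_end = mrna_start + body_len
            if not trans_spliced:
                mrna_start = tss  # cap is the mRNA 5' end
            cds5 = mrna_start + utr_to_cds
            exon1_end = min(mrna_end, cds5 + 200)
            exons = ((mrna_start, exon1_end),)
            if exon1_end + 100 < mrna_end:
                exons = ((mrna_start, exon1_end), (exon1_end + 60, mrna_end))
            first_cds = (cds5, exon1_end)
            acceptor_pos = mrna_start - 1 if trans_spliced else -1
        else:
            slot_end = slot["slot_end"]
            tss = slot_end - 1 - (cfg.outron_max + 50) + outron
            mrna_end = slot_end - (cfg.outron_max + 50)  # half-open 3' of cap
            mrna_start = mrna_end - body_len
            if not trans_spliced:
                mrna_end = tss + 1
            cds5 = mrna_end - 1 - utr_to_cds
            exon1_start = max(mrna_start, cds5 - 200 + 1)
            exons = ((exon1_start, mrna_end),)
            if exon1_start - 100 > mrna_start:
                exons = ((mrna_start, exon1_start - 60), (exon1_start, mrna_end))
            first_cds = (exon1_start, cds5 + 1)
            acceptor_pos = mrna_end if trans_spliced else -1

        exons = tuple(sorted(exons))
        g_start, g_end = exons[0][0], exons[-1][1]
        tx = Transcript(tid, g_start, g_end, exons=exons, cds_5prime=cds5,
                        first_cds=first_cds)
        genes.append(GeneModel(gid, chrom, strand, g_start, g_end, (tx,)))
        footprints.append((chrom, strand, tss, "gene", gid, None, None))

        # annotated TSS record(s), jittered, linked to the gene id
        obs_pos = tss + int(round(rng_tss.normal(0.0, cfg.tss_jitter_sd)))
        obs_pos = min(max(obs_pos, 0), cfg.chrom_length - 1)
        depth = int(rng_tss.integers(cfg.tss_depth_min, cfg.tss_depth_max + 1))
        tss_records.append(TssRecord(chrom, strand, obs_pos, depth, gid, "synthetic"))
        if rng_tss.random() < cfg.frac_extra_tss:
            off = int(rng_tss.integers(20, 61)) * (1 if rng_tss.random() < 0.5 else -1)
            pos2 = min(max(obs_pos + off, 0), cfg.chrom_length - 1)
            tss_records.append(
                TssRecord(chrom, strand, pos2, max(1, depth // 2), gid, "synthetic2")
            )

        # junction / acceptor depth tables
        j_depth = float(np.exp(rng_tables.normal(cfg.junction_log_mean, cfg.junction_log_sd)))
        for _ in range(3):
            junctions.append(JunctionRecord(
                gid, "constitutive", int(round(j_depth * rng_tables.uniform(0.8, 1.2)))))
        for _ in range(2):
            junctions.append(JunctionRecord(
                gid, "major", int(round(0.3 * j_depth * rng_tables.uniform(0.8, 1.2)))))

        if trans_spliced:
            ratio = float(np.exp(rng_tables.normal(
                cfg.acceptor_ratio_log_mean, cfg.acceptor_ratio_log_sd)))
            acceptors.append(AcceptorSite(gid, chrom, strand, acceptor_pos,
                                          int(round(ratio * j_depth))))
        elif rng_tables.random() < cfg.spurious_acceptor_frac:
            ratio = float(np.exp(rng_tables.normal(
                cfg.spurious_ratio_log_mean, cfg.spurious_ratio_log_sd)))
            spur_pos = cds5 - 5 if strand == "+" else cds5 + 5
            acceptors.append(AcceptorSite(gid, chrom, strand, spur_pos,
                                          int(round(ratio * j_depth))))

        truth_rows.append(
            {"gene_id": gid, "transcript_id": tid, "chrom": chrom, "strand": strand,
             "true_tss": tss, "cds_5prime": cds5, "acceptor_pos": acceptor_pos,
             "trans_spliced": trans_spliced, "smy_like": False}
        )

    # --- reads ---------------------------------------------------------
    footprint_lambda = cfg.ip_enrichment * cfg.background_rate * cfg.footprint_mean
    ip_alignments: dict[str, list[ReadAlignment]] = {}
    control_alignments: dict[str, list[ReadAlignment]] = {}
    for rep_i in range(1, cfg.n_replicates + 1):
        rep = str(rep_i)
        reads: list[ReadAlignment] = []
        for chrom, strand, anchor, kind, gid, s, e in footprints:
            clen = genome[chrom]
            if kind == "smy":
                n = rng_reads.poisson(cfg.smy_reads)
                for _ in range(n):
                    length = int(rng_reads.integers(40, max(41, e - s + 1)))
                    start = int(rng_reads.integers(s, max(s + 1, e - length + 1)))
                    reads.append(ReadAlignment(
                        chrom, strand, start, min(clen, start + length), 1, "ip", rep))
            else:
                n = rng_reads.poisson(footprint_lambda)
                reads.extend(_footprint_reads(
                    rng_reads, cfg, chrom, strand, anchor, n, clen, rep))
        reads.extend(_background_reads(rng_reads, cfg, genome, rep, "ip"))
        ip_alignments[rep] = _apply_multimappers(rng_multi, cfg, reads, genome)
        control_alignments[rep] = _apply_multimappers(
            rng_multi, cfg, _background_reads(rng_reads, cfg, genome, rep, "control"), genome
        )

    lfq, lfq_truth = _synthetic_lfq(rng_lfq)
    truth = pd.DataFrame(truth_rows)
    return Bundle(
        config=cfg,
        genome=genome,
        genes=genes,
        tss_records=tss_records,
        ip_alignments=ip_alignments,
        control_alignments=control_alignments,
        acceptor_sites=acceptors,
        junctions=junctions,
        lfq=lfq,
        lfq_truth=lfq_truth,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# truth report


def truth_report(
    records: Sequence[AssociationRecord],
    calls: Mapping[str, AcceptorCall],
    truth: pd.DataFrame,
) -> dict:
    """Confusion counts, sensitivity/specificity and summit-to-TSS distance
    quantiles of a pipeline run against the generator's truth table."""
    tx_truth = truth.set_index("transcript_id")
    gene_truth = truth.set_index("gene_id")

    for gid in calls:
        if gid not in gene_truth.index:
            raise ValueError(f"gene {gid!r} in calls but not in truth table")

    def confusion(pairs):
        tp = sum(1 for pred, lab in pairs if pred and lab)
        fn = sum(1 for pred, lab in pairs if not pred and lab)
        tn = sum(1 for pred, lab in pairs if not pred and not lab)
        fp = sum(1 for pred, lab in pairs if pred and not lab)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
                "sensitivity": sens, "specificity": spec}

    pred_pairs = []
    dist_errors = []
    for r in records:
        if r.transcript_id not in tx_truth.index:
            raise ValueError(f"transcript {r.transcript_id!r} not in truth table")
        row = tx_truth.loc[r.transcript_id]
        if bool(row["smy_like"]):
            continue
        if r.predicted_trans_spliced is not None:
            pred_pairs.append((bool(r.predicted_trans_spliced), bool(row["trans_spliced"])))
        if r.peak is not None and r.peak.summit is not None:
            dist_errors.append(abs(r.peak.summit - int(row["true_tss"])))

    call_pairs = []
    for gid, call in calls.items():
        if call.trans_spliced is None:
            continue
        row = gene_truth.loc[gid]
        if bool(row["smy_like"]):
            continue
        call_pairs.append((bool(call.trans_spliced), bool(row["trans_spliced"])))

    dist = np.array(dist_errors, dtype=float)
    quantiles = (
        {q: float(np.quantile(dist, q)) for q in (0.5, 0.9, 0.95)} if len(dist) else {}
    )
    return {
        "prediction": confusion(pred_pairs),
        "classification": confusion(call_pairs),
        "n_predicted": len(pred_pairs),
        "n_classified": len(call_pairs),
        "summit_tss_abs_quantiles": quantiles,
        "summit_within_1kb": float(np.mean(dist <= 1000)) if len(dist) else float("nan"),
    }
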