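import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ripfoot.io_formats import GeneModel, GenomeLayout, Peak, Transcript, TssRecord
from ripfoot.tss_assoc import (
    AmbiguityError,
    associate,
    curate_tss,
    distance_distributions,
    extend_annotation,
    match_tss_to_gene,
    signed_distance,
)


class TestSignedDistance:
    @pytest.mark.parametrize(
        "a,b,strand,expected",
        [(100, 150, "+", -50), (100, 150, "-", 50), (7, 7, "+", 0), (7, 7, "-", 0)],
    )
    def test_convention(self, a, b, strand, expected):
        assert signed_distance(a, b, strand) == expected

    @given(a=st.integers(0, 10**6), b=st.integers(0, 10**6))
    def test_strand_flip_negates(self, a, b):
        assert signed_distance(a, b, "+") == -signed_distance(a, b, "-")
        assert signed_distance(a, b, "+") == -signed_distance(b, a, "+")


class TestCurateTss:
    def test_highest_depth_wins(self):
        recs = [TssRecord("c", "+", 100, 50, "t1"), TssRecord("c", "+", 300, 30, "t1")]
        out = curate_tss({"t1": recs}, {"t1": 400})
        assert out["t1"].read_depth == 50

    def test_depth_tie_broken_by_distance_to_five_prime(self):
        recs = [TssRecord("c", "+", 200, 50, "t1"), TssRecord("c", "+", 300, 50, "t1")]
        out = curate_tss({"t1": recs}, {"t1": 400})  # |200-400|=200 vs |300-400|=100
        assert out["t1"].position == 300

    def test_single_record_is_itself(self):
        rec = TssRecord("c", "+", 5, 1, "t1")
        assert curate_tss({"t1": [rec]}, {"t1": 100})["t1"] is rec


class TestMatchTssToGene:
    def test_overlapping_gene_wins(self, two_gene_models):
        tss = TssRecord("chr1", "+", 1500, 10)
        assert match_tss_to_gene(tss, two_gene_models).gene_id == "gA"

    def test_nearest_downstream_on_each_strand(self, two_gene_models):
        assert match_tss_to_gene(TssRecord("chr1", "+", 700, 10), two_gene_models).gene_id == "gA"
        assert match_tss_to_gene(TssRecord("chr1", "-", 5300, 10), two_gene_models).gene_id == "gB"
        # upstream on the minus strand means larger coordinates only
        assert match_tss_to_gene(TssRecord("chr1", "-", 100, 10), two_gene_models) is None

    def test_nearest_of_two_downstream_genes(self):
        a = GeneModel("A", "c", "+", 1000, 2000)
        b = GeneModel("B", "c", "+", 5000, 6000)
        assert match_tss_to_gene(TssRecord("c", "+", 700, 1), [a, b]).gene_id == "A"

    def test_linked_id_mismatch_is_dropped(self, two_gene_models):
        tss = TssRecord("chr1", "+", 700, 10, linked_id="other")
        assert match_tss_to_gene(tss, two_gene_models) is None


class TestExtendAnnotation:
    def test_extends_span_to_tss(self, two_gene_models):
        gene = two_gene_models[0]
        out = extend_annotation(gene, TssRecord("chr1", "+", 880, 5), two_gene_models)
        assert out.start == 880 and out.end == gene.end

    def test_overlapping_tss_is_identity(self, two_gene_models):
        gene = two_gene_models[0]
        assert extend_annotation(gene, TssRecord("chr1", "+", 1200, 5)) is gene

    def test_extension_through_neighbour_is_ambiguity_error(self):
        a = GeneModel("A", "c", "+", 1000, 2000)
        b = GeneModel("B", "c", "+", 3000, 4000)
        with pytest.raises(AmbiguityError):
            extend_annotation(b, TssRecord("c", "+", 1500, 5), [a, b])

    def test_minus_strand_extension(self, two_gene_models):
        gene = two_gene_models[1]  # [4000, 5000) on -
        out = extend_annotation(gene, TssRecord("chr1", "-", 5200, 5), two_gene_models)
        assert out.end == 5201 and out.start == 4000


def coding_gene(gene_id, chrom, strand, start, end, cds5, cds_len=150):
    if strand == "+":
        first_cds = (cds5, min(end, cds5 + cds_len))
    else:
        first_cds = (max(start, cds5 - cds_len + 1), cds5 + 1)
    tx = Transcript(f"{gene_id}.1", start, end, exons=((start, end),),
                    cds_5prime=cds5, first_cds=first_cds)
    return GeneModel(gene_id, chrom, strand, start, end, (tx,))


def peak_at(summit, strand="+", width=60, name="p"):
    start = summit - width // 2
    return Peak("c", start, start + width, strand, summit=summit,
                summit_coverage=50, read_count=50, enrichment_score=10, name=name)


class TestAssociate:
    def test_single_candidate(self):
        gene = coding_gene("g", "c", "+", 1000, 2000, 1080)
        tss = TssRecord("c", "+", 1000, 10)
        peak = peak_at(1000)
        (rec,) = associate([gene], [tss], [peak])
        assert rec.tss is tss and rec.peak is peak
        assert rec.d_tss_peak == 0
        assert rec.d_peak_cds == -80
        assert rec.predicted_trans_spliced is True

    @pytest.mark.parametrize("offset,assigned", [(30, True), (60, False)])
    def test_tss_downstream_of_cds_only_within_50bp_inside_cds(self, offset, assigned):
        gene = coding_gene("g", "c", "+", 1000, 2000, 1100, cds_len=200)
        tss = TssRecord("c", "+", 1100 + offset, 10)
        (rec,) = associate([gene], [tss], [])
        assert (rec.tss is not None) is assigned

    def test_tss_past_50bp_never_assigned_even_outside_cds(self):
        # 40 bp downstream but outside the first CDS -> not assigned
        gene = coding_gene("g", "c", "+", 1000, 2000, 1100, cds_len=20)
        (rec,) = associate([gene], [TssRecord("c", "+", 1140, 10)], [])
        assert rec.tss is None

    def test_contested_peak_goes_to_closest_tss(self):
        gene_a = coding_gene("a", "c", "+", 1000, 2000, 1100)
        gene_b = coding_gene("b", "c", "+", 3000, 4000, 3100)
        tss_a = TssRecord("c", "+", 2960, 10)  # |d|=40 to the peak
        tss_b = TssRecord("c", "+", 2990, 10)  # |d|=10
        peak = peak_at(3000)
        records = {r.transcript_id: r for r in associate([gene_a, gene_b], [tss_a, tss_b], [peak])}
        # both TSSs choose transcript b (nearest downstream); b keeps the
        # closer pair, a ends without tss
        assert records["b.1"].tss is tss_b and records["b.1"].peak is peak
        assert records["a.1"].tss is None and records["a.1"].peak is None

    def test_minus_strand_upstream_prediction(self):
        gene = coding_gene("g", "c", "-", 1000, 2000, 1900)
        tss = TssRecord("c", "-", 2100, 10)
        peak = peak_at(2095, strand="-")
        (rec,) = associate([gene], [tss], [peak])
        assert rec.d_peak_cds == signed_distance(2095, 1900, "-") == -195
        assert rec.predicted_trans_spliced is True


# ---------------------------------------------------------------------------
# brute-force oracle: plain-loop reimplementation of rules (i)-(iv)


def oracle_associate(genes, tss_list, peaks, max_down=50):
    transcripts = []
    for g in genes:
        for t in g.transcripts:
            if t.cds_5prime is not None:
                transcripts.append((t.transcript_id, g.chrom, g.strand, t.cds_5prime, t.first_cds))

    # (i)
    assign1 = {}
    for tss in tss_list:
        options = []
        for tid, chrom, strand, cds5, first_cds in transcripts:
            if chrom != tss.chrom or strand != tss.strand:
                continue
            d = signed_distance(tss.position, cds5, strand)
            ok = d <= 0 or (
                d <= max_down
                and first_cds is not None
                and first_cds[0] <= tss.position < first_cds[1]
            )
            if ok:
                options.append((abs(d), tid, d))
        if options:
            options.sort()
            assign1[id(tss)] = (tss, options[0][1], options[0][2])

    # (ii)
    pairs = []
    for tss, tid, d_cds in assign1.values():
        options = []
        for pi, p in enumerate(peaks):
            if p.chrom != tss.chrom or p.strand != tss.strand or p.summit is None:
                continue
            d = signed_distance(p.summit, tss.position, tss.strand)
            options.append((abs(d), p.summit, p.start, pi, d))
        if options:
            options.sort()
            pairs.append({"tss": tss, "tid": tid, "d_cds": d_cds,
                          "pi": options[0][3], "d_tp": options[0][4]})
        else:
            pairs.append({"tss": tss, "tid": tid, "d_cds": d_cds, "pi": None, "d_tp": None})

    # (iii)
    for pi in {p["pi"] for p in pairs if p["pi"] is not None}:
        claimants = [p for p in pairs if p["pi"] == pi]
        claimants.sort(key=lambda e: (abs(e["d_tp"]), e["tss"].position))
        for loser in claimants[1:]:
            loser["pi"] = None
            loser["d_tp"] = None

    # (iv)
    result = {}
    for tid, chrom, strand, cds5, first_cds in transcripts:
        mine = [p for p in pairs if p["tid"] == tid]
        if not mine:
            result[tid] = (None, None)
            continue
        mine.sort(key=lambda e: (
            e["pi"] is None,
            abs(e["d_tp"]) if e["d_tp"] is not None else 0,
            abs(e["d_cds"]),
            peaks[e["pi"]].start if e["pi"] is not None else e["tss"].position,
        ))
        best = mine[0]
        result[tid] = (best["tss"].position, peaks[best["pi"]].summit if best["pi"] is not None else None)
    return result


@given(seed=st.integers(0, 10**6))
def test_associate_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    n_tx = int(rng.integers(1, 4))
    n_tss = int(rng.integers(0, 5))
    n_peaks = int(rng.integers(0, 5))
    genes = []
    for i in range(n_tx):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, 4000))
        end = start + int(rng.integers(300, 800))
        if strand == "+":
            cds5 = start + int(rng.integers(0, 250))
        else:
            cds5 = end - 1 - int(rng.integers(0, 250))
        genes.append(coding_gene(f"g{i}", "c", strand, start, end, cds5))
    tss_list = [
        TssRecord("c", "+" if rng.random() < 0.5 else "-",
                  int(rng.integers(0, 5000)), int(rng.integers(1, 100)))
        for _ in range(n_tss)
    ]
    peaks = [
        peak_at(int(rng.integers(40, 5000)), strand="+" if rng.random() < 0.5 else "-",
                name=f"p{j}")
        for j in range(n_peaks)
    ]
    records = associate(genes, tss_list, peaks)
    expected = oracle_associate(genes, tss_list, peaks)
    got = {
        r.transcript_id: (
            r.tss.position if r.tss else None,
            r.peak.summit if r.peak else None,
        )
        for r in records
    }
    assert got == expected
    # idempotence of the record set under re-running
    records2 = associate(genes, tss_list, peaks)
    assert [(r.transcript_id, r.d_tss_peak, r.d_peak_cds) for r in records]\
        == [(r.transcript_id, r.d_tss_peak, r.d_peak_cds) for r in records2]
    # rule (iii) makes the peak -> record map injective
    used = [id(r.peak) for r in records if r.peak is not None]
    assert len(used) == len(set(used))


def _reflect_genes(genes, length):
    out = []
    flip = {"+": "-", "-": "+"}
    for g in genes:
        tx = []
        for t in g.transcripts:
            exons = tuple(sorted((length - e, length - s) for s, e in t.exons))
            first = None
            cds5 = None
            if t.first_cds is not None:
                s, e = t.first_cds
                first = (length - e, length - s)
                cds5 = length - 1 - t.cds_5prime
            tx.append(Transcript(t.transcript_id, length - t.end, length - t.start,
                                 exons, cds5, first))
        out.append(GeneModel(g.gene_id, g.chrom, flip[g.strand],
                             length - g.end, length - g.start, tuple(tx)))
    return out


def test_strand_reflection_leaves_distances_invariant():
    """Mirroring the genome through its midpoint and flipping strands must
    not change any signed distance or trans-splicing prediction."""
    length = 6000
    flip = {"+": "-", "-": "+"}
    rng = np.random.default_rng(7)
    genes, tss_list, peaks = [], [], []
    for i in range(3):
        start = 500 + i * 1800
        genes.append(coding_gene(f"g{i}", "c", "+", start, start + 900, start + 180))
        tss_list.append(TssRecord("c", "+", start - int(rng.integers(20, 200)), 10))
        peaks.append(peak_at(start - int(rng.integers(0, 150)), name=f"p{i}"))
    fwd = associate(genes, tss_list, peaks)

    r_genes = _reflect_genes(genes, length)
    r_tss = [TssRecord("c", flip[t.strand], length - 1 - t.position, t.read_depth)
             for t in tss_list]
    r_peaks = [
        Peak("c", length - p.end, length - p.start, flip[p.strand],
             summit=length - 1 - p.summit, summit_coverage=p.summit_coverage,
             read_count=p.read_count, enrichment_score=p.enrichment_score, name=p.name)
        for p in peaks
    ]
    rev = associate(r_genes, r_tss, r_peaks)
    assert [(r.transcript_id, r.d_tss_peak, r.d_peak_cds, r.predicted_trans_spliced)
            for r in fwd] == \
           [(r.transcript_id, r.d_tss_peak, r.d_peak_cds, r.predicted_trans_spliced)
            for r in rev]


class TestDistanceDistributions:
    def test_windowing(self):
        gene = coding_gene("g", "c", "+", 10000, 11000, 10100)
        tss = TssRecord("c", "+", 4500, 10)
        peak = peak_at(4600)  # d_peak_cds = -5500, outside the -3000..1000 window
        records = associate([gene], [tss], [peak])
        d = distance_distributions(records)
        assert d["d_peak_cds"].tolist() == [-5500]
        assert d["d_peak_cds_windowed"].tolist() == []

    def test_empty(self):
        d = distance_distributions([])
        assert d["d_peak_cds"].size == 0 and d["d_tss_peak"].size == 0

    def test_synthetic_mode_is_upstream(self, default_run):
        d = distance_distributions(default_run.records)["d_peak_cds"]
        assert np.median(d) < 0
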