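# ripfoot

RIP-Seq footprint localization relative to transcription start sites and
coding sequences, and prediction of spliced-leader *trans*-splicing status
from footprint position.

## The problem

In nematodes, most RNA-polymerase-II pre-mRNAs have their 5′ segment (the
*outron*) replaced by a short spliced-leader (SL) RNA. Proteins that sit at
the capped 5′ end of nascent transcripts leave a characteristic RIP-Seq
signature: a narrow (~60 nt) cluster of protected-fragment reads coincident
with the transcription start site (TSS). Because *trans*-splicing removes the
outron, such a footprint lies *upstream* of the first coding sequence (CDS)
for *trans*-spliced genes but *overlaps* the CDS 5′ end for non-*trans*-spliced
genes — so footprint position predicts *trans*-splicing status.

`ripfoot` implements that inference chain as a tested pipeline for people
analysing stranded IP/control read data against gene models and TSS
catalogues:

1. **Peak calling** (`peakcall`) — per-strand, per-bp Poisson test of the
   extended-read pileup (reads extended `extsize = 75` bp from their 5′ end,
   duplicates retained) against a local background rate
   λ(x) = max(mean control coverage in 75 and 100 bp windows centred at x,
   genome-wide control mean) scaled by library depth; Benjamini–Hochberg
   FDR ≤ 0.05 across all tested base pairs of the strand; significant bases
   merged with gaps ≤ 10 bp, intervals < 10 bp dropped.
2. **Refinement** (`peakrefine`) — shoulders trimmed either side of the
   summit where raw read coverage drops below 50% of the summit coverage;
   quality filter: reads-in-peak ≥ 20, enrichment score ≥ 5,
   width 30–90 bp (inclusive).
3. **Association** (`tss_assoc`) — one TSS per transcript (highest read
   depth, ties by distance to the transcript 5′ end), annotation extension
   upstream to the TSS, then four deterministic heuristics resolving
   (transcript, TSS, peak) triples; signed distances are measured from the
   peak summit in transcript orientation (negative = upstream), and
   `d(peak summit, CDS 5′) < 0` predicts *trans*-splicing.
4. **Null model** (`nullstats`) — equal numbers of random peaks (summits
   uniform per pooled genome bp, widths resampled from the observed set) run
   through the same heuristics; two-sample Kolmogorov–Smirnov tests
   D = sup|F̂₁ − F̂₂| with the Smirnov limiting p-value.
5. **Classification** (`transsplice`) — a gene is *bona fide trans*-spliced
   when its best SL acceptor site (≥ 100 reads, any distance upstream or
   ≤ 50 bp downstream of the CDS 5′ end) has acceptor:background depth ratio
   ≥ 2.9%, background being the median exon–exon junction depth of the
   stronger junction class; concordance with the peak-location prediction is
   a 2×2 Pearson χ² (no continuity correction).
6. **Quantification** (`ripquant`) — fractional counts (1/`n_hits` per
   aligned location, strand-aware any-overlap), median-of-ratios size
   factors, log₂ fold-change ranking with a transparent pooled-count exact
   test as the significance stand-in.
7. **Stoichiometry & qPCR** (`stoich`) — total protein approach
   TPAᵢ = (LFQᵢ/ΣLFQ)/MWᵢ expressed as % of the bait ± SD, and comparative-CT
   ratios 2^(−ΔΔCT).

A first-class synthetic-data generator (`simulate`) produces complete,
ground-truth-labelled bundles (genome, GFF3 gene models, TSS BED, replicated
stranded IP/control alignment BEDs, acceptor/junction tables, LFQ table) so
every stage and the end-to-end run are testable without any download.

## Worked example

```python
from ripfoot import SynthConfig, generate, run_pipeline
from ripfoot.simulate import truth_report

cfg = SynthConfig(seed=1)          # ~500 genes, 85% trans-spliced, 60 nt footprints
bundle = generate(cfg)
result = run_pipeline(
    bundle.genome, bundle.genes, bundle.tss_records,
    bundle.ip_alignments, bundle.control_alignments,
    bundle.acceptor_sites, bundle.junctions, null_reps=10, seed=1,
)
report = result.report()
truth = truth_report(result.records, result.calls, bundle.truth)
```

prints (via the obvious f-strings):

```
peaks called:              505
peaks after quality filter:  505
predicted upstream (%):    85.4
concordance chi2:          435.74
null KS median D:          0.47  (max p = 4.6e-32)
classification sens/spec:  0.995 / 1.000
```

Reading: all 505 footprints (500 gene footprints + 5 SmY-like short genes)
survive the quality filter; 85.4% of associated transcripts have their peak
summit upstream of the CDS 5′ end, matching the generator's 85%
*trans*-spliced fraction; predictions and acceptor-based calls agree far
beyond chance (χ²₁ = 435.7); observed peak–CDS distances differ from the
random-peak null in every replicate; and acceptor-ratio classification
recovers the true labels almost perfectly.

The same stages are available from the shell:

```bash
ripfoot simulate --out data/
ripfoot callpeaks --ip data/ip_rep1.bed,data/ip_rep2.bed \
    --control data/control_rep1.bed,data/control_rep2.bed \
    --genome data/genome.tsv --out peaks.narrowPeak
ripfoot refine --peaks peaks.narrowPeak --ip data/ip_rep1.bed,data/ip_rep2.bed \
    --genome data/genome.tsv --out refined.narrowPeak
ripfoot associate --gff data/genes.gff3 --tss data/tss.bed \
    --peaks refined.narrowPeak --genome data/genome.tsv --out assoc.tsv
ripfoot run-all --seed 1 --out run/      # everything, plus report.json
```

## Layout

```
src/ripfoot/
  io_formats.py   # GFF3 / narrowPeak / BED6 / bedGraph readers-writers, domain types
  peakcall.py     # local-lambda Poisson caller
  peakrefine.py   # shoulder trimming, quality filter, width histogram
  tss_assoc.py    # TSS curation, annotation extension, association heuristics
  nullstats.py    # random-peak null, KS / chi-square / BH utilities
  transsplice.py  # acceptor-based classification and concordance
  ripquant.py     # fractional counting, normalization, enrichment, set overlaps
  stoich.py       # total protein approach, ddCT
  simulate.py     # synthetic-data generator + truth reporting
  pipeline.py     # stage orchestration
  cli.py          # `ripfoot` subcommands
```

See `docs/methods.md` for the statistical model, parameter defaults, and the
scope and limitations of the synthetic data.
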