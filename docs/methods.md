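# Methods

## Coordinate and sign conventions

All internal coordinates are 0-based half-open; GFF3 is converted at the I/O
boundary. Single-bp positions (TSS, summit, CDS 5′ end) denote the base
itself, so on the minus strand the 5′ end of `[s, e)` is `e − 1`. The signed
distance `d(a, b)` is `a − b` on the plus strand and `b − a` on the minus
strand: negative always means *a is 5′ (upstream) of b* in transcript
orientation. All peak distances are measured from the peak summit, so that
observed and random-peak distances are commensurable (the null model places
only summits); an edge-based alternative is not provided.

## Peak calling model

The caller reproduces the semantics of a narrow-peak caller run with the
fragment-size model disabled, as a fully testable per-bp formulation:

* **Pileup.** Each read contributes +1 over `extsize` bp (default 75, the
  sequencing read length) from its strand-aware 5′ end, clipped to
  chromosome bounds. Duplicates are retained — RIP-Seq footprints are
  expected to stack.
* **Local lambda.** At position x, λ(x) = max(mean control coverage in each
  centred window w ∈ {75, 100} bp, genome-wide control mean), multiplied by
  the library-depth ratio (IP reads / control reads), floored at 0.1
  reads/bp. The floor prevents zero-λ singularities in unsequenced regions;
  the genome-wide term guards against control dropouts. The depth scaling is
  a plain ratio of read counts — no duplicate-aware effective depth.
* **Significance.** The per-bp p-value is the Poisson upper tail
  P(X ≥ pileup(x)) under λ(x). BH correction is applied over **all** base
  pairs of the strand (each strand independently, matching the per-strand
  calling design), rather than over candidate regions only; this is a
  conservative, order-independent choice that a brute-force oracle can
  replicate exactly. Significant positions (q ≤ 0.05) are merged when
  separated by ≤ `max_gap` = 10 bp; merged intervals shorter than
  `min_length` = 10 bp are dropped.
* **Peak attributes.** Summit = leftmost maximum of the pileup inside the
  peak (deterministic tie-break); enrichment score = summit pileup / λ(summit);
  read count = number of IP reads whose *extended* footprint overlaps the
  peak; the reported q-value is the q at the summit.

The caller is deliberately simpler than the external tool it emulates: same
statistical model (Poisson vs local lambda with BH), no candidate-region
pre-screening, no bit-level compatibility claimed.

## Refinement

Trimming keeps the maximal contiguous run of positions containing the summit
whose **raw** (unextended) read coverage is ≥ 50% of the summit coverage;
coverage exactly at 50% is kept, and an interior dip truncates the run even
if coverage recovers further out. Because the summit produced by the caller
lives on the extended pileup, the refinement stage first re-anchors the
summit on the raw coverage track (leftmost maximum within the peak) before
trimming. Trimming is idempotent and always returns a sub-interval.

The quality filter retains peaks with reads-in-peak ≥ 20 AND enrichment
score ≥ 5 AND width between 30 and 90 bp, all bounds inclusive. The
read-depth criterion uses reads-in-peak; a flag switches it to summit pileup
for data where per-read records are unavailable.

## Association heuristics

After curating one TSS per transcript (highest read depth; ties broken by
shorter distance to the transcript 5′ end, then leftmost) and extending gene
spans upstream to their matched TSS (an error is raised if extension would
overlap a same-strand neighbour — the method assumes extension is
unambiguous, and the implementation enforces it):

1. each TSS → nearest transcript downstream, measured to the first-CDS 5′
   end; a TSS may lie ≤ 50 bp downstream of that point only when inside the
   first CDS (rescues mis-annotated start codons);
2. each TSS → nearest quality-filtered peak by |summit − TSS|;
3. a peak claimed by several TSSs keeps the closest TSS (ties: leftmost
   TSS), losers become peakless — the peak→record map is injective;
4. a transcript keeps the pair with smallest |d(TSS, peak)|, ties by smaller
   |d(TSS, CDS)|, then leftmost peak. Tie-breaks beyond the primary
   criterion are underdetermined by the method description; the order used
   here is fixed and documented so the procedure is deterministic and
   reproducible by exhaustive enumeration.

`predicted_trans_spliced` = (summit strictly upstream of the CDS 5′ end,
d < 0); d = 0 counts as overlapping/downstream.

## Random-peak null and statistics

Null peaks place summits uniformly over base pairs pooled across
chromosomes (longer chromosomes receive proportionally more), strands
uniform, widths resampled with replacement from the observed peak set, and
are pushed through the identical association heuristics. Distances are
compared with the two-sample KS statistic and the classical Smirnov limiting
p-value Q(√(n₁n₂/(n₁+n₂))·D) — appropriate here because the compared vectors
number in the hundreds to thousands; no exact small-sample computation is
attempted. The 2×2 concordance test is Pearson's χ² without continuity
correction (the continuity-corrected statistic does not reproduce the
recomputable published example). BH q-values are standard step-up with
enforced monotonicity.

## Trans-splicing classification

Background expression per gene is the median junction depth of the more
strongly expressed of the constitutive and major junction classes (compared
by class median — chosen over the sum for robustness; "minor" junctions are
ignored). The selected acceptor is the highest-depth site any distance
upstream or ≤ 50 bp downstream of the CDS 5′ end, subject to a 100-read
floor. Classification: acceptor depth / background ≥ 2.9% (inclusive) →
*trans*-spliced. A gene with background but no qualifying acceptor is
classified **not** *trans*-spliced — this is what makes the concordance
table's negative column meaningful; the call is undetermined only when no
background can be estimated (no junctions, or zero depth). No upper bound
on the ratio is applied. Ratio quantiles use linear-interpolation (type-7)
quantiles.

## Quantification

Fractional counting credits every aligned location overlapping a gene
(any overlap ≥ 1 bp, strand-aware by default — the library protocol is
stranded; a flag disables it) with 1/`n_hits`; the denominator is the read's
total genomic hits, so fractions assigned to intergenic hits are lost and
the total assigned count never exceeds the number of reads. Size factors are
median-of-ratios against the geometric-mean pseudo-reference over genes
positive in all libraries. The enrichment flag comes from a pooled-count
binomial exact test (is the gene's share of IP reads larger than the
library-wide share?) with BH correction — a transparent stand-in, not a
negative-binomial shrinkage model; flagged-gene totals are therefore not
comparable to shrinkage-model outputs, and the ranking (by log₂ fold change
with pseudocount 0.5 on size-factor-normalized means) is the intended
product of this module.

## Stoichiometry and qPCR

TPAᵢ = (LFQᵢ / Σⱼ LFQⱼ) / MWᵢ per replicate; reported as TPAᵢ/TPA_bait in
percent, mean ± sample SD (n−1 divisor; the divisor is a package choice)
across replicates. Proteins with zero intensity in a replicate contribute
zero to that replicate's total and a zero relative abundance (not dropped).
ΔΔCT = (CT_target − CT_ref) − (CT_target,wt − CT_ref,wt); ratio = 2^(−ΔΔCT).

## Synthetic data: what it emulates and what it does not

The generator packs non-overlapping gene models on both strands of a
2 × 650 kb genome (~500 coding genes plus 5 short "SmY-like" high-enrichment
genes), assigns each gene a true TSS, and with probability 0.85 an outron
(truncated normal, mean 200 bp, SD 50, range 50–400) ending at an SL
acceptor 8 bp upstream of the CDS start; non-*trans*-spliced genes get a
short 5′ UTR (uniform 0–30 bp), typical of nematode non-*trans*-spliced
genes whose footprints overlap the CDS start. IP alignments are
protected-fragment footprints: 5′ ends normal around the TSS (SD 8 bp,
modelling capped-end dispersion) with lengths normal(60, 5) — reads longer
than the insert align only over the insert, so the *alignment* carries the
fragment length while the 75 bp read length survives as the caller's
extension size. Background reads (0.01 reads/bp/strand/library) are uniform
in both IP and control; 5% of reads are duplicated to 2 random locations as
multimappers; two replicates per library. Acceptor depths are drawn as
lognormal ratios (median 11.3%, log-SD 0.5) of a lognormal per-gene junction
depth (median 5000, log-SD 0.3); 30% of non-*trans*-spliced genes receive a
spurious low-ratio acceptor (median 0.5%). Annotated TSS records are
jittered (SD 5 bp) and 30% of genes get a second, shallower TSS record so
curation is exercised. One global seed drives a spawned per-component seed
sequence; identical configs give byte-identical bundles.

Not emulated: real sequence content (there are no sequences at all),
library-chemistry artefacts (poly(A) tailing, template switching),
sequencing error, GC/mappability structure, overlapping or nested gene
models, alternative isoforms, and expression-dependent footprint strength.
Passing tests therefore demonstrate correctness of the inference chain under
its stated statistical assumptions — not robustness to every artefact of
real libraries.

Default problem sizes (≈500 genes, ≈130k reads, 10 null replicates) keep a
full end-to-end run in a few seconds on one CPU while leaving per-gene
counts high enough that recovery metrics are tight.

## Numerical and degenerate-input choices

* Lambda floor 0.1 reads/bp; summit ties leftmost; BH per strand.
* Peak q-values are raw (not −log10) in the narrowPeak `qValue` column;
  the `score` column carries summit pileup, `pValue` the reads-in-peak —
  a documented dialect for round-trip fidelity.
* Unknown chromosomes and out-of-bounds intervals are hard errors in every
  reader; TSS BED records must span exactly 1 bp.
* Zero-length control library, empty KS samples, zero chi-square marginals,
  n ≤ 0 random peaks, and quantification without a commonly-positive gene
  are errors; zero junction background yields an undetermined call with a
  warning.
* TSS read depths from different source catalogues are treated as
  comparable integers; no cross-catalogue depth normalization is applied.

## Known limitations

* The caller tests every base pair; on gigabase genomes a candidate-region
  pre-screen would be needed for memory/speed (out of scope at the genome
  sizes used here).
* The significance stand-in in `ripquant` ignores biological dispersion;
  use it for ranking, not differential testing.
* Classification inherits the acceptor catalogue's detection floor: genes
  whose true acceptor has < 100 reads are conservatively called
  not *trans*-spliced when junctions are present.
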