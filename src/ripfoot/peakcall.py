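"""Simplified per-strand peak caller with local-lambda Poisson background.

Semantics follow a narrow-peak caller run with a disabled fragment-size model:
each read is extended to a fixed fragment size (``extsize``) from its
strand-aware 5' end, the extended pileup is compared per base pair against a
local Poisson background rate ("local lambda") estimated from a matched
control library in centered windows (defaults 75 and 100 bp) and against the
genome-wide control mean, Benjamini-Hochberg correction is applied across all
tested base pairs of the strand, and significant positions are merged into
peaks (gaps <= ``max_gap`` bridged, merged intervals < ``min_length``
dropped).

The per-bp model is deliberately simpler than the external tool's candidate
region logic: every base pair is an independent Poisson test, which makes the
caller exactly reproducible by a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import CoverageTrack, GenomeLayout, Peak, ReadAlignment, STRANDS

__all__ = ["CallerParams", "pileup", "raw_coverage", "local_lambda", "call_peaks",
           "call_peaks_from_tracks"]


@dataclass(frozen=True)
class CallerParams:
    """Tunable parameters of the caller (defaults mirror the analysis setup)."""

    extsize: int = 75
    lambda_windows: tuple[int, ...] = (75, 100)
    min_length: int = 10
    max_gap: int = 10
    fdr: float = 0.05
    shift: int = 0
    lambda_floor: float = 0.1

    def __post_init__(self):
        if self.extsize < 1:
            raise ValueError("extsize must be >= 1")
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must be in (0, 1]")
        if any(w < 1 for w in self.lambda_windows):
            raise ValueError("lambda windows must be >= 1 bp")
        if self.lambda_floor <= 0:
            raise ValueError("lambda floor must be > 0")


def _extended_interval(a: ReadAlignment, params: CallerParams, chrom_len: int) -> tuple[int, int]:
    """Fixed-size footprint from the strand-aware 5' end, clipped to bounds."""
    if a.strand == "+":
        start = a.start + params.shift
        end = start + params.extsize
    else:
        end = a.end - params.shift
        start = end - params.extsize
    return max(0, start), min(chrom_len, end)


def pileup(
    alignments: Sequence[ReadAlignment],
    genome: GenomeLayout,
    params: CallerParams,
    strand: str,
) -> CoverageTrack:
    """Extended-read pileup for one strand.  Duplicate reads are retained."""
    diffs = {c: np.zeros(l + 1, dtype=np.float64) for c, l in genome.items()}
    for a in alignments:
        if a.strand != strand:
            raise ValueError("pileup expects alignments from a single strand")
        s, e = _extended_interval(a, params, genome[a.chrom])
        if e > s:
            diffs[a.chrom][s] += 1
            diffs[a.chrom][e] -= 1
    data = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return CoverageTrack(genome, strand, data)


def raw_coverage(
    alignments: Sequence[ReadAlignment], genome: GenomeLayout, strand: str
) -> CoverageTrack:
    """Unextended pileup over the aligned intervals themselves (for trimming)."""
    diffs = {c: np.zeros(l + 1, dtype=np.float64) for c, l in genome.items()}
    for a in alignments:
        if a.strand != strand:
            continue
        diffs[a.chrom][a.start] += 1
        diffs[a.chrom][a.end] -= 1
    data = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return CoverageTrack(genome, strand, data)


def _window_means(arr: np.ndarray, window: int) -> np.ndarray:
    """Mean over a centered window, truncated at chromosome edges."""
    n = len(arr)
    half_lo = window // 2
    half_hi = window - half_lo
    csum = np.concatenate(([0.0], np.cumsum(arr)))
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi, 0, n)
    return (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)


def _lambda_array(
    control_arr: np.ndarray,
    params: CallerParams,
    global_mean: float,
    scale: float,
) -> np.ndarray:
    lam = np.full(len(control_arr), global_mean, dtype=np.float64)
    for w in params.lambda_windows:
        np.maximum(lam, _window_means(control_arr, w), out=lam)
    lam *= scale
    np.maximum(lam, params.lambda_floor, out=lam)
    return lam


def local_lambda(
    control_track: CoverageTrack,
    chrom: str,
    position: int,
    params: CallerParams,
    global_mean: float,
    scale: float = 1.0,
) -> float:
    """Local background rate at one position: max over window means and the
    genome-wide control mean, depth-scaled and floored."""
    if control_track.genome.total_bp <= 0:
        raise ValueError("empty control track")
    arr = control_track[chrom]
    best = global_mean
    for w in params.lambda_windows:
        lo = max(0, position - w // 2)
        hi = min(len(arr), position + (w - w // 2))
        if hi > lo:
            best = max(best, float(arr[lo:hi].mean()))
    return max(best * scale, params.lambda_floor)


def _merge_runs(positions: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    """Merge sorted significant positions into half-open intervals, bridging
    gaps of at most ``max_gap`` bp between consecutive significant bases."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(positions) - 1]))
    return [(int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)]


def call_peaks_from_tracks(
    ip_track: CoverageTrack,
    control_track: CoverageTrack,
    n_ip_reads: int,
    n_control_reads: int,
    params: CallerParams,
    ip_alignments: Sequence[ReadAlignment] | None = None,
) -> list[Peak]:
    """Core per-bp Poisson + BH calling on precomputed single-strand tracks."""
    if n_control_reads <= 0:
        raise ValueError("zero-length control library")
    genome = ip_track.genome
    strand = ip_track.strand
    scale = n_ip_reads / n_control_reads
    global_mean = control_track.mean

    chroms = list(genome.chroms)
    lam = {c: _lambda_array(control_track[c], params, global_mean, scale) for c in chroms}
    pvals = np.concatenate(
        [stats.poisson.sf(np.round(ip_track[c]) - 1, lam[c]) for c in chroms]
    )
    qvals = stats.false_discovery_control(pvals, method="bh")

    # 5' starts of extended IP reads per chromosome, for read-in-peak counts
    ext_starts: dict[str, np.ndarray] = {}
    if ip_alignments is not None:
        for c in chroms:
            starts = [
                _extended_interval(a, params, genome[c])[0]
                for a in ip_alignments
                if a.chrom == c and a.strand == strand
            ]
            ext_starts[c] = np.sort(np.asarray(starts, dtype=np.int64))

    peaks: list[Peak] = []
    offset = 0
    for c in chroms:
        n = genome[c]
        q_c = qvals[offset:offset + n]
        offset += n
        sig = np.flatnonzero(q_c <= params.fdr)
        for s, e in _merge_runs(sig, params.max_gap):
            if e - s < params.min_length:
                continue
            arr = ip_track[c][s:e]
            summit = s + int(np.argmax(arr))  # leftmost maximum
            summit_cov = float(ip_track[c][summit])
            enrich = summit_cov / lam[c][summit]
            read_count = 0.0
            if c in ext_starts:
                starts = ext_starts[c]
                # extended read [t, t+extsize) overlaps [s, e) iff t < e and t > s - extsize
                read_count = float(
                    np.searchsorted(starts, e, side="left")
                    - np.searchsorted(starts, s - params.extsize, side="right")
                )
            peaks.append(
                Peak(
                    chrom=c,
                    start=s,
                    end=e,
                    strand=strand,
                    summit=summit,
                    summit_coverage=summit_cov,
                    read_count=read_count,
                    enrichment_score=float(enrich),
                    q_value=float(q_c[summit]),
                )
            )
    return peaks


def call_peaks(
    ip_alignments: Sequence[ReadAlignment],
    control_alignments: Sequence[ReadAlignment],
    genome: GenomeLayout,
    params: CallerParams | None = None,
    strands: Sequence[str] = STRANDS,
) -> list[Peak]:
    """Call peaks on each strand independently against the matched control."""
    params = params or CallerParams()
    if not ip_alignments or not control_alignments:
        raise ValueError("both IP and control libraries must be non-empty")
    peaks: list[Peak] = []
    for strand in strands:
        ip_s = [a for a in ip_alignments if a.strand == strand]
        ctrl_s = [a for a in control_alignments if a.strand == strand]
        if not ip_s:
            continue
        ip_track = pileup(ip_s, genome, params, strand)
        ctrl_track = pileup(ctrl_s, genome, params, strand)
        peaks.extend(
            call_peaks_from_tracks(
                ip_track,
                ctrl_track,
                n_ip_reads=len(ip_alignments),
                n_control_reads=len(control_alignments),
                params=params,
                ip_alignments=ip_s,
            )
        )
    return peaks
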