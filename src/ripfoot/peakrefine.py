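"""Peak post-processing: shoulder trimming at 50% of summit coverage and the
quality filter (read count >= 20, enrichment >= 5, width 30-90 bp inclusive).

Trimming is contiguous from the summit: the refined interval is the maximal
run of positions containing the summit whose coverage stays at or above half
the summit coverage; an interior dip below the threshold truncates the run
even if coverage recovers further out.  Coverage exactly at 50% is kept
(only coverage strictly below the threshold trims).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack, Peak

__all__ = ["resummit", "trim_shoulders", "filter_peaks", "peak_width_histogram"]


def resummit(peak: Peak, coverage: CoverageTrack) -> Peak:
    """Re-anchor the summit on a coverage track (leftmost maximum within the
    peak).  Used before trimming when the summit was located on a different
    track (e.g. the extended pileup) than the one trimming operates on."""
    arr = coverage[peak.chrom][peak.start:peak.end]
    summit = peak.start + int(np.argmax(arr))
    return replace(peak, summit=summit, summit_coverage=float(arr[summit - peak.start]))


def trim_shoulders(peak: Peak, coverage: CoverageTrack) -> Peak:
    """Trim peak shoulders either side of the summit where coverage drops
    below 50% of the summit coverage."""
    if peak.summit is None or not (peak.start <= peak.summit < peak.end):
        raise ValueError("trim_shoulders requires a summit inside the peak interval")
    arr = coverage[peak.chrom]
    summit_cov = peak.summit_coverage if peak.summit_coverage > 0 else float(arr[peak.summit])
    if summit_cov <= 0:
        raise ValueError("summit coverage must be > 0")
    threshold = 0.5 * summit_cov
    lo = peak.summit
    while lo - 1 >= peak.start and arr[lo - 1] >= threshold:
        lo -= 1
    hi = peak.summit + 1
    while hi < peak.end and arr[hi] >= threshold:
        hi += 1
    return replace(peak, start=lo, end=hi, summit_coverage=summit_cov)


def filter_peaks(
    peaks: Iterable[Peak],
    min_reads: float = 20,
    min_enrichment: float = 5.0,
    min_width: int = 30,
    max_width: int = 90,
    use_summit_depth: bool = False,
) -> list[Peak]:
    """Retain high-quality peaks; all bounds inclusive.

    ``use_summit_depth=True`` applies the read-depth threshold to the summit
    pileup instead of the reads-in-peak count.
    """
    out = []
    for p in peaks:
        depth = p.summit_coverage if use_summit_depth else p.read_count
        if depth >= min_reads and p.enrichment_score >= min_enrichment and min_width <= p.width <= max_width:
            out.append(p)
    return out


def peak_width_histogram(peaks: Sequence[Peak], bin_width: int = 10) -> pd.Series:
    """Counts of peak widths per bin; the index is the left bin edge."""
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    widths = np.array([p.width for p in peaks], dtype=np.int64)
    if len(widths) == 0:
        return pd.Series(dtype=np.int64, name="count")
    bins = (widths // bin_width) * bin_width
    counts = pd.Series(bins).value_counts().sort_index()
    counts.name = "count"
    return counts
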