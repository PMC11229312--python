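"""Random-peak null model and shared statistical utilities.

The null model places peak summits uniformly over the genome (base pairs
pooled across chromosomes, so longer chromosomes receive proportionally more
peaks) with uniform strands, and resamples peak widths with replacement from
the observed peak set.  The random peaks are pushed through the same
association heuristics as the observed peaks, and the resulting distance
distributions are compared with two-sample Kolmogorov-Smirnov tests
(asymptotic p-values; the samples here number in the thousands).

Chi-square tests are Pearson 2x2 without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomeLayout, GeneModel, Peak, TssRecord
from .tss_assoc import AssociationRecord, associate, distance_distributions

__all__ = [
    "KsResult",
    "Chi2Result",
    "random_peaks",
    "ks_two_sample",
    "pearson_chi2_2x2",
    "bh_fdr",
    "null_comparison",
]


@dataclass(frozen=True)
class KsResult:
    D: float
    p_value: float
    n1: int
    n2: int

    def __post_init__(self):
        if not 0.0 <= self.D <= 1.0:
            raise ValueError("KS D must be in [0, 1]")


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self):
        if self.statistic < 0 or self.df < 1:
            raise ValueError("invalid chi-square result")


def random_peaks(
    genome: GenomeLayout,
    n: int,
    width_source: Sequence[int] | int,
    seed: int | np.random.Generator = 0,
) -> list[Peak]:
    """``n`` random peaks: summits uniform over pooled genome bp, strands
    uniform, widths resampled with replacement from ``width_source`` (or a
    fixed width) and centered on the summit, clipped to chromosome bounds."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    widths = np.atleast_1d(np.asarray(width_source, dtype=np.int64))
    if len(widths) == 0 or np.any(widths < 1):
        raise ValueError("width source must contain positive widths")

    chroms = list(genome.chroms)
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    edges = np.concatenate(([0], np.cumsum(lengths)))
    pooled = rng.integers(0, genome.total_bp, size=n)
    chrom_idx = np.searchsorted(edges, pooled, side="right") - 1
    positions = pooled - edges[chrom_idx]
    strands = rng.choice(["+", "-"], size=n)
    drawn = rng.choice(widths, size=n, replace=True)

    peaks = []
    for i in range(n):
        c = chroms[chrom_idx[i]]
        length = lengths[chrom_idx[i]]
        summit = int(positions[i])
        w = int(drawn[i])
        start = max(0, summit - w // 2)
        end = min(length, start + w)
        start = max(0, min(start, summit))
        end = max(end, summit + 1)
        peaks.append(
            Peak(chrom=c, start=start, end=end, strand=str(strands[i]),
                 summit=summit, name=f"null{i}")
        )
    return peaks


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sample KS: D = sup |ECDF_x - ECDF_y|, asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("KS samples must be non-empty")
    d = float(stats.ks_2samp(x, y, method="asymp").statistic)
    # classical Smirnov limiting p-value: Q(sqrt(n1 n2/(n1+n2)) * D)
    en = np.sqrt(len(x) * len(y) / (len(x) + len(y)))
    p = float(np.clip(stats.kstwobign.sf(en * d), 0.0, 1.0))
    return KsResult(D=d, p_value=p, n1=len(x), n2=len(y))


def pearson_chi2_2x2(table) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) <= 0) or np.any(t.sum(axis=1) <= 0):
        raise ValueError("all marginals must be > 0")
    res = stats.chi2_contingency(t, correction=False)
    return Chi2Result(statistic=float(res.statistic), df=1, p_value=float(res.pvalue))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


@dataclass(frozen=True)
class NullComparison:
    replicates: list[KsResult]
    metric: str

    @property
    def median_D(self) -> float:
        return float(np.median([r.D for r in self.replicates]))

    @property
    def max_p(self) -> float:
        return float(max(r.p_value for r in self.replicates))


def null_comparison(
    observed_records: Sequence[AssociationRecord],
    genes: Sequence[GeneModel],
    tss_list: Sequence[TssRecord],
    genome: GenomeLayout,
    n_reps: int = 10,
    seed: int = 0,
    metric: str = "d_peak_cds",
) -> NullComparison:
    """KS comparison of observed association distances against replicated
    random-peak null associations (same number of peaks, widths resampled
    from the observed peaks, same assignment heuristics)."""
    if n_reps <= 0:
        raise ValueError("n_reps must be >= 1")
    if metric not in ("d_peak_cds", "d_tss_peak"):
        raise ValueError(f"unknown metric {metric!r}")
    observed_peaks = [r.peak for r in observed_records if r.peak is not None]
    observed = distance_distributions(observed_records)[metric]
    if len(observed_peaks) == 0 or len(observed) == 0:
        raise ValueError("no observed peak associations to compare")
    widths = [p.width for p in observed_peaks]

    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_reps):
        null_set = random_peaks(genome, len(observed_peaks), widths, rng)
        null_records = associate(genes, tss_list, null_set)
        null_d = distance_distributions(null_records)[metric]
        if len(null_d) == 0:
            results.append(KsResult(D=1.0, p_value=0.0, n1=len(observed), n2=0))
            continue
        results.append(ks_two_sample(observed, null_d))
    return NullComparison(replicates=results, metric=metric)
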