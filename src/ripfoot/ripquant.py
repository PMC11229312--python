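"""Gene-level read quantification with fractional multimapper assignment.

Every aligned location of a read that overlaps a gene annotation (any
overlap >= 1 bp, strand-aware by default) adds ``1 / n_hits`` to that gene,
where ``n_hits`` is the read's total number of genomic hits; a location
overlapping several genes credits each of them.  The total count assigned
therefore never exceeds the number of reads, with equality when every hit of
every read overlaps a gene.

Normalization is median-of-ratios against the geometric-mean pseudo-reference
over genes positive in all libraries.  The enrichment significance flag uses a
transparent pooled-count binomial/Poisson exact test with BH correction; it is
documented as a stand-in and is not equivalent to a negative-binomial
shrinkage model, so flagged-gene totals are not expected to match results
from such models.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GeneModel, ReadAlignment
from .nullstats import bh_fdr

__all__ = ["count_reads", "size_factors", "enrichment_table", "set_intersections"]


def count_reads(
    alignments: Sequence[ReadAlignment],
    genes: Sequence[GeneModel],
    stranded: bool = True,
) -> pd.Series:
    """Per-gene fractional counts (index: gene_id, in input gene order)."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        key = (g.chrom, g.strand if stranded else ".")
        trees.setdefault(key, IntervalTree())[g.start:g.end] = g.gene_id
    counts = {g.gene_id: 0.0 for g in genes}
    for a in alignments:
        key = (a.chrom, a.strand if stranded else ".")
        tree = trees.get(key)
        if tree is None:
            continue
        for hit in tree.overlap(a.start, a.end):
            counts[hit.data] += 1.0 / a.n_hits
    return pd.Series(counts, name="count")


def size_factors(count_matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (genes x libraries matrix)."""
    if count_matrix.shape[1] < 2:
        raise ValueError("size factors require >= 2 libraries")
    positive = (count_matrix > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene is positive in all libraries")
    sub = count_matrix.loc[positive]
    log_ref = np.log(sub).mean(axis=1)
    factors = np.exp((np.log(sub).sub(log_ref, axis=0)).median(axis=0))
    return pd.Series(factors, index=count_matrix.columns, name="size_factor")


def enrichment_table(
    counts: pd.DataFrame,
    ip_cols: Sequence[str],
    control_cols: Sequence[str],
    pseudocount: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene log2 fold change (IP vs control, on normalized means) with an
    enrichment flag from a pooled-count exact test.

    Columns: ``log2fc``, ``p_value``, ``q_value``, ``enriched``, ``rank``
    (1 = most enriched).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    factors = size_factors(counts[list(ip_cols) + list(control_cols)])
    norm = counts.div(factors, axis=1)
    ip_mean = norm[list(ip_cols)].mean(axis=1)
    ctrl_mean = norm[list(control_cols)].mean(axis=1)
    log2fc = np.log2((ip_mean + pseudocount) / (ctrl_mean + pseudocount))

    # pooled-count exact test: is the gene's share of IP reads larger than
    # the library-wide share?  (binomial exact; stand-in for a shrinkage model)
    ip_raw = counts[list(ip_cols)].sum(axis=1)
    ctrl_raw = counts[list(control_cols)].sum(axis=1)
    ip_depth = float(ip_raw.sum())
    ctrl_depth = float(ctrl_raw.sum())
    p0 = ip_depth / (ip_depth + ctrl_depth)
    x = np.round(ip_raw).astype(np.int64)
    n = x + np.round(ctrl_raw).astype(np.int64)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, stats.binom.sf(x - 1, np.maximum(n, 1), p0), 1.0)
    q = bh_fdr(np.clip(p, 0.0, 1.0))
    enriched = (log2fc > 0) & (q <= alpha)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "enriched": enriched,
        },
        index=counts.index,
    )
    out["rank"] = out["log2fc"].rank(ascending=False, method="first").astype(int)
    return out


def set_intersections(named_sets: Mapping[str, set]) -> pd.DataFrame:
    """Exclusive intersection counts for an upset-style summary.

    One row per non-empty membership combination; ``members`` is the sorted
    tuple of set names, ``count`` the number of elements exclusive to that
    combination.  Counts sum to the size of the union.
    """
    if len(named_sets) < 2:
        raise ValueError("need >= 2 sets")
    union = set().union(*named_sets.values())
    combos: dict[tuple[str, ...], int] = {}
    for el in union:
        members = tuple(sorted(name for name, s in named_sets.items() if el in s))
        combos[members] = combos.get(members, 0) + 1
    rows = [
        {"members": members, "count": count}
        for members, count in sorted(combos.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["members", "count"])
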