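"""Proteomics stoichiometry (total protein approach) and comparative-CT qPCR.

Total protein approach (TPA): for each replicate, a protein's relative molar
abundance is ``(LFQ_i / total LFQ signal) / MW_i``; abundances are expressed
as a percentage of the bait (GFP-tagged) protein, then averaged across
replicates with a sample (n-1) standard deviation.  The total-signal
normalization makes the estimate invariant to global rescaling of a
replicate's intensities.  Proteins with zero intensity in a replicate
contribute zero to that replicate's total and a zero relative abundance for
that replicate (they are not dropped).

ddCT: ``dCT = CT_target - CT_reference`` per sample, ``ddCT = dCT_sample -
dCT_wildtype``, fold ratio ``2 ** -ddCT``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["tpa_relative_abundance", "ddct_ratio"]


def tpa_relative_abundance(
    lfq: pd.DataFrame,
    bait_id: str,
    mw_col: str = "mw_kda",
    sample_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-protein mean +/- SD relative abundance as a percentage of the bait.

    ``lfq`` is indexed by protein id with a molecular-weight column (kDa)
    and one column per replicate.  The bait must have positive intensity in
    every replicate; its abundance is exactly 100% +/- 0%.
    """
    if bait_id not in lfq.index:
        raise ValueError(f"bait {bait_id!r} not in LFQ table")
    if sample_cols is None:
        sample_cols = [c for c in lfq.columns if c != mw_col]
    mw = lfq[mw_col].astype(float)
    if (mw <= 0).any():
        raise ValueError("molecular weights must be > 0")
    intensities = lfq[sample_cols].astype(float)
    if (intensities < 0).any().any():
        raise ValueError("LFQ intensities must be >= 0")
    if (intensities.loc[bait_id] <= 0).any():
        raise ValueError(f"bait {bait_id!r} has non-positive intensity in a replicate")

    totals = intensities.sum(axis=0)
    tpa = intensities.div(totals, axis=1).div(mw, axis=0)
    rel_pct = tpa.div(tpa.loc[bait_id], axis=1) * 100.0
    out = pd.DataFrame(
        {
            "mean_pct": rel_pct.mean(axis=1),
            "sd_pct": rel_pct.std(axis=1, ddof=1) if len(sample_cols) > 1 else 0.0,
        },
        index=lfq.index,
    )
    return out


def ddct_ratio(
    ct_target: float,
    ct_reference: float,
    ct_target_wt: float,
    ct_reference_wt: float,
) -> float:
    """Fold ratio relative to wild type via the comparative CT method."""
    ddct = (ct_target - ct_reference) - (ct_target_wt - ct_reference_wt)
    return float(2.0 ** (-ddct))
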