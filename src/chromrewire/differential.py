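"""Differential accessibility between two states from replicate counts.

Normalization is median-of-ratios (the standard size-factor estimator for
sequencing count tables); the per-region test is a Welch t-test on
log2(normalized count + 1), BH-corrected.  A region is called a gain when
log2FC exceeds the threshold and the adjusted p-value falls below alpha;
losses are symmetric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_core import PeakSet, ValidationError, overlap_query

__all__ = [
    "size_factors",
    "differential_test",
    "gain_loss_sets",
    "cross_genotype_overlap",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Factor_j = median over zero-free regions of count_ij / geometric mean_i.
    """
    X = counts.to_numpy(float)
    nonzero = (X > 0).all(axis=1)
    if not nonzero.any():
        raise ValidationError(
            "no region with all-positive counts; add a pseudocount before normalizing"
        )
    sub = X[nonzero]
    geo = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geo[:, None], axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def differential_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    sf: pd.Series | None = None,
    lfc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region differential test of condition B vs A.

    Returns a table with baseMean, log2FC = log2((mean_norm_B + 1) /
    (mean_norm_A + 1)), Welch p on log2(normalized + 1), BH-adjusted p, and a
    call in {gain, loss, unchanged}.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 replicates")
    if sf is None:
        sf = size_factors(counts[group_a + group_b])
    norm = counts[group_a + group_b] / sf
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    la = np.log2(norm[group_a].to_numpy() + 1.0)
    lb = np.log2(norm[group_b].to_numpy() + 1.0)
    tstat, pval = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    pval = np.where(np.isnan(pval), 1.0, pval)
    padj = multipletests(pval, method="fdr_bh")[1]
    call = np.full(len(counts), "unchanged", dtype=object)
    call[(log2fc > lfc_threshold).to_numpy() & (padj < alpha)] = "gain"
    call[(log2fc < -lfc_threshold).to_numpy() & (padj < alpha)] = "loss"
    return pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            "log2FC": log2fc,
            "pvalue": pval,
            "padj": padj,
            "call": call,
        },
        index=counts.index,
    )


def gain_loss_sets(
    results: pd.DataFrame, regions: PeakSet
) -> tuple[PeakSet, PeakSet]:
    """Partition regions by call into (gain, loss) peak sets, ids preserved."""
    gains = results.index[results["call"] == "gain"]
    losses = results.index[results["call"] == "loss"]
    return regions.subset(gains), regions.subset(losses)


def cross_genotype_overlap(
    gain_a: PeakSet, gain_b: PeakSet
) -> dict[str, object]:
    """Venn decomposition of two peak sets by >= 1 bp overlap.

    Shared is reported from both sides (a peak of A overlapping any peak of B,
    and vice versa); exclusives are the complements.
    """
    pairs = overlap_query(gain_a, gain_b)
    shared_a = set(pairs["a_id"])
    shared_b = set(pairs["b_id"])
    a_only = [p for p in gain_a.ids() if p not in shared_a]
    b_only = [p for p in gain_b.ids() if p not in shared_b]
    return {
        "shared_a": sorted(shared_a),
        "shared_b": sorted(shared_b),
        "a_only": a_only,
        "b_only": b_only,
        "n_shared_a": len(shared_a),
        "n_shared_b": len(shared_b),
        "n_a_only": len(a_only),
        "n_b_only": len(b_only),
    }
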