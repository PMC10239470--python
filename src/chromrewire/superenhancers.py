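"""ROSE-style super-enhancer calling and the cluster-3 vulnerability score.

Acetylation peaks are stitched within 12.5 kb, ranked by total
background-subtracted signal, and the super-enhancer cutoff is the tangent
point of a slope-1 line on the rank curve scaled to the unit square: the point
where occupancy signal begins to rise faster than rank.  A super-enhancer is
"affected" when at least half of its overlapping accessibility peaks belong to
the modestly accessible cluster 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_core import PeakSet, ValidationError, merge_intervals, overlap_query
from .signal_clustering import SignalTrack

__all__ = [
    "SECutoff",
    "stitch",
    "rank_regions",
    "find_cutoff",
    "se_affectedness",
]

DEFAULT_STITCH_GAP = 12_500


@dataclass
class SECutoff:
    """Scaled tangent point and the signal threshold it implies."""

    x_scaled: float
    y_scaled: float
    threshold: float  # original signal units
    n_super: int


def stitch(peaks: PeakSet, stitch_gap: int = DEFAULT_STITCH_GAP) -> PeakSet:
    """Merge peaks within ``stitch_gap`` bp into stitched regions.

    Constituent peak ids are carried in the ``source_ids`` column.
    """
    stitched = merge_intervals(peaks, gap=stitch_gap)
    df = stitched.df.copy()
    df["peak_id"] = [f"stitched_{i + 1}" for i in range(len(df))]
    return PeakSet(df)


def rank_regions(
    regions: PeakSet,
    chip: SignalTrack,
    input_track: SignalTrack | None = None,
) -> pd.DataFrame:
    """Rank stitched regions by background-subtracted total signal.

    rank_signal = max(0, sum(chip) - sum(input)) per region (per-bp integral);
    rows sorted ascending with ranks 1..n.
    """
    rows = []
    for chrom, s, e, rid in zip(
        regions.df["chrom"], regions.df["start"], regions.df["end"], regions.df["peak_id"]
    ):
        sig = chip.region_sum(chrom, int(s), int(e))
        if input_track is not None:
            sig -= input_track.region_sum(chrom, int(s), int(e))
        rows.append((rid, chrom, int(s), int(e), max(0.0, sig)))
    out = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "rank_signal"])
    out = out.sort_values(["rank_signal", "region_id"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def find_cutoff(ranked: pd.DataFrame) -> tuple[SECutoff, pd.DataFrame]:
    """Slope-1 tangent cutoff on the scaled rank curve.

    With ranks x and signals y both scaled to [0, 1], the cutoff index is the
    largest i minimizing (y_i - x_i); regions with signal strictly above the
    threshold are super-enhancers.
    """
    if len(ranked) < 3:
        raise ValidationError("need >= 3 ranked regions")
    y_raw = ranked.sort_values("rank")["rank_signal"].to_numpy(float)
    if np.allclose(y_raw, y_raw[0]):
        raise ValidationError("all rank signals equal: no cutoff (no SEs called)")
    n = len(y_raw)
    x = (np.arange(n)) / (n - 1)
    y = (y_raw - y_raw.min()) / (y_raw.max() - y_raw.min())
    diff = y - x
    best = np.flatnonzero(diff == diff.min()).max()  # largest index on ties
    threshold = float(y_raw[best])
    out = ranked.sort_values("rank").copy()
    out["is_super"] = out["rank_signal"] > threshold
    cutoff = SECutoff(float(x[best]), float(y[best]), threshold, int(out["is_super"].sum()))
    return cutoff, out.reset_index(drop=True)


def se_affectedness(
    ses: pd.DataFrame,
    atac: PeakSet,
    cluster3_ids: set[str],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per super-enhancer, the fraction of overlapping ATAC peaks in cluster 3.

    Affected iff fraction >= threshold; regions with no overlapping ATAC peak
    get fraction 0 and are never affected.
    """
    unknown = cluster3_ids - set(atac.ids())
    if unknown:
        raise ValidationError(f"cluster3 ids not in ATAC set: {sorted(unknown)[:3]}...")
    se_peaks = PeakSet(
        ses.rename(columns={"region_id": "peak_id"})[["chrom", "start", "end", "peak_id"]]
    )
    pairs = overlap_query(se_peaks, atac)
    out = ses.copy()
    n_overlap = pairs.groupby("a_id").size()
    n_c3 = pairs[pairs["b_id"].isin(cluster3_ids)].groupby("a_id").size()
    out["n_atac"] = out["region_id"].map(n_overlap).fillna(0).astype(int)
    out["n_cluster3"] = out["region_id"].map(n_c3).fillna(0).astype(int)
    with np.errstate(invalid="ignore"):
        frac = np.where(out["n_atac"] > 0, out["n_cluster3"] / out["n_atac"].where(out["n_atac"] > 0, 1), 0.0)
    out["fraction_cluster3"] = frac
    out["affected"] = (out["n_atac"] > 0) & (out["fraction_cluster3"] >= threshold)
    return out
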