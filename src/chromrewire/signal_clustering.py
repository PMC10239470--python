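"""Signal quantification over regions, accessibility-class clustering, and
chromatin-state enrichment.

The clustering follows the heatmap convention: per-region normalized signal in
each sample, k-means with k=3, and clusters relabeled so cluster 1 holds the
most accessible regions and cluster 3 the modestly accessible ones (the class
that loses accessibility under the mutant condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score  # noqa: F401  (re-export for callers)
from statsmodels.stats.multitest import multipletests

from .genomic_core import (
    ChromStateSegmentation,
    Genome,
    PeakSet,
    ValidationError,
    atomic_write,
    merge_intervals,
    overlap_query,
)
from .differential import size_factors

__all__ = [
    "SignalTrack",
    "quantify_signal",
    "kmeans_partition",
    "state_enrichment",
    "QuartileAtlas",
    "build_quartile_atlas",
    "cluster_quartile_intersection",
]


class SignalTrack:
    """A binned signal track (bedGraph semantics: value over [start, end))."""

    def __init__(self, df: pd.DataFrame):
        for col in ("chrom", "start", "end", "value"):
            if col not in df.columns:
                raise ValidationError(f"signal track missing column {col}")
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self._by_chrom = {
            chrom: (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(float),
            )
            for chrom, sub in self.df.groupby("chrom", sort=False)
        }

    @classmethod
    def read_bedgraph(cls, path: str) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            comment="#",
        )
        return cls(df)

    def write_bedgraph(self, path: str) -> None:
        with atomic_write(path) as fh:
            self.df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")

    @classmethod
    def from_peak_values(cls, peaks: PeakSet, values: pd.Series) -> "SignalTrack":
        df = peaks.df[["chrom", "start", "end"]].copy()
        df["value"] = values.reindex(peaks.ids()).to_numpy()
        return cls(df)

    def chroms(self) -> set[str]:
        return set(self._by_chrom)

    def overlapping(self, chrom: str, start: int, end: int):
        """(values, overlap_bp) of bins intersecting [start, end)."""
        if chrom not in self._by_chrom:
            return None
        starts, ends, vals = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return np.array([]), np.array([], dtype=np.int64)
        s = starts[lo:hi]
        e = ends[lo:hi]
        ov = np.minimum(e, end) - np.maximum(s, start)
        keep = ov > 0
        return vals[lo:hi][keep], ov[keep]

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Per-bp integral of the track over [start, end)."""
        res = self.overlapping(chrom, start, end)
        if res is None:
            raise ValidationError(f"chromosome {chrom} absent from track")
        vals, ov = res
        return float((vals * ov).sum())


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of each value repeated ``weight`` times (matches np.median)."""
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    wts = weights[order].astype(np.int64)
    cum = np.cumsum(wts)
    total = cum[-1]
    lo_idx = np.searchsorted(cum, (total - 1) // 2 + 1)
    hi_idx = np.searchsorted(cum, total // 2 + 1)
    return float((v[lo_idx] + v[hi_idx]) / 2.0)


def quantify_signal(
    track: SignalTrack, regions: PeakSet, stat: str = "median"
) -> pd.Series:
    """Per-region statistic of track values, weighted by overlapping bp.

    ``median`` reproduces the per-bp brute-force median exactly; ``mean`` is
    the bp-weighted mean.
    """
    if stat not in ("median", "mean"):
        raise ValidationError(f"unknown stat {stat!r}")
    out = []
    for chrom, s, e, pid in zip(
        regions.df["chrom"], regions.df["start"], regions.df["end"], regions.df["peak_id"]
    ):
        res = track.overlapping(chrom, int(s), int(e))
        if res is None:
            raise ValidationError(f"region {pid}: chromosome {chrom} absent from track")
        vals, ov = res
        if len(vals) == 0:
            out.append(0.0)
        elif stat == "median":
            out.append(_weighted_median(vals, ov))
        else:
            out.append(float((vals * ov).sum() / ov.sum()))
    return pd.Series(out, index=regions.df["peak_id"].to_numpy(), name=stat)


def kmeans_partition(
    matrix: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
    order_by: list[str] | None = None,
) -> pd.Series:
    """K-means over rows with clusters relabeled by descending mean signal.

    Cluster 1 has the highest mean signal over ``order_by`` columns (default:
    all columns), cluster k the lowest — so with k=3, cluster 3 holds the
    modestly accessible regions.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(matrix) < k:
        raise ValidationError(f"k={k} exceeds number of rows {len(matrix)}")
    X = matrix.to_numpy(float)
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    order_cols = order_by if order_by is not None else list(matrix.columns)
    key = matrix[order_cols].to_numpy(float).mean(axis=1)
    means = np.array([key[raw == c].mean() for c in range(k)])
    # highest-mean raw cluster becomes label 1
    relabel = np.empty(k, dtype=int)
    relabel[np.argsort(-means)] = np.arange(1, k + 1)
    return pd.Series(relabel[raw], index=matrix.index, name="cluster")


def state_enrichment(
    peaks: PeakSet, seg: ChromStateSegmentation, genome: Genome
) -> pd.DataFrame:
    """Fold enrichment of peaks per chromatin state with binomial significance.

    A peak belongs to the state containing its midpoint.  For a state covering
    a fraction g of the genome, FE = (k/n)/g and the two-sided p-value is
    min(1, 2 * binomial tail), upper tail when FE >= 1 and lower otherwise;
    BH-adjusted across states.
    """
    if genome.total_bp <= 0:
        raise ValidationError("zero-length genome")
    if len(seg.df) == 0:
        raise ValidationError("empty segmentation")
    mids = peaks.midpoints()
    n = len(mids)
    state_of: list[str | None] = []
    seg_by_chrom = {
        chrom: (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["state"].to_numpy(),
        )
        for chrom, sub in seg.df.groupby("chrom", sort=False)
    }
    for chrom, pos in zip(mids["chrom"], mids["pos"]):
        entry = seg_by_chrom.get(chrom)
        if entry is None:
            state_of.append(None)
            continue
        starts, ends, states = entry
        idx = np.searchsorted(starts, pos, side="right") - 1
        if idx >= 0 and pos < ends[idx]:
            state_of.append(states[idx])
        else:
            state_of.append(None)
    counts = pd.Series([s for s in state_of if s is not None]).value_counts()
    bp = seg.state_bp()
    rows = []
    for state in seg.states():
        k = int(counts.get(state, 0))
        g = float(bp[state]) / genome.total_bp
        fe = (k / n) / g if n > 0 and g > 0 else np.nan
        if fe >= 1:
            tail = binom.sf(k - 1, n, g)
        else:
            tail = binom.cdf(k, n, g)
        pval = min(1.0, 2.0 * float(tail))
        rows.append((state, k, n, g, fe, pval))
    out = pd.DataFrame(
        rows, columns=["state", "k", "n", "genome_fraction", "fold_enrichment", "p_value"]
    )
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Developmental quartile atlas


@dataclass
class QuartileAtlas:
    """Merged two-cell-type region atlas ranked by accessibility log2FC."""

    regions: PeakSet  # merged atlas with source_ids
    table: pd.DataFrame  # region_id, log2fc, quartile (Q1..Q4)
    summaries: pd.DataFrame  # per-quartile normalized-count summary


def build_quartile_atlas(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    counts: pd.DataFrame,
    groups: dict[str, list[str]],
    n_quartiles: int = 4,
) -> QuartileAtlas:
    """Merge the two peak sets and split regions into fold-change quartiles.

    ``counts`` is indexed by the original peak ids of both sets; a merged
    region's count is the sum over its constituent peaks.  log2FC of B vs A
    uses size-factor-normalized means with pseudocount 1; regions are sorted
    ascending and split into ``n_quartiles`` parts whose sizes differ by at
    most one (Q1 = most A-specific, Q4 = most B-specific).
    """
    union = pd.concat([peaks_a.df, peaks_b.df], ignore_index=True)
    if len(union) == 0:
        raise ValidationError("empty peak union")
    if union["peak_id"].duplicated().any():
        raise ValidationError("peak ids must be unique across the two sets")
    merged = merge_intervals(PeakSet(union), gap=0)
    # aggregate constituent counts per merged region
    agg = np.zeros((len(merged), counts.shape[1]))
    for r, src in enumerate(merged.df["source_ids"]):
        ids = src.split(",")
        agg[r] = counts.loc[ids].to_numpy(float).sum(axis=0)
    region_counts = pd.DataFrame(
        agg, index=pd.Index(merged.ids(), name="region_id"), columns=counts.columns
    )
    sf = size_factors(region_counts)
    norm = region_counts / sf
    mean_a = norm[groups["A"]].mean(axis=1)
    mean_b = norm[groups["B"]].mean(axis=1)
    log2fc = np.log2((mean_b + 1.0) / (mean_a + 1.0))
    table = pd.DataFrame({"region_id": merged.ids(), "log2fc": log2fc.to_numpy()})
    table = table.sort_values(
        ["log2fc", "region_id"], kind="mergesort"
    ).reset_index(drop=True)
    chunks = np.array_split(np.arange(len(table)), n_quartiles)
    quart = np.empty(len(table), dtype=object)
    for qi, idx in enumerate(chunks, start=1):
        quart[idx] = f"Q{qi}"
    table["quartile"] = quart
    summaries = (
        norm.join(table.set_index("region_id")["quartile"])
        .groupby("quartile")
        .agg(["mean", "median"])
    )
    return QuartileAtlas(merged, table, summaries)


def cluster_quartile_intersection(
    atlas: QuartileAtlas, cluster3: PeakSet
) -> pd.DataFrame:
    """Per-quartile counts and proportions of cluster-3 peaks.

    A peak counts in the quartile of the atlas region it overlaps by the most
    bp (ties toward the lower quartile), so each peak counts once and the
    proportions sum to <= 1; peaks overlapping no region are 'unmatched'.
    """
    qa = atlas.table.set_index("region_id")["quartile"]
    pairs = overlap_query(cluster3, atlas.regions)
    best: dict[str, tuple[int, str]] = {}
    c3 = cluster3.df.set_index("peak_id")
    reg = atlas.regions.df.set_index("peak_id")
    for aid, bid in zip(pairs["a_id"], pairs["b_id"]):
        ps, pe = c3.loc[aid, "start"], c3.loc[aid, "end"]
        rs, re = reg.loc[bid, "start"], reg.loc[bid, "end"]
        ov = min(pe, re) - max(ps, rs)
        q = qa[bid]
        cur = best.get(aid)
        if cur is None or ov > cur[0] or (ov == cur[0] and q < cur[1]):
            best[aid] = (ov, q)
    labels = [q for _, q in best.values()]
    n_total = len(cluster3)
    quartiles = sorted(qa.unique())
    rows = []
    for q in quartiles:
        k = labels.count(q)
        rows.append((q, k, k / n_total if n_total else 0.0))
    unmatched = n_total - len(best)
    rows.append(("unmatched", unmatched, unmatched / n_total if n_total else 0.0))
    return pd.DataFrame(rows, columns=["quartile", "count", "proportion"])
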