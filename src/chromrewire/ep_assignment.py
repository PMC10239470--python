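"""Contact-driven enhancer-promoter assignment and the per-gene
common/unique regulatory-peak classifier.

The contact map is binned (50 kb by default), bins holding at least one gene
promoter are indexed, and every bin interacting with a promoter bin is treated
as regulatory territory of that gene.  A peak whose bin interacts with several
promoter bins is assigned to the promoter with the highest interaction
frequency; residual ties break by genomic distance, then gene id.  A gene is
differentially regulated between two conditions when more than two of its
regulatory peaks are exclusive to either condition (i.e. at least three
condition-specific regions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_core import GeneAnnotation, PeakSet, ValidationError, overlap_query
from .hic import ContactMatrix, distance_decay

__all__ = [
    "PromoterBinIndex",
    "build_promoter_bins",
    "interacting_bins",
    "assign_peaks",
    "classify_gene_regulation",
]

DEFAULT_OE_THRESHOLD = 2.0
DEFAULT_MIN_COUNT = 5
DEFAULT_MAX_DIST = 2_000_000


@dataclass
class PromoterBinIndex:
    """Per-chromosome map of bin index -> gene ids with a TSS in the bin."""

    resolution: int
    bins: dict[str, dict[int, list[str]]]
    tss: dict[str, int]  # gene_id -> tss position

    def genes(self) -> list[str]:
        return sorted(self.tss)


def build_promoter_bins(
    genes: list[GeneAnnotation], resolution: int = 50_000
) -> PromoterBinIndex:
    """Index each gene by the bin containing its TSS (floor(tss/resolution))."""
    bins: dict[str, dict[int, list[str]]] = {}
    tss: dict[str, int] = {}
    for g in genes:
        b = g.tss // resolution
        bins.setdefault(g.chrom, {}).setdefault(b, []).append(g.gene_id)
        tss[g.gene_id] = g.tss
    for chrom in bins:
        for b in bins[chrom]:
            bins[chrom][b].sort()
    return PromoterBinIndex(resolution, bins, tss)


def interacting_bins(
    matrix: ContactMatrix,
    promoter_bin: int,
    oe_threshold: float = DEFAULT_OE_THRESHOLD,
    min_count: float = DEFAULT_MIN_COUNT,
    max_dist: int = DEFAULT_MAX_DIST,
    decay: np.ndarray | None = None,
) -> dict[int, float]:
    """Bins interacting with a promoter bin, with their contact frequencies.

    A bin qualifies when it lies within ``max_dist``, its raw count reaches
    ``min_count``, and its observed / distance-decay-expected ratio reaches
    ``oe_threshold``.  The promoter bin itself always qualifies.
    """
    n = matrix.n_bins
    if not (0 <= promoter_bin < n):
        raise ValidationError(f"promoter bin {promoter_bin} out of range (n={n})")
    if decay is None:
        decay = distance_decay(matrix)["mean_count"].to_numpy()
    row = matrix.matrix[promoter_bin].toarray().ravel()
    max_bins = max_dist // matrix.resolution
    lo = max(0, promoter_bin - max_bins)
    hi = min(n - 1, promoter_bin + max_bins)
    out: dict[int, float] = {promoter_bin: float(row[promoter_bin])}
    for b in range(lo, hi + 1):
        if b == promoter_bin:
            continue
        count = row[b]
        if count < min_count:
            continue
        expected = decay[abs(b - promoter_bin)]
        if expected <= 0 or count / expected < oe_threshold:
            continue
        out[b] = float(count)
    return out


def assign_peaks(
    peaks: PeakSet,
    index: PromoterBinIndex,
    matrices: dict[str, ContactMatrix],
    oe_threshold: float = DEFAULT_OE_THRESHOLD,
    min_count: float = DEFAULT_MIN_COUNT,
    max_dist: int = DEFAULT_MAX_DIST,
) -> pd.DataFrame:
    """Assign each peak (by midpoint bin) to at most one gene.

    Candidates are genes whose promoter bin interacts with the peak's bin;
    the winner has the highest interaction frequency, then the smaller
    bin distance, then the lexicographically smaller gene id.
    """
    # per chromosome: candidate gene contacts per bin
    contact_of: dict[str, dict[int, list[tuple[str, float, int]]]] = {}
    for chrom, m in matrices.items():
        if m.resolution != index.resolution:
            raise ValidationError("matrix resolution differs from promoter index")
        decay = distance_decay(m)["mean_count"].to_numpy()
        per_bin: dict[int, list[tuple[str, float, int]]] = {}
        for pbin, gids in index.bins.get(chrom, {}).items():
            inter = interacting_bins(m, pbin, oe_threshold, min_count, max_dist, decay)
            for b, freq in inter.items():
                for gid in gids:
                    per_bin.setdefault(b, []).append((gid, freq, abs(b - pbin)))
        contact_of[chrom] = per_bin

    mids = peaks.midpoints()
    rows = []
    for pid, chrom, pos in zip(mids["peak_id"], mids["chrom"], mids["pos"]):
        b = int(pos) // index.resolution
        cands = contact_of.get(chrom, {}).get(b, [])
        if not cands:
            rows.append((pid, None, np.nan, 0))
            continue
        # max frequency, then min distance, then lexicographic gene id
        best = min(cands, key=lambda t: (-t[1], t[2], t[0]))
        rows.append((pid, best[0], best[1], len(cands)))
    return pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "frequency", "n_competing"]
    ).set_index("peak_id")


def classify_gene_regulation(
    assign_a: pd.DataFrame,
    assign_b: pd.DataFrame,
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    unique_threshold: int = 2,
) -> pd.DataFrame:
    """Per gene: common and condition-exclusive regulatory peak counts.

    A gene's peaks from the two conditions are matched by >= 1 bp overlap;
    matched pairs count as common, unmatched as unique to their condition.
    Differential iff n_unique_A > unique_threshold or n_unique_B >
    unique_threshold (default: more than two, i.e. at least three
    condition-specific regions).
    """
    a = assign_a.dropna(subset=["gene_id"])
    b = assign_b.dropna(subset=["gene_id"])
    genes = sorted(set(a["gene_id"]) | set(b["gene_id"]))
    pa_by_gene = a.groupby("gene_id").groups
    pb_by_gene = b.groupby("gene_id").groups
    rows = []
    for gid in genes:
        ids_a = list(pa_by_gene.get(gid, []))
        ids_b = list(pb_by_gene.get(gid, []))
        if ids_a and ids_b:
            pairs = overlap_query(peaks_a.subset(ids_a), peaks_b.subset(ids_b))
            matched_a = set(pairs["a_id"])
            matched_b = set(pairs["b_id"])
        else:
            matched_a = matched_b = set()
        n_common = len(matched_a)
        n_unique_a = len(ids_a) - len(matched_a)
        n_unique_b = len(ids_b) - len(matched_b)
        differential = n_unique_a > unique_threshold or n_unique_b > unique_threshold
        rows.append((gid, n_common, n_unique_a, n_unique_b, differential))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_common", "n_unique_A", "n_unique_B", "differential"]
    ).set_index("gene_id")
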