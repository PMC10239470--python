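"""Cis contact matrices, loop-strength scoring and aggregate peak analysis.

A loop's strength is ``log2(observed / expected)`` where the expected value is
the mean of the "bottom-left" local neighborhood of the loop pixel — the block
below and to the left of pixel ``(i, j)`` (toward the diagonal), excluding the
peak's own ``(2p+1)^2`` neighborhood.  A loop is called weakened between two
conditions when its strength drops by at least ``log2(fold)`` (default fold
1.5) at identical coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomic_core import Genome, PeakSet, GeneAnnotation, atomic_write

__all__ = [
    "ContactMatrix",
    "APAResult",
    "load_contacts",
    "write_contacts",
    "read_bedpe",
    "write_bedpe",
    "distance_decay",
    "bottom_left_expected",
    "loop_strength",
    "compare_conditions",
    "apa",
    "peaks_in_anchors",
    "genes_near_anchors",
]

DEFAULT_PEAK_RADIUS = 2  # p: half-width of the excluded peak neighborhood
DEFAULT_WINDOW = 5  # w: half-width of the local window


class ContactError(ValueError):
    """Raised for malformed contact inputs."""


class ContactMatrix:
    """Symmetric binned cis contact counts for one chromosome."""

    def __init__(self, chrom: str, resolution: int, matrix: sp.spmatrix,
                 weights: np.ndarray | None = None):
        if matrix.shape[0] != matrix.shape[1]:
            raise ContactError("contact matrix must be square")
        self.chrom = chrom
        self.resolution = int(resolution)
        self.matrix = sp.csr_matrix(matrix)
        self.weights = weights

    @classmethod
    def from_coo(
        cls,
        chrom: str,
        resolution: int,
        n_bins: int,
        i: np.ndarray,
        j: np.ndarray,
        v: np.ndarray,
    ) -> "ContactMatrix":
        """Build a symmetric matrix from upper-triangle (or mixed) triplets.

        Triplets are canonicalized to (min, max); duplicates are summed; each
        off-diagonal value is mirrored to both (i, j) and (j, i).
        """
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        v = np.asarray(v, dtype=np.float64)
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        upper = sp.coo_matrix((v, (lo, hi)), shape=(n_bins, n_bins)).tocsr()
        upper.sum_duplicates()
        diag = sp.diags(upper.diagonal())
        full = upper + upper.T - diag
        return cls(chrom, resolution, full)

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def __getitem__(self, key) -> float:
        i, j = key
        return float(self.matrix[i, j])

    def bin_of(self, pos: int) -> int:
        return int(pos) // self.resolution


def load_contacts(path: str, genome: Genome, resolution: int) -> dict[str, ContactMatrix]:
    """Read COO triplet text ``chrom<TAB>bin_i<TAB>bin_j<TAB>count``.

    Counts are symmetrized (assigned to both (i, j) and (j, i)); duplicate
    triplets are summed.  Returns one matrix per chromosome in the genome.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "bin_i", "bin_j", "count"],
            dtype={"chrom": str, "bin_i": np.int64, "bin_j": np.int64, "count": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ContactError(f"{path}: malformed COO triplet text ({exc})") from exc
    unknown = ~df["chrom"].isin(list(genome))
    if unknown.any():
        lineno = int(np.flatnonzero(unknown)[0]) + 1
        raise ContactError(f"{path}:{lineno}: unknown chromosome {df['chrom'][unknown].iloc[0]}")
    out = {}
    for chrom in genome:
        n_bins = -(-genome[chrom] // resolution)
        sub = df[df["chrom"] == chrom]
        bad = (
            (sub["bin_i"] < 0) | (sub["bin_i"] >= n_bins)
            | (sub["bin_j"] < 0) | (sub["bin_j"] >= n_bins)
        )
        if bad.any():
            lineno = int(sub.index[bad][0]) + 1
            raise ContactError(f"{path}:{lineno}: bin index out of range")
        out[chrom] = ContactMatrix.from_coo(
            chrom, resolution, n_bins,
            sub["bin_i"].to_numpy(), sub["bin_j"].to_numpy(), sub["count"].to_numpy(),
        )
    return out


def write_contacts(matrices: dict[str, ContactMatrix], path: str) -> None:
    """Write the upper triangle (incl. diagonal) as COO triplet text."""
    with atomic_write(path) as fh:
        for chrom in matrices:
            m = sp.triu(matrices[chrom].matrix).tocoo()
            order = np.lexsort((m.col, m.row))
            df = pd.DataFrame(
                {"chrom": chrom, "i": m.row[order], "j": m.col[order], "v": m.data[order]}
            )
            if (df["v"] == df["v"].astype(np.int64)).all():
                df["v"] = df["v"].astype(np.int64)
            df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_bedpe(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    extra = ["loop_id"] if ncol >= 7 else []
    df = df.iloc[:, : 6 + len(extra)]
    df.columns = names + extra
    if not extra:
        df["loop_id"] = [f"loop_{k + 1:04d}" for k in range(len(df))]
    return df


def write_bedpe(loops: pd.DataFrame, path: str) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "loop_id"]
    with atomic_write(path) as fh:
        loops[cols].to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Distance decay


def distance_decay(matrix: ContactMatrix) -> pd.DataFrame:
    """Mean contact per bin offset (zero cells included)."""
    n = matrix.n_bins
    sums = np.zeros(n)
    coo = sp.triu(matrix.matrix).tocoo()
    d = coo.col - coo.row
    np.add.at(sums, d, coo.data)
    counts = n - np.arange(n)
    return pd.DataFrame(
        {
            "distance_bins": np.arange(n),
            "distance_bp": np.arange(n) * matrix.resolution,
            "mean_count": sums / counts,
        }
    )


def fit_decay_exponent(decay: pd.DataFrame, d_min: int = 1, d_max: int | None = None) -> float:
    """Log-log OLS slope of mean contact vs (d+1); returns the slope."""
    sub = decay[decay["distance_bins"] >= d_min]
    if d_max is not None:
        sub = sub[sub["distance_bins"] <= d_max]
    sub = sub[sub["mean_count"] > 0]
    x = np.log(sub["distance_bins"].to_numpy() + 1.0)
    y = np.log(sub["mean_count"].to_numpy())
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Loop strength


def bottom_left_expected(
    matrix: ContactMatrix,
    pixel: tuple[int, int],
    p: int = DEFAULT_PEAK_RADIUS,
    w: int = DEFAULT_WINDOW,
) -> float | None:
    """Mean of the bottom-left block ``{(a, b): i+p < a <= i+w, j-w <= b < j-p}``.

    Returns None (undefined) when the window does not fit between the pixel
    and the diagonal or runs off the matrix edge.
    """
    i, j = pixel
    n = matrix.n_bins
    if not (0 <= i < n and 0 <= j < n):
        raise ContactError(f"pixel {pixel} out of range for {n} bins")
    if j - i <= p + w or i + w >= n or j - w < 0:
        return None
    block = matrix.matrix[i + p + 1 : i + w + 1, j - w : j - p].toarray()
    return float(block.mean())


def _loop_pixels(loops: pd.DataFrame, resolution: int) -> pd.DataFrame:
    """Anchor midpoints -> ordered (bin1 < bin2) pixels at the resolution."""
    out = loops.copy()
    if (out["chrom1"] != out["chrom2"]).any():
        raise ContactError("trans loop in a cis-only loop list")
    m1 = ((out["start1"] + out["end1"]) // 2) // resolution
    m2 = ((out["start2"] + out["end2"]) // 2) // resolution
    out["bin1"] = np.minimum(m1, m2).astype(int)
    out["bin2"] = np.maximum(m1, m2).astype(int)
    return out


def loop_strength(
    loops: pd.DataFrame,
    matrices: dict[str, ContactMatrix],
    p: int = DEFAULT_PEAK_RADIUS,
    w: int = DEFAULT_WINDOW,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-loop ``log2((observed + pc) / (expected + pc))``.

    Observed is the count at the loop pixel; expected is the bottom-left
    local mean.  NaN where the local window does not fit.
    """
    first = next(iter(matrices.values()))
    px = _loop_pixels(loops, first.resolution)
    strengths = []
    for _, row in px.iterrows():
        chrom = row["chrom1"]
        if chrom not in matrices:
            raise ContactError(f"no contact matrix for chromosome {chrom}")
        m = matrices[chrom]
        i, j = int(row["bin1"]), int(row["bin2"])
        exp = bottom_left_expected(m, (i, j), p, w)
        if exp is None:
            strengths.append(np.nan)
            continue
        obs = m[i, j]
        strengths.append(math.log2((obs + pseudocount) / (exp + pseudocount)))
    return pd.Series(strengths, index=px["loop_id"].to_numpy(), name="strength")


def compare_conditions(
    loops: pd.DataFrame,
    matrices_a: dict[str, ContactMatrix],
    matrices_b: dict[str, ContactMatrix],
    fold: float = 1.5,
    p: int = DEFAULT_PEAK_RADIUS,
    w: int = DEFAULT_WINDOW,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify each reference loop as weakened / strengthened / unchanged.

    The same loop coordinates are scored in both conditions; weakened means
    ``strength_A - strength_B >= log2(fold)`` and symmetrically for
    strengthened.  Loops with an undefined strength in either condition are
    classed ``undefined`` and excluded from the reported fractions.
    """
    sa = loop_strength(loops, matrices_a, p, w, pseudocount)
    sb = loop_strength(loops, matrices_b, p, w, pseudocount)
    cut = math.log2(fold)
    delta = sa - sb
    cls = np.full(len(delta), "unchanged", dtype=object)
    cls[(delta >= cut).to_numpy()] = "weakened"
    cls[(-delta >= cut).to_numpy()] = "strengthened"
    cls[(sa.isna() | sb.isna()).to_numpy()] = "undefined"
    out = pd.DataFrame(
        {
            "loop_id": sa.index,
            "strength_A": sa.to_numpy(),
            "strength_B": sb.to_numpy(),
            "delta": delta.to_numpy(),
            "class": cls,
        }
    )
    defined = out[out["class"] != "undefined"]
    n_def = max(len(defined), 1)
    fractions = {
        "weakened": float((defined["class"] == "weakened").sum()) / n_def,
        "strengthened": float((defined["class"] == "strengthened").sum()) / n_def,
        "unchanged": float((defined["class"] == "unchanged").sum()) / n_def,
        "n_defined": float(len(defined)),
        "n_undefined": float(len(out) - len(defined)),
    }
    return out, fractions


# ---------------------------------------------------------------------------
# Aggregate peak analysis


@dataclass
class APAResult:
    """Mean observed/expected submatrix around loop pixels."""

    matrix: np.ndarray  # (2w+1) x (2w+1)
    center: float
    p2ll: float
    n_used: int
    n_excluded: int


def apa(
    loops: pd.DataFrame,
    matrices: dict[str, ContactMatrix],
    w: int = 10,
    p: int = 3,
) -> APAResult:
    """Aggregate the (2w+1)^2 observed/expected submatrix over loop pixels.

    Expected per entry is the matrix-wide distance-decay mean at that entry's
    own diagonal offset.  P2LL is the center value over the mean of the p x p
    lower-left corner block.  Loops whose window crosses the diagonal or the
    matrix edge are excluded (and counted).
    """
    first = next(iter(matrices.values()))
    px = _loop_pixels(loops, first.resolution)
    decay_by_chrom = {
        c: distance_decay(m)["mean_count"].to_numpy() for c, m in matrices.items()
    }
    size = 2 * w + 1
    acc = np.zeros((size, size))
    n_used = n_excluded = 0
    for _, row in px.iterrows():
        chrom = row["chrom1"]
        m = matrices[chrom]
        i, j = int(row["bin1"]), int(row["bin2"])
        n = m.n_bins
        if i - w < 0 or j + w >= n or j - i <= 2 * w:
            n_excluded += 1
            continue
        sub = m.matrix[i - w : i + w + 1, j - w : j + w + 1].toarray()
        offs = (j - i) + (np.arange(size)[None, :] - np.arange(size)[:, None])
        expected = decay_by_chrom[chrom][offs]
        acc += sub / np.maximum(expected, 1e-12)
        n_used += 1
    if n_used == 0:
        raise ContactError("no loop with a fitting APA window")
    mean_oe = acc / n_used
    center = float(mean_oe[w, w])
    lower_left = mean_oe[size - p :, :p]
    p2ll = center / float(lower_left.mean())
    return APAResult(mean_oe, center, p2ll, n_used, n_excluded)


# ---------------------------------------------------------------------------
# Anchor integration


def peaks_in_anchors(loops: pd.DataFrame, peaks: PeakSet) -> pd.DataFrame:
    """Peaks overlapping (>=1 bp) either anchor of each loop."""
    trees = peaks.trees()
    rows = []
    for _, row in loops.iterrows():
        hits: set[str] = set()
        for side in ("1", "2"):
            tree = trees.get(row[f"chrom{side}"])
            if tree is None:
                continue
            for hit in tree.overlap(int(row[f"start{side}"]), int(row[f"end{side}"])):
                hits.add(peaks.df.loc[hit.data, "peak_id"])
        for pid in sorted(hits):
            rows.append((row["loop_id"], pid))
    return pd.DataFrame(rows, columns=["loop_id", "peak_id"])


def genes_near_anchors(
    loops: pd.DataFrame, genes: list[GeneAnnotation], max_dist: int = 10_000
) -> pd.DataFrame:
    """Genes whose TSS lies strictly within ``max_dist`` bp of either anchor.

    Edge distance, 0 when the TSS is inside the anchor; strict inequality.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for _, row in loops.iterrows():
        found: set[str] = set()
        for side in ("1", "2"):
            chrom = row[f"chrom{side}"]
            s, e = int(row[f"start{side}"]), int(row[f"end{side}"])
            for g in by_chrom.get(chrom, []):
                if s <= g.tss < e:
                    d = 0
                elif g.tss < s:
                    d = s - g.tss
                else:
                    d = g.tss - e
                if d < max_dist:
                    found.add(g.gene_id)
        for gid in sorted(found):
            rows.append((row["loop_id"], gid))
    return pd.DataFrame(rows, columns=["loop_id", "gene_id"])
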