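"""Genome model, interval algebra and standard-format I/O.

All coordinates are BED-style: 0-based, half-open ``[start, end)``.  Touching
intervals (``a.end == b.start``) never overlap.  Any printed 1-based input must
be converted at the parser boundary; everything downstream assumes this single
convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Genome",
    "GeneAnnotation",
    "PeakSet",
    "ChromStateSegmentation",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "merge_intervals",
    "overlap_query",
    "annotate_genomic_category",
    "nearest_tss",
    "atomic_write",
]

PROMOTER_UPSTREAM = 10_000
PROMOTER_DOWNSTREAM = 2_000


class BedParseError(ValueError):
    """Raised when a BED-like file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when coordinates or identifiers violate an invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genome:
    """Ordered map of chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        self._sizes: dict[str, int] = {}
        for name, length in sizes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")
            if name in self._sizes:
                raise ValidationError(f"duplicate chromosome {name}")
            self._sizes[name] = int(length)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def to_file(self, path: str) -> None:
        with atomic_write(path) as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its TSS and body extent.

    ``tss`` coincides with ``body.start`` on the + strand and with
    ``body.end - 1`` on the − strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.body.start <= self.tss < self.body.end):
            raise ValidationError(f"gene {self.gene_id}: TSS outside gene body")

    def promoter_window(
        self,
        upstream: int = PROMOTER_UPSTREAM,
        downstream: int = PROMOTER_DOWNSTREAM,
    ) -> GenomicInterval:
        """Strand-oriented promoter window around the TSS (half-open)."""
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream, self.tss + upstream
        return GenomicInterval(self.chrom, max(0, start), max(1, end))


class PeakSet:
    """A set of identified genomic intervals, optionally with signal columns.

    Backed by a DataFrame with columns ``chrom``, ``start``, ``end``,
    ``peak_id`` (+ any extra columns), kept sorted by (chrom, start, end).
    """

    REQUIRED = ("chrom", "start", "end", "peak_id")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"PeakSet missing columns: {missing}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df[(df["start"] < 0) | (df["start"] >= df["end"])].iloc[0]
            raise ValidationError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if df["peak_id"].duplicated().any():
            dup = df.loc[df["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise ValidationError(f"duplicate peak_id {dup!r}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]], ids: Iterable[str] | None = None
    ) -> "PeakSet":
        rows = list(intervals)
        if ids is None:
            ids = [f"peak_{i + 1}" for i in range(len(rows))]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df["peak_id"] = list(ids)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a = self.df[list(self.REQUIRED)].reset_index(drop=True)
        b = other.df[list(self.REQUIRED)].reset_index(drop=True)
        return a.equals(b)

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, s, e)
            for c, s, e in zip(self.df["chrom"], self.df["start"], self.df["end"])
        ]

    def ids(self) -> list[str]:
        return list(self.df["peak_id"])

    def subset(self, ids: Iterable[str]) -> "PeakSet":
        wanted = set(ids)
        return PeakSet(self.df[self.df["peak_id"].isin(wanted)])

    def midpoints(self) -> pd.DataFrame:
        out = self.df[["chrom", "peak_id"]].copy()
        out["pos"] = (self.df["start"] + self.df["end"]) // 2
        return out

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees keyed by peak index."""
        trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            t = IntervalTree()
            for idx, s, e in zip(sub.index, sub["start"], sub["end"]):
                t.addi(int(s), int(e), idx)
            trees[chrom] = t
        return trees


class ChromStateSegmentation:
    """Non-overlapping labeled intervals (chromatin states)."""

    def __init__(self, df: pd.DataFrame):
        for col in ("chrom", "start", "end", "state"):
            if col not in df.columns:
                raise ValidationError(f"segmentation missing column {col}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        prev_end = df.groupby("chrom")["end"].shift(1)
        if (df["start"] < prev_end.fillna(-1)).any():
            raise ValidationError("segmentation intervals overlap")
        self.df = df

    def state_bp(self) -> pd.Series:
        width = self.df["end"] - self.df["start"]
        return width.groupby(self.df["state"]).sum()

    def states(self) -> list[str]:
        return sorted(self.df["state"].unique())


# ---------------------------------------------------------------------------
# I/O


class atomic_write:
    """Context manager writing to ``path`` via a temp file + rename."""

    def __init__(self, path: str):
        self.path = path
        self.tmp = f"{path}.tmp.{os.getpid()}"

    def __enter__(self):
        os.makedirs(os.path.dirname(os.path.abspath(self.path)), exist_ok=True)
        self._fh = open(self.tmp, "w")
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        self._fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False


def read_bed(path: str) -> PeakSet:
    """Read a BED3/BED4/BED6 file into a :class:`PeakSet`.

    Ids come from column 4 when present, else ``peak_<n>`` (1-based).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not (0 <= start < end):
                raise ValidationError(
                    f"{path}:{lineno}: invalid interval {parts[0]}:{start}-{end}"
                )
            name = parts[3] if len(parts) >= 4 and parts[3] not in ("", ".") else None
            rows.append((parts[0], start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"])
    auto = df["peak_id"].isna()
    df.loc[auto, "peak_id"] = [f"peak_{i + 1}" for i in np.flatnonzero(auto.to_numpy())]
    return PeakSet(df)


def write_bed(peaks: PeakSet, path: str, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end", "peak_id"] + (extra_cols or [])
    with atomic_write(path) as fh:
        peaks.df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str) -> Genome:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return Genome(sizes)


def read_segmentation(path: str) -> ChromStateSegmentation:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "state"],
        usecols=[0, 1, 2, 3],
    )
    return ChromStateSegmentation(df)


def write_segmentation(seg: ChromStateSegmentation, path: str) -> None:
    with atomic_write(path) as fh:
        seg.df[["chrom", "start", "end", "state"]].to_csv(
            fh, sep="\t", header=False, index=False
        )


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(peaks: PeakSet, gap: int = 0) -> PeakSet:
    """Union intervals separated by at most ``gap`` bp.

    Output is sorted and non-overlapping; each merged record carries the
    constituent ids in a ``source_ids`` column (comma-joined, input order).
    """
    if gap < 0:
        raise ValidationError("gap must be >= 0")
    df = peaks.df
    out_rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["peak_id"].to_numpy()
        cur_s, cur_e, cur_ids = starts[0], ends[0], [ids[0]]
        for s, e, pid in zip(starts[1:], ends[1:], ids[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, e)
                cur_ids.append(pid)
            else:
                out_rows.append((chrom, cur_s, cur_e, ",".join(cur_ids)))
                cur_s, cur_e, cur_ids = s, e, [pid]
        out_rows.append((chrom, cur_s, cur_e, ",".join(cur_ids)))
    out = pd.DataFrame(out_rows, columns=["chrom", "start", "end", "source_ids"])
    out["peak_id"] = [f"merged_{i + 1}" for i in range(len(out))]
    return PeakSet(out[["chrom", "start", "end", "peak_id", "source_ids"]])


def overlap_query(a: PeakSet, b: PeakSet) -> pd.DataFrame:
    """All pairs of intervals of ``a`` and ``b`` sharing >= 1 bp.

    Returns a DataFrame with columns ``a_id``, ``b_id``.
    """
    trees = b.trees()
    pairs = []
    for chrom, s, e, aid in zip(
        a.df["chrom"], a.df["start"], a.df["end"], a.df["peak_id"]
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(int(s), int(e)):
            pairs.append((aid, b.df.loc[hit.data, "peak_id"]))
    out = pd.DataFrame(pairs, columns=["a_id", "b_id"])
    return out.sort_values(["a_id", "b_id"], kind="mergesort").reset_index(drop=True)


def annotate_genomic_category(
    peaks: PeakSet,
    genes: list[GeneAnnotation],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.Series:
    """Classify peaks as promoter / gene_body / distal_intergenic.

    Promoter = overlap with any strand-oriented promoter window
    (default −10 kb upstream / +2 kb downstream of a TSS); promoter takes
    precedence over gene body.
    """
    if not genes:
        raise ValidationError("gene list is empty")
    prom = IntervalTreeIndex(
        (g.chrom, w.start, w.end)
        for g in genes
        for w in (g.promoter_window(upstream, downstream),)
    )
    body = IntervalTreeIndex((g.chrom, g.body.start, g.body.end) for g in genes)
    cats = []
    for chrom, s, e in zip(peaks.df["chrom"], peaks.df["start"], peaks.df["end"]):
        if prom.any_overlap(chrom, s, e):
            cats.append("promoter")
        elif body.any_overlap(chrom, s, e):
            cats.append("gene_body")
        else:
            cats.append("distal_intergenic")
    return pd.Series(cats, index=peaks.df["peak_id"].to_numpy(), name="category")


class IntervalTreeIndex:
    """Thin per-chromosome intervaltree wrapper for membership queries."""

    def __init__(self, triples: Iterable[tuple[str, int, int]]):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, s, e in triples:
            self._trees.setdefault(chrom, IntervalTree()).addi(int(s), int(e))

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(int(start), int(end)))


def nearest_tss(peaks: PeakSet, genes: list[GeneAnnotation]) -> pd.DataFrame:
    """Per peak, the nearest-TSS gene and signed distance in bp.

    Distance is 0 when the TSS lies inside the peak, otherwise the distance
    from the nearer peak edge (``start`` or ``end``) to the TSS; the sign is
    negative when the TSS lies to the left of the peak.  Ties on absolute
    distance break toward the lexicographically smaller gene id.
    """
    if not genes:
        raise ValidationError("gene list is empty")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for lst in by_chrom.values():
        lst.sort()
    rows = []
    for chrom, s, e, pid in zip(
        peaks.df["chrom"], peaks.df["start"], peaks.df["end"], peaks.df["peak_id"]
    ):
        cands = by_chrom.get(chrom)
        if not cands:
            rows.append((pid, None, np.nan))
            continue
        tss_arr = np.array([t for t, _ in cands])
        # signed distance per spec convention: 0 inside, edge-to-TSS otherwise
        dist = np.where(
            (tss_arr >= s) & (tss_arr < e),
            0,
            np.where(tss_arr < s, tss_arr - s, tss_arr - e),
        )
        order = np.lexsort(([g for _, g in cands], np.abs(dist)))
        best = order[0]
        rows.append((pid, cands[best][1], int(dist[best])))
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"]).set_index(
        "peak_id"
    )
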