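"""Quantification, accessibility clustering, state enrichment, quartiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom
from sklearn.metrics import adjusted_rand_score

from chromrewire import (
    PeakSet,
    SignalTrack,
    build_quartile_atlas,
    cluster_quartile_intersection,
    kmeans_partition,
    quantify_signal,
    state_enrichment,
)
from chromrewire.genomic_core import ChromStateSegmentation, Genome, ValidationError


def track_from(rows):
    return SignalTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


class TestQuantifySignal:
    def test_median_of_bin_values(self):
        track = track_from([("chr1", 0, 10, 1), ("chr1", 10, 20, 2), ("chr1", 20, 30, 9)])
        regions = PeakSet.from_intervals([("chr1", 0, 30)], ids=["r"])
        assert quantify_signal(track, regions)["r"] == 2

    def test_singleton_bin(self):
        track = track_from([("chr1", 0, 100, 7)])
        regions = PeakSet.from_intervals([("chr1", 10, 50)], ids=["r"])
        assert quantify_signal(track, regions)["r"] == 7

    def test_missing_chromosome_names_region(self):
        track = track_from([("chr1", 0, 100, 1)])
        regions = PeakSet.from_intervals([("chr2", 0, 50)], ids=["lonely"])
        with pytest.raises(ValidationError, match="lonely"):
            quantify_signal(track, regions)

    @pytest.mark.parametrize("stat", ["median", "mean"])
    def test_matches_per_bp_brute_force(self, stat):
        rng = np.random.default_rng(11)
        bounds = np.sort(rng.choice(np.arange(1, 2_000), size=150, replace=False))
        bounds = np.concatenate(([0], bounds, [2_000]))
        vals = rng.integers(0, 50, len(bounds) - 1).astype(float)
        track = track_from([
            ("chr1", s, e, v) for s, e, v in zip(bounds[:-1], bounds[1:], vals)
        ])
        per_bp = np.repeat(vals, np.diff(bounds))
        regions = []
        for k in range(200):
            s = int(rng.integers(0, 1_990))
            e = int(rng.integers(s + 1, 2_000))
            regions.append(("chr1", s, e))
        ps = PeakSet.from_intervals(regions, ids=[f"r{k}" for k in range(200)])
        got = quantify_signal(track, ps, stat=stat)
        for (chrom, s, e), rid in zip(regions, [f"r{k}" for k in range(200)]):
            ref = np.median(per_bp[s:e]) if stat == "median" else per_bp[s:e].mean()
            assert got[rid] == pytest.approx(ref), (s, e)


class TestKmeansPartition:
    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(5)
        truth = np.repeat([1, 2, 3], [300, 400, 300])
        means = np.array([10, 3, 0.5])[truth - 1]
        X = pd.DataFrame({
            "control": means + rng.normal(0, 0.2, len(truth)),
            "mutant": means + rng.normal(0, 0.2, len(truth)),
        })
        labels = kmeans_partition(X, k=3, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_duplicate_rows_co_cluster(self):
        X = pd.DataFrame({"a": [5.0, 5.0, 1.0, 1.0, 9.0, 9.0]})
        labels = kmeans_partition(X, k=3, seed=0)
        assert labels.iloc[0] == labels.iloc[1]
        assert labels.iloc[2] == labels.iloc[3]
        assert labels.iloc[4] == labels.iloc[5]

    def test_relabeling_orders_cluster_means(self, landscape):
        labels = kmeans_partition(landscape.signal, k=3, seed=0, order_by=["control"])
        m = [landscape.signal["control"][labels == c].mean() for c in (1, 2, 3)]
        assert m[0] >= m[1] >= m[2]

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValidationError):
            kmeans_partition(pd.DataFrame({"a": [1.0, 2.0]}), k=3)

    def test_deterministic_given_seed(self, landscape):
        a = kmeans_partition(landscape.signal, 3, seed=1)
        b = kmeans_partition(landscape.signal, 3, seed=1)
        assert (a == b).all()


class TestStateEnrichment:
    def test_uniform_peaks_null(self):
        genome = Genome({"chr1": 1_000_000})
        seg = ChromStateSegmentation(pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(0, 1_000_000, 100_000),
            "end": np.arange(100_000, 1_100_000, 100_000),
            "state": ["A", "B"] * 5,
        }))
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 999_000, 10_000)
        peaks = PeakSet.from_intervals(
            [("chr1", int(s), int(s) + 500) for s in starts],
            ids=[f"p{k}" for k in range(10_000)],
        )
        res = state_enrichment(peaks, seg, genome)
        assert res["fold_enrichment"].between(0.9, 1.1).all()

    def test_analytic_fold_enrichment(self):
        genome = Genome({"chr1": 1_000_000})
        seg = ChromStateSegmentation(pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [0, 100_000],
            "end": [100_000, 1_000_000],
            "state": ["hot", "cold"],
        }))
        peaks = PeakSet.from_intervals(
            [("chr1", k * 100, k * 100 + 50) for k in range(100)],
            ids=[f"p{k}" for k in range(100)],
        )
        res = state_enrichment(peaks, seg, genome).set_index("state")
        assert res.loc["hot", "fold_enrichment"] == pytest.approx(10.0)

    def test_union_state_fe_is_one(self):
        genome = Genome({"chr1": 500_000})
        seg = ChromStateSegmentation(pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [500_000], "state": ["all"],
        }))
        peaks = PeakSet.from_intervals([("chr1", k * 1_000, k * 1_000 + 100) for k in range(50)],
                                       ids=[f"p{k}" for k in range(50)])
        res = state_enrichment(peaks, seg, genome)
        assert res["fold_enrichment"].iloc[0] == 1.0

    def test_binomial_p_matches_monte_carlo(self):
        # fixed toy case: n=100 peaks, state fraction 0.3, k observed
        n, g = 100, 0.3
        rng = np.random.default_rng(17)
        draws = rng.binomial(n, g, 100_000)
        for k in (40, 22):
            if k / n >= g:
                mc = (draws >= k).mean()
                analytic = binom.sf(k - 1, n, g)
            else:
                mc = (draws <= k).mean()
                analytic = binom.cdf(k, n, g)
            assert analytic / 2 <= mc <= analytic * 2


class TestQuartileAtlas:
    def _atlas_from_log2fc(self):
        # 8 disjoint regions engineered to land at known fold changes
        fcs = [-3, -2, -1, -0.5, 0.5, 1, 2, 3]
        base = 100
        rows_a, rows_b = [], []
        counts = {}
        for k, fc in enumerate(fcs):
            rid = f"rA{k}"
            rows_a.append(("chr1", k * 10_000, k * 10_000 + 1_000))
            a_val = base
            b_val = (base + 1) * 2 ** fc - 1
            counts[rid] = [a_val, a_val, b_val, b_val]
        peaks_a = PeakSet.from_intervals(rows_a, ids=[f"rA{k}" for k in range(8)])
        peaks_b = PeakSet.from_intervals(
            [("chr2", 0, 100)], ids=["rB0"]
        )
        counts["rB0"] = [base, base, base, base]
        cdf = pd.DataFrame(counts, index=["a1", "a2", "b1", "b2"]).T
        return peaks_a, peaks_b, cdf

    def test_quartile_assignment_of_known_fold_changes(self):
        peaks_a, peaks_b, counts = self._atlas_from_log2fc()
        atlas = build_quartile_atlas(peaks_a, peaks_b, counts,
                                     {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        t = atlas.table.set_index("region_id")
        src = atlas.regions.df.set_index("peak_id")["source_ids"]
        by_src = {src[r]: t.loc[r, "quartile"] for r in t.index}
        # most A-specific constituents in Q1, most B-specific in Q4
        assert by_src["rA0"] == "Q1" and by_src["rA1"] == "Q1"
        assert by_src["rA6"] == "Q4" and by_src["rA7"] == "Q4"

    @pytest.mark.parametrize("n", [5, 8, 10, 13])
    def test_quartile_sizes_differ_by_at_most_one(self, n):
        rng = np.random.default_rng(n)
        peaks = PeakSet.from_intervals(
            [("chr1", k * 1_000, k * 1_000 + 500) for k in range(n)],
            ids=[f"r{k}" for k in range(n)],
        )
        empty = PeakSet.from_intervals([("chr2", 0, 10)], ids=["z"])
        counts = pd.DataFrame(
            rng.integers(10, 1_000, size=(n + 1, 4)),
            index=[f"r{k}" for k in range(n)] + ["z"],
            columns=["a1", "a2", "b1", "b2"],
        )
        atlas = build_quartile_atlas(peaks, empty, counts,
                                     {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        sizes = atlas.table["quartile"].value_counts()
        assert sizes.max() - sizes.min() <= 1
        # reassembling quartiles reproduces the atlas exactly
        assert sorted(atlas.table["region_id"]) == sorted(atlas.regions.ids())

    def test_quartile_boundaries_monotone(self):
        peaks_a, peaks_b, counts = self._atlas_from_log2fc()
        atlas = build_quartile_atlas(peaks_a, peaks_b, counts,
                                     {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        t = atlas.table
        assert t["log2fc"].is_monotonic_increasing
        assert list(t["quartile"]) == sorted(t["quartile"])


class TestClusterQuartileIntersection:
    def _atlas(self):
        rng = np.random.default_rng(1)
        peaks = PeakSet.from_intervals(
            [("chr1", k * 10_000, k * 10_000 + 1_000) for k in range(40)],
            ids=[f"r{k}" for k in range(40)],
        )
        empty = PeakSet.from_intervals([("chr2", 0, 10)], ids=["z"])
        counts = pd.DataFrame(
            {"a1": 100, "a2": 100,
             "b1": np.concatenate([np.full(20, 100), np.full(20, 800), [100]]),
             "b2": np.concatenate([np.full(20, 100), np.full(20, 800), [100]])},
            index=[f"r{k}" for k in range(40)] + ["z"],
        )
        counts[["a1", "a2"]] = 100
        return build_quartile_atlas(peaks, empty, counts, {"A": ["a1", "a2"], "B": ["b1", "b2"]})

    def test_no_overlap_gives_zero_counts(self):
        atlas = self._atlas()
        faraway = PeakSet.from_intervals([("chr1", 5_000_000, 5_000_100)], ids=["x"])
        res = cluster_quartile_intersection(atlas, faraway).set_index("quartile")
        assert res.loc["unmatched", "count"] == 1
        assert res.drop("unmatched")["count"].sum() == 0

    def test_cluster_inside_q4_counts_fully(self):
        atlas = self._atlas()
        q4_regions = atlas.table[atlas.table["quartile"] == "Q4"]["region_id"]
        sub = atlas.regions.subset(q4_regions)
        probe = PeakSet(sub.df[["chrom", "start", "end"]].assign(
            peak_id=[f"c{k}" for k in range(len(sub))]))
        res = cluster_quartile_intersection(atlas, probe).set_index("quartile")
        assert res.loc["Q4", "proportion"] == 1.0
        assert res["proportion"].drop("unmatched").sum() <= 1.0
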