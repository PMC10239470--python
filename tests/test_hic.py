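"""Contact matrices, loop strength, condition comparison, APA, anchors."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from chromrewire import (
    ContactMatrix,
    apa,
    bottom_left_expected,
    compare_conditions,
    distance_decay,
    genes_near_anchors,
    load_contacts,
    loop_strength,
    peaks_in_anchors,
    read_bedpe,
    write_bedpe,
    write_contacts,
    PeakSet,
)
from chromrewire.genomic_core import Genome
from chromrewire.hic import ContactError

from conftest import make_genes


def dense_matrix(arr, chrom="chr1", resolution=10_000):
    return ContactMatrix(chrom, resolution, sp.csr_matrix(np.asarray(arr, float)))


def loops_df(pixels, resolution=10_000, chrom="chr1"):
    rows = []
    for k, (i, j) in enumerate(pixels):
        rows.append((chrom, i * resolution, (i + 1) * resolution,
                     chrom, j * resolution, (j + 1) * resolution, f"L{k}"))
    return pd.DataFrame(rows, columns=[
        "chrom1", "start1", "end1", "chrom2", "start2", "end2", "loop_id"])


class TestContactIO:
    def test_triplet_symmetrized(self, tmp_path):
        path = tmp_path / "m.coo"
        path.write_text("chr1\t0\t5\t10\n")
        genome = Genome({"chr1": 100_000})
        m = load_contacts(str(path), genome, 10_000)["chr1"]
        assert m[0, 5] == 10 and m[5, 0] == 10

    def test_duplicate_triplets_summed(self, tmp_path):
        path = tmp_path / "m.coo"
        path.write_text("chr1\t2\t4\t3\nchr1\t2\t4\t4\n")
        genome = Genome({"chr1": 100_000})
        m = load_contacts(str(path), genome, 10_000)["chr1"]
        assert m[2, 4] == 7

    def test_out_of_range_bin_names_line(self, tmp_path):
        path = tmp_path / "m.coo"
        path.write_text("chr1\t0\t1\t1\nchr1\t0\t99\t1\n")
        genome = Genome({"chr1": 100_000})
        with pytest.raises(ContactError, match=":2"):
            load_contacts(str(path), genome, 10_000)

    def test_write_read_round_trip(self, tmp_path, contact_maps):
        control, _ = contact_maps
        path = tmp_path / "rt.coo"
        write_contacts(control.matrices, str(path))
        genome = Genome({c: m.n_bins * m.resolution for c, m in control.matrices.items()})
        back = load_contacts(str(path), genome, 10_000)
        for chrom, m in control.matrices.items():
            assert (back[chrom].matrix != m.matrix).nnz == 0

    def test_bedpe_round_trip(self, tmp_path, contact_maps):
        control, _ = contact_maps
        path = tmp_path / "loops.bedpe"
        write_bedpe(control.loops, str(path))
        back = read_bedpe(str(path))
        assert list(back["loop_id"]) == list(control.loops["loop_id"])
        assert list(back["start1"]) == list(control.loops["start1"])


class TestDistanceDecay:
    def test_constant_matrix_constant_curve(self):
        m = dense_matrix(np.full((20, 20), 3.0))
        decay = distance_decay(m)
        assert np.allclose(decay["mean_count"], 3.0)

    def test_diagonal_mean_exact(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 10, size=(30, 30)).astype(float)
        a = (a + a.T) / 2
        m = dense_matrix(a)
        decay = distance_decay(m)
        assert decay["mean_count"][0] == pytest.approx(np.diag(a).mean())
        d5 = np.array([a[i, i + 5] for i in range(25)]).mean()
        assert decay.loc[5, "mean_count"] == pytest.approx(d5)


class TestBottomLeftExpected:
    def test_uniform_matrix(self):
        m = dense_matrix(np.full((50, 50), 4.0))
        assert bottom_left_expected(m, (10, 30), p=2, w=5) == 4.0

    def test_hand_block_mean(self):
        a = np.zeros((30, 30))
        i, j, p, w = 10, 20, 0, 2
        # block: rows 11..12, cols 18..19
        a[11, 18], a[11, 19], a[12, 18], a[12, 19] = 2, 2, 6, 6
        m = dense_matrix(a)
        assert bottom_left_expected(m, (i, j), p=p, w=w) == 4.0

    def test_window_not_fitting_is_undefined(self):
        m = dense_matrix(np.ones((30, 30)))
        assert bottom_left_expected(m, (10, 15), p=2, w=5) is None  # j-i <= p+w
        assert bottom_left_expected(m, (27, 35 - 6), p=2, w=5) is None  # off edge

    def test_matches_naive_oracle_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(5, size=(200, 200)).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        m = dense_matrix(a)
        p, w = 2, 5
        checked = 0
        while checked < 1_000:
            i = int(rng.integers(0, 200))
            j = int(rng.integers(0, 200))
            if j <= i:
                continue
            got = bottom_left_expected(m, (i, j), p, w)
            if j - i <= p + w or i + w >= 200 or j - w < 0:
                assert got is None
            else:
                cells = [a[x, y] for x in range(i + p + 1, i + w + 1)
                         for y in range(j - w, j - p)]
                assert got == np.mean(cells)
            checked += 1


class TestLoopStrength:
    def test_observed_over_expected_log2(self):
        a = np.full((40, 40), 4.0)
        a[5, 25] = a[25, 5] = 16.0
        m = {"chr1": dense_matrix(a)}
        s = loop_strength(loops_df([(5, 25)]), m, pseudocount=0)
        assert s["L0"] == pytest.approx(2.0)

    def test_observed_equals_expected_zero(self):
        m = {"chr1": dense_matrix(np.full((40, 40), 7.0))}
        s = loop_strength(loops_df([(5, 25)]), m)
        assert s["L0"] == 0.0

    def test_invariant_under_anchor_swap(self, contact_maps):
        control, _ = contact_maps
        loops = control.loops.head(20)
        swapped = loops.rename(columns={
            "start1": "start2", "end1": "end2", "start2": "start1", "end2": "end1"})
        s1 = loop_strength(loops, control.matrices)
        s2 = loop_strength(swapped, control.matrices)
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), equal_nan=True)

    def test_planted_enrichment_recovered(self, contact_maps, default_config):
        # pure log2(O/E) mode; the local expected sits nearer the diagonal
        # than the pixel, so decay biases it high and the recovered strength
        # lands slightly below log2(fold)
        control, _ = contact_maps
        s = loop_strength(control.loops, control.matrices, pseudocount=0)
        expected = math.log2(default_config.loop_enrichment)
        assert abs(np.nanmedian(s) - expected) <= 0.3


class TestCompareConditions:
    def test_threshold_rule(self):
        a = np.full((60, 60), 8.0)
        b = np.full((60, 60), 8.0)
        a[5, 30] = a[30, 5] = 64.0   # strength_A = log2(65/9) ~ 2.85
        b[5, 30] = b[30, 5] = 24.0   # strength_B = log2(25/9) ~ 1.47 -> weakened
        a[10, 40] = a[40, 10] = 32.0
        b[10, 40] = b[40, 10] = 28.0  # small diff -> unchanged
        loops = loops_df([(5, 30), (10, 40)])
        rec, frac = compare_conditions(
            loops, {"chr1": dense_matrix(a)}, {"chr1": dense_matrix(b)})
        assert list(rec["class"]) == ["weakened", "unchanged"]
        assert frac["weakened"] == 0.5

    def test_identical_matrices_nothing_called(self, contact_maps):
        control, _ = contact_maps
        rec, frac = compare_conditions(
            control.loops, control.matrices, control.matrices)
        assert frac["weakened"] == 0.0 and frac["strengthened"] == 0.0

    def test_planted_rewiring_recovered(self, contact_maps):
        control, mutant = contact_maps
        rec, frac = compare_conditions(
            control.loops, control.matrices, mutant.matrices, fold=1.5)
        truth = control.loops.set_index("loop_id")["weakened_truth"]
        m = rec.set_index("loop_id").join(truth)
        called = m["class"] == "weakened"
        sens = (called & m["weakened_truth"]).sum() / m["weakened_truth"].sum()
        spec = ((~called) & ~m["weakened_truth"]).sum() / (~m["weakened_truth"]).sum()
        assert 0.15 <= frac["weakened"] <= 0.25
        assert sens >= 0.9 and spec >= 0.9


class TestAPA:
    def test_uniform_matrix_flat(self):
        m = {"chr1": dense_matrix(np.full((120, 120), 5.0))}
        res = apa(loops_df([(20, 80), (30, 95)]), m, w=5, p=2)
        assert np.allclose(res.matrix, 1.0)
        assert res.p2ll == pytest.approx(1.0)

    def test_planted_loops_enriched(self, contact_maps):
        control, _ = contact_maps
        res = apa(control.loops, control.matrices, w=10, p=3)
        assert res.p2ll > 1.5

    def test_random_pixels_null(self, contact_maps):
        control, _ = contact_maps
        rng = np.random.default_rng(2)
        loops = control.loops.copy()
        res_bp = 10_000
        d = (loops["bin2"] - loops["bin1"]).to_numpy()
        n_bins = control.matrices["chr1"].n_bins
        newi = rng.integers(25, n_bins - d.max() - 25, len(loops))
        loops["start1"] = newi * res_bp
        loops["end1"] = (newi + 1) * res_bp
        loops["start2"] = (newi + d) * res_bp
        loops["end2"] = (newi + d + 1) * res_bp
        res = apa(loops, control.matrices, w=10, p=3)
        assert 0.8 <= res.p2ll <= 1.2


class TestAnchorIntegration:
    def test_peak_inside_anchor_associated(self):
        loops = loops_df([(5, 25)])
        peaks = PeakSet.from_intervals([("chr1", 51_000, 52_000)], ids=["in1"])
        res = peaks_in_anchors(loops, peaks)
        assert list(res["peak_id"]) == ["in1"]

    def test_touching_anchor_end_not_associated(self):
        loops = loops_df([(5, 25)])  # anchor1 = [50000, 60000)
        peaks = PeakSet.from_intervals([("chr1", 60_000, 61_000)], ids=["touch"])
        assert len(peaks_in_anchors(loops, peaks)) == 0

    def test_matches_brute_force(self, contact_maps):
        control, _ = contact_maps
        rng = np.random.default_rng(3)
        rows = []
        for k in range(1_000):
            chrom = "chr1" if k % 2 else "chr2"
            s = int(rng.integers(0, 19_990_000))
            rows.append((chrom, s, s + int(rng.integers(200, 5_000))))
        peaks = PeakSet.from_intervals(rows, ids=[f"p{k}" for k in range(1_000)])
        loops = control.loops.head(200)
        got = set(map(tuple, peaks_in_anchors(loops, peaks).to_numpy()))
        expected = set()
        for _, lr in loops.iterrows():
            for _, pr in peaks.df.iterrows():
                for side in ("1", "2"):
                    if (pr["chrom"] == lr[f"chrom{side}"]
                            and pr["start"] < lr[f"end{side}"]
                            and lr[f"start{side}"] < pr["end"]):
                        expected.add((lr["loop_id"], pr["peak_id"]))
        assert got == expected

    @pytest.mark.parametrize("offset,included", [(9_999, True), (10_000, False)])
    def test_gene_distance_boundary_strict(self, offset, included):
        loops = loops_df([(5, 25)])  # anchor2 = [250000, 260000)
        genes = make_genes([("g", "chr1", "+", 260_000 + offset, 260_000 + offset,
                             260_000 + offset + 1_000)])
        res = genes_near_anchors(loops, genes, max_dist=10_000)
        assert (len(res) == 1) == included
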