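"""Master-peak matrix construction and the normalization chain."""

import numpy as np
import pandas as pd
import pytest

from thymoatac import accessibility as acc
from thymoatac.core import CutSiteTrack, FragmentSet, GenomicInterval, PeakSet
from conftest import make_peaks


def frag_lib(sample, n, chrom="chr1", start=0, length=100, spacing=150):
    frags = [(chrom, start + i * spacing, start + i * spacing + length)
             for i in range(n)]
    return FragmentSet(sample, frags)


class TestDownsample:
    def test_median_rule(self):
        libs = [frag_lib("a", 100), frag_lib("b", 200), frag_lib("c", 300)]
        out = acc.downsample_fragments(libs, seed=0)
        assert [l.depth for l in out] == [100, 200, 200]

    def test_single_library_unchanged(self):
        lib = frag_lib("a", 50)
        out = acc.downsample_fragments([lib], seed=0)
        assert out[0] is lib

    def test_fragments_kept_intact_and_sampled_without_replacement(self):
        libs = [frag_lib("a", 10), frag_lib("b", 30)]  # median depth 20
        out = acc.downsample_fragments(libs, seed=1)
        sampled = out[1].fragments
        assert len(sampled) == 20
        assert len(set(sampled)) == 20  # without replacement
        assert set(sampled) <= set(libs[1].fragments)  # pairs never split

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            acc.downsample_fragments([], seed=0)


class TestMasterPeaks:
    def test_overlap_merge(self):
        master = acc.make_master_peaks([
            make_peaks([("chr1", 0, 100)]), make_peaks([("chr1", 50, 150)])])
        assert [(iv.start, iv.end) for iv in master.intervals] == [(0, 150)]

    def test_bookended_merge(self):
        master = acc.make_master_peaks([
            make_peaks([("chr1", 0, 100)]), make_peaks([("chr1", 100, 200)])])
        assert [(iv.start, iv.end) for iv in master.intervals] == [(0, 200)]

    def test_disjoint_union_unchanged(self):
        master = acc.make_master_peaks([
            make_peaks([("chr1", 0, 100)]), make_peaks([("chr2", 0, 50)])])
        assert len(master) == 2


class TestFpkm:
    def test_unit_case(self):
        master = make_peaks([("chr1", 0, 1000)])
        frags = [("chr1", 10 * i, 10 * i + 50) for i in range(10)]
        filler = [("chr2", i, i + 1) for i in range(1_000_000 - 10)]
        lib = FragmentSet("s", frags + filler)
        m = acc.fpkm_matrix(master, [lib])
        assert m.values[0, 0] == pytest.approx(10.0)

    def test_no_overlap_zero(self):
        master = make_peaks([("chr1", 5000, 6000)])
        m = acc.fpkm_matrix(master, [frag_lib("s", 10)])
        assert m.values[0, 0] == 0.0

    def test_length_homogeneity(self):
        # all fragments inside [0, 1000) so both regions see the same count
        lib = frag_lib("s", 7, spacing=100, length=50)
        short = acc.fpkm_matrix(make_peaks([("chr1", 0, 1000)]), [lib])
        long = acc.fpkm_matrix(make_peaks([("chr1", 0, 2000)]), [lib])
        # identical fragment count over doubled length halves FPKM
        assert long.values[0, 0] == pytest.approx(short.values[0, 0] / 2)

    def test_any_overlap_counting(self):
        master = make_peaks([("chr1", 100, 200)])
        lib = FragmentSet("s", [("chr1", 50, 101), ("chr1", 199, 260),
                                ("chr1", 0, 100), ("chr1", 200, 300)])
        counts = acc.count_overlapping_fragments(master, lib)
        assert counts[0] == 2  # 1 bp overlap counts; bookended does not

    def test_fragment_order_invariance(self, rng):
        master = make_peaks([("chr1", 0, 500), ("chr1", 700, 1500)])
        frags = [("chr1", int(s), int(s) + 80) for s in rng.integers(0, 1400, 200)]
        a = acc.fpkm_matrix(master, [FragmentSet("s", frags)])
        b = acc.fpkm_matrix(master, [FragmentSet("s", frags[::-1])])
        np.testing.assert_allclose(a.values, b.values)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            acc.fpkm_matrix(make_peaks([("chr1", 0, 10)]), [FragmentSet("s", [])])


class TestTssEnrichment:
    def test_uniform_track_scores_one(self):
        dense = {"chr1": (np.full(5000, 2), np.full(5000, 2))}
        track = CutSiteTrack.from_dense("s", dense)
        tss = [GenomicInterval("chr1", 2500, 2501, "+")]
        assert acc.tss_enrichment(track, tss) == pytest.approx(1.0)

    def test_zero_flanks_floored(self):
        dense = {"chr1": (np.zeros(5000, int), np.zeros(5000, int))}
        dense["chr1"][0][2500] = 100
        track = CutSiteTrack.from_dense("s", dense)
        tss = [GenomicInterval("chr1", 2500, 2501, "+")]
        score = acc.tss_enrichment(track, tss)
        assert np.isfinite(score) and score > 10

    def test_five_fold_rate_recovered(self, rng):
        n = 40
        length = 120_000
        plus = rng.poisson(0.02, length)
        tss = []
        for i in range(n):
            pos = 1500 + i * 2900
            window = slice(pos - 250, pos + 251)
            plus[window] += rng.poisson(0.08, 501)  # 5x total rate near TSS
            tss.append(GenomicInterval("chr1", pos, pos + 1, "+"))
        track = CutSiteTrack.from_dense("s", {"chr1": (plus, np.zeros(length, int))})
        score = acc.tss_enrichment(track, tss)
        assert abs(score - 5.0) < 0.5

    def test_empty_tss_rejected(self):
        track = CutSiteTrack.from_dense("s", {"chr1": (np.zeros(10, int),
                                                       np.zeros(10, int))})
        with pytest.raises(ValueError):
            acc.tss_enrichment(track, [])


def _matrix(values, state="raw_fpkm"):
    values = np.asarray(values, dtype=float)
    regions = [GenomicInterval("chr1", 1000 * i, 1000 * i + 500)
               for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return acc.AccessibilityMatrix(regions, samples, values, state)


class TestNormalization:
    def test_iqr_scaling_reference_column(self):
        """(1,2,3,4,5) -> (-1,-0.5,0,0.5,1) under type-7 quantiles."""
        m = _matrix(np.array([[1.0], [2], [3], [4], [5]]), state="tss_normalized")
        out = acc.iqr_scale(m)
        np.testing.assert_allclose(out.values[:, 0], [-1, -0.5, 0, 0.5, 1])

    def test_post_iqr_median_zero_iqr_one(self, rng):
        m = _matrix(rng.gamma(2, 3, size=(40, 4)), state="tss_normalized")
        out = acc.iqr_scale(m)
        for j in range(4):
            col = out.values[:, j]
            assert np.median(col) == pytest.approx(0.0, abs=1e-9)
            q1, q3 = np.quantile(col, [0.25, 0.75], method="linear")
            assert q3 - q1 == pytest.approx(1.0, abs=1e-9)

    def test_row_max_division(self):
        m = _matrix(np.array([[0.2, 0.4, 0.8, 0.4]]), state="iqr_scaled")
        out = acc.row_max_normalize(m)
        np.testing.assert_allclose(out.values[0], [0.25, 0.5, 1.0, 0.5])

    def test_row_max_exactly_one(self, rng):
        m = _matrix(rng.normal(2, 1, size=(30, 4)), state="iqr_scaled")
        out = acc.row_max_normalize(m)
        good = ~out.flagged
        assert np.all(out.values[good].max(axis=1) == 1.0)

    def test_degenerate_rows_flagged_zero(self):
        m = _matrix(np.array([[1.0, 2.0, 4.0, 3.0],
                              [-1.0, -2.0, -0.5, -3.0],
                              [2.0, 2.0, 2.0, 2.0]]), state="iqr_scaled")
        out = acc.row_max_normalize(m)
        assert list(out.flagged) == [False, True, True]
        np.testing.assert_array_equal(out.values[1], 0.0)
        np.testing.assert_array_equal(out.values[2], 0.0)

    def test_zero_iqr_names_sample(self):
        m = _matrix(np.column_stack([np.arange(5.0), np.full(5, 3.0)]),
                    state="tss_normalized")
        with pytest.raises(ValueError, match="s1"):
            acc.iqr_scale(m)

    def test_state_order_enforced(self, rng):
        m = _matrix(rng.gamma(2, 3, size=(10, 4)))
        with pytest.raises(ValueError, match="state"):
            acc.iqr_scale(m)  # must TSS-normalize first
        with pytest.raises(ValueError, match="state"):
            acc.row_max_normalize(acc.divide_by_enrichment(m, {f"s{j}": 1.0 for j in range(4)}))

    def test_operation_order_matters(self, rng):
        """Permuting IQR and row-max steps changes the output."""
        vals = rng.gamma(2, 3, size=(30, 4))
        enr = {f"s{j}": 1.0 + j for j in range(4)}
        chained = acc.normalize_matrix(_matrix(vals), enr)
        # swapped order: row-max before IQR on the raw values
        swapped = vals / vals.max(axis=1, keepdims=True)
        assert not np.allclose(chained.values, swapped)

    def test_non_positive_enrichment_rejected(self, rng):
        m = _matrix(rng.gamma(2, 3, size=(10, 2)))
        with pytest.raises(ValueError):
            acc.divide_by_enrichment(m, {"s0": 1.0, "s1": 0.0})

    def test_matrix_tsv_roundtrip(self, rng, tmp_path):
        m = acc.normalize_matrix(
            _matrix(rng.gamma(2, 3, size=(20, 4))),
            {f"s{j}": 1.0 for j in range(4)})
        m.to_tsv(tmp_path / "m.tsv")
        back = acc.AccessibilityMatrix.from_tsv(tmp_path / "m.tsv")
        assert back.state == "row_max_normalized"
        np.testing.assert_allclose(back.values, m.values)
        np.testing.assert_array_equal(back.flagged, m.flagged)


class TestReplicateCorrelation:
    def test_self_correlation_one(self, rng):
        x = rng.poisson(20, 50)
        df = pd.DataFrame({"r1": x, "r2": x})
        out = acc.replicate_correlation(df)
        assert out.loc[0, "pearson"] == pytest.approx(1.0)
        assert out.loc[0, "spearman"] == pytest.approx(1.0)

    def test_monotone_transform_rank_invariance(self, rng):
        x = rng.poisson(20, 200).astype(float) + rng.random(200)
        df = pd.DataFrame({"r1": x, "r2": np.exp(x / 5)})
        out = acc.replicate_correlation(df)
        assert out.loc[0, "spearman"] == pytest.approx(1.0)
        assert out.loc[0, "pearson"] < 1.0

    def test_independent_columns_near_zero(self, rng):
        df = pd.DataFrame({"r1": rng.poisson(20, 5000),
                           "r2": rng.poisson(20, 5000)})
        out = acc.replicate_correlation(df)
        assert abs(out.loc[0, "pearson"]) < 0.05
        assert abs(out.loc[0, "spearman"]) < 0.05

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"r1": [1, 2, 3], "r2": [5, 5, 5]})
        out = acc.replicate_correlation(df)
        assert np.isnan(out.loc[0, "pearson"])
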