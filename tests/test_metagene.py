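import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cenmisloc import (
    EXPRESSION_CLASSES,
    GeneAnnotation,
    classify_expression,
    gene_body_mean_signal,
    metagene_profile,
    occupancy_vs_expression,
    tss_aligned_matrix,
)


class TestClassifyExpression:
    @pytest.mark.parametrize(
        "value,label",
        [
            (5.0, "very_low"),
            (7.999, "very_low"),
            (8.0, "low"),
            (9.0, "low"),
            (10.0, "medium"),
            (11.5, "medium"),
            (12.0, "high"),
            (14.0, "high"),
            (14.5, "very_high"),
            (15.0, "very_high"),
        ],
    )
    def test_boundaries(self, value, label):
        assert classify_expression(value) == label

    def test_nonfinite_rejected(self):
        for bad in (math.nan, math.inf, -math.inf):
            with pytest.raises(ValueError):
                classify_expression(bad)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(-100, 100, allow_nan=False))
    def test_partitions_the_line(self, value):
        assert classify_expression(value) in EXPRESSION_CLASSES


def plus_gene(tss, gid="gp", chrom="I", length=1000, expr=9.0):
    return GeneAnnotation(gid, chrom, "+", tss, tss + length, expr, "low")


def minus_gene(tss, gid="gm", chrom="I", length=1000, expr=9.0):
    return GeneAnnotation(gid, chrom, "-", tss, tss - length, expr, "low")


class TestTssAlignedMatrix:
    def test_constant_track_gives_constant_vectors(self, make_track):
        track = make_track(np.full(200, 3.0), spacing=20)
        genes = [plus_gene(1000, "a"), minus_gene(3000, "b")]
        matrix = tss_aligned_matrix(track, genes, upstream=200, downstream=400, bin_size=20)
        assert matrix.shape == (2, 30)
        np.testing.assert_allclose(matrix.to_numpy(), 3.0)

    def test_single_gene_bin_equals_spacing_is_verbatim_lookup(self, make_track):
        rng = np.random.default_rng(5)
        values = rng.normal(size=300)
        track = make_track(values, spacing=20, scale="log2")
        gene = plus_gene(2000, "g")
        matrix = tss_aligned_matrix(track, [gene], upstream=100, downstream=200, bin_size=20)
        # probes at 1900,1920,...,2180 — positions (2000-100)//20 .. in order
        expected = values[95:110]
        np.testing.assert_allclose(matrix.loc["g"].to_numpy(), expected)

    def test_strand_symmetry_on_mirror_signal(self):
        from cenmisloc.simulate import ProbeTrack

        spacing = 20
        n = 500
        positions = np.arange(n) * spacing
        tss_plus, tss_minus = 3000, 7000
        f = lambda rel: np.sin(rel / 97.0) + 0.1 * rel  # arbitrary profile
        values = np.where(
            positions < 5000, f(positions - tss_plus), f(tss_minus - positions)
        )
        track = ProbeTrack(
            np.full(n, "I", dtype=object), positions, values, "log2", spacing
        )
        genes = [plus_gene(tss_plus, "p"), minus_gene(tss_minus, "m")]
        matrix = tss_aligned_matrix(track, genes, upstream=500, downstream=1000, bin_size=20)
        np.testing.assert_allclose(
            matrix.loc["p"].to_numpy(), matrix.loc["m"].to_numpy(), atol=1e-12
        )

    def test_window_beyond_chromosome_skips_gene(self, make_track, caplog):
        track = make_track(np.ones(50), spacing=20)  # covers [0, 1000)
        genes = [plus_gene(100, "early"), plus_gene(500, "ok", length=300)]
        with caplog.at_level("WARNING", logger="cenmisloc"):
            matrix = tss_aligned_matrix(track, genes, upstream=200, downstream=400, bin_size=20)
        assert list(matrix.index) == ["ok"]
        assert any("early" in rec.message for rec in caplog.records)

    def test_empty_bins_are_nan(self, make_track):
        track = make_track(np.ones(10), spacing=100)
        gene = plus_gene(500, "g", length=300)
        matrix = tss_aligned_matrix(track, [gene], upstream=100, downstream=200, bin_size=20)
        row = matrix.loc["g"]
        assert row.notna().sum() < row.size
        assert row.notna().any()


class TestMetageneProfile:
    def test_identical_vectors_zero_ci(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0]] * 4,
            index=[f"g{i}" for i in range(4)],
            columns=[-100, 0, 100],
        )
        classes = {f"g{i}": "medium" for i in range(4)}
        profile = metagene_profile(matrix, classes)
        np.testing.assert_allclose(profile.class_mean("medium").to_numpy(), [1, 2, 3])
        np.testing.assert_allclose(profile.data["ci_half_width"].to_numpy(), 0.0)

    def test_two_gene_class_closed_form_t_interval(self):
        a, b = 1.0, 3.0
        matrix = pd.DataFrame([[a], [b]], index=["g1", "g2"], columns=[0])
        profile = metagene_profile(matrix, {"g1": "high", "g2": "high"}, ci_level=0.99)
        row = profile.data.iloc[0]
        sd = np.std([a, b], ddof=1)
        expected = stats.t.ppf(0.995, 1) * sd / math.sqrt(2)
        assert row["mean"] == pytest.approx((a + b) / 2)
        assert row["ci_half_width"] == pytest.approx(expected)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(
            rng.normal(size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=[0, 20, 40, 60],
        )
        classes = {f"g{i}": ("low" if i % 2 else "high") for i in range(6)}
        p1 = metagene_profile(matrix, classes)
        p2 = metagene_profile(matrix.iloc[::-1], classes)
        pd.testing.assert_frame_equal(p1.data, p2.data)

    def test_singleton_class_reported_without_ci(self):
        matrix = pd.DataFrame(
            [[1.0], [2.0], [5.0]], index=["a", "b", "c"], columns=[0]
        )
        classes = {"a": "low", "b": "low", "c": "very_high"}
        profile = metagene_profile(matrix, classes)
        vh = profile.data[profile.data["expression_class"] == "very_high"]
        assert math.isnan(vh["ci_half_width"].iloc[0])
        assert vh["mean"].iloc[0] == 5.0

class TestOccupancyVsExpression:
    def test_constant_occupancy_gives_constant_curve(self):
        curve = occupancy_vs_expression(np.ones(150), np.arange(150.0), window=100)
        np.testing.assert_allclose(curve["mean_occupancy"], 1.0)
        assert len(curve) == 51

    def test_window_equals_n_gives_single_overall_mean(self):
        rng = np.random.default_rng(0)
        occ, expr = rng.normal(size=100), rng.uniform(5, 15, 100)
        curve = occupancy_vs_expression(occ, expr, window=100)
        assert len(curve) == 1
        assert curve["mean_occupancy"].iloc[0] == pytest.approx(occ.mean())
        assert curve["mean_expression"].iloc[0] == pytest.approx(expr.mean())

    def test_negated_expression_gives_strictly_decreasing_curve(self):
        rng = np.random.default_rng(1)
        expr = rng.uniform(5, 15, 400)
        curve = occupancy_vs_expression(-expr, expr, window=100, step=1)
        assert np.all(np.diff(curve["mean_occupancy"]) < 0)
        assert np.all(np.diff(curve["mean_expression"]) > 0)

    def test_fewer_genes_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            occupancy_vs_expression(np.ones(10), np.ones(10), window=100)
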