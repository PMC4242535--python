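import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemibin import (
    GrayImage,
    NonConvergenceError,
    binarize,
    gap_fraction_picture,
    threshold_edge_detection,
    threshold_isodata,
    threshold_max_entropy,
    threshold_min_error,
    threshold_minimum,
    threshold_minimum_histogram,
    threshold_otsu,
)
from hemibin.thresholding import OUTSIDE, SKY, VEGETATION

from .conftest import mixture_histogram
from . import oracles


class TestBinarize:
    def test_value_equal_to_threshold_is_vegetation(self):
        img = GrayImage(np.array([[100, 101]], np.uint8))
        b = binarize(img, 100)
        assert b.classes[0, 0] == VEGETATION
        assert b.classes[0, 1] == SKY

    def test_t255_makes_everything_vegetation(self):
        img = GrayImage(np.arange(256, dtype=np.uint8).reshape(16, 16))
        assert binarize(img, 255).n_vegetation == 256

    def test_outside_mask_is_outside_class(self):
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        b = binarize(GrayImage(np.zeros((2, 2), np.uint8), mask), 10)
        assert b.classes[0, 0] == VEGETATION
        assert (b.classes[mask == False] == OUTSIDE).all()  # noqa: E712

    def test_out_of_range_threshold_rejected(self):
        img = GrayImage(np.zeros((2, 2), np.uint8))
        with pytest.raises(ValueError):
            binarize(img, 256)


class TestGapFraction:
    def test_direct_counts(self):
        img = GrayImage(np.array([[10, 20, 200]], np.uint8))
        assert gap_fraction_picture(binarize(img, 100)) == pytest.approx(1 / 3)
        assert gap_fraction_picture(binarize(img, 5)) == 1.0

    def test_monotone_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.integers(0, 256, (32, 32)).astype(np.uint8))
        gfs = [gap_fraction_picture(binarize(img, t)) for t in range(0, 256, 5)]
        assert all(a >= b for a, b in zip(gfs, gfs[1:]))

    @given(st.integers(0, 255), st.data())
    @settings(max_examples=30, deadline=None)
    def test_gap_fraction_position_free(self, t, data):
        vals = data.draw(
            st.lists(st.integers(0, 255), min_size=4, max_size=36)
        )
        n = len(vals)
        arr = np.array(vals, np.uint8).reshape(1, n)
        gf = gap_fraction_picture(binarize(GrayImage(arr), t))
        rng = np.random.default_rng(0)
        arr2 = arr.ravel()[rng.permutation(n)].reshape(1, n)
        assert gap_fraction_picture(binarize(GrayImage(arr2), t)) == gf


class TestWorkedExamples:
    """Hand-derived micro-examples for each algorithm."""

    def test_otsu_two_spikes_plateau_and_tie_break(self, two_spike_hist):
        res = threshold_otsu(two_spike_hist)
        assert res.threshold == 50
        # closed form on the plateau: 0.5*0.5*(200-50)^2
        for t in (50, 100, 199):
            assert res.objective[t] == pytest.approx(0.25 * 150**2)

    def test_isodata_two_spikes_fixed_point(self, two_spike_hist):
        assert threshold_isodata(two_spike_hist).threshold == 125

    def test_max_entropy_two_spikes_degenerate_plateau(self, two_spike_hist):
        res = threshold_max_entropy(two_spike_hist)
        assert res.threshold == 50
        assert res.objective[120] == pytest.approx(0.0, abs=1e-12)

    def test_min_error_two_spikes_inadmissible(self, two_spike_hist):
        with pytest.raises(ValueError):
            threshold_min_error(two_spike_hist)

    def test_minimum_two_triangles(self, two_triangle_hist):
        res = threshold_minimum(two_triangle_hist)
        assert res.threshold == 130
        assert res.iterations == 0

    def test_minimum_histogram_two_triangles(self, two_triangle_hist):
        res = threshold_minimum_histogram(two_triangle_hist)
        assert res.threshold == 130
        assert res.iterations == 1

    def test_minimum_unimodal_triangle_never_converges(self):
        counts = np.array([max(0, 60 - abs(g - 128)) for g in range(256)])
        with pytest.raises(NonConvergenceError):
            threshold_minimum(counts)

    def test_single_value_histogram_rejected_everywhere(self):
        counts = np.zeros(256, np.int64)
        counts[77] = 500
        for fn in (
            threshold_otsu,
            threshold_isodata,
            threshold_max_entropy,
            threshold_min_error,
            threshold_minimum,
            threshold_minimum_histogram,
        ):
            with pytest.raises(ValueError):
                fn(counts)

    def test_edge_detection_three_pixel_image(self):
        img = GrayImage(np.array([[10, 60, 200]], np.uint8))
        res = threshold_edge_detection(img)
        assert res.threshold == 60
        assert res.objective[30] == pytest.approx(50.0)
        assert res.objective[100] == pytest.approx(140.0)

    def test_edge_detection_checkerboard_tie_break(self):
        board = np.indices((6, 6)).sum(axis=0) % 2
        img = GrayImage((board * 255).astype(np.uint8))
        res = threshold_edge_detection(img)
        assert res.threshold == 0
        assert res.objective[100] == pytest.approx(255.0)

    def test_edge_detection_constant_image_errors(self):
        with pytest.raises(ValueError):
            threshold_edge_detection(GrayImage(np.full((4, 4), 9, np.uint8)))


class TestSymmetryArguments:
    def test_isodata_mirror_symmetric_histogram(self):
        counts = np.zeros(256, np.int64)
        for g in range(70, 131):
            counts[g] = max(0, 30 - abs(g - 100))
        for g in range(131, 192):
            counts[g] = max(0, 30 - abs(g - 160))
        # mirror-symmetric about gray 130: counts[g] == counts[260 - g]
        for g in range(70, 131):
            assert counts[g] == counts[260 - g]
        res = threshold_isodata(counts)
        assert res.threshold in (129, 130)
        assert res.threshold == oracles.oracle_isodata(counts.tolist())

    def test_max_entropy_uniform_histogram_symmetry(self):
        counts = np.full(256, 10, np.int64)
        res = threshold_max_entropy(counts)
        assert res.threshold == 127
        # objective symmetric under t -> 254 - t for the uniform histogram
        assert res.objective[100] == pytest.approx(res.objective[154])

    def test_max_entropy_two_triangle_symmetric_pair(self, two_triangle_hist):
        counts = np.asarray(two_triangle_hist.counts)
        t = threshold_max_entropy(counts).threshold
        assert t == oracles.oracle_max_entropy(counts.tolist())


class TestOracleEquivalence:
    """Two-route checks: vectorized implementation vs naive exhaustive scan."""

    @pytest.mark.parametrize("seed", range(12))
    def test_otsu_matches_brute_force(self, seed):
        counts = mixture_histogram(np.random.default_rng(seed))
        assert threshold_otsu(counts).threshold == oracles.oracle_otsu(counts.tolist())

    @pytest.mark.parametrize("seed", range(12))
    def test_isodata_matches_scan(self, seed):
        counts = mixture_histogram(np.random.default_rng(100 + seed))
        expect = oracles.oracle_isodata(counts.tolist())
        res = threshold_isodata(counts)
        assert res.converged is (expect is not None)
        if expect is not None:
            assert res.threshold == expect

    @pytest.mark.parametrize("seed", range(12))
    def test_max_entropy_matches_brute_force(self, seed):
        counts = mixture_histogram(np.random.default_rng(200 + seed))
        assert (
            threshold_max_entropy(counts).threshold
            == oracles.oracle_max_entropy(counts.tolist())
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_min_error_matches_brute_force(self, seed):
        counts = mixture_histogram(np.random.default_rng(300 + seed))
        expect = oracles.oracle_min_error(counts.tolist())
        if expect is None:
            with pytest.raises(ValueError):
                threshold_min_error(counts)
        else:
            assert threshold_min_error(counts).threshold == expect

    @pytest.mark.parametrize("seed", range(12))
    def test_minimum_matches_reimplementation(self, seed):
        counts = mixture_histogram(np.random.default_rng(400 + seed))
        expect = oracles.oracle_minimum(counts.tolist())
        if expect is None:
            with pytest.raises(NonConvergenceError):
                threshold_minimum(counts)
        else:
            assert threshold_minimum(counts).threshold == expect

    @pytest.mark.parametrize("seed", range(12))
    def test_minimum_histogram_matches_width_scan(self, seed):
        counts = mixture_histogram(np.random.default_rng(500 + seed))
        expect = oracles.oracle_minimum_histogram(counts.tolist())
        if expect is None:
            with pytest.raises(NonConvergenceError):
                threshold_minimum_histogram(counts)
        else:
            assert threshold_minimum_histogram(counts).threshold == expect

    @pytest.mark.parametrize("seed", range(6))
    def test_edge_detection_matches_pixel_loop(self, seed):
        rng = np.random.default_rng(600 + seed)
        vals = np.where(
            rng.random((8, 8)) < 0.5,
            rng.integers(20, 90, (8, 8)),
            rng.integers(150, 240, (8, 8)),
        ).astype(np.uint8)
        mask = rng.random((8, 8)) < 0.9
        if not mask.any():
            mask[0, 0] = True
        img = GrayImage(vals, mask)
        expect = oracles.oracle_edge_detection(vals.tolist(), mask.tolist())
        if expect is None:
            with pytest.raises(ValueError):
                threshold_edge_detection(img)
        else:
            assert threshold_edge_detection(img).threshold == expect


class TestMinErrorInstability:
    def test_unimodal_histogram_flagged_unstable(self):
        rng = np.random.default_rng(9)
        vals = np.clip(np.rint(rng.normal(120, 15, 100_000)), 0, 255).astype(int)
        counts = np.bincount(vals, minlength=256)
        with pytest.warns(RuntimeWarning):
            res = threshold_min_error(counts)
        assert not res.converged
        assert res.warnings
        # still equals the exhaustive minimizer of the criterion
        assert res.threshold == oracles.oracle_min_error(counts.tolist())

    def test_bimodal_truncated_normals_threshold_between_modes(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate(
            [rng.normal(80, 10, 50_000), rng.normal(180, 10, 50_000)]
        )
        counts = np.bincount(
            np.clip(np.rint(vals), 0, 255).astype(int), minlength=256
        )
        res = threshold_min_error(counts)
        assert res.converged
        assert 80 < res.threshold < 180
        assert res.threshold == oracles.oracle_min_error(counts.tolist())


class TestStructuralProperties:
    def test_thresholds_leave_both_classes_nonempty(self):
        rng = np.random.default_rng(11)
        for seed in range(8):
            counts = mixture_histogram(np.random.default_rng(700 + seed))
            for fn in (threshold_otsu, threshold_isodata, threshold_max_entropy):
                t = fn(counts).threshold
                assert counts[: t + 1].sum() > 0
                assert counts[t + 1 :].sum() > 0

    def test_minimum_agrees_with_minimum_histogram_on_unique_valley(
        self, two_triangle_hist
    ):
        # raw histogram already has exactly two modes and one valley
        a = threshold_minimum(two_triangle_hist).threshold
        b = threshold_minimum_histogram(two_triangle_hist).threshold
        assert a == b == 130

    def test_minimum_histogram_needs_rebinning_on_jagged_valley(
        self, two_triangle_hist
    ):
        counts = np.asarray(two_triangle_hist.counts).copy()
        counts[129] += 3
        counts[131] += 3  # extra width-1 minima around the valley
        res = threshold_minimum_histogram(counts)
        assert res.iterations > 1
        assert res.threshold == oracles.oracle_minimum_histogram(counts.tolist())

    def test_edge_detection_stride_subsampling_still_valid(self, default_scene):
        exact = threshold_edge_detection(default_scene.image)
        coarse = threshold_edge_detection(default_scene.image, stride=2)
        assert 0 <= coarse.threshold <= 255
        # subsampled objective approximates the exact one near its optimum
        assert abs(int(coarse.threshold) - int(exact.threshold)) <= 16


class TestAgainstScikitImage:
    """Loose cross-checks against an independent library (convention
    differences of one gray level are expected)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_otsu_close_to_skimage(self, seed):
        skfilters = pytest.importorskip("skimage.filters")
        counts = mixture_histogram(np.random.default_rng(800 + seed))
        ours = threshold_otsu(counts).threshold
        theirs = skfilters.threshold_otsu(hist=(counts, np.arange(256)))
        assert abs(ours - theirs) <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_isodata_close_to_skimage(self, seed):
        skfilters = pytest.importorskip("skimage.filters")
        counts = mixture_histogram(np.random.default_rng(900 + seed))
        ours = threshold_isodata(counts).threshold
        theirs = skfilters.threshold_isodata(hist=(counts, np.arange(256)))
        # skimage rounds the fixed point instead of scanning for the first
        # t at or past the class-mean midpoint
        assert abs(ours - theirs) <= 2
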