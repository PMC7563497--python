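"""Barcode layouts, brightness mapping, marker coloring and rendering."""

import io

import numpy as np
import pytest
from PIL import Image

from glycobarcode.encode import (
    BarcodeEncoder,
    GridSpec,
    MarkerPanel,
    colorize,
    layout_from_loadings,
    marker_attenuation,
    pca_layout,
    pca_loadings,
    render,
    rt_layout,
    save_png,
    scale_features,
    to_grayscale,
)

from conftest import make_matrix


class TestGrid:
    def test_study_default(self):
        g = GridSpec.for_n_features(1712)
        assert (g.ncols, g.nrows) == (41, 42)
        assert g.blanks(1712) == 10

    @pytest.mark.parametrize("n", [4, 17, 100, 1000])
    def test_general_rule(self, n):
        g = GridSpec.for_n_features(n)
        assert g.capacity >= n
        assert g.nrows == int(np.ceil(np.sqrt(n)))


class TestRtLayout:
    def test_row_major_order(self):
        meta = make_matrix(np.ones((2, 4)), rts=[1, 2, 3, 4], mzs=[900, 901, 902, 903]).feature_meta
        lay = rt_layout(meta, GridSpec(ncols=2, nrows=2))
        assert [lay.cell_of[k] for k in range(4)] == [(0, 0), (1, 0), (0, 1), (1, 1)]

    def test_study_scale_blanks(self, study_cohort):
        lay = rt_layout(study_cohort.matrix.feature_meta)
        assert lay.n_features == 1712
        blanks = lay.blank_cells()
        assert len(blanks) == 10
        # trailing cells of the row-major fill: last row, rightmost columns
        assert blanks == {(c, 41) for c in range(31, 41)}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 37
        rts = rng.uniform(1, 14, n)
        meta = make_matrix(np.ones((2, n)), rts=rts, mzs=rng.uniform(800, 3000, n)).feature_meta
        grid = GridSpec.for_n_features(n)
        lay = rt_layout(meta, grid)
        order = np.argsort(rts, kind="stable")
        for k, f in enumerate(order):
            assert lay.cell_of[int(f)] == (k % grid.ncols, k // grid.ncols)

    def test_overflow_errors(self):
        meta = make_matrix(np.ones((2, 5))).feature_meta
        with pytest.raises(ValueError, match="capacity"):
            rt_layout(meta, GridSpec(ncols=2, nrows=2))


class TestPcaLayout:
    def test_grouping_from_crafted_loadings(self):
        # six features, 2 columns x 3 rows; hand-executed sort/group/sort
        l1 = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        l2 = np.array([9.0, 8.0, 7.0, 3.0, 2.0, 1.0])
        lay = layout_from_loadings(l1, l2, GridSpec(ncols=2, nrows=3))
        # column 0 holds features 0,1,2 ordered by ascending L2: 2,1,0
        assert lay.cell_of[2] == (0, 0)
        assert lay.cell_of[1] == (0, 1)
        assert lay.cell_of[0] == (0, 2)
        # column 1 holds features 3,4,5 ordered as 5,4,3
        assert lay.cell_of[5] == (1, 0)
        assert lay.cell_of[4] == (1, 1)
        assert lay.cell_of[3] == (1, 2)

    def test_study_scale_groups_and_blanks(self, study_cohort):
        lay = pca_layout(study_cohort.matrix)
        cols = np.array([c for c, _ in lay.cell_of.values()])
        counts = np.bincount(cols, minlength=41)
        assert len(counts) == 41
        assert (counts[:40] == 42).all() and counts[40] == 32
        # 10 blanks at the bottom of the last column
        assert lay.blank_cells() == {(40, r) for r in range(32, 42)}

    def test_loadings_sign_canonical(self, tiny_cohort):
        l1, l2 = pca_loadings(tiny_cohort.matrix.values.to_numpy())
        assert l1[np.argmax(np.abs(l1))] > 0
        assert l2[np.argmax(np.abs(l2))] > 0

    def test_sign_flip_preserves_column_comembership(self):
        rng = np.random.default_rng(0)
        l1, l2 = rng.normal(size=(2, 12))
        grid = GridSpec(ncols=4, nrows=3)

        def comembers(lay):
            cols = {}
            for f, (c, _) in lay.cell_of.items():
                cols.setdefault(c, set()).add(f)
            return {frozenset(v) for v in cols.values()}

        a = comembers(layout_from_loadings(l1, l2, grid))
        # a global sign flip mirrors the column order but keeps the groups
        b = comembers(layout_from_loadings(-l1, -l2, grid))
        assert a == b

    def test_degenerate_matrix_errors(self):
        x = np.outer(np.arange(4, dtype=float), np.ones(6))  # rank 1 after scaling
        with pytest.raises(ValueError, match="rank"):
            pca_layout(x, GridSpec(ncols=2, nrows=3))
        with pytest.raises(ValueError, match="2 samples"):
            pca_layout(np.ones((1, 6)), GridSpec(ncols=2, nrows=3))

    def test_scaling_zero_variance_to_zero(self):
        x = np.column_stack([np.arange(5.0), np.full(5, 3.0)])
        s = scale_features(x)
        assert np.allclose(s[:, 1], 0.0)
        assert np.isclose(s[:, 0].std(ddof=1), 1.0)

    def test_purity_beats_rt_on_block_data(self):
        # two anti-correlated feature blocks: the PCA layout should pack each
        # column with features from mostly one block, unlike elution order
        def purity(lay, block):
            cols = {}
            for f, (c, _) in lay.cell_of.items():
                cols.setdefault(c, []).append(block[f])
            per_col = [max(np.mean(b), 1 - np.mean(b)) for b in cols.values()]
            return float(np.mean(per_col))

        n_feat, n_samp = 40, 30
        block = np.repeat([0, 1], n_feat // 2)
        pca_p, rt_p = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            factor = rng.normal(size=n_samp)
            sign = np.where(block == 0, 1.0, -1.0)
            x = np.exp(factor[:, None] * sign[None, :] * 0.5 + 0.2 * rng.normal(size=(n_samp, n_feat)))
            grid = GridSpec.for_n_features(n_feat)
            pca_p.append(purity(pca_layout(x, grid), block))
            rts = rng.uniform(1, 14, n_feat)
            meta = make_matrix(x, rts=rts, mzs=rng.uniform(800, 3000, n_feat)).feature_meta
            rt_p.append(purity(rt_layout(meta, grid), block))
        assert np.mean(pca_p) > np.mean(rt_p)


class TestGrayscale:
    def _layout(self, n=4):
        meta = make_matrix(np.ones((2, n))).feature_meta
        return rt_layout(meta, GridSpec.for_n_features(n))

    def test_midpoint_black_white(self):
        lay = self._layout(3)
        img = to_grayscale(np.array([1.0, 4.0, 0.25]), lay, clip=2.0)
        cells = [img.channels[r, c, 0] for c, r in (lay.cell_of[k] for k in range(3))]
        assert cells == [128, 0, 255]  # mid-gray, black (strong), white (weak)

    def test_blanks_white(self):
        lay = self._layout(3)  # 2x2 grid, one blank
        img = to_grayscale(np.ones(3), lay)
        (c, r) = next(iter(lay.blank_cells()))
        assert tuple(img.channels[r, c]) == (255, 255, 255)
        assert img.is_monochrome()

    def test_monotone_nonincreasing(self):
        lay = self._layout(1)
        ratios = np.linspace(0.01, 10, 200)
        vals = [to_grayscale(np.array([r]), lay).channels[0, 0, 0] for r in ratios]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_validation(self):
        lay = self._layout(2)
        with pytest.raises(ValueError, match="non-negative"):
            to_grayscale(np.array([-1.0, 1.0]), lay)
        with pytest.raises(ValueError, match="clip"):
            to_grayscale(np.ones(2), lay, clip=0.0)


class TestColorize:
    def _mono(self, n=3):
        lay = TestGrayscale()._layout(n)
        return to_grayscale(np.ones(n), lay), lay

    def test_zero_markers_identity(self):
        img, _ = self._mono()
        out = colorize(img, MarkerPanel(0.0, 0.0))
        np.testing.assert_array_equal(out.channels, img.channels)

    def test_saturating_markers_blue_blank(self):
        img, lay = self._mono()
        out = colorize(img, MarkerPanel(1e7, 1e7))
        (c, r) = next(iter(lay.blank_cells()))
        assert tuple(out.channels[r, c]) == (0, 0, 255)

    def test_default_reference_points(self):
        # at the clinical cutoffs the attenuation is 1 - log10(2)/2 ~ 0.849
        img, lay = self._mono()
        f = marker_attenuation(35.0, 35.0)
        assert np.isclose(f, 1 - np.log10(2) / 2)
        out = colorize(img, MarkerPanel(35.0, 70.0))
        (c, r) = next(iter(lay.blank_cells()))
        assert tuple(out.channels[r, c]) == (217, 217, 255)

    def test_blue_channel_untouched(self):
        img, _ = self._mono()
        rng = np.random.default_rng(0)
        for _ in range(5):
            out = colorize(img, MarkerPanel(rng.uniform(0, 500), rng.uniform(0, 500)))
            np.testing.assert_array_equal(out.channels[..., 2], img.channels[..., 0])

    def test_negative_markers_rejected(self):
        with pytest.raises(ValueError):
            MarkerPanel(-1.0, 5.0)

    def test_requires_monochrome(self):
        img, _ = self._mono()
        colored = colorize(img, MarkerPanel(100.0, 100.0))
        with pytest.raises(ValueError, match="monochrome"):
            colorize(colored, MarkerPanel(0.0, 0.0))


class TestRender:
    def test_nearest_neighbor_invents_no_colors(self, tiny_cohort):
        lay = pca_layout(tiny_cohort.matrix)
        img = to_grayscale(tiny_cohort.matrix.values.to_numpy()[0], lay)
        raster = render(img, 227)
        assert raster.shape == (227, 227, 3)
        grid_colors = {tuple(px) for px in img.channels.reshape(-1, 3)}
        raster_colors = {tuple(px) for px in raster.reshape(-1, 3)}
        assert raster_colors <= grid_colors

    def test_png_roundtrip_lossless(self, tmp_path):
        meta = make_matrix(np.ones((2, 4))).feature_meta
        lay = rt_layout(meta, GridSpec(ncols=2, nrows=2))
        img = to_grayscale(np.array([0.3, 1.0, 2.0, 5.0]), lay)
        path = tmp_path / "b.png"
        save_png(img, path, side=64)
        reloaded = np.asarray(Image.open(path))
        np.testing.assert_array_equal(reloaded, render(img, 64))

    def test_all_white_single_cell(self):
        from glycobarcode.encode import BarcodeImage

        img = BarcodeImage(channels=np.full((1, 1, 3), 255, np.uint8), grid=GridSpec(1, 1))
        assert (render(img, 8) == 255).all()

    def test_side_smaller_than_grid_errors(self):
        meta = make_matrix(np.ones((2, 4))).feature_meta
        lay = rt_layout(meta, GridSpec(ncols=2, nrows=2))
        img = to_grayscale(np.ones(4), lay)
        with pytest.raises(ValueError, match="side"):
            render(img, 1)


class TestBarcodeEncoder:
    def test_transform_shapes_and_mono(self, tiny_cohort):
        enc = BarcodeEncoder(layout="pca", color="mono", image_side=64)
        imgs = enc.fit_transform(tiny_cohort.matrix)
        assert imgs.shape == (60, 64, 64, 3) and imgs.dtype == np.uint8
        assert (imgs[..., 0] == imgs[..., 1]).all() and (imgs[..., 1] == imgs[..., 2]).all()

    def test_multicolor_requires_markers(self, tiny_cohort):
        enc = BarcodeEncoder(layout="pca", color="multicolor", image_side=64)
        enc.fit(tiny_cohort.matrix)
        with pytest.raises(ValueError, match="marker"):
            enc.transform(tiny_cohort.matrix)
        imgs = enc.transform(tiny_cohort.matrix, markers=tiny_cohort.markers)
        # only R and G differ from the mono encoding
        mono = BarcodeEncoder(layout="pca", color="mono", image_side=64).fit_transform(
            tiny_cohort.matrix
        )
        np.testing.assert_array_equal(imgs[..., 2], mono[..., 2])
        assert (imgs[..., 0] <= mono[..., 0]).all()

    def test_rt_layout_needs_meta(self):
        enc = BarcodeEncoder(layout="rt")
        with pytest.raises(ValueError, match="feature_meta"):
            enc.fit(np.random.default_rng(0).uniform(size=(5, 9)))

    def test_sklearn_params_roundtrip(self):
        enc = BarcodeEncoder(clip=3.0)
        assert BarcodeEncoder(**enc.get_params()).clip == 3.0
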