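"""Heuristic engine stages against constructed rasters and phantom truth."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from myelinquant import (HeuristicParams, LabelMask, PhantomSpec,
                         clahe_enhance, generate_phantom, ridge_filter,
                         run_heuristic)
from myelinquant.heuristic import (HeuristicSegmenter, associate_segments,
                                   ridge_score, segment_cell_bodies,
                                   subtract_cell_bodies)


class TestClahe:
    def test_constant_raster_stays_constant(self):
        out = clahe_enhance(np.full((64, 64), 7.0))
        assert np.allclose(out, out.flat[0])

    def test_output_range(self, rng):
        out = clahe_enhance(rng.random((128, 128)) * 900)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            clahe_enhance(np.zeros((4, 4, 4)))

    def test_contrast_separation_increases_on_dim_phantom(self):
        spec = PhantomSpec(height_px=256, width_px=256, n_cells=4,
                           p_ensheathing=1.0, noise_sd=0.005, seed=3)
        img, truth = generate_phantom(spec)
        # weak signal riding on a strong illumination gradient: globally
        # normalized contrast is poor, local equalization recovers it
        yy = np.linspace(0.0, 4.0, 256)[:, None]
        raw = img.channels["membrane"] * 0.3 + yy + 0.2 * yy.T
        sheath = truth.sheaths.raster > 0
        norm = (raw - raw.min()) / (raw.max() - raw.min())
        enhanced = clahe_enhance(raw)
        sep_before = norm[sheath].mean() - norm[~sheath].mean()
        sep_after = enhanced[sheath].mean() - enhanced[~sheath].mean()
        assert sep_after > sep_before


def _bar_image(h=200, w=64, width=4, value=1.0):
    img = np.zeros((h, w))
    x0 = w // 2 - width // 2
    img[50:150, x0:x0 + width] = value
    bar = np.zeros((h, w), dtype=bool)
    bar[50:150, x0:x0 + width] = True
    return img, bar


class TestRidgeFilter:
    def test_empty_raster_empty_mask(self):
        assert not ridge_filter(np.zeros((64, 64)), 2.0, 0.05).any()

    def test_bright_bar_recovered(self):
        img, bar = _bar_image()
        mask = ridge_filter(img, sigma=2.0, sensitivity=0.05)
        assert (mask & bar).sum() >= 0.9 * bar.sum()
        assert (mask & ~bar).sum() <= 0.05 * (~bar).sum()

    def test_bar_outscores_equal_peak_blob(self):
        img = np.zeros((128, 128))
        img[20:100, 30:34] = 1.0  # bar
        yy, xx = np.mgrid[:128, :128]
        blob = np.exp(-((yy - 64) ** 2 + (xx - 96) ** 2) / (2 * 4.0 ** 2))
        img = np.maximum(img, blob)
        score = ridge_score(img, sigma=2.0)
        bar_region = np.zeros_like(img, dtype=bool)
        bar_region[15:105, 25:40] = True
        assert score[bar_region].max() > score[~bar_region].max()

    def test_score_matches_finite_difference_hessian_at_bar_center(self):
        img, bar = _bar_image()
        sigma = 2.0
        score = ridge_score(img, sigma)
        y, x = np.unravel_index(np.argmax(score), score.shape)
        # independent oracle: finite-difference Hessian of the smoothed
        # image, eigenvalues sorted by magnitude, same ridge-likeness
        sm = ndi.gaussian_filter(img.astype(float), sigma)
        hyy = sm[y + 1, x] - 2 * sm[y, x] + sm[y - 1, x]
        hxx = sm[y, x + 1] - 2 * sm[y, x] + sm[y, x - 1]
        hxy = (sm[y + 1, x + 1] - sm[y + 1, x - 1]
               - sm[y - 1, x + 1] + sm[y - 1, x - 1]) / 4.0
        evals = np.linalg.eigvalsh([[hyy, hxy], [hxy, hxx]])
        lam1, lam2 = sorted(evals, key=abs)
        oracle = abs(lam2) * (1 - abs(lam1) / abs(lam2)) if lam2 < 0 else 0.0
        assert score[y, x] == pytest.approx(oracle, rel=0.25)

    def test_sensitivity_monotone_in_pixel_count(self, small_phantom):
        img, _ = small_phantom
        enh = clahe_enhance(img.channels["membrane"])
        counts = [ridge_filter(enh, 2.0, s).sum()
                  for s in (0.02, 0.05, 0.10, 0.3)]
        assert counts == sorted(counts)

    def test_oversized_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            ridge_filter(np.zeros((16, 16)), sigma=100.0, sensitivity=0.1)


def _disc_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


class TestCellBodies:
    params = HeuristicParams()

    def test_single_disc_single_body(self):
        membrane = _disc_mask((96, 96), 48, 48, 20).astype(float)
        nuclei = LabelMask(_disc_mask((96, 96), 48, 48, 6).astype(np.uint16))
        bodies = segment_cell_bodies(membrane, nuclei, self.params)
        assert list(bodies.labels) == [1]

    def test_overlapping_discs_split_near_waist(self):
        shape = (96, 160)
        d1 = _disc_mask(shape, 48, 50, 20)
        d2 = _disc_mask(shape, 48, 78, 20)  # overlap ~30% of radius
        membrane = (d1 | d2).astype(float)
        nuc = np.zeros(shape, dtype=np.uint16)
        nuc[_disc_mask(shape, 48, 50, 5)] = 1
        nuc[_disc_mask(shape, 48, 78, 5)] = 2
        bodies = segment_cell_bodies(membrane, LabelMask(nuc), self.params)
        assert set(bodies.labels) == {1, 2}
        # majority of each truth disc's exclusive pixels carry its own label
        for label, disc, other in ((1, d1, d2), (2, d2, d1)):
            own = disc & ~other
            got = bodies.raster[own]
            assert (got == label).sum() > 0.5 * own.sum()

    def test_disc_without_nucleus_dropped(self):
        shape = (96, 160)
        membrane = (_disc_mask(shape, 48, 40, 18)
                    | _disc_mask(shape, 48, 120, 18)).astype(float)
        nuc = np.zeros(shape, dtype=np.uint16)
        nuc[_disc_mask(shape, 48, 40, 5)] = 1
        bodies = segment_cell_bodies(membrane, LabelMask(nuc), self.params)
        assert set(bodies.labels) == {1}
        assert not bodies.raster[:, 100:].any()

    def test_empty_nuclei_empty_result(self):
        membrane = _disc_mask((64, 64), 32, 32, 15).astype(float)
        bodies = segment_cell_bodies(
            membrane, LabelMask(np.zeros((64, 64), dtype=np.uint16)),
            self.params)
        assert len(bodies.labels) == 0


class TestSubtractAndAssociate:
    def test_subtraction_set_arithmetic(self, rng):
        ridge = rng.random((64, 64)) > 0.6
        bodies = LabelMask((rng.random((64, 64)) > 0.7).astype(np.uint16))
        out = subtract_cell_bodies(ridge, bodies)
        assert out.sum() == ridge.sum() - (ridge & (bodies.raster > 0)).sum()
        assert not (out & (bodies.raster > 0)).any()

    def test_disjoint_masks_unchanged(self):
        ridge = np.zeros((32, 32), dtype=bool)
        ridge[:, :8] = True
        bodies = np.zeros((32, 32), dtype=np.uint16)
        bodies[:, 20:] = 1
        out = subtract_cell_bodies(ridge, LabelMask(bodies))
        np.testing.assert_array_equal(out, ridge)

    def test_ridge_inside_body_vanishes(self):
        ridge = np.zeros((32, 32), dtype=bool)
        ridge[10:20, 10:20] = True
        bodies = np.zeros((32, 32), dtype=np.uint16)
        bodies[5:25, 5:25] = 3
        assert not subtract_cell_bodies(ridge, LabelMask(bodies)).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_cell_bodies(np.zeros((8, 8), dtype=bool),
                                 LabelMask(np.zeros((9, 8),
                                                    dtype=np.uint16)))

    def _setup(self):
        bodies = np.zeros((64, 64), dtype=np.uint16)
        bodies[28:36, 2:10] = 1   # body A
        bodies[28:36, 54:62] = 2  # body B
        return LabelMask(bodies)

    def test_nearest_body_wins(self):
        bodies = self._setup()
        seg = np.zeros((64, 64), dtype=np.int32)
        seg[30:34, 11:44] = 1  # 1 px from A, 10 px from B
        out = associate_segments(seg, bodies, HeuristicParams(), 0.5)
        assert out == {1: 1}

    def test_touching_segment_assigned(self):
        bodies = self._setup()
        seg = np.zeros((64, 64), dtype=np.int32)
        seg[30:34, 10:30] = 1  # touches A
        assert associate_segments(seg, bodies, HeuristicParams(),
                                  0.5) == {1: 1}

    def test_far_segment_dropped(self):
        bodies = self._setup()
        seg = np.zeros((64, 64), dtype=np.int32)
        seg[30:34, 31:33] = 1  # ~21 px from both, gap is 4 px
        assert associate_segments(seg, bodies, HeuristicParams(), 0.5) == {}

    def test_empty_inputs_empty_map(self):
        out = associate_segments(
            np.zeros((16, 16), dtype=np.int32),
            LabelMask(np.zeros((16, 16), dtype=np.uint16)),
            HeuristicParams(), 0.5)
        assert out == {}


class TestPipeline:
    def test_recovers_separated_cells(self, small_phantom):
        img, truth = small_phantom
        cells = run_heuristic(img)
        assert len(cells) >= 8  # >= 8 of 10 ensheathing cells
        assert all(c.n_sheaths >= 1 for c in cells)

    def test_no_pixel_claimed_twice(self, small_phantom):
        img, _ = small_phantom
        cells = run_heuristic(img)
        allpx = np.concatenate([c.pixel_indices for c in cells])
        assert len(allpx) == len(np.unique(allpx))

    def test_no_ensheathing_cells_reported_when_none_exist(self):
        spec = PhantomSpec(height_px=512, width_px=512, n_cells=8,
                           p_ensheathing=0.0, noise_sd=0.02, seed=8)
        img, _ = generate_phantom(spec)
        assert run_heuristic(img) == []

    def test_min_length_monotonicity(self, small_phantom):
        img, _ = small_phantom
        loose = {c.cell_id: c.n_sheaths
                 for c in run_heuristic(img, HeuristicParams())}
        strict = {c.cell_id: c.n_sheaths
                  for c in run_heuristic(
                      img, HeuristicParams(min_length_um=25.0))}
        assert set(strict) <= set(loose) or all(
            strict.get(k, 0) <= loose.get(k, 1 << 30) for k in strict)
        for k, n in strict.items():
            assert n <= loose.get(k, 0) or k not in loose

    def test_estimator_wrapper_roundtrip(self, small_phantom):
        img, _ = small_phantom
        est = HeuristicSegmenter(ridge_sensitivity=0.05)
        assert est.get_params()["ridge_sensitivity"] == 0.05
        cells = est.fit().predict(img)
        assert cells and cells[0].pixel_indices.size > 0
        est2 = HeuristicSegmenter(**est.get_params())
        cells2 = est2.predict(img)
        assert len(cells2) == len(cells)
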