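"""Registration, measurement masks, median intensities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clemux.correlation import (
    AffineTransform,
    build_masks,
    fit_affine,
    measure_intensities,
    read_transform,
    write_transform,
)
from clemux.segmentation import CellRecord
from clemux.synthetic import truth_cell_records

RNG = np.random.default_rng(0)
POINTS = RNG.uniform(0, 1000, size=(8, 2))


def _square_cell(cid, cx, cy, half):
    outline = np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
            [cx - half, cy - half],
        ],
        dtype=float,
    )
    return CellRecord(
        id=cid, centroid=(cx, cy), outline=outline,
        area_px=(2 * half) ** 2, area_um2=0.0, circularity=0.8,
    )


class TestAffine:
    def test_identity_on_identical_points(self):
        tform, res = fit_affine(POINTS, POINTS)
        assert np.allclose(tform.matrix, AffineTransform.identity().matrix, atol=1e-10)
        assert np.allclose(res, 0.0, atol=1e-9)

    def test_exact_recovery_of_similarity(self):
        truth = AffineTransform.from_params(8.0, 7.0, (50.0, -20.0))
        tform, res = fit_affine(POINTS, truth(POINTS))
        assert np.abs(tform.matrix - truth.matrix).max() < 1e-9
        assert res.max() < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-2, 2), min_size=6, max_size=6))
    def test_recovers_any_nondegenerate_affine(self, coeffs):
        m = np.array(coeffs).reshape(2, 3)
        m[:, 2] *= 100
        if abs(np.linalg.det(m[:, :2])) < 1e-3:
            return
        truth = AffineTransform(m)
        tform, _ = fit_affine(POINTS, truth(POINTS))
        assert np.abs(tform.matrix - truth.matrix).max() < 1e-6

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_affine(POINTS[:2], POINTS[:2])

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [5, 5]], dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_affine(src, src)

    def test_inverse_composes_to_identity(self):
        t = AffineTransform.from_params(8.0, 7.0, (50.0, -20.0))
        roundtrip = t.compose(t.inverse())
        pts = RNG.uniform(0, 5000, size=(50, 2))
        assert np.abs(roundtrip(pts) - pts).max() < 1e-9

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 0.0]]))

    def test_text_sidecar_roundtrip(self, tmp_path):
        t = AffineTransform.from_params(8.0, 7.0, (50.0, -20.0), direction="LM->EM")
        path = tmp_path / "t.txt"
        write_transform(t, path)
        back = read_transform(path)
        assert np.array_equal(back.matrix, t.matrix)
        assert back.direction == "LM->EM"


class TestBuildMasks:
    def test_isolated_cell_dilation_zero_is_filled_outline(self):
        cell = _square_cell(0, 20, 20, 5)
        (mm,) = build_masks([cell], None, 0.0, AffineTransform.identity(), (50, 50))
        m = mm.mask
        # filled square: all interior pixels, none far outside
        assert m[16:25, 16:25].all()
        assert not m[:14].any() and not m[:, :14].any()

    def test_overlapping_dilations_removed_from_both(self):
        a = _square_cell(0, 20, 20, 6)
        b = _square_cell(1, 30, 20, 6)
        masks = build_masks([a, b], None, 0.3, AffineTransform.identity(), (60, 60), 100.0)
        inter = masks[0].mask & masks[1].mask
        assert not inter.any()
        # the contested column between the squares belongs to neither
        assert not masks[0].mask[:, 25].any() and not masks[1].mask[:, 25].any()

    def test_holes_subtracted(self):
        cell = _square_cell(0, 20, 20, 6)
        holes = np.zeros((60, 60), dtype=bool)
        holes[18:23, 18:23] = True
        (mm,) = build_masks([cell], holes, 0.0, AffineTransform.identity(), (60, 60))
        assert not (mm.mask & holes).any()
        assert mm.n_px > 0

    def test_cell_outside_image_excluded(self):
        cell = _square_cell(0, 500, 500, 5)
        (mm,) = build_masks([cell], None, 0.0, AffineTransform.identity(), (50, 50))
        assert mm.excluded and mm.n_px == 0

    def test_non_ok_cells_skipped(self):
        bad = _square_cell(0, 20, 20, 5)
        bad.flags = frozenset({"excluded_shape"})
        assert build_masks([bad], None, 0.0, AffineTransform.identity(), (50, 50)) == []

    def test_masks_cover_truth_rings(self, em_sample):
        """At default dilation the masks capture >= 95% of each cell's wall ring."""
        cells = truth_cell_records(em_sample, frame="lm")
        masks = build_masks(
            cells, None, 0.2, AffineTransform.identity(), em_sample.lm_shape, 100.0
        )
        mask_of = {m.cell_id: m for m in masks}
        yy, xx = np.mgrid[0 : em_sample.lm_shape[0], 0 : em_sample.lm_shape[1]]
        for _, row in em_sample.truth.iterrows():
            ct, st_ = np.cos(row.theta_rad), np.sin(row.theta_rad)
            dx, dy = xx - row.lm_x, yy - row.lm_y
            rho = np.sqrt(
                ((dx * ct + dy * st_) / row.r1_px) ** 2
                + ((-dx * st_ + dy * ct) / row.r2_px) ** 2
            )
            ring = (rho <= 1.0) & (rho >= 0.65)
            covered = mask_of[int(row.id)].mask[ring].mean()
            assert covered >= 0.95

    def test_masks_pairwise_disjoint_and_hole_free(self, em_sample, detected):
        cells, holes = detected
        tform, _ = fit_affine(
            em_sample.control_points[["em_x", "em_y"]].to_numpy(),
            em_sample.control_points[["lm_x", "lm_y"]].to_numpy(),
        )
        masks = build_masks(cells, holes, 0.2, tform, em_sample.lm_shape, 100.0)
        coverage = np.zeros(em_sample.lm_shape, dtype=np.int32)
        for mm in masks:
            coverage += mm.mask
        assert coverage.max() <= 1
        from clemux.correlation import warp_mask

        holes_lm = warp_mask(holes, tform, em_sample.lm_shape)
        assert not (coverage.astype(bool) & holes_lm).any()


class TestMeasureIntensities:
    def test_constant_image(self):
        img = np.full((1, 30, 30), 7.0)
        cell = _square_cell(0, 15, 15, 5)
        (mm,) = build_masks([cell], None, 0.0, AffineTransform.identity(), (30, 30))
        df = measure_intensities(img, [mm], ["c0"])
        assert df.loc[0, "c0"] == 7.0
        assert df.loc[0, "n_px"] == mm.n_px

    def test_median_definition(self):
        from clemux.correlation import MeasurementMask

        img = np.zeros((1, 2, 3))
        img[0, 0] = [1.0, 2.0, 100.0]
        mm = MeasurementMask(0, np.array([0, 1, 2]), (2, 3))
        df = measure_intensities(img, [mm], ["c0"])
        assert df.loc[0, "c0"] == 2.0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_pixel_order(self, seed):
        from clemux.correlation import MeasurementMask

        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 100, size=(2, 10, 10))
        idx = np.sort(rng.choice(100, size=17, replace=False))
        a = MeasurementMask(0, idx, (10, 10))
        b = MeasurementMask(0, rng.permutation(idx), (10, 10))
        da = measure_intensities(img, [a], ["x", "y"])
        db = measure_intensities(img, [b], ["x", "y"])
        assert (da[["x", "y"]].to_numpy() == db[["x", "y"]].to_numpy()).all()

    def test_empty_mask_gives_nan_row(self):
        from clemux.correlation import MeasurementMask

        img = np.ones((1, 5, 5))
        mm = MeasurementMask(3, np.array([], dtype=np.int64), (5, 5), excluded=True)
        df = measure_intensities(img, [mm], ["c0"])
        assert df.loc[0, "id"] == 3
        assert np.isnan(df.loc[0, "c0"])

    def test_noiseless_sample_medians_exact(self, panel3):
        """On a noiseless sample the masked medians equal the constructed values."""
        from clemux.synthetic import NoiseConfig, enumerate_patterns, render_sample

        noise = NoiseConfig(gaussian_cv=0.0)
        pats = enumerate_patterns(panel3)
        s = render_sample(panel3, pats, 2, noise=noise, seed=13, render_em=False)
        cells = truth_cell_records(s, frame="lm")
        masks = build_masks(cells, None, 0.2, AffineTransform.identity(), s.lm_shape, 100.0)
        df = measure_intensities(s.lm_stack, masks, list(panel3.names)).set_index("id")
        cfg_interior = 0.3  # RenderConfig default interior staining level
        for _, row in s.truth.iterrows():
            bits = [int(b) for b in row.pattern]
            for c, name in enumerate(panel3.names):
                med = df.loc[int(row.id), name]
                if bits[c]:
                    # the median sits between the interior and wall-ring
                    # staining levels, both proportional to the cell brightness
                    lo = cfg_interior * row.brightness + noise.background
                    hi = row.brightness + noise.background
                    assert lo * (1 - 1e-5) <= med <= hi * (1 + 1e-5)
                else:
                    assert med == pytest.approx(noise.background, rel=1e-5)
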