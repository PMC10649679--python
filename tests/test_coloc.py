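import numpy as np
import pytest

from vesiscope.imgmodel import Movie, PipelineParams, Stack3D
from vesiscope.coloc import (
    confocal_coloc,
    huang_threshold,
    pearson_coefficient,
    segment_cells_tirf,
    segment_cytoplasm_confocal,
    tirf_coloc,
)
from vesiscope.synthetic import generate_correlated_pair


class TestPearson:
    def test_identical_channels(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 100, (32, 32))
        assert pearson_coefficient(a, a, np.ones((32, 32), bool)) == pytest.approx(1.0)

    def test_anticorrelated_channels(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, (32, 32))
        b = 200.0 - a
        assert pearson_coefficient(a, b, np.ones((32, 32), bool)) == pytest.approx(-1.0)

    def test_affine_invariance_per_channel(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 50, (40, 40))
        b = rng.uniform(0, 50, (40, 40))
        mask = np.ones((40, 40), bool)
        r = pearson_coefficient(a, b, mask)
        r2 = pearson_coefficient(3.0 * a + 7.0, 0.5 * b + 100.0, mask)
        assert r2 == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("rho", [-0.5, 0.0, 0.5, 0.9])
    def test_recovery_on_correlated_pairs(self, rho):
        f1, f2, _ = generate_correlated_pair((100, 100), rho, seed=17)
        r = pearson_coefficient(f1, f2, np.ones((100, 100), bool))
        assert r == pytest.approx(rho, abs=0.05)

    def test_zero_variance_flagged(self):
        a = np.full((8, 8), 5.0)
        b = np.arange(64, dtype=float).reshape(8, 8)
        with pytest.warns(UserWarning):
            out = pearson_coefficient(a, b, np.ones((8, 8), bool))
        assert np.isnan(out)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            pearson_coefficient(np.ones((4, 4)), np.ones((4, 4)), np.zeros((4, 4), bool))


def test_huang_threshold_separates_bimodal_histogram():
    rng = np.random.default_rng(0)
    img = np.concatenate([rng.normal(20, 3, 6000), rng.normal(150, 12, 3000)])
    t = huang_threshold(img)
    assert 25 < t < 140
    with pytest.raises(ValueError):
        huang_threshold(np.full(100, 3.0))


def _disk(yy, xx, cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def make_tirf_pair(shapes, pixel_size=0.5, n_frames=6, noise=3.0, seed=0):
    """Two-channel movie with the given binary shapes at intensity 100 on
    background 20."""
    rng = np.random.default_rng(seed)
    h = w = 160
    frames = []
    base_mask = np.zeros((h, w), bool)
    for m in shapes:
        base_mask |= m
    for t in range(n_frames):
        img = 20 + 100.0 * base_mask + rng.normal(0, noise, (h, w))
        frames.append(np.clip(img, 0, None))
    mov = Movie.from_array(np.stack(frames), 0.735, pixel_size)
    return mov


class TestSegmentCellsTirf:
    yy, xx = np.mgrid[0:160, 0:160]

    def test_two_disk_cells_tracked(self):
        m1 = _disk(self.yy, self.xx, 50, 50, 12)   # ~113 um^2 at 0.5 um/px
        m2 = _disk(self.yy, self.xx, 110, 110, 16)  # ~200 um^2
        mov = make_tirf_pair([m1, m2])
        cells = segment_cells_tirf(mov, mov)
        assert len(cells) == 2
        areas = sorted(c.areas_um2[0] for c in cells)
        assert areas[0] == pytest.approx(113, rel=0.1)
        assert areas[1] == pytest.approx(201, rel=0.1)
        assert all(c.n_frames() >= 5 for c in cells)

    def test_low_circularity_removed(self):
        # a 2 px wide line: circularity 4*pi*A/P^2 far below 0.2
        line = np.zeros((160, 160), bool)
        line[80:82, 10:150] = True
        mov = make_tirf_pair([line])
        assert segment_cells_tirf(mov, mov) == []

    def test_oversized_cell_removed(self):
        big = _disk(self.yy, self.xx, 80, 80, 50)  # ~1963 px -> 490*... 7850px*0.25=1963 um^2
        mov = make_tirf_pair([big])
        assert segment_cells_tirf(mov, mov) == []

    def test_undersized_fragment_removed(self):
        tiny = _disk(self.yy, self.xx, 80, 80, 5)  # ~78 px -> ~20 um^2 < 25
        mov = make_tirf_pair([tiny])
        assert segment_cells_tirf(mov, mov) == []

    def test_masks_disjoint_and_filters_hold(self, params):
        m1 = _disk(self.yy, self.xx, 50, 50, 12)
        m2 = _disk(self.yy, self.xx, 110, 110, 16)
        mov = make_tirf_pair([m1, m2])
        cells = segment_cells_tirf(mov, mov)
        lo, hi = params.cell_area_range_um2
        for c in cells:
            for a, circ in zip(c.areas_um2, c.circularities):
                assert lo <= a <= hi
                assert circ > params.circularity_min
        for t in cells[0].frames:
            i0 = cells[0].frames.index(t)
            if t in cells[1].frames:
                i1 = cells[1].frames.index(t)
                assert not np.any(cells[0].masks[i0] & cells[1].masks[i1])

    def test_tirf_coloc_pcc_of_identical_channels(self):
        m1 = _disk(self.yy, self.xx, 50, 50, 12)
        mov = make_tirf_pair([m1])
        df, cells = tirf_coloc(mov, mov)
        assert len(cells) == 1
        assert (df["pcc"] > 0.99).all()


def make_confocal_scene(nucleus_radii=(9,), nucleus_centers=((12, 32, 32),),
                        cell_radius=20, cell_center=(12, 32, 32), seed=0,
                        shape=(24, 64, 64), z_spacing=0.6, pixel=0.3):
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    zf = z_spacing / pixel
    cz, cy, cx = cell_center
    cell = ((zz - cz) * zf) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= cell_radius**2
    nuc = np.zeros(shape, bool)
    for (nz, ny, nx), r in zip(nucleus_centers, nucleus_radii):
        nuc |= ((zz - nz) * zf) ** 2 + (yy - ny) ** 2 + (xx - nx) ** 2 <= r**2
    gfp = np.clip(10 + 120.0 * cell + rng.normal(0, 2, shape), 0, None)
    hoechst = np.clip(5 + 150.0 * nuc + rng.normal(0, 2, shape), 0, None)
    return (
        Stack3D.from_array(gfp, pixel, z_spacing),
        Stack3D.from_array(hoechst, pixel, z_spacing),
        cell,
        nuc,
    )


class TestCytoplasmConfocal:
    def test_cytoplasm_is_cell_minus_nucleus(self):
        gfp, hoechst, cell, nuc = make_confocal_scene()
        objs = segment_cytoplasm_confocal(gfp, hoechst, mode="nuclear")
        assert len(objs) == 1
        m = objs[0].mask
        # no cytoplasm voxel inside the true nucleus core (allow the
        # threshold boundary to wiggle by a voxel)
        from scipy import ndimage as ndi

        core = ndi.binary_erosion(nuc, iterations=2)
        assert not np.any(m & core)
        overlap = (m & cell).sum() / m.sum()
        assert overlap > 0.95

    def test_small_nucleus_excluded(self):
        # one real nucleus and one speck of ~6 um^3 (< 20 um^3): only the
        # real one survives the volume filter
        gfp, hoechst, _, _ = make_confocal_scene(
            nucleus_radii=(8, 3),
            nucleus_centers=((12, 32, 20), (12, 32, 46)),
            cell_radius=22,
        )
        objs = segment_cytoplasm_confocal(gfp, hoechst, mode="nuclear",
                                          green_threshold=0.0)
        assert objs
        assert len({o.nucleus_label for o in objs}) == 1

    def test_two_nuclei_partition_by_nearest(self):
        gfp, hoechst, cell, nuc = make_confocal_scene(
            nucleus_radii=(8, 8),
            nucleus_centers=((12, 32, 20), (12, 32, 44)),
            cell_radius=22,
        )
        objs = segment_cytoplasm_confocal(gfp, hoechst, mode="nuclear",
                                          green_threshold=0.0)
        nuclei_of = {o.nucleus_label for o in objs}
        assert len(nuclei_of) == 2
        # objects are pairwise disjoint
        for i in range(len(objs)):
            for j in range(i + 1, len(objs)):
                assert not np.any(objs[i].mask & objs[j].mask)

    def test_confocal_coloc_identical_channels(self):
        gfp, hoechst, _, _ = make_confocal_scene()
        df, _ = confocal_coloc(gfp, gfp, hoechst)
        assert (df["pcc_3d"] > 0.99).all()
        assert (df["pcc_midplane"] > 0.99).all()

    def test_membrane_mode_returns_objects(self):
        gfp, _, cell, _ = make_confocal_scene()
        objs = segment_cytoplasm_confocal(gfp, None, mode="membrane")
        assert objs
        biggest = max(objs, key=lambda o: o.mask.sum())
        # the object covers the cell body (smoothing lets it bleed a little
        # past the true boundary)
        coverage = (biggest.mask & cell).sum() / cell.sum()
        inside = (biggest.mask & cell).sum() / biggest.mask.sum()
        assert coverage > 0.8
        assert inside > 0.6

    def test_nuclear_mode_requires_nuclei(self):
        gfp, _, _, _ = make_confocal_scene()
        with pytest.raises(ValueError):
            segment_cytoplasm_confocal(gfp, None, mode="nuclear")
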