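"""Meshwork morphometry: objects, meshes, skeletons, gaps, widths."""

import math

import numpy as np
import pytest
from skimage.morphology import skeletonize

from tjmesh import (ImageChannel, JunctionMask, MeshworkSpec, MorphometryConfig,
                    OpticsSpec, STED, StrandMask, analyze_roi, gap_stats,
                    generate_geometry, insert_gaps, intensity_per_area,
                    mesh_stats, object_stats, render_channel, skeleton_stats,
                    strand_fwhm)

from conftest import flood_fill_components, skeleton_graph_oracle


def _sm(arr, px=20.0):
    return StrandMask(np.asarray(arr, bool), px)


def _jm(arr, px=20.0):
    return JunctionMask(np.asarray(arr, bool), px)


class TestObjectStats:
    def test_two_disjoint_objects_counted(self):
        m = np.zeros((20, 20), bool)
        m[2, 2:7] = True
        m[10, 10:15] = True
        st = object_stats(_sm(m))
        assert st.n_objects == 2
        assert st.continuity_px == 5.0
        assert st.continuity == pytest.approx(5 * (0.02**2))

    def test_single_object_fragmentation_is_inverse_area(self):
        m = np.zeros((10, 10), bool)
        m[3:6, 3:6] = True
        st = object_stats(_sm(m))
        assert st.fragmentation == pytest.approx(1.0 / st.total_area_um2)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            object_stats(_sm(np.zeros((5, 5))))

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(20):
            m = rng.random((64, 64)) > 0.7
            if not m.any():
                continue
            st = object_stats(_sm(m), connectivity=connectivity)
            oracle = flood_fill_components(m, connectivity)
            assert st.n_objects == len(oracle)
            assert sorted(st.object_areas_px) == sorted(oracle)

    def test_reciprocal_identity(self, rng):
        for _ in range(20):
            m = rng.random((48, 48)) > 0.6
            if not m.any():
                continue
            st = object_stats(_sm(m))
            assert st.fragmentation * st.continuity == pytest.approx(1.0, abs=1e-12)


class TestMeshStats:
    def test_square_ring_encloses_one_mesh(self):
        m = np.zeros((20, 20), bool)
        m[4, 4:16] = m[15, 4:16] = True
        m[4:16, 4] = m[4:16, 15] = True
        st = mesh_stats(_sm(m), _jm(np.ones((20, 20))))
        assert st.mesh_count == 1
        assert st.mesh_areas_px == [100]
        assert st.mesh_equiv_diameter_nm[0] == pytest.approx(
            2 * math.sqrt(100 * 400 / math.pi))

    def test_filled_rectangle_has_no_meshes(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        st = mesh_stats(_sm(m), _jm(np.ones((20, 20))))
        assert st.mesh_count == 0

    def test_regular_grid_mesh_count_matches_construction(self):
        """Strand lines every 25 px on a 201x201 frame enclose 8x8 cells."""
        m = np.zeros((201, 201), bool)
        for k in range(0, 201, 25):
            m[k, :] = True
            m[:, k] = True
        st = mesh_stats(_sm(m), _jm(np.ones((201, 201))))
        assert st.mesh_count == 64
        assert all(a == 24 * 24 for a in st.mesh_areas_px)

    def test_circularity_bounded_with_digitization_tolerance(self, default_truth):
        st = mesh_stats(_sm(default_truth.strand_mask),
                        _jm(default_truth.junction_band))
        assert all(0 < c <= 1.1 for c in st.mesh_circularity)

    def test_holes_outside_junction_region_excluded(self):
        # a ring far outside the junction band is not a mesh of the meshwork
        m = np.zeros((40, 40), bool)
        m[4, 4:16] = m[15, 4:16] = True
        m[4:16, 4] = m[4:16, 15] = True
        band = np.zeros((40, 40), bool)
        band[25:, 25:] = True
        st = mesh_stats(_sm(m), _jm(band))
        assert st.mesh_count == 0

    def test_count_normalized_to_confocal_area(self):
        m = np.zeros((20, 20), bool)
        m[4, 4:16] = m[15, 4:16] = True
        m[4:16, 4] = m[4:16, 15] = True
        conf = _jm(np.ones((20, 20)))
        st = mesh_stats(_sm(m), conf)
        assert st.mesh_count_per_conf_area == pytest.approx(1.0 / conf.area_um2)

    def test_empty_confocal_mask_rejected(self):
        with pytest.raises(ValueError, match="confocal"):
            mesh_stats(_sm(np.ones((5, 5))), _jm(np.zeros((5, 5))))


class TestSkeletonStats:
    def test_straight_line_single_branch(self):
        m = np.zeros((30, 30), bool)
        m[15, 5:25] = True
        st = skeleton_stats(_sm(m))
        assert st.branch_count == 1
        assert st.junction_count == 0
        assert st.branch_lengths_nm[0] == pytest.approx(19 * 20.0)
        assert st.tortuosity[0] == pytest.approx(1.0)

    def test_plus_sign_topology(self):
        m = np.zeros((31, 31), bool)
        m[15, 5:26] = True
        m[5:26, 15] = True
        st = skeleton_stats(_sm(m))
        assert st.junction_count == 1
        assert st.branch_count == 4

    def test_diagonal_steps_weighted_sqrt2(self):
        m = np.zeros((30, 30), bool)
        rr = np.arange(5, 25)
        m[rr, rr] = True
        st = skeleton_stats(_sm(m))
        assert st.branch_lengths_nm[0] == pytest.approx(19 * math.sqrt(2) * 20.0)

    def test_tortuosity_at_least_one_everywhere(self, default_truth):
        st = skeleton_stats(_sm(default_truth.strand_mask))
        assert st.tortuosity and min(st.tortuosity) >= 1.0 - 1e-12

    def test_counts_match_graph_oracle_on_synthetic_meshworks(self):
        for seed in range(8):
            truth = generate_geometry(MeshworkSpec(seed=seed, n_cells=3 + seed % 3))
            st = skeleton_stats(_sm(truth.strand_mask), min_branch_px=1)
            ob, oj = skeleton_graph_oracle(skeletonize(truth.strand_mask))
            assert (st.branch_count, st.junction_count) == (ob, oj)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            skeleton_stats(_sm(np.zeros((5, 5))))


def _band_with_gaps(gap_px, width_px=5, length=400, spacing=80):
    """Straight junctional band with a centre strand missing known runs."""
    band = np.zeros((width_px + 10, length), bool)
    band[5:5 + width_px, :] = True
    strand = np.zeros_like(band)
    mid = 5 + width_px // 2
    strand[mid, :] = True
    pos = 60
    placed = []
    for g in gap_px:
        strand[mid, pos:pos + g] = False
        placed.append((pos, g))
        pos += g + spacing
    return band, strand, placed


class TestGapStats:
    def test_known_gap_lengths_recovered(self):
        """Inserted gaps of 60/160/300 nm: exactly the two over 100 nm are
        detected, at their true lengths within one pixel."""
        band, strand, _ = _band_with_gaps([3, 8, 15])
        st = gap_stats(_sm(strand), _jm(band))
        assert st.n_gaps_over_threshold == 2
        detected = sorted(g for g in st.gap_lengths_nm if g > 100.0)
        assert detected[0] == pytest.approx(160.0, abs=20.0)
        assert detected[1] == pytest.approx(300.0, abs=20.0)

    def test_single_long_gap_counted_once(self):
        band, strand, _ = _band_with_gaps([10])  # 200 nm
        st = gap_stats(_sm(strand), _jm(band))
        assert st.n_gaps_over_threshold == 1

    def test_ungapped_truth_classified_continuous(self, default_truth):
        st = gap_stats(_sm(default_truth.strand_mask),
                       _jm(default_truth.junction_band))
        assert st.classification == "continuous"

    def test_frequent_gaps_classified_discontinuous(self):
        """Six 200-nm gaps on an 8-um junction path exceed the 0.5/um
        frequency threshold."""
        band, strand, _ = _band_with_gaps([10] * 6, spacing=40)
        st = gap_stats(_sm(strand), _jm(band))
        assert st.n_gaps_over_threshold == 6
        assert st.gaps_per_um > 0.5
        assert st.classification == "discontinuous"

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="junction band"):
            gap_stats(_sm(np.ones((5, 5))), _jm(np.zeros((5, 5))))


class TestStrandFwhm:
    def _gaussian_ridge(self, sigma_nm, px_nm=20.0, shape=(60, 200), peak=1000):
        img = np.zeros(shape)
        r0 = shape[0] // 2
        rows = np.arange(shape[0])
        profile = peak * np.exp(-((rows - r0) ** 2) / (2 * (sigma_nm / px_nm) ** 2))
        img[:] = profile[:, None]
        mask = np.zeros(shape, bool)
        mask[r0, 10:-10] = True
        return (ImageChannel(np.rint(img).astype(np.int64), px_nm, STED),
                _sm(mask, px_nm))

    def test_gaussian_ridge_closed_form(self):
        img, mask = self._gaussian_ridge(42.5)
        st = strand_fwhm(img, mask)
        expect = 2 * math.sqrt(2 * math.log(2)) * 42.5  # ~100.1 nm
        assert st.fwhm_mean_nm == pytest.approx(expect, rel=0.05)

    def test_rendered_thin_strand_under_psf(self):
        """A 20-nm strand imaged with a 100-nm PSF appears with FWHM about
        sqrt(100^2 + 20^2) ~ 102 nm."""
        mask = np.zeros((60, 200), bool)
        mask[30, 10:190] = True
        optics = OpticsSpec(psf_fwhm_nm=100.0, photons_per_strand_px=2000.0,
                            background_photons_per_px=0.0, poisson=False)
        img = render_channel(mask, optics)
        st = strand_fwhm(img, _sm(mask))
        assert st.fwhm_mean_nm == pytest.approx(math.hypot(100.0, 20.0), rel=0.10)

    def test_flat_image_rejected(self):
        img = ImageChannel(np.full((30, 30), 5, np.int64), 20.0, STED)
        mask = np.zeros((30, 30), bool)
        mask[15, 5:25] = True
        with pytest.raises(ValueError, match="profiles"):
            strand_fwhm(img, _sm(mask))


class TestIntensityPerArea:
    def test_uniform_counts_arithmetic(self):
        img = ImageChannel(np.full((20, 20), 3, np.int64), 20.0, STED)
        m = np.zeros((20, 20), bool)
        m.ravel()[:100] = True
        st = intensity_per_area(img, _jm(m))
        assert st.photon_count == 300
        assert st.photons_per_um2 == pytest.approx(300 / 0.04)

    def test_linear_in_counts(self, rng):
        pix = rng.poisson(5, (20, 20)).astype(np.int64)
        m = _jm(rng.random((20, 20)) > 0.4)
        a = intensity_per_area(ImageChannel(pix, 20.0, STED), m)
        b = intensity_per_area(ImageChannel(2 * pix, 20.0, STED), m)
        assert b.photons_per_um2 == pytest.approx(2 * a.photons_per_um2)

    def test_poisson_background_density_recovered(self):
        o = OpticsSpec(background_photons_per_px=3.0, seed=6)
        img = render_channel(np.zeros((200, 200), bool), o)
        m = _jm(np.ones((200, 200)))
        st = intensity_per_area(img, m)
        density = 3.0 / (0.02**2)  # photons per um^2
        se = math.sqrt(3.0 * 200 * 200) / m.area_um2
        assert abs(st.photons_per_um2 - density) < 2 * se

    def test_empty_mask_rejected(self):
        img = ImageChannel(np.ones((5, 5), np.int64), 20.0, STED)
        with pytest.raises(ValueError, match="empty"):
            intensity_per_area(img, _jm(np.zeros((5, 5))))


class TestAnalyzeRoi:
    def test_truth_metrics_self_consistent(self, default_truth):
        m1 = default_truth.truth_metrics()
        m2 = analyze_roi(None, _jm(default_truth.junction_band),
                         _sm(default_truth.strand_mask))
        assert m1.object_stats.n_objects == m2.object_stats.n_objects
        assert m1.mesh_stats.mesh_areas_px == m2.mesh_stats.mesh_areas_px
        assert m1.skeleton_stats.branch_count == m2.skeleton_stats.branch_count

    def test_area_ratio_in_unit_interval(self, default_truth):
        m = default_truth.truth_metrics()
        assert 0.0 <= m.sted_over_confocal_area_ratio <= 1.0

    def test_gap_fraction_lowers_median_continuity(self, default_truth):
        conts = {f: [] for f in (0.0, 0.3)}
        for f in conts:
            for seed in range(3):
                out = insert_gaps(default_truth, f, seed=seed)
                m = analyze_roi(None, _jm(out.junction_band), _sm(out.strand_mask))
                conts[f].append(m.object_stats.continuity)
        assert np.median(conts[0.3]) < np.median(conts[0.0])

    def test_errors_carry_stage_label(self, default_truth):
        with pytest.raises(ValueError, match=r"\[object_stats\]"):
            analyze_roi(None, _jm(default_truth.junction_band),
                        _sm(np.zeros_like(default_truth.strand_mask)))
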