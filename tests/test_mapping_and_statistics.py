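"""Projections, hue-coded rendering, histograms, and nematic order."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fibermap as fm
from fibermap.errors import ConfigurationError, DomainError

from conftest import make_stack, two_cluster_spec


def map_of_segments(pixel_lists, image_shape=(32, 32), n_sections=1, n_bins=32):
    segments = [
        fm.FiberSegment(i, plane, np.asarray(px))
        for i, (plane, px) in enumerate(pixel_lists)
    ]
    return fm.OrientationMap(
        label="fixture",
        entries=fm.annotate_segments(segments, n_bins=n_bins),
        n_bins=n_bins,
        image_shape=image_shape,
        n_sections=n_sections,
    )


class TestProjectBinary:
    def test_union_of_disjoint_lines(self, line_stack):
        proj = fm.project_binary(line_stack)
        assert proj.sum() == line_stack.planes.sum()

    def test_idempotent_for_repeated_plane(self):
        plane = np.zeros((8, 8), dtype=np.uint8)
        plane[3, 1:7] = 1
        stack = make_stack(np.stack([plane, plane, plane]))
        np.testing.assert_array_equal(fm.project_binary(stack), plane)

    def test_z_range_restriction(self, line_stack):
        proj = fm.project_binary(line_stack, z_range=(0, 1))
        np.testing.assert_array_equal(proj, line_stack.planes[0])

    def test_empty_z_range_rejected(self, line_stack):
        with pytest.raises(DomainError):
            fm.project_binary(line_stack, z_range=(2, 2))

    def test_map_projection_only_retained_pixels(self, x_plane):
        stack = make_stack(x_plane[np.newaxis])
        omap = fm.analyze_stack(stack, fm.PipelineParams(min_segment_length=1))
        proj = fm.project_binary(omap)
        assert proj[2, 2] == 0  # crossing pixel was pruned
        retained = {tuple(p) for e in omap.entries for p in e.segment.pixels}
        assert {(x, y) for y, x in zip(*np.nonzero(proj))} == retained


class TestHueLUT:
    def test_default_is_32_distinct_colors(self):
        lut = fm.hue_lut()
        assert lut.n_bins == 32
        assert len({tuple(c) for c in lut.colors}) == 32

    def test_hue_monotone_across_bins(self):
        import colorsys

        lut = fm.hue_lut()
        hues = [colorsys.rgb_to_hsv(*(c / 255.0))[0] for c in lut.colors]
        assert all(b > a for a, b in zip(hues, hues[1:]))

    def test_ruler_strip_shape(self):
        ruler = fm.lut_ruler(fm.hue_lut(), bin_width_px=4, height_px=8)
        assert ruler.shape == (8, 32 * 4, 3)
        assert len(np.unique(ruler.reshape(-1, 3), axis=0)) == 32


class TestRenderColoredProjection:
    def test_single_horizontal_segment_painted_bin0(self):
        omap = map_of_segments([(0, [(2, 5), (3, 5), (4, 5), (5, 5), (6, 5)])])
        lut = fm.hue_lut()
        img = fm.render_colored_projection(omap, lut)
        np.testing.assert_array_equal(img[5, 2:7], np.tile(lut.colors[0], (5, 1)))
        assert (img.reshape(-1, 3).sum(axis=1) > 0).sum() == 5

    def test_perpendicular_pair_uses_bins_0_and_16(self):
        omap = map_of_segments(
            [
                (0, [(2, 2), (3, 2), (4, 2), (5, 2)]),  # 0 deg
                (0, [(10, 2), (10, 3), (10, 4), (10, 5)]),  # 90 deg -> bin 16
            ]
        )
        lut = fm.hue_lut()
        img = fm.render_colored_projection(omap, lut)
        colors = {tuple(c) for c in img.reshape(-1, 3)} - {(0, 0, 0)}
        assert colors == {tuple(lut.colors[0]), tuple(lut.colors[16])}

    def test_parallel_segments_share_one_color(self):
        omap = map_of_segments(
            [(0, [(1, 1), (2, 1), (3, 1)]), (0, [(1, 8), (2, 8), (3, 8)])]
        )
        img = fm.render_colored_projection(omap)
        assert len({tuple(c) for c in img.reshape(-1, 3)} - {(0, 0, 0)}) == 1

    def test_degenerate_painted_gray(self):
        omap = map_of_segments([(0, [(4, 4)])])
        img = fm.render_colored_projection(omap)
        assert tuple(img[4, 4]) == fm.mapping_and_statistics.DEGENERATE_GRAY

    def test_topmost_plane_wins_on_overlap(self):
        shared = [(5, 5), (6, 5), (7, 5)]
        vertical = [(6, 4), (6, 5), (6, 6)]
        omap = map_of_segments([(0, shared), (1, vertical)], n_sections=2)
        lut = fm.hue_lut()
        img = fm.render_colored_projection(omap, lut)
        assert tuple(img[5, 6]) == tuple(lut.colors[16])  # plane 1 overwrote plane 0

    def test_lut_size_mismatch_rejected(self):
        omap = map_of_segments([(0, [(1, 1), (2, 1)])], n_bins=32)
        with pytest.raises(ConfigurationError):
            fm.render_colored_projection(omap, fm.hue_lut(n_bins=16))


class TestAngularHistogram:
    def test_three_horizontal_segments(self):
        omap = map_of_segments(
            [(0, [(1, y), (2, y), (3, y)]) for y in (2, 5, 8)]
        )
        hist = fm.angular_histogram(omap)
        assert hist.counts[0] == 3 and hist.counts.sum() == 3

    def test_empty_map_all_zero(self):
        omap = fm.OrientationMap("e", [], 32, (8, 8), 1)
        assert fm.angular_histogram(omap).counts.sum() == 0

    def test_per_pixel_weighting_of_diagonal(self):
        px = [(i, i) for i in range(10)]  # 45 deg, 10 px -> bin 8
        omap = map_of_segments([(0, px)], image_shape=(16, 16))
        hist = fm.angular_histogram(omap, weighting="pixel")
        assert hist.counts[8] == 10 and hist.counts.sum() == 10

    def test_total_conserved_per_segment_mode(self):
        stack, _ = fm.generate_field(two_cluster_spec(seed=5, n_fibers=40))
        omap = fm.analyze_stack(stack)
        hist = fm.angular_histogram(omap)
        assert hist.counts.sum() == len(omap.non_degenerate)

    def test_histogram_file_output(self, tmp_path):
        omap = map_of_segments([(0, [(1, 1), (2, 1), (3, 1)])])
        fm.write_histogram(fm.angular_histogram(omap), tmp_path / "h.tsv")
        lines = (tmp_path / "h.tsv").read_text().strip().splitlines()
        assert len(lines) == 33  # header + 32 bins


class TestAxialOrder:
    def test_identical_angles_give_unit_order(self):
        s = fm.axial_order([37.0] * 25)
        assert s.order_parameter == pytest.approx(1.0)
        assert s.mean_axis_deg == pytest.approx(37.0)

    def test_orthogonal_pair_cancels(self):
        s = fm.axial_order([0.0, 90.0])
        assert s.order_parameter == 0.0
        assert s.mean_axis_deg is None

    def test_uniform_field_is_nearly_isotropic(self):
        rng = np.random.default_rng(123)
        s = fm.axial_order(rng.uniform(0.0, 180.0, 10_000))
        assert s.order_parameter < 0.05

    def test_no_angles_rejected(self):
        with pytest.raises(DomainError):
            fm.axial_order([])

    @given(
        shift=st.floats(min_value=0.0, max_value=179.0),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_rotation_invariance_of_order_parameter(self, shift, seed):
        """S is unchanged by a global rotation; the mean axis shifts with it."""
        rng = np.random.default_rng(seed)
        angles = rng.vonmises(0.6, 8.0, size=40) * 90 / np.pi % 180
        base = fm.axial_order(angles)
        shifted = fm.axial_order((angles + shift) % 180.0)
        assert shifted.order_parameter == pytest.approx(base.order_parameter, abs=1e-9)
        assert (
            fm.axial_difference_deg(shifted.mean_axis_deg, (base.mean_axis_deg + shift) % 180.0)
            < 1e-6
        )

    def test_pixel_weighting_favors_long_segments(self):
        omap = map_of_segments(
            [
                (0, [(x, 2) for x in range(12)]),  # long at 0 deg
                (0, [(2, y) for y in range(4, 7)]),  # short at 90 deg
            ]
        )
        per_segment = fm.axial_order(omap, weighting="segment")
        per_pixel = fm.axial_order(omap, weighting="pixel")
        assert per_pixel.order_parameter > per_segment.order_parameter
        assert per_pixel.mean_axis_deg == pytest.approx(0.0, abs=1e-9)


class TestCompareConditions:
    def test_identical_maps_have_zero_delta(self):
        omap = map_of_segments([(0, [(1, 1), (2, 1), (3, 1)])])
        report = fm.compare_conditions(omap, omap)
        assert report.delta_order_parameter == 0.0

    def test_ordered_vs_isotropic_delta_near_one(self):
        spec_ordered = two_cluster_spec(seed=21, n_fibers=60, kappa=fm.KAPPA_INF)
        spec_iso = two_cluster_spec(seed=22, n_fibers=60, kappa=0.0)
        map_o = fm.analyze_stack(fm.generate_field(spec_ordered)[0])
        map_i = fm.analyze_stack(fm.generate_field(spec_iso)[0])
        ordered_single = fm.OrientationMap(
            "o",
            [e for e in map_o.entries if e.moments.centroid_y < 250],
            32,
            map_o.image_shape,
            map_o.n_sections,
        )
        report = fm.compare_conditions(ordered_single, map_i)
        assert report.delta_order_parameter > 0.85

    def test_disjoint_unimodal_fields_have_disjoint_histograms(self):
        map_a = map_of_segments([(0, [(x, 2) for x in range(6)])])
        map_b = map_of_segments([(0, [(2, y) for y in range(6)])])
        report = fm.compare_conditions(map_a, map_b)
        assert not (report.histogram_a.occupied_bins() & report.histogram_b.occupied_bins())

    def test_n_bins_mismatch_rejected(self):
        map_a = map_of_segments([(0, [(1, 1), (2, 1)])], n_bins=32)
        map_b = map_of_segments([(0, [(1, 1), (2, 1)])], n_bins=16)
        with pytest.raises(ConfigurationError):
            fm.compare_conditions(map_a, map_b)


class TestColorBinConsistency:
    @pytest.mark.parametrize("seed", [2, 9])
    def test_distinct_colors_equal_occupied_bins(self, seed):
        """Every color in the rendering corresponds to an occupied histogram
        bin and vice versa (plus gray iff degenerate segments exist)."""
        stack, _ = fm.generate_field(two_cluster_spec(seed=seed, n_fibers=50, kappa=5.0))
        omap = fm.analyze_stack(stack)
        lut = fm.hue_lut()
        img = fm.render_colored_projection(omap, lut)
        rendered = {tuple(c) for c in img.reshape(-1, 3)} - {(0, 0, 0)}
        expected = {tuple(lut.colors[b]) for b in fm.angular_histogram(omap).occupied_bins()}
        if any(e.degenerate for e in omap.entries):
            expected |= {fm.mapping_and_statistics.DEGENERATE_GRAY}
        assert rendered == expected

    def test_projection_conservation(self):
        stack, _ = fm.generate_field(two_cluster_spec(seed=4, n_fibers=30))
        omap = fm.analyze_stack(stack)
        proj = fm.project_binary(omap)
        retained = {tuple(p) for e in omap.entries for p in e.segment.pixels}
        assert {(x, y) for y, x in zip(*np.nonzero(proj))} == retained


class TestImageOutputs:
    def test_png_and_tiff_round_trip(self, tmp_path):
        import imageio.v3 as iio
        import tifffile

        omap = map_of_segments([(0, [(1, 1), (2, 1), (3, 1)])])
        img = fm.render_colored_projection(omap)
        fm.write_projection_png(img, tmp_path / "c.png")
        np.testing.assert_array_equal(iio.imread(tmp_path / "c.png"), img)
        proj = fm.project_binary(omap)
        fm.write_projection_tiff(proj, tmp_path / "b.tif")
        np.testing.assert_array_equal(tifffile.imread(tmp_path / "b.tif"), proj)
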