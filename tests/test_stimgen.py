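"""Stimulus sampling and rendering: constraints, occlusion, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from bosbench import stimgen
from bosbench.errors import ConfigurationError, ValidationError
from bosbench.stimgen import (GeometryConstraints, LuminanceSpec,
                              RectanglePair, StimulusSpec)


def test_default_constraints_match_reference_values():
    c = GeometryConstraints()
    assert (c.height, c.width) == (227, 227)
    assert (c.margin, c.min_extension, c.min_interior_offset) == (20, 3, 5)
    assert c.min_width == c.min_height == 10


def test_infeasible_constraints_raise():
    with pytest.raises(ConfigurationError):
        GeometryConstraints(height=30, width=30, margin=14)
    with pytest.raises(ConfigurationError):
        GeometryConstraints(margin=0)


def test_sampled_corners_respect_margin_at_full_scale(c227):
    rng = np.random.default_rng(7)
    for _ in range(300):
        p = stimgen.sample_geometry(c227, rng)
        for x, y, w, h in [(p.xL, p.yL, p.wL, p.hL), (p.xR, p.yR, p.wR, p.hR)]:
            assert 20 <= x and x + w <= 207
            assert 20 <= y and y + h <= 207


def test_sampled_pairs_always_intersect(c64):
    # oracle: direct axis-aligned intersection computation
    rng = np.random.default_rng(11)
    for _ in range(1000):
        p = stimgen.sample_geometry(c64, rng)
        iw = min(p.xL + p.wL, p.xR + p.wR) - max(p.xL, p.xR)
        ih = min(p.yL + p.hL, p.yR + p.hR) - max(p.yL, p.yR)
        assert iw * ih >= 1


def test_sampling_is_reproducible(c64):
    a = stimgen.sample_geometry(c64, np.random.default_rng(3))
    b = stimgen.sample_geometry(c64, np.random.default_rng(3))
    assert a == b


def test_rect_outline_path_has_perimeter_length():
    for w, h in [(10, 15), (3, 3), (20, 3)]:
        path = stimgen.rect_outline_path(5, 6, w, h)
        assert len(path) == 2 * (w + h) - 4
        assert len(np.unique(path, axis=0)) == len(path)


def test_contour_rendering_erases_occluded_outline(contour_specs,
                                                   contour_images):
    for spec, img in zip(contour_specs, contour_images):
        fg = spec.geometry.foreground
        interior = stimgen._rect_strict_interior(
            img.pixels.shape, spec.geometry.rect(fg))
        bg = "right" if fg == "left" else "left"
        bg_path = img.paths[bg]
        visible = bg_path[img.visible[bg]]
        assert not interior[visible[:, 0], visible[:, 1]].any()
        # foreground outline is complete
        assert img.visible[fg].all()


def test_corner_overlap_pair_has_two_junctions(contour_images):
    for img in contour_images:
        assert len(stimgen.find_junctions(img)) == 2


def test_solid_overlap_carries_foreground_gray(c64):
    geom = stimgen.sample_geometry(c64, np.random.default_rng(5))
    geom = RectanglePair(**{**geom.__dict__, "foreground": "right"})
    spec = StimulusSpec(geometry=geom,
                        luminance=LuminanceSpec("solid", lL=50, lR=250),
                        constraints=c64)
    img = stimgen.render_solid(spec)
    x, y, w, h = geom.overlap_box()
    assert (img.pixels[y:y + h, x:x + w] == 250).all()


def test_solid_rejects_low_luminance_contrast(c64):
    geom = stimgen.sample_geometry(c64, np.random.default_rng(5))
    spec = StimulusSpec(geometry=geom,
                        luminance=LuminanceSpec("solid", lL=100, lR=120),
                        constraints=c64)
    with pytest.raises(ValidationError):
        stimgen.render_solid(spec)


def test_coincident_rectangles_violate_offset_constraints(c64):
    pair = RectanglePair(20, 20, 20, 20, 20, 20, 20, 20)
    with pytest.raises(ValidationError):
        pair.validate(c64)


def test_solid_painted_area_matches_inclusion_exclusion(c64):
    # oracle: pixel count vs inclusion-exclusion on integer rectangles
    for seed in range(20):
        spec = stimgen.sample_stimulus(c64, "solid", "rectangle", seed)
        img = stimgen.render_solid(spec)
        g = spec.geometry
        ow, oh = g.overlap_size()
        expected = g.wL * g.hL + g.wR * g.hR - ow * oh
        assert int((img.pixels != 0).sum()) == expected


def test_contour_outline_equals_solid_mask_boundaries(contour_specs):
    """Contour pixels = morphological boundaries of the solid fills,
    with the occluded boundary clipped by the foreground interior."""
    for spec in contour_specs[:10]:
        img = stimgen.render_contour(spec)
        shape = img.pixels.shape
        g = spec.geometry
        fg = g.foreground
        bg = "right" if fg == "left" else "left"

        def boundary(rect):
            m = stimgen._rect_fill_mask(shape, rect)
            return m & ~ndimage.binary_erosion(m)

        fg_b = boundary(g.rect(fg))
        bg_b = boundary(g.rect(bg))
        bg_b &= ~stimgen._rect_strict_interior(shape, g.rect(fg))
        assert np.array_equal(img.pixels > 0, fg_b | bg_b)


def test_circle_contour_erases_occluded_arc(c64):
    for seed in range(20):
        spec = stimgen.sample_stimulus(c64, "contour", "circle", seed)
        img = stimgen.render_circle_contour(spec)
        g = spec.geometry
        fg = g.foreground
        cx, cy, r = ((g.cxL, g.cyL, g.rL) if fg == "left"
                     else (g.cxR, g.cyR, g.rR))
        disk = stimgen._circle_disk_mask(img.pixels.shape, cx, cy, r - 0.5)
        bg = "right" if fg == "left" else "left"
        vis = img.paths[bg][img.visible[bg]]
        assert not disk[vis[:, 0], vis[:, 1]].any()


def test_circle_outline_respects_margin(c64):
    m = c64.margin
    for seed in range(200):
        spec = stimgen.sample_stimulus(c64, "contour", "circle", seed)
        img = stimgen.render_circle_contour(spec).pixels
        band = img.copy()
        band[m:-m, m:-m] = 0
        assert not band.any()


def test_symmetric_circles_render_as_point_reflections(c64):
    """Equal radii, symmetric placement: swapping the foreground gives
    the 180-degree rotated image (up to identical rasterisation)."""
    H = c64.height
    r, off = 12, 5
    cx1 = (H - 1 - off) // 2
    cx2 = H - 1 - cx1
    lum = LuminanceSpec("contour")
    imgs = {}
    for fg in ("left", "right"):
        geom = stimgen.CirclePair(cx1, cx1, r, cx2, cx2, r, foreground=fg)
        spec = StimulusSpec(geometry=geom, luminance=lum, constraints=c64,
                            shape_family="circle")
        imgs[fg] = stimgen.render_circle_contour(spec).pixels
    assert np.array_equal(imgs["left"], imgs["right"][::-1, ::-1])


def test_dataset_split_ratios():
    assert stimgen.assign_splits(20).count("train") == 14
    assert stimgen.assign_splits(20).count("val") == 2
    assert stimgen.assign_splits(20).count("test") == 4
    big = stimgen.assign_splits(20000)
    assert (big.count("train"), big.count("val"), big.count("test")) \
        == (14000, 2000, 4000)


def test_dataset_generation_is_deterministic(c64, tmp_path):
    man1, imgs1 = stimgen.generate_dataset(20, "contour", c64, 99)
    man2, imgs2 = stimgen.generate_dataset(20, "contour", c64, 99)
    assert man1.equals(man2)
    assert np.array_equal(imgs1, imgs2)
    man3, _ = stimgen.generate_dataset(20, "contour", c64, 100)
    assert not man3.equals(man1)


def test_dataset_rejects_tiny_n(c64):
    with pytest.raises(ValidationError):
        stimgen.generate_dataset(5, "contour", c64, 0)


def test_dataset_png_round_trip(c64, tmp_path):
    from PIL import Image
    man, imgs = stimgen.generate_dataset(10, "contour", c64, 1,
                                         out_dir=tmp_path)
    for row, img in zip(man.itertuples(), imgs):
        disk = np.asarray(Image.open(tmp_path / row.file))
        assert np.array_equal(disk, img)


def test_spec_from_row_reconstructs_geometry(c64):
    man, _ = stimgen.generate_dataset(10, "solid", c64, 4)
    for _, row in man.iterrows():
        spec = stimgen.spec_from_row(row, c64)
        assert spec.label == row["label"]
        assert spec.geometry.xL == row["xL"]
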