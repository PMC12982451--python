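"""Gap dashing and the 8-fragment factorial partition."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bosbench import fragmentation as fr
from bosbench import stimgen
from bosbench.errors import ValidationError
from bosbench.fragmentation import FragmentCode, GapSpec


def intact_pixel_count(img):
    return sum(len(p) for p in img.paths.values())


class TestGapSpec:
    def test_ratio_parsing(self):
        g = GapSpec.from_ratio("1/5")
        assert (g.border_run, g.gap_run) == (5, 1)
        g = GapSpec.from_ratio(5)
        assert (g.border_run, g.gap_run) == (1, 5)
        assert GapSpec.from_ratio(0).is_intact

    def test_invalid_runs_rejected(self):
        with pytest.raises(ValidationError):
            GapSpec(border_run=0, gap_run=3)
        with pytest.raises(ValidationError):
            GapSpec.from_ratio(-1)

    def test_default_levels_are_ten_groups(self):
        assert len(fr.DEFAULT_GAP_LEVELS) == 10
        ratios = [g.ratio for g in fr.DEFAULT_GAP_LEVELS]
        assert ratios[0] == 0
        assert ratios[1:] == sorted(ratios[1:])
        assert max(ratios) == 5 and min(ratios[1:]) == Fraction(1, 5)


class TestApplyGap:
    def test_intact_level_is_identity(self, contour_images):
        img = contour_images[0]
        out = fr.apply_gap(img, GapSpec.from_ratio(0))
        assert np.array_equal(out.pixels, img.pixels)

    @pytest.mark.parametrize("ratio", ["1/5", "1/2", "1", "3", "5"])
    def test_visible_fraction_tracks_ratio(self, contour_images, ratio):
        gap = GapSpec.from_ratio(ratio)
        target = gap.border_run / (gap.border_run + gap.gap_run)
        for img in contour_images[:20]:
            out = fr.apply_gap(img, gap)
            # the foreground outline is fully visible before dashing, so
            # its dashed fraction is the pattern's: exact up to one
            # partial period per closed path
            fg = img.spec.geometry.foreground
            frac = out.visible[fg].mean()
            period = gap.border_run + gap.gap_run
            assert abs(frac - target) <= period / len(img.paths[fg])

    def test_visible_fraction_one_sixth_at_n5_over_many_stimuli(self, c64):
        # oracle: visible / intact pixel count over 100 seeded stimuli
        gap = GapSpec.from_ratio(5)
        fracs = []
        for seed in range(100):
            spec = stimgen.sample_stimulus(c64, "contour", "rectangle", seed)
            img = stimgen.render_contour(spec)
            out = fr.apply_gap(img, gap)
            vis = sum(v.sum() for v in out.visible.values())
            tot = sum(v.sum() for v in img.visible.values())
            fracs.append(vis / tot)
        assert abs(np.mean(fracs) - 1 / 6) < 0.02

    def test_dashing_conserves_pixel_counts(self, contour_images):
        for img in contour_images[:10]:
            for gap in fr.DEFAULT_GAP_LEVELS:
                out = fr.apply_gap(img, gap)
                for side, path in img.paths.items():
                    visible = out.visible[side].sum()
                    erased = (img.visible[side] & ~out.visible[side]).sum()
                    assert visible + erased == img.visible[side].sum()

    def test_visible_fraction_monotone_in_ratio(self, contour_images):
        img = contour_images[0]
        fractions = []
        for gap in fr.DEFAULT_GAP_LEVELS:
            out = fr.apply_gap(img, gap)
            fractions.append(sum(v.sum() for v in out.visible.values()))
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))


class TestFragmentCode:
    def test_code_00101111_decodes_absent_1_2_4(self):
        assert FragmentCode("00101111").absent_fragments() == [1, 2, 4]

    def test_code_space_has_256_members(self):
        codes = FragmentCode.all_codes()
        assert len(codes) == 256
        assert len({c.digits for c in codes}) == 256

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValidationError):
            FragmentCode("0101")
        with pytest.raises(ValidationError):
            FragmentCode("0010211x")

    def test_bits_order_matches_digits(self):
        assert FragmentCode("10000001").bits.tolist() == [1, 0, 0, 0,
                                                          0, 0, 0, 1]


class TestPartition:
    def test_partition_is_complete_and_disjoint(self, contour_specs,
                                                contour_images):
        for spec, img in zip(contour_specs, contour_images):
            part = fr.build_partition(spec)
            union = np.zeros(part.shape, dtype=bool)
            for mask in part.masks():
                assert not (union & mask).any()
                union |= mask
            intact = np.zeros(part.shape, dtype=bool)
            for path in img.paths.values():
                intact[path[:, 0], path[:, 1]] = True
            assert np.array_equal(union, intact)

    def test_fragment8_contains_both_junctions(self, contour_specs,
                                               contour_images):
        for spec, img in zip(contour_specs, contour_images):
            mask8 = fr.build_partition(spec).mask(8)
            junctions = stimgen.find_junctions(img)
            assert len(junctions) == 2
            assert all(mask8[r, c] for r, c in junctions)

    def test_partition_rejects_circles(self, c64):
        spec = stimgen.sample_stimulus(c64, "contour", "circle", 0)
        with pytest.raises(ValidationError):
            fr.build_partition(spec)

    def test_point_reflected_geometry_reflects_partition(self, c64):
        """180-degree rotation maps a valid pair onto a valid pair with
        left/right roles swapped; each fragment mask maps onto the same
        fragment index (the pairing is point-symmetric)."""
        spec = stimgen.sample_stimulus(c64, "contour", "rectangle", 8)
        g = spec.geometry
        H, W = c64.height, c64.width
        rot = stimgen.RectanglePair(
            xL=W - (g.xR + g.wR), yL=H - (g.yR + g.hR), wL=g.wR, hL=g.hR,
            xR=W - (g.xL + g.wL), yR=H - (g.yL + g.hL), wR=g.wL, hR=g.hL,
            foreground="left" if g.foreground == "right" else "right")
        rot.validate(c64)
        spec_rot = stimgen.StimulusSpec(geometry=rot, luminance=spec.luminance,
                                        constraints=c64)
        part = fr.build_partition(spec)
        part_rot = fr.build_partition(spec_rot)
        for k in range(1, 9):
            expected = part.mask(k)[::-1, ::-1]
            got = part_rot.mask(k)
            # identical up to the half-open pixel convention of rotation
            overlap = (expected & got).sum()
            assert overlap / max(1, expected.sum()) > 0.8


class TestApplyCode:
    def test_all_present_is_identity(self, contour_specs, contour_images):
        spec, img = contour_specs[0], contour_images[0]
        part = fr.build_partition(spec)
        out = fr.apply_code(img, part, FragmentCode("11111111"))
        assert np.array_equal(out.pixels, img.pixels)

    def test_all_absent_is_background(self, contour_specs, contour_images):
        spec, img = contour_specs[0], contour_images[0]
        part = fr.build_partition(spec)
        out = fr.apply_code(img, part, FragmentCode("00000000"))
        assert (out.pixels == img.spec.luminance.background_gray).all()

    def test_example_code_erases_named_fragments(self, contour_specs,
                                                 contour_images):
        spec, img = contour_specs[1], contour_images[1]
        part = fr.build_partition(spec)
        out = fr.apply_code(img, part, FragmentCode("00101111"))
        shown = out.pixels > 0
        for k in (1, 2, 4):
            vis_in_k = shown & part.mask(k)
            # erased except pixels shared with a present fragment's path
            assert vis_in_k.sum() <= 2
        for k in (3, 5, 6, 7, 8):
            mk = part.mask(k)
            if mk.any():
                # present fragments keep their occlusion-visible pixels
                rendered = img.pixels > 0
                assert np.array_equal(shown & mk, rendered & mk)

    @given(a=st.integers(0, 255), b=st.integers(0, 255))
    @settings(max_examples=25, deadline=None)
    def test_code_application_composes_as_bitwise_and(self, a, b):
        c64 = stimgen.GeometryConstraints.at_scale(64)
        spec = stimgen.sample_stimulus(c64, "contour", "rectangle", 17)
        img = stimgen.render_contour(spec)
        part = fr.build_partition(spec)
        ca, cb = FragmentCode.from_int(a), FragmentCode.from_int(b)
        seq = fr.apply_code(fr.apply_code(img, part, ca), part, cb)
        direct = fr.apply_code(img, part, ca & cb)
        assert np.array_equal(seq.pixels, direct.pixels)


class TestSuites:
    def test_gap_suite_shape_and_levels(self, c64):
        man, imgs = fr.gap_level_suite(c64, per_group=12, rng=5)
        assert man["gap_n"].nunique() == 10
        assert len(man) == 120 and len(imgs) == 120
        assert (man.groupby("gap_n").size() == 12).all()

    def test_gap_suite_intact_level_matches_plain_generation(self, c64):
        man, imgs = fr.gap_level_suite(c64, per_group=5, rng=5)
        sel = man["gap_n"] == "0"
        for idx, row in man[sel].iterrows():
            spec = stimgen.sample_stimulus(c64, "contour", "rectangle",
                                           int(row["seed"]))
            assert np.array_equal(imgs[idx],
                                  stimgen.render_contour(spec).pixels)

    def test_gap_suite_requires_levels(self, c64):
        with pytest.raises(ValidationError):
            fr.gap_level_suite(c64, levels=(), per_group=5, rng=0)

    def test_factorial_suite_enumerates_256_codes(self, c64):
        man, imgs = fr.factorial_suite(c64, per_code=2, rng=5)
        assert man["fragment_code"].nunique() == 256
        assert len(man) == 512
        # identity group equals intact renders of the same seeds
        sel = man["fragment_code"] == "11111111"
        for idx, row in man[sel].iterrows():
            spec = stimgen.sample_stimulus(c64, "contour", "rectangle",
                                           int(row["seed"]))
            assert np.array_equal(imgs[idx],
                                  stimgen.render_contour(spec).pixels)
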