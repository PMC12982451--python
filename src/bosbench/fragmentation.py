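"""Degraded test stimuli: dashed (gap-ratio) contours and the 8-fragment factorial.

Two degradations of the contour condition are produced, mirroring the two
robustness protocols of the benchmark:

* **Gap dashing** — each shape's outline is traversed clockwise from its
  top-left-most pixel and turned into a periodic dash pattern of
  ``border_run`` visible pixels followed by ``gap_run`` erased pixels.  The
  gap ratio ``n = gap_run / border_run`` runs from 1/5 (mostly visible) to
  5 (mostly erased); ``n = 0`` denotes the intact contour.

* **Fragment factorial** — the joint outline of the two rectangles is cut
  into 8 fragments, each fragment pairing one arc of the left outline with
  the point-reflected (diagonally opposite) arc of the right outline.
  Fragment 8 is the interlocking corner piece around the overlap region —
  the pixels of both outlines inside the 1-px-dilated intersection
  rectangle, which always contains the T-junction configuration.  The
  remaining outline of each shape is split into 7 equal-length clockwise
  arcs, numbered 1..7 starting clockwise from the corner piece.  An 8-digit
  binary code (digit k = fragment k, 1 = present) indexes all 256
  presence/absence combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from bosbench.errors import ValidationError
from bosbench import stimgen
from bosbench.stimgen import (GeometryConstraints, StimulusImage,
                              StimulusSpec, sample_stimulus)

N_FRAGMENTS = 8
N_CODES = 2 ** N_FRAGMENTS


@dataclass(frozen=True)
class GapSpec:
    """Periodic dash pattern; ``ratio == gap_run / border_run``."""

    border_run: int = 1
    gap_run: int = 0

    def __post_init__(self) -> None:
        if self.gap_run == 0:
            return  # intact contour
        if self.border_run < 1 or self.gap_run < 1:
            raise ValidationError("dash runs must be >= 1")

    @classmethod
    def from_ratio(cls, n: float | Fraction | str) -> "GapSpec":
        frac = Fraction(n).limit_denominator(1000)
        if frac == 0:
            return cls(1, 0)
        if frac < 0:
            raise ValidationError("gap ratio must be >= 0")
        return cls(border_run=frac.denominator, gap_run=frac.numerator)

    @property
    def ratio(self) -> Fraction:
        return Fraction(self.gap_run, self.border_run)

    @property
    def is_intact(self) -> bool:
        return self.gap_run == 0

    def __str__(self) -> str:
        return "0" if self.is_intact else str(self.ratio)


#: The ten default gap groups: intact plus nine ratios from 1/5 to 5.
DEFAULT_GAP_LEVELS: tuple[GapSpec, ...] = tuple(
    GapSpec.from_ratio(r) for r in
    ["0", "1/5", "1/4", "1/3", "1/2", "1", "2", "3", "4", "5"])


@dataclass(frozen=True)
class FragmentCode:
    """8-digit binary presence code; digit k (1-based) is fragment k."""

    digits: str

    def __post_init__(self) -> None:
        if len(self.digits) != N_FRAGMENTS or set(self.digits) - {"0", "1"}:
            raise ValidationError("code must be 8 binary digits")

    @classmethod
    def from_int(cls, value: int) -> "FragmentCode":
        if not 0 <= value < N_CODES:
            raise ValidationError("code integer outside [0, 255]")
        return cls(format(value, "08b"))

    @classmethod
    def all_codes(cls) -> list["FragmentCode"]:
        return [cls.from_int(v) for v in range(N_CODES)]

    @property
    def bits(self) -> np.ndarray:
        """Presence indicators F_1..F_8 as an int array."""
        return np.frombuffer(self.digits.encode(), dtype=np.uint8) - ord("0")

    def present(self, k: int) -> bool:
        """Is fragment k (1-based) present?"""
        return self.digits[k - 1] == "1"

    def absent_fragments(self) -> list[int]:
        return [k for k in range(1, N_FRAGMENTS + 1) if not self.present(k)]

    def __and__(self, other: "FragmentCode") -> "FragmentCode":
        return FragmentCode("".join(
            "1" if a == b == "1" else "0"
            for a, b in zip(self.digits, other.digits)))

    def __str__(self) -> str:
        return self.digits


@dataclass
class FragmentPartition:
    """Assignment of every intact outline pixel to one of 8 fragments.

    ``path_ids[side][i]`` gives the 1-based fragment index of pixel ``i``
    along that side's clockwise outline traversal.
    """

    spec: StimulusSpec
    path_ids: dict[str, np.ndarray]
    shape: tuple[int, int]
    paths: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def mask(self, k: int) -> np.ndarray:
        """Boolean image mask of fragment k's pixels (intact outline)."""
        m = np.zeros(self.shape, dtype=bool)
        for side in ("left", "right"):
            pts = self.paths[side][self.path_ids[side] == k]
            m[pts[:, 0], pts[:, 1]] = True
        return m

    def masks(self) -> list[np.ndarray]:
        return [self.mask(k) for k in range(1, N_FRAGMENTS + 1)]


# ---------------------------------------------------------------------------
# gap dashing


def apply_gap(image: StimulusImage, gap: GapSpec) -> StimulusImage:
    """Dash both outlines of a contour stimulus with the given gap spec.

    The dash phase starts at each traversal's origin (the shape's
    top-left-most outline pixel) and runs clockwise over the *intact*
    outline; occlusion erasure is then re-applied, so the visible set of
    the output is the AND of the dash pattern with the input's visibility.
    """
    if image.paths is None or image.visible is None:
        raise ValidationError("apply_gap requires a contour rendering")
    if gap.is_intact:
        return image
    period = gap.border_run + gap.gap_run
    lum = image.spec.luminance
    pixels = np.full_like(image.pixels, lum.background_gray)
    visible = {}
    for side, path in image.paths.items():
        phase = np.arange(len(path)) % period
        pattern = phase < gap.border_run
        visible[side] = image.visible[side] & pattern
        pts = path[visible[side]]
        pixels[pts[:, 0], pts[:, 1]] = lum.contour_gray
    return StimulusImage(pixels=pixels, spec=image.spec,
                         paths=image.paths, visible=visible)


def gap_level_suite(constraints: GeometryConstraints,
                    levels: tuple[GapSpec, ...] = DEFAULT_GAP_LEVELS,
                    per_group: int = 2000,
                    rng: np.random.Generator | int = 0,
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """One group of dashed contour stimuli per gap level.

    The same base geometries (seeds) are reused across levels so that
    accuracy differences between groups are attributable to the gap level
    alone.  Returns ``(manifest, images)`` with a ``gap_n`` column.
    """
    if not levels:
        raise ValidationError("levels list must be nonempty")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    seeds = rng.integers(0, 2 ** 31, size=per_group)
    base = [stimgen.render_contour(
        sample_stimulus(constraints, "contour", "rectangle", int(s)))
        for s in seeds]
    rows, imgs = [], []
    for gi, gap in enumerate(levels):
        for i, img in enumerate(base):
            dashed = apply_gap(img, gap)
            rows.append(dict(file=f"gap{gi}_{i:05d}.png", condition="contour",
                             shape_family="rectangle", label=img.label,
                             split="test", seed=int(seeds[i]),
                             gap_n=str(gap), group=gi))
            imgs.append(dashed.pixels)
    return pd.DataFrame(rows), np.stack(imgs)


# ---------------------------------------------------------------------------
# fragment factorial


def build_partition(spec: StimulusSpec) -> FragmentPartition:
    """Cut the two rectangle outlines into the 8 diagonally paired fragments.

    Fragment 8 is anchored to the overlap corner: all outline pixels inside
    the 1-px-dilated intersection rectangle, on both shapes.  Each shape's
    remaining outline is divided into 7 equal-length clockwise arcs,
    indexed 1..7 starting immediately after the corner piece; arc j of the
    left outline is paired with arc j of the right outline, which is its
    approximate point reflection about the overlap corner.
    """
    if spec.shape_family != "rectangle":
        raise ValidationError("fragment partition is defined for rectangles")
    geom = spec.geometry
    geom.validate(spec.constraints)
    x0, y0, ow, oh = geom.overlap_box()
    shape = (spec.constraints.height, spec.constraints.width)
    path_ids, paths = {}, {}
    for side in ("left", "right"):
        path = stimgen.rect_outline_path(*geom.rect(side))
        n = len(path)
        in_corner = ((path[:, 1] >= x0 - 1) & (path[:, 1] <= x0 + ow)
                     & (path[:, 0] >= y0 - 1) & (path[:, 0] <= y0 + oh))
        ids = np.zeros(n, dtype=np.int64)
        ids[in_corner] = N_FRAGMENTS
        # remaining pixels form one contiguous circular run; find its start
        # (first non-corner pixel after a corner pixel, circularly)
        rest_idx = np.flatnonzero(~in_corner)
        if len(rest_idx) == 0:
            # degenerate: whole outline sits in the corner window
            path_ids[side] = ids
            paths[side] = path
            continue
        prev_in_corner = in_corner[(rest_idx - 1) % n]
        starts = rest_idx[prev_in_corner]
        start = int(starts[0]) if len(starts) else int(rest_idx[0])
        run = [(start + k) % n for k in range(n)]
        run = [i for i in run if not in_corner[i]]
        # 7 near-equal arcs, clockwise from the corner piece
        bounds = np.linspace(0, len(run), N_FRAGMENTS, dtype=np.int64)
        for j in range(N_FRAGMENTS - 1):
            ids[np.asarray(run[bounds[j]:bounds[j + 1]], dtype=np.int64)] = j + 1
        path_ids[side] = ids
        paths[side] = path
    return FragmentPartition(spec=spec, path_ids=path_ids, shape=shape,
                             paths=paths)


def apply_code(image: StimulusImage, partition: FragmentPartition,
               code: FragmentCode) -> StimulusImage:
    """Erase every absent fragment's pixels; present fragments untouched."""
    if image.paths is None or image.visible is None:
        raise ValidationError("apply_code requires a contour rendering")
    absent = set(code.absent_fragments())
    if not absent:
        return image
    lum = image.spec.luminance
    pixels = np.full_like(image.pixels, lum.background_gray)
    visible = {}
    for side, path in image.paths.items():
        keep = ~np.isin(partition.path_ids[side], list(absent))
        visible[side] = image.visible[side] & keep
        pts = path[visible[side]]
        pixels[pts[:, 0], pts[:, 1]] = lum.contour_gray
    return StimulusImage(pixels=pixels, spec=image.spec,
                         paths=image.paths, visible=visible)


def factorial_suite(constraints: GeometryConstraints,
                    per_code: int = 1000,
                    rng: np.random.Generator | int = 0,
                    codes: list[FragmentCode] | None = None,
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """All 256 fragment-presence groups, ``per_code`` stimuli each.

    The same base geometries are reused across codes (the all-present
    group is therefore bit-identical to the intact contour rendering of
    the same seeds).  Returns ``(manifest, images)`` with a
    ``fragment_code`` column.
    """
    if per_code < 1:
        raise ValidationError("per_code must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    codes = FragmentCode.all_codes() if codes is None else codes
    seeds = rng.integers(0, 2 ** 31, size=per_code)
    base, parts = [], []
    for s in seeds:
        spec = sample_stimulus(constraints, "contour", "rectangle", int(s))
        base.append(stimgen.render_contour(spec))
        parts.append(build_partition(spec))
    rows, imgs = [], []
    for code in codes:
        for i, (img, part) in enumerate(zip(base, parts)):
            frag = apply_code(img, part, code)
            rows.append(dict(file=f"code{code}_{i:05d}.png",
                             condition="contour", shape_family="rectangle",
                             label=img.label, split="test",
                             seed=int(seeds[i]), fragment_code=str(code)))
            imgs.append(frag.pixels)
    return pd.DataFrame(rows), np.stack(imgs)
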