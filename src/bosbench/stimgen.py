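"""Constrained sampling and rendering of two-shape occlusion stimuli.

A stimulus contains two overlapping shapes (axis-aligned rectangles by
default, circles for the cross-shape transfer suite).  The right shape is
always displaced into the lower-right quadrant of the left shape's frame,
which yields an unambiguous occlusion relationship: whichever shape is in
the foreground *owns* the shared border.  Two luminance conditions are
rendered:

``solid``
    both shapes filled with distinct gray levels ``lL, lR in [50, 250]``
    with ``|lL - lR| >= 50``; the foreground is painted last, so the
    overlap region carries its gray.

``contour``
    both shapes drawn as 1-px high-contrast outlines; the occluded shape's
    outline is erased wherever it falls strictly inside the foreground
    shape, producing T-junctions where it terminates on the occluder.

Coordinates are 0-based with a top-left origin; rectangle spans are
half-open ``[x, x + w)``.  Every sampling routine is driven by an explicit
:class:`numpy.random.Generator`, and datasets are reproducible from a
single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from PIL import Image

from bosbench.errors import ConfigurationError, ValidationError

# Reference scale at which the canonical constraint values are defined.
_REF_SIZE = 227
_REF = dict(margin=20, min_extension=3, min_interior_offset=5,
            min_width=10, min_height=10)

#: Default gray levels (configurable per spec of the stimulus).
BACKGROUND_GRAY = 0
CONTOUR_GRAY = 255

LUM_LOW, LUM_HIGH, LUM_MIN_DIFF = 50, 250, 50

_MAX_REJECT = 1000


@dataclass(frozen=True)
class GeometryConstraints:
    """Placement constraints for stimulus sampling.

    ``margin`` (alpha) keeps all object pixels away from the image frame,
    ``min_interior_offset`` (delta) forces the right shape's origin into the
    left shape's interior, ``min_extension`` (beta) forces the right shape
    to extend beyond the overlap region so it is never fully enclosed.
    """

    height: int = _REF_SIZE
    width: int = _REF_SIZE
    margin: int = _REF["margin"]
    min_extension: int = _REF["min_extension"]
    min_interior_offset: int = _REF["min_interior_offset"]
    min_width: int = _REF["min_width"]
    min_height: int = _REF["min_height"]

    def __post_init__(self) -> None:
        if min(self.margin, self.min_extension, self.min_interior_offset,
               self.min_width, self.min_height) < 1:
            raise ConfigurationError("all constraint values must be >= 1")
        if (self.height <= 2 * self.margin + self.min_height
                or self.width <= 2 * self.margin + self.min_width):
            raise ConfigurationError(
                "image too small for margin and minimum shape size")

    @classmethod
    def at_scale(cls, size: int) -> "GeometryConstraints":
        """Constraints proportionally rescaled from the 227-px reference."""
        f = size / _REF_SIZE
        scaled = {k: max(1, round(v * f)) for k, v in _REF.items()}
        return cls(height=size, width=size, **scaled)


@dataclass(frozen=True)
class RectanglePair:
    """Two overlapping axis-aligned rectangles plus the foreground flag."""

    xL: int
    yL: int
    wL: int
    hL: int
    xR: int
    yR: int
    wR: int
    hR: int
    foreground: Literal["left", "right"] = "left"

    def validate(self, c: GeometryConstraints) -> None:
        for x, y, w, h in [(self.xL, self.yL, self.wL, self.hL),
                           (self.xR, self.yR, self.wR, self.hR)]:
            if w < c.min_width or h < c.min_height:
                raise ValidationError("rectangle below minimum size")
            if not (c.margin <= x and x + w <= c.width - c.margin
                    and c.margin <= y and y + h <= c.height - c.margin):
                raise ValidationError("rectangle violates margin frame")
        if (self.xR < self.xL + c.min_interior_offset
                or self.yR < self.yL + c.min_interior_offset):
            raise ValidationError("right rectangle not offset into interior")
        if (self.xR + self.wR < self.xL + self.wL + c.min_extension
                or self.yR + self.hR < self.yL + self.hL + c.min_extension):
            raise ValidationError("right rectangle does not extend past overlap")
        ow, oh = self.overlap_size()
        if ow < 1 or oh < 1:
            raise ValidationError("rectangles do not overlap")

    def overlap_box(self) -> tuple[int, int, int, int]:
        """Intersection rectangle as (x, y, w, h); w or h may be <= 0."""
        x0 = max(self.xL, self.xR)
        y0 = max(self.yL, self.yR)
        x1 = min(self.xL + self.wL, self.xR + self.wR)
        y1 = min(self.yL + self.hL, self.yR + self.hR)
        return x0, y0, x1 - x0, y1 - y0

    def overlap_size(self) -> tuple[int, int]:
        _, _, w, h = self.overlap_box()
        return w, h

    def rect(self, side: str) -> tuple[int, int, int, int]:
        if side == "left":
            return self.xL, self.yL, self.wL, self.hL
        return self.xR, self.yR, self.wR, self.hR


@dataclass(frozen=True)
class CirclePair:
    """Two overlapping circles; the right circle sits below-right."""

    cxL: int
    cyL: int
    rL: int
    cxR: int
    cyR: int
    rR: int
    foreground: Literal["left", "right"] = "left"

    def validate(self, c: GeometryConstraints) -> None:
        for cx, cy, r in [(self.cxL, self.cyL, self.rL),
                          (self.cxR, self.cyR, self.rR)]:
            if r < max(c.min_width, c.min_height) // 2 + 1:
                raise ValidationError("circle radius below minimum")
            if not (c.margin <= cx - r and cx + r <= c.width - 1 - c.margin
                    and c.margin <= cy - r and cy + r <= c.height - 1 - c.margin):
                raise ValidationError("circle violates margin frame")
        if (self.cxR < self.cxL + c.min_interior_offset
                or self.cyR < self.cyL + c.min_interior_offset):
            raise ValidationError("right circle not offset below-right")
        d = float(np.hypot(self.cxR - self.cxL, self.cyR - self.cyL))
        if d >= self.rL + self.rR - c.min_extension:
            raise ValidationError("circles do not properly overlap")
        if d <= abs(self.rL - self.rR) + c.min_extension:
            raise ValidationError("one circle is (nearly) nested in the other")


@dataclass(frozen=True)
class LuminanceSpec:
    condition: Literal["solid", "contour"]
    lL: int = 0
    lR: int = 0
    contour_gray: int = CONTOUR_GRAY
    background_gray: int = BACKGROUND_GRAY

    def validate(self) -> None:
        if self.condition == "solid":
            for l in (self.lL, self.lR):
                if not (LUM_LOW <= l <= LUM_HIGH):
                    raise ValidationError(
                        f"solid gray level {l} outside [{LUM_LOW}, {LUM_HIGH}]")
            if abs(self.lL - self.lR) < LUM_MIN_DIFF:
                raise ValidationError(
                    f"|lL - lR| must be >= {LUM_MIN_DIFF}")
        elif self.condition != "contour":
            raise ValidationError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class StimulusSpec:
    """Complete parametrisation of one stimulus."""

    geometry: RectanglePair | CirclePair
    luminance: LuminanceSpec
    constraints: GeometryConstraints
    shape_family: Literal["rectangle", "circle"] = "rectangle"
    rng_seed: int = 0

    @property
    def label(self) -> str:
        """The occluder owns the shared border."""
        return ("left_owns" if self.geometry.foreground == "left"
                else "right_owns")


# ---------------------------------------------------------------------------
# sampling


def sample_geometry(constraints: GeometryConstraints,
                    rng: np.random.Generator) -> RectanglePair:
    """Draw a rectangle pair by constrained uniform sampling.

    The left rectangle is drawn first, then the right one conditional on
    it; infeasible intermediate ranges trigger a bounded rejection loop.
    The foreground flag is an independent fair draw.  The sampler requires
    the overlap region to be at least 2x2 px so that the T-junction
    configuration is never degenerate.
    """
    c = constraints
    lo_x, hi_x = c.margin, c.width - c.margin   # allowed [lo, hi) span
    lo_y, hi_y = c.margin, c.height - c.margin

    def _draw_axis(lo: int, hi: int, smin: int) -> tuple[int, int, int, int]:
        # positions/sizes for one axis: left (p1,s1) then right (p2,s2)
        # constraints: p2 >= p1 + delta; overlap >= 2; s2 extends >= beta.
        s1_lo = max(smin, c.min_interior_offset + 2)
        s1_hi = hi - lo - c.min_extension - 1
        if s1_lo > s1_hi:
            raise ConfigurationError("no feasible left-shape size")
        s1 = int(rng.integers(s1_lo, s1_hi + 1))
        p1_hi = hi - s1 - c.min_extension  # leave room for right extension
        if lo > p1_hi:
            return (-1, -1, -1, -1)
        p1 = int(rng.integers(lo, p1_hi + 1))
        p2_lo = p1 + c.min_interior_offset
        p2_hi = min(p1 + s1 - 2, hi - smin)  # overlap >= 2, room for right
        if p2_lo > p2_hi:
            return (-1, -1, -1, -1)
        p2 = int(rng.integers(p2_lo, p2_hi + 1))
        s2_lo = max(smin, p1 + s1 + c.min_extension - p2)
        s2_hi = hi - p2
        if s2_lo > s2_hi:
            return (-1, -1, -1, -1)
        s2 = int(rng.integers(s2_lo, s2_hi + 1))
        return (p1, s1, p2, s2)

    for _ in range(_MAX_REJECT):
        xL, wL, xR, wR = _draw_axis(lo_x, hi_x, c.min_width)
        if xL < 0:
            continue
        yL, hL, yR, hR = _draw_axis(lo_y, hi_y, c.min_height)
        if yL < 0:
            continue
        fg = "left" if rng.integers(2) == 0 else "right"
        pair = RectanglePair(xL, yL, wL, hL, xR, yR, wR, hR, foreground=fg)
        pair.validate(c)
        return pair
    raise ConfigurationError(
        f"no valid rectangle pair found in {_MAX_REJECT} attempts")


def sample_circle_geometry(constraints: GeometryConstraints,
                           rng: np.random.Generator) -> CirclePair:
    """Draw an overlapping circle pair (cross-shape transfer suite)."""
    c = constraints
    r_min = max(c.min_width, c.min_height) // 2 + 1
    span = min(c.width, c.height) - 2 * c.margin - 1
    r_max = span // 2
    if r_min > r_max:
        raise ConfigurationError("no feasible circle radius")
    for _ in range(_MAX_REJECT):
        rL = int(rng.integers(r_min, r_max + 1))
        rR = int(rng.integers(r_min, r_max + 1))
        cxL = int(rng.integers(c.margin + rL, c.width - c.margin - rL))
        cyL = int(rng.integers(c.margin + rL, c.height - c.margin - rL))
        # center of the right circle below-right, within reach for overlap
        d_hi = rL + rR - c.min_extension - 1
        off_lo = c.min_interior_offset
        if d_hi < off_lo * np.sqrt(2):
            continue
        cx_hi = min(cxL + d_hi, c.width - c.margin - rR)
        cy_hi = min(cyL + d_hi, c.height - c.margin - rR)
        if cx_hi < cxL + off_lo or cy_hi < cyL + off_lo:
            continue
        cxR = int(rng.integers(cxL + off_lo, cx_hi + 1))
        cyR = int(rng.integers(cyL + off_lo, cy_hi + 1))
        fg = "left" if rng.integers(2) == 0 else "right"
        pair = CirclePair(cxL, cyL, rL, cxR, cyR, rR, foreground=fg)
        try:
            pair.validate(c)
        except ValidationError:
            continue
        return pair
    raise ConfigurationError(
        f"no valid circle pair found in {_MAX_REJECT} attempts")


def sample_luminance(condition: str, rng: np.random.Generator) -> LuminanceSpec:
    """Draw gray levels; solid levels satisfy the |lL - lR| >= 50 rule."""
    if condition == "contour":
        return LuminanceSpec(condition="contour")
    for _ in range(_MAX_REJECT):
        lL = int(rng.integers(LUM_LOW, LUM_HIGH + 1))
        lR = int(rng.integers(LUM_LOW, LUM_HIGH + 1))
        if abs(lL - lR) >= LUM_MIN_DIFF:
            return LuminanceSpec(condition="solid", lL=lL, lR=lR)
    raise ConfigurationError("luminance sampling failed")  # pragma: no cover


def sample_stimulus(constraints: GeometryConstraints, condition: str,
                    shape_family: str, seed: int) -> StimulusSpec:
    """One fully specified stimulus from one integer seed."""
    rng = np.random.default_rng(seed)
    if shape_family == "rectangle":
        geom: RectanglePair | CirclePair = sample_geometry(constraints, rng)
    elif shape_family == "circle":
        geom = sample_circle_geometry(constraints, rng)
    else:
        raise ValidationError(f"unknown shape family {shape_family!r}")
    lum = sample_luminance(condition, rng)
    return StimulusSpec(geometry=geom, luminance=lum, constraints=constraints,
                        shape_family=shape_family, rng_seed=seed)


# ---------------------------------------------------------------------------
# rasterisation helpers


def rect_outline_path(x: int, y: int, w: int, h: int) -> np.ndarray:
    """Ordered clockwise outline pixels of a rectangle, (n, 2) as (row, col).

    Starts at the top-left corner; each pixel appears exactly once, so the
    path length is ``2 (w + h) - 4``.
    """
    top = [(y, cx) for cx in range(x, x + w)]
    right = [(cy, x + w - 1) for cy in range(y + 1, y + h)]
    bottom = [(y + h - 1, cx) for cx in range(x + w - 2, x - 1, -1)]
    left = [(cy, x) for cy in range(y + h - 2, y, -1)]
    return np.array(top + right + bottom + left, dtype=np.int64)


def circle_outline_path(cx: int, cy: int, r: int) -> np.ndarray:
    """Ordered clockwise perimeter pixels of a circle, (n, 2) as (row, col).

    Midpoint-style rasterisation via dense parametric sampling; pixels are
    unique and ordered by angle starting from the topmost point.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, int(16 * max(8, r)), endpoint=False)
    rows = np.round(cy - r * np.cos(theta)).astype(np.int64)
    cols = np.round(cx + r * np.sin(theta)).astype(np.int64)
    pts = np.stack([rows, cols], axis=1)
    _, idx = np.unique(pts, axis=0, return_index=True)
    order = np.sort(idx)
    return pts[order]


def _rect_fill_mask(shape: tuple[int, int], rect: tuple[int, int, int, int]
                    ) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    x, y, w, h = rect
    m[y:y + h, x:x + w] = True
    return m


def _rect_strict_interior(shape: tuple[int, int],
                          rect: tuple[int, int, int, int]) -> np.ndarray:
    x, y, w, h = rect
    m = np.zeros(shape, dtype=bool)
    if w > 2 and h > 2:
        m[y + 1:y + h - 1, x + 1:x + w - 1] = True
    return m


def _circle_disk_mask(shape: tuple[int, int], cx: int, cy: int, r: float
                      ) -> np.ndarray:
    rows, cols = np.ogrid[:shape[0], :shape[1]]
    return (rows - cy) ** 2 + (cols - cx) ** 2 < r ** 2


def _paint(img: np.ndarray, path: np.ndarray, gray: int) -> None:
    img[path[:, 0], path[:, 1]] = gray


@dataclass
class StimulusImage:
    """A rendered stimulus: 8-bit grayscale pixels plus traversal metadata.

    ``paths`` maps shape side ("left"/"right") to the ordered clockwise
    outline traversal of that shape's *intact* outline; ``visible`` maps the
    side to a boolean vector over the path marking pixels that survived
    occlusion erasure (contour condition only).
    """

    pixels: np.ndarray
    spec: StimulusSpec
    paths: dict[str, np.ndarray] | None = None
    visible: dict[str, np.ndarray] | None = None

    @property
    def label(self) -> str:
        return self.spec.label


def _contour_render(spec: StimulusSpec,
                    path_fn, interior_fn) -> StimulusImage:
    c = spec.constraints
    shape = (c.height, c.width)
    lum = spec.luminance
    img = np.full(shape, lum.background_gray, dtype=np.uint8)

    fg = spec.geometry.foreground
    bg = "right" if fg == "left" else "left"
    paths = {side: path_fn(side) for side in ("left", "right")}
    interior = interior_fn(fg, shape)

    visible = {
        fg: np.ones(len(paths[fg]), dtype=bool),
        bg: ~interior[paths[bg][:, 0], paths[bg][:, 1]],
    }
    for side in (bg, fg):  # foreground drawn last (complete outline)
        p = paths[side][visible[side]]
        _paint(img, p, lum.contour_gray)
    return StimulusImage(pixels=img, spec=spec, paths=paths, visible=visible)


def render_contour(spec: StimulusSpec) -> StimulusImage:
    """Render the contour (luminance-invariant) condition.

    Both outlines are 1 px wide; the occluded shape's outline is erased
    wherever it lies strictly inside the foreground shape, leaving
    T-junctions where it terminates on the occluder's outline.
    """
    if spec.luminance.condition != "contour":
        raise ValidationError("render_contour requires a contour spec")
    if spec.shape_family == "circle":
        return render_circle_contour(spec)
    geom = spec.geometry
    geom.validate(spec.constraints)

    def path_fn(side):
        return rect_outline_path(*geom.rect(side))

    def interior_fn(fg, shape):
        return _rect_strict_interior(shape, geom.rect(fg))

    return _contour_render(spec, path_fn, interior_fn)


def render_circle_contour(spec: StimulusSpec) -> StimulusImage:
    """Contour rendering of the two-circle stimulus."""
    if spec.shape_family != "circle":
        raise ValidationError("spec is not a circle stimulus")
    geom = spec.geometry
    geom.validate(spec.constraints)
    circ = {"left": (geom.cxL, geom.cyL, geom.rL),
            "right": (geom.cxR, geom.cyR, geom.rR)}

    def path_fn(side):
        return circle_outline_path(*circ[side])

    def interior_fn(fg, shape):
        cx, cy, r = circ[fg]
        return _circle_disk_mask(shape, cx, cy, r - 0.5)

    return _contour_render(spec, path_fn, interior_fn)


def render_solid(spec: StimulusSpec) -> StimulusImage:
    """Render the solid (luminance-variant) condition.

    The background shape is painted first and the foreground over it, so
    the overlap region carries the foreground's gray level.
    """
    lum = spec.luminance
    lum.validate()
    if lum.condition != "solid":
        raise ValidationError("render_solid requires a solid spec")
    geom = spec.geometry
    geom.validate(spec.constraints)
    c = spec.constraints
    shape = (c.height, c.width)
    img = np.full(shape, lum.background_gray, dtype=np.uint8)
    fg = geom.foreground
    bg = "right" if fg == "left" else "left"
    gray = {"left": lum.lL, "right": lum.lR}
    if spec.shape_family == "rectangle":
        masks = {s: _rect_fill_mask(shape, geom.rect(s)) for s in (bg, fg)}
    else:
        circ = {"left": (geom.cxL, geom.cyL, geom.rL),
                "right": (geom.cxR, geom.cyR, geom.rR)}
        masks = {s: _circle_disk_mask(shape, circ[s][0], circ[s][1],
                                      circ[s][2] + 0.5) for s in (bg, fg)}
    for side in (bg, fg):
        img[masks[side]] = gray[side]
    return StimulusImage(pixels=img, spec=spec)


def render(spec: StimulusSpec) -> StimulusImage:
    """Dispatch to the renderer matching the stimulus condition."""
    if spec.luminance.condition == "solid":
        return render_solid(spec)
    return render_contour(spec)


# ---------------------------------------------------------------------------
# junction detection (oracle used by tests and by the fragmentation module)


def find_junctions(image: StimulusImage) -> np.ndarray:
    """Pixels where the occluded outline terminates on the occluder outline.

    A junction pixel is a *visible* pixel of the occluded shape's outline
    that is 8-adjacent both to a foreground-outline pixel and to an erased
    pixel of its own outline.  Returns an (n, 2) array of (row, col).
    """
    if image.paths is None or image.visible is None:
        raise ValidationError("junction detection requires a contour rendering")
    spec = image.spec
    fg = spec.geometry.foreground
    bg = "right" if fg == "left" else "left"
    h, w = image.pixels.shape

    def to_mask(pts):
        m = np.zeros((h, w), dtype=bool)
        m[pts[:, 0], pts[:, 1]] = True
        return m

    fg_mask = to_mask(image.paths[fg])
    bg_path = image.paths[bg]
    vis = image.visible[bg]
    bg_visible = to_mask(bg_path[vis])
    erased = to_mask(bg_path[~vis]) if (~vis).any() else np.zeros((h, w), bool)

    def dilate8(m):
        out = np.zeros_like(m)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                out |= np.roll(np.roll(m, dr, axis=0), dc, axis=1)
        return out

    cand = bg_visible & dilate8(fg_mask) & dilate8(erased)
    return np.argwhere(cand)


# ---------------------------------------------------------------------------
# dataset generation


MANIFEST_COLUMNS = ["file", "condition", "shape_family", "label", "split",
                    "seed", "xL", "yL", "wL", "hL", "xR", "yR", "wR", "hR",
                    "lL", "lR"]


def assign_splits(n: int) -> list[str]:
    """Deterministic 7:1:2 train/val/test assignment (remainder to train)."""
    n_val, n_test = n // 10, n // 5
    n_train = n - n_val - n_test
    return ["train"] * n_train + ["val"] * n_val + ["test"] * n_test


def _geometry_row(spec: StimulusSpec) -> dict:
    g = spec.geometry
    if spec.shape_family == "rectangle":
        return dict(xL=g.xL, yL=g.yL, wL=g.wL, hL=g.hL,
                    xR=g.xR, yR=g.yR, wR=g.wR, hR=g.hR)
    # circles: bounding boxes in the same columns
    return dict(xL=g.cxL - g.rL, yL=g.cyL - g.rL, wL=2 * g.rL + 1,
                hL=2 * g.rL + 1, xR=g.cxR - g.rR, yR=g.cyR - g.rR,
                wR=2 * g.rR + 1, hR=2 * g.rR + 1)


def generate_dataset(n: int, condition: str,
                     constraints: GeometryConstraints,
                     rng: np.random.Generator | int,
                     shape_family: str = "rectangle",
                     out_dir: str | Path | None = None,
                     file_prefix: str = "stim",
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate ``n`` stimuli and their manifest.

    Returns ``(manifest, images)`` where ``images`` is an ``(n, H, W)``
    uint8 array; if ``out_dir`` is given each image is also written as an
    8-bit grayscale PNG named in the manifest's ``file`` column.  The split
    column partitions rows 7:1:2 into train/val/test.  ``condition`` may be
    ``"solid"``, ``"contour"`` or ``"mixed"`` (fair per-stimulus draw).
    """
    if n < 10:
        raise ValidationError("dataset size must be >= 10")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    seeds = rng.integers(0, 2 ** 31, size=n)
    conditions = (rng.choice(["solid", "contour"], size=n)
                  if condition == "mixed" else np.full(n, condition))
    splits = assign_splits(n)
    images = np.empty((n, constraints.height, constraints.width), dtype=np.uint8)
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i in range(n):
        spec = sample_stimulus(constraints, str(conditions[i]), shape_family,
                               int(seeds[i]))
        img = render(spec)
        images[i] = img.pixels
        fname = f"{file_prefix}_{i:06d}.png"
        rows.append(dict(file=fname, condition=str(conditions[i]),
                         shape_family=shape_family, label=spec.label,
                         split=splits[i], seed=int(seeds[i]),
                         **_geometry_row(spec),
                         lL=spec.luminance.lL, lR=spec.luminance.lR))
        if out_path is not None:
            Image.fromarray(img.pixels, mode="L").save(out_path / fname)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return manifest, images


def spec_from_row(row: pd.Series | dict,
                  constraints: GeometryConstraints) -> StimulusSpec:
    """Rebuild the full stimulus spec from one manifest row (via its seed)."""
    return sample_stimulus(constraints, str(row["condition"]),
                           str(row["shape_family"]), int(row["seed"]))
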